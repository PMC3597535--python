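# Five synthetic pathway topologies used by the power / type-I / path-recovery
# benchmarks.  Node identifiers double as protein identifiers (one protein per
# node).  See docs/methods.md for the design rationale.
pathway_id	edge_id	reactants	products	interaction
catalytic_string	cs_e1	CS1	CS2	activation
catalytic_string	cs_e2	CS2	CS3	activation
catalytic_string	cs_e3	CS3	CS4	activation
catalytic_string	cs_e4	CS4	CS5	activation
inhibitory_string	is_e1	IS1	IS2	inhibition
inhibitory_string	is_e2	IS2	IS3	inhibition
inhibitory_string	is_e3	IS3	IS4	inhibition
inhibitory_string	is_e4	IS4	IS5	inhibition
mixed_string	ms_e1	MS1	MS2	activation
mixed_string	ms_e2	MS2	MS3	inhibition
mixed_string	ms_e3	MS3	MS4	activation
mixed_string	ms_e4	MS4	MS5	inhibition
branched_crossroads	bc_e1	BC3	BC4	activation
branched_crossroads	bc_e2	BC1	BC4	inhibition
branched_crossroads	bc_e3	BC4	BC7	activation
branched_crossroads	bc_e4	BC2	BC5	activation
branched_crossroads	bc_e5	BC5	BC7	activation
branched_crossroads	bc_e6	BC3	BC6	activation
branched_crossroads	bc_e7	BC6	BC8	activation
branched_crossroads	bc_e8	BC6	BC7	activation
long_alternate_route	la_e01	LA01	LA02	activation
long_alternate_route	la_e02	LA02	LA03	activation
long_alternate_route	la_e03	LA03	LA04	activation
long_alternate_route	la_e04	LA01	LA05	activation
long_alternate_route	la_e05	LA05	LA06	activation
long_alternate_route	la_e06	LA06	LA07	activation
long_alternate_route	la_e07	LA07	LA08	activation
long_alternate_route	la_e08	LA08	LA09	activation
long_alternate_route	la_e09	LA09	LA10	inhibition
long_alternate_route	la_e10	LA10	LA11	activation
long_alternate_route	la_e11	LA11	LA12	activation
long_alternate_route	la_e12	LA12	LA13	activation
long_alternate_route	la_e13	LA13	LA14	activation
long_alternate_route	la_e14	LA14	LA04	activation
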