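# Per-protein 'on/off' indicators (d) and the designed differentially
# expressed path for each synthetic pathway.  d = +1 / -1 marks a node built
# around +mu / -mu ('green' / 'red'); d = 0 marks a background ('gray') node
# drawn from the standard normal.  true_path_order is the 1-based position of
# the node on the designed path, 0 for off-path nodes.
pathway_id	protein	d	true_path_order
catalytic_string	CS1	1	1
catalytic_string	CS2	1	2
catalytic_string	CS3	1	3
catalytic_string	CS4	1	4
catalytic_string	CS5	1	5
inhibitory_string	IS1	1	1
inhibitory_string	IS2	-1	2
inhibitory_string	IS3	1	3
inhibitory_string	IS4	-1	4
inhibitory_string	IS5	1	5
mixed_string	MS1	1	1
mixed_string	MS2	1	2
mixed_string	MS3	-1	3
mixed_string	MS4	-1	4
mixed_string	MS5	1	5
branched_crossroads	BC1	0	0
branched_crossroads	BC2	0	0
branched_crossroads	BC3	1	1
branched_crossroads	BC4	1	2
branched_crossroads	BC5	0	0
branched_crossroads	BC6	0	0
branched_crossroads	BC7	1	3
branched_crossroads	BC8	0	0
long_alternate_route	LA01	1	1
long_alternate_route	LA02	1	2
long_alternate_route	LA03	1	3
long_alternate_route	LA04	1	4
long_alternate_route	LA05	0	0
long_alternate_route	LA06	0	0
long_alternate_route	LA07	0	0
long_alternate_route	LA08	0	0
long_alternate_route	LA09	0	0
long_alternate_route	LA10	0	0
long_alternate_route	LA11	0	0
long_alternate_route	LA12	0	0
long_alternate_route	LA13	0	0
long_alternate_route	LA14	0	0
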