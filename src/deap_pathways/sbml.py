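"""Minimal, best-effort SBML import.

Pathway databases frequently distribute their curated pathways as SBML, where
each reaction lists reactant, product and modifier species.  This importer
collapses that representation onto the package's protein-set graph model:

* the reactant species of a reaction form one node, the product species
  another, joined by a catalysis edge;
* each modifier species becomes its own node with an edge onto the products —
  inhibition when the modifier's SBO term marks it as an inhibitor, catalysis
  otherwise.

The import is intentionally lossy (compartments, stoichiometry, kinetics and
annotation semantics are ignored) and every lossy or skipped construct is
logged, never dropped silently.  Level 2 and Level 3 documents are accepted;
the parser matches on local element names so namespace variants do not
matter.
"""

from __future__ import annotations

import logging
from typing import IO

from lxml import etree

from .pathway import (EdgeKind, PathwayEdge, PathwayGraph, PathwayNode,
                      canonical_node_id)

logger = logging.getLogger(__name__)

__all__ = ["import_sbml_minimal", "SbmlImportError"]

# SBO terms that mark a modifier as inhibitory.
_INHIBITOR_SBO = {"SBO:0000020", "SBO:0000206", "SBO:0000597", "SBO:0000536",
                  "SBO:0000537"}


class SbmlImportError(ValueError):
    """Raised when the document is not parseable as SBML at all."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find_children(element, name: str):
    return [child for child in element if _local(child.tag) == name]


def _species_label(species_elem) -> str:
    return species_elem.get("name") or species_elem.get("id") or ""


def import_sbml_minimal(stream: IO[bytes] | IO[str] | str) -> list[PathwayGraph]:
    """Parse an SBML document into pathway graphs (one per model).

    Reactions without mappable reactant or product species are skipped with a
    warning; an empty model yields an empty collection (warned).  Unparseable
    XML raises :class:`SbmlImportError`.
    """
    try:
        if isinstance(stream, str):
            tree = etree.parse(stream)
        else:
            tree = etree.parse(stream)
    except (etree.XMLSyntaxError, OSError) as err:
        raise SbmlImportError(f"cannot parse SBML document: {err}") from err
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SbmlImportError(
            f"root element is <{_local(root.tag)}>, expected <sbml>")

    graphs = []
    for model in _find_children(root, "model"):
        model_id = model.get("id") or model.get("name") or "model"
        species_by_id: dict[str, str] = {}
        for species_list in _find_children(model, "listOfSpecies"):
            for species in _find_children(species_list, "species"):
                sid = species.get("id")
                if sid:
                    species_by_id[sid] = _species_label(species) or sid

        nodes: dict[str, PathwayNode] = {}
        edges: list[PathwayEdge] = []
        seen_edges: set[tuple] = set()

        def node_for(members: frozenset[str]) -> str:
            node_id = canonical_node_id(members)
            nodes.setdefault(node_id, PathwayNode(node_id, members))
            return node_id

        def add_edge(edge_id: str, reactant: str, product: str,
                     kind: EdgeKind) -> None:
            key = (reactant, product, kind)
            if key in seen_edges:
                logger.info("SBML import: collapsing duplicate edge %s", edge_id)
                return
            seen_edges.add(key)
            edges.append(PathwayEdge(edge_id, reactant, product, kind))

        n_reactions = 0
        for reaction_list in _find_children(model, "listOfReactions"):
            for reaction in _find_children(reaction_list, "reaction"):
                n_reactions += 1
                rid = reaction.get("id") or f"reaction{n_reactions}"

                def species_refs(kind_name: str) -> list:
                    refs = []
                    for lst in _find_children(reaction, kind_name):
                        refs.extend(
                            ref for ref in lst
                            if _local(ref.tag).lower().endswith(
                                "speciesreference"))
                    return refs

                def members_of(refs) -> frozenset[str]:
                    labels = set()
                    for ref in refs:
                        sid = ref.get("species")
                        if sid in species_by_id:
                            labels.add(species_by_id[sid])
                        elif sid:
                            logger.warning(
                                "SBML import: reaction %s references unknown "
                                "species %s; keeping identifier", rid, sid)
                            labels.add(sid)
                    return frozenset(labels)

                reactants = members_of(species_refs("listOfReactants"))
                products = members_of(species_refs("listOfProducts"))
                if not reactants or not products:
                    logger.warning(
                        "SBML import: skipping reaction %s (no mappable "
                        "reactants or products)", rid)
                    continue
                add_edge(rid, node_for(reactants), node_for(products),
                         EdgeKind.CATALYSIS)
                for i, ref in enumerate(species_refs("listOfModifiers")):
                    sid = ref.get("species")
                    label = species_by_id.get(sid, sid)
                    if not label:
                        logger.warning(
                            "SBML import: reaction %s has an unmappable "
                            "modifier; skipped", rid)
                        continue
                    sbo = ref.get("sboTerm") or ""
                    kind = (EdgeKind.INHIBITION if sbo in _INHIBITOR_SBO
                            else EdgeKind.CATALYSIS)
                    add_edge(f"{rid}_mod{i + 1}",
                             node_for(frozenset([label])),
                             node_for(products), kind)

        if not edges:
            logger.warning("SBML import: model %s yields no edges; skipped",
                           model_id)
            continue
        graphs.append(PathwayGraph(model_id, nodes.values(), edges))
    if not graphs:
        logger.warning("SBML import: document contained no usable model")
    return graphs
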