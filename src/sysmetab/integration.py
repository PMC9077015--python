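"""Integration of the metabonomics and systems-pharmacology arms.

The two arms produce pathway sets under slightly different free-text naming
conventions, so matching is done on canonicalized names.  Significant
metabolic pathways are partitioned into those that overlap the
systems-pharmacology pathway list and those that do not; the overlapping
pathways are then mapped back ("reverse mapping") through protein→pathway,
compound→protein, and herb→compound relations to the target proteins, the
active compounds that hit them, and the herbs that contain those compounds.
The result is a four-tier herb–compound–protein–pathway network.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "canonicalize_name",
    "overlap_pathways",
    "reverse_map",
    "TripartiteNetwork",
    "export_network",
    "read_network_graphml",
]

_PUNCT = re.compile("[" + re.escape(string.punctuation.replace("/", "")) + "]")
_WS = re.compile(r"\s+")


def canonicalize_name(name: str) -> str:
    """Canonical matching key for a free-text pathway name.

    Case-folded; ``/`` unified with the spelled-out `` or ``; remaining
    punctuation removed; whitespace collapsed.  Stereochemistry prefixes
    (``d-``, ``l-``) survive as plain tokens because hyphen removal applies
    uniformly to both names being compared.
    """
    if not name or not name.strip():
        raise ValueError("empty pathway name")
    key = name.casefold()
    key = key.replace("/", " or ")
    key = _PUNCT.sub(" ", key)
    key = _WS.sub(" ", key).strip()
    return key


def overlap_pathways(
    metab_names: Iterable[str], syspharm_names: Iterable[str]
) -> tuple[list[str], list[str]]:
    """Partition the metabonomics pathway set by membership in the
    systems-pharmacology set.

    Both inputs are free-text names; matching is canonical.  Returns
    ``(overlapping, non_overlapping)`` carrying the original metabonomics
    display names, in input order.
    """
    keys = {canonicalize_name(n) for n in syspharm_names}
    overlapping, non_overlapping = [], []
    for name in metab_names:
        (overlapping if canonicalize_name(name) in keys else non_overlapping).append(
            name
        )
    return overlapping, non_overlapping


@dataclass
class TripartiteNetwork:
    """Typed herb–compound–protein–pathway network with node degrees."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    TIERS = ("herb", "compound", "protein", "pathway")

    def add_node(self, node: str, tier: str) -> None:
        if tier not in self.TIERS:
            raise ValueError(f"unknown tier {tier!r}")
        self.graph.add_node(node, tier=tier)

    def add_edge(self, a: str, b: str) -> None:
        ta, tb = self.graph.nodes[a]["tier"], self.graph.nodes[b]["tier"]
        ia, ib = self.TIERS.index(ta), self.TIERS.index(tb)
        if abs(ia - ib) != 1:
            raise ValueError(f"edge {a!r}–{b!r} joins non-adjacent tiers {ta}/{tb}")
        self.graph.add_edge(a, b)

    def nodes_in_tier(self, tier: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["tier"] == tier}

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def summary(self) -> dict[str, int]:
        return {tier: len(self.nodes_in_tier(tier)) for tier in self.TIERS} | {
            "edges": self.graph.number_of_edges()
        }


def reverse_map(
    overlapping: Iterable[str],
    protein_to_pathways: Mapping[str, set[str]],
    compound_to_proteins: Mapping[str, set[str]],
    herb_to_compounds: Mapping[str, set[str]],
) -> TripartiteNetwork:
    """Reverse-map overlapping pathways to proteins, compounds, and herbs.

    Keeps exactly the proteins annotated to at least one overlapping pathway,
    the compounds hitting at least one kept protein, and the herbs containing
    at least one kept compound; degrees are those of the induced subgraph.
    """
    overlap_keys = {canonicalize_name(n) for n in overlapping}
    net = TripartiteNetwork()
    if not overlap_keys:
        import warnings

        warnings.warn("empty pathway overlap: integration network is empty")
        return net

    display = {canonicalize_name(n): n for n in overlapping}
    kept_proteins: dict[str, set[str]] = {}
    for protein, pathways in protein_to_pathways.items():
        hit = {canonicalize_name(p) for p in pathways} & overlap_keys
        if hit:
            kept_proteins[protein] = hit
    for key in sorted(overlap_keys):
        net.add_node(display[key], tier="pathway")
    for protein in sorted(kept_proteins):
        net.add_node(protein, tier="protein")
        for key in sorted(kept_proteins[protein]):
            net.add_edge(protein, display[key])
    kept_compounds: dict[str, set[str]] = {}
    for compound, proteins in compound_to_proteins.items():
        kept = set(proteins) & set(kept_proteins)
        if kept:
            kept_compounds[compound] = kept
    for compound in sorted(kept_compounds):
        net.add_node(compound, tier="compound")
        for protein in sorted(kept_compounds[compound]):
            net.add_edge(compound, protein)
    for herb in sorted(herb_to_compounds):
        kept = set(herb_to_compounds[herb]) & set(kept_compounds)
        if kept:
            net.add_node(herb, tier="herb")
            for compound in sorted(kept):
                net.add_edge(herb, compound)
    return net


def export_network(net: TripartiteNetwork, path, fmt: str = "sif") -> None:
    """Write the network as Cytoscape-consumable SIF or GraphML.

    SIF lines are ``source<TAB>relation<TAB>target`` with the relation named
    after the tier pair (e.g. ``contains`` for herb–compound).  GraphML nodes
    carry ``tier`` and ``degree`` attributes.
    """
    fmt = fmt.lower()
    if fmt not in {"sif", "graphml"}:
        raise ValueError(f"unsupported format {fmt!r}; supported: sif, graphml")
    if net.graph.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    if fmt == "sif":
        relation = {
            ("herb", "compound"): "contains",
            ("compound", "protein"): "targets",
            ("protein", "pathway"): "participates_in",
        }
        with open(path, "w") as fh:
            for a, b in sorted(net.graph.edges()):
                ta = net.graph.nodes[a]["tier"]
                tb = net.graph.nodes[b]["tier"]
                if (ta, tb) not in relation:
                    a, b, ta, tb = b, a, tb, ta
                fh.write(f"{a}\t{relation[(ta, tb)]}\t{b}\n")
    else:
        g = net.graph.copy()
        for node in g.nodes:
            g.nodes[node]["degree"] = int(net.degree(node))
        nx.write_graphml(g, path)


def read_network_graphml(path) -> TripartiteNetwork:
    g = nx.read_graphml(path)
    net = TripartiteNetwork()
    for node, data in g.nodes(data=True):
        net.add_node(node, tier=data["tier"])
    for a, b in g.edges():
        net.add_edge(a, b)
    return net
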