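"""Pathway library container and its file formats.

A pathway library is a list of pathways, each with a stable id, a display
name, a set of compound (metabolite) members, a set of protein members, and
an undirected edge list over the compound members describing the pathway's
reaction topology.  Membership is serialized in a GMT-like line format and
topology as a two-column edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    compounds: frozenset[str]
    proteins: frozenset[str]
    edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.compounds and not self.proteins:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")
        members = self.compounds
        for a, b in self.edges:
            if a not in members or b not in members:
                raise ValueError(
                    f"edge ({a}, {b}) of {self.pathway_id!r} leaves the "
                    "compound member set"
                )


@dataclass
class PathwayLibrary:
    pathways: list[Pathway] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        from .integration import canonicalize_name

        keys = [canonicalize_name(p.name) for p in self.pathways]
        if len(set(keys)) != len(keys):
            raise ValueError("pathway names collide after canonicalization")

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def by_name(self, name: str) -> Pathway:
        from .integration import canonicalize_name

        key = canonicalize_name(name)
        for p in self.pathways:
            if canonicalize_name(p.name) == key:
                return p
        raise KeyError(name)

    @property
    def compound_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.compounds
        return frozenset(out)

    def protein_to_pathways(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p in self.pathways:
            for prot in p.proteins:
                out.setdefault(prot, set()).add(p.name)
        return out


def write_library(library: PathwayLibrary, members_path, edges_path) -> None:
    """Write membership (GMT-like) and topology (edge list) files.

    Membership lines: ``id<TAB>name<TAB>compound:ID...<TAB>protein:ID...``.
    Edge lines: ``pathway_id<TAB>compound_a<TAB>compound_b``.
    """
    with open(members_path, "w") as fh:
        for p in library:
            cols = [p.pathway_id, p.name]
            cols += [f"compound:{c}" for c in sorted(p.compounds)]
            cols += [f"protein:{t}" for t in sorted(p.proteins)]
            fh.write("\t".join(cols) + "\n")
    with open(edges_path, "w") as fh:
        for p in library:
            for a, b in p.edges:
                fh.write(f"{p.pathway_id}\t{a}\t{b}\n")


def read_library(members_path, edges_path=None, provenance: str = "") -> PathwayLibrary:
    edge_map: dict[str, list[tuple[str, str]]] = {}
    if edges_path is not None and Path(edges_path).exists():
        with open(edges_path) as fh:
            for ln in fh:
                if not ln.strip() or ln.startswith("#"):
                    continue
                pid, a, b = ln.rstrip("\n").split("\t")
                edge_map.setdefault(pid, []).append((a, b))
    pathways = []
    with open(members_path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            cols = ln.rstrip("\n").split("\t")
            pid, name, members = cols[0], cols[1], cols[2:]
            compounds = frozenset(
                m.split(":", 1)[1] for m in members if m.startswith("compound:")
            )
            proteins = frozenset(
                m.split(":", 1)[1] for m in members if m.startswith("protein:")
            )
            pathways.append(
                Pathway(pid, name, compounds, proteins, tuple(edge_map.get(pid, ())))
            )
    return PathwayLibrary(pathways, provenance=provenance)
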