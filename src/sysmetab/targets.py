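"""Target-hit filtering and pathway annotation (systems-pharmacology arm).

Predicted compound–protein hits come from reverse pharmacophore matching as
a per-compound ranked list with a standardized match Z-score.  The screen
keeps, per compound, hits within the top ``top_n`` ranks (default 300) whose
Z-score is at least ``z_min`` (default 0.8, inclusive).  The retained
protein set is then annotated against a pathway library; a literature-mined
list of extra pathway names can be merged in, with each output pathway
tagged by origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .integration import canonicalize_name
from .library import PathwayLibrary

logger = logging.getLogger(__name__)

__all__ = ["TargetHit", "filter_targets", "protein_support", "annotate_pathways"]


@dataclass(frozen=True)
class TargetHit:
    compound_id: str
    protein_id: str
    fit_rank: int
    z_score: float

    def __post_init__(self) -> None:
        if self.fit_rank < 1:
            raise ValueError("fit_rank is 1-based and positive")


def filter_targets(
    hits: Iterable[TargetHit], top_n: int = 300, z_min: float = 0.8
) -> list[TargetHit]:
    """Keep hits with per-compound rank <= top_n and Z-score >= z_min.

    Raises on duplicate (compound, rank) pairs, which indicate a malformed
    ranked list.  Output order is deterministic (compound, rank).
    """
    seen: set[tuple[str, int]] = set()
    kept = []
    for h in hits:
        key = (h.compound_id, h.fit_rank)
        if key in seen:
            raise ValueError(f"duplicate rank {h.fit_rank} for compound {h.compound_id}")
        seen.add(key)
        if h.fit_rank <= top_n and h.z_score >= z_min:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.compound_id, h.fit_rank))


def protein_support(hits: Iterable[TargetHit]) -> pd.DataFrame:
    """Distinct proteins with their supporting-compound counts."""
    support: dict[str, set[str]] = {}
    for h in hits:
        support.setdefault(h.protein_id, set()).add(h.compound_id)
    rows = [
        {"protein_id": p, "n_supporting_compounds": len(cs)}
        for p, cs in sorted(support.items())
    ]
    return pd.DataFrame(rows, columns=["protein_id", "n_supporting_compounds"])


def annotate_pathways(
    proteins: Iterable[str],
    library: PathwayLibrary,
    extra_pathways: Sequence[str] = (),
) -> pd.DataFrame:
    """Annotate a protein set to pathways and merge a literature list.

    Returns one row per pathway with columns ``pathway_id``, ``name``,
    ``origin`` (``annotation``, ``literature``, or ``annotation+literature``
    when both arms name it), and ``n_supporting_proteins``.  Proteins not in
    any library pathway are logged, not raised on.
    """
    proteins = set(proteins)
    rows: dict[str, dict] = {}
    annotated_proteins: set[str] = set()
    for p in library:
        members = proteins & p.proteins
        if members:
            annotated_proteins |= members
            rows[canonicalize_name(p.name)] = {
                "pathway_id": p.pathway_id,
                "name": p.name,
                "origin": "annotation",
                "n_supporting_proteins": len(members),
            }
    unmatched = proteins - annotated_proteins
    if unmatched:
        logger.info("%d proteins matched no library pathway", len(unmatched))
    for name in extra_pathways:
        key = canonicalize_name(name)
        if key in rows:
            rows[key]["origin"] = "annotation+literature"
        else:
            rows[key] = {
                "pathway_id": "",
                "name": name,
                "origin": "literature",
                "n_supporting_proteins": 0,
            }
    return pd.DataFrame(
        list(rows.values()),
        columns=["pathway_id", "name", "origin", "n_supporting_proteins"],
    )
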