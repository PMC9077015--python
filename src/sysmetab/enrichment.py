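"""Metabolite-set over-representation and pathway-topology impact (MetPA style).

For each pathway the record is: the number of query metabolites matched to
its compound members (hits), the pathway size (total), the upper-tail
hypergeometric p-value of observing at least that many hits when drawing
the query from the compound universe, -ln(p), and a topology "impact":
node importances are relative betweenness centralities of the pathway's
compound graph normalized to sum to one, and impact is the summed
importance of the hit nodes.  Pathways are called significant at raw
p < 0.05 and flagged high-impact above 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy import stats as sstats

from .library import Pathway, PathwayLibrary

__all__ = [
    "EnrichmentRow",
    "match_metabolites",
    "ora_pvalue",
    "neg_log",
    "pathway_impact",
    "build_enrichment_table",
]

P_SIGNIFICANT = 0.05
IMPACT_HIGH = 0.1


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    name: str
    hits: int
    total: int
    p_raw: float
    neg_log_p: float
    impact: float
    significant: bool
    high_impact: bool


def match_metabolites(
    query: Iterable[str], library: PathwayLibrary
) -> tuple[dict[str, set[str]], set[str]]:
    """Intersect the query identifier set with each pathway's compounds.

    Returns (per-pathway hit sets keyed by pathway id, unmatched queries).
    Query identifiers should be compound ids (KEGG preferred) matching the
    library's member identifiers.
    """
    query = set(query)
    hit_sets = {p.pathway_id: query & p.compounds for p in library}
    matched: set[str] = set()
    for hs in hit_sets.values():
        matched |= hs
    return hit_sets, query - matched


def ora_pvalue(hits: int, total: int, query_size: int, universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= hits).

    ``universe`` compounds, ``total`` of them in the pathway, ``query_size``
    drawn; X is the number of drawn pathway members.
    """
    if min(hits, total, query_size, universe) < 0:
        raise ValueError("counts must be nonnegative")
    if hits > min(total, query_size) or max(total, query_size) > universe:
        raise ValueError(
            f"inconsistent counts: hits={hits}, total={total}, "
            f"query={query_size}, universe={universe}"
        )
    if hits == 0:
        return 1.0
    return float(sstats.hypergeom.sf(hits - 1, universe, total, query_size))


def neg_log(p: float) -> float:
    """Natural-log enrichment score -ln(p)."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    return -float(np.log(p))


def pathway_impact(hit_nodes: Iterable[str], pathway: Pathway) -> float:
    """Topology impact: summed normalized betweenness of the hit nodes.

    The pathway's compound graph is treated as undirected and simple;
    betweenness is computed per node, normalized so the importances over
    the pathway sum to one.  If every centrality is zero (paths of <= 2
    nodes, complete graphs) the impact is zero by convention.
    """
    hit_nodes = set(hit_nodes)
    missing = hit_nodes - pathway.compounds
    if missing:
        raise ValueError(
            f"hit nodes {sorted(missing)} are not members of {pathway.pathway_id!r}"
        )
    g = nx.Graph()
    g.add_nodes_from(pathway.compounds)
    g.add_edges_from(pathway.edges)
    bc = nx.betweenness_centrality(g, normalized=True)
    denom = sum(bc.values())
    if denom <= 0:
        return 0.0
    return float(sum(bc[n] for n in hit_nodes) / denom)


def build_enrichment_table(
    query: Iterable[str],
    library: PathwayLibrary,
    universe: int | None = None,
) -> list[EnrichmentRow]:
    """Per-pathway enrichment records, sorted by raw p (ties by name).

    Only pathways with at least one hit are reported.  The default universe
    is the number of distinct compounds across the library, mirroring the
    use of the loaded reference library as the background.
    """
    query = set(query)
    if universe is None:
        universe = len(library.compound_universe)
    hit_sets, _ = match_metabolites(query, library)
    rows = []
    for p in library:
        hs = hit_sets[p.pathway_id]
        if not hs:
            continue
        hits, total = len(hs), len(p.compounds)
        q_eff = min(len(query), universe)
        p_raw = ora_pvalue(hits, total, q_eff, universe)
        impact = pathway_impact(hs, p)
        rows.append(
            EnrichmentRow(
                pathway_id=p.pathway_id,
                name=p.name,
                hits=hits,
                total=total,
                p_raw=p_raw,
                neg_log_p=neg_log(p_raw),
                impact=impact,
                significant=p_raw < P_SIGNIFICANT,
                high_impact=impact > IMPACT_HIGH,
            )
        )
    return sorted(rows, key=lambda r: (r.p_raw, r.name))


def enrichment_table(rows: list[EnrichmentRow]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in rows])
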