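"""ADME screening of herbal compounds and the herb–compound network.

Compounds from a multi-herb formula are filtered by four absorption/
distribution descriptors: oral bioavailability OB (percent, keep >= 30),
blood–brain-barrier index BBB (keep > 0.3, strict), drug-likeness DL (keep
>= 0.18), and predicted half-life HL in hours (keep >= 4).  A literature
whitelist can force-retain named (compound, herb) pairs whose descriptors
fall below threshold but whose pharmacological activity is documented —
for example taurine and betaine in Radix Angelicae Sinensis, and six
volatile-oil constituents of Cinnamomi cortex.

Comparisons are exact floating-point comparisons: a compound with BBB equal
to 0.3 is rejected, one with OB equal to 30.0 is retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "ScreenCriteria",
    "Whitelist",
    "DEFAULT_WHITELIST",
    "screen_compounds",
    "merge_duplicate_compounds",
    "build_herb_compound_network",
    "records_from_table",
    "active_table",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One formula compound with its four ADME descriptors.

    ``herbs`` is a set because the same compound can occur in several herbs
    (e.g. sitosterol); duplicate table rows are merged upstream.
    """

    compound_id: str
    name: str
    herbs: frozenset[str]
    ob: float | None
    bbb: float | None
    dl: float | None
    hl: float | None
    pass_reason: str | None = None

    def __post_init__(self) -> None:
        if not self.herbs:
            raise ValueError(f"{self.compound_id}: empty herb set")
        if self.ob is not None and self.ob < 0:
            raise ValueError(f"{self.compound_id}: OB must be >= 0")
        if self.dl is not None and not 0 <= self.dl <= 1:
            raise ValueError(f"{self.compound_id}: DL must lie in [0, 1]")
        if self.hl is not None and self.hl < 0:
            raise ValueError(f"{self.compound_id}: HL must be >= 0")


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds of the four-descriptor screen.

    OB, DL and HL minima are inclusive; the BBB minimum is strict.
    """

    ob_min: float = 30.0
    bbb_min: float = 0.3
    dl_min: float = 0.18
    hl_min: float = 4.0

    def passes(self, r: CompoundRecord) -> bool:
        values = (r.ob, r.bbb, r.dl, r.hl)
        if any(v is None for v in values):
            return False
        return (
            r.ob >= self.ob_min
            and r.bbb > self.bbb_min
            and r.dl >= self.dl_min
            and r.hl >= self.hl_min
        )

    def failure_reasons(self, r: CompoundRecord) -> list[str]:
        reasons = []
        for label, value in zip(("OB", "BBB", "DL", "HL"), (r.ob, r.bbb, r.dl, r.hl)):
            if value is None:
                reasons.append(f"{label} missing")
        if reasons:
            return reasons
        if r.ob < self.ob_min:
            reasons.append(f"OB {r.ob} < {self.ob_min}")
        if not r.bbb > self.bbb_min:
            reasons.append(f"BBB {r.bbb} <= {self.bbb_min}")
        if r.dl < self.dl_min:
            reasons.append(f"DL {r.dl} < {self.dl_min}")
        if r.hl < self.hl_min:
            reasons.append(f"HL {r.hl} < {self.hl_min}")
        return reasons


@dataclass(frozen=True)
class Whitelist:
    """Literature-justified (compound name, herb, citation note) entries that
    bypass the descriptor screen."""

    entries: frozenset[tuple[str, str, str]] = frozenset()

    def matches(self, record: CompoundRecord) -> bool:
        name = record.name.casefold()
        for entry_name, herb, _note in self.entries:
            if entry_name.casefold() == name and herb in record.herbs:
                return True
        return False

    @classmethod
    def from_file(cls, path) -> "Whitelist":
        entries = set()
        with open(path) as fh:
            for ln in fh:
                if not ln.strip() or ln.startswith("#"):
                    continue
                name, herb, *note = ln.rstrip("\n").split("\t")
                entries.add((name, herb, note[0] if note else ""))
        return cls(frozenset(entries))


#: Default literature whitelist: two osmolytes in Radix Angelicae Sinensis
#: (DG) and six volatile-oil constituents of Cinnamomi cortex (RG).
DEFAULT_WHITELIST = Whitelist(
    frozenset(
        {
            ("taurine", "DG", "documented pharmacological component"),
            ("betaine", "DG", "documented pharmacological component"),
            ("cinnamaldehyde", "RG", "volatile-oil constituent, low DL"),
            ("styrone", "RG", "volatile-oil constituent, low DL"),
            ("(l)-alpha-terpineol", "RG", "volatile-oil constituent, low DL"),
            ("(-)-caryophyllene oxide", "RG", "volatile-oil constituent, low DL"),
            ("(Z)-caryophyllene", "RG", "volatile-oil constituent, low DL"),
            ("[(1S)-endo]-(-)-borneol", "RG", "volatile-oil constituent, low DL"),
        }
    )
)


def merge_duplicate_compounds(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """Merge records sharing a compound id into one record with a herb set."""
    merged: dict[str, CompoundRecord] = {}
    for r in records:
        if r.compound_id in merged:
            prev = merged[r.compound_id]
            merged[r.compound_id] = replace(prev, herbs=prev.herbs | r.herbs)
        else:
            merged[r.compound_id] = r
    return list(merged.values())


def screen_compounds(
    records: Iterable[CompoundRecord],
    criteria: ScreenCriteria = ScreenCriteria(),
    whitelist: Whitelist = Whitelist(),
) -> list[CompoundRecord]:
    """Apply the four-descriptor screen with whitelist override.

    Returns retained records annotated with ``pass_reason`` equal to
    ``"screen"`` or ``"whitelist"``.  Records with missing descriptor values
    are rejected (with a logged reason), never raised on.
    """
    retained = []
    for r in records:
        if criteria.passes(r):
            retained.append(replace(r, pass_reason="screen"))
        elif whitelist.matches(r):
            retained.append(replace(r, pass_reason="whitelist"))
        else:
            logger.debug(
                "rejected %s (%s): %s",
                r.compound_id,
                r.name,
                "; ".join(criteria.failure_reasons(r)),
            )
    return retained


def build_herb_compound_network(
    active: Iterable[CompoundRecord], expected_herbs: Iterable[str] | None = None
) -> tuple[nx.Graph, dict[str, int]]:
    """Bipartite herb–compound network over the retained set.

    One node per compound even when it occurs in several herbs; its degree
    is the number of herbs containing it.  Returns the graph and per-herb
    retained-compound counts.  Herbs listed in ``expected_herbs`` but absent
    from the retained set get a zero count and a warning (e.g. a herb with
    no database coverage contributes no compounds).
    """
    g = nx.Graph()
    counts: dict[str, int] = {h: 0 for h in (expected_herbs or ())}
    for r in active:
        g.add_node(r.compound_id, bipartite="compound", name=r.name)
        for herb in r.herbs:
            g.add_node(herb, bipartite="herb")
            g.add_edge(herb, r.compound_id)
            counts[herb] = counts.get(herb, 0) + 1
    for herb, n in counts.items():
        if n == 0:
            warnings.warn(f"herb {herb!r} retained no compounds")
    return g, counts


def records_from_table(table: pd.DataFrame) -> list[CompoundRecord]:
    """Build merged records from a long-format compound table.

    Expected columns: compound_id, name, herb, OB, BBB, DL, HL (one row per
    compound-herb occurrence).
    """
    cols = {c.lower(): c for c in table.columns}
    records = []
    for _, row in table.iterrows():
        def val(key: str):
            v = row[cols[key]]
            return None if pd.isna(v) else float(v)

        records.append(
            CompoundRecord(
                compound_id=str(row[cols["compound_id"]]),
                name=str(row[cols["name"]]),
                herbs=frozenset({str(row[cols["herb"]])}),
                ob=val("ob"),
                bbb=val("bbb"),
                dl=val("dl"),
                hl=val("hl"),
            )
        )
    return merge_duplicate_compounds(records)


def active_table(active: Iterable[CompoundRecord]) -> pd.DataFrame:
    """Tabular view of a retained set (one row per compound)."""
    rows = [
        {
            "compound_id": r.compound_id,
            "name": r.name,
            "herbs": ";".join(sorted(r.herbs)),
            "OB": r.ob,
            "BBB": r.bbb,
            "DL": r.dl,
            "HL": r.hl,
            "pass_reason": r.pass_reason,
        }
        for r in active
    ]
    return pd.DataFrame(
        rows,
        columns=["compound_id", "name", "herbs", "OB", "BBB", "DL", "HL", "pass_reason"],
    )
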