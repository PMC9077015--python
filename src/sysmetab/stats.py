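"""Univariate group comparison of metabolite levels.

Per metabolite: a one-way ANOVA across all groups, followed by the two
pairwise contrasts of interest (disease model vs. control, treated vs.
model) tested with pooled-variance t statistics on the ANOVA's
within-group mean square.  P-values are Bonferroni-adjusted over the whole
family (all metabolites x both contrasts — the most conservative family),
and significance stars are assigned from the adjusted p.  Welch's t-test
is available as an alternative pairwise engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["ComparisonRow", "compare_groups", "comparison_table"]

_STAR_CUTS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p_adj: float) -> str:
    for cut, label in _STAR_CUTS:
        if p_adj < cut:
            return label
    return "ns"


@dataclass(frozen=True)
class ComparisonRow:
    metabolite: str
    contrast: str
    direction: str  # up / down / none
    p_anova: float
    p_raw: float
    p_adj: float
    stars: str


def _pooled_t(a: np.ndarray, b: np.ndarray, ms_within: float, df_within: int) -> float:
    se = np.sqrt(ms_within * (1 / len(a) + 1 / len(b)))
    if se == 0:
        return 0.0
    t = (a.mean() - b.mean()) / se
    return 2 * sstats.t.sf(abs(t), df_within)


def compare_groups(
    levels: pd.DataFrame,
    groups: pd.Series,
    contrasts: tuple[tuple[str, str], ...] = (("model", "control"), ("treated", "model")),
    engine: str = "anova",
) -> list[ComparisonRow]:
    """Compare group means per metabolite with multiplicity correction.

    ``levels``: samples x metabolites; ``groups``: per-sample labels.
    ``contrasts``: ordered (case, reference) label pairs; direction reports
    the sign of case minus reference means.  ``engine``: ``"anova"``
    (pooled-variance pairwise t on the ANOVA mean square) or ``"welch"``.
    """
    if engine not in {"anova", "welch"}:
        raise ValueError(f"unknown engine {engine!r}")
    labels = list(dict.fromkeys(groups))
    by_group = {g: levels.loc[groups == g] for g in labels}
    for g, sub in by_group.items():
        if len(sub) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    m_family = levels.shape[1] * len(contrasts)
    rows: list[ComparisonRow] = []
    for metab in levels.columns:
        samples = [by_group[g][metab].to_numpy(dtype=float) for g in labels]
        grand = np.concatenate(samples)
        n_total = len(grand)
        df_within = n_total - len(labels)
        ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        if ss_within == 0:
            warnings.warn(f"{metab}: zero within-group variance; exact-tie p = 0")
            p_anova = 0.0
            ms_within = 0.0
        else:
            p_anova = float(sstats.f_oneway(*samples).pvalue)
            ms_within = ss_within / df_within
        for case, ref in contrasts:
            a = by_group[case][metab].to_numpy(dtype=float)
            b = by_group[ref][metab].to_numpy(dtype=float)
            diff = a.mean() - b.mean()
            if ss_within == 0:
                p_raw = 0.0 if diff != 0 else 1.0
            elif engine == "welch":
                p_raw = float(sstats.ttest_ind(a, b, equal_var=False).pvalue)
            else:
                p_raw = float(_pooled_t(a, b, ms_within, df_within))
            p_adj = min(1.0, m_family * p_raw)
            direction = "none"
            if p_adj < 0.05 and diff != 0:
                direction = "up" if diff > 0 else "down"
            rows.append(
                ComparisonRow(
                    metabolite=str(metab),
                    contrast=f"{case}_vs_{ref}",
                    direction=direction,
                    p_anova=p_anova,
                    p_raw=p_raw,
                    p_adj=p_adj,
                    stars=_stars(p_adj),
                )
            )
    return rows


def comparison_table(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Wide per-metabolite report with one arrow+stars column per contrast."""
    long = pd.DataFrame([r.__dict__ for r in rows])
    arrow = {"up": "↑", "down": "↓", "none": "—"}
    long["annotation"] = long.apply(
        lambda r: arrow[r.direction] + (r.stars if r.stars != "ns" else ""), axis=1
    )
    wide = long.pivot(index="metabolite", columns="contrast", values="annotation")
    wide.columns.name = None
    return wide.reset_index()
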