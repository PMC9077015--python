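"""Optional figure exports: coefficient plots and enrichment bubble plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .chemometrics import CorrelationLoadings
from .enrichment import EnrichmentRow

__all__ = ["coefficient_plot", "bubble_plot"]


def coefficient_plot(loadings: CorrelationLoadings, path) -> None:
    """Back-scaled covariance vs ppm, colored by |r| (threshold marked)."""
    ppm = np.asarray(loadings.ppm, dtype=float)
    order = np.argsort(ppm)
    fig, ax = plt.subplots(figsize=(10, 4))
    pts = ax.scatter(
        ppm[order],
        loadings.covariance[order],
        c=np.abs(loadings.r[order]),
        cmap="coolwarm",
        vmin=0,
        vmax=1,
        s=6,
    )
    fig.colorbar(pts, ax=ax, label="|r|")
    ax.invert_xaxis()
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel("covariance with predictive scores")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_title(f"|r| threshold = {loadings.threshold:.3f} (n = {loadings.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def bubble_plot(rows: list[EnrichmentRow], path) -> None:
    """-log(p) vs topology impact, bubble size proportional to impact."""
    fig, ax = plt.subplots(figsize=(6, 5))
    impact = np.array([r.impact for r in rows])
    nlp = np.array([r.neg_log_p for r in rows])
    ax.scatter(impact, nlp, s=40 + 400 * impact, c=nlp, cmap="Reds", edgecolor="k", lw=0.5)
    for r in rows:
        if r.significant:
            ax.annotate(r.name, (r.impact, r.neg_log_p), fontsize=7)
    ax.set_xlabel("pathway impact")
    ax.set_ylabel("-ln(p)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
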