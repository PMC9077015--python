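"""Pipeline-wide configuration with the published analysis defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """Every stage parameter in one serializable record.

    Defaults are the analysis settings used throughout: the four ADME
    thresholds, the per-compound target filter (top 300, Z >= 0.8), the
    0.004-ppm bucketing of delta 0.5–8.5 with the water window delta
    4.7–5.2 excluded, alpha = 0.05 with the correlation threshold derived
    from the per-group sample size, enrichment cutoffs p < 0.05 and
    impact > 0.1, and 7-fold cross-validation.
    """

    seed: int = 0
    # screening
    ob_min: float = 30.0
    bbb_min: float = 0.3
    dl_min: float = 0.18
    hl_min: float = 4.0
    # target filter
    top_n: int = 300
    z_min: float = 0.8
    # bucketing
    bucket_width: float = 0.004
    region: tuple[float, float] = (0.5, 8.5)
    exclusions: tuple[tuple[float, float], ...] = ((4.7, 5.2),)
    # multivariate
    n_orth: int = 1
    scaling: str = "uv"
    cv_folds: int = 7
    alpha: float = 0.05
    threshold_n: int | None = None  # None: per-group n of the design
    # enrichment / integration
    p_cut: float = 0.05
    impact_cut: float = 0.1
    # synthetic-mode knobs
    n_per_group: int = 8
    fold_change: float = 2.0
    noise_cv: float = 0.1
    planted_overlap_names: tuple[str, ...] = (
        "Glycolysis/gluconeogenesis",
        "Arginine and proline metabolism",
    )
    contrasts: tuple[tuple[str, str], ...] = field(
        default_factory=lambda: (("model", "control"), ("treated", "model"))
    )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**{k: v for k, v in raw.items()})
        # YAML has no tuple type; restore the nested tuples
        cfg.region = tuple(cfg.region)
        cfg.exclusions = tuple(tuple(e) for e in cfg.exclusions)
        cfg.planted_overlap_names = tuple(cfg.planted_overlap_names)
        cfg.contrasts = tuple(tuple(c) for c in cfg.contrasts)
        return cfg
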