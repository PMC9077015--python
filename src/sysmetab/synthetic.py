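"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all driven by one :class:`SyntheticConfig`:

* :func:`generate_compound_table` — per-herb compound tables whose ADME
  descriptors straddle the four screening thresholds, with a planted set of
  actives that pass all four and all other compounds failing at least one;
* :func:`generate_target_and_pathway_library` — Z-scored target hits for
  the planted actives plus a small pathway library in which designated
  "overlap" pathways contain both proteins hit by actives and metabolites
  carrying planted spectral effects;
* :func:`generate_spectra` — three-group serum-like 1H spectra built from
  Lorentzian multiplets at the serum panel's chemical shifts, with
  group-specific concentration effects, a smooth baseline, a broad residual
  water hump confined to delta 4.7–5.2, per-spectrum dilution, and
  multiplicative concentration noise.

The spectral model is deliberately frequency-domain only: no FID
simulation, phasing, or J-coupling physics — multiplets are fixed line
templates with a 1.5 Hz (0.003 ppm at 500 MHz) Lorentzian linewidth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .nmr import BucketSpec, Spectrum, bucket_centers
from .reference import load_biomarker_annotations, load_biomarker_panel

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SERUM_TEMPLATE",
    "default_effect_table",
    "metabolite_windows",
    "template_bucket_map",
    "generate_compound_table",
    "generate_target_and_pathway_library",
    "generate_spectra",
]

# line patterns: tuples of (ppm offset from multiplet center, relative area);
# areas within a pattern sum to 1.  J splittings fixed at 7 Hz = 0.014 ppm.
PATTERNS: dict[str, tuple[tuple[float, float], ...]] = {
    "s": ((0.0, 1.0),),
    "d": ((-0.007, 0.5), (0.007, 0.5)),
    "t": ((-0.014, 0.25), (0.0, 0.5), (0.014, 0.25)),
    "dd": ((-0.0105, 0.25), (-0.0035, 0.25), (0.0035, 0.25), (0.0105, 0.25)),
    "m": ((-0.014, 0.15), (-0.007, 0.2), (0.0, 0.3), (0.007, 0.2), (0.014, 0.15)),
    # lopsided envelope used where a symmetric multiplet would sit on top of
    # a neighbouring singlet (e.g. glutamate next to methionine)
    "mr": ((0.0, 0.34), (0.007, 0.33), (0.014, 0.33)),
}

#: Half-width at half-maximum of every line: 1.5 Hz at 500 MHz.
LINEWIDTH_HWHM = 0.0015


@dataclass(frozen=True)
class MetaboliteTemplate:
    name: str
    peaks: tuple[tuple[float, str, float], ...]  # (center ppm, pattern, area weight)
    base: float  # control-group concentration, arbitrary units

    def lines(self) -> list[tuple[float, float]]:
        """All (ppm, unit-concentration area) lines of this metabolite."""
        out = []
        for center, pattern, weight in self.peaks:
            for off, rel in PATTERNS[pattern]:
                out.append((center + off, weight * rel))
        return out


def _t(name, peaks, base):
    return MetaboliteTemplate(name, tuple(peaks), base)


#: Serum template: multiplet positions follow the serum biomarker panel;
#: base concentrations are serum-realistic relative magnitudes (glucose and
#: lactate large, aromatic amino acids small).
SERUM_TEMPLATE: dict[str, MetaboliteTemplate] = {
    m.name: m
    for m in [
        _t("HDL", [(0.84, "m", 1.0)], 1.0),
        _t("Lipids", [(0.89, "m", 0.6), (1.29, "m", 0.4)], 3.0),
        _t("Leucine", [(0.95, "d", 1.0)], 1.0),
        _t("Valine", [(0.97, "d", 0.5), (1.02, "d", 0.5)], 0.8),
        _t("Lactate", [(1.33, "d", 0.75), (4.11, "t", 0.25)], 4.0),
        _t("Alanine", [(1.48, "d", 1.0)], 1.2),
        _t("Arginine", [(1.68, "m", 1.0)], 0.7),
        _t("Acetate", [(1.91, "s", 1.0)], 0.8),
        _t("N-Acetyl glycoprotein", [(2.04, "s", 1.0)], 1.5),
        _t("Methionine", [(2.13, "s", 1.0)], 0.5),
        _t("Glutamate", [(2.14, "mr", 1.0)], 0.8),
        _t("Glutamine", [(2.41, "m", 1.0)], 0.9),
        _t("Creatine", [(3.04, "s", 1.0)], 0.8),
        _t("Taurine", [(3.25, "t", 0.5), (3.41, "t", 0.5)], 0.9),
        _t("Threonine", [(3.56, "dd", 1.0)], 0.6),
        _t("Myo-inositol", [(3.63, "dd", 1.0)], 0.7),
        _t("Glycerol", [(3.64, "dd", 0.5), (3.87, "m", 0.5)], 0.8),
        _t("TMAO/Betaine", [(3.27, "s", 1.0)], 0.9),
        _t("Tyrosine", [(6.87, "m", 0.5), (7.17, "m", 0.5)], 0.5),
        _t("beta-Glucose", [(4.64, "d", 1.0)], 3.0),
    ]
}

DEFAULT_FOLD = 2.0


def default_effect_table(fold: float = DEFAULT_FOLD) -> dict[str, tuple[str, str, float]]:
    """Effect table from the bundled serum panel directions.

    Maps metabolite -> (direction model-vs-control, direction
    treated-vs-model, fold change applied per significant direction).
    """
    panel = load_biomarker_panel()
    out = {}
    for _, row in panel.iterrows():
        out[row["metabolite"]] = (
            row["dir_model_vs_control"],
            row["dir_treated_vs_model"],
            fold,
        )
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Shared configuration of the three generators.

    The defaults are the study conditions emulated throughout: nine herbs
    with database coverage, three groups of eight animals, two-fold planted
    concentration effects in the panel's reported directions, 10% biological
    coefficient of variation.
    """

    seed: int = 0
    n_herbs: int = 9
    n_compounds_per_herb: int = 8
    n_planted_active: int = 12
    n_pathways: int = 8
    planted_overlap_names: tuple[str, ...] = (
        "Glycolysis/gluconeogenesis",
        "Arginine and proline metabolism",
    )
    groups: tuple[str, ...] = ("control", "model", "treated")
    n_per_group: int = 8
    effect_table: Mapping[str, tuple[str, str, float]] = field(
        default_factory=default_effect_table
    )
    noise_cv: float = 0.1
    ppm_step: float = 0.0005
    ppm_range: tuple[float, float] = (0.2, 9.0)

    def __post_init__(self) -> None:
        if min(self.n_herbs, self.n_compounds_per_herb, self.n_per_group) <= 0:
            raise ValueError("counts must be positive")
        if self.n_pathways <= 0:
            raise ValueError("n_pathways must be positive")
        if self.n_planted_active > self.n_herbs * self.n_compounds_per_herb:
            raise ValueError("more planted actives than compounds")
        if self.n_planted_active < 0 or self.noise_cv < 0:
            raise ValueError("n_planted_active and noise_cv must be >= 0")
        for name, (d1, d2, fold) in self.effect_table.items():
            if name not in SERUM_TEMPLATE:
                raise KeyError(f"unknown metabolite {name!r} in effect_table")
            if d1 not in {"up", "down", "none"} or d2 not in {"up", "down", "none"}:
                raise ValueError(f"{name}: directions must be up/down/none")
            if fold <= 0:
                raise ValueError(f"{name}: fold change must be positive")
        if len(self.planted_overlap_names) > self.n_pathways:
            raise ValueError("more planted overlap pathways than pathways")

    def herb_codes(self) -> list[str]:
        return [f"H{i + 1:02d}" for i in range(self.n_herbs)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class GroundTruth:
    """What the generators planted, for recovery tests."""

    active_compound_ids: frozenset[str] = frozenset()
    herb_of_compound: dict[str, str] = field(default_factory=dict)
    target_proteins: frozenset[str] = frozenset()
    overlap_pathway_names: tuple[str, ...] = ()
    discriminative_metabolites: frozenset[str] = frozenset()
    group_means: pd.DataFrame | None = None  # metabolite x group concentrations

    def discriminative_windows(self) -> dict[str, list[tuple[float, float]]]:
        return {
            name: metabolite_windows(name)
            for name in sorted(self.discriminative_metabolites)
        }

    def discriminative_bucket_indices(self, spec: BucketSpec = BucketSpec()) -> set[int]:
        centers = bucket_centers(spec)
        out: set[int] = set()
        for windows in self.discriminative_windows().values():
            for lo, hi in windows:
                out |= set(np.flatnonzero((centers >= lo) & (centers <= hi)).tolist())
        return out


def metabolite_windows(name: str, halfwidth: float = 0.006) -> list[tuple[float, float]]:
    """Per-line ppm windows annotating a template metabolite's buckets."""
    lines = SERUM_TEMPLATE[name].lines()
    windows = sorted((ppm - halfwidth, ppm + halfwidth) for ppm, _ in lines)
    merged: list[tuple[float, float]] = []
    for lo, hi in windows:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    return merged


def template_bucket_map() -> dict[str, list[tuple[float, float]]]:
    """Bucket-annotation map for every template metabolite."""
    return {name: metabolite_windows(name) for name in SERUM_TEMPLATE}


# ---------------------------------------------------------------------------
# compound tables


def generate_compound_table(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-herb compound table with planted screen-passing actives.

    Planted actives pass all four descriptor thresholds; every other
    compound fails at least one (drawn to straddle the thresholds).
    """
    rng = config.rng(1)
    herbs = config.herb_codes()
    total = config.n_herbs * config.n_compounds_per_herb
    active_idx = set(rng.choice(total, size=config.n_planted_active, replace=False).tolist())

    rows = []
    herb_of: dict[str, str] = {}
    actives: set[str] = set()
    for i in range(total):
        herb = herbs[i // config.n_compounds_per_herb]
        cid = f"C{i + 1:04d}"
        herb_of[cid] = herb
        ob = rng.uniform(30.0, 90.0)
        bbb = rng.uniform(0.35, 2.0)
        dl = rng.uniform(0.18, 0.95)
        hl = rng.uniform(4.0, 24.0)
        if i in active_idx:
            actives.add(cid)
        else:
            n_fail = int(rng.integers(1, 5))
            fail = rng.choice(4, size=n_fail, replace=False)
            if 0 in fail:
                ob = rng.uniform(2.0, 29.9)
            if 1 in fail:
                bbb = rng.uniform(-0.3, 0.295)
            if 2 in fail:
                dl = rng.uniform(0.01, 0.175)
            if 3 in fail:
                hl = rng.uniform(0.3, 3.9)
        rows.append(
            {
                "compound_id": cid,
                "name": f"compound-{i + 1:04d}",
                "herb": herb,
                "OB": round(ob, 3),
                "BBB": round(bbb, 4),
                "DL": round(dl, 4),
                "HL": round(hl, 3),
            }
        )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        active_compound_ids=frozenset(actives),
        herb_of_compound=herb_of,
    )
    return table, truth


# ---------------------------------------------------------------------------
# target hits and pathway library


def _discriminative_metabolites(config: SyntheticConfig) -> list[str]:
    return [
        name
        for name, (d1, _d2, _f) in config.effect_table.items()
        if d1 != "none"
    ]


def _annotated_kegg_ids(names: list[str]) -> dict[str, str]:
    """KEGG ids for annotatable metabolites (lipid-class entries have none)."""
    ann = load_biomarker_annotations()
    lookup = dict(zip(ann["query"].str.casefold(), ann["kegg"]))
    out = {}
    for name in names:
        key = name.casefold()
        if key == "tmao/betaine":
            out["TMAO"] = lookup["tmao"]
            out["Betaine"] = lookup["betaine"]
        elif key == "beta-glucose":
            out[name] = lookup["beta-glucose"]
        elif key in lookup:
            out[name] = lookup[key]
    return out


def generate_target_and_pathway_library(
    config: SyntheticConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, "PathwayLibrary", GroundTruth]:
    """Target-hit table and pathway library with planted overlap structure.

    Every planted active receives at least one retained hit (rank <= 300,
    Z >= 0.8) on a protein annotated to a planted overlap pathway, plus
    decoy hits that the rank/Z filter must remove.  Overlap pathways carry
    both those proteins and KEGG ids of discriminative metabolites; decoy
    pathways carry neither.
    """
    from .library import Pathway, PathwayLibrary

    if not truth.active_compound_ids:
        raise ValueError("ground truth carries no active compounds; generate the compound table first")
    rng = config.rng(2)
    actives = sorted(truth.active_compound_ids)
    n_overlap = len(config.planted_overlap_names)

    kegg = _annotated_kegg_ids(_discriminative_metabolites(config))
    disc_ids = sorted(kegg.values())
    if len(disc_ids) < 2 * max(1, n_overlap):
        raise ValueError("too few annotatable discriminative metabolites for the requested overlap pathways")

    n_prot = min(max(4, 2 * n_overlap), len(actives)) if actives else 0
    proteins = [f"P{i + 1:03d}" for i in range(n_prot)]
    decoy_proteins = [f"D{i + 1:03d}" for i in range(6)]

    # retained hit per active on an overlap protein, then decoy hits that
    # fail the rank or Z criterion
    hit_rows = []
    for j, cid in enumerate(actives):
        protein = proteins[j % n_prot]
        hit_rows.append(
            {
                "compound_id": cid,
                "protein_id": protein,
                "fit_rank": int(rng.integers(1, 50)),
                "z_score": round(float(rng.uniform(0.8, 3.0)), 4),
            }
        )
        used = {hit_rows[-1]["fit_rank"]}
        for decoy in rng.choice(decoy_proteins, size=2, replace=False):
            if rng.random() < 0.5:
                rank = int(rng.integers(301, 400))
                z = round(float(rng.uniform(0.8, 2.0)), 4)
            else:
                rank = int(rng.integers(50, 300))
                while rank in used:
                    rank = int(rng.integers(50, 300))
                z = round(float(rng.uniform(-0.5, 0.79)), 4)
            used.add(rank)
            hit_rows.append(
                {
                    "compound_id": cid,
                    "protein_id": str(decoy),
                    "fit_rank": rank,
                    "z_score": z,
                }
            )
    hits = pd.DataFrame(hit_rows)

    # overlap pathways: discriminative compound members (round-robin) plus
    # the overlap proteins; decoys: filler compounds, decoy proteins
    pathways = []
    per = max(2, len(disc_ids) // max(1, n_overlap))
    filler = iter(f"C9{i:04d}" for i in range(10_000))
    for k in range(config.n_pathways):
        pid = f"path{k + 1:03d}"
        if k < n_overlap:
            members = [disc_ids[(k * per + j) % len(disc_ids)] for j in range(per)]
            members = list(dict.fromkeys(members)) + [next(filler), next(filler)]
            prots = frozenset(proteins[k::n_overlap]) or frozenset(proteins)
            name = config.planted_overlap_names[k]
        else:
            members = [next(filler) for _ in range(6)]
            prots = frozenset(rng.choice(decoy_proteins, size=2, replace=False).tolist())
            name = f"Decoy pathway {k + 1 - n_overlap:02d}"
        edges = tuple((members[i], members[i + 1]) for i in range(len(members) - 1))
        pathways.append(Pathway(pid, name, frozenset(members), prots, edges))
    library = PathwayLibrary(pathways, provenance=f"synthetic(seed={config.seed})")

    enriched = GroundTruth(
        active_compound_ids=truth.active_compound_ids,
        herb_of_compound=truth.herb_of_compound,
        target_proteins=frozenset(proteins),
        overlap_pathway_names=tuple(config.planted_overlap_names),
        discriminative_metabolites=frozenset(_discriminative_metabolites(config)),
        group_means=truth.group_means,
    )
    return hits, library, enriched


# ---------------------------------------------------------------------------
# spectra


def _group_concentrations(config: SyntheticConfig) -> pd.DataFrame:
    conc = {}
    step = {"up": +1.0, "down": -1.0, "none": 0.0}
    for name, tmpl in SERUM_TEMPLATE.items():
        d1, d2, fold = config.effect_table.get(name, ("none", "none", 1.0))
        control = tmpl.base
        model = control * fold ** step[d1]
        treated = model * fold ** step[d2]
        conc[name] = {"control": control, "model": model, "treated": treated}
    frame = pd.DataFrame(conc).T
    return frame[[g for g in ("control", "model", "treated") if g in frame.columns]]


def _template_matrix(ppm: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Unit-concentration spectra of every template metabolite (columns)."""
    names = list(SERUM_TEMPLATE)
    M = np.zeros((ppm.size, len(names)))
    g = LINEWIDTH_HWHM
    for j, name in enumerate(names):
        for center, area in SERUM_TEMPLATE[name].lines():
            lo, hi = center - 0.25, center + 0.25  # 167 half-widths: tail cut
            sl = slice(*np.searchsorted(ppm, (lo, hi)))
            x = ppm[sl] - center
            M[sl, j] += area * (g / np.pi) / (x * x + g * g)
    return M, names


def _baseline(ppm: np.ndarray) -> np.ndarray:
    u = (ppm - ppm.min()) / (ppm.max() - ppm.min())
    return 2.0 + 3.0 * u * (1 - u)


def _water_hump(ppm: np.ndarray, amplitude: float) -> np.ndarray:
    hump = amplitude * np.exp(-0.5 * ((ppm - 4.95) / 0.08) ** 2)
    hump[(ppm < 4.72) | (ppm > 5.18)] = 0.0  # confined to the excluded window
    return hump


def generate_spectra(
    config: SyntheticConfig,
) -> tuple[list[Spectrum], GroundTruth]:
    """Serum-like labeled spectra for every animal, plus ground truth.

    Per sample: metabolite concentrations are the group means times
    independent log-normal factors with coefficient of variation
    ``noise_cv``; the whole spectrum is scaled by a log-normal dilution
    factor (same CV), shifted by a small random axis misalignment (undone
    by calibration), and perturbed by an additive noise floor.  With
    ``noise_cv = 0`` every spectrum in a group is identical.
    """
    rng = config.rng(3)
    lo, hi = config.ppm_range
    ppm = np.arange(lo, hi + config.ppm_step / 2, config.ppm_step)
    M, names = _template_matrix(ppm)
    means = _group_concentrations(config)

    peak_height = float(
        max(
            SERUM_TEMPLATE[n].base * max(a for _, a in SERUM_TEMPLATE[n].lines())
            for n in names
        )
        / (np.pi * LINEWIDTH_HWHM)
    )
    baseline = _baseline(ppm)
    hump = _water_hump(ppm, 10.0 * peak_height)
    cv = config.noise_cv
    sigma = np.sqrt(np.log1p(cv * cv))

    spectra = []
    for group in config.groups:
        if group not in means.columns:
            raise ValueError(f"group {group!r} has no planted concentrations")
        mu = means[group].reindex(names).to_numpy()
        for i in range(config.n_per_group):
            if cv > 0:
                factors = rng.lognormal(-sigma * sigma / 2, sigma, size=len(names))
                dilution = rng.lognormal(-sigma * sigma / 2, sigma)
                shift = rng.uniform(-0.008, 0.008)
                noise = rng.normal(0.0, 0.1 * cv * peak_height, size=ppm.size)
            else:
                factors, dilution, shift, noise = 1.0, 1.0, 0.0, 0.0
            intensity = dilution * (M @ (mu * factors) + baseline + hump) + noise
            spectra.append(
                Spectrum(
                    ppm + shift,
                    np.clip(intensity, 0.0, None),
                    sample_id=f"{group}-{i + 1:02d}",
                    group=group,
                )
            )
    truth = GroundTruth(
        discriminative_metabolites=frozenset(_discriminative_metabolites(config)),
        group_means=means,
    )
    return spectra, truth
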