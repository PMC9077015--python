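"""1H-NMR spectral preprocessing: calibration, bucketing, normalization.

Spectra arrive as (ppm, intensity) series on a strictly descending chemical
shift axis (NMR display convention).  Preprocessing is

1. chemical shift calibration — a reference doublet (lactate CH3, delta
   1.33) is located near its nominal position and the axis is shifted so
   the doublet midpoint lands exactly on target;
2. bucketing — the analysis region (default delta 0.5–8.5) is tiled with
   fixed-width buckets (default 0.004 ppm, anchored at the region's low
   edge, left-closed/right-open); buckets intersecting an exclusion window
   (default the residual-water region delta 4.7–5.2) are dropped whole;
   each bucket value is the trapezoidal integral of intensity over the
   bucket interval on the native grid (no resampling);
3. normalization — each sample's bucket vector is divided by its own total,
   removing dilution differences; row totals are retained for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BucketSpec",
    "BucketMatrix",
    "CalibrationError",
    "calibrate",
    "bucket",
    "bucket_centers",
    "normalize",
    "bucket_samples",
]


class CalibrationError(RuntimeError):
    pass


@dataclass
class Spectrum:
    """One sample's spectrum on a strictly descending ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be equal-length 1-D arrays")
        d = np.diff(self.ppm)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if np.all(d > 0):  # store descending
            self.ppm = self.ppm[::-1]
            self.intensity = self.intensity[::-1]
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def shifted(self, delta: float) -> "Spectrum":
        return Spectrum(self.ppm + delta, self.intensity, self.sample_id, self.group)


@dataclass(frozen=True)
class BucketSpec:
    """Bucketing parameters (defaults are the serum-metabonomics settings)."""

    width: float = 0.004
    region: tuple[float, float] = (0.5, 8.5)
    exclusions: tuple[tuple[float, float], ...] = ((4.7, 5.2),)
    reference: tuple[str, float] = ("lactate doublet", 1.33)
    search_halfwidth: float = 0.1

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bucket width must be positive")
        lo, hi = self.region
        if not lo < hi:
            raise ValueError("region must be (low, high) with low < high")
        for a, b in self.exclusions:
            if not (lo <= a < b <= hi):
                raise ValueError("exclusions must lie inside the region")

    def edges(self) -> np.ndarray:
        """All bucket edges, ascending, anchored at the region low edge."""
        lo, hi = self.region
        n = int(np.floor((hi - lo) / self.width + 1e-9))
        return lo + self.width * np.arange(n + 1)

    def retained_mask(self) -> np.ndarray:
        """Boolean mask over buckets: True where no exclusion is touched."""
        edges = self.edges()
        left, right = edges[:-1], edges[1:]
        mask = np.ones(left.shape, dtype=bool)
        eps = 1e-6 * self.width  # guard against float error at shared edges
        for a, b in self.exclusions:
            mask &= ~((left < b - eps) & (right > a + eps))
        return mask


def bucket_centers(spec: BucketSpec) -> np.ndarray:
    edges = spec.edges()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers[spec.retained_mask()]


def _local_maxima(y: np.ndarray) -> np.ndarray:
    return np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1


def calibrate(spectrum: Spectrum, spec: BucketSpec = BucketSpec()) -> tuple[Spectrum, float]:
    """Shift the axis so the reference doublet midpoint sits on target.

    The doublet is detected as the two highest local maxima within
    ``search_halfwidth`` of the nominal position; its center is their
    midpoint.  Returns the shifted spectrum and the applied shift.
    """
    _, target = spec.reference
    win = (spectrum.ppm >= target - spec.search_halfwidth) & (
        spectrum.ppm <= target + spec.search_halfwidth
    )
    idx = np.flatnonzero(win)
    if idx.size < 5:
        raise CalibrationError(
            f"{spectrum.sample_id or 'spectrum'}: no data near delta {target}"
        )
    y = spectrum.intensity[idx]
    peaks = _local_maxima(y)
    if peaks.size < 2:
        raise CalibrationError(
            f"{spectrum.sample_id or 'spectrum'}: reference doublet not found "
            f"within {spec.search_halfwidth} ppm of delta {target}"
        )
    top2 = peaks[np.argsort(y[peaks])[-2:]]
    center = float(spectrum.ppm[idx[top2]].mean())
    shift = target - center
    return spectrum.shifted(shift), shift


def _integrate_buckets(spectrum: Spectrum, spec: BucketSpec) -> np.ndarray:
    """Trapezoidal integral of the linear interpolant over every bucket."""
    lo, hi = spec.region
    ppm = spectrum.ppm[::-1]  # ascending
    inten = spectrum.intensity[::-1]
    if ppm[0] > lo + 1e-12 or ppm[-1] < hi - 1e-12:
        raise ValueError(
            f"spectrum covers [{ppm[0]:.3f}, {ppm[-1]:.3f}] but the bucket "
            f"region is [{lo}, {hi}]"
        )
    edges = spec.edges()
    # refine the grid with the bucket edges so each bucket integral is the
    # exact trapezoid of the piecewise-linear interpolant (additive by
    # construction)
    grid = np.union1d(ppm, edges)
    grid = grid[(grid >= edges[0]) & (grid <= edges[-1])]
    vals = np.interp(grid, ppm, inten)
    seg = 0.5 * (vals[1:] + vals[:-1]) * np.diff(grid)
    # per-bucket local sums: a bucket's value depends only on intensity
    # inside its own interval (no global accumulation error)
    pos = np.searchsorted(grid, edges)
    return np.add.reduceat(seg, pos[:-1])


def bucket(spectrum: Spectrum, spec: BucketSpec = BucketSpec()) -> np.ndarray:
    """Raw bucket vector over the retained (non-excluded) buckets."""
    return _integrate_buckets(spectrum, spec)[spec.retained_mask()]


@dataclass
class BucketMatrix:
    """Samples x buckets matrix of normalized integrals with group labels."""

    values: pd.DataFrame  # index: sample ids, columns: bucket-center ppm
    groups: pd.Series  # per-sample group label
    totals: pd.Series = field(default=None)  # pre-normalization row totals

    @property
    def ppm(self) -> np.ndarray:
        return self.values.columns.to_numpy(dtype=float)

    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def class_vector(self, group_a: str, group_b: str) -> "BucketMatrix":
        """Two-group subset (for discriminant modeling)."""
        keep = self.groups.isin([group_a, group_b])
        return BucketMatrix(
            self.values.loc[keep],
            self.groups.loc[keep],
            None if self.totals is None else self.totals.loc[keep],
        )


def normalize(raw: pd.DataFrame, groups: pd.Series) -> BucketMatrix:
    """Total-sum normalization: each row divided by its own total."""
    totals = raw.sum(axis=1)
    bad = totals[totals <= 0]
    if len(bad):
        raise ValueError(
            "nonpositive total integral for sample(s): " + ", ".join(map(str, bad.index))
        )
    values = raw.div(totals, axis=0)
    return BucketMatrix(values, groups.loc[raw.index], totals)


def bucket_samples(
    spectra: Iterable[Spectrum],
    spec: BucketSpec = BucketSpec(),
    calibrate_first: bool = True,
) -> BucketMatrix:
    """Calibrate, bucket, and normalize a set of labeled spectra."""
    centers = bucket_centers(spec)
    rows, ids, groups = [], [], []
    for s in spectra:
        if calibrate_first:
            s, _ = calibrate(s, spec)
        rows.append(bucket(s, spec))
        ids.append(s.sample_id)
        groups.append(s.group)
    raw = pd.DataFrame(np.vstack(rows), index=ids, columns=np.round(centers, 4))
    return normalize(raw, pd.Series(groups, index=ids))
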