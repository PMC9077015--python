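"""Multivariate modeling of bucket matrices: PCA and OPLS-DA.

Both models follow a Model/Results split: construct the model from data,
call :meth:`fit`, and read estimates and diagnostics off the returned
results object.

PCA is the unsupervised check for inherent clustering.  OPLS-DA is the
supervised workhorse: it splits the (scaled) bucket matrix into one
class-predictive component and ``n_orth`` orthogonal components, so that
between-class variation is concentrated in a single score vector t.  Model
quality is summarized by R2X (modeled fraction of X variation), R2Y
(explained class variation) and Q2 (cross-validated predictive fraction,
1 - PRESS/SS over held-out predictions).

Biomarker selection uses correlation loadings: per bucket, the Pearson
correlation r between the predictive scores and the bucket's values.  A
bucket is a candidate when |r| exceeds the critical value of the Pearson
correlation at the chosen two-tailed level for the design's per-group
sample size (n = 8 gives 0.707 at alpha = 0.05); candidates are lifted to
metabolite calls by majority vote over each metabolite's annotated buckets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .nmr import BucketMatrix

__all__ = [
    "ScalingSpec",
    "PCAModel",
    "PCAResults",
    "OPLSDA",
    "OPLSDAResults",
    "CorrelationLoadings",
    "critical_r",
    "select_biomarkers",
]


@dataclass(frozen=True)
class ScalingSpec:
    """Column-wise centering/scaling applied before modeling.

    ``scaling``: ``"uv"`` (unit variance, the SIMCA-style default),
    ``"pareto"`` (square-root of the standard deviation, common for NMR),
    or ``"none"``.
    """

    centering: bool = True
    scaling: str = "uv"

    def __post_init__(self) -> None:
        if self.scaling not in {"uv", "pareto", "none"}:
            raise ValueError(f"unknown scaling {self.scaling!r}")

    def fit(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        center = X.mean(axis=0) if self.centering else np.zeros(X.shape[1])
        sd = X.std(axis=0, ddof=1)
        if self.scaling == "uv":
            scale = sd.copy()
        elif self.scaling == "pareto":
            scale = np.sqrt(sd)
        else:
            scale = np.ones(X.shape[1])
        zero = scale <= 0
        if zero.any():
            scale = np.where(zero, 1.0, scale)
        return (X - center) / scale, center, scale

    def apply(self, X: np.ndarray, center: np.ndarray, scale: np.ndarray) -> np.ndarray:
        return (X - center) / scale


def _as_matrix(data) -> tuple[np.ndarray, np.ndarray | None, pd.Series | None]:
    if isinstance(data, BucketMatrix):
        return data.X(), data.ppm, data.groups
    return np.asarray(data, dtype=float), None, None


def _fix_sign(loading: np.ndarray) -> float:
    """Sign convention: the largest-|value| loading element is positive."""
    i = int(np.argmax(np.abs(loading)))
    return 1.0 if loading[i] >= 0 else -1.0


# ---------------------------------------------------------------------------
# PCA


class PCAModel:
    """Principal component analysis of a bucket matrix (via SVD)."""

    def __init__(self, data, n_components: int = 2, scaling: ScalingSpec = ScalingSpec()):
        self.X, self.ppm, self.groups = _as_matrix(data)
        n, m = self.X.shape
        if n_components > min(n - 1, m):
            raise ValueError(
                f"n_components={n_components} exceeds min(n-1, m)={min(n - 1, m)}"
            )
        self.n_components = n_components
        self.scaling = scaling

    def fit(self) -> "PCAResults":
        Xs, center, scale = self.scaling.fit(self.X)
        ss_total = float((Xs**2).sum())
        if ss_total <= 0:
            raise ValueError("matrix has zero variance after scaling")
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        k = self.n_components
        scores = U[:, :k] * s[:k]
        loadings = Vt[:k].T
        for j in range(k):
            sgn = _fix_sign(loadings[:, j])
            loadings[:, j] *= sgn
            scores[:, j] *= sgn
        r2x = (s[:k] ** 2) / ss_total
        return PCAResults(
            scores=scores,
            loadings=loadings,
            r2x=r2x,
            center=center,
            scale=scale,
            model=self,
        )


@dataclass
class PCAResults:
    scores: np.ndarray
    loadings: np.ndarray
    r2x: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    model: PCAModel

    @property
    def r2x_cum(self) -> np.ndarray:
        return np.cumsum(self.r2x)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.r2x) + 1),
                "R2X": self.r2x,
                "R2X_cum": self.r2x_cum,
            }
        )


# ---------------------------------------------------------------------------
# OPLS-DA


class OPLSDA:
    """Two-class orthogonal PLS discriminant analysis.

    ``y`` is the binary class vector (1 = case, 0 = reference), centered
    internally.  Alternatively build from a labeled :class:`BucketMatrix`
    with :meth:`from_bucket_matrix`.
    """

    def __init__(
        self,
        X,
        y: Sequence[int],
        n_orth: int = 1,
        scaling: ScalingSpec = ScalingSpec(),
    ):
        self.X, self.ppm, _ = _as_matrix(X)
        self.y = np.asarray(y, dtype=float)
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of samples")
        classes = np.unique(self.y)
        if classes.size != 2:
            raise ValueError("OPLS-DA needs exactly two classes present in y")
        if n_orth < 0:
            raise ValueError("n_orth must be >= 0")
        if n_orth > min(self.X.shape) - 2:
            raise ValueError(
                f"n_orth={n_orth} too large for a {self.X.shape} matrix"
            )
        self.n_orth = n_orth
        self.scaling = scaling

    @classmethod
    def from_bucket_matrix(
        cls,
        matrix: BucketMatrix,
        case_group: str,
        reference_group: str,
        n_orth: int = 1,
        scaling: ScalingSpec = ScalingSpec(),
    ) -> "OPLSDA":
        sub = matrix.class_vector(case_group, reference_group)
        y = (sub.groups == case_group).astype(int).to_numpy()
        model = cls(sub.X(), y, n_orth=n_orth, scaling=scaling)
        model.ppm = sub.ppm
        model._groups = sub.groups
        return model

    # -- core decomposition -------------------------------------------------

    @staticmethod
    def _decompose(Xs: np.ndarray, yc: np.ndarray, n_orth: int) -> dict:
        w = Xs.T @ yc
        norm = float(np.linalg.norm(w))
        if norm <= 0:
            raise ValueError("degenerate y/X covariance")
        w = w / norm
        Xw = Xs.copy()
        W_o, P_o, T_o = [], [], []
        for _ in range(n_orth):
            t = Xw @ w
            p = Xw.T @ t / float(t @ t)
            w_o = p - float(w @ p) * w
            n_o = float(np.linalg.norm(w_o))
            if n_o < 1e-12:
                raise ValueError("orthogonal component rank exhausted")
            w_o /= n_o
            t_o = Xw @ w_o
            p_o = Xw.T @ t_o / float(t_o @ t_o)
            Xw = Xw - np.outer(t_o, p_o)
            W_o.append(w_o)
            P_o.append(p_o)
            T_o.append(t_o)
        t = Xw @ w
        p = Xw.T @ t / float(t @ t)
        q = float(yc @ t) / float(t @ t)
        return {
            "w": w,
            "t": t,
            "p": p,
            "q": q,
            "W_o": np.array(W_o).T if W_o else np.zeros((Xs.shape[1], 0)),
            "P_o": np.array(P_o).T if P_o else np.zeros((Xs.shape[1], 0)),
            "T_o": np.array(T_o).T if T_o else np.zeros((Xs.shape[0], 0)),
        }

    def fit(self) -> "OPLSDAResults":
        Xs, center, scale = self.scaling.fit(self.X)
        yc = self.y - self.y.mean()
        d = self._decompose(Xs, yc, self.n_orth)
        # sign convention on the predictive loading
        sgn = _fix_sign(d["p"])
        for key in ("w", "t", "p"):
            d[key] = d[key] * sgn
        d["q"] = d["q"] * sgn
        ss_x = float((Xs**2).sum())
        ss_y = float(yc @ yc)
        t, p = d["t"], d["p"]
        r2x_pred = float(t @ t) * float(p @ p) / ss_x
        r2x_orth = np.array(
            [
                float(d["T_o"][:, i] @ d["T_o"][:, i])
                * float(d["P_o"][:, i] @ d["P_o"][:, i])
                / ss_x
                for i in range(self.n_orth)
            ]
        )
        resid = yc - d["q"] * t
        r2y = 1.0 - float(resid @ resid) / ss_y
        return OPLSDAResults(
            weights=d["w"],
            scores=t,
            loadings=p,
            q=d["q"],
            orth_weights=d["W_o"],
            orth_loadings=d["P_o"],
            orth_scores=d["T_o"],
            r2x_pred=r2x_pred,
            r2x_orth=r2x_orth,
            r2y=r2y,
            center=center,
            scale=scale,
            y_mean=float(self.y.mean()),
            model=self,
        )


@dataclass
class OPLSDAResults:
    weights: np.ndarray
    scores: np.ndarray  # predictive scores t
    loadings: np.ndarray  # predictive loadings p
    q: float  # y-loading of the predictive component
    orth_weights: np.ndarray
    orth_loadings: np.ndarray
    orth_scores: np.ndarray
    r2x_pred: float
    r2x_orth: np.ndarray
    r2y: float
    center: np.ndarray
    scale: np.ndarray
    y_mean: float
    model: OPLSDA
    q2: float | None = field(default=None)

    @property
    def r2x(self) -> float:
        return self.r2x_pred + float(self.r2x_orth.sum())

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Continuous class prediction for new samples (same variables)."""
        Xs = self.model.scaling.apply(np.asarray(X_new, float), self.center, self.scale)
        for i in range(self.orth_weights.shape[1]):
            t_o = Xs @ self.orth_weights[:, i]
            Xs = Xs - np.outer(t_o, self.orth_loadings[:, i])
        t = Xs @ self.weights
        return self.q * t + self.y_mean

    def cross_validate(self, folds: int = 7, seed: int = 0) -> float:
        """K-fold cross-validated Q2 = 1 - PRESS/SS; stores it on the results.

        Fold assignment is round-robin over a seeded shuffle of the sample
        order.  Every training split must contain both classes.
        """
        model = self.model
        n = model.X.shape[0]
        if folds < 2 or folds > n:
            raise ValueError("folds must lie in [2, n_samples]")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        assignment = np.empty(n, dtype=int)
        assignment[order] = np.arange(n) % folds
        press = 0.0
        y = model.y
        yc_ss = float(((y - y.mean()) ** 2).sum())
        for k in range(folds):
            test = assignment == k
            train = ~test
            if np.unique(y[train]).size < 2:
                raise ValueError(f"fold {k}: training split lost a class")
            sub = OPLSDA(
                model.X[train], y[train], n_orth=model.n_orth, scaling=model.scaling
            )
            res = sub.fit()
            y_hat = res.predict(model.X[test])
            press += float(((y[test] - y_hat) ** 2).sum())
        self.q2 = 1.0 - press / yc_ss
        return self.q2

    def correlation_loadings(self, threshold_n: int | None = None, alpha: float = 0.05):
        """Per-bucket correlation/covariance with the predictive scores.

        ``threshold_n`` is the sample size used for the critical |r|; it
        defaults to half the modeled samples (the per-group n of a balanced
        two-class design), matching the reporting convention for these
        coefficient plots.
        """
        # orient by the class coding so positive covariance always means
        # "higher in the case (y = 1) group", independent of the loading
        # sign convention
        t = self.scores * (1.0 if self.q >= 0 else -1.0)
        X = self.model.X
        n = X.shape[0]
        if threshold_n is None:
            threshold_n = n // 2
        tc = t - t.mean()
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ tc / (n - 1)
        sd_x = Xc.std(axis=0, ddof=1)
        sd_t = tc.std(ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / (sd_x * sd_t)
        const = sd_x <= 0
        if const.any():
            warnings.warn(f"{int(const.sum())} constant buckets: r set to 0")
            r = np.where(const, 0.0, r)
        return CorrelationLoadings(
            ppm=self.model.ppm,
            r=r,
            covariance=cov,
            threshold=critical_r(threshold_n, alpha),
            n=threshold_n,
        )

    def summary(self) -> pd.DataFrame:
        rows = {
            "n_samples": self.model.X.shape[0],
            "n_buckets": self.model.X.shape[1],
            "n_orth": self.model.n_orth,
            "R2X": self.r2x,
            "R2X_pred": self.r2x_pred,
            "R2Y": self.r2y,
            "Q2": self.q2 if self.q2 is not None else np.nan,
        }
        return pd.DataFrame({"statistic": list(rows), "value": list(rows.values())})


@dataclass
class CorrelationLoadings:
    """Per-bucket correlation loadings of an OPLS-DA predictive component."""

    ppm: np.ndarray | None
    r: np.ndarray
    covariance: np.ndarray
    threshold: float
    n: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ppm": self.ppm if self.ppm is not None else np.arange(len(self.r)),
                "r": self.r,
                "covariance": self.covariance,
                "selected": np.abs(self.r) >= self.threshold,
            }
        )


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Critical |r| of the Pearson correlation, two-tailed, df = n - 2.

    Inverts the t transform r*sqrt(df/(1-r^2)) ~ t(df):
    r* = t*/sqrt(t*^2 + df).  n = 8 at alpha = 0.05 gives 0.707.
    """
    if n < 3:
        raise ValueError("need n >= 3 for a correlation threshold")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    df = n - 2
    t_star = sstats.t.ppf(1 - alpha / 2, df)
    return float(t_star / np.sqrt(t_star**2 + df))


def select_biomarkers(
    loadings: CorrelationLoadings,
    bucket_map: Mapping[str, Sequence[tuple[float, float]]],
) -> pd.DataFrame:
    """Lift bucket-level |r| calls to metabolite-level biomarker calls.

    ``bucket_map`` assigns each metabolite a list of (low, high) ppm windows.
    A metabolite is called when a strict majority of its annotated buckets
    pass |r| >= threshold; its direction is the sign of the mean covariance
    over its passing buckets.  Passing buckets outside every window are
    reported as ``unassigned`` rows, one per bucket.
    """
    ppm = np.asarray(loadings.ppm, dtype=float)
    passed = np.abs(loadings.r) >= loadings.threshold
    assigned = np.zeros(ppm.shape, dtype=bool)
    rows = []
    for name, windows in bucket_map.items():
        in_win = np.zeros(ppm.shape, dtype=bool)
        for lo, hi in windows:
            in_win |= (ppm >= lo) & (ppm <= hi)
        assigned |= in_win
        n_buckets = int(in_win.sum())
        if n_buckets == 0:
            continue
        n_pass = int((in_win & passed).sum())
        if n_pass * 2 > n_buckets:
            mean_cov = float(loadings.covariance[in_win & passed].mean())
            rows.append(
                {
                    "metabolite": name,
                    "delta": ";".join(f"{lo:.2f}-{hi:.2f}" for lo, hi in windows),
                    "direction": "up" if mean_cov > 0 else "down",
                    "n_buckets": n_buckets,
                    "n_selected": n_pass,
                    "max_abs_r": float(np.abs(loadings.r[in_win]).max()),
                }
            )
    for i in np.flatnonzero(passed & ~assigned):
        rows.append(
            {
                "metabolite": "unassigned",
                "delta": f"{ppm[i]:.3f}",
                "direction": "up" if loadings.covariance[i] > 0 else "down",
                "n_buckets": 1,
                "n_selected": 1,
                "max_abs_r": float(abs(loadings.r[i])),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["metabolite", "delta", "direction", "n_buckets", "n_selected", "max_abs_r"],
    )
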