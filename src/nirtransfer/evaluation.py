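"""Model evaluation metrics and Passing-Bablok method comparison.

Metrics follow standard NIR practice: R^2 is the squared Pearson correlation
between predictions and reference values, RMSE the root mean squared error
(RMSEC on the calibration set, RMSEP on the prediction set), and RPD the
ratio of the reference values' standard deviation to the RMSE (> 2 is
conventionally a useful model).  SEL, the standard error of laboratory, is
the replicate-based noise floor of the reference method:

    SEL = sqrt( sum_samples sum_reps (y_r - ybar)^2 / N ),   N = n samples.

Passing-Bablok regression compares two measurement methods without assuming
an error-free x; the joint null hypothesis (slope = 1, intercept = 0) is
accepted when the slope CI contains 1 and the intercept CI contains 0, and
is used here to pick the master instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectra import ReplicateTable

__all__ = [
    "EvaluationReport",
    "PassingBablokResult",
    "evaluate",
    "sel",
    "passing_bablok",
    "choose_master",
]


@dataclass
class EvaluationReport:
    label: str
    n: int
    r2: float
    rmse: float
    rpd: float  # inf when rmse == 0

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "r2": self.r2,
            "rmse": self.rmse,
            "rpd": self.rpd,
        }

    def __str__(self) -> str:
        rpd = "inf" if np.isinf(self.rpd) else f"{self.rpd:.3f}"
        return (
            f"{self.label}: n={self.n}  R2={self.r2:.3f}  "
            f"RMSE={self.rmse:.3f}%  RPD={rpd}"
        )


def evaluate(predictions, reference, set_label: str = "") -> EvaluationReport:
    """R^2 (squared Pearson), RMSE and RPD of predictions on a named set."""
    yhat = np.asarray(predictions, dtype=float).ravel()
    y = np.asarray(reference, dtype=float).ravel()
    if yhat.size != y.size:
        raise ValueError("predictions and reference have different lengths")
    if y.size < 2:
        raise ValueError("need at least 2 samples to evaluate")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance reference values")
    rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
    if np.ptp(yhat) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(yhat, y)[0, 1] ** 2)
    sd = float(np.std(y, ddof=1))
    rpd = float(sd / rmse) if rmse > 0 else float("inf")
    return EvaluationReport(label=set_label, n=y.size, r2=r2, rmse=rmse, rpd=rpd)


def sel(replicates: ReplicateTable) -> float:
    """Standard error of laboratory from repeated reference measurements.

    Rows with fewer than two finite replicates are excluded with a warning;
    N in the formula counts the rows actually used.
    """
    V = replicates.values
    finite = np.isfinite(V)
    usable = finite.sum(axis=1) >= 2
    if not usable.any():
        raise ValueError("no sample has >= 2 finite replicates")
    if not usable.all():
        dropped = [replicates.sample_ids[i] for i in np.nonzero(~usable)[0]]
        warnings.warn(f"excluding {len(dropped)} sample(s) with <2 replicates: {dropped[:5]}")
    V = V[usable]
    finite = finite[usable]
    means = np.nanmean(np.where(finite, V, np.nan), axis=1, keepdims=True)
    dev2 = np.where(finite, (V - means) ** 2, 0.0)
    return float(np.sqrt(dev2.sum() / V.shape[0]))


@dataclass
class PassingBablokResult:
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    n_slopes: int  # valid pairwise slopes after exclusions
    k_offset: int  # number of slopes < -1 (the 1983 shift)
    h0_accepted: bool


def _median(values: np.ndarray) -> float:
    return float(np.median(values))


def passing_bablok(x, y, confidence: float = 0.95) -> PassingBablokResult:
    """Passing-Bablok (1983) regression of method y against method x.

    All pairwise slopes S_ij = (y_j - y_i)/(x_j - x_i) are formed (pairs with
    x_i = x_j skipped, slopes exactly -1 excluded); the slope estimate is the
    median shifted by K = #{S < -1}, with a rank-based CI using the normal
    approximation Var = n(n-1)(2n+5)/18.  The intercept is
    median(y - slope*x) with CI endpoints from the slope CI bounds.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y have different lengths")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if n < 10:
        warnings.warn("Passing-Bablok with fewer than 10 points is unreliable")
    if np.ptp(x) == 0:
        raise ValueError("all x values identical: slope undefined")

    iu, ju = np.triu_indices(n, k=1)
    dx = x[ju] - x[iu]
    dy = y[ju] - y[iu]
    keep = dx != 0
    S = dy[keep] / dx[keep]
    S = S[S != -1.0]
    S.sort()
    N = S.size
    if N == 0:
        raise ValueError("no valid pairwise slopes")
    K = int(np.count_nonzero(S < -1.0))

    if N % 2 == 1:
        slope = float(S[np.clip((N - 1) // 2 + K, 0, N - 1)])
    else:
        lo = np.clip(N // 2 - 1 + K, 0, N - 1)
        hi = np.clip(N // 2 + K, 0, N - 1)
        slope = float(0.5 * (S[lo] + S[hi]))

    from scipy.stats import norm

    z = norm.ppf(0.5 + confidence / 2.0)
    w = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    M1 = int(np.floor((N - w) / 2.0))  # 1-indexed lower rank
    M2 = N - M1 + 1
    lo_idx = np.clip(M1 + K - 1, 0, N - 1)
    hi_idx = np.clip(M2 + K - 1, 0, N - 1)
    slope_lo = float(S[lo_idx])
    slope_hi = float(S[hi_idx])

    intercept = _median(y - slope * x)
    int_lo = _median(y - slope_hi * x)
    int_hi = _median(y - slope_lo * x)
    if int_lo > int_hi:
        int_lo, int_hi = int_hi, int_lo

    h0 = (slope_lo <= 1.0 <= slope_hi) and (int_lo <= 0.0 <= int_hi)
    return PassingBablokResult(
        slope=slope,
        slope_ci=(slope_lo, slope_hi),
        intercept=intercept,
        intercept_ci=(int_lo, int_hi),
        n_slopes=N,
        k_offset=K,
        h0_accepted=h0,
    )


def choose_master(results: dict[str, PassingBablokResult]) -> str | None:
    """Pick the instrument whose H0 (agreement with the reference) is
    accepted; among several, the slope closest to 1 wins (first on ties).
    Returns None when no instrument is acceptable."""
    if not results:
        raise ValueError("no instruments to compare")
    accepted = [(label, r) for label, r in results.items() if r.h0_accepted]
    if not accepted:
        return None
    best_label, _ = min(accepted, key=lambda item: abs(item[1].slope - 1.0))
    return best_label
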