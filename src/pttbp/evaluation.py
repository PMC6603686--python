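"""Agreement metrics for BP estimators: MAD/STD/MSE, AAMI compliance, BHS
grading, Pearson r-squared and Bland–Altman limits of agreement.

AAMI acceptability requires a mean absolute error of at most 5 mmHg with a
residual standard deviation of at most 8 mmHg. The BHS grade is determined
by the percentage of absolute errors within 5, 10 and 15 mmHg; all three
columns must meet a grade's thresholds (A: 60/85/95, B: 50/75/90,
C: 40/65/85). Some published comparison tables instead use C as a
catch-all lowest category; ``mode='floor_c'`` reproduces that convention,
while the default ``'strict'`` grades such rows as a failure.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EvalReport",
    "error_stats",
    "aami_check",
    "cumulative_error_pct",
    "bhs_grade",
    "pearson_r2",
    "bland_altman",
    "evaluate",
]

BHS_THRESHOLDS = {"A": (60.0, 85.0, 95.0), "B": (50.0, 75.0, 90.0), "C": (40.0, 65.0, 85.0)}


@dataclass
class EvalReport:
    """Summary of one estimator's test-set agreement with reference BP."""

    mad: float
    std: float
    mse: float
    r2: float
    pct_within_5: float
    pct_within_10: float
    pct_within_15: float
    bhs: str
    aami_pass: bool
    ba_mean_diff: float
    ba_lower: float
    ba_upper: float
    ba_fraction_within: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def error_stats(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float]:
    """(MAD, STD, MSE) of the residuals: mean absolute deviation, sample
    (n-1) standard deviation, and mean squared error, all in mmHg (mmHg^2
    for MSE)."""
    y, yhat = _paired(y, yhat)
    resid = y - yhat
    mad = float(np.mean(np.abs(resid)))
    std = float(np.std(resid, ddof=1)) if resid.size > 1 else 0.0
    mse = float(np.mean(resid**2))
    return mad, std, mse


def aami_check(mad: float, std: float) -> bool:
    """AAMI criterion: mean error <= 5 mmHg and STD <= 8 mmHg (inclusive)."""
    if mad < 0 or std < 0:
        raise ValueError("mad and std must be nonnegative")
    return mad <= 5.0 and std <= 8.0


def cumulative_error_pct(
    errors: np.ndarray, thresholds: tuple[float, ...] = (5.0, 10.0, 15.0)
) -> tuple[float, ...]:
    """Percentage of absolute errors within each threshold (inclusive)."""
    e = np.abs(np.asarray(errors, dtype=float))
    if e.size == 0:
        raise ValueError("empty error vector")
    return tuple(float(np.mean(e <= t) * 100.0) for t in thresholds)


def bhs_grade(pct5: float, pct10: float, pct15: float, mode: str = "strict") -> str:
    """BHS grade from the three cumulative-error percentages.

    A grade requires all three thresholds simultaneously. ``mode='strict'``
    returns ``'fail'`` below grade C; ``mode='floor_c'`` treats C as the
    lowest category, as some published comparison tables do.
    """
    for pct in (pct5, pct10, pct15):
        if not 0 <= pct <= 100:
            raise ValueError("percentages must lie in [0, 100]")
    for grade, (t5, t10, t15) in BHS_THRESHOLDS.items():
        if pct5 >= t5 and pct10 >= t10 and pct15 >= t15:
            return grade
    if mode == "floor_c":
        return "C"
    if mode == "strict":
        return "fail"
    raise ValueError(f"unknown BHS mode {mode!r}")


def pearson_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Squared Pearson correlation between reference and predicted BP."""
    y, yhat = _paired(y, yhat)
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("constant vector: correlation undefined")
    r = stats.pearsonr(y, yhat).statistic
    return float(r * r)


def bland_altman(
    y: np.ndarray, yhat: np.ndarray
) -> tuple[float, tuple[float, float], float]:
    """Bland–Altman agreement of d = yhat - y.

    Returns the mean difference, the (lower, upper) 95% limits of agreement
    ``dbar +/- 1.96 * SD(d)`` and the fraction of differences within the
    limits. Identical vectors give zero-width limits (flagged by lower ==
    upper).
    """
    y, yhat = _paired(y, yhat)
    if y.size < 3:
        raise ValueError("need at least 3 pairs")
    d = yhat - y
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lower, upper = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= lower) & (d <= upper)))
    return mean, (lower, upper), within


def evaluate(y: np.ndarray, yhat: np.ndarray, bhs_mode: str = "strict") -> EvalReport:
    """Full agreement report for one estimator on one target."""
    y, yhat = _paired(y, yhat)
    mad, std, mse = error_stats(y, yhat)
    p5, p10, p15 = cumulative_error_pct(y - yhat)
    mean_d, (lo, hi), within = bland_altman(y, yhat)
    return EvalReport(
        mad=mad, std=std, mse=mse,
        r2=pearson_r2(y, yhat),
        pct_within_5=p5, pct_within_10=p10, pct_within_15=p15,
        bhs=bhs_grade(p5, p10, p15, mode=bhs_mode),
        aami_pass=aami_check(mad, std),
        ba_mean_diff=mean_d, ba_lower=lo, ba_upper=hi, ba_fraction_within=within,
        n=int(y.size),
    )


def _paired(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size == 0:
        raise ValueError("empty vectors")
    return y, yhat
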