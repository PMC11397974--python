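"""Goodness-of-fit metrics for paired measured/predicted sequences.

Implements the evaluation quantities reported per subject and device band:
mean squared error, coefficient of determination R², the normalised-RMSE
"% fit" convention from system identification,

    fit% = 100 * (1 - ||y - yhat|| / ||y - ybar||),

and a paired two-sided test on the per-session differences.  R² may be
negative for fits worse than the mean predictor and is reported as computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = ["MetricReport", "mse", "r2", "fit_percent", "paired_pvalue", "evaluate"]


def _paired(y, y_hat, min_n: int = 1):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise InvalidArgumentError(
            f"length mismatch: y has {y.size} elements, y_hat has {y_hat.size}"
        )
    if y.size < min_n:
        raise InvalidArgumentError(f"need at least {min_n} paired observations, got {y.size}")
    return y, y_hat


def mse(y, y_hat) -> float:
    """Mean squared error (1/n) * sum (y_i - yhat_i)^2."""
    y, y_hat = _paired(y, y_hat, min_n=1)
    return float(np.mean((y - y_hat) ** 2))


def r2(y, y_hat) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; negative if worse than mean."""
    y, y_hat = _paired(y, y_hat, min_n=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("r2 undefined: zero variance in y")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def fit_percent(y, y_hat) -> float:
    """Normalised-RMSE fit percentage, 100*(1 - ||y-yhat||/||y-ybar||).

    Equals ``100*(1 - sqrt(1 - r2))`` whenever r2 <= 1; 100 iff the fit is
    perfect, 0 for the mean predictor, negative for worse.
    """
    y, y_hat = _paired(y, y_hat, min_n=2)
    denom = float(np.linalg.norm(y - y.mean()))
    if denom == 0.0:
        raise DegenerateInputError("fit_percent undefined: zero variance in y")
    return 100.0 * (1.0 - float(np.linalg.norm(y - y_hat)) / denom)


def paired_pvalue(y, y_hat, method: str = "ttest") -> float:
    """Two-sided paired test p-value on the differences y_i - yhat_i.

    ``method`` is ``"ttest"`` (paired t-test, default) or ``"wilcoxon"``
    (signed-rank).  Degenerate conventions: identical sequences report p = 1;
    a constant non-zero shift (zero-variance differences) reports p = 0, both
    with a warning.
    """
    y, y_hat = _paired(y, y_hat, min_n=2)
    d = y - y_hat
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            warnings.warn("paired test degenerate: y == y_hat exactly; p = 1 by convention")
            return 1.0
        warnings.warn("paired test degenerate: constant non-zero differences; p = 0 by convention")
        return 0.0
    if method == "ttest":
        return float(stats.ttest_rel(y, y_hat).pvalue)
    if method == "wilcoxon":
        return float(stats.wilcoxon(y, y_hat).pvalue)
    raise InvalidArgumentError(f"unknown paired-test method {method!r}")


@dataclass
class MetricReport:
    """Bundle of all metrics for one (subject, band, pipeline path)."""

    mse: float
    r2: float
    fit_percent: float
    p_value: float
    n: int
    test_name: str = "paired t-test"

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(y, y_hat, method: str = "ttest") -> MetricReport:
    """Compute the full metric report for one paired sequence."""
    y_arr, _ = _paired(y, y_hat, min_n=2)
    return MetricReport(
        mse=mse(y, y_hat),
        r2=r2(y, y_hat),
        fit_percent=fit_percent(y, y_hat),
        p_value=paired_pvalue(y, y_hat, method=method),
        n=int(y_arr.size),
        test_name="paired t-test" if method == "ttest" else "wilcoxon signed-rank",
    )
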