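"""Statistical machinery for strain cohort analysis and reproducibility.

Ordinary least squares (univariable or multivariable, via statsmodels),
one-way ANOVA, two-sample t-tests, and the method-agreement statistics used
in observer-reproducibility studies: Bland-Altman bias and limits of
agreement, the within-subject coefficient of variation, and the two-way
random-effects absolute-agreement single-measure intraclass correlation
ICC(2,1) with its F-distribution confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "RegressionResult",
    "linear_regression",
    "bland_altman",
    "coefficient_of_variation",
    "icc",
    "anova_oneway",
    "ttest_2sample",
]


@dataclass
class PairedMeasurements:
    """Two measurements of the same quantity on the same subjects."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired measurements must be equal-length 1D vectors")
        if len(self.a) < 3:
            raise ValueError("need at least 3 subject pairs")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("non-finite measurement")

    @property
    def n(self) -> int:
        return len(self.a)


@dataclass
class RegressionResult:
    """OLS fit: per-coefficient estimates/p-values plus model r2."""

    params: pd.Series
    pvalues: pd.Series
    r2: float
    r2_adj: float
    n: int
    model: object  # statsmodels results, for diagnostics


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        cols = list(X.columns)
        suspects = []
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                xi, xj = mat[:, i], mat[:, j]
                if np.std(xi) == 0 or np.std(xj) == 0:
                    continue
                if abs(np.corrcoef(xi, xj)[0, 1]) > 1 - 1e-10:
                    suspects.append((cols[i], cols[j]))
        raise ValueError(f"rank-deficient design matrix; collinear columns: {suspects or cols}")


def linear_regression(y: np.ndarray, X: np.ndarray | pd.DataFrame,
                      names: list[str] | None = None) -> RegressionResult:
    """OLS with intercept; two-sided t-test p-value per coefficient.

    ``X`` may be a vector (univariable) or a matrix/DataFrame
    (multivariable).  Raises on a rank-deficient design, naming the
    collinear columns.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        Xdf = X.astype(float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = names or [f"x{i}" for i in range(X.shape[1])]
        Xdf = pd.DataFrame(X, columns=names)
    if len(y) <= Xdf.shape[1] + 1:
        raise ValueError(f"n={len(y)} too small for {Xdf.shape[1]} predictors")
    const = Xdf.std(axis=0) == 0
    if const.any():
        raise ValueError(f"constant predictor columns: {list(Xdf.columns[const])}")
    _check_rank(Xdf)
    design = sm.add_constant(Xdf)
    fit = sm.OLS(y, design).fit()
    return RegressionResult(fit.params, fit.pvalues, float(fit.rsquared),
                            float(fit.rsquared_adj), int(fit.nobs), fit)


def bland_altman(pm: PairedMeasurements) -> dict:
    """Bland-Altman agreement: bias and 1.96-SD limits of agreement."""
    d = pm.a - pm.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "sd_diff": sd,
        "loa_lower": bias - 1.96 * sd,
        "loa_upper": bias + 1.96 * sd,
        "differences": d,
        "means": (pm.a + pm.b) / 2.0,
    }


def coefficient_of_variation(pm: PairedMeasurements, method: str = "rms") -> float:
    """Within-subject coefficient of variation, in percent.

    ``"rms"`` (default): within-subject SD = sqrt(mean(d^2)/2) over the
    per-subject differences d, divided by the grand mean of all
    measurements.  ``"sd_diff"``: SD of the differences divided by the
    grand mean (the common alternative definition).
    """
    grand = float(np.concatenate([pm.a, pm.b]).mean())
    if grand <= 0:
        raise ValueError("coefficient of variation undefined for non-positive grand mean")
    d = pm.a - pm.b
    if method == "rms":
        ws_sd = float(np.sqrt(np.mean(d**2) / 2.0))
    elif method == "sd_diff":
        ws_sd = float(d.std(ddof=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return 100.0 * ws_sd / grand


def icc(pm: PairedMeasurements, model: str = "ICC(2,1)", alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Two-way random-effects absolute-agreement single-measure ICC with CI.

    Variance decomposition of the n x 2 subject-by-rater table:
    ``ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n)``
    with the standard F-distribution confidence bounds.
    """
    if model != "ICC(2,1)":
        raise ValueError("only the ICC(2,1) absolute-agreement model is implemented")
    x = np.column_stack([pm.a, pm.b])
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_m[:, None] - col_m[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = (msr - mse) / denom

    # F-based CI (two-way random, single measure)
    a = k * value / (n * (1 - value)) if value < 1 else np.inf
    b = 1 + k * value * (n - 1) / (n * (1 - value)) if value < 1 else np.inf
    if np.isfinite(a):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lower = upper = 1.0
    return float(value), (float(lower), float(upper))


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValueError(f"group {i} has n={len(g)} < 2")
    if all(np.allclose(g, groups[0].mean()) for g in groups) and \
            all(np.isclose(g.mean(), groups[0].mean()) for g in groups):
        return 0.0, 1.0  # identical groups: no between- or within-variance
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def ttest_2sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample (Student) t-test, two-sided."""
    t, p = sps.ttest_ind(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    return float(t), float(p)
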