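"""Agreement statistics between manual and algorithmic area measurements.

Validation of an automated area pipeline against hand measurements is a
simple-linear-regression problem: with manual areas x and algorithmic areas
y, fit y = a*x + b by least squares and report the Pearson correlation

    r = Cov(X, Y) / sqrt(Var(X) * Var(Y)),

the coefficient of determination

    R^2 = 1 - SS_res / SS_tot,

and its small-sample correction

    adjusted R^2 = 1 - (1 - R^2) * (n - 1) / (n - k - 1)

with k = 1 predictor. A slope near 1 and intercept near 0 indicate the two
methods agree in scale and offset; residual diagnostics (mean, spread, an
omnibus normality statistic) check that remaining errors are random and
unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PairedMeasurements:
    """Matched manual (x) and algorithmic (y) values, in mm^2."""

    x: np.ndarray
    y: np.ndarray
    k: int = 1

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("measurements must be finite")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class RegressionFit:
    """Least-squares fit y = a*x + b with agreement statistics."""

    slope: float
    intercept: float
    r: float
    r2: float
    adjusted_r2: float
    n: int
    k: int
    residuals: np.ndarray

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def summary(self) -> str:
        lines = [
            "Manual vs algorithmic measurement agreement",
            "===========================================",
            f"n                 {self.n:>12d}",
            f"slope a           {self.slope:>12.4f}",
            f"intercept b       {self.intercept:>12.4f}",
            f"Pearson r         {self.r:>12.4f}",
            f"R^2               {self.r2:>12.4f}",
            f"adjusted R^2      {self.adjusted_r2:>12.4f}",
            f"residual mean     {float(np.mean(self.residuals)):>12.4g}",
            f"residual std      {float(np.std(self.residuals, ddof=1)) if self.n > 2 else float('nan'):>12.4g}",
        ]
        return "\n".join(lines)


def fit_regression(data: PairedMeasurements) -> RegressionFit:
    """Fit the least-squares line and agreement statistics.

    Slope is S_xy/S_xx about the means, intercept b = ybar - a*xbar;
    r is the Pearson correlation; R^2 = 1 - SS_res/SS_tot of the fitted
    line; adjusted R^2 applies the (n-1)/(n-k-1) correction (NaN when
    n <= k + 1). Constant x has no defined slope and raises.
    """
    x, y, n, k = data.x, data.y, data.n, data.k
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0.0:
        raise ValueError("x is constant: slope undefined")
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    syy = float(np.sum((y - ybar) ** 2))
    a = sxy / sxx
    b = ybar - a * xbar
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else np.nan
    resid = y - (a * x + b)
    ss_res = float(np.sum(resid**2))
    r2 = 1.0 - ss_res / syy if syy > 0 else np.nan
    if n > k + 1 and np.isfinite(r2):
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    else:
        adj = np.nan
    return RegressionFit(
        slope=a, intercept=b, r=float(r), r2=float(r2), adjusted_r2=float(adj),
        n=n, k=k, residuals=resid,
    )


def residual_diagnostics(fit: RegressionFit) -> dict:
    """Residual summary: mean, spread, omnibus normality statistic, and the
    data for residual-scatter and normal-quantile plots.

    The normality check is D'Agostino-Pearson's K^2 omnibus test (skewness
    plus kurtosis); it needs n >= 8 to be defined, and any diagnostics need
    n >= 3.
    """
    resid = np.asarray(fit.residuals, dtype=float)
    n = len(resid)
    if n < 3:
        raise ValueError("residual diagnostics need at least 3 observations")
    out = {
        "n": n,
        "mean": float(resid.mean()),
        "std": float(resid.std(ddof=1)),
        "residuals": resid,
    }
    if n >= 8 and resid.std() > 0:
        stat, pvalue = stats.normaltest(resid)
        out["normality_test"] = "dagostino_pearson_k2"
        out["normality_stat"] = float(stat)
        out["normality_pvalue"] = float(pvalue)
    else:
        out["normality_test"] = None
        out["normality_stat"] = np.nan
        out["normality_pvalue"] = np.nan
    # quantile-plot data: sorted residuals vs theoretical normal quantiles
    order = np.sort(resid)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    out["qq_theoretical"] = theo
    out["qq_observed"] = order
    return out


def validation_report(data: PairedMeasurements) -> tuple[pd.DataFrame, dict]:
    """(x, y, residual) table plus the JSON-ready fit summary."""
    fit = fit_regression(data)
    table = pd.DataFrame({"x": data.x, "y": data.y, "residual": fit.residuals})
    summary = {
        "a": fit.slope,
        "b": fit.intercept,
        "r": fit.r,
        "R2": fit.r2,
        "adjusted_R2": fit.adjusted_r2,
        "n": fit.n,
    }
    return table, summary
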