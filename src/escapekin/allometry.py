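"""Allometric size correction of jump-performance metrics.

Bigger animals jump differently simply because they are bigger, so species
comparisons of performance first remove the body-size trend: each metric is
log-transformed and regressed on log body mass over the pooled species, and
the residuals — collectively the "overall performance" variables — carry
into the multivariate analysis. Natural logarithms are used; the base only
rescales both axes and leaves the residuals of the log-log fit unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["PerformanceMatrix", "size_correct", "build_performance_matrix", "standardize_columns"]


@dataclass(frozen=True)
class PerformanceMatrix:
    """Size-corrected performance residuals, one row per individual.

    ``data`` columns are residuals of log(metric) on log(mass); each column is
    mean-zero by construction. ``standardized`` marks unit-variance scaling.
    """

    data: pd.DataFrame
    standardized: bool = False

    @property
    def column_names(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def size_correct(metric, mass_g) -> np.ndarray:
    """Residuals of log(metric) regressed on log(body mass) by pooled OLS.

    Both inputs must be strictly positive and the same length with n >= 3.
    When log-mass has zero variance the slope is unidentifiable and the
    function falls back to centering the log metric (with a warning).
    """
    metric = np.asarray(metric, dtype=float)
    mass = np.asarray(mass_g, dtype=float)
    if metric.shape != mass.shape or metric.ndim != 1:
        raise ValueError("metric and mass_g must be 1-D arrays of equal length")
    if metric.size < 3:
        raise ValueError(f"need at least 3 observations, got {metric.size}")
    if np.any(metric <= 0) or np.any(~np.isfinite(metric)):
        raise ValueError("metric values must be finite and > 0 for log transform")
    if np.any(mass <= 0) or np.any(~np.isfinite(mass)):
        raise ValueError("mass values must be finite and > 0 for log transform")
    log_y = np.log(metric)
    log_x = np.log(mass)
    if np.ptp(log_x) == 0.0:
        warnings.warn(
            "log body mass has zero variance; falling back to intercept-only "
            "centering of the log metric",
            stacklevel=2,
        )
        return log_y - log_y.mean()
    fit = sm.OLS(log_y, sm.add_constant(log_x)).fit()
    return np.asarray(fit.resid)


def build_performance_matrix(
    df: pd.DataFrame, metrics: list[str], mass_col: str = "mass_g"
) -> PerformanceMatrix:
    """Size-correct each metric column of ``df`` against ``mass_col``.

    Rows with a missing mass or missing metric value are dropped first
    (individuals without a body-size measurement cannot be corrected).
    """
    cols = [mass_col, *metrics]
    complete = df.dropna(subset=cols)
    resid = {m: size_correct(complete[m], complete[mass_col]) for m in metrics}
    return PerformanceMatrix(data=pd.DataFrame(resid, index=complete.index))


def standardize_columns(matrix: PerformanceMatrix) -> PerformanceMatrix:
    """Rescale every residual column to unit sample SD (mean stays zero)."""
    if len(matrix.data) < 2:
        raise ValueError("need at least 2 rows to standardize")
    sds = matrix.data.std(ddof=1)
    dead = sds.index[sds == 0.0].tolist()
    if dead:
        raise ValueError(f"zero-SD column(s) cannot be standardized: {dead}")
    return replace(matrix, data=matrix.data / sds, standardized=True)
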