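"""Dissipation-plane power laws across enzyme ensembles.

Across ensembles of enzymes spanning many orders of magnitude, total
dissipation scales as a power law in the catalytic parameters,

    dissipation/RT = 10^a * (k_cat/K_M)^b1,
    dissipation/RT = 10^a * (k_cat)^b2,

i.e. straight lines in log10-log10 space, and the points lie close to a
plane in (log10 k_cat, log10 K_M, log10 dissipation/RT) space.  This
module fits those laws by ordinary least squares on the decadic logs
(dissipation treated as the response), compares the two slopes by a
paired case-resampling bootstrap (the two regressions share their
response variable, so standard-error z-tests are invalid), and fits the
3D plane with its residual SD as a thickness statistic.

Rows with nonpositive values, or driven backwards (X < 0), are excluded
with a logged warning before fitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .kinetics import KineticSummary

__all__ = ["ScalingFit", "SlopeComparison", "PlaneFit", "fit_power_law", "compare_slopes", "fit_plane"]

logger = logging.getLogger(__name__)

_PREDICTORS = {"kcat": "kcat", "kcat_over_km": "kcat_over_km"}


@dataclass(frozen=True)
class ScalingFit:
    """OLS fit of log10(dissipation/RT) on log10(predictor)."""

    predictor: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    n: int
    slope_ci95: tuple[float, float]
    residuals: np.ndarray = field(repr=False)
    method: str = "ols"
    n_rejected: int = 0


@dataclass(frozen=True)
class SlopeComparison:
    """Paired bootstrap comparison of the kcat slope minus the kcat/KM slope."""

    delta_slope: float
    ci95: tuple[float, float]
    significant: bool
    method: str
    n_boot: int
    seed: int


@dataclass(frozen=True)
class PlaneFit:
    """Least-squares plane log10(diss/RT) ~ alpha log10(kcat) + beta log10(KM) + gamma."""

    alpha: float
    beta: float
    gamma: float
    residual_sd: float
    r_squared: float
    n: int


def _as_frame(records: Iterable[KineticSummary] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
        if "km" not in frame.columns and "KM" in frame.columns:
            frame = frame.rename(columns={"KM": "km"})
        return frame
    rows = [
        {
            "name": r.name,
            "kcat": r.kcat,
            "km": r.km,
            "kcat_over_km": r.kcat_over_km,
            "dissipation_rt": r.dissipation_rt,
            "forward_driven": r.forward_driven,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def _clean(frame: pd.DataFrame, columns: Sequence[str]) -> tuple[pd.DataFrame, int]:
    """Drop rows unusable on a log scale, logging each exclusion."""
    n_in = len(frame)
    keep = pd.Series(True, index=frame.index)
    if "forward_driven" in frame.columns:
        backward = ~frame["forward_driven"].astype(bool)
        for name in frame.loc[backward, "name"] if "name" in frame.columns else []:
            logger.warning("excluding backward-driven row %r from fit", name)
        keep &= ~backward
    for col in columns:
        bad = ~(np.isfinite(frame[col]) & (frame[col] > 0))
        for idx in frame.index[bad & keep]:
            label = frame.at[idx, "name"] if "name" in frame.columns else idx
            logger.warning("excluding row %r: nonpositive or non-finite %s", label, col)
        keep &= ~bad
    out = frame.loc[keep]
    n_rej = n_in - len(out)
    if n_rej:
        logger.info("power-law fit: %d rows in, %d excluded", n_in, n_rej)
    return out, n_rej


def _ols_line(x: np.ndarray, y: np.ndarray):
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return res


def _orthogonal_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Total-least-squares (orthogonal regression) line through the data."""
    xm, ym = x.mean(), y.mean()
    u = np.column_stack([x - xm, y - ym])
    _, _, vt = np.linalg.svd(u, full_matrices=False)
    nx, ny = vt[-1]  # normal of the best-fit line
    if ny == 0:
        raise ValueError("orthogonal regression degenerate: vertical line")
    slope = -nx / ny
    return slope, ym - slope * xm


def fit_power_law(
    records: Iterable[KineticSummary] | pd.DataFrame,
    predictor: str = "kcat_over_km",
    *,
    response: str = "dissipation_rt",
    method: str = "ols",
) -> ScalingFit:
    """Fit dissipation/RT = 10^a * predictor^b on decadic logs.

    Parameters
    ----------
    records:
        Kinetic summaries or an equivalent DataFrame (columns ``kcat``,
        ``kcat_over_km``, ``dissipation_rt``, optional ``forward_driven``
        and ``name``).
    predictor:
        ``"kcat_over_km"`` or ``"kcat"``.
    method:
        ``"ols"`` (default; slope SE and 95% CI from the t-distribution
        with n-2 df) or ``"orthogonal"`` (total least squares, exposed
        for sensitivity analysis; no analytic SE is reported).
    """
    if predictor not in _PREDICTORS:
        raise ValueError(f"predictor must be one of {sorted(_PREDICTORS)}, got {predictor!r}")
    frame = _as_frame(records)
    frame, n_rej = _clean(frame, [predictor, response])
    n = len(frame)
    if n < 3:
        raise ValueError(f"power-law fit needs at least 3 usable rows, got {n}")
    x = np.log10(frame[predictor].to_numpy(float))
    y = np.log10(frame[response].to_numpy(float))
    if method == "ols":
        res = _ols_line(x, y)
        intercept, slope = res.params
        intercept_se, slope_se = res.bse
        ci = res.conf_int(alpha=0.05)
        slope_ci = (float(ci[1][0]), float(ci[1][1]))
        residuals = np.asarray(res.resid)
        r2 = float(res.rsquared)
    elif method == "orthogonal":
        slope, intercept = _orthogonal_line(x, y)
        residuals = y - (intercept + slope * x)
        r2 = 1.0 - residuals.var() / y.var() if y.var() > 0 else 1.0
        slope_se = intercept_se = math.nan
        slope_ci = (math.nan, math.nan)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ScalingFit(
        predictor=predictor,
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        r_squared=r2,
        n=n,
        slope_ci95=slope_ci,
        residuals=residuals,
        method=method,
        n_rejected=n_rej,
    )


def _fast_slope(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    return float(xm @ (y - y.mean()) / (xm @ xm))


def compare_slopes(
    records: Iterable[KineticSummary] | pd.DataFrame,
    n_boot: int = 2000,
    seed: int | None = None,
    *,
    response: str = "dissipation_rt",
) -> SlopeComparison:
    """Paired bootstrap of (slope vs kcat) - (slope vs kcat/KM).

    Enzymes are case-resampled with replacement; both slopes are refit
    on each resample, so their sampling covariance is respected.  The
    95% percentile CI excluding 0 sets the ``significant`` flag.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if seed is None:
        raise ValueError("compare_slopes is stochastic: a seed is required")
    frame = _as_frame(records)
    frame, _ = _clean(frame, ["kcat", "kcat_over_km", response])
    n = len(frame)
    if n < 3:
        raise ValueError(f"slope comparison needs at least 3 usable rows, got {n}")
    x1 = np.log10(frame["kcat_over_km"].to_numpy(float))
    x2 = np.log10(frame["kcat"].to_numpy(float))
    y = np.log10(frame[response].to_numpy(float))
    delta = _fast_slope(x2, y) - _fast_slope(x1, y)
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.ptp(x1[idx]) == 0 or np.ptp(x2[idx]) == 0:
            deltas[b] = delta  # degenerate resample: fall back to the point estimate
            continue
        deltas[b] = _fast_slope(x2[idx], y[idx]) - _fast_slope(x1[idx], y[idx])
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return SlopeComparison(
        delta_slope=delta,
        ci95=(float(lo), float(hi)),
        significant=not (lo <= 0.0 <= hi),
        method="paired-bootstrap",
        n_boot=n_boot,
        seed=seed,
    )


def fit_plane(
    records: Iterable[KineticSummary] | pd.DataFrame,
    *,
    response: str = "dissipation_rt",
) -> PlaneFit:
    """Least-squares plane in (log10 kcat, log10 KM, log10 diss/RT) space.

    The residual standard deviation (log10 units) is the plane
    "thickness" statistic.  Rank-deficient predictors are rejected.
    """
    frame = _as_frame(records)
    frame, _ = _clean(frame, ["kcat", "km", response])
    n = len(frame)
    if n < 4:
        raise ValueError(f"plane fit needs at least 4 usable rows, got {n}")
    x = np.column_stack([np.log10(frame["kcat"].to_numpy(float)), np.log10(frame["km"].to_numpy(float))])
    y = np.log10(frame[response].to_numpy(float))
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient predictors: kcat and KM are collinear on the log scale")
    res = sm.OLS(y, design).fit()
    gamma, alpha, beta = res.params
    resid = np.asarray(res.resid)
    dof = max(n - 3, 1)
    return PlaneFit(
        alpha=float(alpha),
        beta=float(beta),
        gamma=float(gamma),
        residual_sd=float(np.sqrt(resid @ resid / dof)),
        r_squared=float(res.rsquared),
        n=n,
    )


def slope_t_ci(slope: float, se: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided CI for a regression slope from the t-distribution, n-2 df."""
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return slope - t * se, slope + t * se
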