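"""Phenotype preparation for the pulse-wave-velocity modes.

Each PWV mode is measured twice per visit.  A measurement pair is discarded
when the two readings disagree by more than a mode-specific threshold
(baPWV: 5 m/s, cfPWV: 10 m/s, bfPWV: 25 m/s).  For baPWV and cfPWV the first
reading is used; for bfPWV — the noisiest mode — the two readings are
averaged.  Retained PWV values and blood pressures are natural-log
transformed for all downstream analyses.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "DISCARD_THRESHOLDS",
    "PWV_MODES",
    "select_measurement",
    "select_measurements",
    "log_transform",
    "fit_descriptive_models",
    "partial_correlation",
]

PWV_MODES = ("baPWV", "cfPWV", "bfPWV")

#: maximal tolerated |first - second| difference (m/s) per mode
DISCARD_THRESHOLDS = {"baPWV": 5.0, "cfPWV": 10.0, "bfPWV": 25.0}

#: modes whose retained value is the mean of the two readings
_AVERAGED_MODES = frozenset({"bfPWV"})


def select_measurement(mode: str, first: float, second: float | None = None) -> float:
    """Select the analysis value from a duplicate measurement pair.

    Returns NaN (missing) when the pair violates the discard rule.  When the
    second reading is missing the first is kept unchanged — the discard rule
    cannot be evaluated on a single reading.
    """
    if mode not in DISCARD_THRESHOLDS:
        raise ValueError(f"unknown PWV mode: {mode!r}")
    if first is None or (isinstance(first, float) and math.isnan(first)):
        return float("nan")
    if second is None or (isinstance(second, float) and math.isnan(second)):
        return float(first)
    if abs(first - second) > DISCARD_THRESHOLDS[mode]:
        return float("nan")
    if mode in _AVERAGED_MODES:
        return (float(first) + float(second)) / 2.0
    return float(first)


def select_measurements(raw: pd.DataFrame, modes: tuple[str, ...] = PWV_MODES) -> pd.DataFrame:
    """Vectorised :func:`select_measurement` over a raw phenotype table.

    Expects columns ``{mode}_m1`` and ``{mode}_m2`` per mode and adds one
    selected column per mode named after the mode itself.
    """
    out = raw.copy()
    for mode in modes:
        c1, c2 = f"{mode}_m1", f"{mode}_m2"
        if c1 not in raw.columns:
            continue
        first = raw[c1].to_numpy(dtype=float)
        second = raw[c2].to_numpy(dtype=float) if c2 in raw.columns else np.full_like(first, np.nan)
        sel = first.copy()
        both = ~np.isnan(first) & ~np.isnan(second)
        discard = both & (np.abs(first - second) > DISCARD_THRESHOLDS[mode])
        if mode in _AVERAGED_MODES:
            sel[both] = (first[both] + second[both]) / 2.0
        sel[discard] = np.nan
        out[mode] = sel
    return out


def log_transform(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Add natural-log columns ``log{col}`` for each requested column.

    Missing values propagate.  Non-positive values cannot be log-transformed:
    the offending entries are set to missing in the log column and a warning
    with the row count is logged.
    """
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        bad = ~np.isnan(x) & (x <= 0.0)
        if bad.any():
            logger.warning("log_transform: %d non-positive values in %r excluded", int(bad.sum()), col)
        with np.errstate(divide="ignore", invalid="ignore"):
            lx = np.where(bad, np.nan, np.log(np.where(x > 0, x, np.nan)))
        out[f"log{col}"] = lx
    return out


def fit_descriptive_models(
    table: pd.DataFrame,
    outcomes: list[str],
    covariates: list[str],
) -> pd.DataFrame:
    """Univariate OLS of each outcome on each single covariate.

    Mirrors the descriptive cohort table: per (outcome, covariate) pair the
    slope, its standard error, the two-sided p-value and the adjusted R^2
    (with the usual (n-1)/(n-p-1) correction) are reported.
    """
    rows = []
    for outcome in outcomes:
        for cov in covariates:
            sub = table[[outcome, cov]].dropna()
            if len(sub) < 3:
                raise ValueError(f"fewer than 3 complete cases for {outcome} ~ {cov}")
            x = sub[cov].to_numpy(dtype=float)
            if np.ptp(x) == 0.0:
                raise ValueError(f"constant covariate {cov!r}")
            fit = sm.OLS(sub[outcome].to_numpy(dtype=float), sm.add_constant(x)).fit()
            rows.append(
                {
                    "outcome": outcome,
                    "covariate": cov,
                    "slope": float(fit.params[1]),
                    "se": float(fit.bse[1]),
                    "p": float(fit.pvalues[1]),
                    "adj_r2": float(fit.rsquared_adj),
                    "n": int(fit.nobs),
                }
            )
    return pd.DataFrame(rows)


def partial_correlation(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Correlation of x and y after removing the linear effect of z.

    ``z`` may be a vector or a matrix of controls (columns = variables); an
    intercept is always included.  Computed as the Pearson correlation of the
    OLS residuals of x on z and y on z, which for a single control equals the
    closed form (rxy - rxz*ryz) / sqrt((1 - rxz^2)(1 - ryz^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    zm = np.atleast_2d(np.asarray(z, dtype=float))
    if zm.shape[0] != x.shape[0]:
        zm = zm.T
    if not (x.shape[0] == y.shape[0] == zm.shape[0]):
        raise ValueError("x, y and z must have equal length")
    if x.shape[0] < 4:
        raise ValueError("need at least 4 observations")
    mask = ~np.isnan(x) & ~np.isnan(y) & ~np.isnan(zm).any(axis=1)
    x, y, zm = x[mask], y[mask], zm[mask]
    design = np.column_stack([np.ones(len(x)), zm])
    coef, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    res = np.column_stack([x, y]) - design @ coef
    sx, sy = res.std(axis=0)
    # residuals that are zero up to round-off mean x (or y) lies in span(z)
    tol_x = 1e-10 * max(1.0, float(x.std()))
    tol_y = 1e-10 * max(1.0, float(y.std()))
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero-variance residuals")
    return float(np.corrcoef(res[:, 0], res[:, 1])[0, 1])
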