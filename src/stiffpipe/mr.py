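"""Bidirectional inverse-variance-weighted Mendelian randomization.

The causal effect of an exposure on an outcome is estimated by combining
per-instrument Wald ratios ``beta_y / beta_x`` with inverse-variance weights.
The random-effect variant — the default — inflates the fixed-effect standard
error by ``sqrt(Q / (J - 1))`` whenever Cochran's Q exceeds its expectation,
so heterogeneity across instruments (a signature of pleiotropy) widens the
confidence interval rather than being ignored.

Instrument selection is rule-based in both directions:

- forward (blood pressure -> PWV): published BP SNPs are kept as instruments
  when they are nominally associated with SBP locally, show no nominal PWV
  association (potential direct effect), and are not in LD (r^2 >= 0.1) with
  any local PWV lead SNP;
- reverse (PWV -> blood pressure): independent suggestive PWV SNPs nominally
  significant for the mode under study, excluding SNPs in LD with published
  BP hits.

The study design is one-sample (exposure and outcome estimated in the same
cohort); the estimator is unchanged but weak-instrument bias is then towards
the observational association rather than the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MRResult",
    "select_instruments_forward",
    "select_instruments_reverse",
    "ivw",
    "ci_and_p",
    "cochran_q",
    "bidirectional_report",
]

Z_95 = 1.96  # conventional two-sided 95% normal quantile


@dataclass
class MRResult:
    """Combined causal estimate with heterogeneity diagnostics."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    Q: float | None
    Q_df: int | None
    Q_p: float | None
    J: int
    model: str

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "Q": self.Q,
            "Q_df": self.Q_df,
            "Q_p": self.Q_p,
            "J": self.J,
            "model": self.model,
        }


def _instrument_frame(instruments: pd.DataFrame) -> pd.DataFrame:
    required = {"variant_id", "beta_x", "se_x", "beta_y", "se_y"}
    missing = required - set(instruments.columns)
    if missing:
        raise ValueError(f"instrument table missing columns: {sorted(missing)}")
    if (instruments["se_x"] <= 0).any() or (instruments["se_y"] <= 0).any():
        raise ValueError("instrument standard errors must be positive")
    if (instruments["beta_x"] == 0).any():
        raise ValueError("beta_x = 0 instrument cannot form a Wald ratio")
    return instruments


def ci_and_p(estimate: float, se: float) -> tuple[float, float, float]:
    """95% normal confidence limits (+/-1.96 SE) and two-sided p-value."""
    if se <= 0:
        raise ValueError("se must be positive")
    ci_low = estimate - Z_95 * se
    ci_high = estimate + Z_95 * se
    p = 2.0 * stats.norm.sf(abs(estimate) / se)
    return float(ci_low), float(ci_high), float(min(p, 1.0))


def ivw(
    instruments: pd.DataFrame,
    model: str = "random",
    second_order_se: bool = False,
) -> MRResult:
    """Inverse-variance-weighted causal estimate.

    Parameters
    ----------
    instruments
        One row per instrument with columns ``variant_id, beta_x, se_x,
        beta_y, se_y``.
    model
        ``"random"`` (default) multiplies the fixed-effect SE by
        ``max(1, sqrt(Q / (J - 1)))``; ``"fixed"`` reports the plain IVW SE.
    second_order_se
        When True, the per-ratio SE includes the exposure-uncertainty term
        ``sqrt(se_y^2 / beta_x^2 + beta_y^2 se_x^2 / beta_x^4)`` instead of
        the first-order ``se_y / |beta_x|``.

    With a single instrument the result is the Wald ratio and Q is undefined
    (reported as None).
    """
    if model not in ("random", "fixed"):
        raise ValueError("model must be 'random' or 'fixed'")
    ins = _instrument_frame(instruments)
    J = len(ins)
    if J == 0:
        raise ValueError("no instruments")
    bx = ins["beta_x"].to_numpy(dtype=float)
    by = ins["beta_y"].to_numpy(dtype=float)
    sx = ins["se_x"].to_numpy(dtype=float)
    sy = ins["se_y"].to_numpy(dtype=float)

    ratio = by / bx
    if second_order_se:
        ratio_se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        ratio_se = sy / np.abs(bx)

    w = 1.0 / ratio_se**2
    estimate = float(np.sum(w * ratio) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))

    if J >= 2:
        Q = float(np.sum(((ratio - estimate) / ratio_se) ** 2))
        Q_df = J - 1
        Q_p = float(stats.chi2.sf(Q, Q_df))
    else:
        Q = Q_df = Q_p = None

    se = se_fixed
    if model == "random" and J >= 2:
        se = se_fixed * max(1.0, float(np.sqrt(Q / Q_df)))

    ci_low, ci_high, p = ci_and_p(estimate, se)
    return MRResult(estimate, se, ci_low, ci_high, p, Q, Q_df, Q_p, J, model)


def cochran_q(instruments: pd.DataFrame, estimate: float | None = None) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test across instrument Wald ratios.

    Under homogeneity Q is chi-square with J - 1 degrees of freedom; excess
    heterogeneity flags pleiotropic instruments.  When ``estimate`` is not
    given, the fixed-effect IVW estimate is used (the standard choice).
    """
    ins = _instrument_frame(instruments)
    J = len(ins)
    if J < 2:
        raise ValueError("Cochran's Q requires at least two instruments")
    ratio = (ins["beta_y"] / ins["beta_x"]).to_numpy(dtype=float)
    ratio_se = (ins["se_y"] / ins["beta_x"].abs()).to_numpy(dtype=float)
    if estimate is None:
        w = 1.0 / ratio_se**2
        estimate = float(np.sum(w * ratio) / np.sum(w))
    Q = float(np.sum(((ratio - estimate) / ratio_se) ** 2))
    df = J - 1
    return Q, df, float(stats.chi2.sf(Q, df))


def select_instruments_forward(
    bp_panel: pd.DataFrame,
    local_sbp: pd.DataFrame,
    local_pwv: dict[str, pd.DataFrame],
    pwv_leads: list[str],
    ld: pd.DataFrame | None,
    nominal_alpha: float = 0.05,
    ld_r2_max: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Instrument selection for the blood pressure -> PWV direction.

    Filters, in order, each recorded in the exclusion ledger:

    1. ``unavailable`` — panel SNP absent from the local SBP scan;
    2. ``direct_effect`` — nominal significance (p < ``nominal_alpha``) for
       any PWV mode, i.e. a potential direct effect on the outcome;
    3. ``sbp_not_nominal`` — no nominal local SBP association (weak
       instrument by the study's rule);
    4. ``ld_with_pwv_lead`` — r^2 >= ``ld_r2_max`` with any PWV lead SNP.

    Survivors become instruments with the local SBP effect as ``beta_x``.
    Outcome effects (``beta_y``) are attached per mode downstream, since one
    instrument set serves all three PWV outcomes.
    """
    sbp = local_sbp.set_index("variant_id")
    pwv_p = {mode: df.set_index("variant_id")["p"] for mode, df in local_pwv.items()}
    ledger_rows = []
    kept = []
    for vid in bp_panel["variant_id"]:
        if vid not in sbp.index:
            ledger_rows.append({"variant_id": vid, "reason": "unavailable"})
            continue
        pwv_ps = [float(p[vid]) for p in pwv_p.values() if vid in p.index]
        if pwv_ps and min(pwv_ps) < nominal_alpha:
            ledger_rows.append({"variant_id": vid, "reason": "direct_effect"})
            continue
        if float(sbp.at[vid, "p"]) >= nominal_alpha:
            ledger_rows.append({"variant_id": vid, "reason": "sbp_not_nominal"})
            continue
        if ld is not None and vid in ld.index:
            leads_in_ld = [l for l in pwv_leads if l in ld.columns and float(ld.at[vid, l]) >= ld_r2_max]
            if leads_in_ld:
                ledger_rows.append({"variant_id": vid, "reason": "ld_with_pwv_lead"})
                continue
        kept.append(
            {
                "variant_id": vid,
                "beta_x": float(sbp.at[vid, "beta"]),
                "se_x": float(sbp.at[vid, "se"]),
            }
        )
    ledger = pd.DataFrame(ledger_rows, columns=["variant_id", "reason"])
    if not kept:
        raise ValueError(f"no instruments survive forward selection; ledger:\n{ledger}")
    return pd.DataFrame(kept), ledger


def select_instruments_reverse(
    pwv_suggestive: pd.DataFrame,
    mode: str,
    published_bp_hits: list[str],
    ld_proxy: pd.DataFrame | None,
    nominal_alpha: float = 0.05,
    ld_r2_max: float = 0.1,
    drop_lead: str | None = None,
) -> pd.DataFrame:
    """Instrument selection for the PWV -> blood pressure direction.

    ``pwv_suggestive`` holds the independent (pruned) suggestive PWV SNPs
    with per-mode p-values and effects for the mode under study (columns
    ``variant_id, beta, se, p``).  SNPs failing nominal significance for the
    mode, or in LD (r^2 >= ``ld_r2_max``) with a published BP hit, are
    dropped.  ``drop_lead`` removes one designated lead SNP for the
    secondary sensitivity run.
    """
    kept = []
    for rec in pwv_suggestive.itertuples(index=False):
        vid = rec.variant_id
        if drop_lead is not None and vid == drop_lead:
            continue
        if float(rec.p) >= nominal_alpha:
            continue
        if ld_proxy is not None and vid in ld_proxy.index:
            hits = [h for h in published_bp_hits if h in ld_proxy.columns and float(ld_proxy.at[vid, h]) >= ld_r2_max]
            if hits:
                continue
        kept.append({"variant_id": vid, "beta_x": float(rec.beta), "se_x": float(rec.se)})
    if not kept:
        raise ValueError(f"no instruments survive reverse selection for {mode}")
    return pd.DataFrame(kept)


def attach_outcome(instruments: pd.DataFrame, outcome_stats: pd.DataFrame) -> pd.DataFrame:
    """Join outcome effects onto an instrument set (inner join on variant)."""
    out = outcome_stats.set_index("variant_id")
    merged = instruments.copy()
    merged["beta_y"] = merged["variant_id"].map(out["beta"])
    merged["se_y"] = merged["variant_id"].map(out["se"])
    merged = merged.dropna(subset=["beta_y", "se_y"])
    if merged.empty:
        raise ValueError("no instrument has outcome statistics")
    return merged


def bidirectional_report(
    forward: dict[str, MRResult] | None,
    reverse: dict[str, MRResult] | None,
) -> pd.DataFrame:
    """Combined per-direction, per-mode causal-effect table.

    Missing directions are reported with NaN estimate fields so the table
    shape is stable regardless of which analyses ran.
    """
    if not forward and not reverse:
        raise ValueError("at least one direction must be provided")
    rows = []
    for direction, results in (("SBP->PWV", forward), ("PWV->SBP", reverse)):
        if not results:
            rows.append({"direction": direction, "mode": None, "estimate": np.nan})
            continue
        for mode, res in results.items():
            rows.append({"direction": direction, "mode": mode, **res.as_dict()})
    return pd.DataFrame(rows)
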