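"""LD-score regression: heritability, QC gates and genetic correlation.

Under a polygenic model, the expected association chi-square of variant j is

    E[chi2_j] = 1 + N * h2 * l_j / M + confounding,

where ``l_j`` is the LD score (sum of r^2 between j and its neighbours), N
the GWAS sample size and M the number of variants.  Regressing chi-square on
``N * l_j / M`` therefore estimates the SNP heritability h2 as the slope,
while population stratification and other uniform confounding load on the
intercept.  The cross-trait analogue regresses ``z1_j * z2_j`` on
``sqrt(N1*N2) * l_j / M`` to estimate the genetic covariance, and the genetic
correlation is ``rg = gencov / sqrt(h2_1 * h2_2)``.

Standard errors come from a delete-a-block jackknife over contiguous SNP
blocks (default 20 blocks — a desk-scale default, configurable).  Weighting
is two-step: a first pass with weights ``1 / max(l_j, 1)`` (over-counting
correction), then one re-weighting that also divides by the squared expected
chi-square from the first pass (heteroskedasticity correction).

QC gates applied before interpreting a heritability estimate or entering a
genetic-correlation analysis: heritability Z score > 1.5, mean chi-square of
the test statistics > 1.02, and regression intercept within (0.9, 1.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LdscResult",
    "compute_ld_scores",
    "ldsc_h2",
    "ldsc_qc",
    "ldsc_rg",
]

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_N_BLOCKS = 20


@dataclass
class LdscResult:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    mean_chi2: float
    z: float
    qc_pass: bool

    def as_dict(self) -> dict:
        return {
            "h2": self.h2,
            "h2_se": self.h2_se,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "mean_chi2": self.mean_chi2,
            "z": self.z,
            "qc_pass": self.qc_pass,
        }


def compute_ld_scores(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Per-variant LD scores from in-sample dosages.

    For variant j, ``l_j = sum_k [ r2_jk - (1 - r2_jk) / (n - 2) ]`` over all
    variants k on the same chromosome within ``window_bp`` of j, including
    the self term.  The subtraction is the standard small-sample bias
    adjustment of the squared sample correlation.  Monomorphic variants are
    skipped (NaN score).
    """
    d = np.asarray(dosages, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    sd = d.std(axis=0)
    pos = variants["pos"].to_numpy(dtype=int)
    chrom = variants["chrom"].astype(str).to_numpy()
    m = d.shape[1]
    # standardize once; polymorphic columns only
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (d - d.mean(axis=0)) / sd
    scores = np.full(m, np.nan)
    bias = 1.0 / (n - 2)
    order = np.lexsort((pos, chrom))
    pos_o, chrom_o = pos[order], chrom[order]
    z_o = z[:, order]
    poly_o = sd[order] > 0
    lo = 0
    for i in range(m):
        if not poly_o[i]:
            continue
        while lo < i and (chrom_o[lo] != chrom_o[i] or pos_o[i] - pos_o[lo] > window_bp):
            lo += 1
        hi = i
        while hi + 1 < m and chrom_o[hi + 1] == chrom_o[i] and pos_o[hi + 1] - pos_o[i] <= window_bp:
            hi += 1
        cols = np.arange(lo, hi + 1)
        cols = cols[poly_o[cols]]
        r = z_o[:, cols].T @ z_o[:, i] / n
        r2 = r**2
        scores[order[i]] = float(np.sum(r2 - (1.0 - r2) * bias))
    out = variants[["variant_id"]].copy()
    out["ld_score"] = scores
    return out


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    sw = np.sqrt(w)
    design = np.column_stack([sw, sw * x])
    coef, *_ = np.linalg.lstsq(design, sw * y, rcond=None)
    return float(coef[0]), float(coef[1])


def _two_step_fit(x: np.ndarray, y: np.ndarray, ell: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Two-step weighted regression used by both h2 and rg estimators."""
    w = 1.0 / np.maximum(ell, 1.0)
    a0, b0 = _wls(x, y, w)
    expected = np.maximum(a0 + b0 * x, 0.1)
    w2 = w / expected**2
    a, b = _wls(x, y, w2)
    return a, b, w2


def _jackknife(values: np.ndarray) -> float:
    """Delete-a-block jackknife SE from the per-block leave-out estimates."""
    B = values.size
    mean = values.mean()
    return float(np.sqrt((B - 1.0) / B * np.sum((values - mean) ** 2)))


def _block_slices(m: int, n_blocks: int) -> list[np.ndarray]:
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    return [idx for idx in np.array_split(np.arange(m), n_blocks) if idx.size]


def ldsc_h2(
    assoc: pd.DataFrame,
    ld_scores: pd.DataFrame,
    N: int,
    M: int,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> LdscResult:
    """Univariate LD-score-regression heritability.

    ``assoc`` needs ``variant_id, beta, se``; ``ld_scores`` needs
    ``variant_id, ld_score``.  Variants are matched on id; at least 50
    matched variants are required.  The reported SEs are delete-a-block
    jackknife SEs over ``n_blocks`` contiguous blocks; the QC flag applies
    the three gates of :func:`ldsc_qc`.
    """
    merged = assoc.merge(ld_scores, on="variant_id").dropna(subset=["beta", "se", "ld_score"])
    if len(merged) < 50:
        raise ValueError(f"only {len(merged)} variants matched; need >= 50")
    chi2 = (merged["beta"] / merged["se"]).to_numpy(dtype=float) ** 2
    ell = merged["ld_score"].to_numpy(dtype=float)
    x = N * ell / M

    a, b, _ = _two_step_fit(x, chi2, ell)
    blocks = _block_slices(len(merged), n_blocks)
    est = np.array(
        [
            _two_step_fit(np.delete(x, idx), np.delete(chi2, idx), np.delete(ell, idx))[:2]
            for idx in blocks
        ]
    )
    intercept_se = _jackknife(est[:, 0])
    h2_se = _jackknife(est[:, 1])
    mean_chi2 = float(chi2.mean())
    z = b / h2_se if h2_se > 0 else np.inf
    res = LdscResult(b, h2_se, a, intercept_se, mean_chi2, float(z), False)
    res.qc_pass = ldsc_qc(res)["pass"]
    return res


def ldsc_qc(result: LdscResult) -> dict:
    """The three minimum criteria for a usable heritability estimate.

    Pass requires z > 1.5 AND mean chi-square > 1.02 AND intercept strictly
    inside (0.9, 1.1).  All comparisons are strict.
    """
    flags = {
        "z_gt_1.5": result.z > 1.5,
        "mean_chi2_gt_1.02": result.mean_chi2 > 1.02,
        "intercept_in_0.9_1.1": 0.9 < result.intercept < 1.1,
    }
    flags["pass"] = all(flags.values())
    return flags


def ldsc_rg(
    assoc_1: pd.DataFrame,
    assoc_2: pd.DataFrame,
    ld_scores: pd.DataFrame,
    N1: int,
    N2: int,
    M: int,
    n_blocks: int = DEFAULT_N_BLOCKS,
    require_qc: bool = True,
) -> dict:
    """Cross-trait LD-score regression: genetic correlation.

    The z-score product ``z1_j * z2_j`` is regressed on
    ``sqrt(N1*N2) * l_j / M``; the slope estimates the genetic covariance and
    ``rg = gencov / sqrt(h2_1 * h2_2)``.  The whole pipeline (both h2 fits
    and the covariance fit) is jackknifed per block so the rg SE reflects the
    uncertainty of the denominators too.  rg is clamped to [-1, 1]; a clamp
    is recorded in the output.  With ``require_qc`` (default) both traits
    must pass the univariate QC gates.
    """
    h2_1 = ldsc_h2(assoc_1, ld_scores, N1, M, n_blocks)
    h2_2 = ldsc_h2(assoc_2, ld_scores, N2, M, n_blocks)
    if require_qc and not (h2_1.qc_pass and h2_2.qc_pass):
        raise ValueError("both traits must pass heritability QC (or pass require_qc=False)")
    if h2_1.h2 <= 0 or h2_2.h2 <= 0:
        raise ValueError("non-positive heritability; rg undefined")

    m1 = assoc_1.merge(ld_scores, on="variant_id")
    m2 = assoc_2.merge(ld_scores, on="variant_id")
    merged = m1.merge(m2, on="variant_id", suffixes=("_1", "_2")).dropna(
        subset=["beta_1", "se_1", "beta_2", "se_2", "ld_score_1"]
    )
    z1 = (merged["beta_1"] / merged["se_1"]).to_numpy(dtype=float)
    z2 = (merged["beta_2"] / merged["se_2"]).to_numpy(dtype=float)
    ell = merged["ld_score_1"].to_numpy(dtype=float)
    x = np.sqrt(N1 * N2) * ell / M
    y = z1 * z2

    def _full(ix_keep: np.ndarray | None) -> float:
        if ix_keep is None:
            xx, yy, ee = x, y, ell
            c1, c2 = (z1**2, z2**2)
        else:
            xx, yy, ee = x[ix_keep], y[ix_keep], ell[ix_keep]
            c1, c2 = z1[ix_keep] ** 2, z2[ix_keep] ** 2
        _, gencov, _ = _two_step_fit(xx, yy, ee)
        _, h1, _ = _two_step_fit(N1 * ee / M, c1, ee)
        _, h2, _ = _two_step_fit(N2 * ee / M, c2, ee)
        denom = np.sqrt(max(h1, 1e-12) * max(h2, 1e-12))
        return gencov / denom

    rg = _full(None)
    blocks = _block_slices(len(merged), n_blocks)
    all_ix = np.arange(len(merged))
    rg_blocks = np.array([_full(np.setdiff1d(all_ix, idx)) for idx in blocks])
    rg_se = _jackknife(rg_blocks)
    clamped = bool(abs(rg) > 1.0)
    rg_out = float(np.clip(rg, -1.0, 1.0))
    p = 2.0 * stats.norm.sf(abs(rg) / rg_se) if rg_se > 0 else 0.0
    return {
        "rg": rg_out,
        "rg_unclamped": float(rg),
        "se": float(rg_se),
        "p": float(min(p, 1.0)),
        "clamped": clamped,
        "h2_1": h2_1.as_dict(),
        "h2_2": h2_2.as_dict(),
        "n_snps": int(len(merged)),
    }
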