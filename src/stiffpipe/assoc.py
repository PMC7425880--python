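"""SNP quality control and the covariate-adjusted additive-dosage association scan.

The association model is ordinary least squares of a log-transformed phenotype
on the expected allele count (dosage in [0, 2]) plus covariates, i.e. an
additive mode of inheritance.  Per-variant Wald tests use the t distribution
with residual degrees of freedom, which at cohort sample sizes is numerically
identical to the normal approximation.

Quality-control gates follow the usual post-imputation filters: minor allele
frequency, imputation info score, Hardy-Weinberg exact-test p-value and call
rate.  The info score here is the dosage-variance ratio
``var(dosage) / (2 p (1 - p))`` — the standard imputation-quality statistic
when per-genotype probabilities are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "QcThresholds",
    "hwe_exact_test",
    "info_score",
    "snp_qc",
    "run_gwas",
    "genomic_inflation",
    "gwas_power",
    "detectable_variance",
    "compare_effect_sizes",
]

#: median of the 1-df chi-square distribution, the null expectation used by
#: the genomic-control inflation factor.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...

SUMSTATS_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "EA",
    "OA",
    "EAF",
    "info",
    "phenotype",
    "beta",
    "se",
    "p",
    "n",
]


@dataclass(frozen=True)
class QcThresholds:
    """Post-imputation SNP filters.

    Defaults: MAF >= 0.01, info >= 0.5, HWE exact p >= 1e-6 and call
    rate >= 97%.
    """

    maf_min: float = 0.01
    info_min: float = 0.5
    hwe_p_min: float = 1e-6
    call_rate_min: float = 0.97

    def __post_init__(self) -> None:
        for name in ("maf_min", "info_min", "hwe_p_min", "call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def _hwe_het_distribution(n_rare: int, n_genotypes: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Given the number of rare-allele copies and the number of genotyped
    individuals, return (supported heterozygote counts, probabilities) of the
    exact conditional (Levene-Haldane) distribution, computed by the stable
    mode-anchored recurrence.
    """
    n_common = 2 * n_genotypes - n_rare
    # heterozygote count shares parity with the rare allele count
    h_min = n_rare % 2
    h_max = min(n_rare, n_common)
    hs = np.arange(h_min, h_max + 1, 2)
    probs = np.empty(hs.size)

    # start near the distributional mode to avoid under/overflow
    mode = int(round(n_rare * n_common / (2.0 * n_genotypes - 1.0)))
    if (mode - h_min) % 2 != 0:
        mode += 1
    mode = min(max(mode, h_min), h_max)
    i_mode = (mode - h_min) // 2
    probs[i_mode] = 1.0
    # downward: P(h-2) = P(h) * h*(h-1) / (4 * nAA(h-2+... ) ) via genotype counts
    for i in range(i_mode, 0, -1):
        h = hs[i]
        n_aa = (n_rare - h) / 2.0  # rare homozygotes at het count h
        n_bb = (n_common - h) / 2.0
        probs[i - 1] = probs[i] * h * (h - 1.0) / (4.0 * (n_aa + 1.0) * (n_bb + 1.0))
    # upward: P(h+2) = P(h) * 4*nAA(h)*nBB(h) / ((h+2)(h+1))
    for i in range(i_mode, hs.size - 1):
        h = hs[i]
        n_aa = (n_rare - h) / 2.0
        n_bb = (n_common - h) / 2.0
        probs[i + 1] = probs[i] * 4.0 * n_aa * n_bb / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    return hs, probs


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional test for Hardy-Weinberg equilibrium.

    Parameters are the three genotype counts (either homozygote first).  The
    p-value is the total probability of all heterozygote counts — with the
    observed allele counts held fixed — whose conditional probability does not
    exceed that of the observed count.  Monomorphic variants return 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_a = 2 * n_aa + n_ab
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    hs, probs = _hwe_het_distribution(n_rare, n)
    p_obs = probs[np.searchsorted(hs, n_ab)]
    # tolerance guards against ties lost to floating-point rounding
    p = float(probs[probs <= p_obs * (1.0 + 1e-10)].sum())
    return min(p, 1.0)


def info_score(dosages: np.ndarray) -> float:
    """Imputation-quality statistic for one variant.

    Ratio of the empirical dosage variance to the binomial variance
    ``2 p (1 - p)`` implied by the estimated allele frequency ``p``; clipped
    to (0, 1].  Monomorphic variants (frequency 0 or 1) have no defined info
    score and return NaN.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < 2:
        raise ValueError("need at least two non-missing dosages")
    p_hat = d.mean() / 2.0
    denom = 2.0 * p_hat * (1.0 - p_hat)
    if denom == 0.0:
        return float("nan")
    ratio = d.var(ddof=0) / denom
    if ratio <= 0.0:
        return float(np.finfo(float).tiny)
    return float(min(ratio, 1.0))


def _hard_call_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """Round dosages to the nearest genotype and count (0, 1, 2) classes."""
    d = dosages[~np.isnan(dosages)]
    g = np.clip(np.rint(d), 0, 2).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def snp_qc(
    variants: pd.DataFrame,
    dosages: np.ndarray,
    thresholds: QcThresholds | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the post-imputation SNP filters.

    Parameters
    ----------
    variants
        Table with at least a ``variant_id`` column; ``EAF`` and ``info``
        columns are used when present, otherwise both are computed from the
        dosages.
    dosages
        samples x variants dosage matrix aligned with ``variants`` rows.
    thresholds
        Filter thresholds; defaults to :class:`QcThresholds`.

    Returns
    -------
    kept : list of variant ids passing every filter.
    report : per-variant DataFrame with the measured statistics, the first
        failing filter (``first_fail``) and all failing filters
        (``all_fails``, comma-joined; empty string when passing).

    The gate order (MAF, info, HWE, call rate) only affects ``first_fail``;
    the kept set is the conjunction of all four and is therefore
    order-independent and idempotent.
    """
    thresholds = thresholds or QcThresholds()
    dosages = np.asarray(dosages, dtype=float)
    n_samples = dosages.shape[0]
    rows = []
    for j, rec in enumerate(variants.itertuples(index=False)):
        d = dosages[:, j]
        miss = np.isnan(d)
        call_rate = 1.0 - miss.mean() if n_samples else 0.0
        if hasattr(rec, "EAF") and not pd.isna(rec.EAF):
            eaf = float(rec.EAF)
        else:
            eaf = float(np.nanmean(d) / 2.0)
        maf = min(eaf, 1.0 - eaf)
        if hasattr(rec, "info") and not pd.isna(rec.info):
            info = float(rec.info)
        else:
            info = info_score(d)
        hwe_p = hwe_exact_test(*_hard_call_counts(d))
        fails = []
        if maf < thresholds.maf_min:
            fails.append("MAF")
        if np.isnan(info) or info < thresholds.info_min:
            fails.append("info")
        if hwe_p < thresholds.hwe_p_min:
            fails.append("HWE")
        if call_rate < thresholds.call_rate_min:
            fails.append("call_rate")
        rows.append(
            {
                "variant_id": rec.variant_id,
                "maf": maf,
                "info": info,
                "hwe_p": hwe_p,
                "call_rate": call_rate,
                "first_fail": fails[0] if fails else "",
                "all_fails": ",".join(fails),
                "kept": not fails,
            }
        )
    report = pd.DataFrame(rows)
    kept = report.loc[report["kept"], "variant_id"].tolist()
    return kept, report


def _residualize(m: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``m`` after OLS on ``design``."""
    coef, *_ = np.linalg.lstsq(design, m, rcond=None)
    return m - design @ coef


def run_gwas(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    variants: pd.DataFrame,
    phenotype_name: str = "phenotype",
) -> pd.DataFrame:
    """Per-variant additive-dosage association scan.

    For each variant, fits OLS of ``phenotype`` on ``[1, covariates, dosage]``
    over the complete cases of that variant and reports the dosage
    coefficient, its standard error, the two-sided Wald p-value from the t
    distribution with residual degrees of freedom, and the sample count used.

    The per-variant fit is computed by projecting dosage and phenotype on the
    covariate design (Frisch-Waugh-Lovell), which is algebraically identical
    to the full joint fit.  Variants whose residualized dosage is numerically
    constant (rank-deficient design) are skipped.

    Returns a summary-statistics DataFrame with the interchange columns
    ``variant_id, chrom, pos, EA, OA, EAF, info, phenotype, beta, se, p, n``.
    """
    y_all = np.asarray(phenotype, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    n_total, n_var = dosages.shape
    if y_all.shape[0] != n_total:
        raise ValueError("phenotype length does not match dosage rows")
    if covariates is None:
        cov_all = np.empty((n_total, 0))
    else:
        cov_all = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov_all.shape[0] != n_total:
            cov_all = cov_all.T
    n_cov = cov_all.shape[1]

    base_mask = ~np.isnan(y_all) & ~np.isnan(cov_all).any(axis=1)
    records: list[dict] = []
    tiny = np.finfo(float).tiny

    # fast path: variants with no missing dosages share one design projection
    dos_missing = np.isnan(dosages).any(axis=0)
    idx_fast = np.flatnonzero(~dos_missing)
    idx_slow = np.flatnonzero(dos_missing)

    def _fit_block(g_block: np.ndarray, y: np.ndarray, design: np.ndarray, cols: np.ndarray) -> None:
        n = y.shape[0]
        df = n - (design.shape[1] + 1)
        if df < 1:
            raise ValueError("fewer complete cases than predictors + 2")
        g_res = _residualize(g_block, design)
        y_res = _residualize(y[:, None], design)[:, 0]
        gg = np.einsum("ij,ij->j", g_res, g_res)
        ok = gg > n * 1e-12
        gy = y_res @ g_res
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(ok, gy / np.where(ok, gg, 1.0), np.nan)
            rss = y_res @ y_res - beta * gy
            rss = np.maximum(rss, 0.0)
            sigma2 = rss / df
            se = np.sqrt(np.where(ok, sigma2 / np.where(ok, gg, 1.0), np.nan))
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        p = np.clip(p, tiny, 1.0)
        for k, j in enumerate(cols):
            if not ok[k]:
                records.append(_record(variants, j, phenotype_name, np.nan, np.nan, np.nan, n, "rank_deficient"))
            else:
                records.append(_record(variants, j, phenotype_name, beta[k], se[k], p[k], n))

    if idx_fast.size:
        mask = base_mask
        design = np.column_stack([np.ones(mask.sum()), cov_all[mask]])
        _fit_block(dosages[np.ix_(mask, idx_fast)], y_all[mask], design, idx_fast)
    for j in idx_slow:
        mask = base_mask & ~np.isnan(dosages[:, j])
        if mask.sum() < n_cov + 3:
            records.append(_record(variants, j, phenotype_name, np.nan, np.nan, np.nan, int(mask.sum()), "too_few"))
            continue
        design = np.column_stack([np.ones(mask.sum()), cov_all[mask]])
        _fit_block(dosages[mask][:, [j]], y_all[mask], design, np.array([j]))

    out = pd.DataFrame(records)
    # restore input variant order
    order = {v: i for i, v in enumerate(variants["variant_id"])}
    out = out.sort_values("variant_id", key=lambda s: s.map(order), kind="stable").reset_index(drop=True)
    return out


def _record(variants, j, phen, beta, se, p, n, skip_reason=""):
    rec = variants.iloc[j]
    return {
        "variant_id": rec["variant_id"],
        "chrom": rec.get("chrom", "1"),
        "pos": int(rec.get("pos", 0)),
        "EA": rec.get("EA", "A"),
        "OA": rec.get("OA", "B"),
        "EAF": float(rec.get("EAF", np.nan)),
        "info": float(rec.get("info", np.nan)),
        "phenotype": phen,
        "beta": beta,
        "se": se,
        "p": p,
        "n": int(n),
        "skip_reason": skip_reason,
    }


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic-control inflation factor lambda.

    Median of the 1-df chi-square quantiles corresponding to the observed
    p-values, divided by the null median 0.4549; lambda near 1 indicates no
    systematic inflation of the test statistics.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def _noncentrality(n: float, q2: float, ncp: str) -> float:
    if ncp == "linear":
        return n * q2
    if ncp == "exact":
        return n * q2 / (1.0 - q2)
    raise ValueError("ncp must be 'linear' or 'exact'")


def gwas_power(n: int, q2: float, alpha: float, ncp: str = "linear") -> float:
    """Power of a 1-df additive association test.

    Parameters
    ----------
    n
        Sample size.
    q2
        Fraction of phenotypic variance explained by the variant (0 <= q2 < 1).
    alpha
        Two-sided significance level, e.g. 5e-8 for genome-wide significance.
    ncp
        Noncentrality convention: ``"linear"`` uses ``n * q2`` (the common
        small-effect form used in GWAS power statements), ``"exact"`` uses
        ``n * q2 / (1 - q2)``.  The two are indistinguishable for the
        sub-percent variance fractions relevant here.

    Returns the upper-tail probability of a noncentral 1-df chi-square beyond
    the central (1 - alpha) quantile.
    """
    if not 0.0 <= q2 < 1.0:
        raise ValueError("q2 must lie in [0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if q2 == 0.0:
        return float(alpha)
    crit = stats.chi2.isf(alpha, 1)
    return float(stats.ncx2.sf(crit, 1, _noncentrality(n, q2, ncp)))


def detectable_variance(n: int, power: float, alpha: float, ncp: str = "linear") -> float:
    """Smallest variance fraction detectable with the requested power.

    Inverts :func:`gwas_power` in ``q2`` by monotone root-finding; the
    composition ``gwas_power(n, detectable_variance(n, power, alpha), alpha)``
    returns ``power`` to numerical precision.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if not alpha < power < 1.0:
        raise ValueError("power target must lie in (alpha, 1)")
    f = lambda q2: gwas_power(n, q2, alpha, ncp) - power
    return float(optimize.brentq(f, 1e-12, 1.0 - 1e-9, xtol=1e-14, rtol=1e-14))


def compare_effect_sizes(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Two-sample z test for equality of (standardized) effect sizes.

    ``z = (b1 - b2) / sqrt(se1^2 + se2^2)`` with a two-sided standard-normal
    p-value.  Callers comparing effects across phenotypes are expected to pass
    standardized betas and standard errors.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.hypot(se1, se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))
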