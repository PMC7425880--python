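"""Seedable synthetic cohorts with the statistical structure of a PWV GWAS.

The generator emulates, at configurable scale, the features the downstream
analysis relies on:

- dosage genotypes in LD blocks on one synthetic chromosome (10 kb spacing,
  so a +/-500 kb locus window spans 101 variants), with allele frequencies
  >= 0.01 and imputation-style info scores;
- a log-normal systolic blood pressure (SBP) driven by age, sex and a panel
  of medium-effect SNPs;
- three correlated log-normal PWV modes causally downstream of log-SBP
  (default causal effects 0.612 / 0.481 / 0.715 for baPWV / cfPWV / bfPWV on
  the log scale), with direct genetic effects, a shared latent stiffness
  factor calibrated so the SBP-partialled cross-mode correlations land near
  0.37-0.51, and a polygenic component giving one mode (baPWV) a target
  heritability of 0.28;
- duplicate raw measurements per mode, a configured fraction of which
  violates the measurement-discard thresholds;
- two-sample summary-statistic sets for Mendelian-randomization tests and
  block-LD polygenic summary statistics for LD-score-regression tests.

LD uses a latent-Gaussian threshold model (one factor per block), the
simplest structure with controllable blockwise correlation; the realized
dosage r^2 is below the latent correlation, so block r^2 targets are
approximate.  All randomness flows through one explicitly passed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phenoprep import DISCARD_THRESHOLDS, PWV_MODES

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_genotypes",
    "inject_imputation_noise",
    "simulate_phenotypes",
    "make_two_sample_sumstats",
    "simulate_polygenic_sumstats",
]

VARIANT_SPACING_BP = 10_000

#: default causal effect of log-SBP on each log-PWV mode
DEFAULT_THETA = {"baPWV": 0.612, "cfPWV": 0.481, "bfPWV": 0.715}

#: SBP-partialled cross-mode correlation targets
PARTIAL_CORR_TARGETS = {("baPWV", "cfPWV"): 0.37, ("baPWV", "bfPWV"): 0.49, ("cfPWV", "bfPWV"): 0.51}


@dataclass
class SimConfig:
    """Cohort-simulation parameters.

    The defaults are the study conditions the generator is meant to emulate:
    a mid-size population cohort (n = 6,000), common variants (MAF 0.05-0.5)
    in LD blocks, causal SBP->PWV effects on the published scale, baPWV
    heritability 0.28.
    """

    n_samples: int = 6_000
    n_variants: int = 2_000
    block_sizes: list[int] | None = None  # default: uniform blocks of 20
    within_block_corr: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_info: float = 1.0
    causal_spec: list[tuple[int, str, float]] | None = None
    theta_sbp_to_pwv: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THETA))
    h2_target: float = 0.28
    h2_target_mode: str = "baPWV"
    seed: int = 0

    # cohort structure
    age_range: tuple[float, float] = (40.0, 79.0)
    n_sbp_snps: int = 60
    sbp_h2: float = 0.30  # genetic fraction of the covariate-free log-SBP residual
    polygenic_fraction: float = 0.10  # fraction of variants carrying the h2 background
    shared_factor_scale: float = 1.0  # 0 disables the shared stiffness factor
    measurement_violation_rate: float = 0.03
    second_missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_variants < 1:
            raise ValueError("need n_samples >= 2 and n_variants >= 1")
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 < self.target_info <= 1.0:
            raise ValueError("target_info must lie in (0, 1]")
        if not 0.0 <= self.h2_target < 1.0:
            raise ValueError("h2_target must lie in [0, 1)")
        if self.block_sizes is None:
            size = min(20, self.n_variants)
            full, rem = divmod(self.n_variants, size)
            self.block_sizes = [size] * full + ([rem] if rem else [])
        if sum(self.block_sizes) != self.n_variants:
            raise ValueError("block sizes must sum to n_variants")


@dataclass
class GroundTruth:
    """True simulation parameters for downstream recovery tests."""

    effects: pd.DataFrame  # variant_id, phenotype, beta (log scale)
    theta: dict[str, float]
    h2: dict[str, float]
    variance_components: dict


def simulate_genotypes(config: SimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw dosages in LD blocks via the latent-Gaussian threshold model.

    Each haplotype allele is the indicator that a block-correlated standard
    normal falls below the allele-frequency quantile; the dosage is the sum
    of two independent haplotypes, so hard genotypes are in Hardy-Weinberg
    equilibrium by construction.  Positions sit on one synthetic chromosome
    at fixed 10 kb spacing.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_variants
    freqs = rng.uniform(*config.maf_range, size=m)
    thresholds = stats.norm.ppf(freqs)
    r = config.within_block_corr
    dosage = np.zeros((n, m))
    col = 0
    for size in config.block_sizes:
        sl = slice(col, col + size)
        for _hap in range(2):
            f = rng.standard_normal((n, 1))
            e = rng.standard_normal((n, size))
            latent = np.sqrt(r) * f + np.sqrt(1.0 - r) * e
            dosage[:, sl] += (latent < thresholds[sl]).astype(float)
        col += size
    variants = pd.DataFrame(
        {
            "variant_id": [f"snp{j + 1:05d}" for j in range(m)],
            "chrom": "1",
            "pos": VARIANT_SPACING_BP * (np.arange(m) + 1),
            "EA": "A",
            "OA": "G",
            "EAF": dosage.mean(axis=0) / 2.0,
            "info": 1.0,
        }
    )
    return dosage, variants


def inject_imputation_noise(
    dosages: np.ndarray,
    target_info: float | np.ndarray,
    seed: int,
) -> np.ndarray:
    """Degrade dosages so the realized info statistic approaches a target.

    The dosage is shrunk toward its mean ``2p`` and perturbed with Gaussian
    noise; the shrinkage and noise shares are chosen so the total variance is
    ``target_info * 2p(1-p)`` before clipping to [0, 2].  ``target_info`` may
    be a scalar or a per-variant array; a target of exactly 1 returns the
    input unchanged.
    """
    d = np.asarray(dosages, dtype=float)
    target = np.broadcast_to(np.asarray(target_info, dtype=float), (d.shape[1],)).copy()
    if np.any((target <= 0) | (target > 1)):
        raise ValueError("target_info must lie in (0, 1]")
    if np.all(target == 1.0):
        return d.copy()
    rng = np.random.default_rng(seed)
    p = d.mean(axis=0) / 2.0
    binom_var = 2.0 * p * (1.0 - p)
    var_d = d.var(axis=0)
    # fraction of the target variance carried by fresh noise; scaled down as
    # the target approaches 1 so clipping to [0, 2] does not erode variance
    noise_share = 0.25 * (1.0 - target)
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = np.sqrt(np.where(var_d > 0, target * (1.0 - noise_share) * binom_var / np.where(var_d > 0, var_d, 1.0), 0.0))
    noise_sd = np.sqrt(target * noise_share * binom_var)
    out = 2.0 * p + shrink * (d - 2.0 * p) + noise_sd * rng.standard_normal(d.shape)
    keep = target == 1.0
    out[:, keep] = d[:, keep]
    return np.clip(out, 0.0, 2.0)


def _default_causal_spec(config: SimConfig) -> list[tuple[int, str, float]]:
    """Plant two direct-effect SNPs per PWV mode in well-separated blocks."""
    m = config.n_variants
    # spread across the chromosome, away from index 0 (SBP panel start)
    picks = [int(round(f * (m - 1))) for f in (0.15, 0.30, 0.45, 0.60, 0.75, 0.90)]
    effects = [
        ("baPWV", 0.05),
        ("baPWV", -0.04),
        ("cfPWV", 0.06),
        ("cfPWV", -0.05),
        ("bfPWV", 0.08),
        ("bfPWV", -0.06),
    ]
    return [(idx, mode, beta) for idx, (mode, beta) in zip(picks, effects)]


def _genetic_component(dosages: np.ndarray, idx: np.ndarray, betas: np.ndarray) -> np.ndarray:
    return dosages[:, idx] @ betas


def _partial_corr_loadings() -> dict[str, float]:
    """One-factor loadings reproducing the pairwise partial-correlation targets.

    With residual-standardized loadings u_i, the implied partial correlation
    of modes i and j (given SBP and the covariates) is u_i * u_j; three
    pairwise targets determine the three loadings in closed form.
    """
    t = PARTIAL_CORR_TARGETS
    u_ba = np.sqrt(t[("baPWV", "cfPWV")] * t[("baPWV", "bfPWV")] / t[("cfPWV", "bfPWV")])
    return {"baPWV": float(u_ba), "cfPWV": float(t[("baPWV", "cfPWV")] / u_ba), "bfPWV": float(t[("baPWV", "bfPWV")] / u_ba)}


# per-mode structural defaults (log scale)
_MODE_MEANS = {"baPWV": np.log(10.41), "cfPWV": np.log(18.28), "bfPWV": np.log(18.28)}
_MODE_AGE_EFFECTS = {"baPWV": 0.0065, "cfPWV": 0.0065, "bfPWV": 0.007}
_MODE_SEX_EFFECTS = {"baPWV": -0.06, "cfPWV": 0.03, "bfPWV": 0.09}
#: residual variance of each log mode beyond age, sex and the SBP path
_MODE_RESIDUAL_VAR = {"baPWV": 0.04, "cfPWV": 0.07, "bfPWV": 0.10}

_SBP_MEAN_LOG = np.log(128.94)
_SBP_LOG_VAR = 0.0169  # (16.94 / 128.94)^2, log-scale variance of SBP
_SBP_AGE_EFFECT = 0.004
_SBP_SEX_EFFECT = 0.03
_DBP_MEAN_LOG = np.log(75.42)


def simulate_phenotypes(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the raw phenotype table and its ground truth.

    Structural model (log scale)::

        logSBP   = mu + b_age*age~ + b_sex*sex~ + g_sbp + e_sbp
        logPWV_i = mu_i + b_age_i*age~ + b_sex_i*sex~ + theta_i*(logSBP - mu)
                   + g_i + l_i*F + e_i

    where ``F`` is a shared latent stiffness factor whose loadings are set in
    closed form so the SBP-partialled cross-mode correlations land on the
    0.37-0.51 targets, ``g_sbp`` sums a panel of medium-effect SNPs, and
    ``g_i`` combines the planted direct effects of ``causal_spec`` with a
    polygenic background scaled so the designated mode reaches
    ``h2_target`` (heritability measured against the age/sex-adjusted
    variance).  Raw duplicate measurements per mode are produced with
    measurement error such that a configured fraction violates the
    measurement-discard thresholds.

    Raises ``ValueError`` when the variance bookkeeping would require a
    negative residual noise variance.
    """
    rng = np.random.default_rng(config.seed + 1)
    n, m = dosages.shape
    if m != len(variants):
        raise ValueError("variant table does not match dosage columns")
    freqs = dosages.mean(axis=0) / 2.0

    age = rng.uniform(*config.age_range, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)  # 1 = male
    age_c = age - age.mean()
    sex_c = sex - 0.5
    var_age = np.ptp(config.age_range) ** 2 / 12.0

    # --- SBP ---------------------------------------------------------------
    sbp_resid_var = _SBP_LOG_VAR - _SBP_AGE_EFFECT**2 * var_age - _SBP_SEX_EFFECT**2 * 0.25
    if sbp_resid_var <= 0:
        raise ValueError("SBP variance bookkeeping is non-positive")
    var_g_sbp = config.sbp_h2 * sbp_resid_var
    var_e_sbp = sbp_resid_var - var_g_sbp

    causal_spec = config.causal_spec if config.causal_spec is not None else _default_causal_spec(config)
    for idx, mode, _beta in causal_spec:
        if not 0 <= idx < m:
            raise ValueError(f"causal variant index {idx} outside the panel")
        if mode not in (*PWV_MODES, "logSBP"):
            raise ValueError(f"unknown causal phenotype {mode!r}")
    spec_by_mode: dict[str, list[tuple[int, float]]] = {ph: [] for ph in (*PWV_MODES, "logSBP")}
    for idx, mode, beta in causal_spec:
        spec_by_mode[mode].append((idx, beta))

    occupied = {idx for idx, _, _ in causal_spec}
    n_sbp = min(config.n_sbp_snps, m)
    sbp_idx = np.array([j for j in np.linspace(0, m - 1, n_sbp * 2, dtype=int) if j not in occupied][:n_sbp])
    het = 2.0 * freqs[sbp_idx] * (1.0 - freqs[sbp_idx])
    signs = rng.choice([-1.0, 1.0], size=sbp_idx.size)
    sbp_betas = signs * np.sqrt(var_g_sbp / np.maximum(het, 1e-6) / sbp_idx.size)
    extra_sbp = spec_by_mode["logSBP"]
    if extra_sbp:
        sbp_idx = np.concatenate([sbp_idx, [i for i, _ in extra_sbp]])
        sbp_betas = np.concatenate([sbp_betas, [b for _, b in extra_sbp]])
    g_sbp = _genetic_component(dosages, sbp_idx, sbp_betas)
    g_sbp -= g_sbp.mean()

    log_sbp = (
        _SBP_MEAN_LOG
        + _SBP_AGE_EFFECT * age_c
        + _SBP_SEX_EFFECT * sex_c
        + g_sbp
        + np.sqrt(var_e_sbp) * rng.standard_normal(n)
    )

    # --- PWV modes ---------------------------------------------------------
    loadings_u = _partial_corr_loadings()
    factor = rng.standard_normal(n)
    theta = dict(config.theta_sbp_to_pwv)
    log_pwv: dict[str, np.ndarray] = {}
    h2_true: dict[str, float] = {}
    effect_rows = [
        {"variant_id": variants["variant_id"].iloc[j], "phenotype": "logSBP", "beta": float(b)}
        for j, b in zip(sbp_idx, sbp_betas)
    ]
    components: dict[str, dict] = {
        "logSBP": {"var_genetic": float(var_g_sbp), "var_noise": float(var_e_sbp), "var_age": _SBP_AGE_EFFECT**2 * var_age}
    }

    for mode in PWV_MODES:
        v_i = _MODE_RESIDUAL_VAR[mode]
        l_i = config.shared_factor_scale * loadings_u[mode] * np.sqrt(v_i)
        # planted direct effects
        idx_d = np.array([i for i, _ in spec_by_mode[mode]], dtype=int)
        betas_d = np.array([b for _, b in spec_by_mode[mode]], dtype=float)
        var_spec = float(np.sum(2.0 * freqs[idx_d] * (1.0 - freqs[idx_d]) * betas_d**2)) if idx_d.size else 0.0

        # polygenic background only for the designated heritability mode
        var_poly = 0.0
        poly_idx = np.array([], dtype=int)
        poly_betas = np.array([])
        if mode == config.h2_target_mode and config.h2_target > 0:
            adj_var = theta[mode] ** 2 * sbp_resid_var + v_i
            var_poly = config.h2_target * adj_var - theta[mode] ** 2 * var_g_sbp - var_spec
            if var_poly < 0:
                raise ValueError("h2 target unreachable: direct + SBP-path genetic variance already exceeds it")
            candidates = np.array([j for j in range(m) if j not in occupied and j not in set(sbp_idx)])
            n_poly = max(1, int(round(config.polygenic_fraction * m)))
            poly_idx = rng.choice(candidates, size=min(n_poly, candidates.size), replace=False)
            het_p = 2.0 * freqs[poly_idx] * (1.0 - freqs[poly_idx])
            poly_betas = rng.choice([-1.0, 1.0], size=poly_idx.size) * np.sqrt(
                var_poly / np.maximum(het_p, 1e-6) / poly_idx.size
            )

        var_noise = v_i - l_i**2 - var_spec - var_poly
        if var_noise <= 0:
            raise ValueError(f"non-positive residual variance for {mode}: {var_noise:.4g}")

        g_direct = np.zeros(n)
        if idx_d.size:
            g_direct += _genetic_component(dosages, idx_d, betas_d)
        if poly_idx.size:
            g_direct += _genetic_component(dosages, poly_idx, poly_betas)
        g_direct -= g_direct.mean() if g_direct.any() else 0.0

        log_pwv[mode] = (
            _MODE_MEANS[mode]
            + _MODE_AGE_EFFECTS[mode] * age_c
            + _MODE_SEX_EFFECTS[mode] * sex_c
            + theta[mode] * (log_sbp - _SBP_MEAN_LOG - _SBP_AGE_EFFECT * age_c - _SBP_SEX_EFFECT * sex_c)
            + g_direct
            + l_i * factor
            + np.sqrt(var_noise) * rng.standard_normal(n)
        )
        adj_var = theta[mode] ** 2 * sbp_resid_var + v_i
        h2_true[mode] = float((theta[mode] ** 2 * var_g_sbp + var_spec + var_poly) / adj_var)
        components[mode] = {
            "var_residual": v_i,
            "var_factor": float(l_i**2),
            "var_direct": var_spec,
            "var_polygenic": float(var_poly),
            "var_noise": float(var_noise),
        }
        for j, b in zip(idx_d, betas_d):
            effect_rows.append({"variant_id": variants["variant_id"].iloc[j], "phenotype": mode, "beta": float(b)})
        for j, b in zip(poly_idx, poly_betas):
            effect_rows.append({"variant_id": variants["variant_id"].iloc[j], "phenotype": mode, "beta": float(b)})

    # --- raw duplicate measurements ----------------------------------------
    table = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:06d}" for i in range(n)],
            "age": age,
            "sex": sex.astype(int),
            "SBP": np.exp(log_sbp),
            "DBP": np.exp(_DBP_MEAN_LOG + 0.6 * (log_sbp - _SBP_MEAN_LOG) + 0.07 * rng.standard_normal(n)),
        }
    )
    for mode in PWV_MODES:
        value = np.exp(log_pwv[mode])
        thr = DISCARD_THRESHOLDS[mode]
        violate = rng.random(n) < config.measurement_violation_rate
        second_missing = rng.random(n) < config.second_missing_rate
        violate &= ~second_missing
        d = rng.normal(0.0, thr / 6.0, size=n)
        d = np.clip(d, -0.9 * thr, 0.9 * thr)
        d_viol = rng.choice([-1.0, 1.0], size=n) * thr * (1.05 + np.abs(rng.normal(0.0, 0.5, size=n)))
        d = np.where(violate, d_viol, d)
        if mode == "bfPWV":  # averaged mode: centre the pair on the true value
            m1 = value - d / 2.0
            m2 = value + d / 2.0
        else:
            m1 = value
            m2 = value + d
        m2 = np.where(second_missing, np.nan, m2)
        table[f"{mode}_m1"] = np.maximum(m1, 0.1)
        table[f"{mode}_m2"] = np.where(np.isnan(m2), np.nan, np.maximum(m2, 0.1))

    truth = GroundTruth(
        effects=pd.DataFrame(effect_rows),
        theta=theta,
        h2=h2_true,
        variance_components=components,
    )
    return table, truth


def make_two_sample_sumstats(
    J: int,
    theta: float,
    pleiotropy_sd: float = 0.0,
    seed: int = 0,
    beta_x_mean: float = 0.04,
    beta_x_sd: float = 0.01,
    se_x: float = 0.005,
    se_y: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Two-sample summary statistics for Mendelian-randomization tests.

    True exposure effects are drawn around ``beta_x_mean`` with random signs;
    outcome effects are ``theta * beta_x + pleiotropy`` with independent
    estimation noise in both samples.  Returns the instrument table
    (``variant_id, beta_x, se_x, beta_y, se_y``) and the ground truth.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=J)
    bx_true = signs * np.abs(rng.normal(beta_x_mean, beta_x_sd, size=J))
    pleio = rng.normal(0.0, pleiotropy_sd, size=J) if pleiotropy_sd > 0 else np.zeros(J)
    by_true = theta * bx_true + pleio
    table = pd.DataFrame(
        {
            "variant_id": [f"iv{j + 1:04d}" for j in range(J)],
            "beta_x": bx_true + rng.normal(0.0, se_x, size=J),
            "se_x": se_x,
            "beta_y": by_true + rng.normal(0.0, se_y, size=J),
            "se_y": se_y,
        }
    )
    truth = {"theta": theta, "beta_x_true": bx_true, "pleiotropy": pleio}
    return table, truth


def simulate_polygenic_sumstats(
    M: int = 20_000,
    N: int = 6_000,
    h2: float = 0.28,
    block_size: int = 50,
    block_corrs: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    seed: int = 0,
    rg: float | None = None,
    h2_2: float | None = None,
    N2: int | None = None,
    confounding_var: float = 0.0,
) -> dict:
    """Block-LD polygenic summary statistics for LD-score-regression tests.

    Standardized per-variant effects are infinitesimal, ``beta_j ~ N(0,
    h2/M)``; within each block of ``block_size`` variants the genotype
    correlation is an equicorrelation drawn cyclically from ``block_corrs``
    (a spread of correlations is required so the LD scores vary across
    variants — with constant scores the regression slope and intercept are
    not separable).  The marginal z-scores are drawn exactly from their
    sampling distribution, ``z = sqrt(N) R beta + MVN(0, R)``, so
    ``E[chi2_j] = 1 + N h2 l_j / M`` with the closed-form LD score
    ``l_j = 1 + (block_size - 1) rho_b^2`` in a block with correlation
    ``rho_b``.

    When ``rg`` is given a second trait is generated with per-variant effects
    correlated at ``rg`` (heritability ``h2_2``, sample size ``N2``; both
    default to the first trait's) and independent estimation noise (no sample
    overlap).  ``confounding_var`` adds independent N(0, confounding_var)
    noise to each z-score, which raises the regression intercept by exactly
    that amount while leaving the slope unchanged.

    Returns a dict with ``sumstats`` (per-trait list of DataFrames),
    ``ld_scores``, ``variants`` and the true parameters.
    """
    rng = np.random.default_rng(seed)
    if M % block_size:
        raise ValueError("M must be a multiple of block_size")
    n_blocks = M // block_size
    two = rg is not None
    h2_b = h2_2 if h2_2 is not None else h2
    N_b = N2 if N2 is not None else N

    mats = {}
    for rho in set(block_corrs):
        R = (1.0 - rho) * np.eye(block_size) + rho * np.ones((block_size, block_size))
        mats[rho] = (R, np.linalg.cholesky(R), float(1.0 + (block_size - 1) * rho**2))

    sd1 = np.sqrt(h2 / M)
    z1 = np.empty(M)
    z2 = np.empty(M) if two else None
    ell = np.empty(M)
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        R, L, ell_val = mats[block_corrs[b % len(block_corrs)]]
        ell[sl] = ell_val
        if two:
            cov = np.array(
                [
                    [h2 / M, rg * np.sqrt(h2 * h2_b) / M],
                    [rg * np.sqrt(h2 * h2_b) / M, h2_b / M],
                ]
            )
            beta = rng.multivariate_normal([0.0, 0.0], cov, size=block_size)
            z1[sl] = np.sqrt(N) * (R @ beta[:, 0]) + L @ rng.standard_normal(block_size)
            z2[sl] = np.sqrt(N_b) * (R @ beta[:, 1]) + L @ rng.standard_normal(block_size)
        else:
            beta = rng.normal(0.0, sd1, size=block_size)
            z1[sl] = np.sqrt(N) * (R @ beta) + L @ rng.standard_normal(block_size)
    if confounding_var > 0:
        z1 += rng.normal(0.0, np.sqrt(confounding_var), size=M)
        if two:
            z2 += rng.normal(0.0, np.sqrt(confounding_var), size=M)

    variants = pd.DataFrame(
        {
            "variant_id": [f"snp{j + 1:06d}" for j in range(M)],
            "chrom": "1",
            "pos": VARIANT_SPACING_BP * (np.arange(M) + 1),
        }
    )
    ld_scores = pd.DataFrame({"variant_id": variants["variant_id"], "ld_score": ell})

    def _frame(z: np.ndarray, n_eff: int) -> pd.DataFrame:
        se = 1.0 / np.sqrt(n_eff)
        df = variants.copy()
        df["beta"] = z * se
        df["se"] = se
        df["p"] = 2.0 * stats.norm.sf(np.abs(z))
        return df

    out = {
        "sumstats": [_frame(z1, N)] + ([_frame(z2, N_b)] if two else []),
        "ld_scores": ld_scores,
        "variants": variants,
        "truth": {"h2": h2, "h2_2": h2_b if two else None, "rg": rg, "mean_ld_score": float(ell.mean())},
    }
    return out
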