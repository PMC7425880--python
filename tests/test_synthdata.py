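"""Generator properties: LD structure, frequencies, phenotype causal model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stiffpipe import assoc, mr, phenoprep, synthdata


class TestSimulateGenotypes:
    def test_dosages_bounded_and_frequency_on_target(self):
        cfg = synthdata.SimConfig(n_samples=5_000, n_variants=50, maf_range=(0.3, 0.3), seed=1)
        d, v = synthdata.simulate_genotypes(cfg)
        assert d.min() >= 0 and d.max() <= 2
        np.testing.assert_allclose(v["EAF"], 0.3, atol=0.02)

    def test_zero_correlation_blocks_independent(self):
        cfg = synthdata.SimConfig(
            n_samples=4_000, n_variants=20, block_sizes=[20], within_block_corr=0.0, seed=2
        )
        d, _ = synthdata.simulate_genotypes(cfg)
        r2 = np.corrcoef(d, rowvar=False) ** 2
        off = r2[np.triu_indices(20, 1)]
        assert off.mean() < 4.0 / cfg.n_samples

    def test_near_perfect_correlation_limit(self):
        """Dosage r2 approaches 1 as the latent correlation does.

        The threshold model attenuates latent correlation (tetrachoric vs
        dosage scale), so the approach is monotone but not linear.
        """
        prev = 0.0
        for latent, floor in ((0.99, 0.75), (0.999, 0.9), (0.9999, 0.95)):
            cfg = synthdata.SimConfig(
                n_samples=3_000,
                n_variants=10,
                block_sizes=[10],
                within_block_corr=latent,
                maf_range=(0.3, 0.3),
                seed=3,
            )
            d, _ = synthdata.simulate_genotypes(cfg)
            r2 = np.corrcoef(d, rowvar=False) ** 2
            low = r2[np.triu_indices(10, 1)].min()
            assert low > max(floor, prev)
            prev = low

    def test_across_block_ld_near_zero(self):
        cfg = synthdata.SimConfig(
            n_samples=4_000, n_variants=40, block_sizes=[20, 20], within_block_corr=0.8, seed=4
        )
        d, _ = synthdata.simulate_genotypes(cfg)
        r2 = np.corrcoef(d, rowvar=False) ** 2
        across = r2[:20, 20:]
        assert across.mean() < 4.0 / cfg.n_samples

    def test_positions_fixed_spacing(self):
        cfg = synthdata.SimConfig(n_samples=10, n_variants=5, seed=5)
        _, v = synthdata.simulate_genotypes(cfg)
        assert v["pos"].tolist() == [10_000, 20_000, 30_000, 40_000, 50_000]

    def test_seed_reproducibility(self):
        cfg = synthdata.SimConfig(n_samples=200, n_variants=30, seed=6)
        d1, v1 = synthdata.simulate_genotypes(cfg)
        d2, v2 = synthdata.simulate_genotypes(cfg)
        np.testing.assert_array_equal(d1, d2)
        pd.testing.assert_frame_equal(v1, v2)

    def test_bad_block_spec_rejected(self):
        with pytest.raises(ValueError, match="block sizes"):
            synthdata.SimConfig(n_samples=10, n_variants=10, block_sizes=[3, 3])

    def test_hwe_p_uniform_on_hard_calls(self):
        """Exact-test p-values approximately uniform across 1,000 variants."""
        cfg = synthdata.SimConfig(
            n_samples=8_000, n_variants=1_000, block_sizes=[1] * 1_000,
            within_block_corr=0.0, seed=5,
        )
        d, _ = synthdata.simulate_genotypes(cfg)
        ps = np.array(
            [
                assoc.hwe_exact_test(*np.bincount(d[:, j].astype(int), minlength=3))
                for j in range(1_000)
            ]
        )
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestInjectImputationNoise:
    def test_target_one_is_identity(self, rng):
        d = rng.binomial(2, 0.4, (200, 5)).astype(float)
        np.testing.assert_array_equal(synthdata.inject_imputation_noise(d, 1.0, seed=1), d)

    def test_realized_info_tracks_target(self):
        cfg = synthdata.SimConfig(n_samples=5_000, n_variants=100, seed=6)
        d, _ = synthdata.simulate_genotypes(cfg)
        for target, tol in ((0.5, 0.1), (0.99, None)):
            noisy = synthdata.inject_imputation_noise(d, target, seed=2)
            infos = np.array([assoc.info_score(noisy[:, j]) for j in range(100)])
            if tol is not None:
                assert abs(infos.mean() - target) < tol
            else:
                assert infos.min() >= 0.9

    def test_bad_target_rejected(self, rng):
        d = rng.binomial(2, 0.4, (50, 2)).astype(float)
        with pytest.raises(ValueError):
            synthdata.inject_imputation_noise(d, 1.5, seed=1)


class TestSimulatePhenotypes:
    def test_partial_correlations_near_targets(self, small_cohort, clean_pheno):
        z = np.column_stack([clean_pheno["logSBP"], clean_pheno["age"], clean_pheno["sex"]])
        for (a, b), target in synthdata.PARTIAL_CORR_TARGETS.items():
            mask = clean_pheno[f"log{a}"].notna() & clean_pheno[f"log{b}"].notna()
            pc = phenoprep.partial_correlation(
                clean_pheno.loc[mask, f"log{a}"], clean_pheno.loc[mask, f"log{b}"], z[mask]
            )
            assert pc == pytest.approx(target, abs=0.06)

    def test_null_structure_gives_zero_partials(self):
        """No SBP path and no shared factor: cross-mode partials vanish."""
        cfg = synthdata.SimConfig(
            n_samples=3_000,
            n_variants=100,
            theta_sbp_to_pwv={"baPWV": 0.0, "cfPWV": 0.0, "bfPWV": 0.0},
            h2_target=0.0,
            causal_spec=[],
            shared_factor_scale=0.0,
            seed=9,
        )
        d, v = synthdata.simulate_genotypes(cfg)
        raw, _ = synthdata.simulate_phenotypes(d, v, cfg)
        clean = phenoprep.select_measurements(raw)
        clean = phenoprep.log_transform(clean, list(phenoprep.PWV_MODES) + ["SBP"])
        z = np.column_stack([clean["logSBP"], clean["age"], clean["sex"]])
        for a, b in (("baPWV", "cfPWV"), ("baPWV", "bfPWV"), ("cfPWV", "bfPWV")):
            mask = clean[f"log{a}"].notna() & clean[f"log{b}"].notna()
            pc = phenoprep.partial_correlation(
                clean.loc[mask, f"log{a}"], clean.loc[mask, f"log{b}"], z[mask]
            )
            assert abs(pc) < 0.05

    def test_true_h2_matches_target(self, small_cohort):
        cfg, _d, _v, _raw, truth = small_cohort
        assert truth.h2["baPWV"] == pytest.approx(cfg.h2_target, abs=1e-9)

    def test_gwas_recovers_planted_effect(self):
        """A variant with direct effect 0.05: adjusted scan estimate within 2 SE."""
        cfg = synthdata.SimConfig(
            n_samples=10_000,
            n_variants=200,
            causal_spec=[(50, "cfPWV", 0.05)],
            h2_target=0.0,
            seed=10,
        )
        d, v = synthdata.simulate_genotypes(cfg)
        raw, _ = synthdata.simulate_phenotypes(d, v, cfg)
        clean = phenoprep.select_measurements(raw)
        clean = phenoprep.log_transform(clean, ["cfPWV", "SBP"])
        covars = np.column_stack([clean["sex"], clean["age"], clean["logSBP"]])
        res = assoc.run_gwas(
            d[:, [50]], clean["logcfPWV"].to_numpy(), covars, v.iloc[[50]].reset_index(drop=True)
        )
        assert abs(res["beta"].iloc[0] - 0.05) < 2 * res["se"].iloc[0]

    def test_ivw_recovers_causal_theta(self):
        """SBP-instrument IVW recovers each theta within 2 SE at n = 10,000."""
        cfg = synthdata.SimConfig(n_samples=10_000, n_variants=500, seed=11)
        d, v = synthdata.simulate_genotypes(cfg)
        raw, truth = synthdata.simulate_phenotypes(d, v, cfg)
        clean = phenoprep.select_measurements(raw)
        clean = phenoprep.log_transform(clean, list(phenoprep.PWV_MODES) + ["SBP"])
        covars = np.column_stack([clean["sex"], clean["age"]])
        sbp_ids = truth.effects.loc[truth.effects["phenotype"] == "logSBP", "variant_id"]
        idx = v.index[v["variant_id"].isin(sbp_ids)].to_numpy()
        exposure = assoc.run_gwas(d[:, idx], clean["logSBP"].to_numpy(), covars, v.iloc[idx].reset_index(drop=True))
        for mode in phenoprep.PWV_MODES:
            y = clean[f"log{mode}"].to_numpy()
            outcome = assoc.run_gwas(d[:, idx], y, covars, v.iloc[idx].reset_index(drop=True))
            ins = exposure.rename(columns={"beta": "beta_x", "se": "se_x"})[
                ["variant_id", "beta_x", "se_x"]
            ]
            res = mr.ivw(mr.attach_outcome(ins, outcome))
            assert abs(res.estimate - truth.theta[mode]) < 2.5 * res.se

    def test_variance_bookkeeping_error_raised(self):
        cfg = synthdata.SimConfig(n_samples=100, n_variants=50, h2_target=0.9, seed=12)
        d, v = synthdata.simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="residual|unreachable"):
            synthdata.simulate_phenotypes(d, v, cfg)

    def test_seed_reproducibility(self):
        cfg = synthdata.SimConfig(n_samples=300, n_variants=100, seed=13)
        d, v = synthdata.simulate_genotypes(cfg)
        r1, t1 = synthdata.simulate_phenotypes(d, v, cfg)
        r2, t2 = synthdata.simulate_phenotypes(d, v, cfg)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(t1.effects, t2.effects)


class TestTwoSampleSumstats:
    def test_null_theta_ivw_covers_zero(self):
        tab, _ = synthdata.make_two_sample_sumstats(50, 0.0, seed=20)
        res = mr.ivw(tab)
        assert abs(res.estimate) < 2 * res.se

    def test_recovery_and_pleiotropy_cases_covered_in_mr_suite(self):
        tab, truth = synthdata.make_two_sample_sumstats(49, 0.6, seed=21)
        assert len(tab) == 49
        assert truth["theta"] == 0.6
        assert (tab["se_x"] > 0).all() and (tab["se_y"] > 0).all()

    def test_j_zero_rejected(self):
        with pytest.raises(ValueError):
            synthdata.make_two_sample_sumstats(0, 0.5)
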