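"""HWE exact test, info score, SNP QC, the GWAS scan and its diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from stiffpipe import assoc, synthdata


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Brute-force exact HWE p via log-factorial enumeration.

    Independent of the recurrence in the implementation: the conditional
    probability of each heterozygote count is computed directly from the
    Levene-Haldane formula with gammaln.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a
    if min(n_a, n_b) == 0:
        return 1.0
    hs = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    lg = special.gammaln

    def logp(h):
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        return (
            h * np.log(2)
            + lg(n + 1) - lg(naa + 1) - lg(h + 1) - lg(nbb + 1)
            + lg(n_a + 1) + lg(n_b + 1) - lg(2 * n + 1)
        )

    logs = np.array([logp(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hs, n_ab)]
    return float(probs[probs <= p_obs * (1 + 1e-10)].sum())


class TestHweExactTest:
    @pytest.mark.parametrize(
        ("counts", "expected"),
        [
            ((0, 0, 100), 1.0),  # monomorphic
            ((25, 50, 25), 1.0),  # modal heterozygote configuration
        ],
    )
    def test_degenerate_and_modal_cases(self, counts, expected):
        assert assoc.hwe_exact_test(*counts) == pytest.approx(expected)

    def test_matches_enumeration_oracle_on_fixture(self):
        p = assoc.hwe_exact_test(57, 78, 15)
        assert p == pytest.approx(hwe_enumeration_oracle(57, 78, 15), abs=1e-12)

    @given(
        n_aa=st.integers(0, 60),
        n_ab=st.integers(0, 60),
        n_bb=st.integers(0, 60),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle_everywhere(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        p = assoc.hwe_exact_test(n_aa, n_ab, n_bb)
        assert 0 < p <= 1
        assert p == pytest.approx(hwe_enumeration_oracle(n_aa, n_ab, n_bb), abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            assoc.hwe_exact_test(-1, 5, 5)


class TestInfoScore:
    def test_hard_hwe_genotypes_near_one(self, rng):
        g = rng.binomial(2, 0.3, 10_000).astype(float)
        assert assoc.info_score(g) == pytest.approx(1.0, abs=0.05)

    def test_constant_polymorphic_dosage_fails_qc(self):
        d = np.full(100, 0.6)  # all equal to 2*p_hat, zero variance
        info = assoc.info_score(d)
        assert info == np.finfo(float).tiny
        variants = pd.DataFrame({"variant_id": ["v1"], "EAF": [0.3], "info": [info]})
        kept, report = assoc.snp_qc(variants, d[:, None])
        assert kept == [] and "info" in report["all_fails"].iloc[0]

    def test_monomorphic_undefined(self):
        assert np.isnan(assoc.info_score(np.zeros(100)))

    def test_round_trip_with_injected_noise(self, rng):
        cfg = synthdata.SimConfig(n_samples=5_000, n_variants=100, seed=21)
        d, _ = synthdata.simulate_genotypes(cfg)
        noisy = synthdata.inject_imputation_noise(d, 0.5, seed=3)
        infos = np.array([assoc.info_score(noisy[:, j]) for j in range(100)])
        assert abs(infos.mean() - 0.5) < 0.1


class TestSnpQc:
    def _panel(self, rng):
        n = 400
        cols, rows = [], []
        # one clean variant and one violating each filter
        specs = [
            ("ok", 0.3, 1.0, None),
            ("low_maf", 0.005, 1.0, None),
            ("low_info", 0.3, 0.2, None),
            ("hwe_fail", 0.5, 1.0, "hwe"),
            ("low_call", 0.3, 1.0, "calls"),
        ]
        for name, maf, info_target, special_case in specs:
            g = rng.binomial(2, maf, n).astype(float)
            if special_case == "hwe":
                g = np.where(rng.random(n) < 0.5, 0.0, 2.0)  # no heterozygotes
            if info_target < 1.0:
                g = synthdata.inject_imputation_noise(g[:, None], info_target, seed=1)[:, 0]
            if special_case == "calls":
                g[: int(0.1 * n)] = np.nan
            cols.append(g)
            rows.append({"variant_id": name, "EAF": np.nanmean(g) / 2})
        variants = pd.DataFrame(rows)
        variants["info"] = [assoc.info_score(c) for c in cols]
        return variants, np.column_stack(cols)

    def test_fail_reasons_enumerated(self, rng):
        variants, dosages = self._panel(rng)
        kept, report = assoc.snp_qc(variants, dosages)
        assert kept == ["ok"]
        by_id = report.set_index("variant_id")
        assert by_id.at["low_maf", "first_fail"] == "MAF"
        assert "info" in by_id.at["low_info", "all_fails"]
        assert "HWE" in by_id.at["hwe_fail", "all_fails"]
        assert "call_rate" in by_id.at["low_call", "all_fails"]

    def test_zero_thresholds_keep_everything(self, rng):
        variants, dosages = self._panel(rng)
        kept, _ = assoc.snp_qc(variants, dosages, assoc.QcThresholds(0.0, 0.0, 0.0, 0.0))
        assert kept == variants["variant_id"].tolist()

    def test_order_independent_and_idempotent(self, rng):
        variants, dosages = self._panel(rng)
        perm = [3, 1, 4, 0, 2]
        kept_perm, _ = assoc.snp_qc(variants.iloc[perm].reset_index(drop=True), dosages[:, perm])
        kept, _ = assoc.snp_qc(variants, dosages)
        assert set(kept_perm) == set(kept)
        # re-running QC on the kept subset changes nothing
        keep_mask = variants["variant_id"].isin(kept).to_numpy()
        kept2, _ = assoc.snp_qc(variants[keep_mask].reset_index(drop=True), dosages[:, keep_mask])
        assert kept2 == kept


def gwas_normal_equations_oracle(y, g, covars):
    """Full-design OLS through the normal equations (pinv), for one variant."""
    X = np.column_stack([np.ones(len(y)), covars, g])
    beta = np.linalg.pinv(X.T @ X) @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(cov[-1, -1])
    t = beta[-1] / se
    return beta[-1], se, 2 * stats.t.sf(abs(t), df)


class TestRunGwas:
    def _variants(self, m):
        return pd.DataFrame(
            {
                "variant_id": [f"v{j}" for j in range(m)],
                "chrom": "1",
                "pos": 10_000 * (np.arange(m) + 1),
                "EA": "A",
                "OA": "G",
                "EAF": 0.3,
                "info": 1.0,
            }
        )

    def test_exact_linear_phenotype(self, rng):
        g = rng.binomial(2, 0.4, 200).astype(float)
        res = assoc.run_gwas(g[:, None], 2.0 * g, None, self._variants(1))
        assert res["beta"].iloc[0] == pytest.approx(2.0, abs=1e-10)
        assert res["p"].iloc[0] <= np.finfo(float).tiny * 10

    def test_matches_normal_equations_oracle(self, rng):
        """20-sample fixture: beta/se/p equal the closed-form fit to 1e-10."""
        n = 20
        g = rng.binomial(2, 0.5, n).astype(float)
        covars = np.column_stack([rng.integers(0, 2, n), rng.uniform(40, 80, n)])
        y = 0.3 * g + 0.01 * covars[:, 1] + rng.standard_normal(n)
        res = assoc.run_gwas(g[:, None], y, covars, self._variants(1))
        b_o, se_o, p_o = gwas_normal_equations_oracle(y, g, covars)
        assert res["beta"].iloc[0] == pytest.approx(b_o, abs=1e-10)
        assert res["se"].iloc[0] == pytest.approx(se_o, abs=1e-10)
        assert res["p"].iloc[0] == pytest.approx(p_o, rel=1e-8)

    def test_missing_dosages_use_complete_cases(self, rng):
        n = 100
        g = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 * g + rng.standard_normal(n)
        g_miss = g.copy()
        g_miss[:10] = np.nan
        res = assoc.run_gwas(g_miss[:, None], y, None, self._variants(1))
        assert res["n"].iloc[0] == 90
        b_o, se_o, _ = gwas_normal_equations_oracle(y[10:], g[10:], np.empty((90, 0)))
        assert res["beta"].iloc[0] == pytest.approx(b_o, abs=1e-10)

    def test_type_one_error_calibrated_under_null(self, rng):
        n, m = 300, 1000
        g = rng.binomial(2, 0.3, (n, m)).astype(float)
        y = rng.standard_normal(n)
        res = assoc.run_gwas(g, y, None, self._variants(m))
        frac = (res["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m)

    def test_constant_dosage_skipped(self, rng):
        g = np.column_stack([np.full(50, 1.0), rng.binomial(2, 0.4, 50).astype(float)])
        res = assoc.run_gwas(g, rng.standard_normal(50), None, self._variants(2))
        assert res["skip_reason"].iloc[0] == "rank_deficient"
        assert np.isnan(res["beta"].iloc[0]) and res["skip_reason"].iloc[1] == ""


class TestGenomicInflation:
    def test_definition_cases(self):
        assert assoc.genomic_inflation([0.5] * 7) == pytest.approx(1.0)
        assert assoc.genomic_inflation([0.9, 0.5, 0.1]) == pytest.approx(1.0)

    def test_uniform_p_lambda_near_one(self, rng):
        p = rng.random(100_000)
        assert 0.98 < assoc.genomic_inflation(p) < 1.02

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            assoc.genomic_inflation([0.5, 0.0])


class TestPower:
    def test_zero_variance_gives_alpha(self):
        assert assoc.gwas_power(1000, 0.0, 0.05) == pytest.approx(0.05)

    def test_monte_carlo_oracle(self, rng):
        """Power at n=1000, q2=1%, alpha=0.05 vs 1e6 noncentral draws."""
        n, q2, alpha = 1000, 0.01, 0.05
        ncp = n * q2
        crit = stats.chi2.isf(alpha, 1)
        draws = (rng.standard_normal(1_000_000) + np.sqrt(ncp)) ** 2
        mc = (draws > crit).mean()
        assert assoc.gwas_power(n, q2, alpha) == pytest.approx(mc, abs=0.003)

    def test_detectable_variance_inverts_power(self):
        for n, power, alpha in [(6430, 0.8, 5e-8), (1000, 0.5, 0.05)]:
            q2 = assoc.detectable_variance(n, power, alpha)
            assert assoc.gwas_power(n, q2, alpha) == pytest.approx(power, abs=1e-8)

    def test_exact_ncp_variant_consistent(self):
        q2 = assoc.detectable_variance(5000, 0.8, 5e-8, ncp="exact")
        assert assoc.gwas_power(5000, q2, 5e-8, ncp="exact") == pytest.approx(0.8, abs=1e-8)
        # the exact form has the larger noncentrality at fixed q2, so it
        # needs slightly less variance than the linear form
        assert q2 < assoc.detectable_variance(5000, 0.8, 5e-8, ncp="linear")

    def test_bad_targets_rejected(self):
        with pytest.raises(ValueError):
            assoc.detectable_variance(1000, 0.01, 0.05)  # power below alpha


class TestCompareEffectSizes:
    def test_equal_effects(self):
        z, p = assoc.compare_effect_sizes(0.5, 0.1, 0.5, 0.1)
        assert z == 0.0 and p == 1.0

    def test_normal_tail_oracle(self):
        z, p = assoc.compare_effect_sizes(1.0, 1.0, 0.0, 1.0)
        assert z == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(1 / np.sqrt(2)), abs=1e-12)
        assert p == pytest.approx(0.4795, abs=1e-4)
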