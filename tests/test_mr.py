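"""IVW estimation, Cochran's Q, instrument selection and reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stiffpipe import mr, synthdata


def _instruments(bx, sx, by, sy):
    return pd.DataFrame(
        {
            "variant_id": [f"iv{i}" for i in range(len(bx))],
            "beta_x": bx,
            "se_x": sx,
            "beta_y": by,
            "se_y": sy,
        }
    )


class TestIvw:
    def test_single_instrument_is_wald_ratio(self):
        ins = _instruments([0.05], [0.01], [0.03], [0.012])
        res = mr.ivw(ins)
        assert res.estimate == pytest.approx(0.6)
        assert res.se == pytest.approx(0.012 / 0.05)
        assert res.Q is None and res.Q_df is None

    def test_identical_ratios_q_zero_random_equals_fixed(self):
        ins = _instruments([0.04, 0.08], [0.01, 0.01], [0.02, 0.04], [0.01, 0.01])
        rnd = mr.ivw(ins, model="random")
        fix = mr.ivw(ins, model="fixed")
        assert rnd.Q == pytest.approx(0.0, abs=1e-20)
        assert rnd.se == pytest.approx(fix.se)

    def test_weighted_mean_matches_hand_computation(self):
        """3-instrument fixture: estimate equals the arithmetic oracle to 1e-12."""
        bx, sy = np.array([0.05, -0.04, 0.08]), np.array([0.01, 0.02, 0.015])
        by = np.array([0.03, -0.02, 0.04])
        ratio = by / bx
        w = (bx / sy) ** 2
        oracle = np.sum(w * ratio) / np.sum(w)
        res = mr.ivw(_instruments(bx, [0.01] * 3, by, sy))
        assert res.estimate == pytest.approx(oracle, abs=1e-12)
        assert res.se >= 1.0 / np.sqrt(np.sum(w))  # random-effect never shrinks

    def test_equal_se_reduces_to_unweighted_mean_of_ratios(self):
        bx = np.array([0.05, 0.05, -0.05, 0.05])
        by = np.array([0.01, 0.02, -0.03, 0.04])
        res = mr.ivw(_instruments(bx, [0.01] * 4, by, [0.01] * 4))
        assert res.estimate == pytest.approx(np.mean(by / bx), abs=1e-12)

    def test_joint_sign_flip_invariance(self):
        bx = np.array([0.05, -0.04, 0.08])
        by = np.array([0.03, -0.02, 0.04])
        base = mr.ivw(_instruments(bx, [0.01] * 3, by, [0.01] * 3))
        flip = mr.ivw(_instruments(-bx, [0.01] * 3, -by, [0.01] * 3))
        assert base.estimate == pytest.approx(flip.estimate, abs=1e-12)
        assert base.se == pytest.approx(flip.se, abs=1e-12)

    def test_fixed_se_never_exceeds_random_se(self, rng):
        for seed in range(20):
            tab, _ = synthdata.make_two_sample_sumstats(15, 0.3, pleiotropy_sd=0.01, seed=seed)
            assert mr.ivw(tab, model="fixed").se <= mr.ivw(tab, model="random").se + 1e-15

    def test_zero_beta_x_rejected(self):
        with pytest.raises(ValueError, match="beta_x"):
            mr.ivw(_instruments([0.0], [0.01], [0.01], [0.01]))


class TestCiAndP:
    def test_published_cfpwv_interval(self):
        """Estimate 0.481, SE 0.127 -> 95% CI (0.232, 0.730) at 3 decimals."""
        lo, hi, _p = mr.ci_and_p(0.481, 0.127)
        assert round(lo, 3) == 0.232
        assert round(hi, 3) == 0.730

    def test_null_estimate(self):
        lo, hi, p = mr.ci_and_p(0.0, 1.0)
        assert (lo, hi) == (-1.96, 1.96)
        assert p == 1.0

    def test_p_matches_erfc_oracle(self):
        import math

        est, se = 0.612, 0.079
        _lo, _hi, p = mr.ci_and_p(est, se)
        oracle = math.erfc((est / se) / math.sqrt(2))
        assert p == pytest.approx(oracle, rel=1e-3)


class TestCochranQ:
    def test_identical_ratios(self):
        ins = _instruments([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.01, 0.01])
        Q, df, p = mr.cochran_q(ins)
        assert Q == pytest.approx(0.0, abs=1e-20) and df == 1 and p == pytest.approx(1.0)

    def test_two_instrument_chi_square_tail(self):
        """Ratios 0 and 2 with unit ratio SEs: Q = 2, p = P(chi2_1 > 2)."""
        ins = _instruments([1.0, 1.0], [0.1, 0.1], [0.0, 2.0], [1.0, 1.0])
        Q, df, p = mr.cochran_q(ins)
        assert Q == pytest.approx(2.0, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(2.0, 1), abs=1e-12)
        assert p == pytest.approx(0.1573, abs=1e-4)

    def test_homogeneous_simulation_q_p_uniform(self):
        """Q p-values approximately uniform when instruments are homogeneous."""
        ps = []
        for seed in range(500):
            tab, _ = synthdata.make_two_sample_sumstats(10, 0.5, seed=seed, se_x=0.001)
            ps.append(mr.cochran_q(tab)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_pleiotropy_inflates_q(self):
        hits = 0
        for seed in range(100):
            tab, _ = synthdata.make_two_sample_sumstats(30, 0.5, pleiotropy_sd=0.05, seed=seed)
            if mr.cochran_q(tab)[2] < 0.05:
                hits += 1
        assert hits > 50

    def test_single_instrument_rejected(self):
        with pytest.raises(ValueError):
            mr.cochran_q(_instruments([0.1], [0.01], [0.05], [0.01]))


class TestInstrumentSelection:
    def _local(self, ids, ps, betas=None):
        betas = betas if betas is not None else [0.05] * len(ids)
        return pd.DataFrame(
            {"variant_id": ids, "beta": betas, "se": [0.01] * len(ids), "p": ps}
        )

    def test_forward_ledger_reasons(self):
        panel = pd.DataFrame({"variant_id": ["a", "b", "c", "d", "e"]})
        sbp = self._local(["a", "b", "c", "d"], [0.001, 0.001, 0.5, 0.001])
        pwv = {"baPWV": self._local(["a", "b", "c", "d"], [0.9, 0.01, 0.9, 0.9])}
        # r2 of each panel SNP to the PWV lead: only d is in LD
        ld = pd.DataFrame({"lead1": [0.0, 0.0, 0.0, 0.5]}, index=list("abcd"))
        instruments, ledger = mr.select_instruments_forward(
            panel, sbp, pwv, ["lead1"], ld
        )
        reasons = dict(zip(ledger["variant_id"], ledger["reason"]))
        assert reasons == {
            "e": "unavailable",
            "b": "direct_effect",
            "c": "sbp_not_nominal",
            "d": "ld_with_pwv_lead",
        }
        assert instruments["variant_id"].tolist() == ["a"]

    def test_forward_planted_direct_effects_excluded(self, rng):
        """Panel SNPs with planted PWV effects land in the direct-effect ledger."""
        ids = [f"s{i}" for i in range(10)]
        pwv_p = np.full(10, 0.8)
        pwv_p[[2, 7]] = 1e-4  # two planted direct effects
        panel = pd.DataFrame({"variant_id": ids})
        sbp = self._local(ids, [0.001] * 10)
        pwv = {"cfPWV": self._local(ids, pwv_p)}
        _ins, ledger = mr.select_instruments_forward(panel, sbp, pwv, [], None)
        direct = set(ledger.loc[ledger["reason"] == "direct_effect", "variant_id"])
        assert direct == {"s2", "s7"}

    def test_forward_empty_set_raises_with_ledger(self):
        panel = pd.DataFrame({"variant_id": ["a"]})
        sbp = self._local(["a"], [0.9])
        with pytest.raises(ValueError, match="ledger"):
            mr.select_instruments_forward(panel, sbp, {}, [], None)

    def test_reverse_ld_with_published_hit_dropped(self):
        sugg = self._local(["x", "y"], [0.001, 0.001])
        ld = pd.DataFrame(
            [[1.0, 0.11], [0.11, 1.0]], index=["x", "hit"], columns=["x", "hit"]
        )
        ins = mr.select_instruments_reverse(sugg, "cfPWV", ["hit"], ld)
        assert ins["variant_id"].tolist() == ["y"]

    def test_reverse_all_nominal_all_kept(self):
        sugg = self._local(["x", "y", "z"], [0.01, 0.02, 0.001])
        ins = mr.select_instruments_reverse(sugg, "baPWV", [], None)
        assert len(ins) == 3

    def test_reverse_drop_lead_reduces_by_one(self):
        sugg = self._local(["x", "y", "z"], [0.01, 0.02, 0.001])
        ins = mr.select_instruments_reverse(sugg, "baPWV", [], None, drop_lead="z")
        assert len(ins) == 2 and "z" not in set(ins["variant_id"])


class TestTwoSampleCalibration:
    def test_null_theta_type_one_error(self):
        """IVW at theta = 0, J = 49: empirical size 0.05 +/- 0.02 over 500 reps."""
        rejections = 0
        reps = 500
        for seed in range(reps):
            tab, _ = synthdata.make_two_sample_sumstats(49, 0.0, seed=seed)
            if mr.ivw(tab, model="random").p < 0.05:
                rejections += 1
        assert abs(rejections / reps - 0.05) < 0.02

    def test_recovers_theta_06(self):
        tab, _ = synthdata.make_two_sample_sumstats(49, 0.6, seed=42)
        res = mr.ivw(tab)
        assert abs(res.estimate - 0.6) < 2 * res.se

    def test_pleiotropy_detected_by_q(self):
        flagged = 0
        for seed in range(40):
            tab, _ = synthdata.make_two_sample_sumstats(49, 0.6, pleiotropy_sd=0.05, seed=seed)
            if mr.ivw(tab).Q_p < 0.05:
                flagged += 1
        assert flagged > 20


class TestBidirectionalReport:
    def test_forward_only_marks_reverse_absent(self):
        tab, _ = synthdata.make_two_sample_sumstats(10, 0.5, seed=1)
        res = {"cfPWV": mr.ivw(tab)}
        report = mr.bidirectional_report(res, None)
        reverse_rows = report[report["direction"] == "PWV->SBP"]
        assert np.isnan(reverse_rows["estimate"]).all()

    def test_requires_at_least_one_direction(self):
        with pytest.raises(ValueError):
            mr.bidirectional_report(None, None)
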