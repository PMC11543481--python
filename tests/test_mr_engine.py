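"""Wald ratio, IVW, Bonferroni arithmetic, Steiger and reverse MR."""

import math

import numpy as np
import pytest

from cispqmr.instruments import select_instruments
from cispqmr.mr_engine import (bonferroni_threshold, ivw, mr_estimate,
                               reverse_mr, steiger_test, wald_ratio)
from cispqmr.synthetic_data import ScenarioSpec, simulate_region

from conftest import make_pair


class TestWaldRatio:
    def test_identity_instrument(self):
        res = wald_ratio(make_pair(1.0, 0.01, 0.05, 0.01))
        assert res.beta == pytest.approx(0.05)
        assert res.se == pytest.approx(0.01)

    def test_first_order_delta(self):
        res = wald_ratio(make_pair(0.5, 0.001, 0.1, 0.05))
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1)
        # with negligible exposure SE the second-order SE agrees
        res2 = wald_ratio(make_pair(0.5, 1e-9, 0.1, 0.05), second_order=True)
        assert res2.se == pytest.approx(0.1, rel=1e-6)

    def test_null_outcome_gives_null_estimate(self):
        res = wald_ratio(make_pair(0.5, 0.01, 0.0, 0.05))
        assert res.beta == 0.0
        assert res.pval == 1.0

    def test_zero_exposure_beta_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(make_pair(0.0, 0.01, 0.1, 0.05))

    def test_ci_is_beta_plus_minus_196_se(self):
        res = wald_ratio(make_pair(0.5, 0.01, 0.1, 0.05))
        assert res.ci_low == pytest.approx(res.beta - 1.959964 * res.se)
        assert res.ci_high == pytest.approx(res.beta + 1.959964 * res.se)


class TestIVW:
    def test_replicated_pair_shrinks_se_by_sqrt2(self):
        pairs = [make_pair(0.5, 0.01, 0.1, 0.05, snp_id=f"rs{i}")
                 for i in range(2)]
        res = ivw(pairs)
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1 / math.sqrt(2))

    def test_two_instrument_weighted_combination(self):
        pairs = [make_pair(0.5, 0.01, 0.1, 0.05),
                 make_pair(0.4, 0.01, 0.06, 0.04, snp_id="rs2")]
        res = ivw(pairs)
        assert res.beta == pytest.approx(0.175)
        assert res.se == pytest.approx(0.0707, abs=2e-4)

    def test_matches_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            bx = rng.normal(0.3, 0.1, size=5)
            by = rng.normal(0.05, 0.05, size=5)
            sy = rng.uniform(0.01, 0.1, size=5)
            pairs = [make_pair(bx[i], 0.01, by[i], sy[i], snp_id=f"rs{i}")
                     for i in range(5)]
            res = ivw(pairs)
            w = 1.0 / sy ** 2
            # WLS through the origin: beta = (X'WX)^-1 X'Wy
            beta_wls = np.sum(w * bx * by) / np.sum(w * bx * bx)
            se_wls = math.sqrt(1.0 / np.sum(w * bx * bx))
            assert res.beta == pytest.approx(beta_wls, rel=1e-10)
            assert res.se == pytest.approx(se_wls, rel=1e-10)

    def test_all_null_outcomes_give_zero(self):
        pairs = [make_pair(0.5, 0.01, 0.0, 0.05, snp_id=f"rs{i}")
                 for i in range(3)]
        assert ivw(pairs).beta == 0.0

    def test_single_pair_equals_wald_ratio(self):
        pair = make_pair(0.5, 0.01, 0.1, 0.05)
        a = ivw([pair], _allow_single=True)
        b = wald_ratio(pair)
        assert a.beta == pytest.approx(b.beta, rel=1e-14)
        assert a.se == pytest.approx(b.se, rel=1e-14)

    def test_fewer_than_two_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            ivw([make_pair(0.5, 0.01, 0.1, 0.05)])

    def test_pval_invariant_under_exposure_sign_flip(self):
        pairs = [make_pair(0.5, 0.01, 0.1, 0.05),
                 make_pair(0.4, 0.01, 0.06, 0.04, snp_id="rs2")]
        flipped = [make_pair(-p.exposure.beta, p.exposure.se,
                             p.outcome.beta, p.outcome.se, snp_id=p.snp_id)
                   for p in pairs]
        assert ivw(pairs).pval == pytest.approx(ivw(flipped).pval,
                                                rel=1e-12)
        assert ivw(pairs).beta == pytest.approx(-ivw(flipped).beta)

    def test_random_effects_never_shrinks_se(self):
        pairs = [make_pair(0.5, 0.01, 0.2, 0.02),
                 make_pair(0.5, 0.01, -0.1, 0.02, snp_id="rs2"),
                 make_pair(0.5, 0.01, 0.4, 0.02, snp_id="rs3")]
        assert ivw(pairs, random_effects=True).se >= ivw(pairs).se


class TestBonferroni:
    def test_study_thresholds(self):
        assert bonferroni_threshold(0.05, 1869) == pytest.approx(2.675e-5,
                                                                 rel=1e-3)
        assert bonferroni_threshold(0.05, 3873 * 9) == pytest.approx(
            1.43e-6, rel=4e-3)

    def test_single_test_keeps_alpha(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_zero_tests_is_an_error(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestSteiger:
    def _pair_with_r(self, rx, nx, ry, ny, eaf=0.3):
        # choose beta/se so that z^2/(z^2+n) = r^2 on each side
        def side(r, n):
            z = math.sqrt(r * r * n / (1 - r * r))
            return z * 0.01, 0.01
        bx, sx = side(rx, nx)
        by, sy = side(ry, ny)
        return make_pair(bx, sx, by, sy, eaf=eaf, nx=nx, ny=ny)

    def test_equal_correlations_give_null(self):
        pair = self._pair_with_r(0.05, 50_000, 0.05, 50_000)
        ok, pval = steiger_test(pair)
        assert not ok
        assert pval == pytest.approx(1.0)

    def test_fisher_z_formula(self):
        pair = self._pair_with_r(0.1, 50_000, 0.01, 400_000)
        ok, pval = steiger_test(pair)
        assert ok
        z = (math.atanh(0.1) - math.atanh(0.01)) / math.sqrt(
            1 / (50_000 - 3) + 1 / (400_000 - 3))
        assert z == pytest.approx(19.0, abs=0.1)
        assert pval < 1e-50

    def test_antisymmetric_under_role_swap(self):
        pair = self._pair_with_r(0.1, 50_000, 0.03, 50_000)
        swapped = make_pair(pair.outcome.beta, pair.outcome.se,
                            pair.exposure.beta, pair.exposure.se,
                            nx=pair.outcome.n, ny=pair.exposure.n)
        ok, p = steiger_test(pair)
        ok_s, p_s = steiger_test(swapped)
        assert ok and not ok_s
        assert p == pytest.approx(p_s, rel=1e-12)


class TestReverseMR:
    def test_reverse_null_ci_covers_zero(self):
        # outcome drives the region, but with zero effect on the protein:
        # the reverse estimate must be null
        covered = 0
        n_done = 0
        for s in range(200):
            spec = ScenarioSpec(scenario="reverse", theta=0.0, m_snps=20,
                                ld_rho=0.3, causal_indices=(10,),
                                exposure_effects=(0.05,),
                                n_outcome=100_000, seed=90_000 + s)
            regs = simulate_region(spec)
            res = reverse_mr(regs["outcome"], regs["exposure"])
            if res is None:
                continue
            n_done += 1
            covered += res.ci_low <= 0.0 <= res.ci_high
        assert n_done > 150
        assert covered / n_done >= 0.93

    def test_role_swap_on_symmetric_data_reproduces_forward(self):
        spec = ScenarioSpec(scenario="shared_causal", theta=1.0,
                            m_snps=10, ld_rho=0.0, causal_indices=(5,),
                            exposure_effects=(0.2,), n_exposure=50_000,
                            n_outcome=50_000, seed=5)
        regs = simulate_region(spec)
        fwd = reverse_mr(regs["exposure"], regs["outcome"])
        rev = reverse_mr(regs["outcome"], regs["exposure"])
        # same region, same machinery: both directions give estimates of
        # similar magnitude near theta = 1
        assert fwd is not None and rev is not None
        assert fwd.beta * rev.beta > 0
        assert abs(fwd.beta * rev.beta - 1.0) < 0.5

    def test_no_outcome_instruments_gives_empty_result(self):
        spec = ScenarioSpec(scenario="null", m_snps=10,
                            causal_indices=(5,), exposure_effects=(0.2,),
                            seed=1)
        regs = simulate_region(spec)
        assert reverse_mr(regs["outcome"], regs["exposure"]) is None


class TestDispatch:
    def test_one_instrument_uses_wald_two_use_ivw(self):
        p = make_pair(0.5, 0.01, 0.1, 0.05)
        assert mr_estimate([p]).method == "wald_ratio"
        assert mr_estimate([p, make_pair(0.4, 0.01, 0.06, 0.04,
                                         snp_id="rs2")]).method == "ivw"


class TestIVWCalibration:
    def test_unbiased_with_nominal_coverage_under_shared_causal(self):
        theta = 0.1
        estimates, covered = [], 0
        for s in range(500):
            spec = ScenarioSpec(
                scenario="shared_causal", m_snps=30, ld_rho=0.3,
                causal_indices=(5, 15, 25),
                exposure_effects=(0.15, 0.15, 0.15), theta=theta,
                n_exposure=33_000, n_outcome=100_000, seed=20_000 + s)
            regs = simulate_region(spec)
            pairs = select_instruments(regs["exposure"],
                                       regs["outcome"]).members
            if len(pairs) < 2:
                continue
            res = ivw(pairs)
            estimates.append(res.beta)
            covered += res.ci_low <= theta <= res.ci_high
        n = len(estimates)
        assert n >= 450
        assert abs(np.mean(estimates) - theta) < 0.01
        assert 0.92 <= covered / n <= 0.98
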