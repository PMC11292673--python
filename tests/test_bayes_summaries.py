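"""Inference summaries: PD/p, MAP, HDI, Savage-Dickey BF, split-R-hat, WAIC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from predsupp.bayes import (
    hdi95,
    map_estimate,
    pd_and_p,
    savage_dickey_bf10,
    split_rhat,
    waic,
    waic_diff,
)
from predsupp.exceptions import AlignmentError, DegenerateDrawsWarning


class TestPDandP:
    def test_all_positive(self):
        pd_, p = pd_and_p(np.ones(100))
        assert pd_ == 1.0 and p == 0.0

    def test_exact_half(self):
        draws = np.concatenate([np.ones(50), -np.ones(50)])
        pd_, p = pd_and_p(draws)
        assert pd_ == 0.5 and p == 1.0

    def test_formula_at_97_5_percent(self):
        draws = np.concatenate([np.ones(975), -np.ones(25)])
        _, p = pd_and_p(draws)
        assert p == pytest.approx(0.05)

    def test_degenerate_zero_draws(self):
        with pytest.warns(DegenerateDrawsWarning):
            pd_, p = pd_and_p(np.zeros(10))
        assert pd_ == 0.5

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_sign_flip_symmetry(self, seed):
        draws = np.random.default_rng(seed).normal(0.3, 1.0, 500)
        pd1, p1 = pd_and_p(draws)
        pd2, p2 = pd_and_p(-draws)
        assert pd1 == pd2 and p1 == p2


class TestMAP:
    def test_constant_draws(self):
        assert map_estimate(np.full(200, 3.7)) == 3.7

    def test_standard_normal_mode_near_zero(self):
        draws = np.random.default_rng(0).normal(size=100_000)
        assert abs(map_estimate(draws)) < 0.1

    def test_lognormal_mode_below_mean(self):
        draws = np.random.default_rng(1).lognormal(0.0, 0.8, 100_000)
        assert map_estimate(draws) < draws.mean()


class TestHDI:
    def test_uniform_width(self):
        draws = np.random.default_rng(2).uniform(0, 1, 200_000)
        lo, hi = hdi95(draws)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_normal_quantiles(self):
        draws = np.random.default_rng(3).normal(size=100_000)
        lo, hi = hdi95(draws)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_constant_draws_zero_width(self):
        lo, hi = hdi95(np.full(500, 2.0))
        assert lo == hi == 2.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_never_wider_than_equal_tailed(self, seed):
        draws = np.random.default_rng(seed).gamma(2.0, 1.0, 2000)
        lo, hi = hdi95(draws)
        eq_lo, eq_hi = np.quantile(draws, [0.025, 0.975])
        assert (hi - lo) <= (eq_hi - eq_lo) + 1e-12


class TestSavageDickey:
    def test_no_updating_gives_unity(self):
        rng = np.random.default_rng(4)
        prior = rng.normal(size=50_000)
        post = rng.normal(size=50_000)
        assert savage_dickey_bf10(post, prior) == pytest.approx(1.0, rel=0.1)

    def test_posterior_far_from_null(self):
        rng = np.random.default_rng(5)
        prior = rng.normal(size=20_000)
        post = rng.normal(6.0, 0.5, 20_000)
        assert savage_dickey_bf10(post, prior) > 100

    def test_closed_form_normal_ratio(self):
        rng = np.random.default_rng(6)
        prior = rng.normal(0, 1.0, 100_000)
        post = rng.normal(0, 0.5, 100_000)
        expected = norm.pdf(0, 0, 1.0) / norm.pdf(0, 0, 0.5)
        assert savage_dickey_bf10(post, prior) == pytest.approx(expected, rel=0.1)


class TestSplitRhat:
    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(7)
        chains = rng.normal(size=(6, 1000))
        assert split_rhat(chains) < 1.01

    def test_offset_chains_large(self):
        rng = np.random.default_rng(8)
        chains = rng.normal(size=(2, 1000))
        chains[1] += 5.0
        assert split_rhat(chains) > 1.5

    def test_constant_chains_undefined(self):
        with pytest.warns(DegenerateDrawsWarning):
            r = split_rhat(np.ones((4, 100)))
        assert np.isnan(r)

    def test_matches_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(9)
        chains = rng.normal(size=(4, 500)) + rng.normal(size=(4, 1))
        ours = split_rhat(chains)
        theirs = float(az.rhat(chains[None, ...].squeeze(0)))
        assert ours == pytest.approx(theirs, abs=0.01)


class TestWAIC:
    def test_hand_computed_fixture(self):
        # 2 observations x 3 draws, evaluated against the direct formula
        ll = np.array([[-1.0, -2.0], [-1.5, -2.5], [-0.5, -1.0]])
        res = waic(ll)
        lppd = sum(
            np.log(np.mean(np.exp(ll[:, i]))) for i in range(2)
        )
        p = sum(np.var(ll[:, i], ddof=1) for i in range(2))
        assert res.lppd == pytest.approx(lppd, abs=1e-12)
        assert res.p_waic == pytest.approx(p, abs=1e-12)
        assert res.waic == pytest.approx(-2 * (lppd - p), abs=1e-12)

    def test_single_draw_degenerate(self):
        ll = np.array([[-1.0, -2.0, -3.0]])
        res = waic(ll)
        assert res.p_waic == 0.0
        assert res.waic == pytest.approx(-2 * ll.sum())

    def test_duplicated_observations_double(self):
        rng = np.random.default_rng(10)
        ll = rng.normal(-1.0, 0.3, size=(50, 4))
        a = waic(ll)
        b = waic(np.concatenate([ll, ll], axis=1))
        assert b.lppd == pytest.approx(2 * a.lppd)
        assert b.p_waic == pytest.approx(2 * a.p_waic)

    def test_chain_axis_accepted(self):
        rng = np.random.default_rng(11)
        ll = rng.normal(-1.0, 0.3, size=(2, 25, 4))
        assert waic(ll).waic == pytest.approx(waic(ll.reshape(50, 4)).waic)


class TestWAICDiff:
    def test_identity(self):
        ll = np.random.default_rng(12).normal(-1, 0.2, size=(40, 6))
        a = waic(ll)
        delta, se, sig = waic_diff(a, a)
        assert delta == 0.0 and se == 0.0 and not sig

    def test_direct_formula(self):
        rng = np.random.default_rng(13)
        lla = rng.normal(-1.0, 0.2, size=(60, 8))
        llb = rng.normal(-1.3, 0.2, size=(60, 8))
        a, b = waic(lla), waic(llb)
        delta, se, _ = waic_diff(a, b)
        d = a.pointwise_elpd - b.pointwise_elpd
        assert delta == pytest.approx(a.waic - b.waic)
        assert se == pytest.approx(2 * np.sqrt(8 * d.var(ddof=1)))

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(14)
        lla = rng.normal(-1.0, 0.2, size=(60, 8))
        llb = rng.normal(-1.3, 0.2, size=(60, 8))
        perm = rng.permutation(8)
        d1 = waic_diff(waic(lla), waic(llb))
        d2 = waic_diff(waic(lla[:, perm]), waic(llb[:, perm]))
        assert d1[0] == pytest.approx(d2[0])
        assert d1[1] == pytest.approx(d2[1])

    def test_mismatched_n_rejected(self):
        ll = np.random.default_rng(15).normal(-1, 0.2, size=(40, 6))
        with pytest.raises(AlignmentError):
            waic_diff(waic(ll), waic(ll[:, :5]))
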