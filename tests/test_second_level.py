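"""Second-level measurement-error model: pooling, contrasts, correlations."""

import numpy as np
import pandas as pd
import pytest

from conftest import chain_correlation, make_estimates
from predsupp.exceptions import DataError
from predsupp.second_level import SecondLevelModel, SecondLevelPriors

FAST = dict(chains=2, iters=800, warmup=300)  # 1000 kept draws


@pytest.fixture(scope="module")
def small_fit():
    est = make_estimates(seed=21, n_subjects=4, n_runs=1, rois=("IC", "AC"),
                         tau=1.0, sigma=2.0)
    model = SecondLevelModel(est)
    return model.fit(seed=31, **FAST)


class TestFitBasics:
    def test_contrast_antisymmetry(self, small_fit):
        a = small_fit.contrast_draws("dev4", "dev6", "AC")
        b = small_fit.contrast_draws("dev6", "dev4", "AC")
        assert np.array_equal(a, -b)

    def test_correlation_draws_valid(self, small_fit):
        R = small_fit.draws.params["R"]
        assert np.allclose(R, np.swapaxes(R, -1, -2))
        assert np.allclose(R[..., 0, 0], 1.0)
        assert np.allclose(R[..., 1, 1], 1.0)
        assert (np.abs(R[..., 0, 1]) < 1.0).all()

    def test_contrast_table_complete(self, small_fit):
        table = small_fit.contrasts()
        assert set(table["contrast"]) == {
            "adaptation", "deviant_detection",
            "predictive_suppression", "complete_suppression",
        }
        assert len(table) == 4 * 2  # contrasts x rois
        assert table["bf10"].notna().all()

    def test_shrinkage_vs_raw_cell_means(self, small_fit):
        """Pooling: posterior sd of mu does not exceed the naive spread."""
        model = small_fit.model
        df = model.data
        mu = small_fit.draws.params["mu"]
        for r, roi in enumerate(model.rois):
            for c, cond in enumerate(model.conditions):
                cells = df[(df.roi == roi) & (df.condition == cond)]["beta"]
                naive_sd = cells.std(ddof=1)
                post_sd = mu[..., r, c].std()
                assert post_sd < 2.0 * naive_sd

    def test_unknown_condition_rejected(self, small_fit):
        with pytest.raises(DataError):
            small_fit.contrast_draws("dev4", "nope", "AC")


class TestInformation:
    def test_inflated_se_widens_posteriors(self):
        est = make_estimates(seed=22, n_subjects=4, n_runs=1, rois=("AC",),
                             conditions=("std0", "std1"))
        inflated = est.copy()
        inflated["se"] *= 10.0
        sd_a = SecondLevelModel(est).fit(seed=5, **FAST)
        sd_b = SecondLevelModel(inflated).fit(seed=5, **FAST)
        mu_a = sd_a.draws.params["mu"]
        mu_b = sd_b.draws.params["mu"]
        for c in range(mu_a.shape[-1]):
            assert mu_b[..., 0, c].std() > mu_a[..., 0, c].std()


class TestUnivariateLimit:
    def test_reduces_to_inverse_variance_pooling(self):
        """With tau, sigma forced to ~0 the posterior mean of mu matches the
        closed-form fixed-effect (inverse-variance weighted) estimate."""
        rng = np.random.default_rng(33)
        rows = []
        for s in range(6):
            for r in range(2):
                se = 0.5 + rng.random()
                rows.append(dict(subject=s, run=r, roi="AC", condition="std0",
                                 beta=rng.normal(5.0, se), se=se))
        est = pd.DataFrame(rows)
        priors = SecondLevelPriors(tau_scale=1e-4, sigma_scale=1e-4)
        model = SecondLevelModel(est, priors=priors)
        res = model.fit(seed=8, **FAST)
        w = 1.0 / est["se"] ** 2
        fixed = float((w * est["beta"]).sum() / w.sum())
        fixed_se = float(np.sqrt(1.0 / w.sum()))
        mu = res.draws.params["mu"][..., 0, 0]
        assert mu.mean() == pytest.approx(fixed, abs=3 * fixed_se / 10)
        assert mu.std() == pytest.approx(fixed_se, rel=0.25)

    def test_univariate_correlations_not_applicable(self):
        est = make_estimates(seed=24, n_subjects=3, n_runs=1, rois=("AC",))
        res = SecondLevelModel(est).fit(seed=2, chains=2, iters=400, warmup=200)
        with pytest.raises(DataError):
            res.roi_correlations()

    def test_univariate_R_is_identity(self):
        est = make_estimates(seed=25, n_subjects=3, n_runs=1, rois=("AC",))
        res = SecondLevelModel(est).fit(seed=2, chains=2, iters=400, warmup=200)
        assert np.all(res.draws.params["R"] == 1.0)


class TestCorrelationRecovery:
    def test_chain_structure_recovered(self):
        """Adjacent-pair residual correlations (generative r = 0.6 chain)
        come back clearly positive, well above the non-adjacent pairs."""
        est = make_estimates(seed=41, n_subjects=8, n_runs=2,
                             roi_corr=chain_correlation(0.6), sigma=3.0,
                             se_scale=1.0)
        model = SecondLevelModel(est)
        res = model.fit(seed=42, **FAST)
        corr = res.roi_correlations().set_index("pair")
        adjacent = ["IC-MGB", "MGB-AC", "AC-STG"]
        non_adjacent = ["IC-AC", "IC-STG", "MGB-STG"]
        for pair in adjacent:
            assert corr.loc[pair, "hdi_lower"] > 0.0
        assert (corr.loc[adjacent, "map"].min()
                > corr.loc[non_adjacent, "map"].max())


class TestValidation:
    def test_non_positive_se_rejected(self, estimates_null):
        bad = estimates_null.copy()
        bad.loc[bad.index[0], "se"] = 0.0
        with pytest.raises(DataError):
            SecondLevelModel(bad)

    def test_missing_cells_warn_but_fit(self, estimates_null):
        trimmed = estimates_null[
            ~((estimates_null.subject == 0) & (estimates_null.roi == "IC")
              & (estimates_null.condition == "std0"))
        ]
        with pytest.warns(UserWarning, match="cells have no rows"):
            SecondLevelModel(trimmed)

    def test_unknown_condition_set_rejected(self, estimates_null):
        with pytest.raises(DataError):
            SecondLevelModel(estimates_null, condition_set="weird")
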