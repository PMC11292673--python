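"""Path models: spec construction, data preparation, fitting, comparison."""

import numpy as np
import pandas as pd
import pytest

from _pathsim import (
    DETECTION_BETAS,
    SUPPRESSION_BETAS,
    simulate_detection_table,
    simulate_suppression_table,
)
from predsupp.bayes import waic_diff
from predsupp.exceptions import DataError, UnsupportedStructureError
from predsupp.paths import (
    PathModel,
    PathModelSpec,
    compare_path_models,
    make_specs,
    prepare_path_data,
)

FAST = dict(chains=2, iters=800, warmup=300)


class TestSpecs:
    def test_detection_bottom_up_chain(self):
        bu, td, null = make_specs("detection")
        assert bu.edges == (("IC", "MGB"), ("MGB", "AC"), ("AC", "STG"))
        assert len(bu.edges) == 3
        # source node IC has no incoming edge: intercept-only root
        assert "IC" not in [t for _, t in bu.edges]
        assert td.edges == (("STG", "AC"), ("AC", "MGB"), ("MGB", "IC"))
        assert null.edges == ()
        assert not bu.standardize and not bu.random_intercepts

    def test_suppression_top_down_first_edge(self):
        bu, td, null = make_specs("suppression")
        assert td.edges[0] == ("position", "AC")
        assert bu.edges[0] == ("position", "IC")
        assert null.edges == ()
        assert td.standardize and td.random_intercepts
        assert set(td.nodes) == {"IC", "MGB", "AC"}

    def test_non_chain_rejected(self):
        with pytest.raises(UnsupportedStructureError):
            PathModelSpec("bad", "detection", ("IC", "MGB"),
                          (("IC", "MGB"), ("MGB", "MGB")))


class TestPrepare:
    def test_detection_keeps_only_std0(self):
        table = simulate_detection_table(0, n_subjects=3, n_runs=2)
        table.loc[table.index[:5], "condition"] = "dev4"
        out = prepare_path_data(table, "detection")
        assert len(out) == (table.condition == "std0").sum()

    def test_suppression_zscores_per_subject_roi(self):
        table = simulate_suppression_table(1, n_subjects=4, n_runs=2)
        out = prepare_path_data(table, "suppression")
        for (_, _), g in out.groupby(["subject", "roi"]):
            assert g["beta"].mean() == pytest.approx(0.0, abs=1e-12)
            assert g["beta"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_position_codes_balanced(self):
        table = simulate_suppression_table(2, n_subjects=3, n_runs=2)
        out = prepare_path_data(table, "suppression")
        counts = out.groupby("position").size()
        assert set(counts.index) == {1, 2, 3}
        assert counts.nunique() == 1

    def test_idempotent_standardization(self):
        table = simulate_suppression_table(3, n_subjects=3, n_runs=2)
        once = prepare_path_data(table, "suppression")
        twice = prepare_path_data(once, "suppression")
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_zero_variance_rejected(self):
        table = simulate_suppression_table(4, n_subjects=2, n_runs=1)
        table.loc[table.roi == "AC", "beta"] = 1.0
        with pytest.raises(DataError):
            prepare_path_data(table, "suppression")


class TestFit:
    def test_null_spec_has_no_beta(self):
        table = simulate_detection_table(5, n_subjects=3, n_runs=2)
        data = prepare_path_data(table, "detection")
        null = make_specs("detection")[2]
        res = PathModel(data, null).fit(seed=1, chains=2, iters=400, warmup=200)
        assert "beta" not in res.draws.params
        assert res.beta_summaries().empty

    def test_error_free_limit_matches_ols(self):
        """With negligible observation error the chain betas are the
        sequential least-squares slopes."""
        table = simulate_detection_table(
            6, n_subjects=10, n_runs=4, se_scale=1e-3
        )
        data = prepare_path_data(table, "detection")
        bu = make_specs("detection")[0]
        res = PathModel(data, bu).fit(seed=2, **FAST)
        beta = res.draws.stacked("beta")
        wide = data.pivot_table(index=["subject", "run"], columns="roi",
                                values="beta")
        for e, (src, tgt) in enumerate(bu.edges):
            x, y = wide[src].to_numpy(), wide[tgt].to_numpy()
            X = np.column_stack([np.ones_like(x), x])
            slope = np.linalg.lstsq(X, y, rcond=None)[0][1]
            mc_se = beta[:, e].std()
            assert beta[:, e].mean() == pytest.approx(slope, abs=3 * mc_se + 1e-3)

    def test_beta_recovery_detection(self):
        table = simulate_detection_table(7)
        data = prepare_path_data(table, "detection")
        bu = make_specs("detection")[0]
        res = PathModel(data, bu).fit(seed=3, **FAST)
        summ = res.beta_summaries().set_index("edge")
        for (src, tgt), truth in zip(bu.edges, DETECTION_BETAS):
            row = summ.loc[f"{src}->{tgt}"]
            assert row["hdi_lower"] - 0.3 < truth < row["hdi_upper"] + 0.3


class TestComparison:
    def test_self_difference_zero(self):
        table = simulate_detection_table(8, n_subjects=4, n_runs=2)
        data = prepare_path_data(table, "detection")
        res = PathModel(data, make_specs("detection")[0]).fit(
            seed=4, chains=2, iters=400, warmup=200
        )
        w = res.waic()
        delta, se, sig = waic_diff(w, w)
        assert delta == 0.0 and se == 0.0 and not sig

    def test_directional_data_selects_direction(self):
        table = simulate_suppression_table(9)
        data = prepare_path_data(table, "suppression")
        comparison = compare_path_models(
            data, make_specs("suppression"), seed=5, **FAST
        )
        assert comparison.waics["top_down"].waic < comparison.waics["bottom_up"].waic
        assert comparison.winner in ("top_down", "inconclusive")

    def test_alignment_guard(self):
        table = simulate_detection_table(10, n_subjects=3, n_runs=2)
        data = prepare_path_data(table, "detection")
        spec = make_specs("detection")[0]
        a = PathModel(data, spec).fit(seed=6, chains=2, iters=300, warmup=150)
        b = PathModel(data.iloc[: len(data) // 2], spec).fit(
            seed=6, chains=2, iters=300, warmup=150
        )
        from predsupp.exceptions import AlignmentError

        with pytest.raises(AlignmentError):
            waic_diff(a.waic(), b.waic())
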