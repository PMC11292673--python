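"""First-level GLM: HRF, design matrices, round-trip identity, calibration."""

import numpy as np
import pandas as pd
import pytest

from predsupp.design import DesignParams, generate_run_design, assign_block_conditions, generate_experiment
from predsupp.exceptions import DataError, DegenerateDesignError
from predsupp.glm import (
    ROIGLM,
    build_design_matrix,
    cosine_drift,
    fit_first_level,
    hrf,
    pool_runs,
)
from predsupp.simulate import default_ground_truth, simulate_roi_bold


class TestHRF:
    def test_zero_at_onset(self):
        assert hrf(np.array([0.0]))[0] == 0.0

    def test_peak_location(self):
        t = np.linspace(0, 32, 6401)
        h = hrf(t)
        assert 4.5 <= t[np.argmax(h)] <= 6.5
        assert h.max() == pytest.approx(1.0)

    def test_net_positive_response(self):
        t = np.linspace(0, 32, 6401)
        assert np.trapezoid(hrf(t), t) > 0

    def test_undershoot_present(self):
        t = np.linspace(0, 32, 6401)
        h = hrf(t)
        assert h[(t > 12) & (t < 24)].min() < 0


class TestDesignMatrix:
    def test_oddball_columns(self, default_run):
        dm = build_design_matrix(
            default_run.events_frame(), "oddball", None, 1.53, default_run.n_volumes
        )
        assert dm.condition_columns == ["std0", "std1", "dev4", "dev5", "dev6", "std2"]
        assert dm.modulator_columns == ["std1_pos", "std2_pos"]

    def test_phaseflip_columns(self, small_experiment):
        run = small_experiment.runs[0]
        dm = build_design_matrix(
            run.events_frame(), "phaseflip", None, 1.53, run.n_volumes
        )
        assert dm.condition_columns == ["control", "inphase", "antiphase"]
        assert dm.modulator_columns == []

    def test_silent_only_run_degenerate(self, default_run):
        events = default_run.events_frame()
        silent = events[events.trial_type == "silent"]
        with pytest.raises(DegenerateDesignError):
            build_design_matrix(silent, "oddball", None, 1.53, 200)

    def test_modulator_orthogonal_to_intercept(self, default_run):
        dm = build_design_matrix(
            default_run.events_frame(), "oddball", None, 1.53, default_run.n_volumes
        )
        # centered stick weights: each modulator column integrates to ~0,
        # i.e. it is orthogonal to the run intercept up to edge effects
        for cond in ("std1", "std2"):
            col = dm.frame[f"{cond}_pos"].to_numpy()
            assert abs(col.sum()) < 1e-5 * np.abs(col).sum()

    def test_unknown_label_rejected(self, default_run):
        events = default_run.events_frame()
        events.loc[events.index[3], "trial_type"] = "weird"
        with pytest.raises(DataError):
            build_design_matrix(events, "oddball", None, 1.53, default_run.n_volumes)

    def test_drift_columns_span_cutoff(self):
        drift = cosine_drift(400, 1.53, cutoff=128.0)
        assert drift.shape[1] == int(np.floor(2 * 400 * 1.53 / 128.0))


class TestFit:
    def test_noiseless_round_trip(self, default_run):
        truth = default_ground_truth(noise_sd=0.0, drift_amplitude=0.0)
        for roi in ("IC", "AC"):
            ts = simulate_roi_bold(default_run, truth, roi, seed=3)
            res = ROIGLM(ts.values, ts.design_matrix).fit(ar1=False)
            est = res.condition_estimates().set_index("condition")
            for cond, amp in truth.amplitudes.loc[roi].items():
                assert est.loc[cond, "beta"] == pytest.approx(amp, abs=1e-6)

    def test_single_event_equals_hrf(self):
        # one std0 stick with amplitude 1: the fitted column is the sampled HRF
        rows = [
            (10.0, "std0", None), (40.0, "std1", 2), (55.0, "std1", 3),
            (70.0, "dev4", None), (85.0, "dev5", None), (95.0, "dev6", None),
            (100.0, "std2", 5), (115.0, "std2", 6),
        ]
        events = pd.DataFrame(
            [dict(onset=o, duration=0.0, trial_type=c, modulator=m)
             for o, c, m in rows]
        )
        dm = build_design_matrix(events, "oddball", None, 1.0, 160)
        y = dm.frame["std0"].to_numpy()
        res = ROIGLM(y, dm).fit(ar1=False)
        assert res.params["std0"] == pytest.approx(1.0, abs=1e-9)

    def test_zscore_calibration_white_noise(self):
        """beta/se is standard normal under pure white noise (OLS theory)."""
        params = DesignParams(blocks_per_run=3, trials_per_block=3,
                              silent_trials_per_run=4, n_runs=1)
        run = generate_run_design(0, params)
        dm = build_design_matrix(run.events_frame(), "oddball", None,
                                 params.tr, run.n_volumes)
        rng = np.random.default_rng(99)
        z = []
        for _ in range(200):
            y = rng.normal(size=dm.n_volumes)
            res = ROIGLM(y, dm).fit(ar1=False)
            z.append([res.params[c] / res.bse[c] for c in dm.condition_columns])
        z = np.array(z)
        assert abs(z.mean()) < 0.15
        assert abs(z.std() - 1.0) < 0.15

    def test_duplicated_column_rank_deficiency(self, default_run):
        dm = build_design_matrix(
            default_run.events_frame(), "oddball", None, 1.53, default_run.n_volumes
        )
        dm.frame["dup"] = dm.frame["std0"]
        y = np.random.default_rng(0).normal(size=dm.n_volumes)
        with pytest.raises(DegenerateDesignError):
            ROIGLM(y, dm).fit()

    def test_ar1_noise_autocorrelation(self):
        from predsupp.simulate import _ar1_noise

        acs = []
        for seed in range(10):
            x = _ar1_noise(np.random.default_rng(seed), 5000, rho=0.5, sd=1.0)
            x = x - x.mean()
            acs.append(float(x[1:] @ x[:-1] / (x @ x)))
        assert np.mean(acs) == pytest.approx(0.5, abs=0.05)

    def test_ar1_prewhitening_estimates_rho(self, default_run):
        truth = default_ground_truth(noise_sd=5.0, ar1_rho=0.5, drift_amplitude=0.0)
        rhos = []
        for seed in range(10):
            ts = simulate_roi_bold(default_run, truth, "IC", seed=seed)
            res = ROIGLM(ts.values, ts.design_matrix).fit(ar1=True)
            rhos.append(res.rho)
        # residual-based rho carries the usual small-sample downward bias
        assert np.mean(rhos) == pytest.approx(0.5, abs=0.12)


class TestPooling:
    def test_pooled_se_scales_with_runs(self):
        """With homogeneous noise, pooled SE ~ per-run SE / sqrt(n_runs)."""
        params = DesignParams(blocks_per_run=3, trials_per_block=3,
                              silent_trials_per_run=4, n_runs=4)
        design = generate_experiment(3, params)
        truth = default_ground_truth(noise_sd=5.0, ar1_rho=0.0, drift_amplitude=0.0)
        rows = []
        for run in design.runs:
            ts = simulate_roi_bold(run, truth, "AC", seed=100 + run.run)
            res = ROIGLM(ts.values, ts.design_matrix).fit(ar1=False)
            est = res.condition_estimates()
            est.insert(0, "roi", "AC")
            est.insert(0, "run", run.run)
            est.insert(0, "subject", 0)
            rows.append(est)
        per_run = pd.concat(rows, ignore_index=True)
        per_run = per_run[~per_run.condition.str.endswith("_pos")]
        pooled = pool_runs(per_run)
        for cond in ("std0", "dev4"):
            se_runs = per_run.loc[per_run.condition == cond, "se"]
            se_pool = pooled.loc[pooled.condition == cond, "se"].iloc[0]
            expected = 1.0 / np.sqrt((1.0 / se_runs**2).sum())
            assert se_pool == pytest.approx(expected, rel=1e-12)
            assert se_pool < se_runs.min() / np.sqrt(len(se_runs) - 1)

    def test_fit_first_level_schema(self, small_experiment):
        truth = default_ground_truth(noise_sd=2.0)
        from predsupp.simulate import simulate_experiment_bold

        bold, nuis = simulate_experiment_bold(small_experiment, truth, seed=8)
        est = fit_first_level(small_experiment, bold, nuis, subject=3)
        assert set(est.columns) == {"subject", "run", "roi", "condition", "beta", "se"}
        assert (est["se"] > 0).all()
        pooled = est[est.run == "pooled"]
        assert len(pooled) == 4 * 6  # rois x conditions
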