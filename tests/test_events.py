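"""Event calling, fate classification, alignment, commitment boundary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ktrcycle as kc
from ktrcycle.events import EventConfigError


class TestDetectOnset:
    def test_constant_subthreshold_trace_has_no_onset(self):
        t = np.arange(50) * 0.2
        assert kc.detect_onset(np.full(50, 0.1), t, theta=0.3, w=3) is None

    def test_clean_step_at_frame_40(self):
        t = np.arange(100) * 0.2
        v = np.where(np.arange(100) >= 40, 1.0, 0.0)
        assert kc.detect_onset(v, t, theta=0.5, w=3) == pytest.approx(8.0)

    def test_persistence_rejects_transient_spike(self):
        t = np.arange(50) * 0.2
        v = np.zeros(50)
        v[10:12] = 1.0  # only 2 frames above
        assert kc.detect_onset(v, t, theta=0.5, w=3) is None
        v[30:40] = 1.0
        assert kc.detect_onset(v, t, theta=0.5, w=3) == pytest.approx(6.0)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(EventConfigError):
            kc.detect_onset(np.ones(3), np.arange(3) * 0.2, theta=0.5, w=5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        shift=st.floats(min_value=0.0, max_value=1.0),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_adding_positive_constant_never_delays_onset(self, shift, seed):
        rng = np.random.default_rng(seed)
        v = np.cumsum(rng.normal(0.02, 0.1, 60))
        t = np.arange(60) * 0.2
        base = kc.detect_onset(v, t, theta=0.5, w=3)
        shifted = kc.detect_onset(v + shift, t, theta=0.5, w=3)
        if base is not None:
            assert shifted is not None and shifted <= base


class TestCallEvents:
    def test_all_quiescent_cohort_classified_low(self, calib):
        ts = kc.simulate_population(calib.replace(p_active=0.0), n_cells=100, seed=0)
        ev = kc.call_events(ts)
        assert (ev.class46 == "low").all()
        assert ev.onset2.isna().all()

    def test_high_fraction_matches_activation_probability(self, cohort):
        ev = kc.call_events(cohort)
        frac = (ev.class46 == "high").mean()
        assert frac == pytest.approx(cohort.params.p_active, abs=0.03)

    def test_cdk2_onset_follows_cdk46_onset(self, cohort):
        ev = kc.call_events(cohort)
        both = ev.dropna(subset=["onset46", "onset2"])
        assert len(both) > 100
        assert (both.onset2 >= both.onset46).mean() >= 0.99

    def test_detected_onsets_close_to_truth(self, cohort):
        """Detected CDK4/6 onsets within 2 frames of the generative onset
        for >= 95% of activating cells."""
        ev = kc.call_events(cohort).set_index("cell_id")
        truth = cohort.cells.set_index("cell_id")
        active = truth[truth.is_active46 & (truth.onset46_true < 13.0)]
        det = ev.loc[active.index, "onset46"]
        ok = det.notna()
        # detection includes the threshold-crossing latency of the rise
        latency = (det[ok] - active.onset46_true[ok]).to_numpy()
        within = np.abs(latency) <= 2 * cohort.params.dt + 1e-9
        assert ok.mean() > 0.97
        assert within.mean() >= 0.95

    def test_degron_onset_tracks_apc_inactivation(self, noiseless_active):
        ev = kc.call_events(noiseless_active).set_index("cell_id")
        truth = noiseless_active.cells.set_index("cell_id")
        horizon = noiseless_active.params.horizon
        # the degron needs time to accumulate past its detection threshold
        both = truth[truth.apc_off_true < horizon - 1.5]
        assert len(both) > 0
        det = ev.loc[both.index, "apc_off"]
        assert det.notna().all()
        assert (det >= both.apc_off_true - 1e-9).all()
        assert (det - both.apc_off_true).max() <= 1.0


class TestClassifyFate:
    def test_monotone_rising_trace_is_inc_and_decay_is_low(self, calib):
        # two hand-built cells: one keeps rising, one collapses
        t = np.arange(0, 22.2, 0.2)
        rising = 0.6 + 0.08 * np.clip(t - 4, 0, None)
        falling = np.where(t <= 11, 0.7, 0.7 * np.exp(-(t - 11)) + 0.0)
        rows = []
        for cid, v in ((0, rising), (1, falling)):
            for k, (tt, vv) in enumerate(zip(t, v)):
                rows.append(
                    {"cell_id": cid, "frame": k, "t": tt, "a46_true": 0.0,
                     "a2_true": vv, "e2f_true": 0.0, "r46_obs": 0.0,
                     "r2_obs": vv, "degron_obs": 0.0}
                )
        ts = kc.TraceSet(frames=pd.DataFrame(rows),
                         cells=pd.DataFrame({"cell_id": [0, 1]}))
        fates = kc.classify_fate(ts, t_treat=11.0).set_index("cell_id")
        assert fates.loc[0, "fate"] == "inc"
        assert fates.loc[1, "fate"] == "low"

    def test_gate_excludes_low_cdk2_cells(self, inhibition_cohort):
        fates = kc.classify_fate(inhibition_cohort, t_treat=11.0)
        excluded = fates[~fates.selected]
        assert (excluded.fate == "excluded").all()
        assert (excluded.cdk2_at_treatment < 0.6).all()

    def test_classified_fates_agree_with_generative_truth(self, inhibition_cohort):
        fates = kc.classify_fate(inhibition_cohort, t_treat=11.0)
        sel = fates[fates.selected & fates.fate.isin(["inc", "low"])]
        truth = inhibition_cohort.cells.set_index("cell_id").loc[sel.cell_id]
        assert (truth.outcome_true.to_numpy() == sel.fate.to_numpy()).mean() >= 0.95

    def test_noise_free_fates_reproduce_truth_exactly(self, calib):
        pert = kc.PerturbationSpec(mode="rapid_inhibitor", t_treat=11.0)
        ts = kc.simulate_population(
            calib.replace(horizon=22.0, noise_sd=0.0), pert, n_cells=400, seed=9
        )
        fates = kc.classify_fate(ts, 11.0)
        sel = fates[fates.selected & fates.fate.isin(["inc", "low"])]
        truth = ts.cells.set_index("cell_id").loc[sel.cell_id]
        assert len(sel) > 50
        assert (truth.outcome_true.to_numpy() == sel.fate.to_numpy()).all()

    def test_window_beyond_trace_end_rejected(self, cohort):
        with pytest.raises(EventConfigError):
            kc.classify_fate(cohort, t_treat=11.0)  # 14-h traces end at 21 h


class TestAlignAndSummarize:
    def _flat_traceset(self, values_by_cell, dt=0.2):
        rows = []
        for cid, v in values_by_cell.items():
            for k, vv in enumerate(v):
                rows.append(
                    {"cell_id": cid, "frame": k, "t": k * dt, "r2_obs": vv}
                )
        return kc.TraceSet(
            frames=pd.DataFrame(rows),
            cells=pd.DataFrame({"cell_id": list(values_by_cell)}),
        )

    def test_zero_events_reduce_to_pointwise_mean(self):
        rng = np.random.default_rng(0)
        data = {0: rng.uniform(0, 1, 20), 1: rng.uniform(0, 1, 20)}
        ts = self._flat_traceset(data)
        out = kc.align_and_summarize(ts, {0: 0.0, 1: 0.0}, "r2_obs")
        np.testing.assert_allclose(
            out["mean"].to_numpy(), (data[0] + data[1]) / 2, atol=1e-12
        )

    def test_identical_traces_identical_onsets_zero_ci(self):
        v = np.linspace(0, 1, 15)
        ts = self._flat_traceset({0: v, 1: v, 2: v})
        out = kc.align_and_summarize(ts, {0: 1.0, 1: 1.0, 2: 1.0}, "r2_obs")
        np.testing.assert_allclose(out["mean"].to_numpy(), v, atol=1e-12)
        assert np.allclose(out.ci_halfwidth.to_numpy(), 0.0, atol=1e-12)

    def test_known_lags_realign_step_to_offset_zero(self):
        step = lambda k0: np.where(np.arange(40) >= k0, 1.0, 0.0)  # noqa: E731
        ts = self._flat_traceset({0: step(10), 1: step(20), 2: step(30)})
        out = kc.align_and_summarize(
            ts, {0: 2.0, 1: 4.0, 2: 6.0}, "r2_obs"
        ).set_index("offset")
        assert out.loc[-0.2, "mean"] == pytest.approx(0.0)
        assert out.loc[0.0, "mean"] == pytest.approx(1.0)

    def test_aligned_cdk2_baseline_then_rising(self, cohort):
        """Aligned to CDK4/6 onset, mean CDK2 sits at baseline at offset 0
        and rises over the following hours."""
        ev = kc.call_events(cohort)
        onsets = ev.set_index("cell_id").onset46
        out = kc.align_and_summarize(cohort, onsets, "r2_obs").set_index("offset")
        base = cohort.params.a2_baseline
        assert out.loc[0.0, "mean"] == pytest.approx(base, abs=0.05)
        levels = [out.loc[h, "mean"] for h in (0.0, 1.0, 2.0, 3.0)]
        assert all(b >= a - 0.01 for a, b in zip(levels, levels[1:]))
        assert levels[-1] > levels[0] + 0.05


class TestCommitmentBoundary:
    def test_perfect_separation_reports_midpoint_flagged(self):
        x = np.concatenate([np.linspace(0.2, 0.8, 30), np.linspace(1.2, 1.8, 30)])
        fate = np.array(["low"] * 30 + ["inc"] * 30)
        est = kc.estimate_commitment_boundary(x, fate, n_boot=50, seed=0)
        assert est.separated
        assert est.boundary == pytest.approx(1.0)

    def test_recovers_known_logistic_boundary(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 2, 1000)
        p = 1 / (1 + np.exp(-6.0 * (x - 0.8)))
        fate = np.where(rng.random(1000) < p, "inc", "low")
        est = kc.estimate_commitment_boundary(x, fate, n_boot=200, seed=1)
        assert est.boundary == pytest.approx(0.8, abs=0.05)
        assert est.ci_low < est.boundary < est.ci_high

    def test_estimator_consistency_with_sample_size(self):
        """Mean absolute error shrinks from n=200 to n=2000 (20 seeds)."""
        def err(n, seed):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 2, n)
            p = 1 / (1 + np.exp(-6.0 * (x - 1.0)))
            fate = np.where(rng.random(n) < p, "inc", "low")
            est = kc.estimate_commitment_boundary(x, fate, n_boot=0, seed=0)
            return abs(est.boundary - 1.0)

        e200 = np.mean([err(200, s) for s in range(20)])
        e2000 = np.mean([err(2000, s) for s in range(20)])
        assert e2000 < e200

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            kc.estimate_commitment_boundary(
                np.linspace(0, 1, 20), np.array(["inc"] * 20)
            )

    def test_boundary_recovers_generative_commitment_threshold(self, inhibition_cohort):
        fates = kc.classify_fate(inhibition_cohort, t_treat=11.0)
        sel = fates[fates.selected & fates.fate.isin(["inc", "low"])]
        est = kc.estimate_commitment_boundary(
            sel.cdk2_at_treatment.to_numpy(), sel.fate.to_numpy(),
            n_boot=200, seed=3,
        )
        assert est.boundary == pytest.approx(
            inhibition_cohort.params.theta_commit, abs=0.1
        )


class TestInactivationDelay:
    def test_immediate_step_down_zero_delay(self):
        t = np.arange(100) * 0.2
        v = np.where(t < 10.0, 1.0, 0.0)
        d = kc.inactivation_delay(v, t, t_treat=10.0, theta_off=0.3, w=3)
        assert d == pytest.approx(0.0)

    def test_never_inactivating_trace_returns_none(self):
        t = np.arange(50) * 0.2
        assert kc.inactivation_delay(np.ones(50), t, 5.0, 0.3, 3) is None

    def test_rapid_inhibitor_cohort_short_delay(self, calib):
        pert = kc.PerturbationSpec(mode="rapid_inhibitor", t_treat=8.0)
        ts = kc.simulate_population(
            calib.replace(horizon=14.0), pert, n_cells=300, seed=6
        )
        delays = kc.inactivation_delays(ts, 8.0)
        assert np.nanmedian(delays.to_numpy()) <= 0.5

    def test_withdrawal_cohort_delay_in_generative_band(self, calib):
        pert = kc.PerturbationSpec(mode="mitogen_withdrawal", t_treat=11.0)
        ts = kc.simulate_population(
            calib.replace(horizon=20.0), pert, n_cells=500, seed=4
        )
        delays = kc.inactivation_delays(ts, 11.0)
        med = np.nanmedian(delays.to_numpy())
        assert 4.0 <= med <= 5.0
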