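"""Scenario orchestration: engine-vs-reference cross-checks, reproducibility,
reset contracts, weight-sum conservation and q_max calibration."""

import numpy as np
import pandas as pd
import pytest

import stdplocus._engine as eng
from stdplocus.experiments import (DEFAULT_Q_MAX, ExperimentConfig, _SimState,
                                   _locus_codes, _segment_args,
                                   calibrate_q_max, preset_config,
                                   renormalize_sum, run_competition_experiment,
                                   run_correlation_experiment,
                                   run_latency_experiment)
from stdplocus.plasticity import pair_stdp_online
from stdplocus.synapse import SynapseState, step_stp, stp_transmit_event


def _run_segment(config, state, times, srcs, n_steps, seed=0, **kw):
    args, post_steps, P_snap, q_snap = _segment_args(
        config, state, times, srcs, n_steps, np.random.default_rng(seed), **kw)
    n_post = eng.simulate_segment(*args)
    return post_steps[:n_post] * config.dt, P_snap, q_snap


class TestEngineAgainstReferences:
    def test_stp_trajectory_matches_stepwise_reference(self):
        cfg = ExperimentConfig(paradigm="correlation", rule="none",
                               mechanism="stp", n_inputs=2, duration=1000.0,
                               q_max=0.0)
        rng = np.random.default_rng(5)
        times = np.round(np.sort(rng.uniform(0, 1000, 40)), 1)
        srcs = np.zeros(times.size, dtype=np.int64)
        state = _SimState(cfg, _locus_codes(cfg))
        _run_segment(cfg, state, times, srcs, 10_000)
        ref = SynapseState(P=0.5, q=0.5, mechanism="stp")
        steps = np.round(times / 0.1).astype(int)
        for k in range(10_000):
            step_stp(ref, 0.1, False)
            for _ in range(int(np.sum(steps == k))):
                stp_transmit_event(ref)
        assert state.r[0] == pytest.approx(ref.r, abs=1e-12)
        assert state.pv[0] == pytest.approx(ref.p_v, abs=1e-12)

    def test_pair_rule_accumulates_all_pairs_sum(self):
        """With locus=post and no bound clipping, the engine's total quantal
        change equals the all-pairs STDP sum over (pre, post) spike trains."""
        cfg = ExperimentConfig(paradigm="latency", rule="pair",
                               mechanism="none", locus="post", n_inputs=2,
                               trial_length=400.0, q_max=6.0)
        delays = np.array([95.0, 105.0])
        rng = np.random.default_rng(0)
        times = np.concatenate([np.sort(rng.uniform(d, d + 25.0, 3))
                                for d in delays])
        times = np.round(times, 1)
        srcs = np.repeat(np.array([0, 1], dtype=np.int64), 3)
        state = _SimState(cfg, _locus_codes(cfg))
        post_t, _, _ = _run_segment(cfg, state, times, srcs, 4000)
        assert post_t.size > 0
        for j in range(2):
            d_expected = pair_stdp_online(np.sort(times[srcs == j]), post_t)
            assert state.q[j] - 0.5 == pytest.approx(d_expected, rel=1e-10)

    def test_blocking_freezes_the_blocked_side(self):
        for block, frozen in (("pre", "P"), ("post", "q")):
            cfg = ExperimentConfig(paradigm="correlation", neuron="adex",
                                   rule="tuned", mechanism="stp", block=block,
                                   n_inputs=10, duration=5000.0, rate=50.0)
            res = run_correlation_experiment(cfg, seed=0)
            arr = res.extras[f"{frozen}_snapshots"]
            assert np.all(arr == arr[0, 0])

    def test_lif_refractoriness_in_engine(self):
        cfg = ExperimentConfig(paradigm="correlation", rule="none",
                               mechanism="none", n_inputs=2, duration=500.0,
                               rate=200.0)
        rng = np.random.default_rng(1)
        times = np.round(np.sort(rng.uniform(0, 500.0, 400)), 1)
        srcs = rng.integers(0, 2, size=times.size).astype(np.int64)
        state = _SimState(cfg, _locus_codes(cfg))
        post_t, _, _ = _run_segment(cfg, state, times, srcs, 5000)
        assert post_t.size > 3
        assert np.all(np.diff(post_t) > 1.0 - 1e-9)


class TestReproducibility:
    def test_latency_experiment_bitwise_deterministic(self):
        cfg = preset_config("latency", "reduced", n_inputs=20, n_trials=5)
        a = run_latency_experiment(cfg, seed=3)
        b = run_latency_experiment(cfg, seed=3)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        pd.testing.assert_frame_equal(a.weights, b.weights)

    def test_different_seeds_differ(self):
        cfg = preset_config("latency", "reduced", n_inputs=20, n_trials=5)
        a = run_latency_experiment(cfg, seed=3)
        b = run_latency_experiment(cfg, seed=4)
        assert not a.metrics.equals(b.metrics)


class TestLatencyParadigm:
    def test_no_learning_control_latency_flat(self):
        cfg = preset_config("latency", "reduced", rule="none",
                            mechanism="stochastic", n_inputs=60, n_trials=40)
        slopes = []
        for s in range(4):
            r = run_latency_experiment(cfg, seed=s)
            lat = r.metrics.latency.to_numpy()
            ok = np.isfinite(lat)
            slopes.append(np.polyfit(np.arange(lat.size)[ok], lat[ok], 1)[0])
        # mean slope consistent with zero across seeds
        m, se = np.mean(slopes), np.std(slopes) / np.sqrt(len(slopes))
        assert abs(m) < 3 * max(se, 1e-3)

    def test_stp_variables_reset_each_trial(self):
        cfg = preset_config("latency", "reduced", mechanism="stp",
                            n_inputs=20, n_trials=2)
        state = _SimState(cfg, _locus_codes(cfg))
        state.r[:] = 0.2
        state.pv[:] = 0.9
        state.scalars[eng.S_G] = 3.0
        state.reset_trial(cfg)
        assert np.all(state.r == 1.0)
        assert np.array_equal(state.pv, state.P)
        assert state.scalars[eng.S_G] == 0.0

    def test_missing_latency_recorded_as_nan(self):
        cfg = preset_config("latency", "reduced", rule="none", q_max=1e-6,
                            mechanism="none", n_inputs=10, n_trials=3)
        r = run_latency_experiment(cfg, seed=0)
        assert r.metrics.n_spikes.eq(0).all()
        assert r.metrics.latency.isna().all()


class TestCompetition:
    def test_sum_conserved_through_whole_run(self):
        cfg = preset_config("competition", "reduced", n_inputs=20,
                            duration=5000.0, c_grid=(0.5,), rate_grid=(40.0,))
        r = run_competition_experiment(cfg, seed=0)
        row = r.metrics.iloc[0]
        assert row.sum_W == pytest.approx(row.target_sum, abs=1e-9)

    def test_plasticity_off_no_competition(self):
        cfg = preset_config("competition", "reduced", rule="none", n_inputs=20,
                            duration=5000.0, c_grid=(0.5,), rate_grid=(40.0,))
        r = run_competition_experiment(cfg, seed=0)
        assert r.metrics["diff"].iloc[0] == 0.0

    def test_renormalize_sum_contracts(self):
        P = np.array([0.4, 0.4])
        q = np.array([0.5, 0.5])
        P2, q2 = renormalize_sum(P, q, ["pre", "post"], 0.2)
        assert np.sum(P2 * q2) == pytest.approx(0.2, abs=1e-12)
        # already at target -> identity
        P3, q3 = renormalize_sum(P2, q2, ["pre", "post"], 0.2)
        assert np.allclose(P3, P2) and np.allclose(q3, q2)


class TestCorrelationParadigm:
    def test_c_zero_groups_exchangeable(self):
        cfg = preset_config("correlation", "reduced", rule="pair",
                            mechanism="stochastic", correlation_c=0.0,
                            n_inputs=40, duration=20_000.0)
        finals = []
        for s in range(5):
            r = run_correlation_experiment(cfg, seed=s)
            m = r.metrics.iloc[-1]
            finals.append(m.mean_W_corr - m.mean_W_unc)
        from scipy import stats
        # group difference consistent with zero at alpha = 0.01
        t = stats.ttest_1samp(finals, 0.0)
        assert t.pvalue > 0.01


class TestCalibration:
    def test_frozen_defaults_match_calibration(self):
        assert calibrate_q_max("lif") == pytest.approx(DEFAULT_Q_MAX["lif"],
                                                       rel=1e-3)
        assert calibrate_q_max("adex") == pytest.approx(DEFAULT_Q_MAX["adex"],
                                                        rel=1e-3)

    def test_threshold_behaviour_around_calibration(self):
        # just below the calibrated value the neuron must stay silent
        cfg = ExperimentConfig(paradigm="latency", rule="none",
                               mechanism="none", n_inputs=20,
                               q_max=DEFAULT_Q_MAX["lif"] * 0.98)
        state = _SimState(cfg, _locus_codes(cfg))
        times = np.full(20, 5.0)
        srcs = np.arange(20, dtype=np.int64)
        post_t, _, _ = _run_segment(cfg, state, times, srcs, 1000)
        assert post_t.size == 0


def test_config_validation_errors():
    with pytest.raises(ValueError):
        ExperimentConfig(paradigm="nonesuch")
    with pytest.raises(ValueError):
        ExperimentConfig(correlation_c=1.3)
    with pytest.raises(ValueError):
        ExperimentConfig(n_realizations=0)
    with pytest.raises(ValueError):
        preset_config("latency", preset="huge")
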