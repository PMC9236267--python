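"""Simulation scenarios: latency, correlation, competition, frequency scan.

Every scenario drives one postsynaptic neuron (LIF or AdEx) with plastic
excitatory synapses and is fully reproducible from ``(config, seed)``.

* :func:`run_latency_experiment` — repeated 375 ms trials of delayed Poisson
  bursts (25 ms at 100 Hz per input, onset delays fixed across trials);
  short-term plasticity variables and the membrane are reset to rest at each
  trial onset while long-term weights persist.  Learning shortens the
  postsynaptic first-spike latency.
* :func:`run_correlation_experiment` — continuous stimulation with half of
  the inputs pairwise correlated at level ``c`` (20 ms window) and half
  independent; learning selectively potentiates the correlated group.
* :func:`run_competition_experiment` — all inputs correlated, half
  expressing plasticity presynaptically and half postsynaptically, with the
  summed weight held fixed so the two halves compete; scanned over a
  (correlation, rate) grid.
* :func:`run_frequency_scan` — the correlation paradigm with the
  biologically tuned rule across presynaptic rates, scored by how well a
  linear classifier separates correlated from uncorrelated inputs from their
  weight statistics.

The maximal quantal conductance ``q_max`` is not a free dial: it is
calibrated per neuron model so that ~20 near-synchronous average-strength
inputs (P = q = 0.5) drive the membrane from rest to threshold
(:func:`calibrate_q_max`); the calibrated values are frozen as defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _engine
from ._engine import (LOCUS_KIND, MECH_KIND, NEURON_KIND, RULE_KIND,
                      N_SCALARS, S_G, S_REFRAC, S_V, S_Z, neuron_par_array,
                      simulate_segment)
from .metrics import compute_trial_metrics, fit_classifier, fraction_correct, \
    weight_features
from .neuron import AdExParams, LIFParams
from .plasticity import FLOOR, PairSTDPParams, TunedSTDPParams
from .stimgen import SpikeTrain, draw_delays, gen_correlated_ensemble, \
    gen_latency_trial, gen_poisson
from .synapse import N_SITES, TAU_D, TAU_F

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "preset_config",
    "calibrate_q_max",
    "run_latency_experiment",
    "run_correlation_experiment",
    "run_competition_experiment",
    "run_frequency_scan",
    "renormalize_sum",
    "DEFAULT_Q_MAX",
]

# Calibrated so that 20 simultaneous inputs at W = 0.25 drive rest -> threshold
# (see calibrate_q_max); LIF conductance is in leak units, AdEx in nS.
DEFAULT_Q_MAX = {"lif": 0.41616, "adex": 9.13194}

_PARADIGMS = ("latency", "correlation", "competition", "frequency_scan")


@dataclass
class ExperimentConfig:
    """Complete description of one simulation scenario."""

    paradigm: str = "latency"
    neuron: str = "lif"              # {"lif", "adex"}
    rule: str = "pair"               # {"pair", "tuned", "none"}
    mechanism: str = "stochastic"    # {"stochastic", "stp", "none"}
    locus: str = "both"              # pair rule: {"pre", "post", "both"}
    block: str = "none"              # tuned rule: {"none", "pre", "post"}
    n_inputs: int = 200
    rate: float = 30.0               # Hz, correlation paradigm input rate
    correlation_c: float = 0.5
    tau_corr: float = 20.0           # ms
    trial_length: float = 375.0      # ms
    n_trials: int = 150
    duration: float = 200_000.0      # ms, correlation paradigm
    dt: float = 0.1                  # ms
    n_realizations: int = 10
    base_seed: int = 0
    sum_W_fixed: bool = False
    burst_duration: float = 25.0     # ms
    burst_rate: float = 100.0        # Hz
    mean_delay: float = 100.0        # ms
    sd_delay: float = 15.0           # ms
    P0: float = 0.5
    q0: float = 0.5
    q_max: float | None = None       # None -> calibrated default for the neuron
    snapshot_interval: float = 100.0  # ms
    jitter: bool = True
    c_grid: tuple = (0.1, 0.3, 0.5, 0.7, 0.9, 0.95)
    rate_grid: tuple = (10.0, 20.0, 30.0, 40.0, 60.0, 80.0, 100.0)

    def __post_init__(self):
        if self.paradigm not in _PARADIGMS:
            raise ValueError(f"paradigm must be one of {_PARADIGMS}")
        if self.neuron not in NEURON_KIND:
            raise ValueError("neuron must be 'lif' or 'adex'")
        if self.rule not in RULE_KIND:
            raise ValueError("rule must be 'pair', 'tuned' or 'none'")
        if self.mechanism not in MECH_KIND:
            raise ValueError("mechanism must be 'stochastic', 'stp' or 'none'")
        if self.locus not in LOCUS_KIND:
            raise ValueError("locus must be 'pre', 'post' or 'both'")
        if self.block not in ("none", "pre", "post"):
            raise ValueError("block must be 'none', 'pre' or 'post'")
        if not (0.0 <= self.correlation_c <= 1.0):
            raise ValueError("correlation_c must lie in [0, 1]")
        if self.n_inputs < 2:
            raise ValueError("n_inputs must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if not (0.0 < self.P0 <= 1.0 and 0.0 < self.q0 <= 1.0):
            raise ValueError("P0 and q0 must lie in (0, 1]")

    def resolved_q_max(self) -> float:
        return self.q_max if self.q_max is not None else DEFAULT_Q_MAX[self.neuron]

    def neuron_params(self):
        return LIFParams() if self.neuron == "lif" else AdExParams()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["c_grid"] = list(d["c_grid"])
        d["rate_grid"] = list(d["rate_grid"])
        return d


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    seed: int
    metrics: pd.DataFrame            # per trial (latency) or per sample
    weights: pd.DataFrame            # long format trajectories
    post_spikes: list                # SpikeTrain per trial, or [SpikeTrain]
    extras: dict = field(default_factory=dict)


def preset_config(paradigm: str, preset: str = "paper", **overrides) -> ExperimentConfig:
    """Scenario defaults; ``preset='reduced'`` is the desk-scale variant."""
    kw: dict = {"paradigm": paradigm}
    if paradigm in ("correlation", "frequency_scan"):
        kw.update(n_inputs=200, rate=30.0, duration=200_000.0)
    if paradigm == "competition":
        kw.update(n_inputs=100, duration=100_000.0, mechanism="stochastic",
                  sum_W_fixed=True)
    if paradigm == "frequency_scan":
        kw.update(neuron="adex", rule="tuned", mechanism="stp",
                  rate_grid=tuple(float(r) for r in range(10, 121, 10)))
    if preset == "reduced":
        if paradigm == "latency":
            kw.update(n_inputs=100, n_trials=100)
        elif paradigm == "correlation":
            kw.update(n_inputs=100, duration=100_000.0)
        elif paradigm == "competition":
            # competition needs to reach quasi-steady state to be meaningful
            kw.update(n_inputs=60, duration=100_000.0)
        elif paradigm == "frequency_scan":
            kw.update(n_inputs=100, duration=100_000.0, n_realizations=3)
    elif preset != "paper":
        raise ValueError("preset must be 'paper' or 'reduced'")
    kw.update(overrides)
    return ExperimentConfig(**kw)


# ---------------------------------------------------------------------------
# q_max calibration


def calibrate_q_max(neuron: str = "lif", n_coincident: int = 20,
                    P: float = 0.5, q: float = 0.5, dt: float = 0.01) -> float:
    """Smallest q_max for which ``n_coincident`` simultaneous inputs of
    strength ``P*q`` drive the neuron from rest to threshold (bisection)."""
    params = LIFParams() if neuron == "lif" else AdExParams()

    def spikes(q_max: float) -> bool:
        G = n_coincident * P * q * q_max
        if neuron == "lif":
            V, g = params.E_v, G
            for _ in range(int(100.0 / dt)):
                V += dt * ((params.E_v - V) + g * (params.E_e - V)) / params.tau_V
                g *= np.exp(-dt / params.tau_g)
                if V >= params.V_th:
                    return True
            return False
        V, z, g = params.E_L, 0.0, G
        for _ in range(int(100.0 / dt)):
            arg = min((V - params.V_T) / params.Delta_T, 16.0)
            I_exp = params.g_L * params.Delta_T * np.exp(arg)
            dV = (params.g_L * (params.E_L - V) + I_exp - g * V - z) / params.C
            dz = (params.c_z * (V - params.E_L) - z) / params.tau_W
            V += dt * dV
            z += dt * dz
            g *= np.exp(-dt / params.tau_g)
            if V >= params.V_detect:
                return True
        return False

    lo, hi = 1e-4, 1.0
    while not spikes(hi):
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("calibration failed to bracket threshold")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# engine plumbing


class _SimState:
    """Mutable per-realization simulation state shared across segments."""

    def __init__(self, config: ExperimentConfig, locus_codes: np.ndarray):
        n = config.n_inputs
        self.P = np.full(n, config.P0)
        self.q = np.full(n, config.q0)
        self.r = np.ones(n)
        self.pv = self.P.copy()
        self.x_plus = np.zeros(n)
        self.pre_trace = np.zeros(n)
        self.scalars = np.zeros(N_SCALARS)
        params = config.neuron_params()
        self.scalars[S_V] = params.E_v if config.neuron == "lif" else params.E_L
        self.locus = locus_codes
        pair = PairSTDPParams(P0=config.P0, q0=config.q0, locus="both")
        cap_both = pair.cap_both
        self.capP = np.where(locus_codes == _engine.LOCUS_BOTH, cap_both, 1.0)
        self.capQ = np.where(locus_codes == _engine.LOCUS_BOTH, cap_both, 1.0)

    def reset_trial(self, config: ExperimentConfig):
        """Between latency trials: membrane, conductance and STP to rest;
        long-term weights and plasticity traces persist."""
        params = config.neuron_params()
        self.scalars[S_V] = params.E_v if config.neuron == "lif" else params.E_L
        self.scalars[S_G] = 0.0
        self.scalars[S_Z] = 0.0
        self.scalars[S_REFRAC] = 0.0
        self.r[:] = 1.0
        self.pv[:] = self.P

    @property
    def W(self) -> np.ndarray:
        return self.P * self.q


def _segment_args(config: ExperimentConfig, state: _SimState,
                  times: np.ndarray, srcs: np.ndarray, n_steps: int,
                  uniform_rng: np.random.Generator | None,
                  snap_every: int = 0,
                  renorm: bool = False, target_sum: float = 0.0):
    dt = config.dt
    # epsilon guards times that sit exactly on a step boundary in decimal
    steps = np.minimum(np.floor(times / dt + 1e-6).astype(np.int64),
                       n_steps - 1)
    order = np.argsort(steps, kind="stable")
    steps, srcs = steps[order], srcs[order].astype(np.int64)
    if config.mechanism == "stochastic":
        uniforms = uniform_rng.random((steps.size, N_SITES))
    else:
        uniforms = np.empty((0, N_SITES))
    max_per_step = int(np.bincount(steps).max()) if steps.size else 1
    rel = np.empty(max(1, max_per_step))
    pair = PairSTDPParams(P0=config.P0, q0=config.q0, locus="both")
    tuned = TunedSTDPParams()
    n_snap = n_steps // snap_every if snap_every > 0 else 0
    P_snap = np.empty((n_snap, config.n_inputs))
    q_snap = np.empty((n_snap, config.n_inputs))
    post_steps = np.empty(n_steps, dtype=np.int64)
    args = (
        steps, srcs, n_steps, dt,
        NEURON_KIND[config.neuron], MECH_KIND[config.mechanism],
        RULE_KIND[config.rule],
        neuron_par_array(config.neuron, config.neuron_params()),
        config.resolved_q_max(), N_SITES,
        config.neuron_params().tau_g, TAU_D, TAU_F,
        pair.tau_STDP, pair.c_pot, pair.c_dep, FLOOR,
        state.locus, state.capP, state.capQ,
        tuned.c_plus, tuned.d_minus, tuned.d_plus,
        tuned.tau_x_plus, tuned.tau_y_plus, tuned.tau_y_minus, tuned.alpha,
        1 if config.block == "pre" else 0,
        1 if config.block == "post" else 0,
        1 if renorm else 0, target_sum,
        state.P, state.q, state.r, state.pv, state.x_plus, state.pre_trace,
        state.scalars, uniforms, rel, post_steps, snap_every, P_snap, q_snap,
    )
    return args, post_steps, P_snap, q_snap


def _locus_codes(config: ExperimentConfig) -> np.ndarray:
    if config.paradigm == "competition":
        codes = np.empty(config.n_inputs, dtype=np.int64)
        half = config.n_inputs // 2
        codes[:half] = _engine.LOCUS_PRE
        codes[half:] = _engine.LOCUS_POST
        return codes
    return np.full(config.n_inputs, LOCUS_KIND[config.locus], dtype=np.int64)


# ---------------------------------------------------------------------------
# scenarios


def run_latency_experiment(config: ExperimentConfig,
                           seed: int | None = None) -> ExperimentResult:
    """Latency paradigm: repeated delayed-burst trials with online plasticity."""
    if config.paradigm != "latency":
        raise ValueError("config.paradigm must be 'latency'")
    seed = config.base_seed if seed is None else seed
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    delay_ss, trial_parent, unif_parent = ss.spawn(3)
    delays = draw_delays(config.n_inputs, config.mean_delay, config.sd_delay,
                         np.random.default_rng(delay_ss),
                         burst_duration=config.burst_duration,
                         trial_length=config.trial_length)
    trial_seeds = trial_parent.spawn(config.n_trials)
    unif_seeds = unif_parent.spawn(config.n_trials)

    state = _SimState(config, _locus_codes(config))
    n_steps = int(round(config.trial_length / config.dt))
    early = delays < np.median(delays)

    rows, wrows, post_trains = [], [], []
    for trial in range(config.n_trials):
        stim = gen_latency_trial(delays, trial_seeds[trial],
                                 burst_duration=config.burst_duration,
                                 burst_rate=config.burst_rate,
                                 trial_length=config.trial_length)
        times, srcs = stim.as_arrays()
        state.reset_trial(config)
        args, post_steps, _, _ = _segment_args(
            config, state, times, srcs, n_steps,
            np.random.default_rng(unif_seeds[trial]))
        n_post = simulate_segment(*args)
        post_t = post_steps[:n_post] * config.dt
        post_trains.append(SpikeTrain(-1, post_t))
        m = compute_trial_metrics(post_t, reference=config.mean_delay)
        W = state.W
        rows.append({
            "trial": trial, "latency": m.latency, "duration": m.duration,
            "intraburst_frequency": m.intraburst_frequency,
            "n_spikes": m.n_spikes,
            "mean_W": W.mean(), "mean_W_early": W[early].mean(),
            "mean_W_late": W[~early].mean(),
        })
        for j in range(config.n_inputs):
            wrows.append((trial, j, delays[j], state.P[j], state.q[j], W[j]))

    weights = pd.DataFrame(
        wrows, columns=["trial", "synapse", "delay", "P", "q", "W"])
    return ExperimentResult(config, seed, pd.DataFrame(rows), weights,
                            post_trains, extras={"delays": delays})


def _correlation_stimulus(config: ExperimentConfig, ss: np.random.SeedSequence):
    """Correlated half (ids [0, n/2)) plus independent half; labels per input."""
    half = config.n_inputs // 2
    corr_ss, unc_ss = ss.spawn(2)
    ens = gen_correlated_ensemble(
        half, config.rate, config.correlation_c, config.tau_corr,
        config.duration, np.random.default_rng(corr_ss), jitter=config.jitter)
    trains = list(ens.trains)
    rng = np.random.default_rng(unc_ss)
    for j in range(half, config.n_inputs):
        trains.append(gen_poisson(config.rate, config.duration, rng, source_id=j))
    labels = np.array(["correlated"] * half
                      + ["uncorrelated"] * (config.n_inputs - half))
    times = np.concatenate([t.times for t in trains])
    srcs = np.concatenate([np.full(len(t), t.source_id, dtype=np.int64)
                           for t in trains])
    return times, srcs, labels


def run_correlation_experiment(config: ExperimentConfig,
                               seed: int | None = None) -> ExperimentResult:
    """Correlation paradigm: continuous stimulation, correlated vs not."""
    if config.paradigm not in ("correlation", "frequency_scan"):
        raise ValueError("config.paradigm must be 'correlation'")
    seed = config.base_seed if seed is None else seed
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    stim_ss, unif_ss = ss.spawn(2)
    times, srcs, labels = _correlation_stimulus(config, stim_ss)

    state = _SimState(config, _locus_codes(config))
    n_steps = int(round(config.duration / config.dt))
    snap_every = max(1, int(round(config.snapshot_interval / config.dt)))
    args, post_steps, P_snap, q_snap = _segment_args(
        config, state, times, srcs, n_steps,
        np.random.default_rng(unif_ss), snap_every=snap_every)
    n_post = simulate_segment(*args)
    post_t = post_steps[:n_post] * config.dt

    W_snap = P_snap * q_snap
    snap_t = (np.arange(1, W_snap.shape[0] + 1) * snap_every) * config.dt
    corr = labels == "correlated"
    post_counts = np.histogram(post_t, bins=np.concatenate(([0.0], snap_t)))[0]
    metrics = pd.DataFrame({
        "time_ms": snap_t,
        "mean_W_corr": W_snap[:, corr].mean(axis=1),
        "mean_W_unc": W_snap[:, ~corr].mean(axis=1),
        "post_rate_hz": post_counts / (snap_every * config.dt / 1000.0),
    })
    n_snap, n = W_snap.shape
    weights = pd.DataFrame({
        "time_ms": np.repeat(snap_t, n),
        "synapse": np.tile(np.arange(n), n_snap),
        "label": np.tile(labels, n_snap),
        "P": P_snap.ravel(),
        "q": q_snap.ravel(),
        "W": W_snap.ravel(),
    })
    return ExperimentResult(
        config, seed, metrics, weights, [SpikeTrain(-1, post_t)],
        extras={"labels": labels, "W_snapshots": W_snap,
                "P_snapshots": P_snap, "q_snapshots": q_snap,
                "snapshot_times": snap_t})


def run_competition_experiment(config: ExperimentConfig,
                               seed: int | None = None) -> ExperimentResult:
    """Pre- vs postsynaptic halves competing under a fixed summed weight.

    All inputs are correlated at each grid level ``c``; the first half
    expresses pair-STDP presynaptically, the second half postsynaptically,
    and after every plasticity step the summed weight is rescaled to its
    initial value.  The output per (c, rate) cell is the final
    ``mean(W_pre_half) - mean(W_post_half)``.
    """
    if config.paradigm != "competition":
        raise ValueError("config.paradigm must be 'competition'")
    seed = config.base_seed if seed is None else seed
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    n_steps = int(round(config.duration / config.dt))
    half = config.n_inputs // 2
    rows = []
    for c in config.c_grid:
        for rate in config.rate_grid:
            cell_ss = np.random.SeedSequence(
                entropy=ss.entropy,
                spawn_key=(int(round(1000 * c)), int(round(rate))))
            stim_ss, unif_ss = cell_ss.spawn(2)
            ens = gen_correlated_ensemble(
                config.n_inputs, rate, c, config.tau_corr, config.duration,
                np.random.default_rng(stim_ss), jitter=config.jitter)
            times, srcs = ens.as_arrays()
            state = _SimState(config, _locus_codes(config))
            target = float(np.sum(state.W))
            args, _, _, _ = _segment_args(
                config, state, times, srcs, n_steps,
                np.random.default_rng(unif_ss),
                renorm=config.sum_W_fixed, target_sum=target)
            simulate_segment(*args)
            W = state.W
            rows.append({
                "c": c, "rate": rate,
                "diff": W[:half].mean() - W[half:].mean(),
                "sum_W": W.sum(), "target_sum": target,
            })
    metrics = pd.DataFrame(rows)
    return ExperimentResult(config, seed, metrics,
                            pd.DataFrame(), [], extras={})


def run_frequency_scan(config: ExperimentConfig,
                       seed: int | None = None) -> ExperimentResult:
    """Correlated/uncorrelated separability of the tuned model vs input rate.

    For each rate in ``config.rate_grid`` and each realization, run the
    correlation paradigm, reduce each input to the (mean, variance) of its
    weight over the final half of the run, train the linear classifier on a
    stratified half of the inputs and score the held-out half.
    """
    if config.paradigm != "frequency_scan":
        raise ValueError("config.paradigm must be 'frequency_scan'")
    seed = config.base_seed if seed is None else seed
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rows = []
    for rate in config.rate_grid:
        for k in range(config.n_realizations):
            run_ss = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(int(round(rate)), k))
            sub = dataclasses.replace(config, rate=float(rate))
            res = run_correlation_experiment(sub, seed=run_ss)
            feats = weight_features(res.extras["W_snapshots"], window=0.5)
            labels = res.extras["labels"]
            split_seed = int(run_ss.generate_state(1)[0] % (2 ** 31))
            model = fit_classifier(feats, labels, split_seed=split_seed)
            frac = fraction_correct(model, feats, labels)
            post_rate = (len(res.post_spikes[0].times)
                         / (config.duration / 1000.0))
            rows.append({"rate": rate, "realization": k,
                         "fraction_correct": frac, "post_rate_hz": post_rate})
    metrics = pd.DataFrame(rows)
    summary = metrics.groupby("rate", as_index=False)["fraction_correct"].mean()
    best = summary.loc[summary["fraction_correct"].idxmax()]
    return ExperimentResult(
        config, seed, metrics, pd.DataFrame(), [],
        extras={"summary": summary, "best_rate": float(best["rate"]),
                "best_fraction": float(best["fraction_correct"])})


def renormalize_sum(P: np.ndarray, q: np.ndarray, locus: Sequence[str],
                    target_sum: float, P0: float = 0.5, q0: float = 0.5,
                    floor: float = FLOOR) -> tuple[np.ndarray, np.ndarray]:
    """Rescale weights multiplicatively so that sum(P*q) == target_sum.

    The factor is expressed through each synapse's plastic side (``P`` for
    locus 'pre', ``q`` for 'post', split for 'both'), respecting caps and
    floors; iterated so clipping does not break the conservation.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be > 0")
    P, q = P.copy(), q.copy()
    codes = np.array([LOCUS_KIND[l] for l in locus], dtype=np.int64)
    pair = PairSTDPParams(P0=P0, q0=q0)
    capP = np.where(codes == _engine.LOCUS_BOTH, pair.cap_both, 1.0)
    capQ = np.where(codes == _engine.LOCUS_BOTH, pair.cap_both, 1.0)
    _engine._renormalize(P, q, codes, target_sum, floor, capP, capQ)
    return P, q
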