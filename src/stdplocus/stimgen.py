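"""Synthetic presynaptic spike-train ensembles.

Two stimulus classes drive every simulation in this package:

* **Latency paradigm** — repeated short trials in which each presynaptic
  source fires a brief Poisson burst (default 25 ms at 100 Hz) starting at a
  source-specific delay.  The delays are drawn once from a normal
  distribution and then held fixed across trials, so that the temporal order
  of inputs is a stable feature the neuron can learn.

* **Correlation paradigm** — continuous Poisson stimulation in which a
  subgroup of sources shares correlated rate fluctuations on a timescale
  ``tau_corr`` (default 20 ms) while the remaining sources are independent.

Correlated trains are built with a calibrated multiple-interaction process
(MIP): a "mother" Poisson train is thinned independently into each child
train and every copied event is jittered by a uniform offset.  Jittering
spreads coincident events across bin boundaries and attenuates the same-bin
spike-count correlation by a factor ``rho = 1 - s/(3*tau_corr)`` for jitter
width ``s``; the generator compensates by inflating the copy probability to
``c/rho`` and, for strong correlations, shrinking the jitter width so that
the realized pairwise count correlation at bin width ``tau_corr`` equals the
requested ``c`` while each train's marginal rate is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "StimulusEnsemble",
    "gen_poisson",
    "gen_correlated_ensemble",
    "draw_delays",
    "gen_latency_trial",
    "write_raster",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) of one source (or of the output neuron)."""

    source_id: int
    times: np.ndarray  # ms, non-decreasing

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("spike times must be non-decreasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class StimulusEnsemble:
    """A set of spike trains plus the generation metadata.

    ``labels`` carries one tag per train: the group name (``"correlated"`` /
    ``"uncorrelated"``) in the correlation paradigm, or the assigned delay in
    ms in the latency paradigm.
    """

    trains: list[SpikeTrain]
    labels: list
    duration: float  # ms
    rate: float  # Hz
    correlation_c: float = 0.0
    tau_corr: float = 20.0  # ms
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.labels) != len(self.trains):
            raise ValueError("one label per train required")
        if self.tau_corr <= 0:
            raise ValueError("tau_corr must be > 0")

    @property
    def n_sources(self) -> int:
        return len(self.trains)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (times, source_ids), sorted by time (stable)."""
        times = np.concatenate([t.times for t in self.trains]) if self.trains else np.empty(0)
        srcs = np.concatenate(
            [np.full(len(t), t.source_id, dtype=np.int64) for t in self.trains]
        ) if self.trains else np.empty(0, dtype=np.int64)
        order = np.argsort(times, kind="stable")
        return times[order], srcs[order]


def _check_train(times: np.ndarray, duration: float) -> np.ndarray:
    times = np.sort(times)
    if times.size and (times[0] < 0 or times[-1] > duration):
        raise AssertionError("generated spike outside [0, duration]")
    return times


def gen_poisson(rate: float, duration: float, rng_seed, source_id: int = 0) -> SpikeTrain:
    """Homogeneous Poisson spike train.

    Parameters
    ----------
    rate : float
        Firing rate in Hz (events per second).
    duration : float
        Interval length in ms; events fall in ``[0, duration]``.
    rng_seed : int or numpy.random.Generator
        Seed (or generator) making the draw reproducible.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(rng_seed)
    n = rng.poisson(rate * duration / 1000.0)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    return SpikeTrain(source_id, _check_train(times, duration))


def _mip_params(c: float, tau_corr: float) -> tuple[float, float]:
    """Copy probability and jitter width realizing count correlation ``c``.

    With jitter width ``s`` the same-bin correlation of two children is
    ``rho * c_copy`` with ``rho = 1 - s/(3 tau_corr)``; choose
    ``s = min(tau_corr, 3 tau_corr (1-c))`` so ``c_copy = c/rho <= 1``.
    """
    s = min(tau_corr, 3.0 * tau_corr * (1.0 - c))
    rho = 1.0 - s / (3.0 * tau_corr)
    c_copy = c / rho if rho > 0 else 1.0
    return min(c_copy, 1.0), s


def gen_correlated_ensemble(
    n_sources: int,
    rate: float,
    c: float,
    tau_corr: float,
    duration: float,
    rng_seed,
    jitter: bool = True,
    label: str = "correlated",
    id_offset: int = 0,
) -> StimulusEnsemble:
    """Ensemble of ``n_sources`` trains with pairwise count correlation ``c``.

    Correlation is measured as the Pearson correlation of spike counts in
    bins of width ``tau_corr``.  ``c = 0`` yields independent Poisson trains;
    ``c = 1`` (or ``jitter=False`` with the copy probability then exactly
    ``c``) yields synchronous copies of the mother train.
    """
    if not (0.0 <= c <= 1.0):
        raise ValueError("correlation_c must lie in [0, 1]")
    if n_sources < 2:
        raise ValueError("n_sources must be >= 2")
    if tau_corr <= 0:
        raise ValueError("tau_corr must be > 0")
    rng = np.random.default_rng(rng_seed)

    trains: list[SpikeTrain] = []
    if c == 0.0:
        for j in range(n_sources):
            trains.append(
                gen_poisson(rate, duration, rng, source_id=id_offset + j)
            )
    else:
        c_copy, s = _mip_params(c, tau_corr)
        if not jitter:
            c_copy, s = c, 0.0
        mother_rate = rate / c_copy  # Hz; each child keeps rate = c_copy * mother_rate
        mother = gen_poisson(mother_rate, duration, rng).times
        for j in range(n_sources):
            keep = rng.random(mother.size) < c_copy
            times = mother[keep]
            if s > 0:
                times = times + rng.uniform(0.0, s, size=times.size)
            times = times[(times >= 0.0) & (times <= duration)]
            trains.append(SpikeTrain(id_offset + j, _check_train(times, duration)))

    return StimulusEnsemble(
        trains=trains,
        labels=[label] * n_sources,
        duration=duration,
        rate=rate,
        correlation_c=c,
        tau_corr=tau_corr,
    )


def draw_delays(
    n_sources: int,
    mean_delay: float,
    sd_delay: float,
    rng_seed,
    burst_duration: float = 25.0,
    trial_length: float = 375.0,
) -> np.ndarray:
    """Per-source burst-onset delays (ms), fixed across trials.

    Delays are normal(mean_delay, sd_delay), clipped so the whole burst fits
    inside ``[0, trial_length]``.
    """
    if sd_delay < 0:
        raise ValueError("sd_delay must be >= 0")
    if not (0.0 <= mean_delay <= trial_length):
        raise ValueError("mean_delay must lie within the trial window")
    rng = np.random.default_rng(rng_seed)
    delays = rng.normal(mean_delay, sd_delay, size=n_sources)
    return np.clip(delays, 0.0, trial_length - burst_duration)


def gen_latency_trial(
    delays: np.ndarray,
    rng_seed,
    burst_duration: float = 25.0,
    burst_rate: float = 100.0,
    trial_length: float = 375.0,
) -> StimulusEnsemble:
    """One latency-paradigm trial: a fresh Poisson burst per source.

    Source ``j`` fires a Poisson burst at ``burst_rate`` restricted to
    ``[delays[j], delays[j] + burst_duration]``; the delays are reused across
    trials while the within-burst spikes are redrawn every trial.
    """
    delays = np.asarray(delays, dtype=float)
    if np.any(delays + burst_duration > trial_length):
        raise ValueError("delay + burst_duration exceeds trial_length")
    if np.any(delays < 0):
        raise ValueError("delays must be >= 0")
    rng = np.random.default_rng(rng_seed)
    trains = []
    for j, d in enumerate(delays):
        burst = gen_poisson(burst_rate, burst_duration, rng, source_id=j)
        trains.append(SpikeTrain(j, _check_train(burst.times + d, trial_length)))
    return StimulusEnsemble(
        trains=trains,
        labels=list(delays),
        duration=trial_length,
        rate=burst_rate,
    )


def write_raster(ensemble_or_trains, path) -> None:
    """Write spikes as two-column delimited text: source_id, time_ms."""
    trains: Sequence[SpikeTrain]
    if isinstance(ensemble_or_trains, StimulusEnsemble):
        trains = ensemble_or_trains.trains
    else:
        trains = ensemble_or_trains
    with open(path, "w") as fh:
        fh.write("source_id,time_ms\n")
        for t in trains:
            for x in t.times:
                fh.write(f"{t.source_id},{x!r}\n")
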