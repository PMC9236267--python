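"""Presynaptic transmission: quantal release and short-term plasticity.

The effective synaptic weight factorizes as ``W = P * q`` with the
presynaptic weight ``P`` (baseline release probability) and the postsynaptic
quantal factor ``q``, both in (0, 1]; a transmitted spike increments the
excitatory conductance by a multiple of ``q_max``, the maximal quantal
conductance.

Three transmission mechanisms are supported:

* ``"none"`` — deterministic increment ``P * q * q_max`` (pure weight).
* ``"stochastic"`` — binomial vesicle release over ``N = 5`` independent
  sites: ``k ~ Binomial(N, P)`` released vesicles yield ``(k/N) q q_max``,
  so the expected increment is ``P q q_max`` while the trial-to-trial
  coefficient of variation decreases with P.
* ``"stp"`` — Tsodyks–Markram short-term plasticity.  The per-spike release
  probability ``p = p_v * r`` combines the instantaneous release probability
  ``p_v`` (facilitation, recovering to the baseline ``P^B = P`` with tau_F)
  and the available-resource fraction ``r`` (depression, recovering to 1
  with tau_D)::

      dr/dt   = (1 - r)/tau_D  - p_v r X(t)
      dp_v/dt = (P^B - p_v)/tau_F + P^B (1 - p_v) X(t)

  At a presynaptic spike the facilitation jump is applied first and release
  and depression then use the updated ``p_v`` (facilitation affects the
  triggering spike).  Transmission under STP is a deterministic amplitude
  modulation: increment ``p_v * r * q * q_max``.

With tau_D = 200 ms and tau_F = 50 ms the synapse is mostly depressing; the
closed-form event map (:func:`stp_steady_state`) gives its steady state
under regular stimulation exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapseState",
    "decay_conductance",
    "release_binomial",
    "step_stp",
    "transmit",
    "stp_transmit_event",
    "stp_steady_state",
]

TAU_D = 200.0  # ms, resource recovery (depression)
TAU_F = 50.0   # ms, facilitation decay
N_SITES = 5


@dataclass
class SynapseState:
    P: float = 0.5          # presynaptic weight / baseline release probability
    q: float = 0.5          # quantal factor
    q_max: float = 1.0      # maximal quantal conductance (model units)
    N_sites: int = N_SITES
    r: float = 1.0          # available resources
    p_v: float = 0.5        # instantaneous release probability
    mechanism: str = "none"  # {"none", "stochastic", "stp"}

    def __post_init__(self):
        if not (0.0 < self.P <= 1.0 and 0.0 < self.q <= 1.0):
            raise ValueError("P and q must lie in (0, 1]")
        if not (0.0 <= self.r <= 1.0):
            raise ValueError("r must lie in [0, 1]")

    @property
    def W(self) -> float:
        return self.P * self.q


def decay_conductance(g: float, dt: float, tau_g: float = 5.0) -> float:
    """Exact exponential conductance decay ``g * exp(-dt/tau_g)``."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return g * math.exp(-dt / tau_g)


def release_binomial(state: SynapseState, rng: np.random.Generator) -> float:
    """Stochastic quantal release at one presynaptic spike.

    Draws ``k ~ Binomial(N_sites, P)`` and returns ``(k/N_sites) q q_max``.
    """
    k = rng.binomial(state.N_sites, state.P)
    return (k / state.N_sites) * state.q * state.q_max


def step_stp(state: SynapseState, dt: float, spiked: bool,
             tau_D: float = TAU_D, tau_F: float = TAU_F) -> None:
    """Advance the Tsodyks–Markram variables by ``dt`` (exact between-spike
    relaxation), then apply the spike jumps if ``spiked``.

    Returns nothing; ``state.r`` and ``state.p_v`` are updated in place.
    """
    PB = state.P
    if dt > 0:
        eD = math.exp(-dt / tau_D)
        eF = math.exp(-dt / tau_F)
        state.r = 1.0 - (1.0 - state.r) * eD
        state.p_v = PB + (state.p_v - PB) * eF
    if spiked:
        state.p_v = state.p_v + PB * (1.0 - state.p_v)  # facilitation first
        state.r = state.r * (1.0 - state.p_v)           # depression uses updated p_v


def transmit(state: SynapseState, rng: np.random.Generator | None = None) -> float:
    """Conductance increment for one presynaptic spike.

    This is a pure read of the current state: under ``"stp"`` it returns
    ``p_v * r * q * q_max`` with the state as-is (for a rested synapse,
    ``p_v = P`` and ``r = 1``, this equals the ``"none"`` increment).  The
    spike-triggered facilitation/depression jumps are sequenced by
    :func:`stp_transmit_event`, which is what the simulation engine uses.
    """
    if state.mechanism == "stp":
        return state.p_v * state.r * state.q * state.q_max
    if state.mechanism == "stochastic":
        if rng is None:
            raise ValueError("stochastic transmission requires an rng")
        return release_binomial(state, rng)
    if state.mechanism == "none":
        return state.P * state.q * state.q_max
    raise ValueError(f"unknown mechanism: {state.mechanism!r}")


def stp_transmit_event(state: SynapseState, facilitation_first: bool = True) -> float:
    """Process one presynaptic spike under STP: facilitation jump, release,
    depression.  With ``facilitation_first`` (default, the common convention
    for this model) the jump to ``p_v`` is applied before release, so
    facilitation affects the triggering spike; otherwise release uses the
    pre-jump ``p_v``.  Returns the conductance increment ``p_v r q q_max``
    with ``r`` taken before depression."""
    PB = state.P
    if facilitation_first:
        state.p_v = state.p_v + PB * (1.0 - state.p_v)
        inc = state.p_v * state.r * state.q * state.q_max
        state.r = state.r * (1.0 - state.p_v)
    else:
        inc = state.p_v * state.r * state.q * state.q_max
        state.r = state.r * (1.0 - state.p_v)
        state.p_v = state.p_v + PB * (1.0 - state.p_v)
    return inc


def stp_steady_state(PB: float, rate_hz: float,
                     tau_D: float = TAU_D, tau_F: float = TAU_F) -> dict:
    """Closed-form steady state of the TM event map under a regular train.

    Between spikes separated by ``T = 1000/rate`` the variables relax
    affinely; at each spike ``p_v`` jumps by ``PB (1 - p_v)`` and ``r`` is
    multiplied by ``(1 - p_v_post)``.  The per-interval affine recursions
    have the fixed point (pre-spike values):

        p_v* = PB / (1 - (1 - PB) e_F),       e_F = exp(-T/tau_F)
        r*   = (1 - e_D) / (1 - e_D (1 - p_v_plus*)),  e_D = exp(-T/tau_D)

    with the post-jump ``p_v_plus* = p_v* + PB (1 - p_v*)``.  The effective
    per-spike release probability is ``p* = p_v_plus* * r*``.
    """
    if rate_hz <= 0:
        return {"p_v": PB, "r": 1.0, "p_eff": PB}
    T = 1000.0 / rate_hz
    eF = math.exp(-T / tau_F)
    eD = math.exp(-T / tau_D)
    pv = PB / (1.0 - (1.0 - PB) * eF)
    pv_plus = pv + PB * (1.0 - pv)
    r = (1.0 - eD) / (1.0 - eD * (1.0 - pv_plus))
    return {"p_v": pv, "r": r, "p_eff": pv_plus * r}
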