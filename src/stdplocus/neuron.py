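"""Point-neuron membrane models.

Two models are used: a conductance-based leaky integrate-and-fire (LIF)
neuron for the minimal scenarios, and an adaptive exponential
integrate-and-fire (AdEx) neuron for the biologically tuned scenarios.

LIF (dimensionless synaptic conductance, in units of the leak conductance)::

    tau_V dV/dt = (E_v - V) + g (E_e - V)

with threshold V_th, reset V_reset and a 1 ms refractory period during which
V is clamped at the reset value.  The excitatory drive is depolarizing
(+g (E_e - V)).

AdEx (conductances in nS, currents in pA, capacitance in pF)::

    C dV/dt    = g_L (E_L - V) + g_L Delta_T exp((V - V_T)/Delta_T) - g_e V - z
    tau_W dz/dt = c_z (V - E_L) - z

Spikes are detected when V escapes past ``V_T + 5 Delta_T`` (well beyond the
exponential blow-up); V is then reset to E_L and the adaptation current z is
incremented by b.  The synaptic reversal potential is 0 mV, so the synaptic
term is ``-g_e V``.

Integration is forward Euler at dt = 0.1 ms by default; the conductance decay
uses the exact exponential update (see :mod:`stdplocus.synapse`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LIFParams", "AdExParams", "NeuronState", "step_lif", "step_adex"]

# Cap on the AdEx exponential argument; prevents overflow between the
# blow-up and the numerical detection threshold.
_EXP_ARG_MAX = 16.0


@dataclass(frozen=True)
class LIFParams:
    tau_V: float = 20.0     # ms, membrane time constant
    E_v: float = -74.0      # mV, resting potential
    V_th: float = -54.0     # mV, spike threshold
    V_reset: float = -60.0  # mV, post-spike reset
    t_refrac: float = 1.0   # ms, absolute refractory period
    E_e: float = 0.0        # mV, excitatory reversal
    tau_g: float = 5.0      # ms, conductance decay

    def __post_init__(self):
        if not (self.V_reset < self.V_th):
            raise ValueError("V_reset must be below V_th")
        if min(self.tau_V, self.tau_g, self.t_refrac) <= 0:
            raise ValueError("tau_V, tau_g, t_refrac must be > 0")


@dataclass(frozen=True)
class AdExParams:
    C: float = 281.0        # pF
    g_L: float = 30.0       # nS
    E_L: float = -70.6      # mV
    Delta_T: float = 2.0    # mV, spike-initiation sharpness
    V_T: float = -50.4      # mV, exponential threshold
    c_z: float = 4.0        # nS, subthreshold adaptation coupling
    tau_W: float = 144.0    # ms, adaptation time constant
    b: float = 80.5         # pA, spike-triggered adaptation increment (0.0805 nA)
    tau_g: float = 5.0      # ms, conductance decay

    def __post_init__(self):
        if self.Delta_T <= 0:
            raise ValueError("Delta_T must be > 0")

    @property
    def V_detect(self) -> float:
        """Numerical spike-detection threshold (escape past the blow-up)."""
        return self.V_T + 5.0 * self.Delta_T


@dataclass
class NeuronState:
    """Membrane state; ``g`` is the summed excitatory conductance."""

    V: float
    g: float = 0.0
    z: float = 0.0              # pA, AdEx adaptation current
    refrac_remaining: float = 0.0
    spike_times: list = field(default_factory=list)

    def check_finite(self):
        if not (np.isfinite(self.V) and np.isfinite(self.g) and np.isfinite(self.z)):
            raise FloatingPointError(
                f"non-finite neuron state: V={self.V}, g={self.g}, z={self.z}"
            )


def step_lif(state: NeuronState, params: LIFParams, dt: float,
             t: float | None = None) -> bool:
    """Advance the LIF membrane by one step (in place); return spike flag.

    The conductance ``state.g`` is *not* decayed here; transmission and
    conductance bookkeeping live in :mod:`stdplocus.synapse` so that the
    membrane update can be tested against its closed form in isolation.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if state.g < 0:
        raise ValueError("conductance must be >= 0")
    state.check_finite()
    if state.refrac_remaining > 0:
        state.refrac_remaining = max(0.0, state.refrac_remaining - dt)
        state.V = params.V_reset
        return False
    dV = ((params.E_v - state.V) + state.g * (params.E_e - state.V)) / params.tau_V
    state.V += dt * dV
    if state.V >= params.V_th:
        state.V = params.V_reset
        state.refrac_remaining = params.t_refrac
        if t is not None:
            state.spike_times.append(t)
        return True
    return False


def step_adex(state: NeuronState, params: AdExParams, dt: float,
              t: float | None = None) -> bool:
    """Advance the AdEx membrane and adaptation current by one step."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    state.check_finite()
    arg = min((state.V - params.V_T) / params.Delta_T, _EXP_ARG_MAX)
    I_exp = params.g_L * params.Delta_T * np.exp(arg)           # pA
    dV = (params.g_L * (params.E_L - state.V) + I_exp
          - state.g * state.V - state.z) / params.C             # mV/ms
    dz = (params.c_z * (state.V - params.E_L) - state.z) / params.tau_W
    state.V += dt * dV
    state.z += dt * dz
    if state.V >= params.V_detect:
        state.V = params.E_L
        state.z += params.b
        if t is not None:
            state.spike_times.append(t)
        return True
    return False
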