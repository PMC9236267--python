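"""Long-term plasticity rules with a configurable locus of expression.

Two rules are implemented.

**Additive pair-based STDP.**  Every pre/post spike pair separated by
``delta_t = t_pre - t_post`` contributes a raw increment::

    F(delta_t) = c_pot * exp(delta_t / tau_STDP)    delta_t < 0  (pre before post)
                 c_dep * exp(-delta_t / tau_STDP)   delta_t >= 0 (post before/with pre)

with tau_STDP = 20 ms, c_pot = 0.005, c_dep = -0.00525 (slightly
depression-dominated).  The raw increment ``d`` is then *expressed* at a
chosen locus so that the total weight change ``Delta W`` is identical across
loci when P = q:

* ``locus="post"``: Delta q = d, so Delta W = P d.
* ``locus="pre"``:  Delta P = d, so Delta W = q d.
* ``locus="both"``: P and q change by the same amount Delta, the root of
  ``(P+Delta)(q+Delta) - P q = P d``::

      Delta = -1/2 [ (P+q) - sqrt((P+q)^2 + 4 P d) ]

Bounds keep the attainable total weight change identical across loci: with
initial values P0 = q0, single-locus variables cap at 1 (largest weight
change ``Delta_tot = P0 (1 - q0)``) while for ``locus="both"`` both cap at
``sqrt(P0 q0 + Delta_tot)``.  A small floor (1e-4) keeps transmission from
locking at zero.

**Biologically tuned pre/post rule** (triplet-like, constants fitted to
neocortical layer-5 pyramidal connections).  Spike traces ``x_j+`` (per
presynaptic input), ``y_+`` and ``y_-`` (postsynaptic) decay with
tau_x+ = 66.6 ms, tau_y+ = 230.2 ms, tau_y- = 32.7 ms and jump by 1 at their
spikes.  At each *presynaptic* spike of input j::

    Delta P_j = -d_minus * y_- * y_+  +  d_plus * x_j+ * y_+

(presynaptic LTD and LTP); at each *postsynaptic* spike::

    Delta q_j = c_plus * x_j+ * y_-

followed by a heterosynaptic scaling ``Delta q_j - alpha * <Delta q>``
(alpha = 0.5) that prevents runaway postsynaptic potentiation.  All updates
use trace values from before the triggering spike's own increments.  The
rule expresses LTP both pre- and postsynaptically but LTD only
presynaptically; blocking one side (:func:`block_locus`) zeroes its updates
while keeping the fitted ratios of the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PairSTDPParams",
    "TunedSTDPParams",
    "PlasticityTraces",
    "stdp_kernel",
    "allocate_increment",
    "apply_bounds",
    "pair_stdp_online",
    "pair_stdp_brute_force",
    "tuned_update_on_pre",
    "tuned_update_on_post",
    "update_traces",
    "block_locus",
]

FLOOR = 1e-4  # lower bound on P and q; avoids absorbing silence


@dataclass(frozen=True)
class PairSTDPParams:
    tau_STDP: float = 20.0
    c_pot: float = 0.005
    c_dep: float = -0.00525
    locus: str = "both"         # {"pre", "post", "both"}
    P0: float = 0.5
    q0: float = 0.5
    floor: float = FLOOR

    def __post_init__(self):
        if self.c_pot <= 0 or self.c_dep >= 0:
            raise ValueError("require c_pot > 0 and c_dep < 0")
        if self.locus not in ("pre", "post", "both"):
            raise ValueError(f"unknown locus: {self.locus!r}")
        if abs(self.P0 - self.q0) > 1e-12:
            raise ValueError("matched-increment scheme requires P0 == q0")

    @property
    def Delta_tot(self) -> float:
        """Largest single-locus total weight change: P0 (1 - q0)."""
        return self.P0 * (1.0 - self.q0)

    @property
    def cap_both(self) -> float:
        """Cap on P and q for locus='both': sqrt(P0 q0 + Delta_tot)."""
        return math.sqrt(self.P0 * self.q0 + self.Delta_tot)

    def caps(self) -> tuple[float, float]:
        """(cap_P, cap_q) for this locus."""
        if self.locus == "both":
            return self.cap_both, self.cap_both
        return 1.0, 1.0


@dataclass(frozen=True)
class TunedSTDPParams:
    c_plus: float = 0.0618
    d_minus: float = 0.1771
    d_plus: float = 0.15480
    tau_x_plus: float = 66.6
    tau_y_plus: float = 230.2
    tau_y_minus: float = 32.7
    alpha: float = 0.5
    block: str = "none"         # {"none", "pre", "post"}
    floor: float = FLOOR

    def __post_init__(self):
        if min(self.tau_x_plus, self.tau_y_plus, self.tau_y_minus) <= 0:
            raise ValueError("trace time constants must be > 0")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.block not in ("none", "pre", "post"):
            raise ValueError(f"unknown block: {self.block!r}")


@dataclass
class PlasticityTraces:
    """Exponential spike traces for ``n`` presynaptic inputs."""

    x_plus: np.ndarray          # per-input presynaptic trace (tuned rule)
    pre_trace: np.ndarray       # per-input trace (pair rule, tau_STDP)
    y_plus: float = 0.0         # postsynaptic trace, tau_y+
    y_minus: float = 0.0        # postsynaptic trace, tau_y-
    post_trace: float = 0.0     # postsynaptic trace (pair rule, tau_STDP)

    @classmethod
    def zeros(cls, n: int) -> "PlasticityTraces":
        return cls(x_plus=np.zeros(n), pre_trace=np.zeros(n))


def stdp_kernel(delta_t: float, params: PairSTDPParams = PairSTDPParams()) -> float:
    """Raw pair increment for ``delta_t = t_pre - t_post`` (ms)."""
    if delta_t < 0:
        return params.c_pot * math.exp(delta_t / params.tau_STDP)
    return params.c_dep * math.exp(-delta_t / params.tau_STDP)


def allocate_increment(P: float, q: float, d: float, locus: str,
                       floor: float = FLOOR) -> tuple[float, float]:
    """Split a raw increment ``d`` into (delta_P, delta_q) for the locus.

    For ``locus="both"`` the common increment Delta solves
    ``(P+Delta)(q+Delta) - P q = P d``; if the discriminant is negative
    (a depression too large to realize at the current state) Delta is
    clamped to the largest feasible depression keeping both factors at the
    floor.
    """
    if locus == "post":
        return 0.0, d
    if locus == "pre":
        return d, 0.0
    if locus == "both":
        s = P + q
        disc = s * s + 4.0 * P * d
        if disc < 0.0:
            delta = floor - min(P, q)  # clamp; logged by callers that track it
        else:
            delta = -0.5 * (s - math.sqrt(disc))
        return delta, delta
    raise ValueError(f"unknown locus: {locus!r}")


def apply_bounds(P: float, q: float, locus: str,
                 params: PairSTDPParams) -> tuple[float, float]:
    """Clip (P, q) to (floor, cap] for the given locus."""
    if locus == "both":
        cap_P = cap_q = params.cap_both
    else:
        cap_P = cap_q = 1.0
    P = min(max(P, params.floor), cap_P)
    q = min(max(q, params.floor), cap_q)
    return P, q


def pair_stdp_online(pre_times: np.ndarray, post_times: np.ndarray,
                     params: PairSTDPParams = PairSTDPParams()) -> float:
    """Total raw increment from all pre/post pairs via exponential traces.

    Event-driven implementation of the all-pairs sum: on a presynaptic spike
    the depression term ``c_dep * post_trace`` accrues (ties, delta_t = 0,
    included); on a postsynaptic spike the potentiation term
    ``c_pot * pre_trace`` accrues (ties excluded — they belong to the
    depression branch).  Exactly equals :func:`pair_stdp_brute_force`.
    """
    pre = np.sort(np.asarray(pre_times, dtype=float))
    post = np.sort(np.asarray(post_times, dtype=float))
    tau = params.tau_STDP
    d = 0.0
    pre_trace = 0.0
    post_trace = 0.0
    i = j = 0
    t_prev = None
    while i < pre.size or j < post.size:
        t_pre = pre[i] if i < pre.size else np.inf
        t_post = post[j] if j < post.size else np.inf
        t = min(t_pre, t_post)
        if t_prev is not None:
            decay = math.exp(-(t - t_prev) / tau)
            pre_trace *= decay
            post_trace *= decay
        t_prev = t
        k_post = 0
        while j < post.size and post[j] == t:
            k_post += 1
            j += 1
        k_pre = 0
        while i < pre.size and pre[i] == t:
            k_pre += 1
            i += 1
        # potentiation first (ties excluded from pre_trace), then depression
        # (post_trace already includes the tied posts).
        d += k_post * params.c_pot * pre_trace
        post_trace += k_post
        d += k_pre * params.c_dep * post_trace
        pre_trace += k_pre
    return d


def pair_stdp_brute_force(pre_times: np.ndarray, post_times: np.ndarray,
                          params: PairSTDPParams = PairSTDPParams()) -> float:
    """Direct double sum of the pair kernel over all spike pairs (oracle)."""
    d = 0.0
    for tp in np.asarray(pre_times, dtype=float):
        for to in np.asarray(post_times, dtype=float):
            d += stdp_kernel(tp - to, params)
    return d


def tuned_update_on_pre(traces: PlasticityTraces, j: int,
                        params: TunedSTDPParams) -> float:
    """Presynaptic-weight increment at a presynaptic spike of input ``j``.

    Evaluated with trace values from before this spike increments ``x_j+``:
    ``Delta P_j = -d_minus y_- y_+ + d_plus x_j+ y_+``.
    """
    if params.block == "pre":
        return 0.0
    return (-params.d_minus * traces.y_minus * traces.y_plus
            + params.d_plus * traces.x_plus[j] * traces.y_plus)


def tuned_update_on_post(traces: PlasticityTraces,
                         params: TunedSTDPParams) -> np.ndarray:
    """Per-input quantal increments at a postsynaptic spike, after scaling.

    Raw ``Delta q_j = c_plus x_j+ y_-`` (traces before this spike's own
    increments), then ``Delta q_j - alpha * <Delta q>`` with the mean taken
    over all inputs.
    """
    n = traces.x_plus.size
    if params.block == "post":
        return np.zeros(n)
    dq = params.c_plus * traces.x_plus * traces.y_minus
    return dq - params.alpha * dq.mean()


def update_traces(traces: PlasticityTraces, dt: float,
                  pre_spikes: np.ndarray | list = (),
                  post_spiked: bool = False,
                  params: TunedSTDPParams = TunedSTDPParams(),
                  tau_pair: float = 20.0) -> None:
    """Decay all traces by ``dt`` then add unit impulses for the spikes.

    ``pre_spikes`` lists input indices that fired (an index repeated k times
    increments its traces by k).  Impulses are added after decay, i.e. after
    plasticity has been evaluated at this step.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt > 0:
        traces.x_plus *= math.exp(-dt / params.tau_x_plus)
        traces.pre_trace *= math.exp(-dt / tau_pair)
        traces.y_plus *= math.exp(-dt / params.tau_y_plus)
        traces.y_minus *= math.exp(-dt / params.tau_y_minus)
        traces.post_trace *= math.exp(-dt / tau_pair)
    for j in pre_spikes:
        traces.x_plus[j] += 1.0
        traces.pre_trace[j] += 1.0
    if post_spiked:
        traces.y_plus += 1.0
        traces.y_minus += 1.0
        traces.post_trace += 1.0


def block_locus(rule: PairSTDPParams | TunedSTDPParams, which: str):
    """Return a copy of the rule with one expression side disabled.

    For the tuned rule, ``which`` in {"pre", "post", "none"} zeroes the
    corresponding updates while keeping the fitted ratios of the other side.
    For the pair rule, blocking selects the complementary single locus.
    """
    if which not in ("pre", "post", "none"):
        raise ValueError(f"unknown block: {which!r}")
    if isinstance(rule, TunedSTDPParams):
        return replace(rule, block=which)
    if which == "none":
        return rule
    return replace(rule, locus={"pre": "post", "post": "pre"}[which])
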