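"""Compiled simulation core.

A single numba kernel advances one postsynaptic neuron with ``n`` plastic
synapses over a segment of ``n_steps`` time steps, given the presynaptic
spikes of the segment as (step index, source) pairs sorted by step.  The
kernel covers both neuron models (LIF / AdEx), the three transmission
mechanisms (pure weight, binomial stochastic release, Tsodyks-Markram STP),
both plasticity rules (additive pair STDP with per-synapse locus, and the
biologically tuned pre/post rule) and the optional sum-of-weights
renormalization used by the competition scenario.

Within a time step the order of operations is:

1. exact exponential decay of the conductance, spike traces and STP
   variables;
2. presynaptic transmission for this step's input spikes (STP facilitation
   jump first, release, then depression);
3. forward-Euler membrane update and spike detection;
4. plasticity, evaluated with trace values that exclude this step's own
   impulses (a pre/post pair landing in the same step counts as
   post-before-pre, i.e. depression, for the pair rule);
5. trace impulses, then (if enabled) renormalization of the summed weight.

Under the stochastic mechanism, pair-STDP participation of a presynaptic
spike is weighted by its released vesicle fraction k/N (potentiation
requires transmitter release, and a failed release produces no depression
either); its expectation is P, so the matched-increment comparison across
loci stays unbiased at P = q while potentiated synapses learn faster and
depressed ones more slowly.  The deterministic mechanisms and the tuned
rule are not gated.

All stochasticity is injected through pre-drawn uniform variates, so the
kernel itself is deterministic.  The readable reference implementations of
every elementary operation live in :mod:`stdplocus.neuron`,
:mod:`stdplocus.synapse` and :mod:`stdplocus.plasticity`; the kernel is
cross-checked against them in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# neuron kinds
LIF = 0
ADEX = 1
# mechanisms
MECH_NONE = 0
MECH_STOCHASTIC = 1
MECH_STP = 2
# plasticity rules
RULE_NONE = 0
RULE_PAIR = 1
RULE_TUNED = 2
# loci
LOCUS_PRE = 0
LOCUS_POST = 1
LOCUS_BOTH = 2

NEURON_KIND = {"lif": LIF, "adex": ADEX}
MECH_KIND = {"none": MECH_NONE, "stochastic": MECH_STOCHASTIC, "stp": MECH_STP}
RULE_KIND = {"none": RULE_NONE, "pair": RULE_PAIR, "tuned": RULE_TUNED}
LOCUS_KIND = {"pre": LOCUS_PRE, "post": LOCUS_POST, "both": LOCUS_BOTH}

# scalar-state slot indices
S_V = 0
S_G = 1
S_Z = 2
S_REFRAC = 3
S_YPLUS = 4
S_YMINUS = 5
S_POSTTRACE = 6
N_SCALARS = 7


@njit(cache=True)
def _clip(x, lo, hi):
    if x < lo:
        return lo
    if x > hi:
        return hi
    return x


@njit(cache=True)
def _alloc_pair(P, q, j, d, loc, floor, capP, capQ):
    """Express raw pair increment d at synapse j for its locus, with bounds."""
    if loc == LOCUS_PRE:
        P[j] = _clip(P[j] + d, floor, capP[j])
    elif loc == LOCUS_POST:
        q[j] = _clip(q[j] + d, floor, capQ[j])
    else:
        s = P[j] + q[j]
        disc = s * s + 4.0 * P[j] * d
        if disc < 0.0:
            delta = floor - min(P[j], q[j])
        else:
            delta = -0.5 * (s - math.sqrt(disc))
        P[j] = _clip(P[j] + delta, floor, capP[j])
        q[j] = _clip(q[j] + delta, floor, capQ[j])


@njit(cache=True)
def _renormalize(P, q, locus, target, floor, capP, capQ):
    """Multiplicative rescale of W = P q toward a fixed sum, expressed through
    each synapse's plastic side; iterated so clipping does not break the
    conservation unless every synapse is pinned at a bound."""
    n = P.size
    for _ in range(50):
        s = 0.0
        for j in range(n):
            s += P[j] * q[j]
        if abs(s - target) <= 1e-12 * max(1.0, target):
            break
        f = target / s
        sf = math.sqrt(f)
        for j in range(n):
            if locus[j] == LOCUS_PRE:
                P[j] = _clip(P[j] * f, floor, capP[j])
            elif locus[j] == LOCUS_POST:
                q[j] = _clip(q[j] * f, floor, capQ[j])
            else:
                P[j] = _clip(P[j] * sf, floor, capP[j])
                q[j] = _clip(q[j] * sf, floor, capQ[j])


@njit(cache=True)
def simulate_segment(
    spike_step,      # int64[n_sp], sorted non-decreasing
    spike_src,       # int64[n_sp]
    n_steps, dt,
    neuron_kind, mech_kind, rule_kind,
    neuron_par,      # LIF: [tau_V, E_v, V_th, V_reset, t_refrac, E_e]
                     # AdEx: [C, g_L, E_L, Delta_T, V_T, c_z, tau_W, b]
    q_max, n_sites, tau_g, tau_D, tau_F,
    tau_stdp, c_pot, c_dep, floor, locus, capP, capQ,   # pair rule (per-syn locus)
    c_plus, d_minus, d_plus, tau_xp, tau_yp, tau_ym, alpha,
    block_pre, block_post,                               # tuned rule
    renorm, target_sum,
    P, q, r, pv, x_plus, pre_trace, scalars,             # state, updated in place
    uniforms,        # float64[n_sp, n_sites] (stochastic release draws)
    rel,             # float64 scratch, len >= max spikes in any one step
    post_steps,      # int64 output buffer, len >= n_steps
    snap_every,      # int; 0 disables snapshots
    P_snap, q_snap,  # float64[n_snap, n]
):
    n = P.size
    n_sp = spike_step.size
    eg = math.exp(-dt / tau_g)
    eD = math.exp(-dt / tau_D)
    eF = math.exp(-dt / tau_F)
    e_stdp = math.exp(-dt / tau_stdp)
    e_xp = math.exp(-dt / tau_xp)
    e_yp = math.exp(-dt / tau_yp)
    e_ym = math.exp(-dt / tau_ym)

    V = scalars[S_V]
    g = scalars[S_G]
    z = scalars[S_Z]
    refrac = scalars[S_REFRAC]
    y_plus = scalars[S_YPLUS]
    y_minus = scalars[S_YMINUS]
    post_trace = scalars[S_POSTTRACE]

    dq_tmp = np.empty(n)
    sp = 0
    n_post = 0
    i_snap = 0

    for step in range(n_steps):
        # 1. decays
        g *= eg
        if rule_kind == RULE_PAIR:
            post_trace *= e_stdp
            for j in range(n):
                pre_trace[j] *= e_stdp
        elif rule_kind == RULE_TUNED:
            y_plus *= e_yp
            y_minus *= e_ym
            for j in range(n):
                x_plus[j] *= e_xp
        if mech_kind == MECH_STP:
            for j in range(n):
                r[j] = 1.0 - (1.0 - r[j]) * eD
                pv[j] = P[j] + (pv[j] - P[j]) * eF

        # 2. presynaptic transmission; rel[m] is the released fraction that
        # gates this spike's participation in pair plasticity (1 for the
        # deterministic mechanisms).
        k = 0
        while sp + k < n_sp and spike_step[sp + k] == step:
            j = spike_src[sp + k]
            if mech_kind == MECH_NONE:
                g += P[j] * q[j] * q_max
                rel[k] = 1.0
            elif mech_kind == MECH_STOCHASTIC:
                cnt = 0
                for site in range(n_sites):
                    if uniforms[sp + k, site] < P[j]:
                        cnt += 1
                frac = cnt / n_sites
                g += frac * q[j] * q_max
                rel[k] = frac
            else:  # STP: facilitation jump, release, depression
                pv[j] = pv[j] + P[j] * (1.0 - pv[j])
                g += pv[j] * r[j] * q[j] * q_max
                r[j] = r[j] * (1.0 - pv[j])
                rel[k] = 1.0
            k += 1

        # 3. membrane update
        spiked = False
        if neuron_kind == LIF:
            tau_V = neuron_par[0]
            E_v = neuron_par[1]
            V_th = neuron_par[2]
            V_reset = neuron_par[3]
            t_refrac = neuron_par[4]
            E_e = neuron_par[5]
            if refrac > 0.0:
                refrac -= dt
                if refrac < 0.0:
                    refrac = 0.0
                V = V_reset
            else:
                V += dt * ((E_v - V) + g * (E_e - V)) / tau_V
                if V >= V_th:
                    V = V_reset
                    refrac = t_refrac
                    spiked = True
        else:
            C = neuron_par[0]
            g_L = neuron_par[1]
            E_L = neuron_par[2]
            Delta_T = neuron_par[3]
            V_T = neuron_par[4]
            c_z = neuron_par[5]
            tau_W = neuron_par[6]
            b = neuron_par[7]
            arg = (V - V_T) / Delta_T
            if arg > 16.0:
                arg = 16.0
            I_exp = g_L * Delta_T * math.exp(arg)
            dV = (g_L * (E_L - V) + I_exp - g * V - z) / C
            dz = (c_z * (V - E_L) - z) / tau_W
            V += dt * dV
            z += dt * dz
            if V >= V_T + 5.0 * Delta_T:
                V = E_L
                z += b
                spiked = True
        if spiked:
            post_steps[n_post] = step
            n_post += 1

        # 4. plasticity (traces exclude this step's own impulses)
        changed = False
        if rule_kind == RULE_PAIR:
            if spiked:
                for j in range(n):
                    d = c_pot * pre_trace[j]
                    if d != 0.0:
                        _alloc_pair(P, q, j, d, locus[j], floor, capP, capQ)
                changed = True
            pt = post_trace + (1.0 if spiked else 0.0)
            if pt != 0.0:
                for m in range(k):
                    j = spike_src[sp + m]
                    d = c_dep * pt * rel[m]
                    if d != 0.0:
                        _alloc_pair(P, q, j, d, locus[j], floor, capP, capQ)
                        changed = True
            for m in range(k):
                pre_trace[spike_src[sp + m]] += rel[m]
            if spiked:
                post_trace += 1.0
        elif rule_kind == RULE_TUNED:
            if spiked and block_post == 0:
                mean_dq = 0.0
                for j in range(n):
                    dq_tmp[j] = c_plus * x_plus[j] * y_minus
                    mean_dq += dq_tmp[j]
                mean_dq /= n
                for j in range(n):
                    q[j] = _clip(q[j] + dq_tmp[j] - alpha * mean_dq, floor, 1.0)
                changed = True
            if block_pre == 0:
                for m in range(k):
                    j = spike_src[sp + m]
                    dP = (-d_minus * y_minus * y_plus
                          + d_plus * x_plus[j] * y_plus)
                    P[j] = _clip(P[j] + dP, floor, 1.0)
                    changed = True
            for m in range(k):
                x_plus[spike_src[sp + m]] += 1.0
            if spiked:
                y_plus += 1.0
                y_minus += 1.0

        if renorm == 1 and changed:
            _renormalize(P, q, locus, target_sum, floor, capP, capQ)

        sp += k

        # 5. snapshots
        if snap_every > 0 and (step + 1) % snap_every == 0:
            for j in range(n):
                P_snap[i_snap, j] = P[j]
                q_snap[i_snap, j] = q[j]
            i_snap += 1

    scalars[S_V] = V
    scalars[S_G] = g
    scalars[S_Z] = z
    scalars[S_REFRAC] = refrac
    scalars[S_YPLUS] = y_plus
    scalars[S_YMINUS] = y_minus
    scalars[S_POSTTRACE] = post_trace
    return n_post


def neuron_par_array(kind: str, params) -> np.ndarray:
    """Pack a neuron parameter dataclass into the kernel's float array."""
    if kind == "lif":
        return np.array([params.tau_V, params.E_v, params.V_th,
                         params.V_reset, params.t_refrac, params.E_e])
    return np.array([params.C, params.g_L, params.E_L, params.Delta_T,
                     params.V_T, params.c_z, params.tau_W, params.b])
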