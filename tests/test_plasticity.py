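"""Plasticity rules: kernel values, locus allocation algebra, bounds,
trace/all-pairs equivalence and the tuned rule's update structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stdplocus.plasticity import (PairSTDPParams, PlasticityTraces,
                                  TunedSTDPParams, allocate_increment,
                                  apply_bounds, block_locus,
                                  pair_stdp_brute_force, pair_stdp_online,
                                  stdp_kernel, tuned_update_on_post,
                                  tuned_update_on_pre, update_traces)

PAIR = PairSTDPParams()
TUNED = TunedSTDPParams()


class TestKernel:
    def test_printed_values(self):
        assert stdp_kernel(-20.0) == pytest.approx(0.005 * np.exp(-1))
        assert stdp_kernel(0.0) == pytest.approx(-0.00525)
        assert stdp_kernel(-0.0001) == pytest.approx(0.005, rel=1e-3)

    def test_depression_integral_dominates(self):
        # |c_dep|/c_pot = 1.05 with equal tau: net area negative
        ts = np.linspace(-200, 200, 20001)
        area = np.trapezoid([stdp_kernel(t) for t in ts], ts)
        assert area < 0


class TestAllocation:
    def test_single_locus_routing(self):
        assert allocate_increment(0.5, 0.5, 0.01, "post") == (0.0, 0.01)
        assert allocate_increment(0.5, 0.5, 0.01, "pre") == (0.01, 0.0)

    def test_matched_weight_change_across_loci(self):
        P = q = 0.5
        d = 0.01
        dP, _ = allocate_increment(P, q, d, "pre")
        _, dq = allocate_increment(P, q, d, "post")
        assert q * dP == pytest.approx(P * dq) == pytest.approx(0.005)

    def test_both_locus_root_value(self):
        dP, dq = allocate_increment(0.5, 0.5, 0.02, "both")
        assert dP == dq == pytest.approx(-0.5 + np.sqrt(0.26))
        # resulting weight change equals P*d exactly
        assert (0.5 + dP) * (0.5 + dq) - 0.25 == pytest.approx(0.01, abs=1e-15)

    def test_discriminant_clamp_keeps_factors_positive(self):
        dP, dq = allocate_increment(0.05, 0.05, -0.9, "both")
        assert 0.05 + dP >= PAIR.floor
        assert 0.05 + dq >= PAIR.floor

    @given(P=st.floats(0.05, 0.95), d=st.floats(-0.001, 0.1))
    @settings(max_examples=200, deadline=None)
    def test_matching_identity_property(self, P, d):
        d = max(d, -P * P / 2)
        delta, _ = allocate_increment(P, P, d, "both")
        lhs = (P + delta) ** 2 - P * P
        assert lhs == pytest.approx(P * d, rel=1e-12, abs=1e-15)


class TestBounds:
    def test_both_locus_cap_matches_total_change(self):
        p = PairSTDPParams(P0=0.5, q0=0.5, locus="both")
        assert p.Delta_tot == pytest.approx(0.25)
        assert p.cap_both == pytest.approx(np.sqrt(0.5))
        # capped weight change equals the single-locus maximum Delta_tot
        assert p.cap_both ** 2 - 0.25 == pytest.approx(p.Delta_tot)

    def test_clipping(self):
        p = PairSTDPParams(locus="post")
        assert apply_bounds(0.5, 1.2, "post", p) == (0.5, 1.0)
        assert apply_bounds(0.5, -0.3, "post", p)[1] == p.floor
        P, q = apply_bounds(0.9, 0.9, "both", p)
        assert P == q == pytest.approx(p.cap_both)


class TestPairSum:
    def test_single_pair_value(self):
        d = pair_stdp_online(np.array([0.0]), np.array([10.0]))
        assert d == pytest.approx(0.005 * np.exp(-0.5))

    def test_no_post_spikes_no_increment(self):
        assert pair_stdp_online(np.array([1.0, 5.0, 9.0]), np.array([])) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_online_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pre = np.round(np.sort(rng.uniform(0, 1000, 30)), 1)
        post = np.round(np.sort(rng.uniform(0, 1000, 25)), 1)
        a = pair_stdp_online(pre, post)
        b = pair_stdp_brute_force(pre, post)
        assert a == pytest.approx(b, rel=1e-12, abs=1e-15)

    def test_tie_counts_as_depression(self):
        # coincident pre/post pair contributes c_dep (delta_t = 0 branch)
        d = pair_stdp_online(np.array([5.0]), np.array([5.0]))
        assert d == pytest.approx(-0.00525)
        assert d == pair_stdp_brute_force(np.array([5.0]), np.array([5.0]))


class TestTunedRule:
    def test_update_on_pre_printed_constants(self):
        tr = PlasticityTraces.zeros(3)
        tr.y_minus, tr.y_plus = 1.0, 1.0
        assert tuned_update_on_pre(tr, 0, TUNED) == pytest.approx(-0.1771)
        tr.x_plus[1] = 1.0
        tr.y_minus = 0.0
        assert tuned_update_on_pre(tr, 1, TUNED) == pytest.approx(0.15480)

    def test_no_post_trace_no_pre_update(self):
        tr = PlasticityTraces.zeros(2)
        tr.x_plus[:] = 5.0  # y_+ = 0 gates everything
        assert tuned_update_on_pre(tr, 0, TUNED) == 0.0

    def test_update_on_post_scaling(self):
        tr = PlasticityTraces.zeros(4)
        tr.x_plus[:] = 2.0
        tr.y_minus = 1.0
        dq = tuned_update_on_post(tr, TUNED)
        # uniform traces: scaled increment is (1 - alpha) * raw for all
        assert np.allclose(dq, 0.5 * 0.0618 * 2.0)

    def test_silent_input_depressed_by_scaling(self):
        tr = PlasticityTraces.zeros(4)
        tr.x_plus[:] = 1.0
        tr.x_plus[0] = 0.0
        tr.y_minus = 1.0
        dq = tuned_update_on_post(tr, TUNED)
        assert dq[0] < 0  # competitive depression of the silent input
        assert dq[0] == pytest.approx(-0.5 * np.mean(0.0618 * tr.x_plus))

    def test_trace_decay_and_impulses(self):
        tr = PlasticityTraces.zeros(2)
        tr.y_plus = 1.0
        update_traces(tr, 230.2, params=TUNED)
        assert tr.y_plus == pytest.approx(np.exp(-1))
        update_traces(tr, 0.0, pre_spikes=[1, 1], params=TUNED)
        assert tr.x_plus[1] == 2.0 and tr.x_plus[0] == 0.0
        zero = PlasticityTraces.zeros(2)
        update_traces(zero, 50.0, params=TUNED)
        assert zero.y_plus == zero.y_minus == zero.post_trace == 0.0

    def test_block_locus_contracts(self):
        pre_blocked = block_locus(TUNED, "pre")
        tr = PlasticityTraces.zeros(2)
        tr.y_minus = tr.y_plus = 1.0
        assert tuned_update_on_pre(tr, 0, pre_blocked) == 0.0
        post_blocked = block_locus(TUNED, "post")
        tr.x_plus[:] = 1.0
        assert np.all(tuned_update_on_post(tr, post_blocked) == 0.0)
        assert block_locus(TUNED, "none") == TUNED
        pair_blocked = block_locus(PairSTDPParams(locus="pre"), "pre")
        assert pair_blocked.locus == "post"


def test_params_validation():
    with pytest.raises(ValueError):
        PairSTDPParams(c_dep=0.001)
    with pytest.raises(ValueError):
        PairSTDPParams(P0=0.4, q0=0.6)
    with pytest.raises(ValueError):
        TunedSTDPParams(alpha=1.5)
    with pytest.raises(ValueError):
        allocate_increment(0.5, 0.5, 0.01, "sideways")
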