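import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikecolearn import (
    ClusterNet,
    LearnConfig,
    STDPParams,
    SpikeTrain,
    TeacherConfig,
    apply_bipolar_update,
    build_teacher_signals,
    simulate_cluster,
    stdp_delta,
    train_cluster,
    train_sample,
)
from spikecolearn.ensemble import evaluate
from spikecolearn.structure import EnsembleSNN

from conftest import separable_train


def stdp_oracle(pre, post, p):
    """Explicit double loop over all spike pairs."""
    total = 0.0
    for tp in pre:
        for tq in post:
            if tp < tq:
                total += p.a_plus * math.exp(-(tq - tp) / p.tau_plus)
            else:
                total -= p.a_minus * math.exp(-(tp - tq) / p.tau_minus)
    return total


class TestStdpDelta:
    def test_causal_pair_potentiates(self):
        assert stdp_delta([10.0], [15.0], STDPParams()) > 0

    def test_anti_causal_pair_depresses(self):
        assert stdp_delta([15.0], [10.0], STDPParams()) < 0

    def test_empty_trains_no_change(self):
        p = STDPParams()
        assert stdp_delta([], [10.0], p) == 0.0
        assert stdp_delta([10.0], [], p) == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        p = STDPParams()
        for _ in range(50):
            pre = rng.uniform(0, 100, rng.integers(1, 6))
            post = rng.uniform(0, 100, rng.integers(1, 6))
            assert stdp_delta(pre, post, p) == pytest.approx(
                stdp_oracle(pre, post, p), abs=1e-12
            )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        pre=st.lists(st.floats(0, 99, allow_nan=False), min_size=1, max_size=5),
        post=st.lists(st.floats(0, 99, allow_nan=False), min_size=1, max_size=5),
    )
    def test_antisymmetric_under_swap_with_symmetric_params(self, pre, post):
        # equal amplitudes and time constants: swapping pre/post flips the sign
        p = STDPParams(a_plus=0.3, a_minus=0.3, tau_plus=15.0, tau_minus=15.0)
        if set(pre) & set(post):
            return  # simultaneous pairs depress on both sides; skip ties
        assert stdp_delta(pre, post, p) == pytest.approx(
            -stdp_delta(post, pre, p), abs=1e-10
        )


class TestTeacherBuilder:
    def test_worked_example_four_fired_label_one(self):
        # fired set {0, 1, 7, 8} with label 1: reward 1, punish 0, 7, 8
        cfg = TeacherConfig()
        signals = build_teacher_signals({0, 1, 7, 8}, 1, cfg)
        encourage = [s for s in signals if s.polarity == "encourage"]
        punish = [s for s in signals if s.polarity == "punish"]
        assert [(s.target, s.time) for s in encourage] == [(1, 70.0)]
        assert sorted((s.target, s.time) for s in punish) == [
            (0, 35.0),
            (7, 35.0),
            (8, 35.0),
        ]

    def test_correct_response_needs_no_teachers(self):
        assert build_teacher_signals({3}, 3) == []

    def test_silent_net_gets_encouragement_only(self):
        signals = build_teacher_signals(set(), 5)
        assert len(signals) == 1
        assert signals[0].polarity == "encourage"
        assert signals[0].target == 5

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            build_teacher_signals({0}, 12)


def tiny_net(n_inputs=6, n_decode=3, w=2.0):
    W = np.full((n_inputs, n_decode), w)
    return ClusterNet(W=W, W_init=W.copy(), alive=np.ones_like(W, dtype=bool))


class TestBipolarUpdate:
    def test_no_teachers_no_change(self):
        net = tiny_net()
        before = net.W.copy()
        train = SpikeTrain([0, 1], [5.0, 10.0], 6, 100.0)
        record = simulate_cluster(net, train)
        apply_bipolar_update(net, train, record, [], STDPParams())
        np.testing.assert_array_equal(net.W, before)

    def test_encourage_matches_causal_stdp_oracle(self):
        p = STDPParams()
        cfg = TeacherConfig()
        net = tiny_net()
        before = net.W.copy()
        times = [5.0, 20.0, 40.0]
        train = SpikeTrain([0, 1, 2], times, 6, 100.0)
        record = simulate_cluster(net, train)
        sig = build_teacher_signals(set(), 1, cfg)
        apply_bipolar_update(net, train, record, sig, p)
        for ch, t in zip([0, 1, 2], times):
            expected = stdp_oracle([t], [cfg.encourage_ms], p)
            assert net.W[ch, 1] - before[ch, 1] == pytest.approx(expected)
        # inactive channels and other neurons untouched
        np.testing.assert_array_equal(net.W[3:, :], before[3:, :])
        np.testing.assert_array_equal(net.W[:, [0, 2]], before[:, [0, 2]])

    def test_encourage_never_decreases_punish_never_increases(self):
        # bipolarity: polarity of the teacher bounds the sign of the update
        rng = np.random.default_rng(9)
        p = STDPParams()
        for _ in range(10):
            net = tiny_net(w=5.0)
            n_ev = rng.integers(1, 6)
            train = SpikeTrain(
                rng.choice(6, n_ev, replace=False),
                rng.uniform(0, 99, n_ev),
                6,
                100.0,
            )
            record = simulate_cluster(net, train)
            before = net.W.copy()
            teachers = build_teacher_signals(record.fired_set | {0}, 1)
            apply_bipolar_update(net, train, record, teachers, p)
            assert net.W[:, 1].sum() >= before[:, 1].sum()  # encouraged
            assert net.W[:, 0].sum() <= before[:, 0].sum()  # punished

    def test_weights_stay_clipped(self):
        p = STDPParams(w_min=-1.0, w_max=2.5)
        net = tiny_net(w=2.4)
        train = SpikeTrain([0, 1, 2], [60.0, 65.0, 69.0], 6, 100.0)
        record = simulate_cluster(net, train)
        for _ in range(20):
            sig = build_teacher_signals(set(), 2)
            apply_bipolar_update(net, train, record, sig, p)
        assert net.W.max() <= p.w_max
        assert net.W.min() >= p.w_min

    def test_dead_synapses_never_updated(self):
        p = STDPParams()
        net = tiny_net()
        net.alive[0, :] = False
        before = net.W.copy()
        train = SpikeTrain([0, 1], [5.0, 10.0], 6, 100.0)
        record = simulate_cluster(net, train)
        teachers = build_teacher_signals({0, 2}, 1)
        apply_bipolar_update(net, train, record, teachers, p)
        np.testing.assert_array_equal(net.W[0, :], before[0, :])


class TestTrainSample:
    def test_already_correct_needs_zero_iterations(self):
        # strong drive to neuron 0 only
        W = np.zeros((6, 3))
        W[:3, 0] = 60.0
        net = ClusterNet(W=W, W_init=W.copy(), alive=np.ones_like(W, dtype=bool))
        train = SpikeTrain([0, 1, 2], [5.0, 5.5, 6.0], 6, 100.0)
        net, out = train_sample(net, train, 0)
        assert out.converged
        assert out.iterations == 0
        assert out.final_M == frozenset({0})

    def test_cap_reached_reports_non_convergence(self):
        # every synapse dead: the net can never fire and updates cannot act
        W = np.zeros((6, 3))
        net = ClusterNet(W=W, W_init=W.copy(), alive=np.zeros_like(W, dtype=bool))
        train = SpikeTrain([0, 1], [5.0, 6.0], 6, 100.0)
        cfg = LearnConfig(max_inner_iters=7)
        net, out = train_sample(net, train, 1, cfg)
        assert not out.converged
        assert out.iterations == 7

    def test_two_class_toy_converges_quickly(self):
        # disjoint active channels per class: every sample trains in <= 20 iters
        cfg = LearnConfig()
        net = ClusterNet(
            W=np.random.default_rng(0).uniform(0, 5, (576, 10)),
            W_init=np.zeros((576, 10)),
            alive=np.ones((576, 10), dtype=bool),
        )
        net.W_init[:] = net.W
        for label in (0, 1, 0, 1):
            ch = np.arange(label * 57, (label + 1) * 57)
            train = SpikeTrain(ch, np.linspace(25.0, 40.0, 57), 576, 100.0)
            net, out = train_sample(net, train, label, cfg)
            assert out.converged
            assert out.iterations <= 20


class TestTrainCluster:
    def test_singleton_subset_equals_train_sample(self, enc_cfg):
        from spikecolearn import build_network

        train = separable_train(2)
        a = build_network(enc_cfg, T=1, seed=1).clusters[0]
        b = build_network(enc_cfg, T=1, seed=1).clusters[0]
        train_cluster(a, [(train, 2)])
        train_sample(b, train, 2)
        np.testing.assert_array_equal(a.W, b.W)

    def test_bitwise_reproducible(self, enc_cfg, separable_subset):
        from spikecolearn import build_network

        runs = []
        for _ in range(2):
            net = build_network(enc_cfg, T=1, seed=7).clusters[0]
            train_cluster(net, separable_subset)
            runs.append(net.W.copy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_empty_subset_rejected(self, small_net):
        with pytest.raises(ValueError):
            train_cluster(small_net, [])

    def test_separable_fixture_perfect_after_one_pass(self, enc_cfg, separable_subset):
        from spikecolearn import build_network

        cfg = LearnConfig()
        net = build_network(enc_cfg, T=1, seed=42).clusters[0]
        train_cluster(net, separable_subset, cfg)
        acc = evaluate(EnsembleSNN([net], enc_cfg), separable_subset, cfg.lif)
        assert acc == 100.0
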