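"""Bipolar supervised learning: STDP weight updates shaped by teacher signals.

Training one sample is a closed loop.  The cluster is simulated teacher-free
and the set M of decode neurons that fired is recorded.  While M differs
from {label}, teacher signals are built — one *encouraging* signal for the
label neuron (injection time 70 ms by default) and one *punishing* signal
(35 ms) for every other fired neuron — and the weights are updated:

* synapses onto the encouraged neuron are potentiated by the causal STDP
  kernel against the teacher-forced post spike, so inputs that fired
  earlier (the feature-carrying ones under latency coding) gain the most;
* synapses onto each punished neuron are depressed (anti-STDP) in
  proportion to the magnitude of the pairwise STDP they accumulated with
  that neuron's actual spikes, removing exactly the drive that caused the
  erroneous firing.

The loop therefore converges when the cluster, unaided, fires only the
label neuron, and the convergence flag always refers to teacher-free
behaviour.  The teacher *currents* themselves (suprathreshold depolarizing
pulse / strong hyperpolarizing pulse) are implemented in the simulator and
available for experimentation; the update rule above is their idealized
plasticity effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Literal, Sequence

import numpy as np

from .lif import FiringRecord, LIFParams, simulate_cluster

if TYPE_CHECKING:  # pragma: no cover
    from .encoding import SpikeTrain
    from .structure import ClusterNet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class STDPParams:
    """Pair-based additive STDP parameters.

    a_plus / a_minus are the potentiation / depression amplitudes per spike
    pair; tau_plus / tau_minus the corresponding exponential time constants
    in ms.  Weights are clipped to [w_min, w_max] after every update.
    punish_scale multiplies the anti-STDP depression under a punishing
    teacher (0 disables it, leaving pure suppression).

    The floor is negative: repeated punishment can drive a synapse into an
    effectively inhibitory weight.  This is what lets a decode neuron stay
    silent on a class whose active channels are a superset of its own
    (an all-segments digit contains every stroke of a plainer one) — with a
    floor at zero no threshold unit can separate such pairs.  punish_scale
    is below 1 because the anti-STDP magnitude is dominated by the causal
    (a_plus) term; unscaled it erases drive faster than encouragement
    rebuilds it.
    """

    a_plus: float = 0.2
    a_minus: float = 0.1
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    w_min: float = -50.0
    w_max: float = 50.0
    punish_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.a_plus <= 0 or self.a_minus <= 0:
            raise ValueError("STDP amplitudes must be positive")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")
        if not self.w_min < self.w_max:
            raise ValueError("need w_min < w_max")


@dataclass(frozen=True)
class TeacherSignal:
    """One teacher event: polarity, target decode neuron, time, magnitude."""

    polarity: Literal["encourage", "punish"]
    target: int
    time: float
    magnitude: float = 1e4


@dataclass(frozen=True)
class TeacherConfig:
    """Timing and strength of the two teacher polarities.

    The encouraging signal arrives late in the window (70 ms) so that the
    causal STDP kernel rewards the early, feature-carrying spikes; the
    punishing signal arrives at 35 ms, early enough to suppress most of an
    erroneous neuron's firing.
    """

    encourage_ms: float = 70.0
    punish_ms: float = 35.0
    magnitude: float = 1e4


@dataclass(frozen=True)
class LearnConfig:
    """Everything the per-sample training loop needs."""

    lif: LIFParams = field(default_factory=LIFParams)
    stdp: STDPParams = field(default_factory=STDPParams)
    teacher: TeacherConfig = field(default_factory=TeacherConfig)
    max_inner_iters: int = 50


@dataclass(frozen=True)
class TrainOutcome:
    """Result of training one sample: converged iff the final teacher-free
    fired set equals {label}."""

    converged: bool
    iterations: int
    final_M: frozenset[int]


def stdp_delta(
    pre_times: Sequence[float] | np.ndarray,
    post_times: Sequence[float] | np.ndarray,
    p: STDPParams,
) -> float:
    """All-pairs additive STDP weight change for one synapse.

    Causal pairs (t_pre < t_post) potentiate by a_plus * exp(-dt/tau_plus);
    anti-causal pairs (t_pre >= t_post) depress by a_minus *
    exp(-dt/tau_minus).  Empty trains contribute nothing.
    """
    pre = np.asarray(pre_times, dtype=float)
    post = np.asarray(post_times, dtype=float)
    if pre.size == 0 or post.size == 0:
        return 0.0
    lag = post[None, :] - pre[:, None]  # >0 means causal
    causal = lag > 0
    pot = p.a_plus * np.exp(-lag[causal] / p.tau_plus).sum()
    dep = p.a_minus * np.exp(lag[~causal] / p.tau_minus).sum()
    return float(pot - dep)


def build_teacher_signals(
    M: frozenset[int] | set[int],
    L: int,
    cfg: TeacherConfig | None = None,
    n_classes: int = 10,
) -> list[TeacherSignal]:
    """Teacher signals for fired set M under label L.

    One encouraging signal for neuron L — emitted whether or not L fired,
    since the forced post spike is the only mechanism that can potentiate a
    silent label neuron — and one punishing signal per erroneously fired
    neuron.  The list is empty exactly when M == {L}.
    """
    cfg = cfg or TeacherConfig()
    if not 0 <= L < n_classes:
        raise ValueError(f"label {L} outside [0, {n_classes})")
    if set(M) == {L}:
        return []
    signals = [TeacherSignal("encourage", L, cfg.encourage_ms, cfg.magnitude)]
    signals.extend(
        TeacherSignal("punish", x, cfg.punish_ms, cfg.magnitude)
        for x in sorted(M)
        if x != L
    )
    return signals


def _per_channel_stdp(
    train: "SpikeTrain", post: np.ndarray, n_channels: int, p: STDPParams
) -> np.ndarray:
    """Vector of stdp_delta(pre spikes on channel c, post) for every c."""
    out = np.zeros(n_channels)
    if len(train) == 0 or post.size == 0:
        return out
    lag = post[None, :] - train.times[:, None]
    causal = lag > 0
    contrib = np.where(
        causal,
        p.a_plus * np.exp(-np.abs(lag) / p.tau_plus),
        -p.a_minus * np.exp(-np.abs(lag) / p.tau_minus),
    ).sum(axis=1)
    np.add.at(out, train.channels, contrib)
    return out


def apply_bipolar_update(
    net: "ClusterNet",
    train: "SpikeTrain",
    record: FiringRecord,
    teachers: Sequence[TeacherSignal],
    p: STDPParams,
) -> "ClusterNet":
    """Apply one bipolar weight update in place and return the net.

    Encouraged neurons: each alive synapse gains the causal STDP kernel
    evaluated against the teacher-forced post spike (pre spikes after the
    forced spike contribute nothing — the forced spike is a reward event,
    not evidence against later inputs — so an encouraging signal can never
    lower the summed weight onto its target).  Punished neurons: each alive
    synapse loses punish_scale * |stdp_delta| against that neuron's actual
    spikes.  All weights are clipped to [w_min, w_max]; dead synapses are
    never touched.
    """
    if train.n_channels != net.n_inputs:
        raise ValueError("spike train / network shape mismatch")
    for sig in teachers:
        alive = net.alive[:, sig.target]
        if sig.polarity == "encourage":
            lag = sig.time - train.times  # >0: pre before forced post
            contrib = np.where(lag > 0, p.a_plus * np.exp(-np.abs(lag) / p.tau_plus), 0.0)
            delta = np.zeros(net.n_inputs)
            np.add.at(delta, train.channels, contrib)
        else:
            post = record.spike_times[sig.target]
            delta = -p.punish_scale * np.abs(
                _per_channel_stdp(train, np.asarray(post, dtype=float), net.n_inputs, p)
            )
        net.W[:, sig.target] = np.where(
            alive,
            np.clip(net.W[:, sig.target] + delta, p.w_min, p.w_max),
            net.W[:, sig.target],
        )
    return net


def train_sample(
    net: "ClusterNet",
    s: "SpikeTrain",
    L: int,
    cfg: LearnConfig | None = None,
) -> tuple["ClusterNet", TrainOutcome]:
    """Train one cluster on one labelled spike train until it responds with
    only the label neuron, or the iteration cap is reached.

    Each iteration simulates teacher-free, checks the fired set M, builds
    teacher signals from (M, L) and applies the bipolar update.  The loop
    exits converged as soon as M == {L}; a net already responding correctly
    performs zero updates.  Non-convergence at the cap is an outcome, not
    an error.
    """
    cfg = cfg or LearnConfig()
    iterations = 0
    while True:
        record = simulate_cluster(net, s, (), cfg.lif)
        M = record.fired_set
        if M == {L}:
            return net, TrainOutcome(True, iterations, M)
        if iterations >= cfg.max_inner_iters:
            logger.debug("sample with label %d did not converge in %d iterations", L, iterations)
            return net, TrainOutcome(False, iterations, M)
        teachers = build_teacher_signals(M, L, cfg.teacher, net.n_decode)
        apply_bipolar_update(net, s, record, teachers, cfg.stdp)
        iterations += 1


def train_cluster(
    net: "ClusterNet",
    subset: Sequence[tuple["SpikeTrain", int]],
    cfg: LearnConfig | None = None,
) -> "ClusterNet":
    """One pass of bipolar training over a (sampled-order) subset."""
    if not subset:
        raise ValueError("training subset must be nonempty")
    cfg = cfg or LearnConfig()
    n_fail = 0
    for s, label in subset:
        net, outcome = train_sample(net, s, label, cfg)
        n_fail += not outcome.converged
    if n_fail:
        logger.info("%d/%d samples hit the iteration cap", n_fail, len(subset))
    return net
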