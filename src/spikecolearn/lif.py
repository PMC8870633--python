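"""Clock-driven leaky integrate-and-fire simulation of one cluster.

A cluster's decode layer is a row of one LIF neuron per class, each fully
connected to the input channels.  Every input spike injects an
exponentially decaying synaptic current, weighted by the (alive) synapse,
into every decode neuron.  Teacher signals inject an extra rectangular
current pulse — depolarizing for an encouraging signal, hyperpolarizing for
a punishing one — into their target neuron.

Membrane dynamics follow the standard form

    tau_m dv/dt = -(v - v_rest) + R * I(t)

integrated with the exponential-Euler scheme (exact for the leak term, the
current held constant over a step).  On crossing threshold the neuron
spikes, resets to ``v_reset`` and ignores input for ``t_ref`` ms.  The
whole simulation is deterministic: identical inputs give bit-identical
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy.signal import lfilter

if TYPE_CHECKING:  # pragma: no cover
    from .encoding import SpikeTrain
    from .plasticity import TeacherSignal
    from .structure import ClusterNet


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire neuron and synapse parameters.

    Values are standard textbook / simulator-default choices; all are
    exposed through the run configuration.

    Attributes
    ----------
    tau_m : membrane time constant, ms.
    v_rest : resting potential, mV.
    v_thresh : firing threshold, mV.
    v_reset : post-spike reset potential, mV.
    t_ref : absolute refractory period, ms.
    dt : integration step, ms.
    psc_tau : exponential synaptic-current decay, ms.
    r_m : membrane resistance, mV per unit input current; converts synaptic
        weight (current amplitude) into depolarization scale.
    """

    tau_m: float = 10.0
    v_rest: float = -65.0
    v_thresh: float = -50.0
    v_reset: float = -70.0
    t_ref: float = 2.0
    dt: float = 0.1
    psc_tau: float = 2.0
    r_m: float = 1.0

    def __post_init__(self) -> None:
        if not (self.v_reset <= self.v_rest < self.v_thresh):
            raise ValueError("need v_reset <= v_rest < v_thresh")
        if self.dt <= 0 or self.tau_m <= 0 or self.psc_tau <= 0:
            raise ValueError("dt, tau_m and psc_tau must be positive")


@dataclass
class NeuronState:
    """Mutable state of a single LIF neuron during stepping."""

    v: float
    refractory_until: float = -np.inf
    spike_times: list[float] = field(default_factory=list)
    t: float = 0.0


@dataclass(frozen=True)
class FiringRecord:
    """Per-neuron spike times of one decode layer after a simulation."""

    spike_times: tuple[np.ndarray, ...]

    @property
    def fired_set(self) -> frozenset[int]:
        """Indices of decode neurons that fired at least once (the set M)."""
        return frozenset(i for i, s in enumerate(self.spike_times) if s.size)

    @property
    def first_spike(self) -> tuple[float | None, ...]:
        return tuple(float(s[0]) if s.size else None for s in self.spike_times)

    @property
    def counts(self) -> np.ndarray:
        return np.array([s.size for s in self.spike_times], dtype=np.intp)


def step_lif(state: NeuronState, input_current: float, params: LIFParams) -> NeuronState:
    """Advance one neuron by one time step ``params.dt``.

    During refractoriness the membrane is clamped to ``v_reset`` and the
    input is ignored.  A threshold crossing emits a spike stamped at the
    start of the step, resets the membrane and opens a refractory window.
    """
    if not np.isfinite(input_current):
        raise ValueError("input current must be finite")
    p = params
    t_next = state.t + p.dt
    if state.t < state.refractory_until:
        state.v = p.v_reset
        state.t = t_next
        return state
    alpha = np.exp(-p.dt / p.tau_m)
    state.v = p.v_rest + (state.v - p.v_rest) * alpha + p.r_m * input_current * (1.0 - alpha)
    if state.v >= p.v_thresh:
        state.spike_times.append(state.t)
        state.v = p.v_reset
        state.refractory_until = state.t + p.t_ref
    state.t = t_next
    return state


def synaptic_current(
    train: "SpikeTrain", weights: np.ndarray, params: LIFParams, n_steps: int
) -> np.ndarray:
    """Summed exponential synaptic current per decode neuron per step.

    Each event at time t_e on channel c contributes
    ``weights[c, j] * exp(-(t - t_e)/psc_tau)`` for t >= t_e; implemented as
    an impulse train filtered by a first-order recursive exponential.
    """
    n_out = weights.shape[1]
    impulses = np.zeros((n_steps, n_out))
    if len(train):
        bins = np.minimum((train.times / params.dt).astype(np.intp), n_steps - 1)
        np.add.at(impulses, bins, weights[train.channels, :])
    decay = np.exp(-params.dt / params.psc_tau)
    return lfilter([1.0], [1.0, -decay], impulses, axis=0)


def teacher_current(
    teachers: Iterable["TeacherSignal"],
    n_out: int,
    params: LIFParams,
    n_steps: int,
    pulse_ms: float = 1.0,
) -> np.ndarray:
    """Rectangular teacher current pulses, signed by polarity."""
    cur = np.zeros((n_steps, n_out))
    pulse_steps = max(1, int(round(pulse_ms / params.dt)))
    window = n_steps * params.dt
    for sig in teachers:
        if not 0 <= sig.time < window:
            raise ValueError(f"teacher time {sig.time} ms outside [0, {window}) window")
        if not 0 <= sig.target < n_out:
            raise ValueError("teacher target index out of range")
        start = int(round(sig.time / params.dt))
        amp = sig.magnitude if sig.polarity == "encourage" else -sig.magnitude
        cur[start : start + pulse_steps, sig.target] += amp
    return cur


def simulate_cluster(
    net: "ClusterNet",
    train: "SpikeTrain",
    teachers: Sequence["TeacherSignal"] = (),
    params: LIFParams | None = None,
) -> FiringRecord:
    """Simulate one cluster's decode layer over the full window.

    Input events drive the decode neurons through the alive weight matrix;
    teacher signals add their current pulses.  Pruned (dead) synapses are
    equivalent to zero-weight synapses.  Returns the per-neuron spike times.
    """
    p = params or LIFParams()
    if train.n_channels != net.n_inputs:
        raise ValueError(
            f"spike train has {train.n_channels} channels, network expects {net.n_inputs}"
        )
    n_steps = int(round(train.window_ms / p.dt))
    w_eff = np.where(net.alive, net.W, 0.0)
    current = synaptic_current(train, w_eff, p, n_steps)
    if teachers:
        current = current + teacher_current(teachers, net.n_decode, p, n_steps)

    n_out = net.n_decode
    alpha = np.exp(-p.dt / p.tau_m)
    # exact propagation of the exponential-PSC convolution over one step,
    # so the grid trajectory samples the continuous solution exactly and
    # halving dt only moves event binning, not the integral
    tm, ts = p.tau_m, p.psc_tau
    if abs(tm - ts) > 1e-12:
        drive = p.r_m * ts / (tm - ts) * (np.exp(-p.dt / tm) - np.exp(-p.dt / ts))
    else:
        drive = p.r_m * p.dt / tm * np.exp(-p.dt / tm)
    v = np.full(n_out, p.v_rest)
    refr_until = np.full(n_out, -np.inf)
    spikes: list[list[float]] = [[] for _ in range(n_out)]
    ref_steps = p.t_ref  # compared in ms against step start times
    for n in range(n_steps):
        t = n * p.dt
        refractory = t < refr_until
        v = p.v_rest + (v - p.v_rest) * alpha + drive * current[n]
        v[refractory] = p.v_reset
        fired = (v >= p.v_thresh) & ~refractory
        if fired.any():
            for j in np.flatnonzero(fired):
                spikes[j].append(t)
            v[fired] = p.v_reset
            refr_until[fired] = t + ref_steps
    return FiringRecord(tuple(np.array(s) for s in spikes))
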