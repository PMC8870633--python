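"""Cluster-grouped network construction and structural learning (pruning).

The network is an ensemble of T structurally identical clusters.  Each
cluster pairs an input layer — one relay channel per pooled feature pixel,
4 * floor((29-k)/p)**2 of them — with a decode layer of one LIF neuron per
class, fully connected.  With the default 4x4 kernels and 2x2 pooling that
is 576 input channels and 10 decode neurons: 586 neurons and 5760 synapses
per cluster, 86,400 synapses across the default 15 clusters.

Structural learning follows use-and-disuse: a synapse whose weight moved
less than a threshold from its construction-time snapshot took no part in
learning and is eliminated,

    prune synapse i  iff  |W_current(i) - W_initial(i)| < w_change

with a strict inequality, so a zero threshold prunes nothing.  Pruning only
clears the alive mask; weights are left untouched and the initial snapshot
is never refreshed, so pruning is idempotent and monotone in the threshold.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np

from .encoding import EncoderConfig

if TYPE_CHECKING:  # pragma: no cover
    from .encoding import ImageSample

#: half-range of the uniform initial weight distribution
W_INIT_MAX = 5.0


@dataclass
class ClusterNet:
    """One cluster: full input-to-decode connectivity with an alive mask.

    W is the current weight matrix (n_inputs x n_decode), W_init the
    construction-time snapshot used by structural learning, and alive the
    boolean mask of surviving synapses.  Dead synapses keep their frozen
    weight but contribute nothing to simulation and are never updated.
    """

    W: np.ndarray
    W_init: np.ndarray
    alive: np.ndarray

    def __post_init__(self) -> None:
        if not (self.W.shape == self.W_init.shape == self.alive.shape):
            raise ValueError("W, W_init and alive must share shape")
        if self.W.ndim != 2:
            raise ValueError("weight matrix must be 2D (n_inputs x n_decode)")

    @property
    def n_inputs(self) -> int:
        return self.W.shape[0]

    @property
    def n_decode(self) -> int:
        return self.W.shape[1]

    @classmethod
    def create(cls, n_inputs: int, n_decode: int, rng: np.random.Generator) -> "ClusterNet":
        if n_inputs < 1 or n_decode < 1:
            raise ValueError("layer sizes must be positive")
        w = rng.uniform(0.0, W_INIT_MAX, size=(n_inputs, n_decode))
        return cls(W=w, W_init=w.copy(), alive=np.ones_like(w, dtype=bool))


@dataclass(frozen=True)
class PruneConfig:
    """Threshold for use-and-disuse pruning, in weight units."""

    w_change: float

    def __post_init__(self) -> None:
        if self.w_change < 0:
            raise ValueError("pruning threshold must be non-negative")


@dataclass
class EnsembleSNN:
    """T homogeneous clusters sharing one encoder configuration."""

    clusters: list[ClusterNet]
    encoder_cfg: EncoderConfig

    @property
    def T(self) -> int:
        return len(self.clusters)


def build_network(
    encoder_cfg: EncoderConfig,
    T: int = 15,
    n_classes: int = 10,
    seed: int = 0,
) -> EnsembleSNN:
    """Construct the full ensemble with per-cluster derived seeds.

    Every cluster gets n_inputs = 4 * floor((29-k)/p)**2 channels and one
    decode neuron per class, fully connected, all synapses alive, weights
    drawn uniformly and snapshotted.  Seeding each cluster from
    (seed, cluster index) makes the result independent of the order in
    which clusters are built or trained.
    """
    if T < 1:
        raise ValueError("need at least one cluster")
    if n_classes < 1:
        raise ValueError("need at least one class")
    n_inputs = encoder_cfg.n_channels
    clusters = [
        ClusterNet.create(n_inputs, n_classes, np.random.default_rng([seed, t]))
        for t in range(T)
    ]
    return EnsembleSNN(clusters=clusters, encoder_cfg=encoder_cfg)


def prune(net: ClusterNet, cfg: PruneConfig) -> ClusterNet:
    """Eliminate synapses whose weight barely moved during learning.

    Clears alive exactly where |W - W_init| < w_change (strict); already
    dead synapses stay dead; weight values are untouched.  Returns the same
    net, modified in place.
    """
    unchanged = np.abs(net.W - net.W_init) < cfg.w_change
    net.alive &= ~unchanged
    return net


def count_synapses(ens: EnsembleSNN | ClusterNet) -> tuple[int, int, float]:
    """(alive, total, alive proportion) across all clusters."""
    nets = ens.clusters if isinstance(ens, EnsembleSNN) else [ens]
    alive = sum(int(n.alive.sum()) for n in nets)
    total = sum(n.alive.size for n in nets)
    return alive, total, alive / total


def prune_sweep(
    ens: EnsembleSNN,
    thresholds: Sequence[float],
    eval_set: Sequence["ImageSample"],
    lif_params=None,
) -> list[dict[str, float]]:
    """Evaluate accuracy/sparsity across a grid of pruning thresholds.

    Each threshold is applied to a fresh copy of the trained ensemble, so
    rows are independent.  Rows come back sorted by threshold with keys
    threshold / accuracy / proportion / alive — the schema of the
    structural-learning report.
    """
    from .ensemble import evaluate  # deferred: ensemble builds on structure

    if not len(thresholds):
        raise ValueError("threshold list must be nonempty")
    rows = []
    for thr in sorted(thresholds):
        trial = copy.deepcopy(ens)
        for net in trial.clusters:
            prune(net, PruneConfig(thr))
        alive, total, prop = count_synapses(trial)
        rows.append(
            {
                "threshold": float(thr),
                "accuracy": float(evaluate(trial, eval_set, lif_params)),
                "proportion": 100.0 * prop,
                "alive": float(alive),
            }
        )
    return rows
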