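"""Bootstrap-trained cluster ensemble: end-to-end training and decoding.

Training (structural-and-synaptic co-learning) proceeds as: encode the
whole training set once; initialize T structurally identical clusters; draw
T bootstrap subsets (with replacement) of the encoded set; train cluster t
on subset t with the bipolar supervised rule for a configured number of
passes; optionally prune each cluster after its training.  Clusters are
independent given their subsets and per-cluster seeds, so the result never
depends on the order in which they are trained.

Decoding is teacher-free.  The second decode layer has one accumulator
neuron per class: neuron j sums the spike counts of every cluster's
layer-1 neuron j, and the prediction is the argmax, with ties broken by
the earliest first-spike time across clusters and then by the lowest
label index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .encoding import EncoderConfig, ImageSample, SpikeTrain, encode_image
from .lif import FiringRecord, LIFParams, simulate_cluster
from .plasticity import LearnConfig, train_cluster
from .structure import EnsembleSNN, PruneConfig, build_network, prune


@dataclass(frozen=True)
class TrainConfig:
    """Knobs of the co-learning procedure.

    T : number of clusters in the ensemble (default 15).
    n_sub : samples per bootstrap subset (default 1000).
    iterations : training passes each cluster makes over its subset
        (default 3 — beyond two passes accuracy grows faster with cluster
        count).
    seed : global seed; every other random draw is derived from it.
    prune_threshold : if set, apply use-and-disuse pruning at this weight-
        change threshold to each cluster right after its training pass.
    learn : parameters of the per-sample bipolar learning loop.
    """

    T: int = 15
    n_sub: int = 1000
    iterations: int = 3
    seed: int = 0
    prune_threshold: float | None = None
    learn: LearnConfig = field(default_factory=LearnConfig)

    def __post_init__(self) -> None:
        if self.T < 1 or self.n_sub < 1 or self.iterations < 1:
            raise ValueError("T, n_sub and iterations must all be >= 1")


@dataclass(frozen=True)
class Prediction:
    """Decoded class with the evidence behind it."""

    label: int
    votes: np.ndarray  # per-class aggregate spike counts
    per_cluster: tuple[FiringRecord, ...]
    no_spike: bool = False  # True when no decode neuron fired anywhere


def bootstrap_subsets(
    S: Sequence, T: int, n_sub: int, seed: int = 0
) -> list[list]:
    """Draw T subsets of n_sub samples with replacement from S.

    Deterministic per seed; the T draws are mutually independent.
    """
    if not len(S):
        raise ValueError("cannot bootstrap from an empty training set")
    rng = np.random.default_rng(seed)
    return [[S[i] for i in rng.integers(0, len(S), size=n_sub)] for _ in range(T)]


def train_ensemble(D: Sequence[ImageSample], cfg: TrainConfig,
                   encoder_cfg: EncoderConfig | None = None) -> EnsembleSNN:
    """Run the full co-learning procedure on a labelled image set."""
    if not len(D):
        raise ValueError("training set is empty")
    enc_cfg = encoder_cfg or EncoderConfig()
    encoded = [(encode_image(img, enc_cfg), img.label) for img in D]
    ens = build_network(enc_cfg, T=cfg.T, n_classes=10, seed=cfg.seed)
    subsets = bootstrap_subsets(encoded, cfg.T, cfg.n_sub, cfg.seed)
    for t, (net, subset) in enumerate(zip(ens.clusters, subsets)):
        for _ in range(cfg.iterations):
            train_cluster(net, subset, cfg.learn)
        if cfg.prune_threshold is not None:
            prune(net, PruneConfig(cfg.prune_threshold))
    return ens


def decode(
    ens: EnsembleSNN,
    image: ImageSample | SpikeTrain,
    lif_params: LIFParams | None = None,
) -> Prediction:
    """Classify one image (or pre-encoded train) with the full ensemble.

    Teacher-free by construction: evaluation never injects teacher
    signals.  Layer-2 accumulator j collects the spike counts of neuron j
    in every cluster; prediction is the argmax, ties broken by earliest
    first spike across clusters, then lowest index.  If nothing fired the
    prediction falls back to label 0 and is flagged ``no_spike``.
    """
    if not ens.clusters:
        raise ValueError("ensemble has no clusters")
    train = (
        image
        if isinstance(image, SpikeTrain)
        else encode_image(image, ens.encoder_cfg)
    )
    records = tuple(simulate_cluster(net, train, (), lif_params) for net in ens.clusters)
    n_classes = ens.clusters[0].n_decode
    votes = np.zeros(n_classes, dtype=np.intp)
    earliest = np.full(n_classes, np.inf)
    for rec in records:
        votes += rec.counts
        for j, first in enumerate(rec.first_spike):
            if first is not None and first < earliest[j]:
                earliest[j] = first
    top = votes.max()
    candidates = np.flatnonzero(votes == top)
    label = int(candidates[np.lexsort((candidates, earliest[candidates]))[0]])
    return Prediction(
        label=label,
        votes=votes,
        per_cluster=records,
        no_spike=bool(top == 0),
    )


def evaluate(
    ens: EnsembleSNN,
    test: Sequence[ImageSample | tuple[SpikeTrain, int]],
    lif_params: LIFParams | None = None,
) -> float:
    """Classification accuracy in percent, to two decimals.

    Accepts raw images or (spike train, label) pairs; counting is exact
    rational arithmetic, rounded only for the final report.
    """
    if not len(test):
        raise ValueError("test set is empty")
    correct = 0
    for item in test:
        if isinstance(item, ImageSample):
            x, label = item, item.label
        else:
            x, label = item
        correct += decode(ens, x, lif_params).label == label
    return float(round(Fraction(100 * correct, len(test)), 2))
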