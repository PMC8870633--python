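import numpy as np
import pytest

from spikecolearn import (
    ClusterNet,
    EncoderConfig,
    LearnConfig,
    SpikeTrain,
    build_network,
)


@pytest.fixture(scope="session")
def enc_cfg() -> EncoderConfig:
    return EncoderConfig()  # 4x4 kernels, 2x2 pooling, linear coding


def separable_train(
    label: int,
    n_channels: int = 576,
    per_class: int = 57,
    offset: float = 0.0,
    window_ms: float = 100.0,
) -> SpikeTrain:
    """Spike train of a synthetic class with class-disjoint active channels.

    Class c occupies channels [c*per_class, (c+1)*per_class); spikes are
    packed into the early window so the summed synaptic current of an
    untrained net can reach threshold.
    """
    ch = np.arange(label * per_class, (label + 1) * per_class)
    t = np.linspace(5.0, 20.0, per_class) + offset
    return SpikeTrain(ch, t, n_channels, window_ms)


@pytest.fixture(scope="session")
def separable_subset() -> list[tuple[SpikeTrain, int]]:
    """One sample per class of the 10-class disjoint-channel fixture."""
    return [(separable_train(c), c) for c in range(10)]


@pytest.fixture()
def small_net(enc_cfg) -> ClusterNet:
    return build_network(enc_cfg, T=1, n_classes=10, seed=42).clusters[0]


@pytest.fixture(scope="session")
def learn_cfg() -> LearnConfig:
    return LearnConfig()
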