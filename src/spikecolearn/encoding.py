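"""Spiking encoding: oriented convolution, max pooling, latency coding.

The encoder turns a 28x28 grayscale digit into a spatiotemporal spike
pattern in three stages, mimicking early visual feature extraction:

1. four fixed oriented kernels (horizontal, vertical, two diagonals) are
   cross-correlated with the image (valid mode, stride 1);
2. each of the four raw maps is max-pooled with non-overlapping windows;
3. pooled feature intensities are converted to spike *latencies* by a
   rank-order-style code: the stronger the feature, the earlier the spike.

The latency code works on the raw pixel scale [0, 255]; pooled features are
min-max rescaled to that range per image first, and raw delays are then
mapped linearly onto the simulation window.  A channel whose rescaled
intensity is exactly 0 emits no spike at all, keeping trains sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import correlate2d

IMAGE_SIDE = 28
PIXEL_MAX = 255.0

KERNEL_SIZES = (3, 4, 5)
POOL_SIZES = (2, 3, 4)

#: latency coders: raw pixel/feature intensity V in [0, 255] -> raw delay
#: in [0, 255].  Every coder is strictly non-increasing on [1, 255].
CODERS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": lambda v: PIXEL_MAX - v,
    "exponential": lambda v: PIXEL_MAX / np.power(2.0, v / 32.0),
    "inverse": lambda v: PIXEL_MAX / np.maximum(v, 1.0),
    "power": lambda v: PIXEL_MAX / np.maximum(v, 1.0) ** 2,
}


@dataclass(frozen=True)
class ImageSample:
    """One 28x28 grayscale digit with its class label."""

    pixels: np.ndarray  # (28, 28) uint, values in [0, 255]
    label: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2D grid")
        if px.min() < 0 or px.max() > PIXEL_MAX:
            raise ValueError("pixel intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class EncoderConfig:
    """Configuration of the encoding stage.

    Parameters
    ----------
    kernel_size : int
        Side length of the four oriented kernels; one of {3, 4, 5}.
    pool_size : int
        Side of the non-overlapping max-pooling window; one of {2, 3, 4}.
    method : str
        Latency coder name; one of ``CODERS``.  ``linear`` (delay = 255 - V)
        is the default.
    window_ms : float
        Simulation window length; raw delays [0, 255] are mapped onto
        [0, window_ms).  Must exceed the latest teacher injection time.
    min_intensity : float
        Contrast floor in rescaled intensity units [0, 255]: channels whose
        rescaled feature falls below it emit no spike.  Keeps trains sparse
        and event-driven — a stroke crossing any oriented band scores far
        above this floor, while background fluctuations stay below it.
    """

    kernel_size: int = 4
    pool_size: int = 2
    method: str = "linear"
    window_ms: float = 100.0
    min_intensity: float = 20.0

    def __post_init__(self) -> None:
        if self.kernel_size not in KERNEL_SIZES:
            raise ValueError(f"kernel_size must be one of {KERNEL_SIZES}")
        if self.pool_size not in POOL_SIZES:
            raise ValueError(f"pool_size must be one of {POOL_SIZES}")
        if self.method not in CODERS:
            raise ValueError(
                f"unknown coding method {self.method!r}; "
                f"choose from {sorted(CODERS)}"
            )
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")

    @property
    def map_side(self) -> int:
        """Pooled map side: floor((29 - kernel) / pool) on a 28-side image."""
        conv_side = IMAGE_SIDE - self.kernel_size + 1
        return conv_side // self.pool_size

    @property
    def n_channels(self) -> int:
        """Total spike channels: 4 oriented maps, map_side**2 each."""
        return 4 * self.map_side**2


@dataclass(frozen=True)
class FeatureStack:
    """Four pooled oriented feature maps of identical shape."""

    maps: np.ndarray  # (4, side, side)

    def __post_init__(self) -> None:
        m = np.asarray(self.maps, dtype=float)
        if m.ndim != 3 or m.shape[0] != 4 or m.shape[1] != m.shape[2]:
            raise ValueError("maps must be 4 square grids of equal size")
        object.__setattr__(self, "maps", m)


@dataclass(frozen=True)
class SpikeTrain:
    """Timed events on flattened feature channels, sorted by time.

    ``channels[i]`` spikes at ``times[i]`` ms; at most one event per channel.
    """

    channels: np.ndarray  # int, indices into the flattened FeatureStack
    times: np.ndarray  # float ms, within [0, window_ms)
    n_channels: int
    window_ms: float

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=np.intp)
        t = np.asarray(self.times, dtype=float)
        if ch.shape != t.shape or ch.ndim != 1:
            raise ValueError("channels and times must be 1D and aligned")
        order = np.argsort(t, kind="stable")
        ch, t = ch[order], t[order]
        if ch.size:
            if ch.min() < 0 or ch.max() >= self.n_channels:
                raise ValueError("channel index out of range")
            if t.min() < 0 or t.max() >= self.window_ms:
                raise ValueError("spike times must lie in [0, window_ms)")
        object.__setattr__(self, "channels", ch)
        object.__setattr__(self, "times", t)

    @property
    def events(self) -> list[tuple[int, float]]:
        return list(zip(self.channels.tolist(), self.times.tolist()))

    def __len__(self) -> int:
        return int(self.channels.size)


def make_kernels(size: int) -> list[np.ndarray]:
    """Build the four oriented kernels of a given side length.

    Orientations are horizontal (transverse), vertical (longitudinal) and
    the two diagonals.  The oriented band carries weight +1; everything else
    is 0.  For even sizes the "center" band is the two middle rows/columns
    and each diagonal is the unit-offset pair of diagonals, keeping the four
    kernels weight-balanced.
    """
    if size not in KERNEL_SIZES:
        raise ValueError(f"unsupported kernel size {size}; use one of {KERNEL_SIZES}")
    horizontal = np.zeros((size, size))
    if size % 2:
        horizontal[size // 2, :] = 1.0
    else:
        horizontal[size // 2 - 1 : size // 2 + 1, :] = 1.0
    vertical = horizontal.T.copy()

    diag = np.eye(size)
    anti = np.fliplr(diag).copy()
    if size % 2 == 0:
        # widen even-size diagonals to a 2-wide band so all four kernels
        # carry comparable total weight
        diag = diag + np.eye(size, k=1)
        anti = np.fliplr(diag).copy()
    return [horizontal, vertical, diag, anti]


def convolve(image: ImageSample | np.ndarray, kernels: Sequence[np.ndarray]) -> np.ndarray:
    """Valid-mode, stride-1 cross-correlation of the image with each kernel.

    Returns an array of shape (len(kernels), N-k+1, N-k+1).  No kernel flip
    is applied (cross-correlation, not mathematical convolution).
    """
    px = image.pixels if isinstance(image, ImageSample) else np.asarray(image)
    px = px.astype(float)
    out = []
    for k in kernels:
        k = np.asarray(k, dtype=float)
        if k.shape[0] > px.shape[0] or k.shape[1] > px.shape[1]:
            raise ValueError("kernel larger than image")
        out.append(correlate2d(px, k, mode="valid"))
    return np.stack(out)


def maxpool(maps: np.ndarray, pool_size: int) -> FeatureStack:
    """Non-overlapping max pooling, stride = pool_size.

    Incomplete border rows/columns are dropped, so the output side is
    floor(input side / pool_size).
    """
    maps = np.asarray(maps, dtype=float)
    if pool_size < 2:
        raise ValueError("pool_size must be at least 2")
    side = maps.shape[-1]
    out_side = side // pool_size
    if out_side < 1:
        raise ValueError("pool window larger than feature map")
    crop = out_side * pool_size
    m = maps[..., :crop, :crop]
    m = m.reshape(maps.shape[0], out_side, pool_size, out_side, pool_size)
    return FeatureStack(m.max(axis=(2, 4)))


def encode(stack: FeatureStack, cfg: EncoderConfig) -> SpikeTrain:
    """Convert pooled features into a latency-coded spike train.

    Features are min-max rescaled to [0, 255] jointly across the four maps
    (preserving relative kernel responses), raw delays are computed by the
    configured coder, and delays are mapped linearly onto [0, window_ms).
    Channels whose rescaled intensity is 0 or below the contrast floor
    stay silent.
    """
    coder = CODERS[cfg.method]
    flat = stack.maps.reshape(-1)
    lo, hi = flat.min(), flat.max()
    if hi == lo:
        scaled = np.zeros_like(flat)
    else:
        scaled = (flat - lo) / (hi - lo) * PIXEL_MAX
    active = (scaled > 0) & (scaled >= cfg.min_intensity)
    raw_delay = coder(scaled[active])
    # raw [0, 255] -> [0, window): 256 bins keep the latest delay inside
    times = raw_delay * cfg.window_ms / (PIXEL_MAX + 1.0)
    return SpikeTrain(
        channels=np.flatnonzero(active),
        times=times,
        n_channels=flat.size,
        window_ms=cfg.window_ms,
    )


def encode_image(image: ImageSample | np.ndarray, cfg: EncoderConfig) -> SpikeTrain:
    """Full pipeline: oriented convolution -> max pooling -> latency code."""
    kernels = make_kernels(cfg.kernel_size)
    return encode(maxpool(convolve(image, kernels), cfg.pool_size), cfg)
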