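"""Datasets, file formats and run configuration.

Provides the big-endian IDX reader/writer used by the MNIST distribution,
a deterministic synthetic digit generator (stroke glyphs on a dark field,
emulating MNIST statistics) so the whole pipeline is testable without any
download, plus the spike-train CSV dialect, the model container, and
YAML/JSON configuration with documented defaults.
"""

from __future__ import annotations

import difflib
import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .encoding import EncoderConfig, ImageSample, SpikeTrain
from .lif import LIFParams
from .plasticity import LearnConfig, STDPParams, TeacherConfig
from .structure import ClusterNet, EnsembleSNN
from .ensemble import TrainConfig

logger = logging.getLogger(__name__)

IDX_IMAGES_MAGIC = 0x00000803
IDX_LABELS_MAGIC = 0x00000801


@dataclass
class DatasetHandle:
    """A loaded dataset: 28x28 labelled images plus provenance."""

    images: list[ImageSample]
    source: str  # "synthetic" | "idx"
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.images)


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic digit generator settings.

    Each class is a fixed seven-segment-style stroke glyph (intensity 255
    strokes on a 0 background); samples vary by integer translation jitter
    of up to ``jitter_px`` pixels per axis and clipped Gaussian pixel noise
    of standard deviation ``noise_sd`` intensity units.
    """

    n_per_class: int = 100
    classes: tuple[int, ...] = tuple(range(10))
    noise_sd: float = 10.0
    jitter_px: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(c not in range(10) for c in self.classes):
            raise ValueError("classes must be a subset of 0..9")


# ---------------------------------------------------------------------------
# IDX (MNIST container) reading and writing

def _read_exact(fh, n: int, path) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise ValueError(f"truncated IDX file: {path}")
    return buf


def read_idx(images_path, labels_path) -> DatasetHandle:
    """Parse a big-endian IDX image/label file pair.

    Validates both magic numbers and that the item counts match; yields
    28x28 uint8 images with their labels.
    """
    images_path, labels_path = Path(images_path), Path(labels_path)
    with open(images_path, "rb") as fh:
        magic, n, rows, cols = struct.unpack(">4i", _read_exact(fh, 16, images_path))
        if magic != IDX_IMAGES_MAGIC:
            raise ValueError(
                f"bad magic 0x{magic:08x} in {images_path} (expected image file)"
            )
        data = np.frombuffer(_read_exact(fh, n * rows * cols, images_path), dtype=np.uint8)
    with open(labels_path, "rb") as fh:
        magic, n_lab = struct.unpack(">2i", _read_exact(fh, 8, labels_path))
        if magic != IDX_LABELS_MAGIC:
            raise ValueError(
                f"bad magic 0x{magic:08x} in {labels_path} (expected label file)"
            )
        labels = np.frombuffer(_read_exact(fh, n_lab, labels_path), dtype=np.uint8)
    if n != n_lab:
        raise ValueError(f"{n} images but {n_lab} labels")
    pixels = data.reshape(n, rows, cols)
    images = [ImageSample(pixels[i], int(labels[i])) for i in range(n)]
    return DatasetHandle(images, source="idx", meta={"images": str(images_path), "labels": str(labels_path)})


def write_idx(images: Sequence[ImageSample], images_path, labels_path) -> None:
    """Write images and labels as an IDX pair (inverse of read_idx)."""
    arr = np.stack([img.pixels.astype(np.uint8) for img in images])
    n, rows, cols = arr.shape
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">4i", IDX_IMAGES_MAGIC, n, rows, cols))
        fh.write(arr.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">2i", IDX_LABELS_MAGIC, n))
        fh.write(bytes(img.label for img in images))


# ---------------------------------------------------------------------------
# Synthetic digits

_SEGMENTS = {
    "A": (slice(4, 6), slice(9, 20)),     # top bar
    "G": (slice(13, 15), slice(9, 20)),   # middle bar
    "D": (slice(22, 24), slice(9, 20)),   # bottom bar
    "F": (slice(4, 15), slice(9, 11)),    # upper left
    "B": (slice(4, 15), slice(18, 20)),   # upper right
    "E": (slice(13, 24), slice(9, 11)),   # lower left
    "C": (slice(13, 24), slice(18, 20)),  # lower right
}

_DIGIT_SEGMENTS = {
    0: "ABCDEF",
    1: "BC",
    2: "ABGED",
    3: "ABGCD",
    4: "FGBC",
    5: "AFGCD",
    6: "AFGECD",
    7: "ABC",
    8: "ABCDEFG",
    9: "ABCDFG",
}


def digit_templates() -> dict[int, np.ndarray]:
    """Noise-free 28x28 stroke glyph for each class, intensity 255 strokes."""
    out = {}
    for digit, segs in _DIGIT_SEGMENTS.items():
        canvas = np.zeros((28, 28))
        for s in segs:
            canvas[_SEGMENTS[s]] = 255.0
        out[digit] = canvas
    return out


def synth_digits(cfg: SynthConfig | None = None) -> DatasetHandle:
    """Render a deterministic synthetic digit dataset.

    Samples are generated class by class in label order; pixel values are
    clipped to [0, 255] and rounded to integers, so the result is
    byte-identical across platforms for a given configuration.
    """
    cfg = cfg or SynthConfig()
    templates = digit_templates()
    rng = np.random.default_rng(cfg.seed)
    images = []
    for digit in cfg.classes:
        base = templates[digit]
        for _ in range(cfg.n_per_class):
            canvas = base
            if cfg.jitter_px:
                dy, dx = rng.integers(-cfg.jitter_px, cfg.jitter_px + 1, size=2)
                canvas = np.roll(np.roll(base, dy, axis=0), dx, axis=1)
            if cfg.noise_sd:
                canvas = canvas + rng.normal(0.0, cfg.noise_sd, size=canvas.shape)
            pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
            images.append(ImageSample(pixels, digit))
    return DatasetHandle(images, source="synthetic", meta={"config": cfg})


# ---------------------------------------------------------------------------
# Spike-train CSV dialect

def write_spike_csv(train: SpikeTrain, path) -> None:
    """One event per line `channel,time_ms`, with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# n_channels={train.n_channels}, window_ms={train.window_ms}\n")
        fh.write("channel,time_ms\n")
        for ch, t in zip(train.channels, train.times):
            fh.write(f"{int(ch)},{float(t)!r}\n")


def read_spike_csv(path) -> SpikeTrain:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"missing spike CSV header in {path}")
        meta = dict(kv.strip().split("=") for kv in header[1:].split(","))
        fh.readline()  # column names
        rows = [line.strip().split(",") for line in fh if line.strip()]
    channels = np.array([int(r[0]) for r in rows], dtype=np.intp)
    times = np.array([float(r[1]) for r in rows])
    return SpikeTrain(
        channels=channels,
        times=times,
        n_channels=int(meta["n_channels"]),
        window_ms=float(meta["window_ms"]),
    )


# ---------------------------------------------------------------------------
# Model container: .npz of flat arrays plus an embedded JSON manifest

def save_model(ens: EnsembleSNN, path, extra_meta: dict | None = None) -> None:
    manifest = {
        "format": "spikecolearn-model",
        "version": __version__,
        "T": ens.T,
        "encoder": {
            "kernel_size": ens.encoder_cfg.kernel_size,
            "pool_size": ens.encoder_cfg.pool_size,
            "method": ens.encoder_cfg.method,
            "window_ms": ens.encoder_cfg.window_ms,
        },
        **(extra_meta or {}),
    }
    arrays = {"manifest": np.array(json.dumps(manifest))}
    for t, net in enumerate(ens.clusters):
        arrays[f"W_{t}"] = net.W
        arrays[f"Winit_{t}"] = net.W_init
        arrays[f"alive_{t}"] = net.alive
    np.savez_compressed(path, **arrays)


def load_model(path) -> EnsembleSNN:
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        clusters = [
            ClusterNet(
                W=data[f"W_{t}"],
                W_init=data[f"Winit_{t}"],
                alive=data[f"alive_{t}"].astype(bool),
            )
            for t in range(manifest["T"])
        ]
    return EnsembleSNN(clusters=clusters, encoder_cfg=EncoderConfig(**manifest["encoder"]))


# ---------------------------------------------------------------------------
# Run configuration

DEFAULT_CONFIG: dict = {
    "encoder": {"kernel_size": 4, "pool_size": 2, "method": "linear", "window_ms": 100.0},
    "lif": {
        "tau_m": 10.0,
        "v_rest": -65.0,
        "v_thresh": -50.0,
        "v_reset": -70.0,
        "t_ref": 2.0,
        "dt": 0.1,
        "psc_tau": 2.0,
        "r_m": 1.0,
    },
    "stdp": {
        "a_plus": 0.2,
        "a_minus": 0.1,
        "tau_plus": 20.0,
        "tau_minus": 20.0,
        "w_min": -50.0,
        "w_max": 50.0,
        "punish_scale": 0.5,
    },
    "teacher": {"encourage_ms": 70.0, "punish_ms": 35.0, "magnitude": 1e4},
    "train": {
        "T": 15,
        "n_sub": 1000,
        "iterations": 3,
        "seed": 0,
        "max_inner_iters": 50,
        "prune_threshold": None,
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    merged = dict(defaults)
    for key, value in override.items():
        here = f"{path}{key}"
        if key not in defaults:
            hint = difflib.get_close_matches(key, defaults, n=1)
            suffix = f"; did you mean {path}{hint[0]!r}?" if hint else ""
            raise KeyError(f"unknown config key {here!r}{suffix}")
        base = defaults[key]
        if isinstance(base, dict):
            if not isinstance(value, dict):
                raise TypeError(f"config key {here!r} must be a mapping")
            merged[key] = _merge(base, value, f"{here}.")
        else:
            type_ok = isinstance(value, type(base)) or (
                isinstance(base, float) and isinstance(value, int)
            )
            if base is not None and value is not None and not type_ok:
                raise TypeError(
                    f"config key {here!r} expects {type(base).__name__}, got {type(value).__name__}"
                )
            merged[key] = value
    return merged


def load_config(path=None) -> dict:
    """Load a YAML/JSON run configuration merged over the defaults.

    Unknown keys are rejected with a nearest-key suggestion; the resolved
    configuration is echoed to the log so saved models can embed it.
    """
    override: dict = {}
    if path is not None:
        text = Path(path).read_text()
        override = yaml.safe_load(text) or {}
        if not isinstance(override, dict):
            raise TypeError(f"config file {path} must contain a mapping")
    resolved = _merge(DEFAULT_CONFIG, override)
    logger.info("resolved configuration: %s", json.dumps(resolved))
    return resolved


def build_run(config: dict) -> tuple[EncoderConfig, TrainConfig]:
    """Materialize configuration dictionaries into typed parameter objects."""
    enc = EncoderConfig(**config["encoder"])
    learn = LearnConfig(
        lif=LIFParams(**config["lif"]),
        stdp=STDPParams(**config["stdp"]),
        teacher=TeacherConfig(**config["teacher"]),
        max_inner_iters=config["train"]["max_inner_iters"],
    )
    tr = config["train"]
    train_cfg = TrainConfig(
        T=tr["T"],
        n_sub=tr["n_sub"],
        iterations=tr["iterations"],
        seed=tr["seed"],
        prune_threshold=tr["prune_threshold"],
        learn=learn,
    )
    return enc, train_cfg
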