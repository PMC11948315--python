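"""Synthetic inputs for desk-scale testing of the controller stack.

Three generators cover the data the controller's surroundings consume:

* :func:`make_blob_dataset` — K-class labeled image sets where each class
  is a Gaussian blob prototype at a distinct position and color, plus
  pixel noise.  The class signal is learnable by construction (a
  nearest-prototype classifier is perfect at zero noise and at chance at
  zero signal), which is what an end-to-end controller run needs; nothing
  about real photographs (texture, pose, illumination) is emulated.
* :func:`make_green_plant_image` — rasters with an exact, known subset of
  pixels inside the plant-green color window, for testing the masker
  against ground truth.
* :class:`ScriptedTrainer` — a TrainerPort double whose "validation loss"
  per epoch is read from a scripted table, enabling exact golden-trace
  tests of the switching logic.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import colorsys
import copy
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import MetricsReport
from .preprocess import MaskRange, PLANT_GREEN_RANGE, SplitSpec, hsv_channels, split_dataset
from .tinycnn import TinyCNN

__all__ = [
    "SyntheticDatasetSpec",
    "BlobDataset",
    "make_blob_dataset",
    "nearest_prototype_accuracy",
    "make_green_plant_image",
    "ScriptedLossTable",
    "ScenarioCoverageError",
    "ScriptedTrainer",
    "scripted_trainer",
    "make_tiny_cnn",
]


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Recipe for a blob-image classification set.

    ``signal_strength`` scales the blob's brightness above the background
    (0 makes all classes identical); ``noise_sd`` is the per-pixel
    Gaussian noise standard deviation on the 0-255 scale.
    """

    n_classes: int = 4
    n_per_class: int = 30
    image_size: int = 32
    signal_strength: float = 40.0
    noise_sd: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_per_class < 1:
            raise ValueError("need at least one image per class")
        if self.image_size < 8:
            raise ValueError("image too small to place blobs")
        if self.signal_strength < 0 or self.noise_sd < 0:
            raise ValueError("signal_strength and noise_sd must be >= 0")


@dataclass(frozen=True)
class BlobDataset:
    images: np.ndarray  # (N, H, W, 3) uint8
    labels: np.ndarray  # (N,) int
    prototypes: np.ndarray  # (K, H, W, 3) float
    spec: SyntheticDatasetSpec

    def splits(
        self, fractions: tuple[float, ...] = (0.7, 0.15, 0.15), seed: int | None = None
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Stratified split into named (images, labels) pairs."""
        seed = self.spec.seed if seed is None else seed
        spec = SplitSpec(fractions=fractions, seed=seed, stratified=True)
        parts = split_dataset(self.labels, spec)
        names = ("train", "test") if len(parts) == 2 else ("train", "val", "test")
        return {
            name: (self.images[idx], self.labels[idx])
            for name, idx in zip(names, parts)
        }


def make_blob_dataset(spec: SyntheticDatasetSpec) -> BlobDataset:
    """Generate a labeled blob-image set, reproducible from its seed."""
    rng = np.random.default_rng(spec.seed)
    size, k = spec.image_size, spec.n_classes
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    background = 40.0
    prototypes = np.empty((k, size, size, 3))
    for cls in range(k):
        angle = 2.0 * math.pi * cls / k
        cy = size / 2.0 + (size / 4.0) * math.sin(angle)
        cx = size / 2.0 + (size / 4.0) * math.cos(angle)
        sigma = size / 8.0
        blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)))
        color = np.array(colorsys.hsv_to_rgb(cls / k, 0.9, 1.0))
        prototypes[cls] = np.clip(
            background + spec.signal_strength * blob[..., None] * color, 0, 255
        )
    labels = np.repeat(np.arange(k), spec.n_per_class)
    noise = rng.normal(0.0, spec.noise_sd, size=(len(labels), size, size, 3))
    images = np.clip(prototypes[labels] + noise, 0, 255).round().astype(np.uint8)
    return BlobDataset(images=images, labels=labels, prototypes=prototypes, spec=spec)


def nearest_prototype_accuracy(dataset: BlobDataset) -> float:
    """Accuracy of classifying each image by its nearest class prototype."""
    flat = dataset.images.reshape(len(dataset.labels), -1).astype(float)
    protos = dataset.prototypes.reshape(dataset.spec.n_classes, -1)
    d2 = ((flat[:, None, :] - protos[None, :, :]) ** 2).sum(axis=2)
    return float((d2.argmin(axis=1) == dataset.labels).mean())


def _sample_outside_rgb(rng, n: int, mask_range: MaskRange) -> np.ndarray:
    lo, hi = mask_range.lower[0], mask_range.upper[0]
    # force the first channel outside its window; other channels are free
    if hi < 255:
        c0 = rng.integers(hi + 1, 256, size=n)
    else:
        c0 = rng.integers(0, lo, size=n)
    rest = rng.integers(0, 256, size=(n, 2))
    return np.column_stack([c0, rest]).astype(np.uint8)


def _inside(channels: np.ndarray, mask_range: MaskRange) -> np.ndarray:
    lower = np.asarray(mask_range.lower, dtype=float)
    upper = np.asarray(mask_range.upper, dtype=float)
    return np.all((channels >= lower) & (channels <= upper), axis=-1)


def _rejection_sample_hsv(rng, n: int, mask_range: MaskRange, want_inside: bool):
    """Draw uint8 RGB pixels that land (strictly) inside/outside the HSV
    window after the round trip through 8-bit RGB."""
    from skimage.color import hsv2rgb

    out = np.empty((0, 3), dtype=np.uint8)
    lower = np.asarray(mask_range.lower, dtype=float)
    upper = np.asarray(mask_range.upper, dtype=float)
    scale = np.array([179.0, 255.0, 255.0])
    for _ in range(200):
        if len(out) >= n:
            break
        m = max(4 * (n - len(out)), 64)
        if want_inside:
            hsv = rng.uniform(lower / scale, upper / scale, size=(m, 3))
            rgb = np.clip(hsv2rgb(hsv[None]) * 255.0, 0, 255).round()[0]
        else:
            rgb = rng.integers(0, 256, size=(m, 3)).astype(float)
        ok = _inside(hsv_channels(rgb[None].astype(np.uint8))[0], mask_range)
        if not want_inside:
            ok = ~ok
        out = np.vstack([out, rgb[ok].astype(np.uint8)])
    if len(out) < n:
        raise RuntimeError("rejection sampling failed to fill the pixel budget")
    return out[:n]


def make_green_plant_image(
    seed: int,
    green_fraction: float,
    size: int = 32,
    mask_range: MaskRange = PLANT_GREEN_RANGE,
) -> tuple[np.ndarray, np.ndarray]:
    """A raster with exactly ``round(green_fraction * size**2)`` pixels
    inside the color window, plus the exact boolean ground-truth mask."""
    if not 0.0 <= green_fraction <= 1.0:
        raise ValueError("green_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = size * size
    n_green = int(round(green_fraction * n))
    positions = rng.permutation(n)
    mask = np.zeros(n, dtype=bool)
    mask[positions[:n_green]] = True
    pixels = np.empty((n, 3), dtype=np.uint8)
    if mask_range.colorspace == "rgb":
        lower = np.asarray(mask_range.lower)
        upper = np.asarray(mask_range.upper)
        pixels[mask] = rng.integers(lower, upper + 1, size=(n_green, 3))
        pixels[~mask] = _sample_outside_rgb(rng, n - n_green, mask_range)
    else:
        pixels[mask] = _rejection_sample_hsv(rng, n_green, mask_range, True)
        pixels[~mask] = _rejection_sample_hsv(rng, n - n_green, mask_range, False)
    return pixels.reshape(size, size, 3), mask.reshape(size, size)


# -- scripted trainers -----------------------------------------------------


class ScenarioCoverageError(KeyError):
    """A scripted run consulted a (activation, epoch) cell that the table
    does not cover."""


@dataclass(frozen=True)
class ScriptedLossTable:
    """Per-activation validation-loss columns for scripted training.

    ``columns[af][k]`` is the loss returned by the k-th training epoch
    performed under ``af`` (counting every epoch trained under that
    activation from the reference state, probes included).  When
    ``probe_losses`` is given, each value is prepended to its column —
    modeling the probe as the activation's first training epoch.  With
    ``hold_last`` a column repeats its final value once exhausted (a
    converged plateau); otherwise running past the end raises
    :class:`ScenarioCoverageError`.
    """

    columns: Mapping[str, tuple[float, ...]]
    probe_losses: Mapping[str, float] | None = None
    hold_last: bool = False

    def __post_init__(self):
        merged = {}
        for af, col in self.columns.items():
            col = tuple(float(v) for v in col)
            if self.probe_losses and af in self.probe_losses:
                col = (float(self.probe_losses[af]),) + col
            if not col:
                raise ValueError(f"empty loss column for {af!r}")
            merged[af] = col
        object.__setattr__(self, "columns", merged)
        object.__setattr__(self, "probe_losses", None)

    @property
    def afs(self) -> list[str]:
        return list(self.columns)

    def loss(self, af: str, position: int) -> float:
        if af not in self.columns:
            raise ScenarioCoverageError(f"no loss column for activation {af!r}")
        col = self.columns[af]
        if position >= len(col):
            if self.hold_last:
                return col[-1]
            raise ScenarioCoverageError(
                f"scenario exhausted: {af!r} epoch {position + 1} of {len(col)}"
            )
        return col[position]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (af, i + 1, v)
            for af, col in self.columns.items()
            for i, v in enumerate(col)
        ]
        return pd.DataFrame(rows, columns=["af", "epoch", "val_loss"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, hold_last: bool = False) -> "ScriptedLossTable":
        frame = pd.read_csv(path).sort_values(["af", "epoch"])
        columns = {
            af: tuple(sub["val_loss"]) for af, sub in frame.groupby("af", sort=False)
        }
        return cls(columns=columns, hold_last=hold_last)


class ScriptedTrainer:
    """TrainerPort double that replays losses from a scripted table.

    Each activation has a position counter (epochs consumed from its
    column); counters, the active activation and the epoch number are all
    part of the snapshot, so restore replays positions exactly and a rerun
    is bit-reproducible.
    """

    def __init__(self, table: ScriptedLossTable, active: str | None = None):
        self.table = table
        self._positions = {af: 0 for af in table.afs}
        self._active = active if active is not None else table.afs[0]
        if self._active not in table.columns:
            raise ScenarioCoverageError(f"no loss column for {self._active!r}")
        self._epoch = 0
        self._snapshots: dict[int, dict] = {}
        self._next_token = 0
        self.last_epoch_metrics: dict[str, float] = {}

    @property
    def current_epoch(self) -> int:
        return self._epoch

    @property
    def active_activation(self) -> str:
        return self._active

    def set_activation(self, name: str) -> None:
        if name not in self.table.columns:
            raise ScenarioCoverageError(f"no loss column for {name!r}")
        self._active = name

    def train_one_epoch(self) -> float:
        loss = self.table.loss(self._active, self._positions[self._active])
        self._positions[self._active] += 1
        self._epoch += 1
        self.last_epoch_metrics = {"val_loss": loss}
        return loss

    def evaluate(self, split: str = "test") -> MetricsReport:
        nan = float("nan")
        return MetricsReport(nan, nan, nan, nan, loss=nan)

    def snapshot(self) -> int:
        token = self._next_token
        self._next_token += 1
        self._snapshots[token] = {
            "positions": dict(self._positions),
            "active": self._active,
            "epoch": self._epoch,
        }
        return token

    def restore(self, token: int) -> None:
        snap = self._snapshots[token]
        self._positions = dict(snap["positions"])
        self._active = snap["active"]
        self._epoch = snap["epoch"]


def scripted_trainer(
    table: ScriptedLossTable | Mapping[str, Sequence[float]], **kwargs
) -> ScriptedTrainer:
    """Build a :class:`ScriptedTrainer`, accepting a bare column mapping."""
    if not isinstance(table, ScriptedLossTable):
        table = ScriptedLossTable(columns=table, **kwargs)
        kwargs = {}
    return ScriptedTrainer(table, **kwargs)


def make_tiny_cnn(
    n_classes: int = 4,
    seed: int = 0,
    dataset: BlobDataset | None = None,
    fractions: tuple[float, ...] = (0.7, 0.15, 0.15),
    **cnn_kwargs,
) -> TinyCNN:
    """A TrainerPort-conformant small CNN on a blob dataset.

    With no dataset given, generates the default blob set for ``n_classes``
    from ``seed`` and splits it 70/15/15 stratified.  Deterministic:
    identical arguments give bit-identical trainers.
    """
    if dataset is None:
        dataset = make_blob_dataset(SyntheticDatasetSpec(n_classes=n_classes, seed=seed))
    elif dataset.spec.n_classes != n_classes:
        raise ValueError("dataset class count does not match n_classes")
    data = dataset.splits(fractions=fractions, seed=seed)
    if "val" not in data:
        data["val"] = data["test"]
    return TinyCNN(data=data, n_classes=n_classes, seed=seed, **cnn_kwargs)
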