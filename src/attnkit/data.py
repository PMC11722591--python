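"""Seeded generator of small noisy-label image datasets.

The generator emulates the operative property of noisy-label medical image
collections (pathology slides, X-rays): distinct classes that share visual
patterns, with annotation errors concentrated between the similar classes.
Classes are grouped into pairs; each class has its own oriented-grating
texture plus a shared pair pattern (a second grating and a Gaussian blob)
mixed in with weight ``similarity``.  Labels are then flipped *within* each
pair at rate ``noise_rate`` — asymmetric flips between lookalike classes,
exactly the regime that degrades ordinary training.

Everything is derived from the config seed; images are quantized to uint8
before the final float conversion, so a fixed seed yields byte-identical
datasets across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SyntheticConfig", "LabeledSet", "make_dataset"]


@dataclass
class SyntheticConfig:
    """Conditions of one synthetic dataset.

    - ``similarity`` in [0, 1): weight of the shared pair pattern (0 = fully
      distinct classes, near 1 = near-identical pair members).
    - ``noise_rate`` in [0, 0.5): fraction of each pair member's labels
      flipped to its partner class; exactly ``round(noise_rate *
      n_per_class)`` flips per member.
    """

    n_classes: int = 4
    n_per_class: int = 60
    image_size: int = 32
    similarity: float = 0.0
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.image_size < 1:
            raise ValueError("image_size must be >= 1")
        if not (0.0 <= self.similarity < 1.0):
            raise ValueError("similarity must lie in [0, 1)")
        if not (0.0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must lie in [0, 0.5)")


@dataclass
class LabeledSet:
    """Images (N, H, W, 1) in [0, 1] with observed and true labels."""

    images: np.ndarray
    observed_labels: np.ndarray
    true_labels: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.images)
        if len(self.observed_labels) != n or len(self.true_labels) != n:
            raise ValueError("label arrays must match the number of images")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def flipped(self) -> np.ndarray:
        return self.observed_labels != self.true_labels


def _class_pattern(c: int, n_classes: int, size: int) -> np.ndarray:
    """Class-specific oriented grating on the integer pixel grid."""
    ii, jj = np.mgrid[0:size, 0:size].astype(np.float64)
    theta = np.pi * c / n_classes
    freq = 2.0 + (c % 3)
    phase = 2 * np.pi * freq * (np.cos(theta) * ii + np.sin(theta) * jj) / size
    return 0.5 + 0.5 * np.sin(phase)


def _pair_pattern(pair: int, n_pairs: int, size: int) -> np.ndarray:
    """Pattern shared by both members of a pair: blob + diagonal grating."""
    ii, jj = np.mgrid[0:size, 0:size].astype(np.float64)
    # blob center cycles through image quadrants with the pair index
    cy = size * (0.3 + 0.4 * ((pair + 1) % 2))
    cx = size * (0.3 + 0.4 * ((pair // 2) % 2))
    blob = np.exp(-(((ii - cy) ** 2 + (jj - cx) ** 2) / (2 * (size / 5.0) ** 2)))
    theta = np.pi * (pair + 0.5) / max(n_pairs, 1)
    grating = 0.5 + 0.5 * np.sin(
        2 * np.pi * 3.0 * (np.cos(theta) * ii - np.sin(theta) * jj) / size
    )
    return 0.6 * blob + 0.4 * grating


def make_dataset(cfg: SyntheticConfig) -> LabeledSet:
    """Generate a labeled set under the config's conditions.

    Per sample, the class texture is jittered (random phase roll, amplitude
    scale and pixel noise) so members of a class vary; the shared pair
    pattern is mixed in with weight ``similarity``; finally labels are
    flipped between pair members at the configured rate.
    """
    rng = np.random.default_rng(cfg.seed)
    s, size = cfg.similarity, cfg.image_size
    n_pairs = cfg.n_classes // 2
    images = []
    true_labels = []
    for c in range(cfg.n_classes):
        base = _class_pattern(c, cfg.n_classes, size)
        pair = c // 2
        shared = (
            _pair_pattern(pair, n_pairs, size)
            if pair < n_pairs or cfg.n_classes % 2 == 0
            else np.zeros((size, size))
        )
        for _ in range(cfg.n_per_class):
            dy, dx = rng.integers(0, size, size=2)
            jittered = np.roll(np.roll(base, dy, axis=0), dx, axis=1)
            amp = rng.uniform(0.7, 1.0)
            img = (1.0 - s) * amp * jittered + s * shared
            img = img + rng.normal(0.0, 0.08, size=(size, size))
            img = np.clip(img, 0.0, 1.0)
            # quantize: byte-identical datasets for a fixed seed
            images.append(np.round(img * 255).astype(np.uint8))
            true_labels.append(c)
    images = np.stack(images).astype(np.float64)[..., None] / 255.0
    true_labels = np.asarray(true_labels, dtype=np.int64)
    observed = true_labels.copy()
    n_flips = int(round(cfg.noise_rate * cfg.n_per_class))
    for pair in range(n_pairs):
        a, b = 2 * pair, 2 * pair + 1
        for src, dst in ((a, b), (b, a)):
            idx = np.flatnonzero(true_labels == src)
            chosen = rng.choice(idx, size=n_flips, replace=False)
            observed[chosen] = dst
    return LabeledSet(images, observed, true_labels)
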