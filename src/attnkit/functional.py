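"""Forward computation of the global-context / local-interaction attention
pipeline on plain NumPy arrays.

All feature maps are channels-last ``(H, W, C)``.  The pipeline:

1.  ``context_weights`` — a learned linear projection scores every spatial
    position; a spatial softmax turns the scores into a context map ``alpha``
    (non-negative, sums to 1), a lightweight stand-in for the long-range
    dependency modeling of self-attention.
2.  ``context_weighted_map`` — re-weights the input by ``alpha``; summing the
    result over space recovers the global context vector.
3.  ``global_max_descriptor`` / ``global_avg_descriptor`` — the two pooled
    channel descriptors (max over the context-weighted map, average over the
    raw map).
4.  ``select_features`` — a width-7 1-D convolution over the stacked 2xC
    descriptor block followed by SiLU selects the informative channels.
5.  ``local_interaction`` — a width-3 1-D convolution models each channel's
    interaction with its neighbours, without any dimensionality reduction.
6.  ``gate`` — sigmoid of the interaction output multiplies the input
    channelwise.

``gcli_a_forward`` composes the six steps (module A); ``gcli_b_forward``
applies them to only the first ``floor(f*C)`` channels and passes the rest
through untouched (module B, the partial attention strategy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GCLIParams",
    "GCLIConfig",
    "context_weights",
    "context_weighted_map",
    "global_max_descriptor",
    "global_avg_descriptor",
    "select_features",
    "local_interaction",
    "gate",
    "gcli_a_forward",
    "partial_split",
    "gcli_b_forward",
]


def _check_feature_map(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"feature map must be (H, W, C), got shape {x.shape}")
    if min(x.shape) < 1:
        raise ValueError("feature map axes must all be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    return x


@dataclass
class GCLIParams:
    """Learnable weights of one module: context projection (with bias), the
    2x7 selection kernel and the length-3 interaction kernel (both bias-free)."""

    wk: np.ndarray  # (C,)
    bias: float
    k7: np.ndarray  # (2, selection_kernel)
    k3: np.ndarray  # (interaction_kernel,)

    def num_params(self) -> int:
        return self.wk.size + 1 + self.k7.size + self.k3.size

    @classmethod
    def init(
        cls, channels: int, rng: np.random.Generator,
        selection_kernel: int = 7, interaction_kernel: int = 3,
    ) -> "GCLIParams":
        """Uniform init in [-b, b] with b = 1/sqrt(fan-in) per parameter group."""
        b_wk = 1.0 / np.sqrt(channels)
        b_k7 = 1.0 / np.sqrt(2 * selection_kernel)
        b_k3 = 1.0 / np.sqrt(interaction_kernel)
        return cls(
            wk=rng.uniform(-b_wk, b_wk, size=channels),
            bias=float(rng.uniform(-b_wk, b_wk)),
            k7=rng.uniform(-b_k7, b_k7, size=(2, selection_kernel)),
            k3=rng.uniform(-b_k3, b_k3, size=interaction_kernel),
        )


@dataclass
class GCLIConfig:
    """Configuration axes of the module family.

    ``fraction`` is the share of channels routed through the attention
    computation (1 = module A, 0.5 / 0.25 = the partial-attention variants);
    ``pooling_gc`` pools the context-weighted branch (max by default),
    ``pooling_plain`` pools the conventional branch (avg by default).
    """

    fraction: float = 1.0
    pooling_gc: str = "max"
    pooling_plain: str = "avg"
    selection_kernel: int = 7
    interaction_kernel: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must lie in (0, 1]")
        if self.pooling_gc not in ("max", "avg"):
            raise ValueError("pooling_gc must be 'max' or 'avg'")
        if self.pooling_plain not in ("avg", "max", "none"):
            raise ValueError("pooling_plain must be 'avg', 'max' or 'none'")
        for k in (self.selection_kernel, self.interaction_kernel):
            if k < 1 or k % 2 == 0:
                raise ValueError("kernels must be odd positive integers")


def context_weights(x: np.ndarray, wk: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Spatial softmax over per-position projection scores.

    Returns ``alpha`` of shape (H, W) with non-negative entries summing to 1.
    Computed with the max-subtraction stabilizer, so arbitrary logit scales
    stay finite.
    """
    x = _check_feature_map(x)
    wk = np.asarray(wk, dtype=np.float64)
    if wk.shape != (x.shape[2],):
        raise ValueError(f"wk length {wk.shape} does not match C={x.shape[2]}")
    logits = x @ wk + bias  # (H, W)
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def context_weighted_map(x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-position re-weighting ``alpha(i,j) * x(i,j,:)``.

    Summing the result over all positions yields the global context vector.
    """
    x = _check_feature_map(x)
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.shape != x.shape[:2]:
        raise ValueError(
            f"alpha shape {alpha.shape} does not match spatial extent {x.shape[:2]}"
        )
    return alpha[:, :, None] * x


def global_max_descriptor(m: np.ndarray) -> np.ndarray:
    """Channelwise max over all spatial positions (length-C descriptor)."""
    m = _check_feature_map(m)
    return m.max(axis=(0, 1))


def global_avg_descriptor(x: np.ndarray) -> np.ndarray:
    """Channelwise mean over all spatial positions (length-C descriptor)."""
    x = _check_feature_map(x)
    return x.mean(axis=(0, 1))


def _conv1d_same(row: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded same-length 1-D correlation along the channel axis."""
    k = kernel.size
    pad = k // 2
    padded = np.pad(row, pad)
    return np.array([padded[i : i + k] @ kernel for i in range(row.size)])


def select_features(
    f_gmp: np.ndarray, f_gap: np.ndarray, k7: np.ndarray
) -> np.ndarray:
    """Slide a 2-row kernel along the stacked (2, C) descriptor block, then SiLU.

    Zero padding keeps the output length C; there is no bias term.
    """
    f_gmp = np.asarray(f_gmp, dtype=np.float64)
    f_gap = np.asarray(f_gap, dtype=np.float64)
    if f_gmp.shape != f_gap.shape or f_gmp.ndim != 1:
        raise ValueError("descriptors must be 1-D and of equal length")
    k7 = np.asarray(k7, dtype=np.float64)
    if k7.ndim != 2 or k7.shape[0] != 2 or k7.shape[1] % 2 == 0:
        raise ValueError("selection kernel must be (2, odd_width)")
    z = _conv1d_same(f_gmp, k7[0]) + _conv1d_same(f_gap, k7[1])
    return z * _sigmoid(z)  # SiLU


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def local_interaction(f_s: np.ndarray, k3: np.ndarray) -> np.ndarray:
    """Width-3 (or any odd width) 1-D convolution along the channel axis."""
    f_s = np.asarray(f_s, dtype=np.float64)
    if f_s.ndim != 1 or f_s.size < 1:
        raise ValueError("descriptor must be a non-empty 1-D array")
    k3 = np.asarray(k3, dtype=np.float64)
    if k3.ndim != 1 or k3.size % 2 == 0:
        raise ValueError("interaction kernel must be 1-D with odd width")
    return _conv1d_same(f_s, k3)


def gate(x: np.ndarray, f_att: np.ndarray) -> np.ndarray:
    """Multiply each channel by ``sigmoid(F_att(c))``; gates lie in (0, 1)."""
    x = _check_feature_map(x)
    f_att = np.asarray(f_att, dtype=np.float64)
    if f_att.shape != (x.shape[2],):
        raise ValueError("attention descriptor length must equal C")
    return x * _sigmoid(f_att)[None, None, :]


def gcli_a_forward(
    x: np.ndarray, p: GCLIParams, cfg: GCLIConfig | None = None
) -> np.ndarray:
    """Module A: full-width composition of the six pipeline steps."""
    cfg = cfg or GCLIConfig()
    x = _check_feature_map(x)
    alpha = context_weights(x, p.wk, p.bias)
    m = context_weighted_map(x, alpha)
    if cfg.pooling_gc == "max":
        f_ctx = global_max_descriptor(m)
    else:
        f_ctx = global_avg_descriptor(m)
    if cfg.pooling_plain == "avg":
        f_plain = global_avg_descriptor(x)
    elif cfg.pooling_plain == "max":
        f_plain = global_max_descriptor(x)
    else:  # single-branch ablation: duplicate the context descriptor
        f_plain = f_ctx
    f_s = select_features(f_ctx, f_plain, p.k7)
    f_att = local_interaction(f_s, p.k3)
    return gate(x, f_att)


def partial_split(x: np.ndarray, f: float) -> tuple[np.ndarray, np.ndarray]:
    """Split channels into the interacted slice (first floor(f*C)) and the rest."""
    x = _check_feature_map(x)
    if not (0.0 < f <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    width = int(np.floor(f * x.shape[2]))
    if width < 1:
        raise ValueError("fraction too small: no channels would be interacted")
    return x[:, :, :width], x[:, :, width:]


def gcli_b_forward(x: np.ndarray, p: GCLIParams, cfg: GCLIConfig) -> np.ndarray:
    """Module B: attend to the interacted slice, pass the rest through.

    The untouched channels are copied bit-identically; the module parameters
    are sized to the interacted width, not to C.
    """
    interacted, untouched = partial_split(x, cfg.fraction)
    attended = gcli_a_forward(interacted, p, cfg)
    if untouched.shape[2] == 0:
        return attended
    return np.concatenate([attended, untouched], axis=2)
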