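"""Trainable attention modules, channels-last, built on the autodiff tensors.

Each module transforms a batched feature map ``(N, H, W, C)`` to the same
shape.  Calling a module with a plain NumPy array (batched or a single
``(H, W, C)`` map) runs the forward pass and returns a NumPy array; calling
``forward`` with a :class:`~attnkit.autodiff.Tensor` keeps the computation on
the gradient tape so modules can be trained inside a host network.

The family:

- :class:`GCLIA` — global-context softmax pooling, dual max/avg descriptors,
  a width-7 selection convolution with SiLU, a width-3 local-interaction
  convolution, sigmoid channel gating.
- :class:`GCLIB` — the partial-attention variant: only the first
  ``floor(fraction * C)`` channels are attended, the rest pass through.
- :class:`GCBlock`, :class:`ECA`, :class:`CBAM`, :class:`CA`, :class:`ECAGC`
  — the comparison baselines and the first-attempt ablation, configured for
  exact parameter parity with their published counts.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv2d_same
from .specs import ModuleSpec

__all__ = [
    "AttentionModule",
    "GCLIA",
    "GCLIB",
    "GCBlock",
    "ECA",
    "CBAM",
    "CA",
    "ECAGC",
    "build_module",
    "make_variant",
    "VARIANTS",
]

_LN_EPS = 1e-5


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    b = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-b, b, size=shape), requires_grad=True)


class AttentionModule:
    """Base class: parameter bookkeeping and the NumPy convenience call."""

    channels: int

    def _params(self) -> dict[str, Tensor]:
        return {k: v for k, v in vars(self).items() if isinstance(v, Tensor)}

    def parameters(self) -> list[Tensor]:
        return list(self._params().values())

    def num_params(self) -> int:
        """Direct enumeration of trainable scalar values."""
        return int(sum(p.data.size for p in self.parameters()))

    def set_all_zero(self) -> None:
        for p in self.parameters():
            p.data[...] = 0.0

    def forward(self, x: Tensor, trace: dict | None = None) -> Tensor:
        raise NotImplementedError

    def __call__(self, x, trace: dict | None = None):
        if isinstance(x, Tensor):
            return self.forward(x, trace)
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.ndim != 4:
            raise ValueError("expected (H, W, C) or (N, H, W, C) input")
        if x.shape[-1] != self.channels:
            raise ValueError(
                f"input has {x.shape[-1]} channels, module expects {self.channels}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("input contains non-finite values")
        out = self.forward(Tensor(x), trace).data
        return out[0] if single else out


# --------------------------------------------------------------------------
# shared differentiable building blocks


def _spatial_softmax(logits: Tensor) -> Tensor:
    """Softmax over the (H, W) axes of an (N, H, W) tensor, max-stabilized."""
    z = logits - logits.max(axis=(1, 2), keepdims=True)
    e = z.exp()
    return e / e.sum(axis=(1, 2), keepdims=True)


def _context_alpha(x: Tensor, wk: Tensor, bias: Tensor) -> Tensor:
    logits = (x * wk).sum(axis=3) + bias
    return _spatial_softmax(logits)


def _conv1d_rows(rows: Tensor, kernel: Tensor) -> Tensor:
    """Zero-padded same-length 1-D convolution of (N, L) rows with a (k,) kernel."""
    k = kernel.shape[0]
    pad = k // 2
    n_ch = rows.shape[-1]
    padded = rows.pad_last(pad, pad)
    out = None
    for j in range(k):
        term = kernel[j] * padded[:, j : j + n_ch]
        out = term if out is None else out + term
    return out


def _select_conv(f_top: Tensor, f_bot: Tensor, k7: Tensor) -> Tensor:
    """2-row selection convolution over stacked (N, L) descriptors."""
    width = k7.shape[1]
    pad = width // 2
    n_ch = f_top.shape[-1]
    top = f_top.pad_last(pad, pad)
    bot = f_bot.pad_last(pad, pad)
    out = None
    for j in range(width):
        term = k7[0, j] * top[:, j : j + n_ch] + k7[1, j] * bot[:, j : j + n_ch]
        out = term if out is None else out + term
    return out


def _gate(x: Tensor, f_att: Tensor, trace: dict | None) -> Tensor:
    g = f_att.sigmoid()
    if trace is not None:
        trace["gate"] = g.data.copy()
    n, c = g.shape
    return x * g.reshape(n, 1, 1, c)


# --------------------------------------------------------------------------
# GCLI family


class GCLIA(AttentionModule):
    """Module A: full-width global-context + local-interaction attention."""

    fraction = 1.0

    def __init__(
        self,
        channels: int,
        pooling_gc: str = "max",
        pooling_plain: str = "avg",
        selection_kernel: int = 7,
        interaction_kernel: int = 3,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        if pooling_gc not in ("max", "avg"):
            raise ValueError("pooling_gc must be 'max' or 'avg'")
        if pooling_plain not in ("avg", "max", "none"):
            raise ValueError("pooling_plain must be 'avg', 'max' or 'none'")
        self.channels = channels
        self.pooling_gc = pooling_gc
        self.pooling_plain = pooling_plain
        self.wk = _param(rng, channels, channels)
        self.bias = _param(rng, (), channels)
        self.k7 = _param(rng, (2, selection_kernel), 2 * selection_kernel)
        self.k3 = _param(rng, interaction_kernel, interaction_kernel)

    def forward(self, x: Tensor, trace: dict | None = None) -> Tensor:
        n, h, w, c = x.shape
        alpha = _context_alpha(x, self.wk, self.bias)
        if trace is not None:
            trace["alpha"] = alpha.data.copy()
        m = alpha.reshape(n, h, w, 1) * x
        if self.pooling_gc == "max":
            f_ctx = m.max(axis=(1, 2))
        else:
            f_ctx = m.mean(axis=(1, 2))
        if self.pooling_plain == "avg":
            f_plain = x.mean(axis=(1, 2))
        elif self.pooling_plain == "max":
            f_plain = x.max(axis=(1, 2))
        else:
            f_plain = f_ctx
        f_s = _select_conv(f_ctx, f_plain, self.k7).silu()
        f_att = _conv1d_rows(f_s, self.k3)
        return _gate(x, f_att, trace)


class GCLIB(AttentionModule):
    """Module B: partial attention — attend to the first floor(f*C) channels."""

    def __init__(
        self,
        channels: int,
        fraction: float = 0.5,
        rng: np.random.Generator | None = None,
        **kwargs,
    ):
        if not (0.0 < fraction <= 1.0):
            raise ValueError("fraction must lie in (0, 1]")
        width = int(np.floor(fraction * channels))
        if width < 1:
            raise ValueError("fraction too small: interacted width would be 0")
        self.channels = channels
        self.fraction = fraction
        self.interacted_width = width
        self.inner = GCLIA(width, rng=rng or np.random.default_rng(0), **kwargs)

    def parameters(self) -> list[Tensor]:
        return self.inner.parameters()

    def set_all_zero(self) -> None:
        self.inner.set_all_zero()

    def forward(self, x: Tensor, trace: dict | None = None) -> Tensor:
        w = self.interacted_width
        interacted = x[:, :, :, :w]
        attended = self.inner.forward(interacted, trace)
        if w == self.channels:
            return attended
        untouched = x[:, :, :, w:]
        return concat([attended, untouched], axis=3)


class ECAGC(AttentionModule):
    """First-attempt ablation: global context pooling, then a single
    average-pooled branch through a width-3 convolution and a sigmoid gate."""

    fraction = 1.0

    def __init__(self, channels: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.wk = _param(rng, channels, channels)
        self.bias = _param(rng, (), channels)
        self.kernel = _param(rng, k, k)

    def forward(self, x: Tensor, trace: dict | None = None) -> Tensor:
        n, h, w, c = x.shape
        alpha = _context_alpha(x, self.wk, self.bias)
        if trace is not None:
            trace["alpha"] = alpha.data.copy()
        m = alpha.reshape(n, h, w, 1) * x
        f = m.mean(axis=(1, 2))
        f_att = _conv1d_rows(f, self.kernel)
        return _gate(x, f_att, trace)


# --------------------------------------------------------------------------
# baselines


class GCBlock(AttentionModule):
    """Global-context block: softmax context vector, bottleneck channel
    transformation (conv - LayerNorm - ReLU - conv), additive fusion."""

    def __init__(self, channels: int, ratio: int = 16, rng: np.random.Generator | None = None):
        if channels % ratio != 0:
            raise ValueError(f"channels {channels} not divisible by ratio {ratio}")
        rng = rng or np.random.default_rng(0)
        cr = channels // ratio
        self.channels = channels
        self.ratio = ratio
        self.wk = _param(rng, channels, channels)
        self.bias = _param(rng, (), channels)
        self.wv1 = _param(rng, (channels, cr), channels)
        self.b1 = _param(rng, cr, channels)
        self.ln_gamma = Tensor(np.ones(cr), requires_grad=True)
        self.ln_beta = Tensor(np.zeros(cr), requires_grad=True)
        self.wv2 = _param(rng, (cr, channels), cr)
        self.b2 = _param(rng, channels, cr)

    def forward(self, x: Tensor, trace: dict | None = None) -> Tensor:
        n, h, w, c = x.shape
        alpha = _context_alpha(x, self.wk, self.bias)
        if trace is not None:
            trace["alpha"] = alpha.data.copy()
        ctx = (alpha.reshape(n, h, w, 1) * x).sum(axis=(1, 2))  # (N, C)
        y = ctx @ self.wv1 + self.b1
        mu = y.mean(axis=1, keepdims=True)
        var = ((y - mu) ** 2).mean(axis=1, keepdims=True)
        y = (y - mu) / ((var + _LN_EPS) ** 0.5) * self.ln_gamma + self.ln_beta
        z = y.relu() @ self.wv2 + self.b2
        if trace is not None:
            trace["gate"] = z.data.copy()  # additive delta, not a (0,1) gate
        return x + z.reshape(n, 1, 1, c)


class ECA(AttentionModule):
    """Efficient channel attention: GAP, width-k 1-D convolution, sigmoid."""

    def __init__(self, channels: int, k: int = 3, rng: np.random.Generator | None = None):
        if k % 2 == 0 or k < 1:
            raise ValueError("eca kernel width must be odd and positive")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.k = k
        self.kernel = _param(rng, k, k)

    def forward(self, x: Tensor, trace: dict | None = None) -> Tensor:
        f = x.mean(axis=(1, 2))
        f_att = _conv1d_rows(f, self.kernel)
        return _gate(x, f_att, trace)


class CBAM(AttentionModule):
    """Sequential channel gate (shared bias-free MLP over avg+max descriptors)
    then spatial gate (bias-free 7x7 convolution over pooled mean/max maps)."""

    def __init__(self, channels: int, ratio: int = 16, rng: np.random.Generator | None = None):
        if channels % ratio != 0:
            raise ValueError(f"channels {channels} not divisible by ratio {ratio}")
        rng = rng or np.random.default_rng(0)
        cr = channels // ratio
        self.channels = channels
        self.ratio = ratio
        self.w1 = _param(rng, (channels, cr), channels)
        self.w2 = _param(rng, (cr, channels), cr)
        self.wsp = _param(rng, (7, 7, 2, 1), 7 * 7 * 2)

    def forward(self, x: Tensor, trace: dict | None = None) -> Tensor:
        n, h, w, c = x.shape
        mlp = lambda d: (d @ self.w1).relu() @ self.w2
        g_ch = (mlp(x.mean(axis=(1, 2))) + mlp(x.max(axis=(1, 2)))).sigmoid()
        if trace is not None:
            trace["gate"] = g_ch.data.copy()
        x1 = x * g_ch.reshape(n, 1, 1, c)
        pooled = concat(
            [x1.mean(axis=3, keepdims=True), x1.max(axis=3, keepdims=True)], axis=3
        )
        g_sp = conv2d_same(pooled, self.wsp).sigmoid()
        return x1 * g_sp


class CA(AttentionModule):
    """Coordinate attention: directional (height / width) pooling, shared
    reduction with normalization and SiLU, two directional expansion gates."""

    def __init__(self, channels: int, m: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        m = m if m is not None else max(8, channels // 32)
        if m < 1:
            raise ValueError("intermediate width must be >= 1")
        self.channels = channels
        self.m = m
        self.w_red = _param(rng, (channels, m), channels)
        self.b_red = _param(rng, m, channels)
        self.bn_gamma = Tensor(np.ones(m), requires_grad=True)
        self.bn_beta = Tensor(np.zeros(m), requires_grad=True)
        self.w_h = _param(rng, (m, channels), m)
        self.b_h = _param(rng, channels, m)
        self.w_w = _param(rng, (m, channels), m)
        self.b_w = _param(rng, channels, m)

    def forward(self, x: Tensor, trace: dict | None = None) -> Tensor:
        n, h, w, c = x.shape
        xh = x.mean(axis=2)  # (N, H, C)
        xw = x.mean(axis=1)  # (N, W, C)
        y = concat([xh, xw], axis=1)  # (N, H+W, C)
        y = (y.reshape(n * (h + w), c) @ self.w_red + self.b_red).reshape(n, h + w, self.m)
        mu = y.mean(axis=(1,), keepdims=True)
        var = ((y - mu) ** 2).mean(axis=(1,), keepdims=True)
        y = (y - mu) / ((var + _LN_EPS) ** 0.5) * self.bn_gamma + self.bn_beta
        y = y.silu()
        yh = y[:, :h, :].reshape(n * h, self.m)
        yw = y[:, h:, :].reshape(n * w, self.m)
        gh = (yh @ self.w_h + self.b_h).sigmoid().reshape(n, h, 1, c)
        gw = (yw @ self.w_w + self.b_w).sigmoid().reshape(n, 1, w, c)
        if trace is not None:
            trace["gate"] = (gh.data.reshape(n, h, c).mean(axis=1)
                             * gw.data.reshape(n, w, c).mean(axis=1))
        return x * gh * gw


# --------------------------------------------------------------------------
# factory


def build_module(spec: ModuleSpec, rng: np.random.Generator | None = None) -> AttentionModule:
    """Instantiate the module a :class:`ModuleSpec` describes."""
    rng = rng or np.random.default_rng(0)
    kind, c = spec.kind, spec.channels
    if kind == "gcli-a":
        return GCLIA(
            c,
            pooling_gc=spec.opt("pooling_gc", "max"),
            pooling_plain=spec.opt("pooling_plain", "avg"),
            selection_kernel=spec.opt("selection_kernel", 7),
            interaction_kernel=spec.opt("interaction_kernel", 3),
            rng=rng,
        )
    if kind == "gcli-avg-avg":
        return GCLIA(c, pooling_gc="avg", pooling_plain="avg", rng=rng)
    if kind == "gcli-b":
        return GCLIB(
            c,
            fraction=spec.opt("fraction", 0.5),
            pooling_gc=spec.opt("pooling_gc", "max"),
            pooling_plain=spec.opt("pooling_plain", "avg"),
            selection_kernel=spec.opt("selection_kernel", 7),
            interaction_kernel=spec.opt("interaction_kernel", 3),
            rng=rng,
        )
    if kind == "eca-gc":
        return ECAGC(c, k=spec.opt("k", 3), rng=rng)
    if kind == "gc":
        return GCBlock(c, ratio=spec.opt("ratio", 16), rng=rng)
    if kind == "eca":
        return ECA(c, k=spec.opt("k", 3), rng=rng)
    if kind == "cbam":
        return CBAM(c, ratio=spec.opt("ratio", 16), rng=rng)
    if kind == "ca":
        return CA(c, m=spec.opt("m", None), rng=rng)
    raise ValueError(f"unknown module kind {kind!r}")


# ablation-lattice names -> ModuleSpec factories
VARIANTS = {
    "GC": lambda c: ModuleSpec("gc", c),
    "ECA+GC": lambda c: ModuleSpec("eca-gc", c),
    "GCLI-avg-avg": lambda c: ModuleSpec("gcli-avg-avg", c),
    "GCLI-A": lambda c: ModuleSpec("gcli-a", c),
    "GCLI-B-C4": lambda c: ModuleSpec("gcli-b", c, {"fraction": 0.25}),
    "GCLI-B-C2": lambda c: ModuleSpec("gcli-b", c, {"fraction": 0.5}),
    "ECA": lambda c: ModuleSpec("eca", c),
    "CBAM": lambda c: ModuleSpec("cbam", c),
    "CA": lambda c: ModuleSpec("ca", c),
}


def make_variant(
    name: str, channels: int, rng: np.random.Generator | None = None
) -> AttentionModule:
    """Build a configured module from its ablation-lattice name.

    Recognised names: GC, ECA+GC, GCLI-avg-avg, GCLI-A, GCLI-B-C4, GCLI-B-C2
    (plus the plain baselines ECA, CBAM, CA).  Case-insensitive.
    """
    lookup = {k.lower(): v for k, v in VARIANTS.items()}
    key = name.strip().lower()
    if key not in lookup:
        raise ValueError(f"unknown variant {name!r}; expected one of {sorted(VARIANTS)}")
    return build_module(lookup[key](channels), rng)


def variant_spec(name: str, channels: int) -> ModuleSpec:
    """The :class:`ModuleSpec` behind a variant name (for accounting)."""
    lookup = {k.lower(): v for k, v in VARIANTS.items()}
    key = name.strip().lower()
    if key not in lookup:
        raise ValueError(f"unknown variant {name!r}")
    return lookup[key](channels)
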