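"""Attaching attention modules to a host network and exporting their traces.

Hosts are modeled abstractly as ordered stages with declared output channel
widths — enough to study where attention modules sit (after every feature
extraction block, or after every neck scale of a multi-scale detector) and
what they do there, without reproducing any full published architecture.
A small configurable staged CNN (:class:`StagedCNN`) ships as the reference
host for the benchmark harness.

An :class:`InsertionPlan` carries one module per position, each sized to the
host's channel width at that position.  :func:`forward_with_trace` runs the
host with the plan attached and records every module's spatial context map
(``alpha``) and channel gate vector; :func:`export_attention_maps` writes
those records as grayscale PNGs plus a CSV of gate descriptors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .autodiff import Tensor, conv2d_same
from .modules import AttentionModule, build_module
from .specs import ModuleSpec

__all__ = [
    "InsertionPlan",
    "StagedCNN",
    "attach_to_stages",
    "attach_to_neck",
    "forward_with_trace",
    "export_attention_maps",
]


@dataclass
class InsertionPlan:
    """One attention module per (position index, channel width) pair."""

    positions: list[tuple[int, int]]
    modules: list[AttentionModule]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.modules):
            raise ValueError("one module required per position")
        for (_, width), mod in zip(self.positions, self.modules):
            if mod.channels != width:
                raise ValueError(
                    f"module sized for {mod.channels} channels attached to a "
                    f"width-{width} position"
                )

    def added_params(self) -> int:
        return sum(m.num_params() for m in self.modules)

    def module_at(self, stage: int) -> AttentionModule | None:
        for (pos, _), mod in zip(self.positions, self.modules):
            if pos == stage:
                return mod
        return None


def _make_plan(widths, spec: ModuleSpec, rng: np.random.Generator | None) -> InsertionPlan:
    rng = rng or np.random.default_rng(0)
    widths = list(widths)
    if any(w < 1 for w in widths):
        raise ValueError("stage widths must be positive")
    modules = [build_module(spec.with_channels(w), rng) for w in widths]
    return InsertionPlan(list(enumerate(widths)), modules)


def attach_to_stages(
    stage_widths, spec: ModuleSpec, rng: np.random.Generator | None = None
) -> InsertionPlan:
    """Plan one module after every extraction stage, sized to its width."""
    return _make_plan(stage_widths, spec, rng)


def attach_to_neck(
    scale_widths, spec: ModuleSpec, rng: np.random.Generator | None = None
) -> InsertionPlan:
    """Plan one module after every neck scale of a multi-scale detector.

    Structurally identical to :func:`attach_to_stages`; kept separate because
    the two placements are distinct design choices in a detection host.
    """
    return _make_plan(scale_widths, spec, rng)


class StagedCNN:
    """Reference host: per stage a same-padded 3x3 convolution, ReLU and 2x2
    average pooling; global average pooling and a linear head at the end.

    Channels-last ``(N, H, W, C)``; the spatial extent must be divisible by
    ``2 ** n_stages``.
    """

    def __init__(
        self,
        stage_widths=(8, 16),
        n_classes: int = 4,
        in_channels: int = 1,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.stage_widths = list(stage_widths)
        self.n_classes = n_classes
        self.in_channels = in_channels
        self.conv_w: list[Tensor] = []
        self.conv_b: list[Tensor] = []
        cin = in_channels
        # He-scaled weights and zero biases: keeps early gradients healthy on
        # low-contrast inputs, where uniform fan-in init stalls on a plateau
        for cout in self.stage_widths:
            fan = 3 * 3 * cin
            w = rng.normal(0.0, np.sqrt(2.0 / fan), (3, 3, cin, cout))
            self.conv_w.append(Tensor(w, requires_grad=True))
            self.conv_b.append(Tensor(np.zeros(cout), requires_grad=True))
            cin = cout
        self.head_w = Tensor(
            rng.normal(0.0, np.sqrt(1.0 / cin), (cin, n_classes)), requires_grad=True
        )
        self.head_b = Tensor(np.zeros(n_classes), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [*self.conv_w, *self.conv_b, self.head_w, self.head_b]

    @staticmethod
    def _pool2(x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial extent must be even at every pooling step")
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def forward(
        self,
        x: Tensor,
        plan: InsertionPlan | None = None,
        trace: list[dict] | None = None,
    ) -> Tensor:
        for i, (w, b) in enumerate(zip(self.conv_w, self.conv_b)):
            x = conv2d_same(x, w, b).relu()
            x = self._pool2(x)
            mod = plan.module_at(i) if plan is not None else None
            if mod is not None:
                record: dict | None = None
                if trace is not None:
                    record = {"position": i, "channels": mod.channels}
                    trace.append(record)
                x = mod.forward(x, record)
        feat = x.mean(axis=(1, 2))
        return feat @ self.head_w + self.head_b

    def __call__(self, x: np.ndarray, plan: InsertionPlan | None = None) -> np.ndarray:
        return self.forward(Tensor(np.asarray(x, dtype=np.float64)), plan).data


def forward_with_trace(
    host: StagedCNN, plan: InsertionPlan | None, x: np.ndarray
) -> tuple[np.ndarray, list[dict]]:
    """Run the host with the plan attached; return (outputs, trace records).

    Each record holds the module's position, its spatial context map
    ``alpha`` (if the module computes one) and its channel gate descriptor.
    """
    if plan is not None:
        for (pos, width) in plan.positions:
            if pos >= len(host.stage_widths) or host.stage_widths[pos] != width:
                raise ValueError(
                    f"plan position {pos} (width {width}) does not match host widths "
                    f"{host.stage_widths}"
                )
    trace: list[dict] = []
    out = host.forward(Tensor(np.asarray(x, dtype=np.float64)), plan, trace)
    return out.data, trace


def export_attention_maps(trace: list[dict], out_dir) -> list[Path]:
    """Write one grayscale PNG per recorded alpha map (sample 0, min-max
    normalized per map; a constant map renders mid-gray) and a ``gates.csv``
    with one row of gate values per module."""
    if not trace:
        raise ValueError("trace is empty: nothing to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for rec in trace:
        alpha = rec.get("alpha")
        if alpha is None:
            continue
        a = np.asarray(alpha)[0]  # first sample of the batch
        lo, hi = a.min(), a.max()
        if hi - lo < 1e-12:
            img = np.full(a.shape, 128, dtype=np.uint8)
        else:
            img = np.round((a - lo) / (hi - lo) * 255).astype(np.uint8)
        path = out_dir / f"alpha_pos{rec['position']}.png"
        Image.fromarray(img, mode="L").save(path)
        written.append(path)
    csv_path = out_dir / "gates.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["position", "channels", "gate_values"])
        for rec in trace:
            g = rec.get("gate")
            vals = "" if g is None else ";".join(
                f"{v:.6g}" for v in np.asarray(g)[0].ravel()
            )
            writer.writerow([rec["position"], rec["channels"], vals])
    written.append(csv_path)
    return written
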