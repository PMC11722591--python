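"""Declarative module specifications.

A :class:`ModuleSpec` carries everything needed to (a) instantiate an
attention module deterministically and (b) compute its parameter count in
closed form — the two must always agree, which the accounting layer checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["ModuleSpec", "KINDS"]

# canonical module kinds; aliases are resolved by the variant factory
KINDS = ("gcli-a", "gcli-b", "gcli-avg-avg", "eca-gc", "gc", "eca", "cbam", "ca")


@dataclass
class ModuleSpec:
    """Kind + channel width + configuration options of one attention module.

    Recognised options (all optional, defaults in parentheses):

    - ``fraction`` — interacted channel share for gcli-b (0.5)
    - ``pooling_gc`` / ``pooling_plain`` — branch poolings ("max" / "avg")
    - ``selection_kernel`` (7), ``interaction_kernel`` (3)
    - ``ratio`` — bottleneck reduction for gc / cbam (16)
    - ``k`` — eca kernel width (3)
    - ``m`` — ca intermediate width (max(8, C // 32))
    """

    kind: str
    channels: int
    options: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown module kind {self.kind!r}; expected one of {KINDS}")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")

    def opt(self, name: str, default):
        return self.options.get(name, default)

    def with_channels(self, channels: int) -> "ModuleSpec":
        return ModuleSpec(self.kind, channels, dict(self.options))
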