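"""Desk-scale training harness for studying attention modules under label noise.

Trains the reference staged CNN — plain, or with an attention module attached
after every stage — on a synthetic noisy-label dataset, and evaluates on a
clean held-out set drawn from the same class patterns.  The recipe is fixed
(Adam, constant learning rate, cross-entropy, per-image standardized inputs,
shuffled mini-batches) and fully determined by the seed, so two runs with the same
arguments produce identical metric histories.

This is a property harness, not a benchmark of record: it exercises
determinism and the relative behavior of modules at sizes a single CPU
handles in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .data import LabeledSet, SyntheticConfig, make_dataset
from .integration import InsertionPlan, StagedCNN, attach_to_stages
from .metrics import EvalCounts, compute_counts, confusion_matrix, macro_metrics
from .specs import ModuleSpec

__all__ = ["SmokeResult", "smoke_train", "cross_entropy"]

# offset separating the test-set stream from the training stream; any fixed
# value below 2**30 works, it only has to differ from the train seed
_TEST_SEED_OFFSET = 690_001


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of (N, K) logits against integer labels."""
    n = logits.shape[0]
    m = logits.max(axis=1, keepdims=True)
    z = logits - m
    lse = z.exp().sum(axis=1, keepdims=True).log()
    picked = z[np.arange(n), np.asarray(labels, dtype=np.int64)]
    return (lse.reshape(n) - picked).mean()


@dataclass
class SmokeResult:
    """Outcome of one smoke-training run."""

    loss_history: list[float]
    metrics: dict[str, float]
    counts: EvalCounts
    confusion: np.ndarray
    diverged: bool = False
    added_params: int = 0


def _standardize(images: np.ndarray) -> np.ndarray:
    """Per-image zero-mean / unit-variance normalization."""
    m = images.mean(axis=(1, 2, 3), keepdims=True)
    s = images.std(axis=(1, 2, 3), keepdims=True) + 1e-6
    return (images - m) / s


def _predict(host: StagedCNN, plan: InsertionPlan | None, images: np.ndarray,
             batch: int = 64) -> np.ndarray:
    preds = []
    for i in range(0, len(images), batch):
        logits = host.forward(Tensor(_standardize(images[i : i + batch])), plan).data
        preds.append(logits.argmax(axis=1))
    return np.concatenate(preds)


class _Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - 0.9**self.t
        b2c = 1.0 - 0.999**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= 0.9
            m += 0.1 * g
            v *= 0.999
            v += 0.001 * g * g
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + 1e-8)


def smoke_train(
    module_spec: ModuleSpec | None,
    cfg: SyntheticConfig,
    epochs: int = 15,
    seed: int = 0,
    stage_widths=(8, 16),
    batch_size: int = 16,
    lr: float = 0.02,
    n_test_per_class: int | None = None,
) -> SmokeResult:
    """Train on the noisy set, evaluate on a clean set; deterministic in seed.

    ``module_spec`` selects the attention module attached after every stage
    (None = plain host).  The test set reuses the generator conditions with
    noise removed, so evaluation measures recovery of the true classes.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    train = make_dataset(cfg)
    test_cfg = SyntheticConfig(
        n_classes=cfg.n_classes,
        n_per_class=n_test_per_class or cfg.n_per_class,
        image_size=cfg.image_size,
        similarity=cfg.similarity,
        noise_rate=0.0,
        seed=cfg.seed + _TEST_SEED_OFFSET,
    )
    test = make_dataset(test_cfg)

    rng = np.random.default_rng(seed)
    host = StagedCNN(stage_widths, n_classes=cfg.n_classes, in_channels=1,
                     seed=int(rng.integers(0, 2**31 - 1)))
    plan = None
    added = 0
    if module_spec is not None:
        plan = attach_to_stages(stage_widths, module_spec, rng)
        added = plan.added_params()
    params = host.parameters() + (
        [p for m in plan.modules for p in m.parameters()] if plan else []
    )
    opt = _Adam(params, lr)

    losses: list[float] = []
    n = len(train)
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            x = Tensor(_standardize(train.images[idx]))
            loss = cross_entropy(host.forward(x, plan), train.observed_labels[idx])
            if not np.isfinite(loss.data):
                return SmokeResult(losses, {}, None, None, diverged=True,
                                   added_params=added)
            for p in params:
                p.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / n_batches)

    preds = _predict(host, plan, test.images)
    counts = compute_counts(preds, test.true_labels, cfg.n_classes)
    return SmokeResult(
        loss_history=losses,
        metrics=macro_metrics(counts),
        counts=counts,
        confusion=confusion_matrix(preds, test.true_labels, cfg.n_classes),
        added_params=added,
    )
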