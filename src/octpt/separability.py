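"""Automatic separability experiment.

An external preset classifier is trained on *original* images only (60/20/20
balanced train/validation/test split, weights taken from the epoch with the
lowest validation loss).  Converted images are then classified: if they are
assigned their *target* preset rather than their source preset, the
translation carries the target's visual features.  Accuracy is
(TP+TN)/(TP+TN+FP+FN) with positives defined as the target class of the model
under test; in the synthetic test there are no true negatives or false
positives by construction, so specificity is not computable.

The default backbone is a small 3-stage convolutional network trained with
Adam on this package's autodiff engine — the experiment's logic, not the
backbone capacity, is what is under test at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import Tensor, Module, Conv2d, Linear, Adam
from .nn.autograd import set_default_dtype, get_default_dtype
from .nn.functional import global_mean_pool
from .phantom import BScanImage

__all__ = ["SplitSpec", "SeparabilityReport", "split_sizes", "split_dataset",
           "accuracy", "ClassifierConfig", "PresetClassifier",
           "ClassifierResults", "synthetic_separability_test"]


# --------------------------------------------------------------------------
# dataset splitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    train_frac: float = 0.6
    val_frac: float = 0.2
    test_frac: float = 0.2
    seed: int = 0
    balance_by: str = "preset"

    def __post_init__(self):
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")


def split_sizes(n: int, spec: SplitSpec | None = None) -> tuple[int, int, int]:
    """(train, val, test) sizes: val and test take the floor of their
    fractions, the remainder goes to train.  Deterministic in n alone."""
    spec = spec or SplitSpec()
    if n < 5:
        raise ValueError("need at least 5 items for non-empty splits")
    val = int(np.floor(spec.val_frac * n))
    test = int(np.floor(spec.test_frac * n))
    train = n - val - test
    if min(train, val, test) < 1:
        raise ValueError(f"n={n} too small for non-empty splits")
    return train, val, test


def split_dataset(n: int, spec: SplitSpec | None = None,
                  labels=None) -> dict[str, np.ndarray]:
    """Random membership under ``spec.seed``; sizes depend only on ``n``.

    With ``labels``, classes are balanced within each split to within one
    image: each class contributes its proportional share, remainders assigned
    largest-fraction-first.
    """
    spec = spec or SplitSpec()
    train_n, val_n, test_n = split_sizes(n, spec)
    rng = np.random.default_rng(spec.seed)
    if labels is None:
        perm = rng.permutation(n)
        return {"train": np.sort(perm[:train_n]),
                "val": np.sort(perm[train_n:train_n + val_n]),
                "test": np.sort(perm[train_n + val_n:])}
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels length must equal n")
    classes = sorted(set(labels.tolist()))
    remaining = {"train": train_n, "val": val_n, "test": test_n}
    out = {k: [] for k in remaining}
    class_indices = {c: rng.permutation(np.flatnonzero(labels == c))
                     for c in classes}
    # proportional allocation per class, largest remainder first
    alloc = {k: {} for k in remaining}
    for split, size in remaining.items():
        exact = {c: size * len(class_indices[c]) / n for c in classes}
        base = {c: int(np.floor(exact[c])) for c in classes}
        short = size - sum(base.values())
        order = sorted(classes, key=lambda c: exact[c] - base[c], reverse=True)
        for c in order[:short]:
            base[c] += 1
        alloc[split] = base
    for c in classes:
        idx = class_indices[c]
        pos = 0
        for split in ("train", "val", "test"):
            take = alloc[split][c]
            out[split].extend(idx[pos:pos + take].tolist())
            pos += take
    return {k: np.sort(np.asarray(v, dtype=int)) for k, v in out.items()}


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion counts sum to zero")
    return (tp + tn) / total


# --------------------------------------------------------------------------
# classifier (Model / Results)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    epochs: int = 40
    batch_size: int = 16
    lr: float = 2e-3
    width: int = 8
    seed: int = 0
    backbone: str = "small_cnn"  # only conv backbone available in-engine

    def __post_init__(self):
        if self.backbone != "small_cnn":
            raise ValueError(
                "only the reduced 'small_cnn' backbone is available; larger "
                "dense backbones require an external deep-learning framework")


class _SmallCNN(Module):
    """3 stride-2 conv stages -> global mean pool -> linear logits (2)."""

    def __init__(self, width: int, rng: np.random.Generator):
        w = width
        self.conv1 = Conv2d(1, w, 3, stride=2, padding=1, rng=rng)
        self.conv2 = Conv2d(w, 2 * w, 3, stride=2, padding=1, rng=rng)
        self.conv3 = Conv2d(2 * w, 4 * w, 3, stride=2, padding=1, rng=rng)
        self.fc = Linear(4 * w, 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(x * 2.0 - 1.0).leaky_relu(0.1)
        h = self.conv2(h).leaky_relu(0.1)
        h = self.conv3(h).leaky_relu(0.1)
        return self.fc(global_mean_pool(h))


def _ce_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    lse = logits.logsumexp(axis=1)
    picked = logits[np.arange(len(labels)), labels]
    return (lse - picked).mean()


def _normalize(px: np.ndarray) -> np.ndarray:
    lo, hi = px.min(), px.max()
    return (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)


class PresetClassifier:
    """Binary preset classifier built from images + preset labels."""

    def __init__(self, images: list[BScanImage], labels=None,
                 config: ClassifierConfig | None = None):
        if labels is None:
            labels = [img.preset for img in images]
        self.class_names = sorted(set(labels))
        if len(self.class_names) != 2:
            raise ValueError(f"need exactly 2 classes, got {self.class_names}")
        self.config = config or ClassifierConfig()
        # per-image min-max normalisation to [0, 1]
        self.X = np.stack([_normalize(img.pixels) for img in images])[:, None]
        self.y = np.asarray([self.class_names.index(l) for l in labels])

    def fit(self, split: dict[str, np.ndarray] | None = None,
            split_spec: SplitSpec | None = None) -> "ClassifierResults":
        cfg = self.config
        if split is None:
            split = split_dataset(len(self.y),
                                  split_spec or SplitSpec(seed=cfg.seed),
                                  labels=self.y)
        for part in ("train", "val"):
            if len(set(self.y[split[part]].tolist())) < 2:
                raise ValueError(f"{part} split contains a single class")
        prev = get_default_dtype()
        set_default_dtype(np.float32)
        try:
            return self._fit(split)
        finally:
            set_default_dtype(prev)

    def _fit(self, split):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        net = _SmallCNN(cfg.width, rng)
        opt = Adam(net.parameters(), lr=cfg.lr, beta1=0.9, beta2=0.999)
        tr, va = split["train"], split["val"]
        curves = []
        best = (np.inf, None, -1)
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(len(tr))
            tr_loss, tr_correct = 0.0, 0
            for start in range(0, len(tr), cfg.batch_size):
                idx = tr[order[start:start + cfg.batch_size]]
                # horizontal-flip augmentation only
                xb = self.X[idx].copy()
                flip = rng.random(len(idx)) < 0.5
                xb[flip] = xb[flip, :, :, ::-1]
                logits = net(Tensor(xb))
                loss = _ce_loss(logits, self.y[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                tr_loss += loss.item() * len(idx)
                tr_correct += int((logits.data.argmax(1) == self.y[idx]).sum())
            val_logits = net(Tensor(self.X[va]))
            val_loss = _ce_loss(val_logits, self.y[va]).item()
            val_acc = float((val_logits.data.argmax(1) == self.y[va]).mean())
            curves.append({"epoch": epoch, "train_loss": tr_loss / len(tr),
                           "val_loss": val_loss,
                           "train_acc": tr_correct / len(tr),
                           "val_acc": val_acc})
            if val_loss < best[0]:
                best = (val_loss, net.state_dict(), epoch)
        net.load_state_dict(best[1])
        return ClassifierResults(model=self, net=net,
                                 curves=pd.DataFrame(curves),
                                 best_epoch=best[2], split=split)


@dataclass
class ClassifierResults:
    model: PresetClassifier
    net: _SmallCNN
    curves: pd.DataFrame
    best_epoch: int
    split: dict[str, np.ndarray]

    def predict(self, images: list[BScanImage]) -> list[str]:
        X = np.stack([_normalize(img.pixels) for img in images])[:, None]
        logits = self.net(Tensor(X.astype(np.float32)))
        return [self.model.class_names[i] for i in logits.data.argmax(1)]

    def evaluate_split(self, part: str) -> float:
        idx = self.split[part]
        X = Tensor(self.model.X[idx].astype(np.float32))
        pred = self.net(X).data.argmax(1)
        return float((pred == self.model.y[idx]).mean())

    def summary(self) -> str:
        accs = {p: self.evaluate_split(p) for p in ("train", "val", "test")}
        return "\n".join([
            "Preset classifier results",
            "=" * 34,
            f"classes:       {self.model.class_names}",
            f"best epoch:    {self.best_epoch} (lowest validation loss)",
            f"parameters:    {self.net.n_parameters()}",
            "accuracy:      " + "  ".join(f"{p}={a:.3f}"
                                          for p, a in accs.items()),
        ])


# --------------------------------------------------------------------------
# synthetic separability test
# --------------------------------------------------------------------------

@dataclass
class SeparabilityReport:
    target_preset: str
    tp: int
    fn: int
    n: int
    accuracy: float
    note: str = ("positives are images of the target class; the synthetic "
                 "test has no true negatives or false positives, so "
                 "specificity is not computable")

    @property
    def counts(self) -> dict[str, int]:
        return {"TP": self.tp, "TN": 0, "FP": 0, "FN": self.fn}


def synthetic_separability_test(classifier: ClassifierResults,
                                synthetic_images: list[BScanImage],
                                target_preset: str) -> SeparabilityReport:
    """Classify converted images with a classifier trained on originals and
    report the fraction assigned to their target preset."""
    if not synthetic_images:
        raise ValueError("synthetic image set is empty")
    if target_preset not in classifier.model.class_names:
        raise ValueError(f"unknown target preset {target_preset!r}")
    preds = classifier.predict(synthetic_images)
    tp = sum(p == target_preset for p in preds)
    fn = len(preds) - tp
    return SeparabilityReport(target_preset=target_preset, tp=tp, fn=fn,
                              n=len(preds),
                              accuracy=accuracy(tp, 0, 0, fn))
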