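"""Spectrogram-image CNN: architecture, training protocol, evaluation.

The classifier distinguishes rumble from noise snippets rendered as
232 × 115 RGB spectrogram images.  Three networks are trained per study:
S-CNN on seismic images, I-CNN on infrasound images and C-CNN on the union
of both training splits; each is evaluated on both held-out test sets,
giving six confusion matrices (within-domain and cross-domain).

Architecture (fixed): three convolutional blocks — 2×Conv(32, 5×5),
2×Conv(64, 3×3), 2×Conv(128, 5×5) — each followed by 2×2 max-pooling and
25 % dropout; then a dense layer of 128 ReLU units with 40 % dropout and a
2-class softmax head.  Training uses RMSprop (lr 5e-4, ε 1e-8), batch
size 8, sparse categorical cross-entropy, a 70/10/20 train/validation/test
split and early stopping within a 30-epoch cap.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .sigproc import (
    IMAGE_SIZE,
    SNIPPET_LENGTH,
    SnippetImage,
    bandpass_filter,
    snippet_image_from_traces,
)
from .trace import SEISMIC, Trace

logger = logging.getLogger(__name__)

LABEL_NOISE, LABEL_RUMBLE = 0, 1
CLASS_NAMES = ("noise", "rumble")


# ----------------------------------------------------------------------
# Specifications


@dataclass(frozen=True)
class ModelSpec:
    """Layer plan of the rumble/noise CNN (do not change lightly: the
    parameter count and evaluation protocol assume this exact sequence)."""

    input_shape: tuple[int, int, int] = (IMAGE_SIZE[1], IMAGE_SIZE[0], 3)
    blocks: tuple[tuple[int, int, int], ...] = (
        (2, 32, 5),  # (conv layers, filters, kernel)
        (2, 64, 3),
        (2, 128, 5),
    )
    block_dropout: float = 0.25
    dense_units: int = 128
    dense_dropout: float = 0.40
    n_classes: int = 2


def expected_parameter_count(spec: ModelSpec = ModelSpec()) -> int:
    """Closed-form trainable parameter count implied by the layer plan.

    Each conv layer contributes (k²·c_in + 1)·filters; pooling halves the
    spatial dims (floor); the dense head sees the flattened final block.
    """
    h, w, c = spec.input_shape
    total = 0
    for n_layers, filters, k in spec.blocks:
        for _ in range(n_layers):
            total += (k * k * c + 1) * filters
            c = filters
        h, w = h // 2, w // 2
    total += (h * w * c + 1) * spec.dense_units
    total += (spec.dense_units + 1) * spec.n_classes
    return total


@dataclass
class TrainConfig:
    """Optimization protocol for all classifier trainings."""

    learning_rate: float = 5e-4
    epsilon: float = 1e-8
    rho: float = 0.9
    batch_size: int = 8
    max_epochs: int = 30
    patience: int = 5
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


# ----------------------------------------------------------------------
# Dataset


@dataclass
class SnippetDataset:
    """Stacked snippet images with integer labels (0 noise / 1 rumble)."""

    images: np.ndarray  # (N, H, W, 3) float32 in [0, 1]
    labels: np.ndarray  # (N,) int64
    domain: str = "seismic"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.shape[0] != self.labels.shape[0]:
            raise ValueError("images and labels length mismatch")

    @classmethod
    def from_snippets(
        cls, snippets: Sequence[SnippetImage], domain: str | None = None
    ) -> "SnippetDataset":
        labels = []
        for s in snippets:
            if s.label not in CLASS_NAMES:
                raise ValueError(f"snippet has no class label (got {s.label!r})")
            labels.append(CLASS_NAMES.index(s.label))
        images = np.stack([s.as_float() for s in snippets])
        return cls(images, np.array(labels), domain or snippets[0].domain)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "SnippetDataset":
        return SnippetDataset(self.images[idx], self.labels[idx], self.domain)

    @staticmethod
    def concatenate(parts: Sequence["SnippetDataset"]) -> "SnippetDataset":
        return SnippetDataset(
            np.concatenate([p.images for p in parts]),
            np.concatenate([p.labels for p in parts]),
            "+".join(dict.fromkeys(p.domain for p in parts)),
        )


def dataset_from_traces(
    samples: Sequence[tuple[Sequence[Trace], int]], domain: str
) -> SnippetDataset:
    """Render (traces, label) pairs into a classifier-ready dataset."""
    snippets = [
        snippet_image_from_traces(traces, label=CLASS_NAMES[label])
        for traces, label in samples
    ]
    return SnippetDataset.from_snippets(snippets, domain)


# ----------------------------------------------------------------------
# Model


class SpectrogramCNN:
    """The rumble/noise classifier with a fit/evaluate surface.

    Thin wrapper around the :mod:`rumblekit.nn` stack that owns the seeds,
    the training history and checkpointing.
    """

    def __init__(self, spec: ModelSpec = ModelSpec(), seed: int = 0, name: str = "CNN"):
        self.spec = spec
        self.seed = seed
        self.name = name
        init_rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0]
        )
        h, w, c = spec.input_shape
        layers: list[nn.Layer] = []
        for n_layers, filters, k in spec.blocks:
            for _ in range(n_layers):
                layers.append(
                    nn.Conv2D(
                        c,
                        filters,
                        k,
                        activation="relu",
                        rng=init_rng,
                        need_input_grad=len(layers) > 0,
                    )
                )
                c = filters
            layers.append(nn.MaxPool2D())
            layers.append(nn.Dropout(spec.block_dropout, self._dropout_rng))
            h, w = h // 2, w // 2
        layers.append(nn.Flatten())
        layers.append(
            nn.Dense(h * w * c, spec.dense_units, activation="relu", rng=init_rng)
        )
        layers.append(nn.Dropout(spec.dense_dropout, self._dropout_rng))
        layers.append(nn.Dense(spec.dense_units, spec.n_classes, rng=init_rng))
        self.net = nn.Sequential(layers)
        self.history: pd.DataFrame | None = None

    # ------------------------------------------------------------------
    @property
    def n_params(self) -> int:
        return self.net.n_params

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        if images.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"input shape {images.shape[1:]} != expected {self.spec.input_shape}"
            )
        return self.net.predict_proba(images, batch_size=batch_size)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def fit(
        self,
        train: SnippetDataset,
        val: SnippetDataset,
        config: TrainConfig | None = None,
    ) -> pd.DataFrame:
        """Train with RMSprop + early stopping; returns the epoch history.

        Early stopping monitors validation loss with the configured
        patience inside the hard ``max_epochs`` cap and restores the best
        weights afterwards.
        """
        config = config or TrainConfig()
        if len(train) == 0 or len(val) == 0:
            raise ValueError("train and validation sets must be non-empty")
        opt = nn.RMSprop(config.learning_rate, config.rho, config.epsilon)
        shuffle_rng = np.random.default_rng(config.seed)
        best_loss, best_weights, best_epoch = np.inf, None, -1
        rows = []
        for epoch in range(config.max_epochs):
            order = shuffle_rng.permutation(len(train))
            losses, correct = [], 0
            for i in range(0, len(order), config.batch_size):
                idx = order[i : i + config.batch_size]
                xb, yb = train.images[idx], train.labels[idx]
                loss, dlogits = self.net.loss_and_grad(xb, yb, training=True)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"{self.name}: training diverged (non-finite loss at "
                        f"epoch {epoch + 1})"
                    )
                # recover batch predictions from the fused softmax gradient
                p = dlogits * len(yb)
                p[np.arange(len(yb)), yb] += 1.0
                correct += int((p.argmax(axis=1) == yb).sum())
                dout = dlogits
                for layer in reversed(self.net.layers):
                    dout = layer.backward(dout)
                opt.step(self.net.layers)
                losses.append(loss * len(yb))
            val_loss, val_acc = self.net.evaluate_loss_acc(val.images, val.labels)
            rows.append(
                {
                    "epoch": epoch + 1,
                    "train_loss": float(np.sum(losses) / len(train)),
                    "train_accuracy": correct / len(train),
                    "val_loss": val_loss,
                    "val_accuracy": val_acc,
                }
            )
            if val_loss < best_loss - 1e-6:
                best_loss, best_epoch = val_loss, epoch
                best_weights = self.net.get_weights()
            elif epoch - best_epoch >= config.patience:
                logger.info("%s: early stop at epoch %d", self.name, epoch + 1)
                break
        if best_weights is not None:
            self.net.set_weights(best_weights)
        self.history = pd.DataFrame(rows)
        return self.history

    def save(self, path: str | Path) -> None:
        np.savez(
            Path(path),
            **{f"w_{i}": w for i, w in enumerate(self.net.get_weights())},
        )

    def load(self, path: str | Path) -> None:
        with np.load(Path(path)) as data:
            self.net.set_weights(
                [data[f"w_{i}"] for i in range(len(data.files))]
            )


def build_model(spec: ModelSpec = ModelSpec(), seed: int = 0, name: str = "CNN") -> SpectrogramCNN:
    """Build the classifier; identical seeds give identical initial weights."""
    return SpectrogramCNN(spec, seed=seed, name=name)


# ----------------------------------------------------------------------
# Splitting, evaluation, protocol


def split_dataset(
    dataset: SnippetDataset, config: TrainConfig | None = None
) -> tuple[SnippetDataset, SnippetDataset, SnippetDataset]:
    """Stratified random 70/10/20 split; disjoint, seeded, remainder to
    train.

    Validation and test sizes are rounded on the whole dataset (so 10
    images split 7/1/2) and apportioned across classes by largest
    remainder, keeping the subsets as class-balanced as the rounding
    allows.
    """
    config = config or TrainConfig()
    classes = np.unique(dataset.labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    n_total = len(dataset)
    rng = np.random.default_rng(config.seed)

    def apportion(n_part: int) -> dict:
        quota = {
            c: n_part * (dataset.labels == c).sum() / n_total for c in classes
        }
        base = {c: int(np.floor(q)) for c, q in quota.items()}
        short = n_part - sum(base.values())
        order = sorted(classes, key=lambda c: (base[c] - quota[c], c))
        for c in order[:short]:
            base[c] += 1
        return base

    n_val = int(np.floor(config.split[1] * n_total + 0.5))
    n_test = int(np.floor(config.split[2] * n_total + 0.5))
    val_per, test_per = apportion(n_val), apportion(n_test)
    tr_idx, va_idx, te_idx = [], [], []
    for cls in classes:
        idx = np.flatnonzero(dataset.labels == cls)
        rng.shuffle(idx)
        k_te, k_va = test_per[cls], val_per[cls]
        te_idx.append(idx[:k_te])
        va_idx.append(idx[k_te : k_te + k_va])
        tr_idx.append(idx[k_te + k_va :])
    cat = lambda parts: np.sort(np.concatenate(parts))
    return (
        dataset.subset(cat(tr_idx)),
        dataset.subset(cat(va_idx)),
        dataset.subset(cat(te_idx)),
    )


@dataclass
class EvalReport:
    """Confusion matrix and accuracies for one train/test pairing."""

    confusion_matrix: np.ndarray  # rows: true class, cols: predicted
    train_domain: str
    test_domain: str

    def __post_init__(self) -> None:
        self.confusion_matrix = np.asarray(self.confusion_matrix, dtype=np.int64)
        if self.confusion_matrix.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")

    @property
    def n_test(self) -> int:
        return int(self.confusion_matrix.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion_matrix)) / self.n_test

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        out = {}
        for i, name in enumerate(CLASS_NAMES):
            row = self.confusion_matrix[i]
            out[name] = float(row[i]) / row.sum() if row.sum() else float("nan")
        return out

    def summary(self) -> str:
        cm = self.confusion_matrix
        lines = [
            f"{self.train_domain} evaluated on {self.test_domain} "
            f"(n={self.n_test})",
            f"  accuracy: {self.accuracy:.3f}",
            "             pred:noise  pred:rumble",
            f"  true:noise   {cm[0, 0]:6d}      {cm[0, 1]:6d}",
            f"  true:rumble  {cm[1, 0]:6d}      {cm[1, 1]:6d}",
        ]
        pca = self.per_class_accuracy
        lines.append(
            f"  per-class: noise {pca['noise']:.3f}, rumble {pca['rumble']:.3f}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "train_domain": self.train_domain,
            "test_domain": self.test_domain,
            "n_test": self.n_test,
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "confusion_matrix": self.confusion_matrix.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate(
    model: SpectrogramCNN, test: SnippetDataset, train_domain: str | None = None
) -> EvalReport:
    """Confusion matrix and accuracy on a labeled test set (no updates)."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    pred = model.predict(test.images)
    cm = np.zeros((2, 2), dtype=np.int64)
    np.add.at(cm, (test.labels, pred), 1)
    return EvalReport(cm, train_domain or model.name, test.domain)


@dataclass
class ProtocolResult:
    """Outcome of the three-network, two-test-set evaluation protocol."""

    reports: dict[tuple[str, str], EvalReport]
    models: dict[str, SpectrogramCNN]
    train_sizes: dict[str, int]
    histories: dict[str, pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> str:
        return "\n\n".join(
            self.reports[k].summary() for k in sorted(self.reports)
        )

    def accuracy_table(self) -> pd.DataFrame:
        rows = [
            {
                "model": k[0],
                "test_domain": k[1],
                "accuracy": r.accuracy,
                "n_test": r.n_test,
            }
            for k, r in self.reports.items()
        ]
        return pd.DataFrame(rows).sort_values(["model", "test_domain"]).reset_index(
            drop=True
        )


def run_protocol(
    seismic: SnippetDataset,
    infrasound: SnippetDataset,
    config: TrainConfig | None = None,
) -> ProtocolResult:
    """Train S-CNN, I-CNN and C-CNN and evaluate each on both test sets.

    The C-CNN trains on the union of the seismic and infrasound training
    (and validation) splits; test sets are never pooled, so the six reports
    cover every {S, I, C} × {seismic, infrasound} pairing.
    """
    config = config or TrainConfig()
    s_train, s_val, s_test = split_dataset(seismic, config)
    i_train, i_val, i_test = split_dataset(infrasound, config)
    pairs = {
        "S-CNN": (s_train, s_val),
        "I-CNN": (i_train, i_val),
        "C-CNN": (
            SnippetDataset.concatenate([s_train, i_train]),
            SnippetDataset.concatenate([s_val, i_val]),
        ),
    }
    reports: dict[tuple[str, str], EvalReport] = {}
    models: dict[str, SpectrogramCNN] = {}
    histories: dict[str, pd.DataFrame] = {}
    for name, (train, val) in pairs.items():
        model = build_model(seed=config.seed, name=name)
        histories[name] = model.fit(train, val, config)
        models[name] = model
        for test in (s_test, i_test):
            reports[(name, test.domain)] = evaluate(model, test, train_domain=name)
    return ProtocolResult(
        reports=reports,
        models=models,
        train_sizes={k: len(v[0]) for k, v in pairs.items()},
        histories=histories,
    )


# ----------------------------------------------------------------------
# Continuous scanning


def scan_continuous(
    traces: Sequence[Trace],
    model: SpectrogramCNN,
    hop: float = 2.0,
    threshold: float = 0.5,
    batch_size: int = 32,
) -> pd.DataFrame:
    """Slide 12-s windows over a continuous record and detect rumbles.

    Each window is rendered exactly like a training snippet and classified;
    runs of consecutive windows whose rumble probability exceeds the
    threshold are merged into a single detection reported at the run's
    peak-score window centre.  Returns a DataFrame with columns
    ``time_s``, ``score`` and ``n_windows`` (run length).
    """
    if hop <= 0:
        raise ValueError("hop must be positive")
    duration = traces[0].duration
    half = SNIPPET_LENGTH / 2.0
    if duration < SNIPPET_LENGTH:
        warnings.warn("trace shorter than one 12-s window; no detections")
        return pd.DataFrame(columns=["time_s", "score", "n_windows"])
    filtered = [bandpass_filter(tr) for tr in traces]
    centers = np.arange(half, duration - half + 1e-9, hop)
    images = []
    for t in centers:
        snippet_traces = [tr.slice(t - half, t + half) for tr in filtered]
        img = snippet_image_from_traces(snippet_traces)
        images.append(img.as_float())
    scores = model.predict_proba(np.stack(images), batch_size=batch_size)[
        :, LABEL_RUMBLE
    ]
    above = scores > threshold
    detections = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            k = i + int(np.argmax(scores[i : j + 1]))
            detections.append(
                {
                    "time_s": float(centers[k]),
                    "score": float(scores[k]),
                    "n_windows": j - i + 1,
                }
            )
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(detections, columns=["time_s", "score", "n_windows"])
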