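"""ACA-AMDN: atrous multi-scale DenseNet for three-class lesion typing.

A DenseNet-style classifier over {normal, benign, malignant}: dense blocks
whose layers are 3x3 atrous convolutions with the dilation rate cycling
through (1, 2, 4) — the multi-scale element — each block followed by a
squeeze-and-excitation channel-attention unit, with 1x1+pool transitions
halving channels and resolution, and a global-average-pool softmax head.

The input is a 2-channel tensor (grayscale image, lesion mask): the
upstream segmenter's output localises the lesion while the raw image keeps
its appearance; a normal case simply carries an empty mask channel.

The optimizer tunes the width knob ("hidden neurons" 5-255, mapped to the
dense growth rate g = max(4, hidden // 8)), the epoch count (5-50) and the
batch size ({2, 4, 8, 16, 32, 64}). The tuning objective is
``S2 = 1/Arcy + XY`` on a validation split, with Arcy the multiclass
accuracy and XY the malignant-vs-rest false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metrics import classification_metrics, confusion_counts
from .nn import Adam, Conv2d, Linear, Module, SqueezeExcite, Tensor

__all__ = [
    "CLASS_ORDER",
    "ClsHyperparams",
    "ClsOutput",
    "ACAAMDN",
    "build_aca_amdn",
    "train_classifier",
    "classify",
    "s2_objective",
    "s2_from_scores",
    "CLS_BATCH_CHOICES",
]

#: Fixed class order; ties in argmax break toward the earlier class.
CLASS_ORDER = ("normal", "benign", "malignant")

CLS_BATCH_CHOICES = (2, 4, 8, 16, 32, 64)

_DILATION_CYCLE = (1, 2, 4)


@dataclass(frozen=True)
class ClsHyperparams:
    hidden_neurons: int
    epochs: int
    batch_size: int

    def __post_init__(self):
        if not 5 <= self.hidden_neurons <= 255:
            raise ValueError(f"hidden_neurons={self.hidden_neurons} outside [5, 255]")
        if not 5 <= self.epochs <= 50:
            raise ValueError(f"epochs={self.epochs} outside [5, 50]")
        if self.batch_size not in CLS_BATCH_CHOICES:
            raise ValueError(
                f"batch_size={self.batch_size} not in {CLS_BATCH_CHOICES}"
            )

    @property
    def growth_rate(self) -> int:
        return max(4, self.hidden_neurons // 8)


@dataclass(frozen=True)
class ClsOutput:
    """Class probabilities (simplex over CLASS_ORDER) and the argmax label."""

    probabilities: np.ndarray
    predicted_label: str


class _DenseBlock(Module):
    def __init__(self, cin, growth, n_layers, rng):
        self.layers = []
        c = cin
        for l in range(n_layers):
            d = _DILATION_CYCLE[l % len(_DILATION_CYCLE)]
            self.layers.append(Conv2d(c, growth, 3, dilation=d, rng=rng))
            c += growth
        self.cout = c

    def __call__(self, x: Tensor) -> Tensor:
        for conv in self.layers:
            y = conv(x).relu()
            x = Tensor.concat([x, y], axis=1)
        return x


class ACAAMDN(Module):
    """Classifier network; see module docstring for the layout."""

    def __init__(self, hp: ClsHyperparams, blocks: int = 3,
                 layers_per_block: int = 4, seed: int = 0, in_channels: int = 2):
        rng = np.random.default_rng(seed)
        self.hp = hp
        g = hp.growth_rate
        self.stem = Conv2d(in_channels, 2 * g, 3, rng=rng)
        c = 2 * g
        self.blocks = []
        self.attn = []
        self.trans = []
        for b in range(blocks):
            db = _DenseBlock(c, g, layers_per_block, rng)
            self.blocks.append(db)
            c = db.cout
            self.attn.append(SqueezeExcite(c, rng=rng))
            if b < blocks - 1:
                self.trans.append(Conv2d(c, c // 2, 1, rng=rng))
                c = c // 2
        self.head = Linear(c, len(CLASS_ORDER), rng)

    def forward_logits(self, x: Tensor) -> Tensor:
        x = self.stem(x).relu().avg_pool2()
        for b, (db, se) in enumerate(zip(self.blocks, self.attn)):
            x = se(db(x))
            if b < len(self.trans):
                x = self.trans[b](x).relu().avg_pool2()
        return self.head(x.mean(axis=(2, 3)))

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward_logits(x).softmax(axis=-1)


def build_aca_amdn(hp: ClsHyperparams, blocks: int = 3, layers_per_block: int = 4,
                   seed: int = 0) -> ACAAMDN:
    """Build a freshly initialised classifier; seeded, hence reproducible."""
    return ACAAMDN(hp, blocks=blocks, layers_per_block=layers_per_block, seed=seed)


def _stack_inputs(samples) -> tuple[np.ndarray, np.ndarray]:
    """Samples of (image, mask, label) -> 2-channel batch + integer labels."""
    xs, ys = [], []
    for image, mask, label in samples:
        if label not in CLASS_ORDER:
            raise ValueError(f"unknown label {label!r}; expected one of {CLASS_ORDER}")
        xs.append(np.stack([np.asarray(image, dtype=np.float64),
                            np.asarray(mask, dtype=np.float64)]))
        ys.append(CLASS_ORDER.index(label))
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


def train_classifier(
    model: ACAAMDN,
    samples: Sequence,
    hp: ClsHyperparams,
    seed: int = 0,
    lr: float = 1e-2,
    max_epochs: int | None = None,
):
    """Train with Adam on categorical cross-entropy; returns loss/accuracy trace."""
    samples = list(samples)
    if not samples:
        raise ValueError("empty training set")
    x_all, y_all = _stack_inputs(samples)
    n = len(samples)
    rng = np.random.default_rng(seed)
    opt = Adam(model.params(), lr=lr)
    epochs = hp.epochs if max_epochs is None else min(hp.epochs, max_epochs)

    log = {"loss": [], "accuracy": [], "epochs": epochs}
    for _ in range(epochs):
        order = rng.permutation(n)
        total, correct, losses = 0, 0, []
        for s in range(int(np.ceil(n / hp.batch_size))):
            idx = order[s * hp.batch_size : (s + 1) * hp.batch_size]
            logits = model.forward_logits(Tensor(x_all[idx]))
            loss = logits.softmax_cross_entropy(y_all[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int(np.sum(np.argmax(logits.data, axis=1) == y_all[idx]))
            total += idx.size
        log["loss"].append(float(np.mean(losses)))
        log["accuracy"].append(correct / total)
    return model, log


def classify(model: ACAAMDN, image: np.ndarray, mask: np.ndarray) -> ClsOutput:
    """Probabilities over CLASS_ORDER plus the argmax label (ties -> earlier)."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    probs = model(Tensor(np.stack([image, mask])[None])).data[0]
    return ClsOutput(probabilities=probs,
                     predicted_label=CLASS_ORDER[int(np.argmax(probs))])


def predict_batch(model: ACAAMDN, samples) -> list:
    """Batched classify over (image, mask, label) or (image, mask) samples."""
    xs = []
    for s in samples:
        image, mask = s[0], s[1]
        xs.append(np.stack([np.asarray(image, dtype=np.float64),
                            np.asarray(mask, dtype=np.float64)]))
    probs = model(Tensor(np.stack(xs))).data
    return [
        ClsOutput(p, CLASS_ORDER[int(np.argmax(p))]) for p in probs
    ]


def evaluate_classifier(model: ACAAMDN, samples):
    """(multiclass accuracy, malignant-vs-rest FPR, predicted labels) on samples."""
    samples = list(samples)
    preds = [o.predicted_label for o in predict_batch(model, samples)]
    truths = [s[2] for s in samples]
    acc = float(np.mean([p == t for p, t in zip(preds, truths)]))
    c = confusion_counts(preds, truths, positive_label="malignant")
    fpr = classification_metrics(c, mode="standard").fpr
    fpr = 0.0 if np.isnan(fpr) else float(fpr)
    return acc, fpr, preds


def s2_from_scores(arcy: float, xy: float) -> float:
    """The classification tuning objective S2 = 1/Arcy + XY; sentinel at Arcy=0."""
    if arcy <= 0:
        return 1e9
    return 1.0 / arcy + xy


def fit_and_score_cls(
    hp: ClsHyperparams,
    train_samples,
    val_samples,
    seed: int,
    blocks: int = 3,
    layers_per_block: int = 4,
    max_epochs: int | None = None,
    lr: float = 1e-2,
):
    """Train a fresh classifier; return (Arcy, XY) on the validation samples."""
    model = build_aca_amdn(hp, blocks=blocks, layers_per_block=layers_per_block, seed=seed)
    try:
        train_classifier(model, train_samples, hp, seed=seed,
                         max_epochs=max_epochs, lr=lr)
    except Exception as exc:
        raise RuntimeError(f"classifier training failed for {hp}: {exc}") from exc
    acc, fpr, _ = evaluate_classifier(model, val_samples)
    return acc, fpr


def s2_objective(
    hp: ClsHyperparams,
    dataset,
    split_seed: int = 0,
    blocks: int = 3,
    layers_per_block: int = 4,
    max_epochs: int | None = None,
) -> float:
    """Hyperparameter fitness: train on an 80/20 split, return S2 on the 20%."""
    samples = list(dataset)
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(samples))
    n_val = max(1, len(samples) // 5)
    val = [samples[i] for i in order[:n_val]]
    train = [samples[i] for i in order[n_val:]]
    arcy, xy = fit_and_score_cls(
        hp, train, val, seed=split_seed, blocks=blocks,
        layers_per_block=layers_per_block, max_epochs=max_epochs,
    )
    return s2_from_scores(arcy, xy)
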