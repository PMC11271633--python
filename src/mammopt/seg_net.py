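"""ACA-ATRUNet: atrous-convolution attentive U-Net for lesion segmentation.

The architecture is a U-Net whose encoder blocks are residual multi-scale
atrous units (a parallel sum of 3x3 convolutions at several dilation rates
plus a 1x1 shortcut), whose bottleneck is a single transformer encoder
block (multi-head self-attention over flattened spatial tokens with a
learned positional embedding), and whose decoder gates every skip
connection with an additive attention gate before concatenation. The head
is a 1x1 convolution producing a single-channel logit map; a sigmoid turns
it into a per-pixel foreground probability.

Three integers are exposed to the hyperparameter optimizer: the base
channel width ("hidden neurons", 5-255), the epoch count (5-50) and the
steps per epoch (300-1000). The tuning objective is
``S1 = 1 / (Dice + Arcy)`` on a held-out validation split, where Dice is
the mean per-image overlap with the ground-truth mask and Arcy the mean
pixel accuracy; minimising S1 maximises both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import dice as dice_score
from .nn import (
    InstanceNorm2d,
    Adam,
    AttentionGate,
    Conv2d,
    LayerNorm,
    Linear,
    Module,
    MultiHeadSelfAttention,
    Tensor,
)

__all__ = [
    "SegHyperparams",
    "SegModelConfig",
    "SegOutput",
    "ACAATRUNet",
    "build_aca_atrunet",
    "train_segmenter",
    "segment",
    "s1_objective",
    "s1_from_scores",
    "SEG_TUNING_RANGES",
]

#: Printed tuning ranges for the three optimised integers.
SEG_TUNING_RANGES = {
    "hidden_neurons": (5, 255),
    "epochs": (5, 50),
    "steps_per_epoch": (300, 1000),
}


@dataclass(frozen=True)
class SegHyperparams:
    """Optimizer-tunable training knobs, each held to its tuning range."""

    hidden_neurons: int
    epochs: int
    steps_per_epoch: int

    def __post_init__(self):
        for name, (lo, hi) in SEG_TUNING_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside tuning range [{lo}, {hi}]")


@dataclass(frozen=True)
class SegModelConfig:
    """Fixed architecture knobs (not searched)."""

    levels: int = 4
    dilation_rates: tuple = (1, 2, 4)
    attention_heads: int = 4
    input_size: int = 128

    def __post_init__(self):
        if self.input_size % (2 ** self.levels):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^levels={2**self.levels}"
            )
        if any(int(d) <= 0 for d in self.dilation_rates):
            raise ValueError("dilation rates must be positive integers")


@dataclass(frozen=True)
class SegOutput:
    """Per-pixel foreground probabilities and the thresholded binary mask."""

    probability_map: np.ndarray
    binary_mask: np.ndarray
    threshold: float = 0.5


class _AtrousResBlock(Module):
    """Parallel-dilation residual unit: sum of dilated 3x3 convs + 1x1 shortcut.

    Branch weights are rescaled by 1/sqrt(#branches) so the *sum* of the
    parallel paths preserves activation variance; He init alone accounts
    only for each branch's own fan-in and lets variance grow with depth,
    which at unlucky seeds saturates the sigmoid head before training
    starts.
    """

    def __init__(self, cin, cout, rates, rng, norm: bool = True, norm_eps: float = 1e-5):
        self.branches = [Conv2d(cin, cout, 3, dilation=d, rng=rng) for d in rates]
        self.shortcut = Conv2d(cin, cout, 1, rng=rng)
        self.norm = InstanceNorm2d(cout, eps=norm_eps) if norm else None
        scale = 1.0 / np.sqrt(len(self.branches) + 1)
        for conv in (*self.branches, self.shortcut):
            conv.w.data *= scale

    def __call__(self, x: Tensor) -> Tensor:
        out = self.shortcut(x)
        for br in self.branches:
            out = out + br(x)
        if self.norm is not None:
            out = self.norm(out)
        return out.relu()


class _TransformerBlock(Module):
    """Post-norm transformer encoder block over spatial tokens.

    The norms use a widened epsilon so their gain on near-constant token
    fields is bounded: a zero image then leaks only a faint trace of the
    (small-init) positional embedding instead of being renormalised into
    O(1) spatial structure.
    """

    def __init__(self, dim, tokens, heads, rng):
        # zero-init: the embedding is learned, and an untrained network
        # then has no spatial symmetry breaker at all
        self.pos = Tensor(np.zeros((1, tokens, dim)), requires_grad=True)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.ln1 = LayerNorm(dim, eps=1e-2)
        self.fc1 = Linear(dim, 2 * dim, rng)
        self.fc2 = Linear(2 * dim, dim, rng)
        self.ln2 = LayerNorm(dim, eps=1e-2)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.pos
        x = self.ln1(x + self.attn(x))
        return self.ln2(x + self.fc2(self.fc1(x).relu()))


class ACAATRUNet(Module):
    """Segmentation network; see module docstring for the layout."""

    def __init__(self, hp: SegHyperparams, cfg: SegModelConfig, seed: int):
        rng = np.random.default_rng(seed)
        self.hp = hp
        self.cfg = cfg
        widths = [min(hp.hidden_neurons * 2 ** l, 512) for l in range(cfg.levels)]
        self.widths = widths

        self.enc = []
        cin = 1
        for w in widths:
            self.enc.append(_AtrousResBlock(cin, w, cfg.dilation_rates, rng))
            cin = w

        bott_hw = cfg.input_size // (2 ** cfg.levels)
        heads = cfg.attention_heads
        while widths[-1] % heads:
            heads //= 2
        self.bottleneck = _TransformerBlock(widths[-1], bott_hw * bott_hw, heads, rng)
        self._bott_hw = bott_hw

        self.gates = []
        self.dec = []
        up_ch = widths[-1]
        for w in reversed(widths):
            self.gates.append(AttentionGate(w, up_ch, max(2, w // 2), rng))
            self.dec.append(_AtrousResBlock(up_ch + w, w, (1,), rng, norm_eps=1e-2))
            up_ch = w
        self.head = Conv2d(widths[0], 1, 1, rng=rng)

    def forward_logits(self, x: Tensor) -> Tensor:
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = x.avg_pool2()

        N, C, H, W = x.shape
        t = x.reshape(N, C, H * W).transpose(0, 2, 1)
        t = self.bottleneck(t)
        x = t.transpose(0, 2, 1).reshape(N, C, H, W)

        for gate, block, skip in zip(self.gates, self.dec, reversed(skips)):
            x = x.upsample2()
            s = gate(skip, x)
            x = block(Tensor.concat([x, s], axis=1))
        return self.head(x)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward_logits(x).sigmoid()


def build_aca_atrunet(hp: SegHyperparams, cfg: SegModelConfig | None = None,
                      seed: int = 0) -> ACAATRUNet:
    """Build a freshly initialised network; identical seeds give identical weights."""
    return ACAATRUNet(hp, cfg or SegModelConfig(), seed)


def _as_batch(images: Sequence[np.ndarray]) -> np.ndarray:
    arr = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    return arr[:, None, :, :]  # (N, 1, H, W)


def _seg_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Compound Dice + binary cross-entropy loss on a batch."""
    bce = logits.bce_with_logits(target)
    p = logits.sigmoid()
    t = Tensor(target)
    inter = (p * t).sum()
    smooth = 1.0
    dice_l = 1.0 - (2.0 * inter + smooth) / (p.sum() + t.sum() + smooth)
    return bce + dice_l


def train_segmenter(
    model: ACAATRUNet,
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    hp: SegHyperparams,
    seed: int = 0,
    batch_size: int = 4,
    lr: float = 1e-2,
    max_epochs: int | None = None,
    max_steps_per_epoch: int | None = None,
):
    """Train with Adam on the Dice+BCE loss; returns the per-epoch loss trace.

    Each epoch runs ``min(hp.steps_per_epoch, available batches)`` optimizer
    steps over a seeded shuffle of the data. ``max_epochs`` and
    ``max_steps_per_epoch`` cap the schedule below the hyperparameter values
    (used as a reduced surrogate budget during hyperparameter search).
    """
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != len(masks):
        raise ValueError(f"unpaired data: {len(images)} images vs {len(masks)} masks")
    x_all = _as_batch(images)
    y_all = _as_batch(masks)
    n = x_all.shape[0]
    rng = np.random.default_rng(seed)
    opt = Adam(model.params(), lr=lr)

    epochs = hp.epochs if max_epochs is None else min(hp.epochs, max_epochs)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        n_batches = max(1, int(np.ceil(n / batch_size)))
        steps = min(hp.steps_per_epoch, n_batches)
        if max_steps_per_epoch is not None:
            steps = min(steps, max_steps_per_epoch)
        epoch_loss = 0.0
        for s in range(steps):
            idx = order[s * batch_size : (s + 1) * batch_size]
            if idx.size == 0:
                break
            logits = model.forward_logits(Tensor(x_all[idx]))
            loss = _seg_loss(logits, y_all[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        losses.append(epoch_loss / max(1, steps))
    return model, {"loss": losses, "epochs": epochs}


def segment(model: ACAATRUNet, image: np.ndarray, threshold: float = 0.5) -> SegOutput:
    """Run one image through the network and threshold the probability map."""
    image = np.asarray(image, dtype=np.float64)
    want = model.cfg.input_size
    if image.shape != (want, want):
        raise ValueError(f"image shape {image.shape} != model input {(want, want)}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    prob = model(Tensor(image[None, None])).data[0, 0]
    return SegOutput(
        probability_map=prob,
        binary_mask=(prob >= threshold).astype(np.uint8),
        threshold=threshold,
    )


def segment_batch(model: ACAATRUNet, images: Sequence[np.ndarray],
                  threshold: float = 0.5) -> list:
    """Vectorised :func:`segment` over a list of images."""
    probs = model(Tensor(_as_batch(images))).data[:, 0]
    return [
        SegOutput(p, (p >= threshold).astype(np.uint8), threshold) for p in probs
    ]


def evaluate_segmenter(model: ACAATRUNet, images, masks, threshold: float = 0.5):
    """Mean per-image Dice and mean pixel accuracy on paired data."""
    dices, accs = [], []
    for out, m in zip(segment_batch(model, images, threshold), masks):
        m = np.asarray(m)
        dices.append(dice_score(out.binary_mask, m))
        accs.append(float(np.mean(out.binary_mask == m)))
    return float(np.mean(dices)), float(np.mean(accs))


def s1_from_scores(dice: float, arcy: float) -> float:
    """The segmentation tuning objective S1 = 1/(Dice + Arcy); sentinel at 0."""
    total = dice + arcy
    if total <= 0:
        return 1e9
    return 1.0 / total


def fit_and_score_seg(
    hp: SegHyperparams,
    train_pairs,
    val_pairs,
    cfg: SegModelConfig,
    seed: int,
    max_epochs: int | None = None,
    max_steps_per_epoch: int | None = None,
    lr: float = 1e-2,
):
    """Train a fresh network on train_pairs; return (mean Dice, mean Arcy) on val."""
    imgs, msks = zip(*train_pairs)
    model = build_aca_atrunet(hp, cfg, seed)
    try:
        train_segmenter(
            model, imgs, msks, hp, seed=seed,
            max_epochs=max_epochs, max_steps_per_epoch=max_steps_per_epoch, lr=lr,
        )
    except Exception as exc:
        raise RuntimeError(f"segmenter training failed for {hp}: {exc}") from exc
    v_imgs, v_msks = zip(*val_pairs)
    return evaluate_segmenter(model, v_imgs, v_msks)


def s1_objective(
    hp: SegHyperparams,
    dataset,
    split_seed: int = 0,
    cfg: SegModelConfig | None = None,
    max_epochs: int | None = None,
    max_steps_per_epoch: int | None = None,
) -> float:
    """Hyperparameter fitness: train on an 80/20 split, return S1 on the 20%.

    ``dataset`` is a sequence of (image, mask) pairs. The split, weight
    initialisation and shuffling all derive from ``split_seed``.
    """
    cfg = cfg or SegModelConfig()
    pairs = list(dataset)
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(pairs))
    n_val = max(1, len(pairs) // 5)
    val = [pairs[i] for i in order[:n_val]]
    train = [pairs[i] for i in order[n_val:]]
    d, a = fit_and_score_seg(
        hp, train, val, cfg, seed=split_seed,
        max_epochs=max_epochs, max_steps_per_epoch=max_steps_per_epoch,
    )
    return s1_from_scores(d, a)
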