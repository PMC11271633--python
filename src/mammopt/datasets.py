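"""Synthetic mammogram phantoms and readers for the two public archives.

The phantom generator is the package's primary test substrate. Each sample
is a grayscale image in [0, 1] containing:

* a half-ellipse breast region against a dark exterior (chest wall at the
  left edge, as in an MLO/CC film),
* a lumpy tissue background — Poisson-random Gaussian blobs at three
  spatial scales, the standard stochastic texture stand-in for anatomical
  background in imaging phantoms,
* optionally one lesion: a smooth radially symmetric bright bump (benign)
  or a bright core with narrow radiating spicules (malignant), the classic
  mammographic malignancy sign,
* additive Gaussian pixel noise.

The ground-truth mask marks pixels where the noiseless lesion contribution
exceeds half its peak; normal samples carry an all-zero mask. Everything is
reproducible from the config seed.

The MIAS reader parses the archive's whitespace-delimited 7-field metadata
(reference, tissue character, abnormality class, severity, x, y, radius;
normal cases carry only the first three) and can rasterise the
centre+radius circle annotations into approximate masks. The CBIS-DDSM
side is a thin CSV+image adapter; neither archive is required for tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "generate_phantoms",
    "MIASRecord",
    "read_mias_metadata",
    "load_image_pairs",
    "write_manifest",
]

LABELS = ("normal", "benign", "malignant")


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters; geometry defaults scale with image size."""

    size: int = 128
    n_samples: int = 100
    class_mix: tuple = (1 / 3, 1 / 3, 1 / 3)
    lesion_radius_range: tuple | None = None  # pixels; default ~ (0.05, 0.11) * size
    contrast: float = 0.45                    # lesion peak lift over background
    spicule_count_range: tuple = (6, 12)      # malignant only
    background_blob_density: float = 0.004    # expected blobs per pixel
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {self.class_mix}")
        if self.lesion_radius_range is None:
            object.__setattr__(
                self,
                "lesion_radius_range",
                (max(3.0, 0.05 * self.size), 0.11 * self.size),
            )
        rmin, rmax = self.lesion_radius_range
        if not (0 < rmin <= rmax < self.size / 4):
            raise ValueError(
                f"lesion radii {self.lesion_radius_range} must be positive and below size/4"
            )


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray          # float64 in [0, 1]
    mask: np.ndarray           # uint8 {0, 1}
    label: str
    provenance: dict = field(default_factory=dict)


def _breast_region(size: int) -> np.ndarray:
    """Half-ellipse breast area: chest wall on the left edge."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    a, b, cy = 0.88 * size, 0.44 * size, size / 2.0
    return (xx / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _lumpy_background(size: int, density: float, region: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Clipped multiscale superposition of Gaussian blobs at Poisson centres."""
    tex = np.zeros((size, size))
    scale = size / 128.0
    for sigma, weight in ((2.0 * scale, 1.0), (4.0 * scale, 1.0), (8.0 * scale, 0.7)):
        impulses = rng.poisson(density / 3.0, size=(size, size)).astype(np.float64)
        impulses *= rng.uniform(0.5, 1.5, size=(size, size))
        blob = gaussian_filter(impulses, sigma)
        sd = blob.std()
        if sd > 0:
            tex += weight * (blob - blob.mean()) / sd
    tex = 0.45 + 0.07 * tex / max(1e-12, tex.std())
    out = np.where(region, tex, 0.02)
    return np.clip(out, 0.0, 1.0)


def _benign_profile(size: int, cx: float, cy: float, r: float,
                    amp: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    d2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / (r * r)
    return amp * np.exp(-(d2 ** 2))  # steep-edged, radially symmetric bump


def _malignant_profile(size: int, cx: float, cy: float, r: float, amp: float,
                       n_spicules: int, rng: np.random.Generator) -> np.ndarray:
    core = _benign_profile(size, cx, cy, 0.8 * r, amp)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    spikes = np.zeros((size, size))
    width = max(1.0, 0.012 * size)
    angles = rng.uniform(0, 2 * np.pi, size=n_spicules)
    lengths = rng.uniform(1.6 * r, 2.6 * r, size=n_spicules)
    for th, ln in zip(angles, lengths):
        u = dx * np.cos(th) + dy * np.sin(th)        # along the ray
        v = -dx * np.sin(th) + dy * np.cos(th)       # across the ray
        ray = np.exp(-((v / width) ** 2)) * np.exp(-((u / ln) ** 2)) * (u >= 0)
        spikes = np.maximum(spikes, 0.7 * amp * ray)
    return np.maximum(core, spikes)


def _sample_center(region: np.ndarray, margin: float,
                   rng: np.random.Generator) -> tuple[float, float]:
    """Pick a lesion centre whose margin-disc stays inside the breast region."""
    from scipy.ndimage import distance_transform_edt

    size = region.shape[0]
    dist = distance_transform_edt(region)
    ys, xs = np.nonzero(dist > margin)
    inside = (xs > margin) & (xs < size - margin) & (ys > margin) & (ys < size - margin)
    ys, xs = ys[inside], xs[inside]
    if len(xs) == 0:
        raise ValueError("breast region too small for the configured lesion radius")
    i = rng.integers(len(xs))
    return float(xs[i]), float(ys[i])


def _make_sample(label: str, cfg: PhantomConfig, seed: int) -> PhantomSample:
    rng = np.random.default_rng(seed)
    size = cfg.size
    region = _breast_region(size)
    bg = _lumpy_background(size, cfg.background_blob_density, region, rng)

    lesion = np.zeros((size, size))
    prov = {"label": label, "seed": seed, "size": size}
    if label != "normal":
        rmin, rmax = cfg.lesion_radius_range
        r = float(rng.uniform(rmin, rmax))
        margin = 2.8 * rmax
        cx, cy = _sample_center(region, margin, rng)
        if label == "benign":
            lesion = _benign_profile(size, cx, cy, r, cfg.contrast)
        else:
            n_sp = int(rng.integers(cfg.spicule_count_range[0],
                                    cfg.spicule_count_range[1] + 1))
            lesion = _malignant_profile(size, cx, cy, r, cfg.contrast, n_sp, rng)
            prov["n_spicules"] = n_sp
        prov.update(center=(cx, cy), radius=r)

    mask = (lesion > 0.5 * lesion.max()).astype(np.uint8) if lesion.max() > 0 else (
        np.zeros((size, size), dtype=np.uint8)
    )
    noise = rng.normal(0.0, cfg.noise_sd, size=(size, size))
    image = np.clip(bg + lesion + noise, 0.0, 1.0)

    if label != "normal":
        prov["lesion_mean_lift"] = float(lesion[mask.astype(bool)].mean())
        prov["background_mean"] = float(bg[region].mean())
    return PhantomSample(image=image, mask=mask, label=label, provenance=prov)


def generate_phantoms(cfg: PhantomConfig) -> list[PhantomSample]:
    """Generate the configured mixture of phantoms, fully seeded."""
    rng = np.random.default_rng(cfg.seed)
    counts = [int(round(p * cfg.n_samples)) for p in cfg.class_mix]
    while sum(counts) < cfg.n_samples:
        counts[int(np.argmax(cfg.class_mix))] += 1
    while sum(counts) > cfg.n_samples:
        counts[int(np.argmax(counts))] -= 1
    labels = [l for l, c in zip(LABELS, counts) for _ in range(c)]
    order = rng.permutation(len(labels))
    seeds = rng.integers(0, 2 ** 31 - 1, size=len(labels))
    return [
        _make_sample(labels[i], cfg, int(seeds[k])) for k, i in enumerate(order)
    ]


# ---------------------------------------------------------------------------
# MIAS archive support
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MIASRecord:
    reference: str
    tissue_character: str
    abnormality_class: str
    severity: str | None = None
    x: int | None = None
    y: int | None = None
    radius: int | None = None


def read_mias_metadata(source) -> list[MIASRecord]:
    """Parse the whitespace-delimited MIAS metadata listing.

    ``source`` may be a path or an iterable of lines. Lines carry either 3
    tokens (normal case) or 7 (abnormality with severity, centre and
    radius). Malformed lines raise with their line number; coordinates must
    lie in [0, 1024).
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)

    records = []
    for ln, raw in enumerate(lines, start=1):
        tokens = raw.split()
        if not tokens:
            continue
        if len(tokens) == 3:
            records.append(MIASRecord(*tokens))
        elif len(tokens) == 7:
            ref, tissue, abcls, sev = tokens[:4]
            try:
                x, y, r = (int(t) for t in tokens[4:])
            except ValueError as exc:
                raise ValueError(f"line {ln}: non-integer geometry fields: {raw!r}") from exc
            if not (0 <= x < 1024 and 0 <= y < 1024):
                raise ValueError(f"line {ln}: coordinates ({x}, {y}) outside [0, 1024)")
            records.append(MIASRecord(ref, tissue, abcls, sev, x, y, r))
        else:
            raise ValueError(f"line {ln}: expected 3 or 7 fields, got {len(tokens)}: {raw!r}")
    return records


def _severity_to_label(severity: str | None) -> str:
    return {"B": "benign", "M": "malignant", None: "normal"}.get(severity, "normal")


def _disc_mask(shape: tuple, x: int, y: int, radius: int,
               origin_bottom_left: bool = True) -> np.ndarray:
    h, w = shape
    row = (h - 1 - y) if origin_bottom_left else y
    yy, xx = np.ogrid[0:h, 0:w]
    return ((xx - x) ** 2 + (yy - row) ** 2 <= radius ** 2).astype(np.uint8)


def load_image_pairs(image_dir, records: Sequence[MIASRecord],
                     circle_to_mask: bool = True,
                     origin_bottom_left: bool = True,
                     extension: str = ".pgm") -> list[tuple]:
    """Load (image, mask, label) triples for MIAS-style records.

    Images are rescaled to [0, 1] by their dtype's full range. The MIAS
    circle annotations are rasterised into approximate disc masks; the
    archive's bottom-left coordinate origin is honoured by default.
    Missing files raise, naming every absent reference.
    """
    import imageio.v3 as iio

    missing = [
        r.reference for r in records
        if not os.path.exists(os.path.join(image_dir, r.reference + extension))
    ]
    if missing:
        raise FileNotFoundError(f"missing image files for references: {missing}")

    out = []
    for r in records:
        arr = np.asarray(iio.imread(os.path.join(image_dir, r.reference + extension)))
        if arr.ndim == 3:
            arr = arr.mean(axis=-1)
        denom = float(np.iinfo(arr.dtype).max) if np.issubdtype(arr.dtype, np.integer) else 1.0
        image = arr.astype(np.float64) / denom
        if circle_to_mask and r.x is not None:
            mask = _disc_mask(image.shape, r.x, r.y, r.radius, origin_bottom_left)
        else:
            mask = np.zeros(image.shape, dtype=np.uint8)
        out.append((image, mask, _severity_to_label(r.severity)))
    return out


def write_manifest(samples: Iterable[PhantomSample], outdir, seed: int) -> str:
    """Write phantom PNGs plus a manifest CSV; returns the manifest path."""
    import imageio.v3 as iio
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        pi = os.path.join(outdir, f"sample_{i:04d}.png")
        pm = os.path.join(outdir, f"sample_{i:04d}_mask.png")
        iio.imwrite(pi, (s.image * 255).astype(np.uint8))
        iio.imwrite(pm, (s.mask * 255).astype(np.uint8))
        rows.append({"sample_id": i, "label": s.label, "path_image": pi,
                     "path_mask": pm, "seed": seed})
    path = os.path.join(outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
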