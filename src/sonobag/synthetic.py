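"""Synthetic grouped-ultrasound datasets and oracle-calibrated scores.

Real abdominal ultrasound studies produce a *group* of B-mode frames per
subject: a variable number of liver views whose echotexture brightens as
hepatic fat accumulates, interleaved with frames of other organs that
carry no information about the liver. The generator here emulates
exactly that structure — variable group size, a class-graded liver
texture, and label-irrelevant distractor frames — using a first-order
multiplicative speckle model (pixel = smooth tissue template × Rayleigh
factor, clipped to [0, 1]).

Speckle is not frame-independent noise: it is determined by the tissue's
scatterer configuration, so repeated shots of the same organ reproduce
largely the same speckle pattern, decorrelated only by probe motion.
The generator therefore draws one liver speckle realization per subject
and models each liver shot as a convex mixture of that realization with
a fresh one (`motion` = the fresh fraction). This is what makes
embeddings of same-organ shots correlate far more strongly than
embeddings of different organs — the premise behind thresholding the
feature correlation graph. Distractor frames get independent templates
and realizations. No attempt is made at B-mode physics; the job is to
produce encoder-separable classes with the statistical shape the
downstream pipeline assumes.

`gen_calibrated_scores` produces i.i.d. (score vector, label) pairs in
which the label is drawn *from* the score vector, so the scores are
calibrated by construction and the samples are exchangeable — the exact
hypothesis under which split-conformal coverage is guaranteed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "SubjectRecord",
    "ScoreLabelSample",
    "gen_grouped_subjects",
    "gen_calibrated_scores",
    "write_dataset",
    "read_manifest",
]

# Subject-level brightness jitter (SD, intensity units). class_effect is
# expressed in multiples of this scale: class k mean brightness is
# BASE_BRIGHTNESS + class_effect * BRIGHTNESS_SD * (k - 1).
BASE_BRIGHTNESS = 0.35
BRIGHTNESS_SD = 0.03
BLOB_CONTRAST = 0.05


@dataclass
class SubjectRecord:
    """One subject's group of images plus its subject-level label.

    `images` is a list of (H, W) float arrays in [0, 1]; the label is an
    integer class in {1..K} shared by the whole group (individual images
    are never labelled).
    """

    subject_id: str
    images: list[np.ndarray]
    label: int
    is_distractor: list[bool] = field(default_factory=list)

    @property
    def S(self) -> int:
        return len(self.images)


@dataclass
class ScoreLabelSample:
    scores: np.ndarray  # length-K probability vector
    label: int  # in {1..K}


def _speckle(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    # Rayleigh with unit mean: scale sqrt(2/pi)
    return rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=shape)


def _blob_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean, unit-SD smooth field (coarse parenchymal blobs).

    Centred over the image so that contrast patterns the texture without
    shifting its mean level — brightness and contrast stay decoupled and
    class_effect keeps its meaning in brightness-SD units."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    f = f - f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _liver_template(
    rng: np.random.Generator, shape: tuple[int, int], label: int, class_effect: float
) -> np.ndarray:
    """The subject's liver: mean brightness and coarse-blob contrast
    increase with the class index, scaled by class_effect."""
    mean = BASE_BRIGHTNESS + class_effect * BRIGHTNESS_SD * (label - 1)
    mean += rng.normal(0.0, BRIGHTNESS_SD)
    contrast = BLOB_CONTRAST * (1.0 + 0.3 * class_effect * (label - 1))
    return np.clip(mean + contrast * _blob_field(rng, shape, sigma=min(shape) / 8), 0.0, None)


def _distractor_image(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Class-independent texture mimicking a frame of some other
    structure. Non-liver content in abdominal scans (vessels, kidney
    cortex, gallbladder) is predominantly hypoechoic relative to liver
    parenchyma, so distractors are darker, with a depth gradient."""
    h = shape[0]
    gradient = np.linspace(0.30, 0.10, h)[:, None]
    template = gradient + 0.06 * _blob_field(rng, shape, sigma=min(shape) / 5)
    return np.clip(np.clip(template, 0.0, None) * _speckle(rng, shape), 0.0, 1.0)


def gen_grouped_subjects(
    n_subjects: int,
    K: int = 2,
    size_range: tuple[int, int] = (2, 12),
    class_effect: float = 1.0,
    distractor_rate: float = 0.3,
    image_shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    motion: float = 0.05,
) -> list[SubjectRecord]:
    """Generate `n_subjects` grouped-image records.

    Each subject draws a group size S uniformly from `size_range` and a
    label uniformly from {1..K}. Each image is a liver frame — brightness
    and blob contrast increasing with the class index, scaled by
    `class_effect` (in units of the subject-level brightness SD) — or,
    with probability `distractor_rate`, a class-independent distractor.
    Liver frames of one subject share a single speckle realization,
    remixed with a fresh realization in proportion `motion` (probe-motion
    decorrelation). At least one liver frame per subject is guaranteed.
    Deterministic given `seed`.
    """
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid size_range {size_range}")
    if not 0.0 <= distractor_rate < 1.0:
        raise ValueError(f"distractor_rate must be in [0, 1), got {distractor_rate}")
    if class_effect < 0:
        raise ValueError("class_effect must be nonnegative")
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0.0 <= motion <= 1.0:
        raise ValueError("motion must be in [0, 1]")

    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        label = int(rng.integers(1, K + 1))
        S = int(rng.integers(lo, hi + 1))
        is_distractor = list(rng.random(S) < distractor_rate)
        if all(is_distractor):
            is_distractor[int(rng.integers(S))] = False
        template = _liver_template(rng, image_shape, label, class_effect)
        liver_base = template * _speckle(rng, image_shape)
        images = []
        for d in is_distractor:
            if d:
                images.append(_distractor_image(rng, image_shape))
            else:
                fresh = template * _speckle(rng, image_shape)
                images.append(
                    np.clip((1.0 - motion) * liver_base + motion * fresh, 0.0, 1.0)
                )
        subjects.append(
            SubjectRecord(
                subject_id=f"subj{i:05d}",
                images=images,
                label=label,
                is_distractor=is_distractor,
            )
        )
    return subjects


def gen_calibrated_scores(
    n: int,
    K: int = 4,
    concentration: float | np.ndarray = 1.0,
    seed: int = 0,
) -> list[ScoreLabelSample]:
    """Draw i.i.d. oracle-calibrated (scores, label) pairs.

    Scores follow a Dirichlet(concentration) law; the label is drawn
    from the categorical distribution with those scores as
    probabilities. P(label = k | scores) = scores[k], so the scores are
    perfectly calibrated and the samples are exchangeable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    conc = np.broadcast_to(np.asarray(concentration, dtype=float), (K,)).copy()
    if np.any(conc <= 0):
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    scores = rng.dirichlet(conc, size=n)
    u = rng.random(n)
    labels = 1 + (scores.cumsum(axis=1) < u[:, None]).sum(axis=1)
    labels = np.minimum(labels, K)  # guard against fp roundoff at the top
    return [ScoreLabelSample(scores=s, label=int(l)) for s, l in zip(scores, labels)]


def write_dataset(subjects: list[SubjectRecord], out_dir: str | Path) -> Path:
    """Write 8-bit grayscale PNGs plus a tab-separated manifest.

    The manifest has one row per image: subject_id, label, relative file
    path. Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["subject_id", "label", "path"])
        for rec in subjects:
            for j, img in enumerate(rec.images):
                rel = f"{rec.subject_id}_{j:03d}.png"
                arr = np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(out / rel)
                w.writerow([rec.subject_id, rec.label, rel])
    return manifest


def read_manifest(manifest_path: str | Path) -> list[SubjectRecord]:
    """Load a dataset written by :func:`write_dataset` back into records."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    groups: dict[str, SubjectRecord] = {}
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sid = row["subject_id"]
            img = np.asarray(Image.open(root / row["path"]).convert("L"), dtype=float) / 255.0
            if sid not in groups:
                groups[sid] = SubjectRecord(subject_id=sid, images=[], label=int(row["label"]))
            groups[sid].images.append(img)
    return list(groups.values())
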