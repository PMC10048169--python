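"""Synthetic micro-expression generator.

Real micro-expression corpora are licensed and cannot ship with the package,
so every stage of the pipeline is exercised on generated data: per-subject
face templates (smooth textured ellipse with brows, eyes, nose and mouth) with
consistent 68-point landmarks, and class-specific apex frames produced by
warping the template with Gaussian-weighted displacement fields anchored on
action-unit-like loci:

- Positive: lip corners pulled up and outward (AU12-like);
- Negative: inner brow ends pulled down and inward (AU4-like);
- Surprise: both brows raised and the lower lip dropped (AU1/2 + AU25-like).

Displacement magnitude and additive pixel noise are controllable, labels
follow the imbalanced Negative/Positive/Surprise composite-corpus proportions
by default, and everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .geometry import Landmarks68, save_landmarks_csv

CLASSES = ("Negative", "Positive", "Surprise")

#: Composite-corpus class imbalance (250:109:83).
DEFAULT_PROPORTIONS = (250 / 442, 109 / 442, 83 / 442)


@dataclass
class SynthConfig:
    """Generator conditions.

    displacement_px is the peak apex displacement at the warp anchors;
    noise_sd is additive Gaussian pixel noise on the 0–255 intensity scale;
    warp_sigma_frac sets the Gaussian radius of each warp as a fraction of
    the face width.
    """

    n_subjects: int = 10
    samples_per_subject: int = 30
    class_proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    displacement_px: float = 3.0
    noise_sd: float = 1.0
    image_size: tuple[int, int] = (128, 128)
    warp_sigma_frac: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.displacement_px < 0:
            raise ValueError("displacement must be non-negative")


@dataclass
class SubjectTemplate:
    subject_id: str
    image: np.ndarray               # (H, W) float in [0, 255], noise-free
    landmarks: Landmarks68


@dataclass
class MESample:
    sample_id: str
    subject_id: str
    source: str
    raw_label: str
    onset: np.ndarray
    apex: np.ndarray
    landmarks: Landmarks68


# ---------------------------------------------------------------------------
# face template
# ---------------------------------------------------------------------------

def _subject_rng(config: SynthConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, subject_index]))


def _landmark_layout(cx: float, cy: float, a: float, b: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Parametric 68-point layout on a face ellipse with half-axes (a, b)."""
    j = lambda s: rng.uniform(-s, s)  # noqa: E731 - per-subject jitter
    pts = np.zeros((68, 2))
    # jaw 0-16 along the lower half of the ellipse, chin at index 8
    t = np.pi - np.arange(17) * (np.pi / 16)
    pts[0:17, 0] = cx + a * np.cos(t)
    pts[0:17, 1] = cy + b * np.sin(t) * (1.0 + j(0.03))
    brow_y = cy - b * (0.38 + j(0.02))
    brow_arc = b * 0.03
    # left brow 17-21 (outer to inner), right brow 22-26 (inner to outer)
    lx = cx - a * np.linspace(0.62, 0.20, 5) * (1.0 + j(0.04))
    rx = cx + a * np.linspace(0.20, 0.62, 5) * (1.0 + j(0.04))
    arc = brow_arc * np.array([0.0, -0.7, -1.0, -0.7, 0.0])
    pts[17:22] = np.column_stack([lx, brow_y + arc])
    pts[22:27] = np.column_stack([rx, brow_y + arc[::-1]])
    # nose 27-35, base at 33
    nose_y0, nose_y1 = cy - b * 0.26, cy + b * (0.06 + j(0.01))
    pts[27:31] = np.column_stack([np.full(4, cx), np.linspace(nose_y0, nose_y1, 4)])
    nrow_y = cy + b * 0.12
    pts[31:36] = np.column_stack([cx + a * np.linspace(-0.12, 0.12, 5), np.full(5, nrow_y)])
    pts[33, 1] = nrow_y  # nose base
    # eyes 36-47; 36/45 outer corners, 39/42 inner corners
    eye_y = cy - b * (0.20 + j(0.01))
    ew, eh = a * 0.15, b * 0.05
    for base, ex in ((36, cx - a * 0.42), (42, cx + a * 0.42)):
        xs = [ex - ew, ex - ew / 2, ex + ew / 2, ex + ew, ex + ew / 2, ex - ew / 2]
        ys = [eye_y, eye_y - eh, eye_y - eh, eye_y, eye_y + eh, eye_y + eh]
        pts[base:base + 6] = np.column_stack([xs, ys])
    # mouth 48-67
    mw, m_y = a * 0.25 * (1.0 + j(0.05)), cy + b * (0.45 + j(0.02))
    top_y, bot_y = m_y - b * 0.07, m_y + b * 0.07
    pts[48] = (cx - mw, m_y)
    pts[54] = (cx + mw, m_y)
    pts[49:54] = np.column_stack([cx + mw * np.linspace(-0.6, 0.6, 5),
                                  top_y + b * 0.01 * np.array([1, 0, 0, 0, 1])])
    pts[51] = (cx, top_y)
    pts[55:60] = np.column_stack([cx + mw * np.linspace(0.6, -0.6, 5),
                                  np.full(5, bot_y)])
    pts[57] = (cx, bot_y)
    pts[60:65] = np.column_stack([cx + mw * np.linspace(-0.7, 0.7, 5), np.full(5, m_y - b * 0.02)])
    pts[65:68] = np.column_stack([cx + mw * np.linspace(0.5, -0.5, 3), np.full(3, m_y + b * 0.02)])
    return pts


def _ellipse_mask(shape: tuple[int, int], cx: float, cy: float,
                  a: float, b: float) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def make_subject(config: SynthConfig, subject_index: int) -> SubjectTemplate:
    """Deterministic per-subject face template and landmarks."""
    rng = _subject_rng(config, subject_index)
    w, h = config.image_size
    cx = w / 2.0 + rng.uniform(-3, 3)
    cy = h / 2.0 + rng.uniform(-2, 2)
    a = 0.34 * w * rng.uniform(0.94, 1.06)
    b = 0.44 * h * rng.uniform(0.94, 1.06)
    pts = _landmark_layout(cx, cy, a, b, rng)
    lm = Landmarks68(pts, (w, h))

    img = np.full((h, w), 55.0)
    face = _ellipse_mask((h, w), cx, cy, a, b)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    skin = (165.0 + rng.uniform(-15, 15)) - 35.0 * r2
    img[face] = skin[face]

    def darken(mask: np.ndarray, amount: float) -> None:
        img[mask] -= amount

    brow_h = b * 0.035
    for sl in (slice(17, 22), slice(22, 27)):
        bx, by = pts[sl, 0], pts[sl, 1]
        darken(_ellipse_mask((h, w), bx.mean(), by.mean(), (bx.max() - bx.min()) / 2 + 1, brow_h + 1), 55.0)
    for base in (36, 42):
        ex, ey = pts[base:base + 6, 0], pts[base:base + 6, 1]
        darken(_ellipse_mask((h, w), ex.mean(), ey.mean(), (ex.max() - ex.min()) / 2, b * 0.045), 45.0)
    darken(_ellipse_mask((h, w), cx, cy - b * 0.08, a * 0.045, b * 0.20), 12.0)
    darken(_ellipse_mask((h, w), pts[31, 0], pts[31, 1], 2.0, 1.6), 30.0)
    darken(_ellipse_mask((h, w), pts[35, 0], pts[35, 1], 2.0, 1.6), 30.0)
    mx, my = pts[48:60, 0], pts[48:60, 1]
    darken(_ellipse_mask((h, w), cx, my.mean(), (mx.max() - mx.min()) / 2, (my.max() - my.min()) / 2), 40.0)

    img = gaussian_filter(img, sigma=1.2)
    # static texture over the whole scene: real onset/apex pairs share a
    # textured background, and brightness-constancy flow is unconstrained on
    # uniform regions
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
    texture *= 22.0 / max(np.abs(texture).max(), 1e-9)
    img = img + texture
    return SubjectTemplate(subject_id=f"SYNTH_s{subject_index:02d}",
                           image=np.clip(img, 0.0, 255.0), landmarks=lm)


# ---------------------------------------------------------------------------
# class-specific apex warps
# ---------------------------------------------------------------------------

def _warp_anchors(landmarks: Landmarks68, label: str, magnitude: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """(anchor position, displacement vector) pairs for one expression class."""
    p = landmarks.points
    m = magnitude
    if label == "Positive":          # lip corners up and outward
        return [(p[48], m * np.array([-0.6, -0.8])),
                (p[54], m * np.array([0.6, -0.8]))]
    if label == "Negative":          # inner brow ends down and inward
        return [(p[21], m * np.array([0.6, 0.8])),
                (p[22], m * np.array([-0.6, 0.8]))]
    if label == "Surprise":          # brows raised, lower lip dropped
        return [(p[19], m * np.array([0.0, -1.0])),
                (p[24], m * np.array([0.0, -1.0])),
                (p[57], m * np.array([0.0, 1.0]))]
    raise ValueError(f"unknown class label {label!r}; expected one of {CLASSES}")


def class_warp_field(landmarks: Landmarks68, label: str, magnitude: float,
                     sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Dense (dx, dy) displacement field of the apex warp (the flow oracle)."""
    w, h = landmarks.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    dx = np.zeros((h, w))
    dy = np.zeros((h, w))
    for anchor, vec in _warp_anchors(landmarks, label, magnitude):
        g = np.exp(-((xx - anchor[0]) ** 2 + (yy - anchor[1]) ** 2) / (2.0 * sigma ** 2))
        dx += vec[0] * g
        dy += vec[1] * g
    return dx, dy


def make_sample(subject: SubjectTemplate, class_label: str, config: SynthConfig,
                sample_index: int = 0, subject_index: int = 0) -> MESample:
    """One onset/apex pair: template plus a localized class-specific warp."""
    lm = subject.landmarks
    face_width = lm.x(15) - lm.x(1)
    sigma = config.warp_sigma_frac * face_width
    dx, dy = class_warp_field(lm, class_label, config.displacement_px, sigma)
    h, w = subject.image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    apex_clean = map_coordinates(subject.image, [yy - dy, xx - dx], order=1, mode="nearest")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, subject_index, sample_index, 7]))
    onset = subject.image + rng.normal(0.0, config.noise_sd, (h, w))
    apex = apex_clean + rng.normal(0.0, config.noise_sd, (h, w))
    return MESample(
        sample_id=f"{subject.subject_id}_{sample_index:03d}",
        subject_id=subject.subject_id, source="SYNTH", raw_label=class_label,
        onset=np.clip(onset, 0.0, 255.0), apex=np.clip(apex, 0.0, 255.0),
        landmarks=lm)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _label_sequence(n_total: int, proportions: tuple[float, ...]) -> list[str]:
    """Deterministic label stream matching the proportions at every prefix."""
    assigned = np.zeros(len(proportions))
    labels = []
    target = np.asarray(proportions)
    for t in range(1, n_total + 1):
        deficit = target * t - assigned
        k = int(np.argmax(deficit))
        assigned[k] += 1
        labels.append(CLASSES[k])
    return labels


def generate_samples(config: SynthConfig) -> list[MESample]:
    """All samples, in memory, subject-major order."""
    n_total = config.n_subjects * config.samples_per_subject
    labels = _label_sequence(n_total, config.class_proportions)
    samples = []
    k = 0
    for si in range(config.n_subjects):
        subject = make_subject(config, si)
        for sj in range(config.samples_per_subject):
            samples.append(make_sample(subject, labels[k], config,
                                       sample_index=sj, subject_index=si))
            k += 1
    return samples


def make_dataset(config: SynthConfig, out_dir) -> pd.DataFrame:
    """Write PNG frames, landmark CSVs and the manifest; return the manifest."""
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "landmarks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in generate_samples(config):
        onset_path = out / "frames" / f"{s.sample_id}_onset.png"
        apex_path = out / "frames" / f"{s.sample_id}_apex.png"
        lm_path = out / "landmarks" / f"{s.sample_id}.csv"
        iio.imwrite(onset_path, np.round(s.onset).astype(np.uint8))
        iio.imwrite(apex_path, np.round(s.apex).astype(np.uint8))
        save_landmarks_csv(lm_path, s.landmarks, s.sample_id)
        rows.append({
            "sample_id": s.sample_id, "subject_id": s.subject_id,
            "source": s.source, "raw_label": s.raw_label,
            "onset_path": str(onset_path.relative_to(out)),
            "apex_path": str(apex_path.relative_to(out)),
            "landmark_path": str(lm_path.relative_to(out)),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
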