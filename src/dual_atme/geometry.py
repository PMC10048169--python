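"""Landmark-driven face preprocessing.

Deterministic geometry for the hand-crafted attention-region-selection (HARS)
stage: in-plane face alignment from the outer eye corners, face cropping from
cheek/jaw landmarks, eyebrow and mouth region-of-interest boxes, and assembly
of the "puzzled" image (two eyebrow tiles over a mouth tile).

Landmarks follow the 68-point iBUG-300W convention, 0-based: 0–16 jaw,
17–26 eyebrows, 27–35 nose, 36–47 eyes (36/45 outer corners), 48–67 mouth
(48/54 corners, 51/57 top/bottom lip).  Coordinates are pixels, x right,
y down.  Boxes are half-open ``[left, right) × [top, bottom)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, resize, warp


class DegenerateLandmarksError(ValueError):
    """Raised when a landmark configuration makes a crop or angle undefined."""


# Index map sending each landmark to its horizontal mirror partner.
FLIP_PERM = np.array(
    list(range(16, -1, -1))            # jaw 0-16 reversed
    + list(range(26, 16, -1))          # brows 17-26 reversed
    + [27, 28, 29, 30]                 # nose bridge fixed
    + [35, 34, 33, 32, 31]             # nostrils reversed
    + [45, 44, 43, 42, 47, 46]         # left eye -> right eye
    + [39, 38, 37, 36, 41, 40]         # right eye -> left eye
    + [54, 53, 52, 51, 50, 49, 48]     # outer lip top
    + [59, 58, 57, 56, 55]             # outer lip bottom
    + [64, 63, 62, 61, 60]             # inner lip top
    + [67, 66, 65]                     # inner lip bottom
)


@dataclass
class Landmarks68:
    """68 facial landmarks for one frame."""

    points: np.ndarray                      # (68, 2) float, (x, y)
    image_size: tuple[int, int]             # (width, height)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (68, 2):
            raise ValueError(f"expected (68, 2) landmark array, got {self.points.shape}")
        if not np.isfinite(self.points).all():
            raise ValueError("landmark coordinates must be finite")

    def x(self, i: int) -> float:
        return float(self.points[i, 0])

    def y(self, i: int) -> float:
        return float(self.points[i, 1])

    def mirrored(self) -> "Landmarks68":
        """Landmarks of the horizontally mirrored image (indices re-labelled)."""
        w = self.image_size[0]
        pts = self.points[FLIP_PERM].copy()
        pts[:, 0] = (w - 1) - pts[:, 0]
        return Landmarks68(pts, self.image_size)


@dataclass
class Box:
    """Half-open pixel box [left, right) × [top, bottom), y down."""

    left: float
    top: float
    right: float
    bottom: float

    @property
    def width(self) -> float:
        return self.right - self.left

    @property
    def height(self) -> float:
        return self.bottom - self.top

    def clamped(self, image_size: tuple[int, int]) -> "Box":
        w, h = image_size
        box = Box(max(0.0, self.left), max(0.0, self.top),
                  min(float(w), self.right), min(float(h), self.bottom))
        if box.right <= box.left or box.bottom <= box.top:
            raise DegenerateLandmarksError(f"box empty after clamping to {image_size}: {self}")
        return box

    def as_slices(self) -> tuple[slice, slice]:
        """Integer (row, col) slices for array cropping."""
        return (slice(int(round(self.top)), int(round(self.bottom))),
                slice(int(round(self.left)), int(round(self.right))))

    def translated(self, dx: float, dy: float) -> "Box":
        return Box(self.left + dx, self.top + dy, self.right + dx, self.bottom + dy)


@dataclass
class ROILayout:
    """All crop geometry for one aligned face."""

    face: Box
    left_eyebrow: Box
    right_eyebrow: Box
    mouth: Box
    puzzle_size: tuple[int, int] = (56, 56)
    alignment_angle: float = 0.0

    def to_json(self) -> str:
        def box(b: Box):
            return {"left": b.left, "top": b.top, "right": b.right, "bottom": b.bottom}
        return json.dumps({
            "face": box(self.face), "left_eyebrow": box(self.left_eyebrow),
            "right_eyebrow": box(self.right_eyebrow), "mouth": box(self.mouth),
            "puzzle_size": list(self.puzzle_size),
            "alignment_angle": self.alignment_angle,
        })

    @staticmethod
    def from_json(s: str) -> "ROILayout":
        d = json.loads(s)
        def box(v):
            return Box(v["left"], v["top"], v["right"], v["bottom"])
        return ROILayout(box(d["face"]), box(d["left_eyebrow"]), box(d["right_eyebrow"]),
                         box(d["mouth"]), tuple(d["puzzle_size"]), d["alignment_angle"])


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def alignment_angle(landmarks: Landmarks68) -> float:
    """In-plane rotation of the eye line, degrees in (-180, 180].

    atan2 of the vector from the left outer eye corner (36) to the right
    outer eye corner (45); 0 for level eyes, positive when the right eye
    sits lower (y down).
    """
    dx = landmarks.x(45) - landmarks.x(36)
    dy = landmarks.y(45) - landmarks.y(36)
    if dx == 0.0 and dy == 0.0:
        raise DegenerateLandmarksError("outer eye corners coincide; angle undefined")
    theta = math.degrees(math.atan2(dy, dx))
    if theta <= -180.0:
        theta += 360.0
    return theta

def _rotation_about_center(theta_deg: float, image_size: tuple[int, int]) -> np.ndarray:
    """3x3 matrix sending original (x, y) to eye-levelled coordinates."""
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    # M @ (dx, dy) rotates the eye vector onto the +x axis
    m = np.array([[c, s], [-s, c]])
    cx, cy = (image_size[0] - 1) / 2.0, (image_size[1] - 1) / 2.0
    centre = np.array([cx, cy])
    shift = centre - m @ centre
    out = np.eye(3)
    out[:2, :2] = m
    out[:2, 2] = shift
    return out


def align_face(image: np.ndarray, landmarks: Landmarks68) -> tuple[np.ndarray, Landmarks68]:
    """Rotate image and landmarks about the image centre so the eyes are level.

    The same rigid transform is applied to both, so no landmark re-detection
    is needed after rotation.
    """
    theta = alignment_angle(landmarks)
    if abs(theta) < 1e-12:
        return image.copy(), Landmarks68(landmarks.points.copy(), landmarks.image_size)
    mat = _rotation_about_center(theta, landmarks.image_size)
    tform = AffineTransform(matrix=mat)
    aligned = warp(image, tform.inverse, order=1, mode="edge", preserve_range=True)
    pts = (landmarks.points @ mat[:2, :2].T) + mat[:2, 2]
    return aligned.astype(image.dtype, copy=False), Landmarks68(pts, landmarks.image_size)


# ---------------------------------------------------------------------------
# crop boxes
# ---------------------------------------------------------------------------

def face_crop_box(landmarks: Landmarks68) -> Box:
    """Face crop from cheek (1, 15) and jaw (8) landmarks.

    The top boundary expands upward from the brow (19) by d, the mean
    brow-to-eye gap ((y38-y20) + (y43-y23)) / 2, keeping margin above the
    eyebrows.
    """
    d = ((landmarks.y(38) - landmarks.y(20)) + (landmarks.y(43) - landmarks.y(23))) / 2.0
    box = Box(left=landmarks.x(1), top=landmarks.y(19) - d,
              right=landmarks.x(15), bottom=landmarks.y(8))
    return box.clamped(landmarks.image_size)


def eyebrow_roi_boxes(landmarks: Landmarks68) -> tuple[Box, Box]:
    """Left and right eyebrow ROIs, expanded by a quarter of their extent.

    Each box widens by len/4 on both sides, rises by height/4 above the brow,
    and stops height/4 above the upper eyelid to keep the eye out.
    """
    le_h = landmarks.y(37) - landmarks.y(19)
    le_l = landmarks.x(21) - landmarks.x(17)
    re_h = landmarks.y(44) - landmarks.y(24)
    re_l = landmarks.x(26) - landmarks.x(22)
    if le_h <= 0 or le_l <= 0 or re_h <= 0 or re_l <= 0:
        raise DegenerateLandmarksError(
            f"non-positive eyebrow extents: le_h={le_h}, le_l={le_l}, re_h={re_h}, re_l={re_l}")
    left = Box(landmarks.x(17) - le_l / 4.0, landmarks.y(19) - le_h / 4.0,
               landmarks.x(21) + le_l / 4.0, landmarks.y(37) - le_h / 4.0)
    right = Box(landmarks.x(22) - re_l / 4.0, landmarks.y(24) - re_h / 4.0,
                landmarks.x(26) + re_l / 4.0, landmarks.y(44) - re_h / 4.0)
    return left.clamped(landmarks.image_size), right.clamped(landmarks.image_size)


def mouth_roi_box(landmarks: Landmarks68) -> Box:
    """Mouth ROI: corners (48, 54) widened by m_l/4, lips (51, 57) padded by m_h/2."""
    m_h = landmarks.y(51) - landmarks.y(33)
    m_l = landmarks.x(54) - landmarks.x(48)
    if m_h <= 0 or m_l <= 0:
        raise DegenerateLandmarksError(f"non-positive mouth extents: m_h={m_h}, m_l={m_l}")
    box = Box(landmarks.x(48) - m_l / 4.0, landmarks.y(51) - m_h / 2.0,
              landmarks.x(54) + m_l / 4.0, landmarks.y(57) + m_h / 2.0)
    return box.clamped(landmarks.image_size)


def roi_layout(landmarks: Landmarks68, puzzle_size: tuple[int, int] = (56, 56),
               angle: float = 0.0) -> ROILayout:
    """Bundle all crop geometry for one aligned face."""
    left, right = eyebrow_roi_boxes(landmarks)
    return ROILayout(face=face_crop_box(landmarks), left_eyebrow=left,
                     right_eyebrow=right, mouth=mouth_roi_box(landmarks),
                     puzzle_size=tuple(puzzle_size), alignment_angle=angle)


# ---------------------------------------------------------------------------
# cropping / puzzle assembly
# ---------------------------------------------------------------------------

def crop(image: np.ndarray, box: Box) -> np.ndarray:
    rows, cols = box.as_slices()
    out = image[rows, cols]
    if out.size == 0:
        raise DegenerateLandmarksError(f"empty crop for {box}")
    return out


def _resize_tile(tile: np.ndarray, shape_hw: tuple[int, int]) -> np.ndarray:
    return resize(tile.astype(float), shape_hw, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def assemble_puzzle(image: np.ndarray, layout: ROILayout) -> np.ndarray:
    """Tile eyebrow and mouth crops into one image.

    The two eyebrow crops fill the top half side by side (left brow on the
    left); the mouth crop fills the bottom half.  Output is
    ``(H, W) = (puzzle_size[1], puzzle_size[0])``, bilinear resampling.
    """
    w, h = layout.puzzle_size
    if w < 2 or h < 2:
        raise ValueError("puzzle_size must be at least 2x2")
    half_h, left_w = h // 2, w // 2
    lb = _resize_tile(crop(image, layout.left_eyebrow), (half_h, left_w))
    rb = _resize_tile(crop(image, layout.right_eyebrow), (half_h, w - left_w))
    mo = _resize_tile(crop(image, layout.mouth), (h - half_h, w))
    out = np.empty((h, w), dtype=float)
    out[:half_h, :left_w] = lb
    out[:half_h, left_w:] = rb
    out[half_h:, :] = mo
    return out


# ---------------------------------------------------------------------------
# landmark sidecar I/O
# ---------------------------------------------------------------------------

def save_landmarks_csv(path, landmarks: Landmarks68, sample_id: str) -> None:
    df = pd.DataFrame({
        "sample_id": sample_id,
        "point_index": np.arange(68),
        "x": landmarks.points[:, 0],
        "y": landmarks.points[:, 1],
        "image_width": landmarks.image_size[0],
        "image_height": landmarks.image_size[1],
    })
    df.to_csv(path, index=False)


def load_landmarks_csv(path) -> Landmarks68:
    df = pd.read_csv(path).sort_values("point_index")
    if len(df) != 68:
        raise ValueError(f"landmark file {path} has {len(df)} rows, expected 68")
    pts = df[["x", "y"]].to_numpy(dtype=float)
    size = (int(df["image_width"].iloc[0]), int(df["image_height"].iloc[0]))
    return Landmarks68(pts, size)
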