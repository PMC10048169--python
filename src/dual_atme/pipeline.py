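"""End-to-end preprocessing: frames + landmarks → network-ready flow features.

For each sample the onset and apex frames are rotated with the onset
landmarks so the eyes are level, the face is cropped, the eyebrow/mouth
puzzle is assembled, and TV-L1 flow + strain features are built for both the
full-face crop and the puzzle.  Features can be kept in memory or persisted
as one ``.npz`` per sample beside a features manifest CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import (Landmarks68, align_face, assemble_puzzle, crop,
                       face_crop_box, load_landmarks_csv, roi_layout)
from .motion import FlowFeature, TVL1Config, build_feature


@dataclass
class PipelineConfig:
    """Preprocessing knobs.

    puzzle_size is the working resolution at which the puzzle is assembled
    and its flow computed (larger than the network input so ROI motion keeps
    near-native amplitude); resize_to is the network input resolution.
    """

    puzzle_size: tuple[int, int] = (56, 56)
    resize_to: tuple[int, int] = (28, 28)
    flow: TVL1Config = field(default_factory=TVL1Config)


def preprocess_pair(onset: np.ndarray, apex: np.ndarray, landmarks: Landmarks68,
                    config: PipelineConfig | None = None) -> tuple[FlowFeature, FlowFeature]:
    """(entire, puzzled) flow features for one onset/apex pair."""
    config = config or PipelineConfig()
    onset_a, lm = align_face(np.asarray(onset, dtype=float), landmarks)
    apex_a, _ = align_face(np.asarray(apex, dtype=float), landmarks)
    face = face_crop_box(lm)
    entire = build_feature(crop(onset_a, face), crop(apex_a, face),
                           resize_to=config.resize_to, role="entire", config=config.flow)
    layout = roi_layout(lm, puzzle_size=config.puzzle_size)
    puzzled = build_feature(assemble_puzzle(onset_a, layout), assemble_puzzle(apex_a, layout),
                            resize_to=config.resize_to, role="puzzled", config=config.flow)
    return entire, puzzled


def compute_features(samples, config: PipelineConfig | None = None) -> dict:
    """In-memory features for a list of MESample objects."""
    config = config or PipelineConfig()
    return {
        s.sample_id: preprocess_pair(s.onset, s.apex, s.landmarks, config)
        for s in samples
    }


def preprocess_manifest(data_dir, manifest: pd.DataFrame, out_dir,
                        config: PipelineConfig | None = None) -> pd.DataFrame:
    """Compute and persist features for every manifest row.

    Writes ``<sample_id>.npz`` (arrays ``entire``, ``puzzled``) under
    ``out_dir`` and returns the features manifest, which is also saved as
    ``features.csv``.
    """
    config = config or PipelineConfig()
    data_dir, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in manifest.itertuples(index=False):
        onset = iio.imread(data_dir / rec.onset_path).astype(float)
        apex = iio.imread(data_dir / rec.apex_path).astype(float)
        lm = load_landmarks_csv(data_dir / rec.landmark_path)
        entire, puzzled = preprocess_pair(onset, apex, lm, config)
        path = out / f"{rec.sample_id}.npz"
        np.savez(path, entire=entire.channels, puzzled=puzzled.channels)
        rows.append({"sample_id": rec.sample_id, "feature_path": path.name})
    features = pd.DataFrame(rows)
    features.to_csv(out / "features.csv", index=False)
    return features


def load_features(features_dir) -> dict:
    """Features written by :func:`preprocess_manifest`, as sample_id -> arrays."""
    features_dir = Path(features_dir)
    table = pd.read_csv(features_dir / "features.csv")
    out = {}
    for rec in table.itertuples(index=False):
        data = np.load(features_dir / rec.feature_path)
        out[rec.sample_id] = (data["entire"], data["puzzled"])
    return out
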