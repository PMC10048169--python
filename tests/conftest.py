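import numpy as np
import pandas as pd
import pytest

from dual_atme.pipeline import compute_features
from dual_atme.synthdata import SynthConfig, generate_samples, make_subject


@pytest.fixture(scope="session")
def tiny_config():
    """Small three-subject generator configuration shared across tests."""
    return SynthConfig(n_subjects=3, samples_per_subject=6, displacement_px=3.0,
                       noise_sd=1.0, seed=123)


@pytest.fixture(scope="session")
def subject(tiny_config):
    return make_subject(tiny_config, 0)


@pytest.fixture(scope="session")
def tiny_samples(tiny_config):
    return generate_samples(tiny_config)


@pytest.fixture(scope="session")
def tiny_manifest(tiny_samples):
    rows = [{"sample_id": s.sample_id, "subject_id": s.subject_id,
             "source": s.source, "raw_label": s.raw_label,
             "composite_label": s.raw_label} for s in tiny_samples]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def tiny_features(tiny_samples):
    """Flow features for the tiny dataset (computed once per session)."""
    return compute_features(tiny_samples)


def landmarks_from(values: dict, size=(400, 400)):
    """68-point array with only the listed indices set (exact-arithmetic tests)."""
    from dual_atme.geometry import Landmarks68
    pts = np.zeros((68, 2))
    for idx, (x, y) in values.items():
        pts[idx] = (x, y)
    return Landmarks68(pts, size)
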