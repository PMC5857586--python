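import numpy as np
import pandas as pd
import pytest

from gazepipe.cohort import (
    ArtifactModel,
    CohortConfig,
    NoiseModel,
    TraitModel,
    TrialCounts,
)
from gazepipe.geometry import ScreenGeometry
from gazepipe.recording_io import RECORDING_COLUMNS, Recording


@pytest.fixture
def geometry():
    return ScreenGeometry()


@pytest.fixture
def clean_config():
    """Noiseless, artifact-free cohort configuration (identifiability regime)."""
    return CohortConfig(
        n_participants=1,
        seed=11,
        noise=NoiseModel(
            latency_sd_ms=0.0, pupil_sd_mm=0.0, reach_sd_ms=0.0,
            gaze_jitter_px=0.0, baseline_sd_mm=0.0,
        ),
        artifacts=ArtifactModel(
            blink_rate_hz=0.0, spike_rate_hz=0.0,
            dropout_prediction=0.0, dropout_evaluation=0.0, dropout_reach=0.0,
        ),
    )


@pytest.fixture
def small_config():
    """Small but fully featured cohort for end-to-end tests."""
    return CohortConfig(n_participants=6, seed=42)


def make_recording(t, x, y, valid=None, pupil_left=None, pupil_right=None,
                   sample_rate=60.0, participant_id="p000"):
    n = len(t)
    if valid is None:
        valid = np.ones(n, bool)
    samples = pd.DataFrame(
        {
            "t": np.asarray(t, float),
            "gaze_x": np.asarray(x, float),
            "gaze_y": np.asarray(y, float),
            "pupil_left": np.full(n, 3.5) if pupil_left is None else np.asarray(pupil_left, float),
            "pupil_right": np.full(n, 3.5) if pupil_right is None else np.asarray(pupil_right, float),
            "valid_left": np.asarray(valid, bool),
            "valid_right": np.asarray(valid, bool),
        }
    )[RECORDING_COLUMNS]
    return Recording(
        participant_id=participant_id,
        age_group="6mo",
        sample_rate=sample_rate,
        geometry=ScreenGeometry(),
        samples=samples,
    )
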