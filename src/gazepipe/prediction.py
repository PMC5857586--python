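"""Action-prediction scoring: gaze latency to the mouth AOI.

Each eating-action trial is scored from detected fixations against two
rectangular areas of interest (bowl and mouth, each 6.3 x 3.8 visual degrees
by default). A trial contributes data only if (1) a bowl-AOI fixation overlaps
the interval from food pickup until the spoon leaves the bowl, and (2) within
the scoring window — from the spoon leaving the bowl until 1 s after it
reaches the mouth — a bowl-AOI fixation is followed by a mouth-AOI fixation.
The dependent variable is the onset of that first qualifying mouth fixation
relative to the spoon's arrival at the mouth, in milliseconds; negative values
mean the gaze arrived before the spoon (a predictive gaze shift).

AOI membership is decided by the fixation centroid. A fixation that started
before a window but persists into it counts, with latency measured from its
onset. Participants need at least two scored trials to enter the analysis;
included participants with a mean latency below zero are classified
predictive, otherwise reactive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .fixation import Fixation
from .geometry import ScreenGeometry
from .recording_io import TrialAnnotation


@dataclass(frozen=True)
class AOI:
    name: str  # "bowl" | "mouth"
    center_x: float
    center_y: float
    width_deg: float = 6.3
    height_deg: float = 3.8

    def __post_init__(self) -> None:
        if self.width_deg < 0 or self.height_deg < 0:
            raise ConfigError("AOI extents must be non-negative")


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned pixel rectangle [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


def aoi_to_pixels(aoi: AOI, geometry: ScreenGeometry) -> Rect:
    """Convert an AOI sized in visual degrees to a pixel rectangle.

    Extent per axis is ``2 * viewing_distance * tan(deg / 2)`` millimetres,
    converted through the screen's mm-per-pixel density. A 0x0 AOI yields a
    degenerate empty rectangle.
    """
    w = geometry.degrees_to_pixels_x(aoi.width_deg)
    h = geometry.degrees_to_pixels_y(aoi.height_deg)
    return Rect(
        x0=aoi.center_x - w / 2.0,
        y0=aoi.center_y - h / 2.0,
        x1=aoi.center_x + w / 2.0,
        y1=aoi.center_y + h / 2.0,
    )


SCORED = "scored"
NO_BOWL_FIXATION = "no_bowl_fixation"
NO_MOUTH_FIXATION = "no_mouth_fixation"
NO_DATA = "no_data"


@dataclass(frozen=True)
class TrialPredictionScore:
    trial_id: str
    status: str
    latency_ms: float | None = None

    def __post_init__(self) -> None:
        assert (self.status == SCORED) == (self.latency_ms is not None)


def score_prediction_trial(
    fixations: Sequence[Fixation],
    annotation: TrialAnnotation,
    bowl_rect: Rect,
    mouth_rect: Rect,
    post_arrival_window_s: float = 1.0,
) -> TrialPredictionScore:
    """Score one eating-action trial; every failure mode is a status."""
    if annotation.task != "prediction":
        raise ValueError(f"trial {annotation.trial_id} is not a prediction trial")
    pickup = annotation.food_pickup_t
    leaves = annotation.spoon_leaves_bowl_t
    arrival = annotation.spoon_reaches_mouth_t
    window_end = arrival + post_arrival_window_s

    trial_fix = [f for f in fixations if f.overlaps(pickup, window_end)]
    if not trial_fix:
        return TrialPredictionScore(annotation.trial_id, NO_DATA)

    def in_bowl(f: Fixation) -> bool:
        return bowl_rect.contains(f.centroid_x, f.centroid_y)

    def in_mouth(f: Fixation) -> bool:
        return mouth_rect.contains(f.centroid_x, f.centroid_y)

    # Step 1: a bowl fixation during [food pickup, spoon leaves bowl].
    if not any(in_bowl(f) and f.overlaps(pickup, leaves) for f in trial_fix):
        return TrialPredictionScore(annotation.trial_id, NO_BOWL_FIXATION)

    # Step 2: within the scoring window, bowl fixation then mouth fixation
    # (strict ordering of onsets; intervening elsewhere-fixations ignored).
    window_fix = sorted(
        (f for f in trial_fix if f.overlaps(leaves, window_end)),
        key=lambda f: f.onset_t,
    )
    bowl_onsets = [f.onset_t for f in window_fix if in_bowl(f)]
    if bowl_onsets:
        first_bowl = min(bowl_onsets)
        for f in window_fix:
            if in_mouth(f) and f.onset_t > first_bowl:
                # Step 3: latency from the mouth fixation onset (which may
                # predate the window start) to the spoon's arrival.
                return TrialPredictionScore(
                    annotation.trial_id,
                    SCORED,
                    latency_ms=(f.onset_t - arrival) * 1000.0,
                )
    return TrialPredictionScore(annotation.trial_id, NO_MOUTH_FIXATION)


PREDICTIVE = "predictive"
REACTIVE = "reactive"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class ParticipantPredictionScore:
    participant_id: str
    n_valid_trials: int
    mean_latency_ms: float | None
    included: bool
    classification: str


def aggregate_prediction(
    trial_scores: Sequence[TrialPredictionScore],
    participant_id: str,
    min_trials: int = 2,
) -> ParticipantPredictionScore:
    """Collapse trial scores into one prediction score per participant.

    Participants with fewer than ``min_trials`` scored trials (default 2) are
    excluded; included participants are predictive iff their mean latency is
    negative.
    """
    latencies = [s.latency_ms for s in trial_scores if s.status == SCORED]
    n = len(latencies)
    if n < min_trials:
        return ParticipantPredictionScore(participant_id, n, None, False, EXCLUDED)
    mean = float(np.mean(latencies))
    return ParticipantPredictionScore(
        participant_id, n, mean, True, PREDICTIVE if mean < 0 else REACTIVE
    )
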