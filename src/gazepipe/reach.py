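"""Motor-development scoring: reach-onset latency relative to midline crossing.

The coded table is produced by human frame-by-frame video coding; this module
only converts it into the dependent variable. A trial is valid when the infant
attended to the object (coding criterion 1) and the coded movement qualified
as a reach (3 cm toward the object plus a qualifying follow-event). Latency is
reach onset minus the moment the object crossed the infant's midline; negative
values are predictive reaches. Slow-object trials carry no usable signal for
the individual-differences analysis and are dropped: only fast trials enter
the participant mean. A single valid fast trial suffices for inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Sequence

import numpy as np

from .prediction import EXCLUDED, PREDICTIVE, REACTIVE
from .recording_io import ReachCodingRow


@dataclass(frozen=True)
class ReachTrialScore:
    trial_index: int
    valid: bool
    latency_s: float | None = None
    reason: str | None = None


def score_reach_trial(row: ReachCodingRow) -> ReachTrialScore:
    """Latency in seconds, or an invalid score with a reason."""
    if not row.attended_ok:
        return ReachTrialScore(row.trial_index, False, reason="not_attending")
    if not row.reach_valid:
        return ReachTrialScore(row.trial_index, False, reason="no_valid_reach")
    return ReachTrialScore(row.trial_index, True, latency_s=row.reach_onset_t - row.midline_t)


@dataclass(frozen=True)
class ParticipantReachScore:
    participant_id: str
    n_valid_trials: int
    mean_latency_s: float | None
    included: bool
    classification: str


def aggregate_reach(
    rows: Sequence[ReachCodingRow],
    participant_id: str,
    use_speeds: FrozenSet[str] = frozenset({"fast"}),
    min_trials: int = 1,
) -> ParticipantReachScore:
    """Mean latency over valid trials of the selected speeds (default fast only)."""
    latencies = []
    for row in rows:
        if row.speed not in use_speeds:
            continue
        s = score_reach_trial(row)
        if s.valid:
            latencies.append(s.latency_s)
    n = len(latencies)
    if n < min_trials:
        return ParticipantReachScore(participant_id, n, None, False, EXCLUDED)
    mean = float(np.mean(latencies))
    return ParticipantReachScore(
        participant_id, n, mean, True, PREDICTIVE if mean < 0 else REACTIVE
    )
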