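"""Event-related pupillometry: four-step cleaning and baseline-corrected
dilation scores.

Cleaning applies, strictly in order:

1. range filter — samples outside 2.5–5.5 mm become missing (the bounds
   themselves are retained);
2. step filter — a sample whose absolute difference from the previous
   *retained* value exceeds 1 mm becomes missing (the reference is the last
   value that survived steps 1–2, so a removed spike does not cascade);
3. interpolation — interior missing runs shorter than 10 samples are linearly
   interpolated between the flanking retained values; runs of 10 or more, and
   runs touching either edge, stay missing;
4. smoothing — a 10-sample moving average over retained values. With an even
   window the average spans ``[i-5, i+4]``, truncated at edges and at
   missing-data boundaries (the window never crosses a gap); output is missing
   where input is missing.

Scoring compares the mean pupil size over a 1000 ms baseline ending at the
giver's grasp with the mean over the 3000 ms analysis window that follows; the
trial's change score is analysis minus baseline. A window is usable when at
least half of its samples are retained. The participant-level dependent
variable is the mean change on inappropriate trials minus the mean change on
appropriate trials, requiring at least three valid trials per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError


@dataclass(frozen=True)
class CleaningParams:
    range_mm: tuple[float, float] = (2.5, 5.5)
    max_step_mm: float = 1.0
    max_gap_samples: int = 10
    ma_window: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.range_mm
        if not (lo < hi) or self.max_step_mm <= 0 or self.max_gap_samples < 1 or self.ma_window < 1:
            raise ConfigError("invalid pupil cleaning parameters")


@dataclass(frozen=True)
class PupilTrace:
    """Pupil diameter on a uniform time grid; NaN marks missing samples."""

    t: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.t) != len(self.values):
            raise ValidationError("t and values must have equal length")
        if len(self.t) >= 3:
            dt = np.diff(np.asarray(self.t, float))
            if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6 * dt.mean():
                raise ValidationError("pupil trace must lie on a uniform, increasing grid")
        with np.errstate(invalid="ignore"):
            if np.any(np.asarray(self.values, float) <= 0):
                raise ValidationError("pupil values, where present, must be > 0")


def combine_eyes(samples: pd.DataFrame) -> PupilTrace:
    """Average the valid eyes' pupil diameters per sample.

    A sample uses the mean of both eyes when both are valid, the single valid
    eye otherwise, and is missing when neither eye is valid (or no finite
    diameter was recorded).
    """
    t = samples["t"].to_numpy(float)
    pl = samples["pupil_left"].to_numpy(float)
    pr = samples["pupil_right"].to_numpy(float)
    ul = samples["valid_left"].to_numpy(bool) & np.isfinite(pl)
    ur = samples["valid_right"].to_numpy(bool) & np.isfinite(pr)
    num = np.where(ul, pl, 0.0) + np.where(ur, pr, 0.0)
    den = ul.astype(float) + ur.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / np.maximum(den, 1.0), np.nan)
    return PupilTrace(t=t, values=values)


# ---------------------------------------------------------------------------
# Cleaning (batched core: rows are independent traces on a common grid)


def clean_matrix(values: np.ndarray, params: CleaningParams = CleaningParams()) -> np.ndarray:
    """Apply the four cleaning steps to each row of a (traces x samples) array."""
    X = np.array(values, dtype=float, copy=True)
    if X.ndim != 2:
        raise ValueError("clean_matrix expects a 2-D array")
    m, n = X.shape
    if n == 0:
        return X
    lo, hi = params.range_mm

    # Step 1: range filter (bounds retained).
    with np.errstate(invalid="ignore"):
        X[(X < lo) | (X > hi)] = np.nan

    # Step 2: step filter against the last retained value, sequential in time
    # but vectorized across traces.
    last = np.full(m, np.nan)
    for j in range(n):
        col = X[:, j]
        present = ~np.isnan(col)
        with np.errstate(invalid="ignore"):
            bad = present & ~np.isnan(last) & (np.abs(col - last) > params.max_step_mm)
        if bad.any():
            X[bad, j] = np.nan
        keep = present & ~bad
        last[keep] = col[keep]

    # Steps 3 and 4 operate per trace.
    for r in range(m):
        X[r] = _interpolate_gaps(X[r], params.max_gap_samples)
        X[r] = _moving_average(X[r], params.ma_window)
    return X


def _interpolate_gaps(x: np.ndarray, max_gap: int) -> np.ndarray:
    miss = np.isnan(x)
    if not miss.any() or miss.all():
        return x
    mi = np.flatnonzero(miss)
    breaks = np.flatnonzero(np.diff(mi) > 1)
    starts = np.concatenate(([mi[0]], mi[breaks + 1]))
    ends = np.concatenate((mi[breaks], [mi[-1]]))
    n = len(x)
    for a, b in zip(starts, ends):
        length = b - a + 1
        if a == 0 or b == n - 1 or length >= max_gap:
            continue
        left, right = x[a - 1], x[b + 1]
        frac = np.arange(1, length + 1) / (length + 1)
        x[a : b + 1] = left + frac * (right - left)
    return x


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Moving average within contiguous valid runs; window [i-before, i+after]
    with before = window // 2, after = window - 1 - before, truncated at run
    boundaries. Missing samples stay missing."""
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    if not ok.any():
        return out
    before = window // 2
    after = window - 1 - before
    oi = np.flatnonzero(ok)
    breaks = np.flatnonzero(np.diff(oi) > 1)
    starts = np.concatenate(([oi[0]], oi[breaks + 1]))
    ends = np.concatenate((oi[breaks], [oi[-1]]))
    for a, b in zip(starts, ends):
        seg = x[a : b + 1]
        c = np.concatenate(([0.0], np.cumsum(seg)))
        i = np.arange(len(seg))
        lo = np.maximum(i - before, 0)
        hi = np.minimum(i + after, len(seg) - 1)
        out[a : b + 1] = (c[hi + 1] - c[lo]) / (hi - lo + 1)
    return out


def clean_pupil(trace: PupilTrace, params: CleaningParams = CleaningParams()) -> PupilTrace:
    """Clean a single pupil trace with the four steps, in order."""
    cleaned = clean_matrix(np.asarray(trace.values, float)[None, :], params)[0]
    return replace(trace, values=cleaned)


# ---------------------------------------------------------------------------
# Scoring


@dataclass(frozen=True)
class TrialDilation:
    trial_id: str
    condition: str
    baseline_mean: float | None
    analysis_mean: float | None
    change: float | None
    valid: bool
    reason: str | None = None


def score_dilation_trial(
    trace: PupilTrace,
    grasp_t: float,
    *,
    trial_id: str = "",
    condition: str = "n/a",
    baseline_ms: float = 1000.0,
    analysis_ms: float = 3000.0,
    min_valid_fraction: float = 0.5,
) -> TrialDilation:
    """Baseline-corrected change score for one trial.

    Baseline window is ``[grasp_t - baseline, grasp_t)``, analysis window
    ``[grasp_t, grasp_t + analysis)``; each window must retain at least
    ``min_valid_fraction`` of its samples.
    """
    t = np.asarray(trace.t, float)
    v = np.asarray(trace.values, float)
    b0 = grasp_t - baseline_ms / 1000.0
    a1 = grasp_t + analysis_ms / 1000.0
    if len(t) == 0 or b0 < t[0] - 1e-9 or a1 > t[-1] + (t[1] - t[0] if len(t) > 1 else 0) + 1e-9:
        return TrialDilation(trial_id, condition, None, None, None, False, "window_outside_trace")

    base = v[(t >= b0 - 1e-9) & (t < grasp_t - 1e-9)]
    anal = v[(t >= grasp_t - 1e-9) & (t < a1 - 1e-9)]

    def window_mean(w: np.ndarray) -> float | None:
        if len(w) == 0:
            return None
        frac = np.mean(~np.isnan(w))
        if frac < min_valid_fraction:
            return None
        return float(np.nanmean(w))

    bm = window_mean(base)
    am = window_mean(anal)
    if bm is None or am is None:
        return TrialDilation(trial_id, condition, bm, am, None, False, "insufficient_valid_samples")
    return TrialDilation(trial_id, condition, bm, am, am - bm, True)


@dataclass(frozen=True)
class ParticipantDilationScore:
    participant_id: str
    n_valid_appropriate: int
    n_valid_inappropriate: int
    mean_change_appropriate: float | None
    mean_change_inappropriate: float | None
    difference: float | None  # inappropriate - appropriate
    included: bool


def aggregate_dilation(
    trial_dilations: Sequence[TrialDilation],
    participant_id: str,
    min_per_condition: int = 3,
) -> ParticipantDilationScore:
    """Condition means over valid trials and their difference.

    Participants are included only with at least ``min_per_condition`` valid
    trials in each condition (default 3).
    """
    app = [d.change for d in trial_dilations if d.valid and d.condition == "appropriate"]
    inapp = [d.change for d in trial_dilations if d.valid and d.condition == "inappropriate"]
    n_app, n_inapp = len(app), len(inapp)
    mean_app = float(np.mean(app)) if n_app else None
    mean_inapp = float(np.mean(inapp)) if n_inapp else None
    included = n_app >= min_per_condition and n_inapp >= min_per_condition
    diff = (mean_inapp - mean_app) if included else None
    return ParticipantDilationScore(
        participant_id, n_app, n_inapp, mean_app, mean_inapp, diff, included
    )
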