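"""Sliding-window velocity fixation detection (I-VT style, two parameters).

The filter reimplements the classic two-parameter windowed-velocity fixation
filter shipped with Tobii analysis software (Olsson-style). Per sample, a
velocity is estimated as the Euclidean distance between the mean gaze position
of the ``window`` samples before the sample and the ``window`` samples from it
onward (units: pixels per window). Saccades appear as super-threshold velocity
excursions; each maximal super-threshold run contributes one fixation boundary
at its velocity peak, so detected fixation onsets land at the saccade rather
than drifting by ~``window`` samples as a naive below-threshold-run rule
would. Runs of invalid gaze always terminate a fixation. Consecutive
candidates whose centroids are closer than ``distance_threshold`` pixels are
merged (centroid recomputed over all member samples); an invalid-gaze gap may
be bridged by a merge only when it is shorter than ``window`` samples.

Published parameter values: velocity threshold 35 pixels/window, distance
threshold 35 pixels. The window length is not published; the default of 5
samples is the classic implementation's default and is configurable, as is the
minimum duration (default 1 sample: no unstated minimum is imposed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import ConfigError

if TYPE_CHECKING:  # pragma: no cover
    from .recording_io import Recording


@dataclass(frozen=True)
class FilterParams:
    velocity_threshold: float = 35.0  # pixels per window
    distance_threshold: float = 35.0  # pixels
    window: int = 5  # samples
    min_duration: int = 1  # samples

    def __post_init__(self) -> None:
        if (
            self.velocity_threshold <= 0
            or self.distance_threshold <= 0
            or self.window < 1
            or self.min_duration < 1
        ):
            raise ConfigError("all fixation filter parameters must be strictly positive")


@dataclass(frozen=True)
class Fixation:
    onset_t: float
    offset_t: float
    centroid_x: float
    centroid_y: float
    n_samples: int

    def overlaps(self, start: float, end: float) -> bool:
        """True if the fixation interval intersects [start, end]."""
        return self.onset_t <= end and self.offset_t >= start


def sample_velocities(
    x: np.ndarray, y: np.ndarray, valid: np.ndarray, window: int
) -> np.ndarray:
    """Per-sample windowed velocity in pixels/window; NaN where undefined.

    Velocity at sample ``i`` compares the mean position over ``[i-window, i)``
    with the mean over ``[i, i+window)``. It is undefined for samples too
    close to an edge and wherever either window touches invalid gaze.
    """
    if window < 1:
        raise ConfigError("window must be >= 1")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    valid = np.asarray(valid, bool) & np.isfinite(x) & np.isfinite(y)
    n = len(x)
    v = np.full(n, np.nan)
    if n < 2 * window:
        return v
    xs = np.where(valid, x, 0.0)
    ys = np.where(valid, y, 0.0)
    cx = np.concatenate(([0.0], np.cumsum(xs)))
    cy = np.concatenate(([0.0], np.cumsum(ys)))
    cv = np.concatenate(([0], np.cumsum(valid.astype(np.int64))))
    i = np.arange(window, n - window + 1)
    defined = (cv[i + window] - cv[i - window]) == 2 * window
    bx = (cx[i] - cx[i - window]) / window
    by = (cy[i] - cy[i - window]) / window
    ax = (cx[i + window] - cx[i]) / window
    ay = (cy[i + window] - cy[i]) / window
    vel = np.hypot(ax - bx, ay - by)
    v[i] = np.where(defined, vel, np.nan)
    return v


def recording_velocities(recording: "Recording", window: int = 5) -> np.ndarray:
    s = recording.samples
    return sample_velocities(
        s["gaze_x"].to_numpy(float),
        s["gaze_y"].to_numpy(float),
        recording.gaze_valid(),
        window,
    )


#: Velocity-peak tie tolerance (px/window): within a super-threshold run the
#: boundary is the first sample whose velocity is within this of the maximum.
_PEAK_TOL = 1e-6


class _Candidate:
    __slots__ = ("start", "end", "sum_x", "sum_y", "n")

    def __init__(self, start: int, end: int, sum_x: float, sum_y: float, n: int):
        self.start = start
        self.end = end
        self.sum_x = sum_x
        self.sum_y = sum_y
        self.n = n

    @property
    def centroid(self) -> tuple[float, float]:
        return self.sum_x / self.n, self.sum_y / self.n


def detect_fixations_arrays(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    valid: np.ndarray,
    params: FilterParams = FilterParams(),
) -> list[Fixation]:
    """Detect fixations on raw sample arrays. See the module docstring."""
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    valid = np.asarray(valid, bool) & np.isfinite(x) & np.isfinite(y)
    n = len(t)
    if n == 0 or not valid.any():
        return []
    v = sample_velocities(x, y, valid, params.window)

    # Maximal runs of valid gaze.
    vi = np.flatnonzero(valid)
    breaks = np.flatnonzero(np.diff(vi) > 1)
    seg_starts = np.concatenate(([vi[0]], vi[breaks + 1]))
    seg_ends = np.concatenate((vi[breaks], [vi[-1]]))

    candidates: list[_Candidate] = []
    for a, b in zip(seg_starts, seg_ends):
        # Boundaries: one per maximal run of defined super-threshold velocity,
        # placed at the run's (first) velocity maximum.
        over = np.zeros(b - a + 1, bool)
        vv = v[a : b + 1]
        with np.errstate(invalid="ignore"):
            over = np.isfinite(vv) & (vv >= params.velocity_threshold)
        cuts: list[int] = []
        oi = np.flatnonzero(over)
        if oi.size:
            obreaks = np.flatnonzero(np.diff(oi) > 1)
            run_starts = np.concatenate(([oi[0]], oi[obreaks + 1]))
            run_ends = np.concatenate((oi[obreaks], [oi[-1]]))
            for p, q in zip(run_starts, run_ends):
                run = vv[p : q + 1]
                # first sample at the run's velocity maximum, with a small
                # tolerance so exact plateaus are not decided by round-off
                k = p + int(np.flatnonzero(run >= run.max() - _PEAK_TOL)[0])
                cuts.append(a + k)
        start = a
        for k in cuts:
            if k >= start:
                candidates.append(_make_candidate(start, k, x, y))
            start = k + 1
        if start <= b:
            candidates.append(_make_candidate(start, b, x, y))

    # Sequential centroid merge, recomputing the running centroid.
    merged: list[_Candidate] = []
    current = candidates[0]
    for nxt in candidates[1:]:
        gap = nxt.start - current.end - 1
        cx, cy = current.centroid
        nx, ny = nxt.centroid
        dist = float(np.hypot(cx - nx, cy - ny))
        if gap < params.window and dist < params.distance_threshold:
            current = _Candidate(
                current.start, nxt.end,
                current.sum_x + nxt.sum_x, current.sum_y + nxt.sum_y,
                current.n + nxt.n,
            )
        else:
            merged.append(current)
            current = nxt
    merged.append(current)

    out = []
    for c in merged:
        if c.n < params.min_duration:
            continue
        cx, cy = c.centroid
        out.append(
            Fixation(
                onset_t=float(t[c.start]),
                offset_t=float(t[c.end]),
                centroid_x=cx,
                centroid_y=cy,
                n_samples=c.n,
            )
        )
    return out


def _make_candidate(start: int, end: int, x: np.ndarray, y: np.ndarray) -> _Candidate:
    return _Candidate(
        start, end,
        float(np.sum(x[start : end + 1])), float(np.sum(y[start : end + 1])),
        end - start + 1,
    )


def detect_fixations(
    recording: "Recording", params: FilterParams = FilterParams()
) -> list[Fixation]:
    """Detect fixations in a :class:`~gazepipe.recording_io.Recording`."""
    s = recording.samples
    return detect_fixations_arrays(
        s["t"].to_numpy(float),
        s["gaze_x"].to_numpy(float),
        s["gaze_y"].to_numpy(float),
        recording.gaze_valid(),
        params,
    )


def fixations_to_rows(
    participant_id: str, fixations: Sequence[Fixation]
) -> list[dict]:
    """Rows for a ``fixations.tsv`` export."""
    return [
        {
            "participant_id": participant_id,
            "onset_t": f.onset_t,
            "offset_t": f.offset_t,
            "centroid_x": f.centroid_x,
            "centroid_y": f.centroid_y,
            "n_samples": f.n_samples,
        }
        for f in fixations
    ]
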