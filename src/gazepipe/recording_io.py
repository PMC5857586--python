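"""Tabular I/O for raw recordings, trial annotations and coded reach tables.

All three dialects are UTF-8 TSV with a fixed header row. Missing values are
empty fields (never 0 or -1: vendor exports that flag invalid samples with
sentinel coordinates are expected to be normalized through the validity
columns before entering this dialect). Time is seconds from recording onset,
shared between a recording and its annotations. Floats are written with
``repr`` so that write -> read -> write is byte-identical and read(write(r))
reproduces sample values exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .geometry import ScreenGeometry

log = logging.getLogger(__name__)

RECORDING_COLUMNS = [
    "t", "gaze_x", "gaze_y", "pupil_left", "pupil_right", "valid_left", "valid_right",
]
TRIAL_COLUMNS = [
    "participant_id", "trial_id", "task", "condition",
    "food_pickup_t", "spoon_leaves_bowl_t", "spoon_reaches_mouth_t", "grasp_t",
]
REACH_COLUMNS = [
    "participant_id", "trial_index", "speed", "attended_ok",
    "object_start_t", "reach_onset_t", "midline_t", "reach_valid", "caught",
]

#: Relative tolerance for the median inter-sample interval vs 1 / sample_rate.
ISI_TOLERANCE = 0.10


@dataclass(eq=False)
class Recording:
    """A participant's raw sample stream plus screen/viewing geometry.

    ``samples`` is a DataFrame with the columns of ``RECORDING_COLUMNS``:
    ``t`` seconds, gaze in screen pixels (origin top-left, y downward), pupil
    diameters in mm (NaN when missing), and per-eye validity booleans.
    """

    participant_id: str
    age_group: str  # "6mo" | "10mo"
    sample_rate: float
    geometry: ScreenGeometry
    samples: pd.DataFrame
    n_rejected_rows: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be strictly positive")
        missing = [c for c in RECORDING_COLUMNS if c not in self.samples.columns]
        if missing:
            raise FormatError(f"samples missing mandatory column(s): {missing}")
        _check_sample_stream(self.samples, self.sample_rate)

    def __len__(self) -> int:
        return len(self.samples)

    def gaze_valid(self) -> np.ndarray:
        """Boolean per sample: usable gaze (some eye tracked, finite coords)."""
        s = self.samples
        tracked = s["valid_left"].to_numpy(bool) | s["valid_right"].to_numpy(bool)
        finite = np.isfinite(s["gaze_x"].to_numpy(float)) & np.isfinite(
            s["gaze_y"].to_numpy(float)
        )
        return tracked & finite

    def equals(self, other: "Recording") -> bool:
        if (
            self.participant_id != other.participant_id
            or self.age_group != other.age_group
            or self.sample_rate != other.sample_rate
            or self.geometry != other.geometry
            or len(self) != len(other)
        ):
            return False
        a, b = self.samples, other.samples
        for c in ("t", "gaze_x", "gaze_y", "pupil_left", "pupil_right"):
            x = a[c].to_numpy(float)
            y = b[c].to_numpy(float)
            if not np.array_equal(x, y, equal_nan=True):
                return False
        for c in ("valid_left", "valid_right"):
            if not np.array_equal(a[c].to_numpy(bool), b[c].to_numpy(bool)):
                return False
        return True


def _check_sample_stream(samples: pd.DataFrame, sample_rate: float) -> None:
    t = samples["t"].to_numpy(float)
    if len(t) >= 2:
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            row = int(bad[0]) + 1  # index of the offending sample, 0-based header-free
            raise ValidationError(
                f"timestamps not strictly increasing: first violation at data row {row + 1}"
            )
        median_isi = float(np.median(dt))
        nominal = 1.0 / sample_rate
        if abs(median_isi - nominal) > ISI_TOLERANCE * nominal:
            raise ValidationError(
                f"median inter-sample interval {median_isi:.6f}s deviates more than "
                f"{ISI_TOLERANCE:.0%} from 1/sample_rate = {nominal:.6f}s"
            )


# ---------------------------------------------------------------------------
# recording.tsv


def _parse_bool(token: str) -> bool | None:
    if token in ("1", "true", "True"):
        return True
    if token in ("0", "false", "False", ""):
        return False
    return None


def _parse_float(token: str) -> float:
    if token == "":
        return math.nan
    return float(token)  # may raise ValueError


def read_recording(
    path: str | Path,
    geometry: ScreenGeometry | None = None,
    *,
    participant_id: str | None = None,
    age_group: str = "6mo",
    sample_rate: float = 60.0,
) -> Recording:
    """Read a ``recording.tsv`` sample stream.

    Rows whose non-time numerics fail to parse become invalid samples (both
    validity flags cleared); rows with an unparseable timestamp are rejected
    and counted in ``Recording.n_rejected_rows`` (and logged), never silently
    dropped. A missing mandatory column raises :class:`FormatError`;
    non-monotonic timestamps raise :class:`ValidationError` citing the first
    offending data row.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t") if header_line else []
        for col in RECORDING_COLUMNS:
            if col not in header:
                raise FormatError(f"{path.name}: missing mandatory column '{col}'")
        idx = {c: header.index(c) for c in RECORDING_COLUMNS}
        rows: list[tuple] = []
        n_rejected = 0
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1 and fields[0] == "":
                continue  # trailing blank line
            if len(fields) < len(header):
                fields += [""] * (len(header) - len(fields))
            try:
                t = float(fields[idx["t"]])
            except ValueError:
                n_rejected += 1
                log.warning("%s line %d: unparseable timestamp, row rejected", path.name, lineno)
                continue
            ok = True
            nums = {}
            for c in ("gaze_x", "gaze_y", "pupil_left", "pupil_right"):
                try:
                    nums[c] = _parse_float(fields[idx[c]])
                except ValueError:
                    nums[c] = math.nan
                    ok = False
            vl = _parse_bool(fields[idx["valid_left"]])
            vr = _parse_bool(fields[idx["valid_right"]])
            if vl is None or vr is None:
                vl = vr = False
                ok = False
            if not ok:
                vl = vr = False
                log.warning("%s line %d: unparseable numerics, sample marked invalid", path.name, lineno)
            rows.append((t, nums["gaze_x"], nums["gaze_y"], nums["pupil_left"], nums["pupil_right"], vl, vr))
    samples = pd.DataFrame(rows, columns=RECORDING_COLUMNS)
    samples = samples.astype(
        {c: float for c in RECORDING_COLUMNS[:5]} | {"valid_left": bool, "valid_right": bool}
    )
    return Recording(
        participant_id=participant_id if participant_id is not None else path.stem,
        age_group=age_group,
        sample_rate=sample_rate,
        geometry=geometry if geometry is not None else ScreenGeometry(),
        samples=samples,
        n_rejected_rows=n_rejected,
    )


def _fmt_float(v: float) -> str:
    if v is None or not math.isfinite(v):
        return ""
    return repr(float(v))


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write ``recording.samples`` as TSV, re-readable at full precision."""
    path = Path(path)
    s = recording.samples
    cols = [s[c].to_numpy(float) for c in RECORDING_COLUMNS[:5]]
    vl = s["valid_left"].to_numpy(bool)
    vr = s["valid_right"].to_numpy(bool)
    lines = ["\t".join(RECORDING_COLUMNS)]
    for i in range(len(s)):
        lines.append(
            "\t".join(
                [_fmt_float(col[i]) for col in cols]
                + ["1" if vl[i] else "0", "1" if vr[i] else "0"]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# trials.tsv


@dataclass(frozen=True)
class TrialAnnotation:
    """Per-trial event timestamps and condition labels (recording clock)."""

    participant_id: str
    trial_id: str
    task: str  # "prediction" | "evaluation"
    condition: str  # "appropriate" | "inappropriate" | "n/a"
    food_pickup_t: float | None = None
    spoon_leaves_bowl_t: float | None = None
    spoon_reaches_mouth_t: float | None = None
    grasp_t: float | None = None

    def __post_init__(self) -> None:
        if self.task == "prediction":
            times = (self.food_pickup_t, self.spoon_leaves_bowl_t, self.spoon_reaches_mouth_t)
            if any(v is None for v in times):
                raise ValidationError(
                    f"trial {self.trial_id}: prediction trial requires food_pickup_t, "
                    "spoon_leaves_bowl_t and spoon_reaches_mouth_t"
                )
            if not (times[0] < times[1] < times[2]):
                raise ValidationError(
                    f"trial {self.trial_id}: event times must satisfy "
                    "food_pickup_t < spoon_leaves_bowl_t < spoon_reaches_mouth_t"
                )
        elif self.task == "evaluation":
            if self.condition not in ("appropriate", "inappropriate"):
                raise ValidationError(
                    f"trial {self.trial_id}: evaluation trial missing/invalid field 'condition'"
                )
            if self.grasp_t is None:
                raise ValidationError(f"trial {self.trial_id}: evaluation trial missing field 'grasp_t'")
            if self.grasp_t < 1.0:
                raise ValidationError(
                    f"trial {self.trial_id}: grasp_t must be >= 1.0 s into the data "
                    "so the baseline window fits"
                )
        else:
            raise ValidationError(f"trial {self.trial_id}: unknown task '{self.task}'")


def read_trials(path: str | Path) -> list[TrialAnnotation]:
    """Read ``trials.tsv`` into validated annotations, ordered as on disk."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column '{col}'")

    def opt(v: str) -> float | None:
        if v == "":
            return None
        try:
            return float(v)
        except ValueError as e:
            raise FormatError(f"{path.name}: unparseable time value {v!r}") from e

    out = []
    for rec in df.to_dict("records"):
        out.append(
            TrialAnnotation(
                participant_id=rec["participant_id"],
                trial_id=rec["trial_id"],
                task=rec["task"],
                condition=rec["condition"] if rec["condition"] else "n/a",
                food_pickup_t=opt(rec["food_pickup_t"]),
                spoon_leaves_bowl_t=opt(rec["spoon_leaves_bowl_t"]),
                spoon_reaches_mouth_t=opt(rec["spoon_reaches_mouth_t"]),
                grasp_t=opt(rec["grasp_t"]),
            )
        )
    return out


def write_trials(trials: Sequence[TrialAnnotation], path: str | Path) -> None:
    lines = ["\t".join(TRIAL_COLUMNS)]
    for a in trials:
        lines.append(
            "\t".join(
                [
                    a.participant_id,
                    a.trial_id,
                    a.task,
                    a.condition,
                    _fmt_float(a.food_pickup_t) if a.food_pickup_t is not None else "",
                    _fmt_float(a.spoon_leaves_bowl_t) if a.spoon_leaves_bowl_t is not None else "",
                    _fmt_float(a.spoon_reaches_mouth_t) if a.spoon_reaches_mouth_t is not None else "",
                    _fmt_float(a.grasp_t) if a.grasp_t is not None else "",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def trials_for(trials: Iterable[TrialAnnotation], participant_id: str, task: str) -> list[TrialAnnotation]:
    return [a for a in trials if a.participant_id == participant_id and a.task == task]


# ---------------------------------------------------------------------------
# reaches.tsv


@dataclass(frozen=True)
class ReachCodingRow:
    """One human-coded reaching trial.

    The 3 cm movement criterion and the follow-event requirement are coder
    judgements, carried here as the ``reach_valid`` boolean; ``attended_ok``
    is the attention/posture criterion applied before anything else.
    """

    participant_id: str
    trial_index: int
    speed: str  # "slow" | "fast"
    attended_ok: bool
    object_start_t: float
    reach_onset_t: float | None
    midline_t: float
    reach_valid: bool
    caught: bool

    def __post_init__(self) -> None:
        if self.speed not in ("slow", "fast"):
            raise ValidationError(f"reach trial {self.trial_index}: unknown speed '{self.speed}'")
        if self.reach_valid and self.reach_onset_t is None:
            raise ValidationError(
                f"reach trial {self.trial_index}: reach_valid requires reach_onset_t"
            )


def read_reaches(path: str | Path) -> list[ReachCodingRow]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REACH_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column '{col}'")
    out = []
    for rec in df.to_dict("records"):
        vb = {k: _parse_bool(rec[k]) for k in ("attended_ok", "reach_valid", "caught")}
        if any(v is None for v in vb.values()):
            raise FormatError(f"{path.name}: unparseable boolean in reach row {rec['trial_index']}")
        out.append(
            ReachCodingRow(
                participant_id=rec["participant_id"],
                trial_index=int(rec["trial_index"]),
                speed=rec["speed"],
                attended_ok=vb["attended_ok"],
                object_start_t=float(rec["object_start_t"]),
                reach_onset_t=None if rec["reach_onset_t"] == "" else float(rec["reach_onset_t"]),
                midline_t=float(rec["midline_t"]),
                reach_valid=vb["reach_valid"],
                caught=vb["caught"],
            )
        )
    return out


def write_reaches(rows: Sequence[ReachCodingRow], path: str | Path) -> None:
    lines = ["\t".join(REACH_COLUMNS)]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.participant_id,
                    str(r.trial_index),
                    r.speed,
                    "1" if r.attended_ok else "0",
                    _fmt_float(r.object_start_t),
                    _fmt_float(r.reach_onset_t) if r.reach_onset_t is not None else "",
                    _fmt_float(r.midline_t),
                    "1" if r.reach_valid else "0",
                    "1" if r.caught else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
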