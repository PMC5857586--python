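"""Recording / trial / reach table I/O: dialects, validation, round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_recording
from gazepipe.errors import FormatError, ValidationError
from gazepipe.recording_io import (
    ReachCodingRow,
    TrialAnnotation,
    read_recording,
    read_reaches,
    read_trials,
    write_reaches,
    write_recording,
    write_trials,
)

HEADER = "t\tgaze_x\tgaze_y\tpupil_left\tpupil_right\tvalid_left\tvalid_right"


def test_well_formed_file_round_trips(tmp_path):
    path = tmp_path / "r.tsv"
    path.write_text(
        HEADER + "\n"
        "0.0\t100.0\t200.0\t3.1\t3.2\t1\t1\n"
        "0.016666666666666666\t101.0\t201.0\t3.1\t\t1\t0\n"
        "0.03333333333333333\t102.0\t202.0\t\t\t0\t0\n"
    )
    rec = read_recording(path, participant_id="p1")
    assert len(rec) == 3
    assert rec.n_rejected_rows == 0
    assert np.isnan(rec.samples["pupil_right"].iloc[1])
    assert list(rec.gaze_valid()) == [True, True, False]


def test_missing_column_raises_format_error_naming_it(tmp_path):
    path = tmp_path / "r.tsv"
    path.write_text("t\tgaze_x\tgaze_y\tpupil_left\tpupil_right\tvalid_left\n0.0\t1\t1\t3\t3\t1\n")
    with pytest.raises(FormatError, match="valid_right"):
        read_recording(path)


def test_decreasing_timestamps_cite_offending_row(tmp_path):
    path = tmp_path / "r.tsv"
    path.write_text(
        HEADER + "\n0.0\t1\t1\t3\t3\t1\t1\n-0.5\t1\t1\t3\t3\t1\t1\n0.1\t1\t1\t3\t3\t1\t1\n"
    )
    with pytest.raises(ValidationError, match="row 2"):
        read_recording(path)


def test_unparseable_numerics_become_invalid_samples_not_failures(tmp_path):
    path = tmp_path / "r.tsv"
    path.write_text(
        HEADER + "\n"
        "0.0\t100.0\t200.0\t3.1\t3.2\t1\t1\n"
        "0.016666666666666666\tbroken\t201.0\t3.1\t3.2\t1\t1\n"
        "oops\t1\t1\t3\t3\t1\t1\n"
        "0.03333333333333333\t102.0\t202.0\t3.1\t3.2\t1\t1\n"
    )
    rec = read_recording(path)
    # no row silently dropped: samples + rejected == data lines
    assert len(rec) + rec.n_rejected_rows == 4
    assert rec.n_rejected_rows == 1  # the unparseable timestamp
    assert not rec.gaze_valid()[1]  # broken gaze -> invalid sample


def test_isi_far_from_nominal_rejected():
    with pytest.raises(ValidationError, match="inter-sample"):
        make_recording(t=np.arange(20) / 30.0, x=np.zeros(20), y=np.zeros(20), sample_rate=60.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_recording_round_trip_randomized(tmp_path_factory, seed):
    """read(write(R)) == R with bit-equal values, and write∘read idempotent."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(0, 80))
    t = np.arange(n) / 60.0
    x = rng.uniform(0, 1920, n)
    y = rng.uniform(0, 1080, n)
    x[rng.random(n) < 0.1] = np.nan
    pl = rng.uniform(2.0, 6.0, n)
    pr = rng.uniform(2.0, 6.0, n)
    pl[rng.random(n) < 0.2] = np.nan
    valid = rng.random(n) < 0.9
    rec = make_recording(t, x, y, valid, pl, pr)
    d = tmp_path_factory.mktemp("rt")
    write_recording(rec, d / "a.tsv")
    back = read_recording(d / "a.tsv", participant_id="p000")
    assert back.equals(rec)
    write_recording(back, d / "b.tsv")
    assert (d / "a.tsv").read_bytes() == (d / "b.tsv").read_bytes()


def test_empty_recording_writes_header_only(tmp_path):
    rec = make_recording(t=[], x=[], y=[])
    write_recording(rec, tmp_path / "empty.tsv")
    assert (tmp_path / "empty.tsv").read_text() == HEADER + "\n"


# ---------------------------------------------------------------------------
# Trials


def test_prediction_trial_requires_ordered_times():
    with pytest.raises(ValidationError, match="food_pickup_t < spoon_leaves_bowl_t"):
        TrialAnnotation("p", "t1", "prediction", "n/a", 2.0, 5.6, 5.5)


def test_evaluation_trial_missing_condition_names_field():
    with pytest.raises(ValidationError, match="condition"):
        TrialAnnotation("p", "t1", "evaluation", "n/a", grasp_t=2.5)


def test_twelve_trial_evaluation_file_round_trips(tmp_path):
    trials = [
        TrialAnnotation(
            "p0", f"e{i}", "evaluation",
            "appropriate" if i < 6 else "inappropriate", grasp_t=2.5 + 9.0 * i,
        )
        for i in range(12)
    ]
    write_trials(trials, tmp_path / "trials.tsv")
    back = read_trials(tmp_path / "trials.tsv")
    assert len(back) == 12
    conditions = [a.condition for a in back]
    assert conditions.count("appropriate") == 6
    assert conditions.count("inappropriate") == 6
    assert back == trials


def test_single_prediction_row(tmp_path):
    trials = [TrialAnnotation("p0", "t0", "prediction", "n/a", 2.0, 4.0, 5.5)]
    write_trials(trials, tmp_path / "trials.tsv")
    assert read_trials(tmp_path / "trials.tsv") == trials


# ---------------------------------------------------------------------------
# Reaches


def test_reach_valid_requires_onset():
    with pytest.raises(ValidationError, match="reach_onset_t"):
        ReachCodingRow("p", 1, "fast", True, 0.5, None, 2.0, True, False)


def test_reach_table_round_trip(tmp_path):
    rows = [
        ReachCodingRow("p0", 1, "slow", True, 0.5, 2.3, 2.0, True, False),
        ReachCodingRow("p0", 2, "fast", False, 0.5, None, 2.0, False, False),
    ]
    write_reaches(rows, tmp_path / "reaches.tsv")
    assert read_reaches(tmp_path / "reaches.tsv") == rows
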