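"""End-to-end orchestration: raw recordings -> participant summaries -> stats.

Two entry points cover the same analysis path. :func:`run_all` is file-based:
it reads a cohort directory (``recordings/*.tsv``, ``trials.tsv``,
``reaches.tsv``), scores every participant and writes the four reporting
tables plus a provenance file. :func:`simulate_and_summarize` runs the
identical scoring chain on an in-memory synthetic cohort without touching
disk, which is what replicate-based validation (correlation recovery, null
calibration) uses.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    Cohort,
    CohortConfig,
    evaluation_conditions,
    evaluation_trial_rng,
    prediction_trial_rng,
    reach_rng,
    sample_traits,
    simulate_evaluation_trial,
    simulate_prediction_trial,
    simulate_reach_rows,
)
from .errors import GazepipeError
from .fixation import FilterParams, detect_fixations, detect_fixations_arrays
from .geometry import ScreenGeometry
from .prediction import (
    AOI,
    ParticipantPredictionScore,
    aggregate_prediction,
    aoi_to_pixels,
    score_prediction_trial,
)
from .pupil import (
    CleaningParams,
    ParticipantDilationScore,
    PupilTrace,
    aggregate_dilation,
    clean_matrix,
    clean_pupil,
    combine_eyes,
    score_dilation_trial,
)
from .reach import ParticipantReachScore, aggregate_reach
from .recording_io import (
    ReachCodingRow,
    Recording,
    TrialAnnotation,
    read_reaches,
    read_recording,
    read_trials,
    trials_for,
)
from .stats import (
    classify_cohort,
    correlation_matrix,
    correlation_table,
    one_sample_t,
    orient_variables,
    skewness,
)

SUMMARY_MEASURES = ["prediction_latency_ms", "dilation_difference_mm", "reach_latency_s"]


@dataclass(frozen=True)
class AnalysisParams:
    """Every tunable of the scoring chain, defaulting to the published values."""

    filter_params: FilterParams = field(default_factory=FilterParams)
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    post_arrival_window_s: float = 1.0
    min_prediction_trials: int = 2
    baseline_ms: float = 1000.0
    analysis_ms: float = 3000.0
    min_valid_fraction: float = 0.5
    min_trials_per_condition: int = 3
    min_reach_trials: int = 1
    aoi_width_deg: float = 6.3
    aoi_height_deg: float = 3.8
    bowl_center: tuple[float, float] = (760.0, 800.0)
    mouth_center: tuple[float, float] = (760.0, 300.0)

    def aoi_rects(self, geometry: ScreenGeometry):
        bowl = AOI("bowl", *self.bowl_center, self.aoi_width_deg, self.aoi_height_deg)
        mouth = AOI("mouth", *self.mouth_center, self.aoi_width_deg, self.aoi_height_deg)
        return aoi_to_pixels(bowl, geometry), aoi_to_pixels(mouth, geometry)


def score_participant_prediction(
    recording: Recording,
    annotations: Sequence[TrialAnnotation],
    params: AnalysisParams = AnalysisParams(),
) -> ParticipantPredictionScore:
    """Fixation-filter a recording and score its eating-action trials."""
    bowl_rect, mouth_rect = params.aoi_rects(recording.geometry)
    fixations = detect_fixations(recording, params.filter_params)
    scores = [
        score_prediction_trial(fixations, a, bowl_rect, mouth_rect, params.post_arrival_window_s)
        for a in annotations
    ]
    return aggregate_prediction(scores, recording.participant_id, params.min_prediction_trials)


def score_participant_dilation(
    recording: Recording,
    annotations: Sequence[TrialAnnotation],
    params: AnalysisParams = AnalysisParams(),
) -> ParticipantDilationScore:
    """Clean the recording's pupil series once, then score each giving trial."""
    trace = clean_pupil(combine_eyes(recording.samples), params.cleaning)
    dil = [
        score_dilation_trial(
            trace,
            a.grasp_t,
            trial_id=a.trial_id,
            condition=a.condition,
            baseline_ms=params.baseline_ms,
            analysis_ms=params.analysis_ms,
            min_valid_fraction=params.min_valid_fraction,
        )
        for a in annotations
    ]
    return aggregate_dilation(dil, recording.participant_id, params.min_trials_per_condition)


def build_summary(
    prediction: Sequence[ParticipantPredictionScore],
    dilation: Sequence[ParticipantDilationScore],
    reach: Sequence[ParticipantReachScore],
) -> pd.DataFrame:
    """One row per participant; excluded measures are NaN with flags False."""
    pred = {s.participant_id: s for s in prediction}
    dil = {s.participant_id: s for s in dilation}
    rch = {s.participant_id: s for s in reach}
    pids = sorted(set(pred) | set(dil) | set(rch))
    rows = []
    for pid in pids:
        p, d, r = pred.get(pid), dil.get(pid), rch.get(pid)
        rows.append(
            {
                "participant_id": pid,
                "prediction_latency_ms": p.mean_latency_ms if p and p.included else np.nan,
                "prediction_included": bool(p.included) if p else False,
                "prediction_n_trials": p.n_valid_trials if p else 0,
                "dilation_difference_mm": d.difference if d and d.included else np.nan,
                "dilation_included": bool(d.included) if d else False,
                "reach_latency_s": r.mean_latency_s if r and r.included else np.nan,
                "reach_included": bool(r.included) if r else False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# In-memory synthetic path (identical scoring chain, no file round-trip)


@dataclass
class CohortScores:
    summary: pd.DataFrame
    prediction: list[ParticipantPredictionScore]
    dilation: list[ParticipantDilationScore]
    reach: list[ParticipantReachScore]
    traits: pd.DataFrame


def simulate_and_summarize(
    config: CohortConfig, params: AnalysisParams = AnalysisParams()
) -> CohortScores:
    """Generate a cohort trial by trial and push it through the full scoring
    chain: raw samples -> fixation filter -> AOI scoring for prediction;
    raw pupil -> four-step cleaning -> window scoring for evaluation; coded
    table -> fast-trial mean for reaching.

    Evaluation traces are cleaned as one batch (rows are independent trials),
    which keeps replicate studies fast without changing any result.
    """
    traits = sample_traits(config)
    bowl_rect, mouth_rect = params.aoi_rects(config.geometry)
    lay = config.layout
    rate = config.sample_rate

    pred_scores: list[ParticipantPredictionScore] = []
    eval_rows: list[np.ndarray] = []
    eval_meta: list[tuple[int, str, str]] = []  # participant index, trial id, condition
    reach_scores: list[ParticipantReachScore] = []

    for i, row in enumerate(traits.itertuples(index=False)):
        pid = row.participant_id
        trial_scores = []
        for j in range(config.counts.prediction):
            ts, ev = simulate_prediction_trial(
                row.theta_pred_ms, config, prediction_trial_rng(config, i, j)
            )
            ann = TrialAnnotation(
                participant_id=pid,
                trial_id=f"{pid}_pred{j:02d}",
                task="prediction",
                condition="n/a",
                food_pickup_t=ev["food_pickup_t"],
                spoon_leaves_bowl_t=ev["spoon_leaves_bowl_t"],
                spoon_reaches_mouth_t=ev["spoon_reaches_mouth_t"],
            )
            fixations = detect_fixations_arrays(ts.t, ts.gaze_x, ts.gaze_y, ts.valid, params.filter_params)
            trial_scores.append(
                score_prediction_trial(fixations, ann, bowl_rect, mouth_rect, params.post_arrival_window_s)
            )
        pred_scores.append(aggregate_prediction(trial_scores, pid, params.min_prediction_trials))

        for j, condition in enumerate(evaluation_conditions(config, i)):
            ts, ev = simulate_evaluation_trial(
                row.theta_eval_mm, condition, config, evaluation_trial_rng(config, i, j)
            )
            values = np.where(ts.valid, ts.pupil, np.nan)
            eval_rows.append(values)
            eval_meta.append((i, f"{pid}_eval{j:02d}", condition))

        reach_rows = simulate_reach_rows(row.theta_motor_ms, pid, config, reach_rng(config, i))
        reach_scores.append(aggregate_reach(reach_rows, pid, min_trials=params.min_reach_trials))

    # Batched pupil cleaning and per-trial scoring.
    n_eval = round(lay.evaluation_trial_s * rate)
    t_eval = np.arange(n_eval) / rate
    cleaned = clean_matrix(np.vstack(eval_rows), params.cleaning) if eval_rows else np.empty((0, 0))
    per_participant: dict[int, list] = {i: [] for i in range(config.n_participants)}
    for (i, trial_id, condition), values in zip(eval_meta, cleaned):
        per_participant[i].append(
            score_dilation_trial(
                PupilTrace(t_eval, values),
                lay.grasp_s,
                trial_id=trial_id,
                condition=condition,
                baseline_ms=params.baseline_ms,
                analysis_ms=params.analysis_ms,
                min_valid_fraction=params.min_valid_fraction,
            )
        )
    dil_scores = [
        aggregate_dilation(per_participant[i], traits["participant_id"].iloc[i],
                           params.min_trials_per_condition)
        for i in range(config.n_participants)
    ]

    summary = build_summary(pred_scores, dil_scores, reach_scores)
    return CohortScores(summary, pred_scores, dil_scores, reach_scores, traits)


def recovered_pred_eval_correlation(scores: CohortScores):
    """Oriented prediction×evaluation Pearson cell from a scored cohort."""
    oriented, _ = orient_variables(scores.summary)
    cells = correlation_matrix(oriented, ["prediction_latency_ms", "dilation_difference_mm"])
    return cells[("prediction_latency_ms", "dilation_difference_mm")]


# ---------------------------------------------------------------------------
# File-based run


def analyze_cohort_dir(
    in_dir: str | Path,
    params: AnalysisParams = AnalysisParams(),
    geometry: ScreenGeometry | None = None,
    sample_rate: float = 60.0,
    age_group: str = "6mo",
) -> CohortScores:
    """Score every participant found in a cohort directory."""
    in_dir = Path(in_dir)
    trials = read_trials(in_dir / "trials.tsv")
    reaches = read_reaches(in_dir / "reaches.tsv")
    rec_paths = sorted((in_dir / "recordings").glob("*.tsv"))
    pred_scores, dil_scores = [], []
    for path in rec_paths:
        rec = read_recording(path, geometry, age_group=age_group, sample_rate=sample_rate)
        pred_scores.append(
            score_participant_prediction(rec, trials_for(trials, rec.participant_id, "prediction"), params)
        )
        dil_scores.append(
            score_participant_dilation(rec, trials_for(trials, rec.participant_id, "evaluation"), params)
        )
    by_pid: dict[str, list[ReachCodingRow]] = {}
    for r in reaches:
        by_pid.setdefault(r.participant_id, []).append(r)
    reach_scores = [
        aggregate_reach(rows, pid, min_trials=params.min_reach_trials)
        for pid, rows in sorted(by_pid.items())
    ]
    summary = build_summary(pred_scores, dil_scores, reach_scores)
    truth_path = in_dir / "truth.tsv"
    traits = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else pd.DataFrame()
    return CohortScores(summary, pred_scores, dil_scores, reach_scores, traits)


def _fmt_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")


def write_stats_outputs(scores: CohortScores, out_dir: str | Path) -> dict[str, Path]:
    """Write summary/correlations/ttests/classification TSVs; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    summary = scores.summary
    paths["summary"] = out_dir / "summary.tsv"
    _fmt_table(summary, paths["summary"])

    oriented, signs = orient_variables(summary)
    present = [m for m in SUMMARY_MEASURES if m in oriented.columns]
    cells = correlation_matrix(oriented, present)
    corr = correlation_table(cells, present)
    corr["oriented"] = True
    paths["correlations"] = out_dir / "correlations.tsv"
    _fmt_table(corr, paths["correlations"])

    trows = []
    for m in present:
        vals = summary[m].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if len(vals) >= 2 and np.std(vals, ddof=1) > 0:
            r = one_sample_t(vals, 0.0)
            sk = skewness(vals) if len(vals) >= 3 else np.nan
            trows.append(
                {"measure": m, "n": len(vals), "mean": r.mean, "se": r.se,
                 "t": r.t, "df": r.df, "p": r.p, "skewness": sk}
            )
    paths["ttests"] = out_dir / "ttests.tsv"
    _fmt_table(pd.DataFrame(trows), paths["ttests"])

    crow = []
    for task, slist in (("prediction", scores.prediction), ("reach", scores.reach)):
        c = classify_cohort(slist)
        crow.append(
            {
                "task": task,
                "n_predictive": c.n_predictive, "n_reactive": c.n_reactive,
                "n_excluded": c.n_excluded,
                "pct_predictive": c.pct_predictive, "pct_reactive": c.pct_reactive,
                "pct_excluded": c.pct_excluded,
                "pct_predictive_of_included": (
                    c.pct_predictive_of_included if c.pct_predictive_of_included is not None else np.nan
                ),
            }
        )
    paths["classification"] = out_dir / "classification.tsv"
    _fmt_table(pd.DataFrame(crow), paths["classification"])
    return paths


def run_all(
    in_dir: str | Path,
    out_dir: str | Path,
    params: AnalysisParams = AnalysisParams(),
    geometry: ScreenGeometry | None = None,
    sample_rate: float = 60.0,
) -> dict[str, Path]:
    """Score a cohort directory and write all reporting tables + provenance."""
    out_dir = Path(out_dir)
    try:
        scores = analyze_cohort_dir(in_dir, params, geometry, sample_rate)
    except GazepipeError as e:
        raise type(e)(f"stage analyze_cohort_dir failed: {e}") from e
    paths = write_stats_outputs(scores, out_dir)
    provenance = {
        "gazepipe_version": __version__,
        "input_dir": str(Path(in_dir).resolve()),
        "sample_rate": sample_rate,
        "params": asdict(params),
        "geometry": asdict(geometry) if geometry is not None else asdict(ScreenGeometry()),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    ppath = out_dir / "provenance.json"
    ppath.write_text(json.dumps(provenance, indent=2, default=str) + "\n", encoding="utf-8")
    paths["provenance"] = ppath
    return paths
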