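"""Synthetic infant cohorts with known latent traits.

The generator emulates the statistical structure the analysis assumes: each
participant carries three latent abilities — gaze-prediction latency (ms,
negative = predictive), pupil-dilation surprise amplitude (mm), and reach
latency (ms, negative = predictive) — drawn from a trivariate normal whose
correlation structure is configured on the *oriented* scale (high = better
performance). Default means and spreads are the published 6-month group
values (−40 ms, 0.063 mm, −380 ms; SDs recovered from the printed standard
errors as SE·√n ≈ 418 ms, 0.139 mm, 357 ms), and the default oriented
correlations are the published 6-month cells (prediction×evaluation 0.34,
prediction×motor 0.33, evaluation×motor 0.12).

Each trait is then expressed through raw 60 Hz recordings: eating-action
trials place a bowl fixation through the pickup window, a 2-sample saccade,
and a mouth fixation whose onset embeds the trial latency; block-giving trials
add a gamma-shaped pupil response (peak ~1.2 s) scaled by the dilation trait
on inappropriate trials only, on top of a per-trial baseline ~N(3.5, 0.2) mm.
Blinks (missing runs of geometric length), out-of-range spikes and per-task
trial dropout exercise the cleaning and inclusion rules. The pupil kernel is
normalized so that its mean over the 3 s analysis window on the sampling grid
equals 1: the amplitude parameter *is* the expected baseline-corrected change
score, which is what parameter-recovery checks compare against. The kernel is
a generator-side assumption only; nothing in the scoring modules knows it.

All randomness flows from ``numpy`` ``SeedSequence`` streams keyed by
``(seed, stream, participant, trial)`` so any subset of the cohort regenerates
identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geometry import ScreenGeometry
from .recording_io import (
    RECORDING_COLUMNS,
    ReachCodingRow,
    Recording,
    TrialAnnotation,
    write_reaches,
    write_recording,
    write_trials,
)

# Stream identifiers for seed derivation.
_STREAM_TRAITS = 0
_STREAM_PREDICTION = 1
_STREAM_EVALUATION = 2
_STREAM_REACH = 3


@dataclass(frozen=True)
class TrialCounts:
    prediction: int = 6
    evaluation_per_condition: int = 6  # 6 appropriate + 6 inappropriate
    slow_reaches: int = 3
    fast_reaches: int = 3


@dataclass(frozen=True)
class TraitModel:
    """Latent ability distribution (means/SDs on the raw measurement scale)."""

    mean_prediction_ms: float = -40.0
    mean_dilation_mm: float = 0.063
    mean_reach_ms: float = -380.0
    sd_prediction_ms: float = 418.0
    sd_dilation_mm: float = 0.139
    sd_reach_ms: float = 357.0
    #: Correlations on the oriented (high = better) scale:
    #: order (prediction, evaluation, motor).
    correlations: tuple[tuple[float, ...], ...] = (
        (1.0, 0.34, 0.33),
        (0.34, 1.0, 0.12),
        (0.33, 0.12, 1.0),
    )
    distribution: str = "normal"  # "normal" | "student_t"
    t_df: float = 8.0

    def correlation_array(self) -> np.ndarray:
        c = np.asarray(self.correlations, float)
        if c.shape != (3, 3) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ConfigError("trait correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-9:
            raise ConfigError("trait correlation matrix must be positive semi-definite")
        return c


@dataclass(frozen=True)
class NoiseModel:
    latency_sd_ms: float = 150.0  # trial-to-trial gaze-latency noise
    pupil_sd_mm: float = 0.05  # per-sample pupil noise
    reach_sd_ms: float = 100.0  # trial-to-trial reach-latency noise
    gaze_jitter_px: float = 2.0  # fixational jitter (below the velocity threshold)
    baseline_mean_mm: float = 3.5
    baseline_sd_mm: float = 0.2


@dataclass(frozen=True)
class ArtifactModel:
    """Blink / spike / dropout rates.

    Per-task trial dropout matches the published data yield: ~3.5 of 6 valid
    eating-action trials, ~5.5 of 6 valid giving trials, ~1.4 of 3 fast reach
    trials.
    """

    blink_rate_hz: float = 0.10  # blinks per second of recording
    blink_mean_samples: float = 6.0  # geometric mean length
    spike_rate_hz: float = 0.05  # out-of-range pupil artifacts per second
    dropout_prediction: float = 0.42
    dropout_evaluation: float = 0.07
    dropout_reach: float = 0.55

    def __post_init__(self) -> None:
        for p in (self.dropout_prediction, self.dropout_evaluation, self.dropout_reach):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("dropout probabilities must lie in [0, 1]")


_KERNEL_NORM_CACHE: dict = {}


@dataclass(frozen=True)
class PupilKernel:
    """Gamma-shaped dilation response; ``peak_s`` is the mode."""

    peak_s: float = 1.2
    shape: float = 2.0

    def __post_init__(self) -> None:
        if self.shape <= 1.0 or self.peak_s <= 0:
            raise ConfigError("kernel requires shape > 1 and peak_s > 0")

    def _raw(self, x: np.ndarray) -> np.ndarray:
        scale = self.peak_s / (self.shape - 1.0)
        x = np.asarray(x, float)
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.power(x[pos], self.shape - 1.0) * np.exp(-x[pos] / scale)
        return out

    def norm_constant(self, sample_rate: float, analysis_s: float = 3.0) -> float:
        """Mean of the un-normalized kernel over the analysis window grid."""
        key = (sample_rate, analysis_s)
        cached = _KERNEL_NORM_CACHE.get((self, key))
        if cached is None:
            grid = np.arange(round(analysis_s * sample_rate)) / sample_rate
            cached = float(np.mean(self._raw(grid)))
            _KERNEL_NORM_CACHE[(self, key)] = cached
        return cached

    def values(self, tau: np.ndarray, sample_rate: float, analysis_s: float = 3.0) -> np.ndarray:
        """Kernel evaluated at lags ``tau`` (s), normalized so its mean over
        the analysis window on the sampling grid is 1."""
        return self._raw(tau) / self.norm_constant(sample_rate, analysis_s)


@dataclass(frozen=True)
class StimulusLayout:
    """Event times (s, within-trial) and AOI placement for synthetic stimuli."""

    bowl_center: tuple[float, float] = (760.0, 800.0)
    mouth_center: tuple[float, float] = (760.0, 300.0)
    aoi_width_deg: float = 6.3
    aoi_height_deg: float = 3.8
    eval_gaze_center: tuple[float, float] = (960.0, 540.0)
    prediction_trial_s: float = 9.0
    food_pickup_s: float = 2.0
    spoon_leaves_bowl_s: float = 4.0
    spoon_reaches_mouth_s: float = 5.5
    evaluation_trial_s: float = 9.0
    grasp_s: float = 2.5
    reach_object_start_s: float = 0.5
    reach_midline_s: float = 2.0


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 118
    seed: int = 0
    age_group: str = "6mo"
    sample_rate: float = 60.0
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    counts: TrialCounts = field(default_factory=TrialCounts)
    traits: TraitModel = field(default_factory=TraitModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    artifacts: ArtifactModel = field(default_factory=ArtifactModel)
    kernel: PupilKernel = field(default_factory=PupilKernel)
    layout: StimulusLayout = field(default_factory=StimulusLayout)

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.sample_rate <= 0:
            raise ConfigError("n_participants and sample_rate must be positive")
        self.traits.correlation_array()  # validate eagerly

    def with_pred_eval_correlation(self, rho: float) -> "CohortConfig":
        """Convenience: replace the oriented prediction×evaluation correlation."""
        c = self.traits.correlation_array()
        c[0, 1] = c[1, 0] = rho
        return replace(self, traits=replace(self.traits, correlations=tuple(map(tuple, c))))


def _rng(config: CohortConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, *key)))


def participant_ids(config: CohortConfig) -> list[str]:
    return [f"p{i:03d}" for i in range(config.n_participants)]


def sample_traits(config: CohortConfig) -> pd.DataFrame:
    """Draw latent traits; columns theta_pred_ms, theta_eval_mm, theta_motor_ms.

    Traits are sampled as oriented abilities (high = better) with the
    configured correlation matrix, then mapped to the raw measurement scale
    (latencies are sign-flipped). Deterministic under the config seed.
    """
    tm = config.traits
    corr = tm.correlation_array()
    sds = np.array([tm.sd_prediction_ms, tm.sd_dilation_mm, tm.sd_reach_ms])
    cov = corr * np.outer(sds, sds)
    rng = _rng(config, _STREAM_TRAITS)
    n = config.n_participants
    if tm.distribution == "normal":
        z = rng.multivariate_normal(np.zeros(3), cov, size=n, method="eigh")
    elif tm.distribution == "student_t":
        g = rng.multivariate_normal(np.zeros(3), cov, size=n, method="eigh")
        w = rng.chisquare(tm.t_df, size=n) / tm.t_df
        z = g / np.sqrt(w)[:, None] * math.sqrt((tm.t_df - 2.0) / tm.t_df)
    else:
        raise ConfigError(f"unknown trait distribution '{tm.distribution}'")
    oriented_means = np.array(
        [-tm.mean_prediction_ms, tm.mean_dilation_mm, -tm.mean_reach_ms]
    )
    oriented = oriented_means + z
    return pd.DataFrame(
        {
            "participant_id": participant_ids(config),
            "theta_pred_ms": -oriented[:, 0],
            "theta_eval_mm": oriented[:, 1],
            "theta_motor_ms": -oriented[:, 2],
        }
    )


@dataclass
class TrialSamples:
    """Raw samples of one simulated trial, on the within-trial clock."""

    t: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    pupil: np.ndarray  # both eyes share one diameter series
    valid: np.ndarray


def _inject_blinks(valid: np.ndarray, rate_hz: float, mean_len: float,
                   sample_rate: float, rng: np.random.Generator) -> None:
    n = len(valid)
    n_blinks = rng.poisson(rate_hz * n / sample_rate)
    for _ in range(n_blinks):
        start = int(rng.integers(0, n))
        length = int(rng.geometric(1.0 / mean_len))
        valid[start : min(n, start + length)] = False


def simulate_prediction_trial(
    theta_pred_ms: float, config: CohortConfig, rng: np.random.Generator
) -> tuple[TrialSamples, dict[str, float]]:
    """One eating-action trial embedding the participant's latency trait.

    Gaze holds the bowl AOI from trial start through the pickup window, makes
    a 2-sample saccade, and holds the mouth AOI from an onset at
    ``arrival + theta + N(0, latency_sd)``. The latency is truncated to what
    the trial's event geometry can express. With probability
    ``dropout_prediction`` the scoring span is invalid (inattention).
    """
    lay, noise, art = config.layout, config.noise, config.artifacts
    rate = config.sample_rate
    n = round(lay.prediction_trial_s * rate)
    t = np.arange(n) / rate
    leaves_idx = round(lay.spoon_leaves_bowl_s * rate)

    latency_s = (theta_pred_ms + rng.normal(0.0, noise.latency_sd_ms)) / 1000.0
    lo = (leaves_idx + 3) / rate - lay.spoon_reaches_mouth_s
    hi = 0.9  # keep the mouth fixation inside the 1 s post-arrival window
    latency_s = min(max(latency_s, lo), hi)
    m0 = round((lay.spoon_reaches_mouth_s + latency_s) * rate)

    bx, by = lay.bowl_center
    mx, my = lay.mouth_center
    x = np.full(n, bx)
    y = np.full(n, by)
    # 2-sample saccade immediately before the mouth fixation onset.
    x[m0 - 2] = bx + (mx - bx) / 3.0
    y[m0 - 2] = by + (my - by) / 3.0
    x[m0 - 1] = bx + 2.0 * (mx - bx) / 3.0
    y[m0 - 1] = by + 2.0 * (my - by) / 3.0
    x[m0:] = mx
    y[m0:] = my
    if noise.gaze_jitter_px > 0:
        x = x + rng.normal(0.0, noise.gaze_jitter_px, n)
        y = y + rng.normal(0.0, noise.gaze_jitter_px, n)

    pupil = noise.baseline_mean_mm + (
        rng.normal(0.0, noise.pupil_sd_mm, n) if noise.pupil_sd_mm > 0 else 0.0
    )
    valid = np.ones(n, bool)
    _inject_blinks(valid, art.blink_rate_hz, art.blink_mean_samples, rate, rng)
    if rng.random() < art.dropout_prediction:
        valid[round(lay.food_pickup_s * rate) :] = False

    events = {
        "food_pickup_t": lay.food_pickup_s,
        "spoon_leaves_bowl_t": lay.spoon_leaves_bowl_s,
        "spoon_reaches_mouth_t": lay.spoon_reaches_mouth_s,
        "true_latency_s": latency_s,
    }
    return TrialSamples(t, x, y, pupil, valid), events


def simulate_evaluation_trial(
    theta_eval_mm: float, condition: str, config: CohortConfig, rng: np.random.Generator
) -> tuple[TrialSamples, dict[str, float]]:
    """One block-giving trial; inappropriate trials carry the dilation response.

    Pupil = per-trial baseline + kernel × amplitude (inappropriate only) +
    white noise; blinks produce missing runs, spikes produce out-of-range
    values, and with probability ``dropout_evaluation`` the whole trial is
    invalid (looked away).
    """
    lay, noise, art = config.layout, config.noise, config.artifacts
    rate = config.sample_rate
    n = round(lay.evaluation_trial_s * rate)
    t = np.arange(n) / rate

    baseline = rng.normal(noise.baseline_mean_mm, noise.baseline_sd_mm)
    amp = theta_eval_mm if condition == "inappropriate" else 0.0
    pupil = baseline + amp * config.kernel.values(t - lay.grasp_s, rate)
    if noise.pupil_sd_mm > 0:
        pupil = pupil + rng.normal(0.0, noise.pupil_sd_mm, n)

    gx, gy = lay.eval_gaze_center
    x = gx + (rng.normal(0.0, noise.gaze_jitter_px, n) if noise.gaze_jitter_px > 0 else 0.0)
    y = gy + (rng.normal(0.0, noise.gaze_jitter_px, n) if noise.gaze_jitter_px > 0 else 0.0)

    valid = np.ones(n, bool)
    _inject_blinks(valid, art.blink_rate_hz, art.blink_mean_samples, rate, rng)
    n_spikes = rng.poisson(art.spike_rate_hz * lay.evaluation_trial_s)
    for _ in range(n_spikes):
        pupil[int(rng.integers(0, n))] = rng.uniform(5.8, 7.5)
    if rng.random() < art.dropout_evaluation:
        valid[:] = False

    return (
        TrialSamples(t, np.asarray(x, float), np.asarray(y, float), pupil, valid),
        {"grasp_t": lay.grasp_s, "true_amplitude_mm": amp},
    )


def simulate_reach_rows(
    theta_motor_ms: float, participant_id: str, config: CohortConfig,
    rng: np.random.Generator,
) -> list[ReachCodingRow]:
    """The participant's coded reach table: slow trials first, then fast."""
    lay, noise, art = config.layout, config.noise, config.artifacts
    rows = []
    idx = 0
    for speed, count in (("slow", config.counts.slow_reaches), ("fast", config.counts.fast_reaches)):
        for _ in range(count):
            idx += 1
            latency_s = (theta_motor_ms + rng.normal(0.0, noise.reach_sd_ms)) / 1000.0
            dropped = rng.random() < art.dropout_reach
            attended = not (dropped and rng.random() < 0.5)
            reach_valid = not dropped
            onset = lay.reach_midline_s + latency_s if reach_valid else None
            rows.append(
                ReachCodingRow(
                    participant_id=participant_id,
                    trial_index=idx,
                    speed=speed,
                    attended_ok=attended,
                    object_start_t=lay.reach_object_start_s,
                    reach_onset_t=onset,
                    midline_t=lay.reach_midline_s,
                    reach_valid=reach_valid,
                    caught=bool(reach_valid and rng.random() < 0.57),
                )
            )
    return rows


def prediction_trial_rng(config: CohortConfig, participant: int, trial: int) -> np.random.Generator:
    return _rng(config, _STREAM_PREDICTION, participant, trial)


def evaluation_trial_rng(config: CohortConfig, participant: int, trial: int) -> np.random.Generator:
    return _rng(config, _STREAM_EVALUATION, participant, trial)


def reach_rng(config: CohortConfig, participant: int) -> np.random.Generator:
    return _rng(config, _STREAM_REACH, participant)


def evaluation_conditions(config: CohortConfig, participant: int) -> list[str]:
    """Deterministic alternating condition order per participant."""
    k = config.counts.evaluation_per_condition
    order = ["appropriate", "inappropriate"] * k
    if participant % 2:
        order = order[::-1]
    return order


@dataclass
class Cohort:
    config: CohortConfig
    traits: pd.DataFrame
    recordings: dict[str, Recording]
    trials: list[TrialAnnotation]
    reaches: list[ReachCodingRow]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the complete cohort: one recording per participant (eating
    trials followed by giving trials on a single clock), the shared trial
    annotation table, and the coded reach table."""
    traits = sample_traits(config)
    recordings: dict[str, Recording] = {}
    all_trials: list[TrialAnnotation] = []
    all_reaches: list[ReachCodingRow] = []
    for i, row in enumerate(traits.itertuples(index=False)):
        pid = row.participant_id
        chunks: list[TrialSamples] = []
        offset = 0.0
        for j in range(config.counts.prediction):
            ts, ev = simulate_prediction_trial(
                row.theta_pred_ms, config, prediction_trial_rng(config, i, j)
            )
            chunks.append(ts)
            all_trials.append(
                TrialAnnotation(
                    participant_id=pid,
                    trial_id=f"{pid}_pred{j:02d}",
                    task="prediction",
                    condition="n/a",
                    food_pickup_t=offset + ev["food_pickup_t"],
                    spoon_leaves_bowl_t=offset + ev["spoon_leaves_bowl_t"],
                    spoon_reaches_mouth_t=offset + ev["spoon_reaches_mouth_t"],
                )
            )
            offset += config.layout.prediction_trial_s
        for j, condition in enumerate(evaluation_conditions(config, i)):
            ts, ev = simulate_evaluation_trial(
                row.theta_eval_mm, condition, config, evaluation_trial_rng(config, i, j)
            )
            chunks.append(ts)
            all_trials.append(
                TrialAnnotation(
                    participant_id=pid,
                    trial_id=f"{pid}_eval{j:02d}",
                    task="evaluation",
                    condition=condition,
                    grasp_t=offset + ev["grasp_t"],
                )
            )
            offset += config.layout.evaluation_trial_s
        recordings[pid] = _assemble_recording(pid, chunks, config)
        all_reaches.extend(
            simulate_reach_rows(row.theta_motor_ms, pid, config, reach_rng(config, i))
        )
    return Cohort(config, traits, recordings, all_trials, all_reaches)


def _assemble_recording(pid: str, chunks: list[TrialSamples], config: CohortConfig) -> Recording:
    rate = config.sample_rate
    parts = []
    offset_samples = 0
    for ts in chunks:
        parts.append(
            pd.DataFrame(
                {
                    "t": (offset_samples + np.arange(len(ts.t))) / rate,
                    "gaze_x": ts.gaze_x,
                    "gaze_y": ts.gaze_y,
                    "pupil_left": ts.pupil,
                    "pupil_right": ts.pupil,
                    "valid_left": ts.valid,
                    "valid_right": ts.valid,
                }
            )
        )
        offset_samples += len(ts.t)
    samples = pd.concat(parts, ignore_index=True)[RECORDING_COLUMNS]
    return Recording(
        participant_id=pid,
        age_group=config.age_group,
        sample_rate=rate,
        geometry=config.geometry,
        samples=samples,
    )


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Emit recordings/<pid>.tsv, trials.tsv, reaches.tsv and truth.tsv.

    The analysis pipeline consumes only the first three; truth.tsv holds the
    latent traits for parameter-recovery checks.
    """
    directory = Path(directory)
    (directory / "recordings").mkdir(parents=True, exist_ok=True)
    for pid, rec in cohort.recordings.items():
        write_recording(rec, directory / "recordings" / f"{pid}.tsv")
    write_trials(cohort.trials, directory / "trials.tsv")
    write_reaches(cohort.reaches, directory / "reaches.tsv")
    cohort.traits.to_csv(directory / "truth.tsv", sep="\t", index=False)
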