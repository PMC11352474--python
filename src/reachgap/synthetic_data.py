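"""Synthetic behavioural sessions and ROI BOLD data with planted structure.

Nothing in the analysis chain requires real recordings: this module
generates (a) reaching trajectories whose horizontal aiming error is
controlled by a small motor-noise model, (b) cohorts of participants with
age/sex/activity covariates, (c) head-motion parameter tables, and (d) ROI
BOLD timeseries in which selected ROI pairs carry an across-subject
connectivity–behaviour association of known slope.

Behavioural model
-----------------
A reach is simulated at 72 Hz.  The hand's horizontal heading is steered
each step toward the direction from the *perceived* hand position to the
target with gain ``reaim_gain``; while the cursor is visible the perceived
position is the rotated cursor, afterwards the true (proprioceptive) hand.
The heading is corrupted by AR(1) directional noise with stationary SD
``heading_noise_sd`` (degrees per step) and persistence
``heading_noise_persistence``; speed follows a bell-shaped (minimum-jerk)
profile.  Straight, accurate reaches emerge at low noise and high gain;
meandering, inaccurate reaches at high noise and low gain.  Cohort-level
defaults are calibrated so that simulated young/middle-aged and older-adult
groups reproduce the mean-gap-angle statistics the analysis is designed
around (about 2.5 +/- 0.8 deg and 18.5 +/- 12.6 deg respectively).

BOLD model
----------
Per subject and run, unit-variance "neural" ROI signals are drawn from a
factor model: planted ROI pairs are sampled with population correlation
``tanh(baseline_z + slope * standardized_score)``; all other pairs share a
weak score-independent background correlation.  Low-frequency drift,
motion-coupled artifact, and white-matter/CSF source leakage are added on
top, to be removed again by the denoising chain.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from math import atan2, cos, hypot, pi, sin, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import Trajectory, ParticipantScore, score_session
from .task_protocol import (
    SessionSchedule,
    TaskGeometry,
    TrialSpec,
    generate_schedule,
    target_point,
)

SAMPLING_RATE_HZ = 72.0
MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


# ---------------------------------------------------------------------------
# Ability profiles and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbilityProfile:
    """Motor-noise parameters of one simulated participant.

    ``heading_noise_sd`` is the stationary SD of the AR(1) heading noise in
    degrees per 72 Hz step; ``reaim_gain`` the per-step fraction of the
    aiming error corrected; ``early_stop_prob`` the probability of ending
    the reach between 90% and 100% extension.
    """

    heading_noise_sd: float
    heading_noise_persistence: float
    reaim_gain: float
    early_stop_prob: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.heading_noise_sd < 0:
            raise ValueError("heading_noise_sd must be >= 0")
        if not 0 <= self.heading_noise_persistence < 1:
            raise ValueError("heading_noise_persistence must be in [0, 1)")
        if not 0 < self.reaim_gain <= 1:
            raise ValueError("reaim_gain must be in (0, 1]")
        if not 0 <= self.early_stop_prob <= 1:
            raise ValueError("early_stop_prob must be in [0, 1]")


# Defaults calibrated against the emulated cohort statistics (see module
# docstring and docs/methods.md); do not retune casually.
YOUNG_DEFAULT = AbilityProfile(
    heading_noise_sd=7.3,
    heading_noise_persistence=0.85,
    reaim_gain=0.4,
    early_stop_prob=0.02,
    label="young_default",
)
OLDER_DEFAULT = AbilityProfile(
    heading_noise_sd=9.1,
    heading_noise_persistence=0.9,
    reaim_gain=0.12,
    early_stop_prob=0.15,
    label="older_default",
)


@dataclass(frozen=True)
class CohortModel:
    """Population a simulated cohort is drawn from.

    Per subject, an :class:`AbilityProfile` is picked from ``profiles`` by
    ``weights`` and its ``heading_noise_sd`` multiplied by a lognormal
    factor with log-SD ``noise_spread_log_sd`` (between-subject
    heterogeneity).  ``score_mean`` / ``score_sd`` are the cohort-level
    mean-gap-angle statistics the profile defaults were calibrated to; they
    also parameterize :func:`sample_subject_records`.
    """

    profiles: tuple[AbilityProfile, ...]
    weights: tuple[float, ...]
    noise_spread_log_sd: float
    age_low: float
    age_high: float
    sex_p: float = 0.5
    activity_probs: tuple[float, ...] = (6 / 40, 24 / 40, 7 / 40, 3 / 40)
    answer_threshold_deg: float = 10.0
    answer_slope_deg: float = 8.0
    false_alarm_rate: float = 0.1
    score_mean: float = 18.5
    score_sd: float = 12.6
    label: str = "custom"


YOUNG_COHORT = CohortModel(
    profiles=(YOUNG_DEFAULT,),
    weights=(1.0,),
    noise_spread_log_sd=0.34,
    age_low=25.0,
    age_high=60.0,
    answer_threshold_deg=8.0,
    score_mean=2.5,
    score_sd=0.8,
    label="young_default",
)
OLDER_COHORT = CohortModel(
    profiles=(OLDER_DEFAULT,),
    weights=(1.0,),
    noise_spread_log_sd=0.75,
    age_low=70.0,
    age_high=85.0,
    answer_threshold_deg=14.0,
    score_mean=18.5,
    score_sd=12.6,
    label="older_default",
)
# Non-default alternative emulating a bimodal older cohort (a low-error and
# a high-error subgroup).
OLDER_BIMODAL = CohortModel(
    profiles=(
        dataclasses.replace(OLDER_DEFAULT, heading_noise_sd=5.0),
        dataclasses.replace(OLDER_DEFAULT, heading_noise_sd=16.0),
    ),
    weights=(12 / 33, 21 / 33),
    noise_spread_log_sd=0.30,
    age_low=70.0,
    age_high=85.0,
    answer_threshold_deg=14.0,
    score_mean=18.5,
    score_sd=12.6,
    label="older_bimodal",
)

_COHORTS = {
    "young_default": YOUNG_COHORT,
    "older_default": OLDER_COHORT,
    "older_bimodal": OLDER_BIMODAL,
}


def resolve_cohort(cohort: str | CohortModel) -> CohortModel:
    if isinstance(cohort, CohortModel):
        return cohort
    try:
        return _COHORTS[cohort]
    except KeyError:
        raise ValueError(
            f"unknown cohort {cohort!r}; options: {sorted(_COHORTS)}"
        ) from None


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

def simulate_trajectory(
    trial: TrialSpec,
    geometry: TaskGeometry,
    profile: AbilityProfile,
    seed_or_rng,
    duration_s: float = 1.0,
    vertical_bow_fraction: float = 0.04,
) -> Trajectory:
    """Simulate one 72 Hz reach for ``trial`` under ``profile``.

    The reach terminates once horizontal extension passes 100% of |OT| (or
    an early-stop point drawn in [90%, 100%) with ``early_stop_prob``), or
    after six nominal movement durations, whichever comes first.  A small
    vertical bow is added so trajectories are genuinely 3D.
    """
    rng = _as_rng(seed_or_rng)
    dt = 1.0 / SAMPLING_RATE_HZ
    origin = geometry.origin_array
    ox, oy, oz = origin
    target = target_point(trial, geometry)
    tx, tz = target[0] - ox, target[2] - oz
    reach = geometry.target_distance
    occl = geometry.cursor_occlusion_fraction

    rot = float(np.deg2rad(trial.rotation_deg))
    cr, sr = cos(rot), sin(rot)
    sd = float(np.deg2rad(profile.heading_noise_sd))
    rho = profile.heading_noise_persistence
    gain = profile.reaim_gain

    if rng.random() < profile.early_stop_prob:
        stop_ext = float(rng.uniform(0.90, 1.0))
    else:
        stop_ext = 1.0

    n_plan = int(round(duration_s / dt))
    max_steps = 6 * n_plan
    innov = rng.standard_normal(max_steps) * (sd * sqrt(1.0 - rho * rho))
    eps = float(rng.normal(0.0, sd)) if sd > 0 else 0.0

    phi = atan2(tx, tz)  # initial heading: straight at the target
    px = pz = 0.0
    ts = [0.0]
    xs = [ox]
    ys = [oy]
    zs = [oz]
    bow = vertical_bow_fraction * reach
    for k in range(1, max_steps + 1):
        tau = min(k / n_plan, 0.9)
        speed = 30.0 * tau * tau * (1.0 - tau) * (1.0 - tau) * reach / duration_s
        ext = hypot(px, pz) / reach
        if rot != 0.0 and ext < occl:
            # displayed cursor = hand rotated about the vertical axis
            cx = cr * px + sr * pz
            cz = -sr * px + cr * pz
        else:
            cx, cz = px, pz
        psi = atan2(tx - cx, tz - cz)
        err = (psi - phi + pi) % (2.0 * pi) - pi
        eps = rho * eps + innov[k - 1]
        phi += gain * err + eps
        step = speed * dt
        px += step * sin(phi)
        pz += step * cos(phi)
        ext = hypot(px, pz) / reach
        ts.append(k * dt)
        xs.append(ox + px)
        ys.append(oy + bow * sin(pi * min(ext, 1.0)))
        zs.append(oz + pz)
        if ext >= stop_ext:
            break

    return Trajectory(
        t=np.array(ts),
        positions=np.column_stack([xs, ys, zs]),
        sampling_rate=SAMPLING_RATE_HZ,
        trial_index=trial.index,
    )


@dataclass
class SimulatedSession:
    participant_id: str
    schedule: SessionSchedule
    trajectories: dict[int, Trajectory]
    score: ParticipantScore | None = None


def simulate_session(
    seed: int,
    profile: AbilityProfile,
    geometry: TaskGeometry | None = None,
    n_task: int = 108,
    n_practice: int = 10,
) -> tuple[SessionSchedule, dict[int, Trajectory]]:
    """One full session (schedule + a trajectory per trial)."""
    geometry = geometry or TaskGeometry()
    rng = np.random.default_rng(seed)
    schedule = generate_schedule(
        _child_seed(rng), geometry=geometry, n_task=n_task,
        n_practice=n_practice,
    )
    traj_rng = np.random.default_rng(_child_seed(rng))
    trajectories = {
        trial.index: simulate_trajectory(trial, geometry, profile, traj_rng)
        for trial in schedule.trials
    }
    return schedule, trajectories


def _simulate_answers(
    schedule: SessionSchedule, cohort: CohortModel, rng: np.random.Generator
) -> int:
    """Correct count of the post-trial rotation judgements (task trials)."""
    correct = 0
    for trial in schedule.task_trials:
        if trial.is_rotated:
            p_yes = float(
                stats.norm.cdf(
                    (abs(trial.rotation_deg) - cohort.answer_threshold_deg)
                    / cohort.answer_slope_deg
                )
            )
        else:
            p_yes = cohort.false_alarm_rate
        answered_rotated = rng.random() < p_yes
        correct += answered_rotated == trial.is_rotated
    return correct


def simulate_cohort(
    n: int,
    cohort: str | CohortModel = "older_default",
    seed: int = 0,
    geometry: TaskGeometry | None = None,
    n_task: int = 108,
    n_practice: int = 10,
) -> tuple[list[SimulatedSession], pd.DataFrame]:
    """Simulate ``n`` participants: covariates, full sessions, and scores.

    Returns the sessions and a subject table with columns participant_id,
    age, sex (0 = male, 1 = female), activity_level, correct_count,
    mean_gap_angle_deg, n_unattained, excluded.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cohort = resolve_cohort(cohort)
    geometry = geometry or TaskGeometry()
    rng = np.random.default_rng(seed)

    sessions: list[SimulatedSession] = []
    rows = []
    for i in range(n):
        pid = f"sub-{i + 1:03d}"
        age = float(rng.uniform(cohort.age_low, cohort.age_high))
        sex = int(rng.random() < cohort.sex_p)
        activity = int(rng.choice(len(cohort.activity_probs),
                                  p=cohort.activity_probs))
        base = cohort.profiles[
            int(rng.choice(len(cohort.profiles), p=np.asarray(cohort.weights)
                           / np.sum(cohort.weights)))
        ]
        mult = float(np.exp(rng.normal(0.0, cohort.noise_spread_log_sd)))
        profile = dataclasses.replace(
            base, heading_noise_sd=base.heading_noise_sd * mult
        )
        schedule, trajectories = simulate_session(
            _child_seed(rng), profile, geometry=geometry, n_task=n_task,
            n_practice=n_practice,
        )
        score = score_session(schedule, trajectories, geometry, pid)
        correct = _simulate_answers(schedule, cohort, rng)
        sessions.append(SimulatedSession(pid, schedule, trajectories, score))
        rows.append(
            {
                "participant_id": pid,
                "age": age,
                "sex": sex,
                "activity_level": activity,
                "correct_count": correct,
                "mean_gap_angle_deg": score.mean_gap_angle_deg,
                "n_unattained": score.n_unattained,
                "excluded": False,
            }
        )
    return sessions, pd.DataFrame(rows)


def sample_subject_records(
    n: int, cohort: str | CohortModel = "older_default", seed: int = 0
) -> pd.DataFrame:
    """Draw subject covariates and behavioural scores without trajectories.

    Mean gap angles are drawn from a lognormal matched to the cohort's
    calibrated score mean/SD — a lightweight stand-in for the full
    schedule -> trajectory -> scoring chain when only the participant-level
    score is needed (e.g. repeated connectivity-recovery simulations).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cohort = resolve_cohort(cohort)
    rng = np.random.default_rng(seed)
    cv2 = (cohort.score_sd / cohort.score_mean) ** 2
    sigma = sqrt(np.log1p(cv2))
    mu = np.log(cohort.score_mean) - 0.5 * sigma**2
    return pd.DataFrame(
        {
            "participant_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "age": rng.uniform(cohort.age_low, cohort.age_high, n),
            "sex": (rng.random(n) < cohort.sex_p).astype(int),
            "activity_level": rng.choice(
                len(cohort.activity_probs), size=n, p=cohort.activity_probs
            ),
            "mean_gap_angle_deg": np.exp(rng.normal(mu, sigma, n)),
            "excluded": False,
        }
    )


# ---------------------------------------------------------------------------
# Head-motion simulation
# ---------------------------------------------------------------------------

def simulate_motion_params(
    n_volumes: int,
    seed_or_rng=0,
    spikes: list[tuple[int, float]] | None = None,
    drift_amp_mm: float = 0.03,
    n_drift_components: int = 3,
) -> pd.DataFrame:
    """Six realignment parameters per volume: smooth drift plus spikes.

    Translations in mm, rotations in radians.  Baseline drift is a sum of
    slow sinusoids whose per-volume increments are far below the 0.5 mm
    outlier threshold; each entry of ``spikes`` ``(volume, magnitude_mm)``
    injects a step of that size in the first translation at that volume.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    rng = _as_rng(seed_or_rng)
    t = np.arange(n_volumes, dtype=float)
    motion = np.zeros((n_volumes, 6))
    for j in range(6):
        amp = drift_amp_mm if j < 3 else drift_amp_mm / 50.0
        for _ in range(n_drift_components):
            period = rng.uniform(80.0, 400.0)
            phase = rng.uniform(0.0, 2.0 * pi)
            motion[:, j] += (
                amp / n_drift_components * np.sin(2.0 * pi * t / period + phase)
            )
    for volume, magnitude in spikes or []:
        if not 0 < volume < n_volumes:
            raise ValueError("spike volume out of range")
        motion[volume:, 0] += magnitude
    return pd.DataFrame(motion, columns=MOTION_COLUMNS)


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

def roi_labels(n_rois: int) -> list[str]:
    return [f"ROI{i + 1:03d}" for i in range(n_rois)]


@dataclass(frozen=True)
class PlantedEdge:
    """An ROI pair whose Fisher-z connectivity depends on the behaviour score.

    The population correlation of the pair for a subject with standardized
    score ``s`` is ``tanh(baseline_z + slope * s)``; a negative slope means
    stronger connectivity in better performers (smaller gap angles).
    """

    seed_roi: str
    target_roi: str
    slope: float = -0.5
    baseline_z: float = 0.25

    def __post_init__(self) -> None:
        if self.seed_roi == self.target_roi:
            raise ValueError("seed_roi and target_roi must differ")


def default_planted_edges(n_rois: int = 140) -> list[PlantedEdge]:
    """Three negatively-sloped edges on the first six ROIs."""
    labels = roi_labels(n_rois)
    return [
        PlantedEdge(labels[0], labels[1]),
        PlantedEdge(labels[2], labels[3]),
        PlantedEdge(labels[4], labels[5]),
    ]


@dataclass
class BoldSimSpec:
    """Dimensions and noise structure of the simulated resting-state data.

    Defaults follow the acquisition the pipeline is built for: 2 runs of
    450 volumes at TR 0.8 s (6 min each) over 140 ROIs.  Amplitudes are in
    units of the unit-variance neural signal.
    """

    n_rois: int = 140
    n_volumes_per_run: int = 450
    n_runs: int = 2
    tr: float = 0.8
    planted: list[PlantedEdge] | None = None
    background_corr: float = 0.1
    drift_amp: float = 1.0
    motion_gain: float = 0.5
    wmcsf_leak: float = 0.5
    n_wm_sources: int = 20
    n_csf_sources: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes_per_run < 2:
            raise ValueError("n_volumes_per_run must be >= 2")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 <= self.background_corr < 1:
            raise ValueError("background_corr must be in [0, 1)")
        if self.planted is None:
            self.planted = default_planted_edges(self.n_rois)

    @property
    def run_duration_s(self) -> float:
        return self.n_volumes_per_run * self.tr


@dataclass
class SubjectBold:
    """One subject's simulated runs with their nuisance sources."""

    participant_id: str
    runs: list[pd.DataFrame]       # each volumes x ROIs, labelled columns
    motion: list[pd.DataFrame]     # per run, 6 realignment parameters
    wm: list[np.ndarray]           # per run, white-matter source signals
    csf: list[np.ndarray]          # per run, CSF source signals
    tr: float


def _nuisance_sources(
    rng: np.random.Generator, n_volumes: int, n_sources: int
) -> tuple[np.ndarray, np.ndarray]:
    """(sources, latent factors): 2 latent factors + 30% independent noise."""
    factors = rng.standard_normal((n_volumes, 2))
    loadings = rng.standard_normal((2, n_sources))
    sources = factors @ loadings + 0.3 * rng.standard_normal(
        (n_volumes, n_sources)
    )
    return sources, factors


def simulate_bold(
    spec: BoldSimSpec, subjects: pd.DataFrame
) -> dict[str, SubjectBold]:
    """Simulate per-subject ROI BOLD runs with planted edge-behaviour slopes.

    ``subjects`` must carry ``participant_id`` and ``mean_gap_angle_deg``
    (standardized across the table to form the score each planted edge's
    correlation depends on).  Runs are generated independently.
    """
    if "mean_gap_angle_deg" not in subjects.columns:
        raise ValueError("subjects must have mean_gap_angle_deg filled")
    if subjects["mean_gap_angle_deg"].isna().any():
        raise ValueError("subjects must have mean_gap_angle_deg filled")
    labels = roi_labels(spec.n_rois)
    label_to_idx = {lab: i for i, lab in enumerate(labels)}
    planted = spec.planted or []
    planted_idx: list[tuple[int, int]] = []
    used: set[int] = set()
    for e in planted:
        a, b = label_to_idx[e.seed_roi], label_to_idx[e.target_roi]
        if a in used or b in used:
            raise ValueError("planted edges must not share ROIs")
        used.update((a, b))
        planted_idx.append((a, b))

    scores = subjects["mean_gap_angle_deg"].to_numpy(dtype=float)
    std = scores.std(ddof=0)
    if std == 0:
        raise ValueError("behavioural scores are constant; cannot standardize")
    s = (scores - scores.mean()) / std

    rng = np.random.default_rng(spec.rng_seed)
    lam = sqrt(spec.background_corr)
    T = spec.n_volumes_per_run
    out: dict[str, SubjectBold] = {}
    for subj_i, pid in enumerate(subjects["participant_id"]):
        z_targets = np.array(
            [e.baseline_z + e.slope * s[subj_i] for e in planted]
        )
        if np.any(np.abs(z_targets) > 4.0):
            raise ValueError(
                "planted slope drives |target correlation| too close to 1"
            )
        r_targets = np.tanh(z_targets)

        runs, motions, wms, csfs = [], [], [], []
        for _ in range(spec.n_runs):
            e = rng.standard_normal((T, spec.n_rois))
            g = rng.standard_normal(T)
            neural = sqrt(1.0 - lam * lam) * e + lam * g[:, None]
            for (a, b), r in zip(planted_idx, r_targets):
                neural[:, a] = e[:, a]
                neural[:, b] = r * e[:, a] + sqrt(1.0 - r * r) * e[:, b]

            # low-frequency drift, below the analysis passband
            tsec = np.arange(T) * spec.tr
            freqs = rng.uniform(0.002, 0.006, spec.n_rois)
            phases = rng.uniform(0.0, 2.0 * pi, spec.n_rois)
            drift = spec.drift_amp * np.sin(
                2.0 * pi * freqs[None, :] * tsec[:, None] + phases[None, :]
            )

            motion = simulate_motion_params(T, rng)
            m = motion.to_numpy()
            mz = (m - m.mean(0)) / np.where(m.std(0) == 0, 1.0, m.std(0))
            art = (spec.motion_gain / sqrt(6.0)) * (
                mz @ rng.standard_normal((6, spec.n_rois))
            )

            wm, wm_f = _nuisance_sources(rng, T, spec.n_wm_sources)
            csf, csf_f = _nuisance_sources(rng, T, spec.n_csf_sources)
            leak = (spec.wmcsf_leak / 2.0) * (
                wm_f @ rng.standard_normal((2, spec.n_rois))
                + csf_f @ rng.standard_normal((2, spec.n_rois))
            )

            values = 500.0 + 10.0 * (neural + drift + art + leak)
            runs.append(pd.DataFrame(values, columns=labels))
            motions.append(motion)
            wms.append(wm)
            csfs.append(csf)
        out[str(pid)] = SubjectBold(
            participant_id=str(pid), runs=runs, motion=motions, wm=wms,
            csf=csfs, tr=spec.tr,
        )
    return out


# ---------------------------------------------------------------------------
# Writers for the downstream readers
# ---------------------------------------------------------------------------

def write_bold_subject(subject: SubjectBold, out_dir) -> None:
    """Write one subject's runs as sub-<id>_run-<k>[...].tsv files."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    stem = subject.participant_id
    for k, (run, motion, wm, csf) in enumerate(
        zip(subject.runs, subject.motion, subject.wm, subject.csf), start=1
    ):
        run.to_csv(
            os.path.join(out_dir, f"{stem}_run-{k}.tsv"), sep="\t", index=False
        )
        motion.to_csv(
            os.path.join(out_dir, f"{stem}_run-{k}_motion.tsv"),
            sep="\t", index=False,
        )
        pd.DataFrame(wm).to_csv(
            os.path.join(out_dir, f"{stem}_run-{k}_wm.tsv"),
            sep="\t", index=False,
        )
        pd.DataFrame(csf).to_csv(
            os.path.join(out_dir, f"{stem}_run-{k}_csf.tsv"),
            sep="\t", index=False,
        )


def write_subject_table(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, index=False)
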