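"""Gap-angle kinematics for the reaching task.

The behavioural score of the task is the *mean gap angle*: for every trial,
the angle at the origin O between the target T and the point P90 where the
reach first attains 90% of the origin–target distance, all three points
projected onto the horizontal plane,

    theta = arccos( (O->P90 . O->T) / (|O->P90| |O->T|) ),

averaged over the session's task trials.  The 90% point (rather than the
movement endpoint) is used because some participants stop short once the
cursor disappears in the second half of the reach; the score is meant to
capture horizontal aiming accuracy, not reach completion or depth accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_protocol import (
    SessionSchedule,
    TaskGeometry,
    VERTICAL_AXIS,
    target_point,
)

#: Fraction of |OT| at which the gap angle is evaluated.
P90_FRACTION = 0.9

TRAJECTORY_COLUMNS = ["t", "x", "y", "z", "trial_index"]


@dataclass
class Trajectory:
    """A sampled reach: times (s) and 3D positions, nominally 72 Hz."""

    t: np.ndarray
    positions: np.ndarray  # (n, 3)
    sampling_rate: float = 72.0
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if len(self.t) != len(self.positions):
            raise ValueError("t and positions length mismatch")
        if len(self.t) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def check_starts_at(self, origin, tol: float = 1e-3) -> None:
        if np.linalg.norm(self.positions[0] - np.asarray(origin, float)) > tol:
            raise ValueError("trajectory does not start at the origin")


@dataclass
class GapAngleRecord:
    """Per-trial gap angle and the 90%-extension point it was measured at."""

    trial_index: int
    p90: np.ndarray
    theta_deg: float
    attained_p90: bool


@dataclass
class ParticipantScore:
    """Participant-level mean gap angle over the task trials used."""

    participant_id: str
    mean_gap_angle_deg: float
    n_trials_used: int
    per_trial: list[GapAngleRecord] = field(default_factory=list)

    @property
    def n_unattained(self) -> int:
        return sum(not r.attained_p90 for r in self.per_trial)


def project_horizontal(
    p: np.ndarray, vertical_axis: int = VERTICAL_AXIS
) -> np.ndarray:
    """Drop the vertical coordinate, keeping the horizontal ones unchanged."""
    p = np.asarray(p, dtype=float)
    keep = [i for i in range(p.shape[-1]) if i != vertical_axis]
    return p[..., keep]


def find_p90(
    traj: Trajectory, origin: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Locate the 90%-extension point of a reach.

    Returns the first point along the sampled path whose *horizontal*
    distance from the origin reaches ``P90_FRACTION * |OT|``, linearly
    interpolating between the bracketing samples.  If the reach never gets
    that far, returns the sample of maximal horizontal extension with
    ``attained = False``.
    """
    origin = np.asarray(origin, dtype=float)
    target = np.asarray(target, dtype=float)
    ot = np.linalg.norm(project_horizontal(target - origin))
    if ot == 0:
        raise ValueError("degenerate target: |OT| = 0")
    threshold = P90_FRACTION * ot

    d = np.linalg.norm(project_horizontal(traj.positions - origin), axis=1)
    crossing = np.nonzero(d >= threshold)[0]
    if crossing.size == 0:
        return traj.positions[int(np.argmax(d))].copy(), False
    i = int(crossing[0])
    if i == 0:
        return traj.positions[0].copy(), True
    frac = (threshold - d[i - 1]) / (d[i] - d[i - 1])
    p90 = traj.positions[i - 1] + frac * (traj.positions[i] - traj.positions[i - 1])
    return p90, True


def trial_gap_angle(
    p90: np.ndarray, origin: np.ndarray, target: np.ndarray
) -> float:
    """Gap angle in degrees between O->P90 and O->T after horizontal projection.

    The arccos argument is clamped to [-1, 1] to absorb rounding, so the
    result always lies in [0, 180].
    """
    u = project_horizontal(np.asarray(p90, float) - np.asarray(origin, float))
    v = project_horizontal(np.asarray(target, float) - np.asarray(origin, float))
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length projected vector")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def mean_gap_angle(
    records: list[GapAngleRecord], participant_id: str = ""
) -> ParticipantScore:
    """Arithmetic mean of per-trial gap angles (task trials only)."""
    if len(records) == 0:
        raise ValueError("no gap-angle records")
    mean = float(np.mean([r.theta_deg for r in records]))
    return ParticipantScore(
        participant_id=participant_id,
        mean_gap_angle_deg=mean,
        n_trials_used=len(records),
        per_trial=list(records),
    )


def score_session(
    schedule: SessionSchedule,
    trajectories: dict[int, Trajectory],
    geometry: TaskGeometry | None = None,
    participant_id: str = "",
) -> ParticipantScore:
    """Run find_p90 -> trial_gap_angle over a session's task trials.

    ``trajectories`` maps trial index to the recorded reach; practice trials
    are excluded from the mean.  Trials that never attain 90% extension are
    scored at their point of maximal extension and flagged, but included.
    """
    geometry = geometry or schedule.geometry
    origin = geometry.origin_array
    records: list[GapAngleRecord] = []
    for trial in schedule.task_trials:
        traj = trajectories[trial.index]
        target = target_point(trial, geometry)
        p90, attained = find_p90(traj, origin, target)
        theta = trial_gap_angle(p90, origin, target)
        records.append(
            GapAngleRecord(
                trial_index=trial.index, p90=p90, theta_deg=theta,
                attained_p90=attained,
            )
        )
    return mean_gap_angle(records, participant_id=participant_id)


# ---------------------------------------------------------------------------
# Trajectory and score I/O (delimited text)
# ---------------------------------------------------------------------------

def trajectories_to_frame(trajectories: dict[int, Trajectory]) -> pd.DataFrame:
    parts = []
    for idx in sorted(trajectories):
        traj = trajectories[idx]
        parts.append(
            pd.DataFrame(
                {
                    "t": traj.t,
                    "x": traj.positions[:, 0],
                    "y": traj.positions[:, 1],
                    "z": traj.positions[:, 2],
                    "trial_index": idx,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_trajectories(trajectories: dict[int, Trajectory], path) -> None:
    trajectories_to_frame(trajectories).to_csv(path, sep="\t", index=False)


def read_trajectories(path, sampling_rate: float = 72.0) -> dict[int, Trajectory]:
    """Read a long-format trajectory table (columns t, x, y, z, trial_index)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    out: dict[int, Trajectory] = {}
    for idx, g in df.groupby("trial_index", sort=True):
        out[int(idx)] = Trajectory(
            t=g["t"].to_numpy(),
            positions=g[["x", "y", "z"]].to_numpy(),
            sampling_rate=sampling_rate,
            trial_index=int(idx),
        )
    return out


def write_scores(scores: list[ParticipantScore], path) -> None:
    pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in scores],
            "mean_gap_angle_deg": [s.mean_gap_angle_deg for s in scores],
            "n_trials_used": [s.n_trials_used for s in scores],
            "n_unattained": [s.n_unattained for s in scores],
        }
    ).to_csv(path, sep="\t", index=False)
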