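"""Trial schedules and geometry for a VR visuomotor-rotation reaching task.

The task: a participant wearing a head-mounted display moves a cursor from
an origin sphere (fixed in front of the chin) to a target sphere placed on a
frontal arc at 90% of the calibrated maximum reach.  On interspersed trials
the cursor is rotated about the vertical axis relative to the true hand
position (1°–24° clockwise or 1°–25° counterclockwise), each rotated trial
being followed by one or two unrotated washout trials.  The cursor is hidden
once the arm passes roughly half of the origin–target distance, and after
every trial the participant reports whether a rotation was applied.

Coordinate frame
----------------
Right-handed with the vertical axis *up* as the second coordinate (y-up):
x points to the participant's right, z straight ahead.  The origin sphere is
the coordinate origin.  Azimuths are measured from straight ahead (+z),
positive toward +x, so a positive rotation is clockwise when viewed from
above.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Index of the vertical (up) coordinate in 3-vectors.
VERTICAL_AXIS = 1

#: Permitted cursor rotations, degrees: 1–24 clockwise (positive),
#: 1–25 counterclockwise (negative).  0 marks an unrotated trial.
CLOCKWISE_ROTATIONS = tuple(range(1, 25))
COUNTERCLOCKWISE_ROTATIONS = tuple(range(-25, 0))
ROTATION_SET = COUNTERCLOCKWISE_ROTATIONS + CLOCKWISE_ROTATIONS

SCHEDULE_COLUMNS = [
    "trial_index",
    "is_practice",
    "rotation_deg",
    "target_azimuth_deg",
    "target_x",
    "target_y",
    "target_z",
]


@dataclass(frozen=True)
class TaskGeometry:
    """Spatial layout of the reaching task.

    Parameters
    ----------
    arm_length:
        Calibrated maximum reach of the participant, metres.
    target_distance_fraction:
        Targets sit at this fraction of ``arm_length`` from the origin
        (default 0.9).
    cursor_occlusion_fraction:
        The cursor disappears once the horizontal extension passes this
        fraction of the origin–target distance (default 0.5; the boundary
        itself counts as hidden).
    origin:
        Position of the origin sphere (in front of the chin); coordinate
        origin by convention.
    """

    arm_length: float = 0.7
    target_distance_fraction: float = 0.9
    cursor_occlusion_fraction: float = 0.5
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.arm_length > 0:
            raise ValueError("arm_length must be positive")
        if not 0 < self.target_distance_fraction <= 1:
            raise ValueError("target_distance_fraction must be in (0, 1]")
        if not 0 < self.cursor_occlusion_fraction < 1:
            raise ValueError("cursor_occlusion_fraction must be in (0, 1)")

    @property
    def target_distance(self) -> float:
        """Origin-to-target distance |OT| in metres."""
        return self.target_distance_fraction * self.arm_length

    @property
    def origin_array(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)


@dataclass(frozen=True)
class SpeedWindow:
    """Acceptable movement-duration window for the speed feedback, seconds."""

    lower: float = 0.8
    upper: float = 1.2

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError("require 0 < lower < upper")


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the session.

    ``rotation_deg`` is the signed integer cursor rotation (0 = unrotated,
    positive = clockwise viewed from above); ``target_azimuth_deg`` the
    target's azimuth on the frontal arc.
    """

    index: int
    rotation_deg: int
    target_azimuth_deg: float
    is_practice: bool = False

    def __post_init__(self) -> None:
        if self.rotation_deg != 0 and self.rotation_deg not in ROTATION_SET:
            raise ValueError(
                f"rotation_deg {self.rotation_deg} outside permitted set"
            )

    @property
    def is_rotated(self) -> bool:
        return self.rotation_deg != 0


@dataclass
class SessionSchedule:
    """Ordered trial list for one session (practice trials first)."""

    trials: list[TrialSpec]
    n_task_trials: int = 108
    n_practice: int = 10
    rng_seed: int = 0
    geometry: TaskGeometry = field(default_factory=TaskGeometry)

    @property
    def task_trials(self) -> list[TrialSpec]:
        return [t for t in self.trials if not t.is_practice]

    @property
    def practice_trials(self) -> list[TrialSpec]:
        return [t for t in self.trials if t.is_practice]

    def validate(self) -> None:
        """Check the washout invariants; raise ``ValueError`` on violation."""
        task = self.task_trials
        if len(task) != self.n_task_trials:
            raise ValueError("wrong number of task trials")
        rotated_idx = [i for i, t in enumerate(task) if t.is_rotated]
        for a, b in zip(rotated_idx, rotated_idx[1:]):
            n_washout = b - a - 1
            if n_washout not in (1, 2):
                raise ValueError(
                    f"{n_washout} washout trials between rotated trials"
                )
        # Every rotated trial except possibly the last trial of the session
        # must be followed by at least one unrotated trial.
        for i in rotated_idx:
            if i + 1 < len(task) and task[i + 1].is_rotated:
                raise ValueError("rotated trial followed by rotated trial")


def generate_schedule(
    seed: int,
    geometry: TaskGeometry | None = None,
    n_task: int = 108,
    n_practice: int = 10,
    arc_half_width_deg: float = 45.0,
) -> SessionSchedule:
    """Generate a session schedule.

    Task trials are built as repeated blocks ``[rotated, k washouts]`` with
    ``k`` drawn uniformly from {1, 2}, truncated to exactly ``n_task``
    trials, so consecutive rotated trials are always separated by one or two
    unrotated trials.  Rotation angles are drawn uniformly from the
    permitted set and target azimuths uniformly from
    ``[-arc_half_width_deg, +arc_half_width_deg]``.  Practice trials are
    unrotated.  Deterministic given ``seed``.
    """
    if n_task < 1:
        raise ValueError("n_task must be >= 1")
    if n_practice < 0:
        raise ValueError("n_practice must be >= 0")
    geometry = geometry or TaskGeometry()
    rng = np.random.default_rng(seed)

    rotations: list[int] = []
    while len(rotations) < n_task:
        rotations.append(int(rng.choice(ROTATION_SET)))
        k = int(rng.integers(1, 3))  # washout count in {1, 2}
        rotations.extend([0] * k)
    rotations = rotations[:n_task]

    trials: list[TrialSpec] = []
    for i in range(n_practice):
        az = float(rng.uniform(-arc_half_width_deg, arc_half_width_deg))
        trials.append(
            TrialSpec(index=i + 1, rotation_deg=0, target_azimuth_deg=az,
                      is_practice=True)
        )
    for j, rot in enumerate(rotations):
        az = float(rng.uniform(-arc_half_width_deg, arc_half_width_deg))
        trials.append(
            TrialSpec(index=n_practice + j + 1, rotation_deg=rot,
                      target_azimuth_deg=az, is_practice=False)
        )

    schedule = SessionSchedule(
        trials=trials, n_task_trials=n_task, n_practice=n_practice,
        rng_seed=seed, geometry=geometry,
    )
    schedule.validate()
    return schedule


def place_target(
    rng: np.random.Generator | None,
    geometry: TaskGeometry,
    azimuth_deg: float | None = None,
    arc_half_width_deg: float = 45.0,
) -> np.ndarray:
    """Target position on the frontal arc.

    The target lies in the horizontal plane through the origin at distance
    ``target_distance_fraction * arm_length``.  If ``azimuth_deg`` is None
    it is drawn uniformly from the arc using ``rng``.
    """
    if azimuth_deg is None:
        if rng is None:
            raise ValueError("rng required when azimuth_deg is not given")
        azimuth_deg = float(rng.uniform(-arc_half_width_deg, arc_half_width_deg))
    az = np.deg2rad(azimuth_deg)
    d = geometry.target_distance
    return geometry.origin_array + d * np.array([np.sin(az), 0.0, np.cos(az)])


def apply_rotation(
    hand: np.ndarray, origin: np.ndarray, rotation_deg: float
) -> np.ndarray:
    """Rotate ``hand`` about the vertical axis through ``origin``.

    Positive angles are clockwise viewed from above (+z rotates toward +x).
    The vertical coordinate and the distance from ``origin`` are preserved.
    """
    hand = np.asarray(hand, dtype=float)
    origin = np.asarray(origin, dtype=float)
    v = hand - origin
    th = np.deg2rad(rotation_deg)
    c, s = np.cos(th), np.sin(th)
    out = np.empty_like(v)
    out[..., 0] = c * v[..., 0] + s * v[..., 2]
    out[..., 1] = v[..., 1]
    out[..., 2] = -s * v[..., 0] + c * v[..., 2]
    return origin + out


def horizontal_extension(
    hand: np.ndarray, origin: np.ndarray, target: np.ndarray
) -> float:
    """|OP| / |OT| using horizontal (vertical-dropped) distances."""
    hand = np.asarray(hand, dtype=float)
    origin = np.asarray(origin, dtype=float)
    target = np.asarray(target, dtype=float)
    keep = [i for i in range(3) if i != VERTICAL_AXIS]
    op = np.linalg.norm((hand - origin)[..., keep], axis=-1)
    ot = np.linalg.norm((target - origin)[..., keep], axis=-1)
    if np.any(ot == 0):
        raise ValueError("degenerate target: |OT| = 0")
    return op / ot


def cursor_visible(
    hand: np.ndarray,
    origin: np.ndarray,
    target: np.ndarray,
    geometry: TaskGeometry,
) -> bool:
    """True while the cursor is displayed.

    The cursor is hidden once the horizontal extension reaches the occlusion
    fraction; the boundary itself counts as hidden.
    """
    return bool(
        horizontal_extension(hand, origin, target)
        < geometry.cursor_occlusion_fraction
    )


def answer_correct(answered_rotated: bool, trial: TrialSpec) -> bool:
    """Whether the post-trial rotation judgement was correct."""
    return bool(answered_rotated) == trial.is_rotated


def classify_speed(
    movement_duration: float, window: SpeedWindow | None = None
) -> str:
    """Classify a movement duration as ``too_fast`` / ``ok`` / ``too_slow``."""
    if not movement_duration > 0:
        raise ValueError("movement_duration must be positive")
    window = window or SpeedWindow()
    if movement_duration < window.lower:
        return "too_fast"
    if movement_duration > window.upper:
        return "too_slow"
    return "ok"


# ---------------------------------------------------------------------------
# Schedule I/O (TSV)
# ---------------------------------------------------------------------------

def schedule_to_frame(schedule: SessionSchedule) -> pd.DataFrame:
    rows = []
    for t in schedule.trials:
        tx, ty, tz = place_target(None, schedule.geometry, t.target_azimuth_deg)
        rows.append(
            {
                "trial_index": t.index,
                "is_practice": int(t.is_practice),
                "rotation_deg": t.rotation_deg,
                "target_azimuth_deg": t.target_azimuth_deg,
                "target_x": tx,
                "target_y": ty,
                "target_z": tz,
            }
        )
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def write_schedule(schedule: SessionSchedule, path) -> None:
    schedule_to_frame(schedule).to_csv(path, sep="\t", index=False)


def read_schedule(
    path, geometry: TaskGeometry | None = None
) -> SessionSchedule:
    df = pd.read_csv(path, sep="\t")
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule file missing columns: {sorted(missing)}")
    trials = [
        TrialSpec(
            index=int(r.trial_index),
            rotation_deg=int(r.rotation_deg),
            target_azimuth_deg=float(r.target_azimuth_deg),
            is_practice=bool(r.is_practice),
        )
        for r in df.itertuples()
    ]
    n_practice = sum(t.is_practice for t in trials)
    return SessionSchedule(
        trials=trials,
        n_task_trials=len(trials) - n_practice,
        n_practice=n_practice,
        geometry=geometry or TaskGeometry(),
    )


def target_point(trial: TrialSpec, geometry: TaskGeometry) -> np.ndarray:
    """Convenience: the 3D target position of a trial."""
    return place_target(None, geometry, trial.target_azimuth_deg)
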