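"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from reachgap.task_protocol import TaskGeometry


@pytest.fixture
def geometry() -> TaskGeometry:
    return TaskGeometry(arm_length=0.7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Brute-force gap-angle oracle: scalar math, explicit loops, no reuse of the
# package's vectorized code paths.
# ---------------------------------------------------------------------------

def oracle_horizontal(p):
    """Drop the vertical (second) coordinate."""
    return (p[0], p[2])


def oracle_p90(points, origin, target):
    """First crossing of 90% of |OT| by linear scan and interpolation."""
    ox, oz = oracle_horizontal(origin)
    tx, tz = oracle_horizontal(target)
    threshold = 0.9 * math.hypot(tx - ox, tz - oz)
    prev_d = None
    for i, p in enumerate(points):
        px, pz = oracle_horizontal(p)
        d = math.hypot(px - ox, pz - oz)
        if d >= threshold:
            if i == 0:
                return tuple(points[0]), True
            f = (threshold - prev_d) / (d - prev_d)
            q = tuple(
                points[i - 1][k] + f * (points[i][k] - points[i - 1][k])
                for k in range(3)
            )
            return q, True
        prev_d = d
    best = max(
        range(len(points)),
        key=lambda i: math.hypot(
            points[i][0] - ox, points[i][2] - oz
        ),
    )
    return tuple(points[best]), False


def oracle_angle(p90, origin, target):
    """Angle at the origin between P90 and T, horizontal plane, degrees."""
    ux = p90[0] - origin[0]
    uz = p90[2] - origin[2]
    vx = target[0] - origin[0]
    vz = target[2] - origin[2]
    nu = math.hypot(ux, uz)
    nv = math.hypot(vx, vz)
    c = (ux * vx + uz * vz) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def oracle_trial_angle(points, origin, target):
    p90, _ = oracle_p90(points, origin, target)
    return oracle_angle(p90, origin, target)


def make_random_trajectory(rng: np.random.Generator, reach: float = 0.63):
    """A meandering 3D path from the origin; may or may not attain 90%."""
    n = int(rng.integers(20, 120))
    az = rng.uniform(-np.pi / 4, np.pi / 4)
    target = reach * np.array([np.sin(az), 0.0, np.cos(az)])
    max_ext = rng.uniform(0.5, 1.3) * reach
    heading = az + rng.normal(0, 0.3)
    pos = np.zeros(3)
    pts = [pos.copy()]
    step = max_ext / n
    for _ in range(n):
        heading += rng.normal(0, 0.25)
        pos = pos + np.array(
            [step * np.sin(heading), rng.normal(0, 0.01), step * np.cos(heading)]
        )
        pts.append(pos.copy())
    t = np.arange(len(pts)) / 72.0
    return t, np.array(pts), target
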