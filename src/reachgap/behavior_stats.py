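"""Participant exclusion and the nonparametric behavioural test battery.

Participants are excluded when their count of correct post-trial rotation
judgements is deviant (more than three population SDs from the cohort mean)
or when every response was wrong — both taken as signs the task was
misunderstood.  Because the mean-gap-angle distributions are non-normal,
group comparisons and associations use rank-based tests: Shapiro–Wilk for
the normality check itself, Spearman correlation, Mann–Whitney U, and
Kruskal–Wallis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExclusionReport:
    participant_id: str
    correct_count: int
    reason: str  # none | deviant_correct_count | all_incorrect
    excluded: bool


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    n: int | tuple[int, ...]

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def apply_exclusion(
    correct_counts: pd.Series | dict[str, int], sd_multiplier: float = 3.0
) -> pd.DataFrame:
    """Flag participants with deviant or all-incorrect answer counts.

    A participant is excluded iff ``|count - mean| > sd_multiplier * SD``
    (population SD over all candidates, single pass, no re-computation) or
    ``count == 0``.  Returns one row per participant with the reason.
    """
    if isinstance(correct_counts, dict):
        correct_counts = pd.Series(correct_counts)
    if len(correct_counts) < 2:
        raise ValueError("need at least 2 participants")
    counts = correct_counts.to_numpy(dtype=float)
    mean = counts.mean()
    sd = counts.std(ddof=0)
    rows = []
    for pid, c in correct_counts.items():
        if c == 0:
            reason = "all_incorrect"
        elif abs(c - mean) > sd_multiplier * sd:
            reason = "deviant_correct_count"
        else:
            reason = "none"
        rows.append(
            ExclusionReport(str(pid), int(c), reason, reason != "none")
        )
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in rows],
            "correct_count": [r.correct_count for r in rows],
            "reason": [r.reason for r in rows],
            "excluded": [r.excluded for r in rows],
        }
    )


def shapiro_normality(values) -> StatResult:
    """Shapiro–Wilk test of normality."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro–Wilk needs n >= 3")
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: all values identical")
    w, p = stats.shapiro(values)
    return StatResult("shapiro_wilk", float(w), float(p), len(values))


def spearman_assoc(x, y) -> StatResult:
    """Spearman rank correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    r, p = stats.spearmanr(x, y)
    return StatResult("spearman", float(r), float(p), len(x))


def mann_whitney(group_a, group_b) -> StatResult:
    """Mann–Whitney U, two-sided.

    Exact enumeration for small tie-free samples (both n <= 8), otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult("mann_whitney", float(u), float(p), (len(a), len(b)))


def kruskal_wallis(groups) -> StatResult:
    """Kruskal–Wallis H with chi-square p (tie-corrected)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    h, p = stats.kruskal(*groups)
    return StatResult(
        "kruskal_wallis", float(h), float(p), tuple(len(g) for g in groups)
    )


def behavioral_battery(subjects: pd.DataFrame) -> pd.DataFrame:
    """Run the standard battery on a subject table.

    Expects columns mean_gap_angle_deg, age, sex, activity_level and,
    optionally, has_mri (for the four-way sex x MRI grouping).  Returns one
    row per test: test, statistic, p, n.
    """
    results: list[StatResult] = []
    mga = subjects["mean_gap_angle_deg"]
    results.append(shapiro_normality(mga))
    results.append(spearman_assoc(subjects["age"], mga))
    if "activity_level" in subjects.columns:
        results.append(spearman_assoc(subjects["activity_level"], mga))
    males = mga[subjects["sex"] == 0]
    females = mga[subjects["sex"] == 1]
    if len(males) and len(females):
        results.append(mann_whitney(males, females))
    if "has_mri" in subjects.columns:
        groups = [
            g["mean_gap_angle_deg"].to_numpy()
            for _, g in subjects.groupby(["sex", "has_mri"])
            if len(g)
        ]
        if len(groups) >= 2:
            results.append(kruskal_wallis(groups))
    return pd.DataFrame(
        {
            "test": [r.test_name for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p_value for r in results],
            "n": [str(r.n) for r in results],
        }
    )
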