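"""Edge-wise group GLM linking connectivity to the behavioural score.

Each edge's Fisher-z values across subjects are regressed on four
covariates — age, sex, physical activity level, and the mean gap angle —
with no separate intercept, so the residual degrees of freedom are
``n_subjects - 4`` (16 subjects give T(12)).  The contrast tests the mean
gap angle.  Two-sided p-values are adjusted by Benjamini–Hochberg FDR,
by default within each seed ROI's family of ``n_rois - 1`` edges (a
global family over all C(n_rois, 2) edges is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DESIGN_COLUMNS = ["age", "sex", "activity_level", "mean_gap_angle"]


@dataclass
class GroupDesign:
    """Subjects x regressors design with the mean-gap-angle contrast."""

    X: np.ndarray
    columns: list[str]
    contrast: np.ndarray
    df_residual: int

    def __post_init__(self) -> None:
        if self.df_residual < 1:
            raise ValueError("df_residual must be >= 1")


@dataclass
class FdrReport:
    """Edges significant at an FDR threshold, sorted by |t| descending."""

    family: str  # per_seed | global
    m: int       # family size
    alpha: float
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_significant(self) -> int:
        return len(self.edges)


def build_design(
    subjects: pd.DataFrame,
    include_intercept: bool = False,
    center_covariates: bool = False,
) -> GroupDesign:
    """Design matrix with columns [age, sex, activity_level, mean_gap_angle].

    No separate intercept by default (matching df = n - 4 with four
    regressors); ``include_intercept=True`` prepends a constant column.
    ``center_covariates`` mean-centres age/sex/activity (not the contrast
    column) — irrelevant to the contrast t without an intercept but
    affecting betas.
    """
    score_col = (
        "mean_gap_angle" if "mean_gap_angle" in subjects.columns
        else "mean_gap_angle_deg"
    )
    cols = ["age", "sex", "activity_level", score_col]
    missing = [c for c in cols if c not in subjects.columns]
    if missing:
        raise ValueError(f"subject table missing columns: {missing}")
    if subjects[cols].isna().any().any():
        raise ValueError("missing covariate values")
    X = subjects[cols].to_numpy(dtype=float)
    if center_covariates:
        X[:, :3] = X[:, :3] - X[:, :3].mean(axis=0)
    names = list(DESIGN_COLUMNS)
    if include_intercept:
        X = np.hstack([np.ones((len(X), 1)), X])
        names = ["intercept"] + names
    n, k = X.shape
    if n < k + 1:
        raise ValueError("need at least n_regressors + 1 subjects")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    contrast = np.zeros(k)
    contrast[names.index("mean_gap_angle")] = 1.0
    return GroupDesign(X=X, columns=names, contrast=contrast,
                       df_residual=n - k)


def fit_edges(Y: np.ndarray, design: GroupDesign) -> pd.DataFrame:
    """OLS fit of every column of ``Y`` (subjects x edges) on the design.

    Returns per edge: beta (contrast estimate), t, df, p (two-sided).
    Edges with zero residual variance get NaN t/p with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.X
    if Y.shape[0] != X.shape[0]:
        raise ValueError("subject count mismatch between Y and design")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)                       # k x m
    resid = Y - X @ beta
    df = design.df_residual
    ss = (resid**2).sum(axis=0)
    sigma2 = ss / df
    c = design.contrast
    cb = c @ beta
    cvar = float(c @ xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * cvar)
        t = cb / se
    degenerate = sigma2 <= np.finfo(float).eps * np.maximum(ss.max(), 1.0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} edge(s) with zero residual variance; "
            "t undefined", RuntimeWarning,
        )
        t = np.where(degenerate, np.nan, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"beta": cb, "t": t, "df": df, "p": p})


def fit_edge_glm(z_values, design: GroupDesign) -> pd.Series:
    """Single-edge convenience wrapper around :func:`fit_edges`."""
    return fit_edges(np.asarray(z_values, dtype=float), design).iloc[0]


def fdr_adjust(
    p_values, family: str = "global", families: np.ndarray | None = None
) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values.

    ``family='global'`` adjusts all p-values together.  With
    ``family='per_seed'``, ``families`` assigns each p-value to a family and
    adjustment is done within each family separately.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if family == "global":
        return multipletests(p, method="fdr_bh")[1]
    if family != "per_seed":
        raise ValueError("family must be 'global' or 'per_seed'")
    if families is None:
        raise ValueError("per_seed adjustment requires family labels")
    families = np.asarray(families)
    adj = np.empty_like(p)
    for fam in np.unique(families):
        idx = families == fam
        adj[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return adj


def edge_stats_table(
    Z: np.ndarray,
    design: GroupDesign,
    roi_labels: list[str],
    family: str = "per_seed",
) -> pd.DataFrame:
    """Fit the GLM for every unordered ROI pair and attach FDR-adjusted p.

    ``Z`` stacks subjects x ROIs x ROIs Fisher-z matrices.  With the
    default per-seed family, each edge (i, j) is adjusted within the
    139-edge family of seed i and of seed j, and receives the smaller of
    the two adjusted values (a seed-level report would list it under
    either seed).
    """
    Z = np.asarray(Z, dtype=float)
    n_sub, n_rois, _ = Z.shape
    ia, ib = np.triu_indices(n_rois, k=1)
    Y = Z[:, ia, ib]
    table = fit_edges(Y, design)
    table.insert(0, "seed_roi", [roi_labels[i] for i in ia])
    table.insert(1, "target_roi", [roi_labels[j] for j in ib])
    p = table["p"].to_numpy()
    if family == "global":
        p_fdr = fdr_adjust(p, family="global")
    elif family == "per_seed":
        # Duplicate every unordered edge into both of its seed families.
        fam = np.concatenate([ia, ib])
        p2 = np.concatenate([p, p])
        adj2 = fdr_adjust(p2, family="per_seed", families=fam)
        p_fdr = np.minimum(adj2[: len(p)], adj2[len(p):])
    else:
        raise ValueError("family must be 'global' or 'per_seed'")
    table["p_fdr"] = np.maximum(p_fdr, p)  # adjusted p is never below raw p
    table["family"] = family
    return table


def significant_edges(
    table: pd.DataFrame, alpha: float = 0.05
) -> FdrReport:
    """Edges with p_fdr < alpha, sorted by |t| (ties by seed, target)."""
    family = str(table["family"].iloc[0]) if len(table) else "per_seed"
    if len(table):
        n_rois = len(
            set(table["seed_roi"]).union(table["target_roi"])
        )
        m = n_rois - 1 if family == "per_seed" else len(table)
    else:
        m = 0
    sig = table[table["p_fdr"] < alpha].copy()
    if len(sig):
        sig = sig.sort_values(
            ["t", "seed_roi", "target_roi"],
            key=lambda s: -s.abs() if s.name == "t" else s,
        ).reset_index(drop=True)
    return FdrReport(family=family, m=m, alpha=alpha, edges=sig)


# ---------------------------------------------------------------------------
# End-to-end pipeline driver
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_subjects": 16,
    "cohort": "older_default",
    "behavioral": "simulate",  # simulate (full sessions) | sample (scores only)
    "n_rois": 140,
    "n_volumes_per_run": 450,
    "n_runs": 2,
    "tr": 0.8,
    "glm": {"family": "per_seed", "alpha": 0.05},
    "out_dir": None,
}


def _merge_config(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def run_pipeline(config: dict | None = None) -> dict:
    """Synthetic end-to-end run: behaviour -> exclusion -> rsFC -> GLM -> FDR.

    Returns a bundle with the subject table, exclusion report, per-subject
    connectivity, the edge-stat table (C(n_rois, 2) rows) and the FDR
    report.  With ``out_dir`` set, all tables are written as TSV.
    """
    from . import behavior_stats, connectivity, synthetic_data

    cfg = _merge_config(config)
    rng = np.random.default_rng(cfg["seed"])
    seeds = {name: int(rng.integers(2**31))
             for name in ("behavior", "bold")}

    if cfg["behavioral"] == "simulate":
        _, subjects = synthetic_data.simulate_cohort(
            cfg["n_subjects"], cfg["cohort"], seed=seeds["behavior"]
        )
        exclusion = behavior_stats.apply_exclusion(
            pd.Series(
                subjects["correct_count"].to_numpy(),
                index=subjects["participant_id"],
            )
        )
        subjects = subjects.merge(
            exclusion[["participant_id", "excluded"]].rename(
                columns={"excluded": "excluded_flag"}
            ),
            on="participant_id",
        )
        subjects["excluded"] = subjects.pop("excluded_flag")
    else:
        subjects = synthetic_data.sample_subject_records(
            cfg["n_subjects"], cfg["cohort"], seed=seeds["behavior"]
        )
        exclusion = pd.DataFrame()
    analyzed = subjects[~subjects["excluded"]].reset_index(drop=True)

    spec = synthetic_data.BoldSimSpec(
        n_rois=cfg["n_rois"],
        n_volumes_per_run=cfg["n_volumes_per_run"],
        n_runs=cfg["n_runs"],
        tr=cfg["tr"],
        rng_seed=seeds["bold"],
    )
    bold = synthetic_data.simulate_bold(spec, analyzed)
    labels = synthetic_data.roi_labels(cfg["n_rois"])

    Z = np.stack(
        [
            connectivity.subject_connectivity(
                b.runs, b.motion, b.wm, b.csf, b.tr, labels
            ).z
            for b in bold.values()
        ]
    )
    design = build_design(analyzed)
    table = edge_stats_table(Z, design, labels,
                             family=cfg["glm"]["family"])
    report = significant_edges(table, alpha=cfg["glm"]["alpha"])

    bundle = {
        "config": cfg,
        "subjects": subjects,
        "exclusion": exclusion,
        "connectivity": Z,
        "roi_labels": labels,
        "edge_stats": table,
        "fdr_report": report,
    }
    if cfg["out_dir"]:
        import os

        os.makedirs(cfg["out_dir"], exist_ok=True)
        subjects.to_csv(
            os.path.join(cfg["out_dir"], "subjects.tsv"), sep="\t",
            index=False,
        )
        if len(exclusion):
            exclusion.to_csv(
                os.path.join(cfg["out_dir"], "exclusion.tsv"), sep="\t",
                index=False,
            )
        table.to_csv(
            os.path.join(cfg["out_dir"], "edge_stats.tsv"), sep="\t",
            index=False,
        )
        report.edges.to_csv(
            os.path.join(cfg["out_dir"], "significant_edges.tsv"), sep="\t",
            index=False,
        )
    return bundle
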