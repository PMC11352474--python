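"""ROI-timeseries denoising and Fisher-z ROI-to-ROI connectivity.

Per run the chain is: framewise-displacement/global-signal outlier
detection, assembly of a confound matrix (constant + linear trend, the six
realignment parameters and their first derivatives, one-hot outlier
indicators, and 5+5 CompCor components from white-matter and CSF source
signals), ordinary-least-squares confound regression, then bandpass
filtering to 0.008–0.09 Hz.  Confound regression precedes filtering.
Connectivity is the weighted Pearson correlation of each ROI pair pooled
across runs — volumes early in a run are down-weighted by the rectified
step-times-HRF response to discount pre-steady-state magnetization — mapped
through Fisher's z = atanh(r).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Head radius (mm) used to convert rotational realignment parameters to a
#: displacement at the scalp in the framewise-displacement sum.
FD_HEAD_RADIUS_MM = 50.0
FD_THRESHOLD_MM = 0.5
GLOBAL_Z_THRESHOLD = 3.0
BANDPASS_HZ = (0.008, 0.09)
N_COMPCOR = 5


@dataclass
class OutlierMask:
    """Per-volume outlier flags with the series that produced them."""

    flags: np.ndarray
    fd: np.ndarray
    global_z: np.ndarray

    @property
    def n_outliers(self) -> int:
        return int(self.flags.sum())


@dataclass
class ConnectivityMatrix:
    """Symmetric ROIs x ROIs Fisher-z matrix; the diagonal is undefined (NaN)."""

    z: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.roi_labels,
                            columns=self.roi_labels)

    def edge_list(self) -> pd.DataFrame:
        """Long format over unordered ROI pairs: roi_a, roi_b, z."""
        n = self.z.shape[0]
        ia, ib = np.triu_indices(n, k=1)
        labels = self.roi_labels or [str(i) for i in range(n)]
        return pd.DataFrame(
            {
                "roi_a": [labels[i] for i in ia],
                "roi_b": [labels[j] for j in ib],
                "z": self.z[ia, ib],
            }
        )


def framewise_displacement(motion) -> np.ndarray:
    """Per-volume framewise displacement, mm.

    ``motion`` has six columns: three translations (mm) and three rotations
    (radians).  FD[t] is the sum of absolute backward differences with
    rotations scaled by a 50 mm head radius; FD[0] = 0.
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion must have 6 columns")
    d = np.abs(np.diff(m, axis=0))
    fd = d[:, :3].sum(axis=1) + FD_HEAD_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def detect_outlier_scans(
    fd: np.ndarray,
    global_signal: np.ndarray,
    fd_threshold: float = FD_THRESHOLD_MM,
    global_z_threshold: float = GLOBAL_Z_THRESHOLD,
) -> OutlierMask:
    """Flag volumes with FD > 0.5 mm or |z-scored global-signal change| > 3."""
    fd = np.asarray(fd, dtype=float)
    g = np.asarray(global_signal, dtype=float)
    if len(fd) != len(g):
        raise ValueError("fd and global_signal length mismatch")
    dg = np.concatenate([[0.0], np.diff(g)])
    sd = dg.std(ddof=0)
    gz = dg / sd if sd > 0 else np.zeros_like(dg)
    flags = (fd > fd_threshold) | (np.abs(gz) > global_z_threshold)
    return OutlierMask(flags=flags, fd=fd, global_z=gz)


def outlier_regressors(mask: OutlierMask) -> np.ndarray:
    """One-hot indicator column per flagged volume (possibly 0 columns)."""
    idx = np.nonzero(mask.flags)[0]
    out = np.zeros((len(mask.flags), len(idx)))
    for j, i in enumerate(idx):
        out[i, j] = 1.0
    return out


def compcor_components(
    noise_signals: np.ndarray,
    n_components: int = N_COMPCOR,
    orthogonalize_against: np.ndarray | None = None,
    rank_rtol: float = 1e-10,
) -> np.ndarray:
    """Principal components of noise-tissue signals for nuisance regression.

    The average noise signal and any supplied regressors are projected out
    first; the top ``n_components`` left singular vectors of the residual
    are returned (unit-norm, mutually orthogonal columns).
    """
    x = np.asarray(noise_signals, dtype=float)
    if x.ndim != 2:
        raise ValueError("noise_signals must be 2D (volumes x signals)")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    mean_signal = x.mean(axis=1, keepdims=True)
    design = mean_signal
    if orthogonalize_against is not None:
        extra = np.asarray(orthogonalize_against, dtype=float)
        if extra.ndim == 1:
            extra = extra[:, None]
        design = np.hstack([design, extra])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    rank = int((s > rank_rtol * max(s[0], 1.0)).sum()) if s.size else 0
    if n_components > rank:
        raise ValueError(
            f"requested {n_components} components but residual rank is {rank}"
        )
    return u[:, :n_components]


def regress_confounds(values: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """OLS residuals of each ROI column on the confound matrix.

    Rank-deficient confounds trigger a warning and a pseudo-inverse fit.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(confounds, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if len(y) != len(x):
        raise ValueError("values and confounds volume counts differ")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        warnings.warn(
            "confound matrix is rank deficient; using pseudo-inverse",
            RuntimeWarning,
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def bandpass_filter(
    values: np.ndarray,
    tr: float,
    low_hz: float = BANDPASS_HZ[0],
    high_hz: float = BANDPASS_HZ[1],
) -> np.ndarray:
    """Frequency-domain bandpass of one run (columns filtered independently).

    Fourier components with frequency outside ``[low_hz, high_hz]`` —
    including DC — are zeroed.  Applied after confound regression.
    """
    y = np.asarray(values, dtype=float)
    nyquist = 0.5 / tr
    if not 0 <= low_hz < high_hz:
        raise ValueError("require 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError("high_hz must be below the Nyquist frequency")
    n = y.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr)
    spec = np.fft.rfft(y, axis=0)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=0)


def canonical_hrf(tr: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR, unit sum.

    Peak at 6 s, undershoot at 16 s, peak-to-undershoot ratio 6.
    """
    t = np.arange(0.0, duration_s + tr, tr)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    return h / h.sum()


def compute_scan_weights(n_volumes: int, tr: float) -> np.ndarray:
    """Per-volume weights discounting the pre-steady-state run onset.

    A unit step at the run onset is convolved with the canonical HRF and
    rectified; the steady-state plateau is 1, so early volumes are
    down-weighted while the bulk of the run carries full weight.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    h = canonical_hrf(tr)
    step = np.ones(n_volumes)
    w = np.convolve(step, h)[:n_volumes]
    return np.clip(w, 0.0, None)


def weighted_correlation(
    values: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Weighted Pearson correlation matrix across rows of ``values``."""
    y = np.asarray(values, dtype=float)
    if weights is None:
        w = np.ones(y.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, not all zero")
    w = w / w.sum()
    mu = w @ y
    yc = y - mu
    xw = yc * np.sqrt(w)[:, None]
    cov = xw.T @ xw
    var = np.diag(cov).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance ROI(s); entries set to NaN",
            RuntimeWarning,
        )
        var[zero] = np.nan
    denom = np.sqrt(np.outer(var, var))
    return cov / denom


def roi_to_roi_fisherz(
    runs: list[np.ndarray],
    weights: list[np.ndarray] | None = None,
    roi_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Fisher-z connectivity pooled across runs.

    Volumes of all runs enter one weighted correlation (weights per run,
    e.g. from :func:`compute_scan_weights`; uniform if None), and
    ``z = atanh(r)``.  The diagonal is NaN.
    """
    if len(runs) == 0:
        raise ValueError("need at least one run")
    ncols = {np.asarray(r).shape[1] for r in runs}
    if len(ncols) != 1:
        raise ValueError("runs have inconsistent ROI counts")
    y = np.vstack([np.asarray(r, dtype=float) for r in runs])
    if weights is None:
        w = None
    else:
        if len(weights) != len(runs):
            raise ValueError("one weight series per run required")
        w = np.concatenate([np.asarray(x, dtype=float) for x in weights])
        if len(w) != len(y):
            raise ValueError("weights and volumes length mismatch")
    r = weighted_correlation(y, w)
    r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    z = (z + z.T) / 2.0  # enforce exact symmetry against rounding
    return ConnectivityMatrix(z=z, roi_labels=roi_labels or [])


# ---------------------------------------------------------------------------
# Per-run denoising driver
# ---------------------------------------------------------------------------

@dataclass
class DenoiseResult:
    values: np.ndarray
    confounds: np.ndarray
    confound_names: list[str]
    outliers: OutlierMask


def build_confound_matrix(
    n_volumes: int,
    motion: np.ndarray,
    outliers: OutlierMask,
    wm_components: np.ndarray,
    csf_components: np.ndarray,
    wm_mean: np.ndarray | None = None,
    csf_mean: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the per-run confound matrix.

    Columns: run constant, linear trend, 6 motion parameters, their 6 first
    derivatives, one-hot outlier indicators, the mean white-matter and CSF
    signals, and 5+5 CompCor components.  The components are computed
    orthogonal to the tissue averages, so the averages themselves must be
    regressed too for the noise-tissue span to be fully removed.  (When runs
    are processed separately, the run-effect regressor of a concatenated
    design is exactly the per-run constant.)
    """
    m = np.asarray(motion, dtype=float)
    dm = np.vstack([np.zeros((1, m.shape[1])), np.diff(m, axis=0)])
    trend = np.linspace(-1.0, 1.0, n_volumes)[:, None]
    out = outlier_regressors(outliers)
    cols = [
        np.ones((n_volumes, 1)),
        trend,
        m,
        dm,
        out,
    ]
    names = (
        ["constant", "trend"]
        + [f"motion_{i}" for i in range(m.shape[1])]
        + [f"motion_deriv_{i}" for i in range(m.shape[1])]
        + [f"outlier_{i}" for i in range(out.shape[1])]
    )
    for name, mean in (("wm_mean", wm_mean), ("csf_mean", csf_mean)):
        if mean is not None:
            cols.append(np.asarray(mean, dtype=float).reshape(-1, 1))
            names.append(name)
    cols.append(np.asarray(wm_components, dtype=float))
    cols.append(np.asarray(csf_components, dtype=float))
    names += [f"wm_comp_{i}"
              for i in range(np.asarray(wm_components).shape[1])]
    names += [f"csf_comp_{i}"
              for i in range(np.asarray(csf_components).shape[1])]
    return np.hstack(cols), names


def denoise_run(
    values: np.ndarray | pd.DataFrame,
    motion: np.ndarray | pd.DataFrame,
    wm_signals: np.ndarray,
    csf_signals: np.ndarray,
    tr: float,
    n_compcor: int = N_COMPCOR,
    band_hz: tuple[float, float] = BANDPASS_HZ,
) -> DenoiseResult:
    """Denoise one run: outliers -> confound regression -> bandpass."""
    y = np.asarray(values, dtype=float)
    m = np.asarray(motion, dtype=float)
    fd = framewise_displacement(m)
    outliers = detect_outlier_scans(fd, y.mean(axis=1))
    base = np.hstack(
        [
            np.ones((len(y), 1)),
            np.linspace(-1.0, 1.0, len(y))[:, None],
            m,
            outlier_regressors(outliers),
        ]
    )
    wm_pcs = compcor_components(wm_signals, n_compcor, base)
    csf_pcs = compcor_components(csf_signals, n_compcor, base)
    confounds, names = build_confound_matrix(
        len(y), m, outliers, wm_pcs, csf_pcs,
        wm_mean=np.asarray(wm_signals, dtype=float).mean(axis=1),
        csf_mean=np.asarray(csf_signals, dtype=float).mean(axis=1),
    )
    resid = regress_confounds(y, confounds)
    filtered = bandpass_filter(resid, tr, *band_hz)
    return DenoiseResult(
        values=filtered, confounds=confounds, confound_names=names,
        outliers=outliers,
    )


def subject_connectivity(
    runs: list[np.ndarray | pd.DataFrame],
    motions: list[np.ndarray | pd.DataFrame],
    wm: list[np.ndarray],
    csf: list[np.ndarray],
    tr: float,
    roi_labels: list[str] | None = None,
    use_scan_weights: bool = True,
) -> ConnectivityMatrix:
    """Full denoise -> weighted Fisher-z chain for one subject."""
    denoised = [
        denoise_run(r, m, w, c, tr).values
        for r, m, w, c in zip(runs, motions, wm, csf)
    ]
    if use_scan_weights:
        weights = [compute_scan_weights(len(d), tr) for d in denoised]
    else:
        weights = None
    return roi_to_roi_fisherz(denoised, weights, roi_labels)
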