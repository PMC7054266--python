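"""First-level GLM machinery for event-related BOLD analysis.

Builds design matrices from event regressors (boxcars at 0.1 s
microtime resolution, scaled by optional parametric amplitudes),
convolves them with a canonical double-gamma hemodynamic response
function, samples at the volume acquisition times, and fits ordinary
least squares with t/z contrast statistics.  High-pass filtering is
implemented as discrete-cosine drift columns added to the design.
Session-level combination is inverse-variance-weighted fixed effects;
the across-subject level is a one-sample t-test, with clusters
extracted from the z map by 26-connected components above a threshold.

Three standard designs are supported by composition:

* simple GLM — all stimuli as one regressor, incongruent stimuli as a
  second;
* RT GLM — all stimuli, plus a regressor whose amplitudes are the
  log-transformed, z-scored RTs;
* DV-GLM — correct-trial events first, then 100 ms events centered on
  the expected-DV extraction time with z-scored DV amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "EventRegressor",
    "DesignMatrix",
    "GLMResult",
    "double_gamma_hrf",
    "build_design",
    "dct_drift",
    "fit_glm",
    "fixed_effects_combine",
    "one_sample_group",
    "extract_clusters",
    "combine_levels",
    "log_zscore_rt",
    "dv_event_onsets",
]

MICROTIME = 0.1  # s; boxcar resolution before HRF convolution


@dataclass
class EventRegressor:
    """A named series of events with durations and parametric amplitudes."""

    name: str
    onsets: np.ndarray
    durations: np.ndarray | float = 1.0
    amplitudes: np.ndarray | float = 1.0

    def __post_init__(self):
        self.onsets = np.atleast_1d(np.asarray(self.onsets, float))
        self.durations = np.broadcast_to(
            np.asarray(self.durations, float), self.onsets.shape).copy()
        self.amplitudes = np.broadcast_to(
            np.asarray(self.amplitudes, float), self.onsets.shape).copy()
        if np.any(self.durations <= 0):
            raise ValueError(f"regressor {self.name!r}: durations must be > 0")


@dataclass
class DesignMatrix:
    """Named design: HRF-convolved task columns plus unconvolved confounds."""

    frame: pd.DataFrame
    task_columns: list[str]
    tr: float

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self):
        return len(self.frame)


def double_gamma_hrf(time_grid) -> np.ndarray:
    """Canonical double-gamma HRF sampled on ``time_grid``.

    Difference of two gamma densities (response peak delay 6 s,
    undershoot delay 16 s, both with unit dispersion, undershoot ratio
    1/6), normalized to a peak of 1.  Zero at t = 0 and for t < 0.
    """
    t = np.asarray(time_grid, float)
    if t.size > 1 and np.max(np.diff(t)) > MICROTIME + 1e-9:
        raise ValueError("HRF grid step must be <= 0.1 s")
    h = (stats.gamma.pdf(t, 6.0, scale=1.0)
         - stats.gamma.pdf(t, 16.0, scale=1.0) / 6.0)
    h = np.where(t < 0, 0.0, h)
    peak = h.max()
    return h / peak if peak > 0 else h


def dct_drift(n_volumes: int, tr: float, cutoff: float = 100.0) -> pd.DataFrame:
    """Discrete-cosine drift columns for high-pass filtering.

    Includes all DCT basis functions with period longer than ``cutoff``
    seconds (the 0.01 Hz convention corresponds to cutoff = 100 s).
    """
    duration = n_volumes * tr
    order = int(np.floor(2 * duration / cutoff))
    frame = np.arange(n_volumes)
    cols = {}
    for k in range(1, max(order, 0) + 1):
        cols[f"drift_{k}"] = np.cos(np.pi * k * (2 * frame + 1) / (2 * n_volumes))
    return pd.DataFrame(cols)


def build_design(events: list[EventRegressor], n_volumes: int,
                 tr: float = 2.0, confounds: pd.DataFrame | None = None,
                 highpass: float | None = None,
                 microtime: float = MICROTIME) -> DesignMatrix:
    """HRF-convolved design matrix sampled at volume acquisition times.

    Each event regressor becomes a boxcar at microtime resolution
    (amplitude x duration), is convolved with the canonical
    double-gamma HRF, and is sampled at ``k * TR`` (volume 0 acquired
    at t = 0).  Confound columns and drift columns are appended
    unconvolved.  Design construction is linear in the amplitudes.
    """
    scan_end = n_volumes * tr
    n_fine = int(np.round(scan_end / microtime))
    hrf = double_gamma_hrf(np.arange(0, 32.0 + microtime / 2, microtime))
    vol_idx = np.round(np.arange(n_volumes) * tr / microtime).astype(int)

    cols = {}
    task_cols = []
    for reg in events:
        if np.any(reg.onsets < 0) or np.any(reg.onsets >= scan_end):
            bad = reg.onsets[(reg.onsets < 0) | (reg.onsets >= scan_end)]
            raise ValueError(
                f"regressor {reg.name!r}: event onset(s) {bad} outside the "
                f"scan [0, {scan_end}) s")
        fine = np.zeros(n_fine)
        for onset, dur, amp in zip(reg.onsets, reg.durations, reg.amplitudes):
            i0 = int(np.round(onset / microtime))
            i1 = min(int(np.round((onset + dur) / microtime)), n_fine)
            fine[i0:max(i1, i0 + 1)] += amp
        conv = np.convolve(fine, hrf)[:n_fine]
        cols[reg.name] = conv[vol_idx]
        task_cols.append(reg.name)

    frame = pd.DataFrame(cols)
    if highpass is not None:
        drift = dct_drift(n_volumes, tr, cutoff=highpass)
        frame = pd.concat([frame, drift], axis=1)
    if confounds is not None:
        confounds = confounds.reset_index(drop=True)
        frame = pd.concat([frame, confounds], axis=1)
    frame["intercept"] = 1.0

    zero = [c for c in task_cols if np.allclose(frame[c], 0)]
    if zero:
        raise ValueError(f"all-zero task regressor column(s): {zero}")
    return DesignMatrix(frame, task_cols, tr)


def log_zscore_rt(rts) -> np.ndarray:
    """Log-transform then z-score RTs (population sd) for the RT GLM."""
    x = np.log(np.asarray(rts, float))
    return (x - x.mean()) / x.std(ddof=0)


def dv_event_onsets(trial_onsets, rts, window_center: float,
                    duration: float = 0.1) -> tuple[np.ndarray, float]:
    """Onsets of DV regressor events centered on their extraction time.

    The expected DV for a window centered ``window_center`` seconds
    before the response maps to scanner time
    ``onset + rt + window_center``; the event of the given duration is
    centered there, so it starts half a duration earlier.
    """
    onsets = (np.asarray(trial_onsets, float) + np.asarray(rts, float)
              + window_center - duration / 2)
    return onsets, duration


@dataclass
class GLMResult:
    """OLS fit of one design against one or more series."""

    betas: np.ndarray            # (n_params, n_series)
    sigma2: np.ndarray           # (n_series,)
    dof: int
    columns: list[str]
    xtx_inv: np.ndarray
    contrasts: dict = field(default_factory=dict)

    def beta(self, column: str) -> np.ndarray:
        return self.betas[self.columns.index(column)]

    def contrast(self, name: str) -> dict:
        return self.contrasts[name]


def fit_glm(data, design: DesignMatrix, contrasts: dict | None = None
            ) -> GLMResult:
    """Ordinary least squares with t/z contrast statistics.

    ``data`` is (n_volumes, n_series); contrasts map names to weight
    vectors over the design columns (shorter vectors are zero-padded on
    the right, covering just the task columns).  For each contrast:
    ``t = c'b / sqrt(sigma2 * c'(X'X)^-1 c)`` and z is the standard
    normal deviate matching the t tail probability.
    """
    y = np.asarray(data, float)
    if y.ndim == 1:
        y = y[:, None]
    X = design.values
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"data has {y.shape[0]} rows but design has {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify offending columns via correlation of residualized columns
        bad = []
        for j in range(p):
            others = np.delete(X, j, axis=1)
            proj, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            if np.allclose(others @ proj, X[:, j], atol=1e-8):
                bad.append(design.columns[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)

    result = GLMResult(beta, sigma2, dof, design.columns, xtx_inv)
    for name, c in (contrasts or {}).items():
        c = np.asarray(c, float)
        if c.size < p:
            c = np.concatenate([c, np.zeros(p - c.size)])
        est = c @ beta
        var = sigma2 * float(c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(var > 0, est / np.sqrt(var), 0.0)
        zval = t_to_z(tval, dof)
        result.contrasts[name] = {"estimate": est, "variance": var,
                                  "t": tval, "z": zval}
    return result


def t_to_z(tval, dof: int) -> np.ndarray:
    """Map t statistics to standard-normal deviates (sign-preserving)."""
    t_arr = np.asarray(tval, float)
    p_tail = stats.t.sf(np.abs(t_arr), dof)
    p_tail = np.clip(p_tail, 1e-300, 1.0)
    return np.sign(t_arr) * stats.norm.isf(p_tail)


def fixed_effects_combine(estimates, variances) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-variance-weighted fixed-effects combination across sessions."""
    est = np.asarray(estimates, float)
    var = np.asarray(variances, float)
    if est.shape[0] == 1:
        return est[0], var[0]
    w = 1.0 / np.clip(var, 1e-300, None)
    comb = (est * w).sum(axis=0) / w.sum(axis=0)
    return comb, 1.0 / w.sum(axis=0)


def one_sample_group(maps) -> dict:
    """One-sample t-test across subjects, per voxel/series.

    Returns mean, t and z arrays (z via the t tail probability).
    """
    m = np.asarray(maps, float)
    n = m.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects for a group test")
    mean = m.mean(axis=0)
    se = m.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, mean / se, 0.0)
    return {"mean": mean, "t": tval, "z": t_to_z(tval, n - 1), "dof": n - 1}


_STRUCTURES = {6: ndimage.generate_binary_structure(3, 1),
               18: ndimage.generate_binary_structure(3, 2),
               26: ndimage.generate_binary_structure(3, 3)}


def extract_clusters(zmap: np.ndarray, threshold: float = 2.5,
                     connectivity: int = 26) -> list[dict]:
    """Connected suprathreshold clusters of a 3D z map.

    Returns one record per cluster (size, peak z, peak index, voxel
    indices), sorted by size descending; empty list when nothing
    survives the threshold.
    """
    zmap = np.asarray(zmap, float)
    labels, n = ndimage.label(zmap > threshold, structure=_STRUCTURES[connectivity])
    out = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        vals = zmap[labels == lab]
        peak = idx[np.argmax(vals)]
        out.append({"size": len(idx), "peak_z": float(vals.max()),
                    "peak_index": tuple(int(i) for i in peak),
                    "voxels": [tuple(int(i) for i in v) for v in idx]})
    out.sort(key=lambda c: -c["size"])
    return out


def combine_levels(session_estimates, session_variances=None,
                   cluster_threshold: float = 2.5) -> dict:
    """Second- then third-level combination.

    ``session_estimates`` is a nested sequence: per subject, per session,
    a voxel array of contrast estimates (with matching variances when
    given).  Sessions are combined by fixed effects; subjects by a
    one-sample t-test; clusters are extracted from the group z map at
    the given threshold (26-connectivity) when it is 3-D.
    """
    subject_maps = []
    for si, sessions in enumerate(session_estimates):
        est = np.asarray(sessions, float)
        if session_variances is not None:
            var = np.asarray(session_variances[si], float)
        else:
            var = np.ones_like(est)
        comb, _ = fixed_effects_combine(est, var)
        subject_maps.append(comb)
    subject_maps = np.asarray(subject_maps)
    group = one_sample_group(subject_maps)
    group["subject_maps"] = subject_maps
    if group["z"].ndim == 3:
        group["clusters"] = extract_clusters(group["z"], cluster_threshold)
    return group
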