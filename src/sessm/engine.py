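"""Transition-matrix first-passage engine for the SE-SSM.

The defective first-passage time densities of the SE-SSM have no closed
form (the conflict-counteraction ramp makes the drift time-varying), so
they are computed numerically: the decision-variable distribution is
discretized on a uniform grid and propagated step by step through a
(possibly time-varying) Gaussian transition kernel; states at or beyond
the bounds are absorbing.  Because the drift does not depend on the
decision variable itself, each transition matrix is a Toeplitz
(shift-invariant) convolution, which is what makes the propagation fast.

The absorbed-mass increments above the upper bound and below the lower
bound give the defective CDFs for correct and error responses; the
densities are obtained by numerical differentiation of those CDFs.
Response-time-domain densities are produced by shifting by the base
non-decision time and convolving with the uniform jitter kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .params import (SEParams, BehavioralDataset, instantaneous_drift,
                     starting_point, validate_condition)

__all__ = [
    "EngineConfig",
    "FirstPassageDensity",
    "build_grid",
    "propagate",
    "apply_nondecision",
    "trial_loglik",
]

try:  # optional JIT acceleration of the propagation loop
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba present in normal installs
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class EngineConfig:
    """Numerical settings for the first-passage engine.

    dx : decision-variable grid spacing (0.01 coarse pass, 0.005 refinement)
    dt : time step in seconds
    t_max : decision-time horizon in seconds
    boundary_pad : grid extension beyond +/- x_th, in multiples of s*sqrt(dt)
    density_floor : minimum density entering the log-likelihood
    """

    dx: float = 0.01
    dt: float = 0.001
    t_max: float = 5.0
    boundary_pad: float = 5.0
    density_floor: float = 1e-10

    def __post_init__(self):
        if self.dx <= 0 or self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dx, dt and t_max must all be > 0")
        if self.boundary_pad < 5:
            raise ValueError("boundary_pad must be >= 5")
        if self.density_floor <= 0:
            raise ValueError("density_floor must be > 0")

    def replace(self, **kw) -> "EngineConfig":
        return replace(self, **kw)


@dataclass
class FirstPassageDensity:
    """Defective first-passage densities/CDFs for one trial condition.

    ``time_grid`` holds decision times at spacing ``dt`` (or observed RT
    after :func:`apply_nondecision`); ``pdf_correct``/``pdf_error`` are
    the defective densities (1/s) and ``cdf_correct``/``cdf_error`` the
    defective CDFs.  ``cdf_correct[-1] + cdf_error[-1] <= 1``, the gap
    being mass still unabsorbed at the horizon.
    """

    time_grid: np.ndarray
    pdf_correct: np.ndarray
    pdf_error: np.ndarray
    cdf_correct: np.ndarray
    cdf_error: np.ndarray
    condition: int

    @property
    def total_mass(self) -> float:
        return float(self.cdf_correct[-1] + self.cdf_error[-1])

    @property
    def p_correct(self) -> float:
        return float(self.cdf_correct[-1])

    def interp_pdf(self, rt, correct: bool):
        """Linearly interpolate a defective density at the given time(s).

        Times outside the grid return 0.
        """
        pdf = self.pdf_correct if correct else self.pdf_error
        return np.interp(np.asarray(rt, float), self.time_grid, pdf,
                         left=0.0, right=0.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time": self.time_grid,
            "pdf_correct": self.pdf_correct,
            "pdf_error": self.pdf_error,
            "cdf_correct": self.cdf_correct,
            "cdf_error": self.cdf_error,
        })


def _interior_cells(params: SEParams, config: EngineConfig
                    ) -> tuple[int, float]:
    """Number and width of interior cells tiling (-x_th, +x_th).

    Cells are edge-aligned with the bounds: m cells of width
    ``2*x_th/m`` (m chosen so the width is as close as possible to the
    nominal dx), so the absorbing boundary sits exactly at the
    threshold rather than half a cell inside it.
    """
    m = int(round(2 * params.x_th / config.dx))
    if m < 1:
        raise ValueError(
            f"grid spacing dx={config.dx} leaves no states inside |x| < "
            f"x_th={params.x_th}")
    return m, 2 * params.x_th / m


def build_grid(params: SEParams, config: EngineConfig) -> np.ndarray:
    """Uniform decision-variable grid spanning ``+/-(x_th + pad*s*sqrt(dt))``.

    Cell centers are edge-aligned with the bounds (the edge between the
    last interior and first absorbing cell lies exactly at ``+/-x_th``),
    so grid points with ``|x| > x_th`` are the absorbing states.  Raises
    if the grid has no interior states or the starting bias falls
    outside the interior.
    """
    m, dxe = _interior_cells(params, config)
    pad = int(np.ceil(config.boundary_pad * params.s * np.sqrt(config.dt) / dxe))
    j = np.arange(-pad, m + pad)
    grid = -params.x_th + dxe * (j + 0.5)
    if params.x_b >= params.x_th:
        raise ValueError("starting bias x_b lies outside the grid interior")
    return grid


def _step_kernels(params: SEParams, c: int, config: EngineConfig,
                  n_steps: int, dxe: float) -> np.ndarray:
    """Per-step displacement kernels, one row per time step.

    Each row is the Gaussian single-step transition column with mean
    ``drift(d_k) * dt`` and sd ``s*sqrt(dt)``, integrated over
    destination cells of width ``dxe`` (tails folded into the end
    taps, so each column sums to one and interior probability is
    conserved before absorption accounting).  For c=0 the kernel is
    time-invariant and a single row is returned.
    """
    from scipy.special import ndtr

    sigma = params.s * np.sqrt(config.dt)
    if c == 0 or params.b == 0:
        d = np.zeros(1)
    else:
        d = np.arange(n_steps) * config.dt
    mu = instantaneous_drift(params, c, d) * config.dt
    mu = np.atleast_1d(mu)
    half_w = int(np.ceil((np.max(np.abs(mu)) + 6.0 * sigma) / dxe))
    edges = (np.arange(-half_w, half_w + 1) + 0.5) * dxe
    cdf = ndtr((edges[None, :] - mu[:, None]) / sigma)
    w = np.empty((mu.size, 2 * half_w + 1))
    w[:, 0] = cdf[:, 0]
    w[:, 1:] = np.diff(cdf, axis=1)
    w[:, -1] += 1.0 - cdf[:, -1]
    return np.ascontiguousarray(w)


def _propagate_py(p, kernels, n_steps):
    """Pure-numpy propagation loop (reference path)."""
    m = p.size
    half_w = (kernels.shape[1] - 1) // 2
    tv = kernels.shape[0] > 1
    abs_hi = np.zeros(n_steps)
    abs_lo = np.zeros(n_steps)
    k_used = n_steps
    for k in range(n_steps):
        w = kernels[k] if tv else kernels[0]
        conv = np.convolve(p, w)
        abs_lo[k] = conv[:half_w].sum()
        abs_hi[k] = conv[m + half_w:].sum()
        p = conv[half_w:m + half_w]
        if p.sum() < 1e-12:
            k_used = k + 1
            break
    return abs_hi, abs_lo, k_used


if _HAVE_NUMBA:

    @_njit(cache=True, fastmath=True)
    def _propagate_nb(p0, kernels, n_steps):  # pragma: no cover - jitted
        m = p0.size
        width = kernels.shape[1]
        half_w = (width - 1) // 2
        tv = kernels.shape[0] > 1
        p = p0.copy()
        abs_hi = np.zeros(n_steps)
        abs_lo = np.zeros(n_steps)
        k_used = n_steps
        conv = np.zeros(m + 2 * half_w)
        for k in range(n_steps):
            w = kernels[k] if tv else kernels[0]
            for i in range(conv.size):
                conv[i] = 0.0
            for i in range(m):
                pi = p[i]
                if pi > 0.0:
                    for j in range(width):
                        conv[i + j] += pi * w[j]
            lo = 0.0
            hi = 0.0
            for j in range(half_w):
                lo += conv[j]
                hi += conv[m + half_w + j]
            abs_lo[k] = lo
            abs_hi[k] = hi
            tot = 0.0
            for i in range(m):
                p[i] = conv[half_w + i]
                tot += p[i]
            if tot < 1e-12:
                k_used = k + 1
                break
        return abs_hi, abs_lo, k_used


def propagate(params: SEParams, c, config: EngineConfig | None = None,
              t_max: float | None = None) -> FirstPassageDensity:
    """First-passage densities of the SE-SSM for one condition.

    Starting from a point mass at the grid point nearest the condition's
    starting point, the decision-variable distribution is pushed through
    the per-step Gaussian displacement kernel; mass landing at or beyond
    ``+x_th`` (``-x_th``) is absorbed into the correct (error) CDF.  On
    conflict trials with ``b > 0`` the kernel mean shifts with elapsed
    time, so one kernel row is used per step; otherwise a single kernel
    is reused ("the transition matrix is fixed on non-conflict trials").
    """
    config = config or EngineConfig()
    ci = validate_condition(c)
    horizon = config.t_max if t_max is None else min(t_max, config.t_max)
    n_steps = max(1, int(round(horizon / config.dt)))

    m, dxe = _interior_cells(params, config)
    x_int = -params.x_th + dxe * (np.arange(m) + 0.5)

    # initial mass linearly split between the two centers bracketing x0
    x0 = starting_point(params, ci)
    p0 = np.zeros(m)
    f = (x0 - x_int[0]) / dxe
    i0 = int(np.clip(np.floor(f), 0, m - 1))
    i1 = min(i0 + 1, m - 1)
    frac = float(np.clip(f - i0, 0.0, 1.0))
    p0[i0] += 1.0 - frac
    p0[i1] += frac

    kernels = _step_kernels(params, ci, config, n_steps, dxe)
    if _HAVE_NUMBA:
        abs_hi, abs_lo, k_used = _propagate_nb(p0, kernels, n_steps)
    else:
        abs_hi, abs_lo, k_used = _propagate_py(p0, kernels, n_steps)

    if not (np.isfinite(abs_hi).all() and np.isfinite(abs_lo).all()):
        raise FloatingPointError("NaN/inf encountered in first-passage propagation")

    cdf_c = np.concatenate([[0.0], np.cumsum(abs_hi)])
    cdf_e = np.concatenate([[0.0], np.cumsum(abs_lo)])
    if k_used < n_steps:  # everything absorbed early; pad flat
        cdf_c[k_used + 1:] = cdf_c[k_used]
        cdf_e[k_used + 1:] = cdf_e[k_used]

    leak = 1.0 - (cdf_c[-1] + cdf_e[-1])
    if t_max is None and leak > 1e-3:
        warnings.warn(
            f"{leak:.2e} of first-passage mass not absorbed by t_max="
            f"{horizon}s; consider a longer horizon", RuntimeWarning)

    time_grid = np.arange(n_steps + 1) * config.dt
    # "the cumulative density is numerically differentiated"
    pdf_c = np.gradient(cdf_c, config.dt)
    pdf_e = np.gradient(cdf_e, config.dt)
    return FirstPassageDensity(time_grid, pdf_c, pdf_e, cdf_c, cdf_e, ci)


def _uniform_kernel(s_t: float, dt: float) -> np.ndarray:
    """Discretized centered uniform kernel of total width ``s_t``.

    Weights are bin overlaps with [-s_t/2, +s_t/2], normalized to sum 1,
    so convolution conserves mass exactly.
    """
    if s_t == 0:
        return np.ones(1)
    half = s_t / 2.0
    k = int(np.ceil(half / dt + 0.5))
    centers = np.arange(-k, k + 1) * dt
    lo = np.maximum(centers - dt / 2, -half)
    hi = np.minimum(centers + dt / 2, half)
    w = np.clip(hi - lo, 0.0, None)
    total = w.sum()
    if total <= 0:
        return np.ones(1)
    return w / total


def apply_nondecision(fpd: FirstPassageDensity, params: SEParams
                      ) -> FirstPassageDensity:
    """Map decision-time densities to observed-RT densities.

    Shifts the time axis by the base non-decision time ``t`` and
    convolves each defective density with the uniform jitter kernel of
    width ``s_t``; total mass is preserved.
    """
    if params.s_t < 0:
        raise ValueError("s_t must be >= 0")
    dt = float(fpd.time_grid[1] - fpd.time_grid[0])
    w = _uniform_kernel(params.s_t, dt)
    k = (w.size - 1) // 2
    if k == 0:
        return FirstPassageDensity(
            fpd.time_grid + params.t, fpd.pdf_correct, fpd.pdf_error,
            fpd.cdf_correct, fpd.cdf_error, fpd.condition)
    pdf_c = np.convolve(fpd.pdf_correct, w)
    pdf_e = np.convolve(fpd.pdf_error, w)
    time = params.t + np.arange(-k, fpd.time_grid.size + k) * dt + fpd.time_grid[0]
    # the CDF of a sum is the CDF convolved with the addend's density
    # (the kernel is symmetric, so orientation is immaterial)
    cdf_c = _convolve_cdf(fpd.cdf_correct, w, k)
    cdf_e = _convolve_cdf(fpd.cdf_error, w, k)
    return FirstPassageDensity(time, pdf_c, pdf_e, cdf_c, cdf_e, fpd.condition)


def _convolve_cdf(cdf: np.ndarray, w: np.ndarray, k: int) -> np.ndarray:
    ext = np.concatenate([np.zeros(2 * k), cdf, np.full(2 * k, cdf[-1])])
    return np.convolve(ext, w, mode="valid")


def rt_densities(params: SEParams, config: EngineConfig | None = None,
                 t_max: float | None = None) -> dict[int, FirstPassageDensity]:
    """RT-domain densities for both conditions (one propagation each)."""
    config = config or EngineConfig()
    return {c: apply_nondecision(propagate(params, c, config, t_max=t_max), params)
            for c in (0, 1)}


def trial_loglik(dataset: BehavioralDataset, params: SEParams,
                 config: EngineConfig | None = None) -> float:
    """Negative log-likelihood (nats) of a dataset under the SE-SSM.

    Two propagations (conflict and non-conflict) are shared by all
    trials; each trial contributes ``-log max(floor, f_{choice,c}(rt))``
    with the RT-domain defective density linearly interpolated at the
    observed RT.  The decision-time horizon is adapted to the slowest
    observed response (capped at ``config.t_max``).
    """
    config = config or EngineConfig()
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    max_rt = float(np.max(dataset.rt))
    horizon = max_rt - params.t + params.s_t / 2 + 2 * config.dt
    horizon = min(max(horizon, 10 * config.dt), config.t_max)

    beyond = dataset.rt > config.t_max + params.t + params.s_t / 2
    if beyond.any():
        warnings.warn(
            f"{int(beyond.sum())} trial(s) have RTs beyond the engine horizon; "
            "they contribute the density floor", RuntimeWarning)

    nll = 0.0
    for c in (0, 1):
        sel = dataset.condition == c
        if not sel.any():
            continue
        dens = apply_nondecision(propagate(params, c, config, t_max=horizon), params)
        for correct in (True, False):
            sub = sel & (dataset.correct == correct)
            if not sub.any():
                continue
            f = dens.interp_pdf(dataset.rt[sub], correct)
            nll -= np.log(np.maximum(f, config.density_floor)).sum()
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite negative log-likelihood")
    return float(nll)
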