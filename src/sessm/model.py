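"""Maximum-likelihood fitting of the SE-SSM.

The public surface follows the modelling-object convention: build a
:class:`SimonSSM` from a behavioral dataset (or DataFrame), call
``fit()``, and get a :class:`SimonSSMResults` carrying the estimates,
the negative log-likelihood, AIC, per-restart diagnostics and a
``summary()`` table.  ``fit_subject`` is the functional core.

Estimation minimizes the negative log-likelihood of the joint choice-RT
distribution (both correct and error trials) with a bounded compass
(generalized pattern) search: several independently initialized
restarts at the coarse decision-variable resolution, then one
refinement pass at the fine resolution starting from the best restart.
Starting points are drawn from fixed distributions over plausible
parameter values (Gamma for v, x_th, t and x_b, half-normal for b,
uniform for s_t).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .params import SEParams, BehavioralDataset
from .engine import EngineConfig, trial_loglik

__all__ = [
    "ModelSpec",
    "MODELS",
    "FitConfig",
    "FitResult",
    "sample_initial_params",
    "fit_subject",
    "SimonSSM",
    "SimonSSMResults",
]


@dataclass(frozen=True)
class ModelSpec:
    """A member of the M1-M4 candidate family.

    M1 is the basic SSM (v, x_th, t, s_t free); M2 adds the conflict
    counteraction gain b; M3 adds the starting bias x_b; M4 (the full
    SE-SSM) frees both.
    """

    name: str
    free_b: bool
    free_xb: bool

    @property
    def n_free(self) -> int:
        return 4 + int(self.free_b) + int(self.free_xb)

    @property
    def free_names(self) -> tuple[str, ...]:
        names = ["v", "x_th", "t", "s_t"]
        if self.free_b:
            names.append("b")
        if self.free_xb:
            names.append("x_b")
        return tuple(names)


MODELS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", free_b=False, free_xb=False),
    "M2": ModelSpec("M2", free_b=True, free_xb=False),
    "M3": ModelSpec("M3", free_b=False, free_xb=True),
    "M4": ModelSpec("M4", free_b=True, free_xb=True),
}


@dataclass(frozen=True)
class FitConfig:
    """Settings for the restart/refinement fitting procedure."""

    n_restarts: int = 5
    coarse_dx: float = 0.01
    fine_dx: float = 0.005
    rng_seed: int = 0
    nll_tol: float = 1e-3
    max_poll_iter: int = 120
    engine: EngineConfig = field(default_factory=EngineConfig)

    def __post_init__(self):
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    def replace(self, **kw) -> "FitConfig":
        return replace(self, **kw)


@dataclass
class FitResult:
    """Outcome of one subject-level fit."""

    params: SEParams
    nll: float
    model: ModelSpec
    restart_nlls: list[float]
    restart_params: list[SEParams]
    converged: bool
    n_evals: int

    @property
    def n_free(self) -> int:
        return self.model.n_free

    @property
    def aic(self) -> float:
        return 2 * self.model.n_free + 2 * self.nll


# initialization distributions: Gamma parameterized by (mean, sd) via
# moment matching shape=(mean/sd)^2, scale=sd^2/mean; half-normal by sd;
# uniform by its limits
_INIT = {
    "v": ("gamma", 3.0, 1.0),
    "x_th": ("gamma", 0.6, 0.15),
    "t": ("gamma", 0.3, 0.075),
    "b": ("halfnormal", 2.5),
    "x_b": ("gamma", 0.1, 0.06),
    "s_t": ("uniform", 0.0, 0.15),
}

# Box bounds for the search; chosen to enclose the initialization
# distributions with wide margins.  s_t and x_b additionally respect the
# coupled constraints s_t <= 2t - 0.01 and x_b <= 0.95 x_th.
_BOUNDS = {
    "v": (1e-3, 20.0),
    "x_th": (0.05, 5.0),
    "t": (0.05, 1.5),
    "s_t": (0.0, 0.5),
    "b": (0.0, 20.0),
    "x_b": (0.0, 4.75),  # static cap; 0.95*x_th applied dynamically
}


def _gamma_moment_match(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return shape, scale


def sample_initial_params(model_spec: ModelSpec | str, rng=None) -> SEParams:
    """Draw a random valid starting point for the optimizer.

    Parameters fixed by the model spec (b and/or x_b) are forced to 0;
    the noise scale s is fixed at 1.  Draws violating the coupled
    invariants (x_b < x_th, t - s_t/2 > 0) are nudged inside.
    """
    spec = MODELS[model_spec] if isinstance(model_spec, str) else model_spec
    rng = np.random.default_rng(rng)
    draws = {}
    for name, dist in _INIT.items():
        if dist[0] == "gamma":
            shape, scale = _gamma_moment_match(dist[1], dist[2])
            draws[name] = rng.gamma(shape, scale)
        elif dist[0] == "halfnormal":
            draws[name] = abs(rng.normal(0.0, dist[1]))
        else:
            draws[name] = rng.uniform(dist[1], dist[2])
    if not spec.free_b:
        draws["b"] = 0.0
    if not spec.free_xb:
        draws["x_b"] = 0.0
    return SEParams(**_project(draws))


def _project(vals: dict) -> dict:
    """Clip a raw parameter dict into the feasible box (incl. couplings)."""
    out = {}
    for name in ("v", "x_th", "t", "s_t", "b", "x_b"):
        lo, hi = _BOUNDS[name]
        out[name] = float(np.clip(vals[name], lo, hi))
    out["s_t"] = min(out["s_t"], 2 * out["t"] - 0.01)
    out["s_t"] = max(out["s_t"], 0.0)
    out["x_b"] = min(out["x_b"], 0.95 * out["x_th"])
    out["s"] = 1.0
    return out


# initial poll step per parameter (about one prior standard deviation);
# the mesh halves on failed polls down to _MESH_SHRINK of these
_POLL_SCALE = {"v": 1.0, "x_th": 0.15, "t": 0.075, "s_t": 0.05,
               "b": 2.0, "x_b": 0.06}
_MESH_SHRINK = 1.0 / 256.0


def _pattern_search(objective: Callable[[dict], float], start: dict,
                    free_names: Sequence[str], init_frac: float,
                    nll_tol: float, max_iter: int) -> tuple[dict, float, int, bool]:
    """Bounded compass (generalized pattern) search.

    Polls +/- one mesh step along each free coordinate; moves greedily
    to any improvement and halves the mesh when a full poll fails.
    Converges when the mesh has contracted below 1/256 of the initial
    poll scale and the last contraction cycle improved the NLL by less
    than ``nll_tol``.  Deterministic; evaluations are cached.
    """
    mesh = {n: init_frac * _POLL_SCALE[n] for n in free_names}
    floor = {n: _MESH_SHRINK * _POLL_SCALE[n] for n in free_names}
    x = _project(start)
    cache: dict[tuple, float] = {}
    n_evals = 0

    def ev(vals: dict) -> float:
        nonlocal n_evals
        key = tuple(round(vals[n], 10) for n in ("v", "x_th", "t", "s_t", "b", "x_b"))
        if key not in cache:
            cache[key] = objective(vals)
            n_evals += 1
        return cache[key]

    f = ev(x)
    converged = False
    f_at_last_contraction = f
    for _ in range(max_iter):
        improved = False
        for name in free_names:
            for sign in (+1.0, -1.0):
                cand = dict(x)
                cand[name] = cand[name] + sign * mesh[name]
                cand = _project(cand)
                fc = ev(cand)
                if fc < f - 1e-12:
                    x, f = cand, fc
                    improved = True
        if not improved:
            small = all(mesh[n] <= floor[n] for n in free_names)
            if small and f_at_last_contraction - f < nll_tol:
                converged = True
                break
            f_at_last_contraction = f
            for n in free_names:
                mesh[n] = max(mesh[n] * 0.5, floor[n])
    return x, f, n_evals, converged


def _make_objective(dataset: BehavioralDataset, spec: ModelSpec,
                    engine: EngineConfig):
    def objective(vals: dict) -> float:
        p = dict(vals)
        if not spec.free_b:
            p["b"] = 0.0
        if not spec.free_xb:
            p["x_b"] = 0.0
        try:
            params = SEParams(**_project(p))
            return trial_loglik(dataset, params, engine)
        except (ValueError, FloatingPointError):
            return np.inf
    return objective


def fit_subject(dataset: BehavioralDataset,
                model_spec: ModelSpec | str = "M4",
                fit_config: FitConfig | None = None,
                start: SEParams | None = None,
                extra_starts: Sequence[SEParams] = ()) -> FitResult:
    """Fit one subject by multi-restart pattern search with refinement.

    Runs ``n_restarts`` independent searches at the coarse grid
    resolution, then a single refinement pass at the fine resolution
    starting from the best candidate (the best coarse solution or any
    of ``extra_starts``, e.g. nested-submodel solutions, evaluated at
    the fine resolution).  Deterministic given ``fit_config.rng_seed``.
    """
    spec = MODELS[model_spec] if isinstance(model_spec, str) else model_spec
    cfg = fit_config or FitConfig()
    if not dataset.has_both_conditions():
        raise ValueError(
            f"subject {dataset.subject_id!r}: fitting requires at least one "
            "trial of each condition")

    import warnings as _w

    rng = np.random.default_rng(cfg.rng_seed)
    coarse_engine = cfg.engine.replace(dx=cfg.coarse_dx)
    fine_engine = cfg.engine.replace(dx=cfg.fine_dx)
    obj_coarse = _make_objective(dataset, spec, coarse_engine)
    obj_fine = _make_objective(dataset, spec, fine_engine)

    restart_nlls: list[float] = []
    restart_params: list[SEParams] = []
    total_evals = 0
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        for r in range(cfg.n_restarts):
            if start is not None and r == 0:
                p0 = start.to_dict()
            else:
                p0 = sample_initial_params(spec, rng).to_dict()
            x, f, nev, _ = _pattern_search(
                obj_coarse, p0, spec.free_names, init_frac=1.0,
                nll_tol=cfg.nll_tol, max_iter=cfg.max_poll_iter)
            restart_nlls.append(f)
            restart_params.append(SEParams(**x))
            total_evals += nev

        if not np.isfinite(restart_nlls).any():
            raise RuntimeError(
                f"subject {dataset.subject_id!r}, model {spec.name}: all "
                f"{cfg.n_restarts} restarts failed "
                f"(restart NLLs: {restart_nlls})")

        # "one further pass using the previous best model as a starting point"
        best = int(np.argmin(restart_nlls))
        candidates = [restart_params[best], *extra_starts]
        fine_at = [obj_fine(p.to_dict()) for p in candidates]
        total_evals += len(candidates)
        start_fine = candidates[int(np.argmin(fine_at))]
        x, f, nev, converged = _pattern_search(
            obj_fine, start_fine.to_dict(), spec.free_names,
            init_frac=0.25, nll_tol=cfg.nll_tol, max_iter=cfg.max_poll_iter)
        total_evals += nev

    return FitResult(params=SEParams(**x), nll=f, model=spec,
                     restart_nlls=restart_nlls, restart_params=restart_params,
                     converged=converged, n_evals=total_evals)


class SimonSSM:
    """SE-SSM likelihood model for one subject's choice-RT data.

    Parameters
    ----------
    data : BehavioralDataset or DataFrame
        Trials with columns/fields ``condition`` (0 = non-conflict,
        1 = conflict), ``rt`` (s) and ``correct``.
    model : str or ModelSpec
        Candidate family member, one of M1-M4 (default the full SE-SSM).
    engine : EngineConfig, optional
        Numerical settings for the likelihood engine.

    Examples
    --------
    >>> mod = SimonSSM.from_dataframe(df, model="M4")
    >>> res = mod.fit(FitConfig(rng_seed=1))
    >>> print(res.summary())
    """

    def __init__(self, data: BehavioralDataset | pd.DataFrame,
                 model: str | ModelSpec = "M4",
                 engine: EngineConfig | None = None):
        if isinstance(data, pd.DataFrame):
            data = BehavioralDataset.from_dataframe(data)
        self.data = data
        self.spec = MODELS[model] if isinstance(model, str) else model
        self.engine = engine or EngineConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, subject_id: str = "subject",
                       **kw) -> "SimonSSM":
        return cls(BehavioralDataset.from_dataframe(df, subject_id), **kw)

    def loglike(self, params: SEParams) -> float:
        """Log-likelihood (nats) of the data at ``params``."""
        return -trial_loglik(self.data, params, self.engine)

    def nloglike(self, params: SEParams) -> float:
        return trial_loglik(self.data, params, self.engine)

    def fit(self, fit_config: FitConfig | None = None,
            start: SEParams | None = None) -> "SimonSSMResults":
        cfg = fit_config or FitConfig()
        cfg = cfg.replace(engine=self.engine)
        res = fit_subject(self.data, self.spec, cfg, start=start)
        return SimonSSMResults(self, res, cfg)

    def simulate(self, params: SEParams, n_per_condition: int,
                 rng=None, **kw):
        from .simulate import simulate_dataset

        return simulate_dataset(params, n_per_condition, rng=rng,
                                subject_id=self.data.subject_id, **kw)


class SimonSSMResults:
    """Fitted SE-SSM: estimates, fit quality and diagnostics."""

    def __init__(self, model: SimonSSM, fit: FitResult, config: FitConfig):
        self.model = model
        self.fit_result = fit
        self.config = config

    @property
    def params(self) -> SEParams:
        return self.fit_result.params

    @property
    def nll(self) -> float:
        return self.fit_result.nll

    @property
    def llf(self) -> float:
        return -self.fit_result.nll

    @property
    def aic(self) -> float:
        return self.fit_result.aic

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    def params_frame(self) -> pd.DataFrame:
        spec = self.fit_result.model
        rows = []
        for name in ("v", "x_th", "t", "s_t", "b", "x_b", "s"):
            rows.append({
                "parameter": name,
                "estimate": getattr(self.params, name),
                "free": name in spec.free_names,
            })
        return pd.DataFrame(rows).set_index("parameter")

    def summary(self) -> str:
        spec = self.fit_result.model
        d = self.model.data
        lines = [
            "Simon-effect SSM fit",
            "=" * 46,
            f"subject:        {d.subject_id}",
            f"model:          {spec.name} ({spec.n_free} free parameters)",
            f"n trials:       {len(d)} "
            f"(non-conflict {int((d.condition == 0).sum())}, "
            f"conflict {int((d.condition == 1).sum())})",
            f"neg. loglik:    {self.nll:.3f} nats",
            f"AIC:            {self.aic:.3f}",
            f"converged:      {self.converged}",
            f"restart NLLs:   {', '.join(f'{v:.2f}' for v in self.fit_result.restart_nlls)}",
            "-" * 46,
            f"{'parameter':>10}  {'estimate':>10}  {'free':>5}",
        ]
        for name, row in self.params_frame().iterrows():
            lines.append(
                f"{name:>10}  {row['estimate']:>10.4f}  "
                f"{'yes' if row['free'] else 'no':>5}")
        return "\n".join(lines)

    def simulate(self, n_per_condition: int, rng=None, **kw):
        """Resimulate behavior at the fitted parameters."""
        return self.model.simulate(self.params, n_per_condition, rng=rng, **kw)

    def predicted_densities(self, t_max: float | None = None):
        """RT-domain defective densities per condition at the estimates."""
        from .engine import rt_densities

        return rt_densities(self.params, self.model.engine, t_max=t_max)

    def plot_fit(self, ax=None, n_bins: int = 30):
        """Overlay predicted RT densities on the observed RT histograms."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dens = self.predicted_densities()
        d = self.model.data
        colors = {0: "tab:orange", 1: "tab:blue"}
        labels = {0: "non-conflict", 1: "conflict"}
        for c in (0, 1):
            sel = (d.condition == c) & d.correct
            if sel.any():
                ax.hist(d.rt[sel], bins=n_bins, density=True, alpha=0.3,
                        color=colors[c], label=f"{labels[c]} (data)")
            fp = dens[c]
            pc = fp.cdf_correct[-1]
            if pc > 0:
                ax.plot(fp.time_grid, fp.pdf_correct / pc, color=colors[c],
                        label=f"{labels[c]} (model)")
        ax.set_xlabel("RT (s)")
        ax.set_ylabel("density (correct responses)")
        ax.legend()
        return ax
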