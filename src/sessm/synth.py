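"""Synthetic cohorts and BOLD fixtures with a realistic task structure.

The behavioral generator emulates a two-session Simon task cohort:
21 subjects, 2 sessions each, every session holding 48 congruent, 48
incongruent and 24 null trials of 2.5 s (TR = 2 s, 151 volumes per
session).  Subject-level SE-SSM parameters are drawn from a population
with coupled conflict parameters (see :func:`sample_population_params`),
so cohort-level Simon signatures (slower and less accurate conflict
responses, fast conflict errors) emerge from the model rather than
being painted on.

The imaging generators produce small 3-D beta-map groups with planted
covariate-linked regions and 4-D series with planted HRF-convolved
responses plus white noise — enough structure to validate every
pipeline stage without any download.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy import stats

from .params import SEParams, BehavioralDataset, BehavioralTrial
from .model import _gamma_moment_match, _project
from .simulate import simulate_trials
from .glm import EventRegressor, build_design

__all__ = [
    "CohortSpec",
    "SyntheticScanSpec",
    "SyntheticSubject",
    "sample_population_params",
    "generate_cohort",
    "generate_group_maps",
    "generate_bold",
    "events_frame",
]


def sample_population_params(rng=None, copula_rho: float = 0.5,
                             b_scale: float = 1.5) -> SEParams:
    """Draw one subject's parameters from the synthetic population.

    Marginals: v ~ G(3, 1), x_th ~ G(0.6, 0.15), t ~ G(0.3, 0.075),
    s_t ~ U(0, 0.15), x_b ~ G(0.1, 0.06) and b ~ HN(b_scale).  The
    conflict-specific pair (b, x_b) is coupled through a Gaussian
    copula (rho = 0.5, Spearman ~ 0.48): subjects with a stronger
    automatic bias deploy stronger counteraction.  The coupling — and a
    population counteraction scale weaker than the optimizer's
    initialization prior (about half of real subjects show little or no
    counteraction) — is what lets the cohort-level Simon RT cost
    (~25 ms) emerge: counteraction alone *speeds* conflict trials, so
    an uncoupled population frequently cancels the effect.  It also
    leaves RT summaries only weakly informative about either conflict
    parameter, the situation the across-subject negative control
    probes.
    """
    rng = np.random.default_rng(rng)
    shape_v, scale_v = _gamma_moment_match(3.0, 1.0)
    shape_th, scale_th = _gamma_moment_match(0.6, 0.15)
    shape_t, scale_t = _gamma_moment_match(0.3, 0.075)
    shape_xb, scale_xb = _gamma_moment_match(0.1, 0.06)
    z1 = rng.standard_normal()
    z2 = copula_rho * z1 + math.sqrt(1 - copula_rho ** 2) * rng.standard_normal()
    draws = {
        "v": rng.gamma(shape_v, scale_v),
        "x_th": rng.gamma(shape_th, scale_th),
        "t": rng.gamma(shape_t, scale_t),
        "s_t": rng.uniform(0.0, 0.15),
        "x_b": stats.gamma.ppf(stats.norm.cdf(z1), shape_xb, scale=scale_xb),
        "b": stats.halfnorm.ppf(stats.norm.cdf(z2), scale=b_scale),
    }
    return SEParams(**_project(draws))


@dataclass(frozen=True)
class CohortSpec:
    """Structure of a synthetic behavioral cohort (typical Simon-task fMRI protocol)."""

    n_subjects: int = 21
    sessions_per_subject: int = 2
    n_congruent: int = 48
    n_incongruent: int = 48
    n_null: int = 24
    trial_duration: float = 2.5
    stimulus_duration: float = 1.0
    rng_seed: int = 0
    model: str = "M4"

    def __post_init__(self):
        if min(self.n_subjects, self.sessions_per_subject, self.n_congruent,
               self.n_incongruent) < 1 or self.n_null < 0:
            raise ValueError("cohort counts must be positive")

    @property
    def trials_per_session(self) -> int:
        return self.n_congruent + self.n_incongruent + self.n_null


@dataclass(frozen=True)
class SyntheticScanSpec:
    """Structure of a synthetic scan (EPI-like grid and timing)."""

    shape: tuple = (10, 10, 10)
    tr: float = 2.0
    n_volumes: int = 151
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be > 0")


@dataclass
class SyntheticSubject:
    subject_id: str
    params: SEParams
    dataset: BehavioralDataset
    events: dict[str, pd.DataFrame] = field(default_factory=dict)


def events_frame(trials: list[dict], spec: CohortSpec) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type,
    response_time, correct)."""
    return pd.DataFrame(trials, columns=[
        "onset", "duration", "trial_type", "response_time", "correct"])


def _session_events(params: SEParams, spec: CohortSpec, rng,
                    session_id: str) -> tuple[pd.DataFrame, list[BehavioralTrial]]:
    n_resp = spec.n_congruent + spec.n_incongruent
    conditions = np.concatenate([
        np.zeros(spec.n_congruent, int), np.ones(spec.n_incongruent, int)])
    rng.shuffle(conditions)
    # null trials interleaved at uniformly random slots
    slots = rng.choice(spec.trials_per_session, size=spec.n_null, replace=False)
    is_null = np.zeros(spec.trials_per_session, bool)
    is_null[slots] = True

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sims = {c: simulate_trials(params, c, int((conditions == c).sum()),
                                   rng=rng) for c in (0, 1)}
    take = {0: 0, 1: 0}
    rows, trials = [], []
    ci = 0
    for slot in range(spec.trials_per_session):
        onset = slot * spec.trial_duration
        if is_null[slot]:
            rows.append({"onset": onset, "duration": spec.trial_duration,
                         "trial_type": "null", "response_time": "n/a",
                         "correct": "n/a"})
            continue
        c = int(conditions[ci])
        ci += 1
        sim = sims[c]
        i = take[c]
        take[c] += 1
        rt, corr = float(sim.rt[i]), bool(sim.correct[i])
        rows.append({"onset": onset, "duration": spec.stimulus_duration,
                     "trial_type": "congruent" if c == 0 else "incongruent",
                     "response_time": round(rt, 6), "correct": int(corr)})
        if not sim.censored[i]:
            trials.append(BehavioralTrial(c, rt, corr, session_id=session_id))
    return events_frame(rows, spec), trials


def generate_cohort(spec: CohortSpec | None = None,
                    params_list: list[SEParams] | None = None
                    ) -> list[SyntheticSubject]:
    """Draw subject parameters and simulate a full behavioral cohort.

    Parameters are drawn once per subject from the synthetic
    population (or supplied explicitly); trials are
    simulated per session with onsets on the 2.5 s grid and null trials
    at random slots.  Fully reproducible from ``spec.rng_seed``.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.rng_seed)
    subjects = []
    for si in range(spec.n_subjects):
        sid = f"sub-{si + 1:02d}"
        params = (params_list[si] if params_list is not None
                  else sample_population_params(rng))
        all_trials = []
        events = {}
        for se in range(spec.sessions_per_subject):
            ses = f"ses-{se + 1}"
            ev, trials = _session_events(params, spec, rng, ses)
            events[ses] = ev
            all_trials.extend(trials)
        subjects.append(SyntheticSubject(
            sid, params, BehavioralDataset(all_trials, subject_id=sid), events))
    return subjects


def generate_group_maps(scan_spec: SyntheticScanSpec, covariate,
                        region: list[tuple] | None = None,
                        slope: float = 1.0, noise_sd: float | None = None,
                        rng=None) -> np.ndarray:
    """Per-subject beta maps with a planted covariate-linked region.

    Voxels in ``region`` get ``slope * covariate + N(0, sd)``; all other
    voxels are pure noise.  Returns an array of shape
    ``(n_subjects, *scan_spec.shape)``.
    """
    rng = np.random.default_rng(rng)
    covariate = np.asarray(covariate, float)
    sd = scan_spec.noise_sd if noise_sd is None else noise_sd
    maps = rng.normal(0.0, sd, size=(covariate.size,) + tuple(scan_spec.shape))
    for vox in (region or []):
        if any(i < 0 or i >= s for i, s in zip(vox, scan_spec.shape)):
            raise ValueError(f"planted voxel {vox} outside the grid")
        maps[(slice(None),) + tuple(vox)] += slope * covariate
    return maps


def generate_bold(scan_spec: SyntheticScanSpec,
                  planted: list[tuple] | None = None,
                  rng=None, baseline: float = 100.0) -> np.ndarray:
    """4-D BOLD series: baseline + planted HRF responses + white noise.

    ``planted`` maps voxels to signal: each entry is
    ``(voxel_index, EventRegressor, beta)``; the regressor is convolved
    with the canonical HRF exactly as in the analysis GLM, scaled by
    ``beta`` and added at that voxel.  Returns ``(*shape, n_volumes)``.
    """
    rng = np.random.default_rng(rng)
    shape = tuple(scan_spec.shape)
    data = rng.normal(0.0, scan_spec.noise_sd,
                      size=shape + (scan_spec.n_volumes,))
    data += baseline
    for vox, reg, beta in (planted or []):
        design = build_design([reg], scan_spec.n_volumes, tr=scan_spec.tr)
        data[tuple(vox)] += beta * design.frame[reg.name].to_numpy()
    return data
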