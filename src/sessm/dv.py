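"""Expected decision-variable reconstruction for within-trial BOLD regressors.

Given a subject's fitted parameters, a large pool of simulated trials
with stored traces is matched to each real trial by condition, choice
and RT (within a 25 ms bin centered on the observed RT).  Matched traces
are aligned at their threshold crossing and averaged backwards in time,
yielding the expected decision variable leading up to the response.
Mean DV amplitudes in 50 ms windows stepping back from the response are
z-scored across trials and become parametric regressor amplitudes for
the DV-GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import SEParams, BehavioralDataset, BehavioralTrial
from .simulate import SimulatedTrials, simulate_trials

__all__ = [
    "DVPool",
    "ExpectedDVTrace",
    "match_and_average",
    "expected_dv_traces",
    "extract_windows",
    "zscore_amplitudes",
    "window_centers",
]

DEFAULT_N_SIM = 750_000
DEFAULT_MATCH_RESOLUTION = 0.025
DEFAULT_MIN_MATCHES = 10
WINDOW_WIDTH = 0.050
FIRST_CENTER = -0.025
DEFAULT_N_WINDOWS = 8


@dataclass
class DVPool:
    """Per-condition pools of simulated trials with stored traces.

    The pool is generated once from a single subject's fitted
    parameters; ``n_sim`` is the total number of simulated trials,
    split evenly between the two conditions.
    """

    pools: dict[int, SimulatedTrials]
    params: SEParams
    match_resolution: float = DEFAULT_MATCH_RESOLUTION

    def __post_init__(self):
        n = sum(len(p) for p in self.pools.values())
        if n < 10_000:
            raise ValueError(f"DV pool needs >= 10^4 simulated trials, got {n}")

    @property
    def n_sim(self) -> int:
        return sum(len(p) for p in self.pools.values())

    @classmethod
    def from_params(cls, params: SEParams, n_sim: int = DEFAULT_N_SIM,
                    dt: float = 0.001, rng=None,
                    match_resolution: float = DEFAULT_MATCH_RESOLUTION,
                    t_max: float = 5.0) -> "DVPool":
        """Simulate the trace pool for both conditions."""
        rng = np.random.default_rng(rng)
        half = n_sim // 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pools = {
                c: simulate_trials(params, c, half, dt=dt, rng=rng,
                                   keep_traces=True, t_max=t_max)
                for c in (0, 1)
            }
        return cls(pools, params, match_resolution)


@dataclass
class ExpectedDVTrace:
    """Response-aligned mean decision variable for one real trial.

    ``aligned_time`` runs backwards from the threshold crossing (its
    last entry is 0); ``mean_dv`` is the average over matched simulated
    traces, computed only where at least half of them have samples.
    """

    trial_id: int
    condition: int
    rt: float
    correct: bool
    aligned_time: np.ndarray
    mean_dv: np.ndarray
    n_matched: int
    excluded: bool = False
    window_values: dict = field(default_factory=dict)


def match_and_average(pool: DVPool, trial: BehavioralTrial,
                      params: SEParams | None = None,
                      trial_id: int = 0,
                      min_matches: int = DEFAULT_MIN_MATCHES
                      ) -> ExpectedDVTrace:
    """Expected DV trace for one trial from RT/choice-matched simulations.

    Simulated trials of the same condition and correctness whose RT lies
    within ``match_resolution/2`` of the observed RT are aligned at
    their threshold crossing and averaged backwards over samples where
    at least 50% of the matched traces exist.  Trials with fewer than
    ``min_matches`` matches are flagged excluded.
    """
    params = params or pool.params
    sim = pool.pools[trial.condition]
    if sim.traces is None:
        raise ValueError("pool was simulated without keep_traces")
    tol = pool.match_resolution / 2.0
    mask = ((sim.correct == trial.correct) & sim.uncensored
            & (np.abs(sim.rt - trial.rt) <= tol))
    idx = np.flatnonzero(mask)
    if idx.size < min_matches:
        warnings.warn(
            f"trial {trial_id}: only {idx.size} simulated matches "
            f"(< {min_matches}); trial excluded", RuntimeWarning)
        return ExpectedDVTrace(trial_id, trial.condition, trial.rt,
                               trial.correct, np.empty(0), np.empty(0),
                               int(idx.size), excluded=True)

    traces = [sim.traces[i] for i in idx]
    max_len = max(tr.size for tr in traces)
    sums = np.zeros(max_len)
    counts = np.zeros(max_len, dtype=np.int64)
    for tr in traces:  # align on the crossing sample (the last one)
        sums[max_len - tr.size:] += tr
        counts[max_len - tr.size:] += 1

    covered = counts >= max(1, int(np.ceil(idx.size / 2)))
    start = int(np.argmax(covered))  # earliest sample with >= 50% coverage
    mean_dv = sums[start:] / counts[start:]
    aligned_time = (np.arange(start, max_len) - (max_len - 1)) * sim.dt
    return ExpectedDVTrace(trial_id, trial.condition, trial.rt, trial.correct,
                           aligned_time, mean_dv, int(idx.size))


def expected_dv_traces(pool: DVPool, dataset: BehavioralDataset,
                       min_matches: int = DEFAULT_MIN_MATCHES
                       ) -> list[ExpectedDVTrace]:
    """Expected DV traces for every trial of a dataset."""
    return [match_and_average(pool, tr, trial_id=i, min_matches=min_matches)
            for i, tr in enumerate(dataset)]


def window_centers(n_windows: int = DEFAULT_N_WINDOWS,
                   first_center: float = FIRST_CENTER,
                   step: float = WINDOW_WIDTH) -> np.ndarray:
    """Window centers stepping back from the response: -25, -75, ... ms."""
    return first_center - step * np.arange(n_windows)


def extract_windows(traces: list[ExpectedDVTrace],
                    window_width: float = WINDOW_WIDTH,
                    first_center: float = FIRST_CENTER,
                    n_windows: int = DEFAULT_N_WINDOWS) -> pd.DataFrame:
    """Per-trial mean DV within response-locked windows.

    Window k covers ``[center_k - w/2, center_k + w/2)`` with
    ``center_k = first_center - w*k``.  Windows reaching back before a
    trial's trace start (or trials excluded at the matching stage) yield
    NaN.  Returns a DataFrame with one row per trial and one column per
    window center (plus trial metadata columns).
    """
    centers = window_centers(n_windows, first_center, window_width)
    rows = []
    for tr in traces:
        row = {"trial_id": tr.trial_id, "condition": tr.condition,
               "rt": tr.rt, "correct": tr.correct, "excluded": tr.excluded}
        for ck in centers:
            key = round(float(ck), 6)
            if tr.excluded:
                row[key] = np.nan
                continue
            lo, hi = ck - window_width / 2, ck + window_width / 2
            if lo < tr.aligned_time[0] - 1e-12:
                row[key] = np.nan  # window extends before the trace start
                continue
            sel = (tr.aligned_time >= lo - 1e-12) & (tr.aligned_time < hi - 1e-12)
            row[key] = float(tr.mean_dv[sel].mean()) if sel.any() else np.nan
        if not tr.excluded:
            tr.window_values = {round(float(c), 6): row[round(float(c), 6)]
                                for c in centers}
        rows.append(row)
    return pd.DataFrame(rows).set_index("trial_id")


def zscore_amplitudes(amplitudes, condition=None) -> np.ndarray:
    """Z-score window amplitudes across trials into regressor amplitudes.

    Uses the population standard deviation; missing values are imputed
    as 0 *after* z-scoring (the post-z-score mean), keeping the event
    count constant across windows.  With ``condition`` given, returns a
    (n_trials, 2) array whose columns are the per-condition amplitudes,
    z-scored separately and zero off-condition — the split-DV regressor
    pair.
    """
    a = np.asarray(amplitudes, dtype=float)
    if condition is not None:
        condition = np.asarray(condition)
        out = np.zeros((a.size, 2))
        for j, c in enumerate((0, 1)):
            sel = condition == c
            if sel.any():
                out[sel, j] = zscore_amplitudes(a[sel])
        return out

    ok = np.isfinite(a)
    if not ok.any():
        warnings.warn("all window amplitudes missing; returning zeros",
                      RuntimeWarning)
        return np.zeros_like(a)
    if ok.sum() < 3:
        raise ValueError("need >= 3 non-missing trials to z-score")
    mu = a[ok].mean()
    sd = a[ok].std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance across trials; cannot z-score")
    out = np.zeros_like(a)
    out[ok] = (a[ok] - mu) / sd
    return out
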