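"""Euler-Maruyama trace simulation of the SE-SSM and behavioral summaries.

The simulator is the ground truth against which the transition-matrix
engine is validated, the source of decision-variable traces for the
expected-DV reconstruction, and the core of the synthetic-data
generator.  Trials evolve the decision variable in steps of ``dt`` with
i.i.d. Gaussian increments; a response is recorded at the first sample
with ``|x| >= x_th`` (no within-step bridge correction; ``dt`` is small
enough that the discretization bias stays below the test tolerances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (SEParams, BehavioralDataset, BehavioralTrial,
                     sample_nondecision_time, starting_point,
                     validate_condition)

__all__ = [
    "SimulatedTrial",
    "SimulatedTrials",
    "simulate_trials",
    "simulate_dataset",
    "behavioral_summary",
    "BehavioralSummary",
]

PERCENTILE_EDGES = (0, 20, 40, 60, 80, 100)


@dataclass(frozen=True)
class SimulatedTrial:
    condition: int
    rt: float
    correct: bool
    decision_time: float
    t_eff: float
    censored: bool = False
    trace: np.ndarray | None = None


class SimulatedTrials:
    """Column-oriented collection of simulated trials.

    Attributes are parallel arrays (``rt``, ``correct``,
    ``decision_time``, ``t_eff``, ``censored``); ``traces`` (optional) is
    a list of float32 arrays sampled at ``dt``, starting at the trial's
    starting point and ending at the first threshold-crossing sample.
    """

    def __init__(self, condition, rt, correct, decision_time, t_eff,
                 censored, dt, traces=None):
        self.condition = int(condition)
        self.rt = np.asarray(rt, float)
        self.correct = np.asarray(correct, bool)
        self.decision_time = np.asarray(decision_time, float)
        self.t_eff = np.asarray(t_eff, float)
        self.censored = np.asarray(censored, bool)
        self.dt = float(dt)
        self.traces = traces

    def __len__(self):
        return self.rt.size

    def __getitem__(self, i) -> SimulatedTrial:
        return SimulatedTrial(
            self.condition, float(self.rt[i]), bool(self.correct[i]),
            float(self.decision_time[i]), float(self.t_eff[i]),
            bool(self.censored[i]),
            None if self.traces is None else self.traces[i])

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def uncensored(self) -> np.ndarray:
        return ~self.censored

    def accuracy(self) -> float:
        ok = self.uncensored
        return float(self.correct[ok].mean())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition,
            "rt": self.rt,
            "correct": self.correct.astype(int),
            "decision_time": self.decision_time,
            "t_eff": self.t_eff,
            "censored": self.censored.astype(int),
        })


def simulate_trials(params: SEParams, c, n: int, dt: float = 0.001,
                    rng=None, keep_traces: bool = False,
                    t_max: float = 5.0) -> SimulatedTrials:
    """Simulate ``n`` SE-SSM trials of one condition.

    Each trial starts at ``x0 = x_b(1-2c)`` and accumulates
    ``dx = v(1 + c*b*d)dt + s*xi1*sqrt(dt)`` until ``|x| >= x_th``; the
    observed RT adds a drawn non-decision time.  Trials still running at
    ``t_max`` are flagged censored (and excluded from RT summaries by
    downstream consumers).  Identical seeds give bit-identical output.
    """
    if n < 1:
        raise ValueError("need n >= 1 trials")
    ci = validate_condition(c)
    rng = np.random.default_rng(rng)
    n_steps = int(round(t_max / dt))
    x0 = starting_point(params, ci)
    sdt = params.s * np.sqrt(dt)

    x = np.full(n, x0)
    active = np.arange(n)
    decision_steps = np.full(n, n_steps, dtype=np.int64)
    correct = np.zeros(n, dtype=bool)
    censored = np.ones(n, dtype=bool)

    buf = None
    if keep_traces:
        buf = np.empty((n, 512), dtype=np.float32)
        buf[:, 0] = x0

    for k in range(n_steps):
        drift = params.v * (1.0 + ci * params.b * k * dt)
        x[active] += drift * dt + sdt * rng.standard_normal(active.size)
        if keep_traces:
            if k + 1 >= buf.shape[1]:
                buf = np.concatenate(
                    [buf, np.empty((n, buf.shape[1]), dtype=np.float32)], axis=1)
            buf[active, k + 1] = x[active]
        hit = np.abs(x[active]) >= params.x_th
        if hit.any():
            done = active[hit]
            decision_steps[done] = k + 1
            correct[done] = x[done] >= params.x_th
            censored[done] = False
            active = active[~hit]
            if active.size == 0:
                break

    if censored.any():
        warnings.warn(
            f"{int(censored.sum())}/{n} trial(s) did not reach a bound by "
            f"t_max={t_max}s; flagged censored", RuntimeWarning)

    decision_time = decision_steps * dt
    t_eff = sample_nondecision_time(params, rng, size=n)
    rt = decision_time + t_eff

    traces = None
    if keep_traces:
        traces = [buf[i, :decision_steps[i] + 1].copy() for i in range(n)]

    return SimulatedTrials(ci, rt, correct, decision_time, t_eff,
                           censored, dt, traces)


def simulate_dataset(params: SEParams, n_per_condition: int | dict,
                     dt: float = 0.001, rng=None, t_max: float = 5.0,
                     subject_id: str = "sim") -> BehavioralDataset:
    """Simulate both conditions and pack uncensored trials into a dataset."""
    rng = np.random.default_rng(rng)
    counts = (n_per_condition if isinstance(n_per_condition, dict)
              else {0: n_per_condition, 1: n_per_condition})
    trials = []
    for c, n in counts.items():
        sim = simulate_trials(params, c, n, dt=dt, rng=rng, t_max=t_max)
        for i in np.flatnonzero(sim.uncensored):
            trials.append(BehavioralTrial(c, float(sim.rt[i]), bool(sim.correct[i])))
    return BehavioralDataset(trials, subject_id=subject_id)


@dataclass
class BehavioralSummary:
    """Per-condition RT/accuracy statistics and delta-plot style bins."""

    stats: pd.DataFrame          # index: condition; mean_rt, sd_rt, accuracy, n
    bins: pd.DataFrame           # percentile-bin accuracy (correct-response RTs)
    error_split: pd.DataFrame    # single 50% split of error-response RTs

    def mean_rt(self, condition: int) -> float:
        return float(self.stats.loc[condition, "mean_rt"])

    def sd_rt(self, condition: int) -> float:
        return float(self.stats.loc[condition, "sd_rt"])

    def accuracy(self, condition: int) -> float:
        return float(self.stats.loc[condition, "accuracy"])


def _as_behavior_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    if isinstance(trials, BehavioralDataset):
        return trials.to_dataframe()
    if isinstance(trials, SimulatedTrials):
        df = trials.to_dataframe()
        return df[df["censored"] == 0]
    # generic iterable of trial-like records
    return pd.DataFrame([
        {"condition": tr.condition, "rt": tr.rt, "correct": int(tr.correct)}
        for tr in trials])


def behavioral_summary(trials, edges=PERCENTILE_EDGES) -> BehavioralSummary:
    """Condition-wise RT and accuracy summaries with percentile-bin accuracy.

    For each condition: mean RT, RT standard deviation and accuracy; the
    fraction of correct responses within RT-percentile bins whose edges
    (default [0, 20, 40, 60, 80, 100]%) are taken from the RT
    distribution of all responses in that condition — the delta-plot
    signature that exposes fast errors on conflict trials.  Error
    responses get a single 50% split (they are typically too few for
    five bins).
    """
    df = _as_behavior_frame(trials)
    stats_rows, bin_rows, err_rows = [], [], []
    for c in sorted(df["condition"].unique()):
        sub = df[df["condition"] == c]
        if len(sub) < 5:
            raise ValueError(
                f"condition {c}: need at least 5 trials for a summary, "
                f"got {len(sub)}")
        rts = sub["rt"].to_numpy(float)
        corr = sub["correct"].to_numpy(bool)
        stats_rows.append({
            "condition": c, "mean_rt": rts.mean(), "sd_rt": rts.std(ddof=1),
            "accuracy": corr.mean(), "n": len(sub)})

        cuts = np.percentile(rts, edges)
        cuts[-1] = np.nextafter(cuts[-1], np.inf)  # include the slowest trial
        for j in range(len(edges) - 1):
            inbin = (rts >= cuts[j]) & (rts < cuts[j + 1])
            center = np.percentile(rts, (edges[j] + edges[j + 1]) / 2)
            bin_rows.append({
                "condition": c, "pct_lo": edges[j], "pct_hi": edges[j + 1],
                "center_rt": center,
                "accuracy": corr[inbin].mean() if inbin.any() else np.nan,
                "n": int(inbin.sum())})

        err_rt = rts[~corr]
        if err_rt.size:
            med = np.median(err_rt)
            err_rows.append({"condition": c, "median_error_rt": med,
                             "n_errors": int(err_rt.size)})
        else:
            err_rows.append({"condition": c, "median_error_rt": np.nan,
                             "n_errors": 0})

    return BehavioralSummary(
        stats=pd.DataFrame(stats_rows).set_index("condition"),
        bins=pd.DataFrame(bin_rows),
        error_split=pd.DataFrame(err_rows).set_index("condition"))
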