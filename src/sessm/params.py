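"""Parameterization of the Simon-effect sequential sampling model (SE-SSM).

The SE-SSM is an accuracy-coded drift-diffusion model with two
conflict-specific extensions: an automatic starting-point bias ``x_b``
that points *toward the error bound* on conflict trials, and a
conflict-counteraction gain ``b`` that ramps the drift up linearly in
elapsed decision time on conflict trials (compensating for the bias and
shrinking the conflict RT spread).

Within a trial the decision variable ``x`` evolves as

    dx = v * (1 + c * b * d) * dt + s * xi1 * sqrt(dt)

from the starting point ``x0 = x_b * (1 - 2c)``, where ``c`` is 1 on
conflict trials and 0 otherwise and ``d`` is the elapsed decision time.
A response is produced when ``|x|`` reaches the threshold ``x_th``; the
upper bound codes the correct response.  The observed response time adds
a non-decision component ``t_eff = t + xi2 * s_t`` with ``xi2`` uniform
on [-1/2, 1/2], i.e. ``s_t`` is the *range* of the uniform jitter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEParams",
    "BehavioralTrial",
    "BehavioralDataset",
    "validate_condition",
    "instantaneous_drift",
    "starting_point",
    "sample_nondecision_time",
]


def validate_condition(c) -> int:
    """Check a conflict indicator and return it as a plain int (0 or 1)."""
    ci = int(c)
    if ci != c or ci not in (0, 1):
        raise ValueError(f"conflict indicator must be exactly 0 or 1, got {c!r}")
    return ci


@dataclass(frozen=True)
class SEParams:
    """SE-SSM parameter set.

    Parameters
    ----------
    v : float
        Drift rate (evidence units / s), > 0.
    x_th : float
        Decision threshold; symmetric absorbing bounds at ``+/- x_th``.
    t : float
        Base non-decision time (s).
    s_t : float
        Range of the uniform non-decision-time jitter (s), >= 0.
    b : float
        Conflict-counteraction gain (1/s), >= 0.  Scales the linear
        within-trial drift ramp on conflict trials.
    x_b : float
        Starting-bias magnitude (evidence units), ``0 <= x_b < x_th``.
    s : float
        Diffusion noise scale (evidence units / sqrt(s)); fixed at 1 in
        all fitting contexts.
    """

    v: float
    x_th: float
    t: float
    s_t: float = 0.0
    b: float = 0.0
    x_b: float = 0.0
    s: float = 1.0

    def __post_init__(self):
        if not np.isfinite([self.v, self.x_th, self.t, self.s_t, self.b,
                            self.x_b, self.s]).all():
            raise ValueError("all SE-SSM parameters must be finite")
        if self.v <= 0:
            raise ValueError(f"drift rate v must be > 0, got {self.v}")
        if self.x_th <= 0:
            raise ValueError(f"threshold x_th must be > 0, got {self.x_th}")
        if self.t <= 0:
            raise ValueError(f"non-decision time t must be > 0, got {self.t}")
        if self.s_t < 0:
            raise ValueError(f"jitter range s_t must be >= 0, got {self.s_t}")
        if self.b < 0:
            raise ValueError(f"conflict gain b must be >= 0, got {self.b}")
        if self.x_b < 0:
            raise ValueError(f"bias x_b must be >= 0, got {self.x_b}")
        if self.s <= 0:
            raise ValueError(f"noise scale s must be > 0, got {self.s}")
        if self.x_b >= self.x_th:
            raise ValueError(
                f"bias x_b={self.x_b} must lie strictly inside the bounds "
                f"(x_th={self.x_th})")
        if self.t - self.s_t / 2 <= 0:
            raise ValueError(
                f"effective non-decision time can reach {self.t - self.s_t / 2:.4f}"
                " <= 0; require t - s_t/2 > 0")

    def replace(self, **kw) -> "SEParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "SEParams":
        d = dict(d)
        d.setdefault("s", 1.0)  # noise scale defaults to the fixed value
        return cls(**{k: float(d[k]) for k in ("v", "x_th", "t", "s_t", "b", "x_b", "s")})

    @classmethod
    def from_json(cls, src) -> "SEParams":
        if isinstance(src, str) and src.lstrip().startswith("{"):
            return cls.from_dict(json.loads(src))
        with open(src) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class BehavioralTrial:
    """One response: conflict code, RT from stimulus onset (s), correctness."""

    condition: int
    rt: float
    correct: bool
    session_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "condition", validate_condition(self.condition))
        object.__setattr__(self, "correct", bool(self.correct))
        if not np.isfinite(self.rt) or self.rt <= 0:
            raise ValueError(f"rt must be finite and > 0, got {self.rt}")


class BehavioralDataset:
    """Ordered collection of trials for one subject.

    Construct from a sequence of :class:`BehavioralTrial` or via
    :meth:`from_dataframe` from a table with columns ``condition`` (0/1),
    ``rt`` (s) and ``correct``.
    """

    def __init__(self, trials: Iterable[BehavioralTrial], subject_id: str = "subject"):
        self.trials: list[BehavioralTrial] = list(trials)
        self.subject_id = subject_id
        if not self.trials:
            raise ValueError("BehavioralDataset must contain at least one trial")
        arr = np.array([(tr.condition, tr.rt, tr.correct) for tr in self.trials])
        self.condition = arr[:, 0].astype(int)
        self.rt = arr[:, 1].astype(float)
        self.correct = arr[:, 2].astype(bool)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[BehavioralTrial]:
        return iter(self.trials)

    def has_both_conditions(self) -> bool:
        return 0 in self.condition and 1 in self.condition

    def subset(self, condition: int) -> "BehavioralDataset":
        c = validate_condition(condition)
        return BehavioralDataset(
            [tr for tr in self.trials if tr.condition == c], self.subject_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition,
            "rt": self.rt,
            "correct": self.correct.astype(int),
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, subject_id: str = "subject"
                       ) -> "BehavioralDataset":
        sess = df["session_id"] if "session_id" in df else [None] * len(df)
        trials = [
            BehavioralTrial(int(c), float(rt), bool(corr), session_id=sid)
            for c, rt, corr, sid in zip(df["condition"], df["rt"], df["correct"], sess)
        ]
        return cls(trials, subject_id=subject_id)


def instantaneous_drift(params: SEParams, c, d):
    """Drift rate at elapsed decision time ``d``: ``v * (1 + c*b*d)``.

    On non-conflict trials (``c = 0``) the drift is constant at ``v``;
    on conflict trials it grows linearly with slope ``v*b``.
    Accepts scalar or array ``d`` (all entries must be >= 0).
    """
    ci = validate_condition(c)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("elapsed decision time d must be >= 0")
    out = params.v * (1.0 + ci * params.b * d)
    return float(out) if out.ndim == 0 else out


def starting_point(params: SEParams, c) -> float:
    """Initial decision variable ``x0 = x_b * (1 - 2c)``.

    The bias points toward the correct (upper) bound on non-conflict
    trials and toward the error (lower) bound on conflict trials.
    """
    ci = validate_condition(c)
    return params.x_b * (1 - 2 * ci)


def sample_nondecision_time(params: SEParams, rng=None, size=None):
    """Draw effective non-decision times ``t_eff = t + u * s_t``.

    ``u`` is uniform on [-1/2, 1/2], so ``s_t`` is the total range of the
    jitter and the support of ``t_eff`` is ``[t - s_t/2, t + s_t/2]``
    with mean ``t``.
    """
    rng = np.random.default_rng(rng)
    u = rng.uniform(-0.5, 0.5, size=size)
    return params.t + u * params.s_t
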