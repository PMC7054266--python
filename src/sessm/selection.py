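"""AIC-based comparison of the M1-M4 candidate family.

AIC = 2k + 2*NLL; Akaike weights w_i = exp(-Delta_i/2) / sum_j
exp(-Delta_j/2) with Delta_i = AIC_i - min AIC, read as the probability
of model i being the best of the candidate set.  Ties in the winner are
broken toward the simpler model (fewer free parameters).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import BehavioralDataset
from .model import MODELS, FitConfig, FitResult, ModelSpec, fit_subject

__all__ = ["aic", "waic", "compare_subject", "compare_cohort", "ComparisonTable"]


def aic(nll: float, n_free: int) -> float:
    """Akaike information criterion from an NLL in nats."""
    if not np.isfinite(nll):
        raise ValueError(f"nll must be finite, got {nll}")
    if n_free < 0:
        raise ValueError("n_free must be >= 0")
    return 2.0 * n_free + 2.0 * float(nll)


def waic(aics) -> np.ndarray:
    """Akaike weights of a candidate set (overflow-safe).

    Weights are invariant to adding a constant to every AIC and sum to 1.
    """
    a = np.asarray(aics, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 candidates")
    if not np.isfinite(a).all():
        raise ValueError("all AICs must be finite")
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()


class ComparisonTable:
    """Per-subject AIC / Akaike-weight table over M1-M4."""

    model_names = ("M1", "M2", "M3", "M4")

    def __init__(self, rows: list[dict]):
        self.frame = pd.DataFrame(rows).set_index("subject_id")

    def winners(self) -> pd.Series:
        return self.frame["winner"]

    def winner_counts(self) -> pd.Series:
        return (self.frame["winner"].value_counts()
                .reindex(self.model_names, fill_value=0))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)

    def __repr__(self):
        return f"ComparisonTable({len(self.frame)} subjects)\n{self.frame}"


def _winner(aics: dict[str, float]) -> str:
    # ties broken toward the simpler model: sort by (AIC, n_free, name)
    order = sorted(aics, key=lambda m: (aics[m], MODELS[m].n_free, m))
    return order[0]


def compare_subject(dataset: BehavioralDataset,
                    fit_config: FitConfig | None = None,
                    models=("M1", "M2", "M3", "M4")
                    ) -> tuple[dict, dict[str, FitResult]]:
    """Fit every candidate model to one subject and tabulate AIC/wAIC.

    Returns the table row (dict with per-model AIC, wAIC, NLL and the
    winner) and the underlying :class:`FitResult` objects.
    """
    cfg = fit_config or FitConfig()
    # nested warm starts: every larger model also starts its refinement
    # from the solutions of the models nested inside it, which makes the
    # nesting inequality NLL(M4) <= min(NLL(M2), NLL(M3)) <= NLL(M1) hold
    # by construction (refinement never increases the NLL)
    nested = {"M1": (), "M2": ("M1",), "M3": ("M1",), "M4": ("M1", "M2", "M3")}
    fits: dict[str, FitResult] = {}
    for name in models:
        try:
            extra = [fits[m].params for m in nested.get(name, ())
                     if m in fits]
            fits[name] = fit_subject(dataset, name, cfg, extra_starts=extra)
        except Exception as err:
            raise RuntimeError(
                f"model {name} failed for subject "
                f"{dataset.subject_id!r}: {err}") from err
    aics = {name: fr.aic for name, fr in fits.items()}
    weights = waic([aics[m] for m in models])
    row = {"subject_id": dataset.subject_id}
    for m, w in zip(models, weights):
        row[f"aic_{m}"] = aics[m]
        row[f"waic_{m}"] = float(w)
        row[f"nll_{m}"] = fits[m].nll
    row["winner"] = _winner(aics)
    return row, fits


def compare_cohort(datasets, fit_config: FitConfig | None = None,
                   models=("M1", "M2", "M3", "M4")) -> ComparisonTable:
    """Run :func:`compare_subject` across a cohort."""
    rows = []
    for ds in datasets:
        row, _ = compare_subject(ds, fit_config, models)
        rows.append(row)
    return ComparisonTable(rows)
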