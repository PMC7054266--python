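"""File formats: BIDS-style events TSV, parameter JSON, NIfTI maps, CSV.

All on-disk times are in seconds; events use 0-based scan time with
volume 0 acquired at t = 0.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .params import SEParams, BehavioralDataset, BehavioralTrial

__all__ = [
    "read_events",
    "write_events",
    "read_covariates",
    "save_map",
    "load_map",
    "save_params",
    "load_params",
]

EVENT_COLUMNS = ("onset", "duration", "trial_type", "response_time", "correct")
_TRIAL_TYPE_TO_C = {"congruent": 0, "incongruent": 1}


def read_events(path, subject_id: str | None = None
                ) -> tuple[BehavioralDataset, pd.DataFrame]:
    """Read a BIDS-style events TSV.

    Returns the behavioral dataset (null trials dropped, trial_type
    mapped to the conflict code: congruent -> 0, incongruent -> 1) and
    the full events table (nulls retained for scan timing).  Responded
    trials with non-numeric RTs raise; rows with RT <= 0 are rejected
    with a warning.
    """
    path = Path(path)
    # keep literal "null"/"n/a" strings (BIDS conventions) out of pandas'
    # default NaN handling
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    df["onset"] = df["onset"].astype(float)
    df["duration"] = df["duration"].astype(float)

    trials = []
    for i, row in df.iterrows():
        tt = row["trial_type"]
        if tt == "null":
            continue
        if tt not in _TRIAL_TYPE_TO_C:
            raise ValueError(
                f"{path}, row {i}: unknown trial_type {tt!r} "
                f"(expected congruent/incongruent/null)")
        try:
            rt = float(row["response_time"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}, row {i}: non-numeric response_time "
                f"{row['response_time']!r} on a responded trial") from None
        if not np.isfinite(rt) or rt <= 0:
            warnings.warn(f"{path}, row {i}: RT {rt!r} <= 0 or non-finite; "
                          "row rejected", RuntimeWarning)
            continue
        correct = str(row["correct"]).strip().lower() in ("1", "true", "yes")
        trials.append(BehavioralTrial(_TRIAL_TYPE_TO_C[tt], rt, correct))
    dataset = BehavioralDataset(trials, subject_id=subject_id or path.stem)
    return dataset, df


def write_events(df: pd.DataFrame, path) -> None:
    """Write an events table as TSV (the dialect read_events accepts)."""
    df.to_csv(path, sep="\t", index=False)


def read_covariates(path) -> pd.Series:
    """Covariate CSV with columns subject_id, value -> Series by subject."""
    df = pd.read_csv(path)
    for col in ("subject_id", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df.set_index("subject_id")["value"].astype(float)


def save_map(arr: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Save a 3-D map or 4-D series as NIfTI (identity affine by default)."""
    import nibabel as nib

    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(arr, np.float64), affine), str(path))


def load_map(path) -> np.ndarray:
    import nibabel as nib

    try:
        img = nib.load(str(path))
        return np.asarray(img.get_fdata())
    except Exception as err:
        raise ValueError(f"could not read NIfTI file {path}: {err}") from err


def save_params(params: SEParams, path) -> None:
    params.to_json(path)


def load_params(path) -> SEParams:
    return SEParams.from_json(path)


def save_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
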