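"""CSV/JSON readers and writers for the documented table dialects.

All tables are plain UTF-8 comma-separated CSV with a header row; angles are
degrees in plain decimal notation.  Structured results are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .psychometric import CONDITIONS, STIMULUS_RANGE_DEG
from .prior import PriorModelFit

TRIAL_COLUMNS = ["subject_id", "age_years", "condition", "stimulus_deg", "response"]
FIT_COLUMNS = [
    "subject_id",
    "age_years",
    "condition",
    "pse_deg",
    "jnd_deg",
    "lapse_rate",
    "log_likelihood",
    "converged",
    "n_trials",
]
GROUP_BIAS_COLUMNS = [
    "modality",
    "age_group_label",
    "mean_age_years",
    "mean_bias_deg",
    "sem_deg",
    "n",
]

_FLOAT_FMT = "%.6f"


def read_trials_csv(path) -> pd.DataFrame:
    """Read and validate a trial table; errors name the offending row."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    lo, hi = STIMULUS_RANGE_DEG
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        if row.condition not in CONDITIONS:
            raise ValueError(f"{path}, line {i}: unknown condition {row.condition!r}")
        if not (lo <= row.stimulus_deg <= hi):
            raise ValueError(
                f"{path}, line {i}: stimulus_deg {row.stimulus_deg} outside [{lo}, {hi}]"
            )
        if row.response not in (0, 1):
            raise ValueError(f"{path}, line {i}: response must be 0 or 1")
        if not row.age_years > 0:
            raise ValueError(f"{path}, line {i}: age_years must be positive")
    return df[TRIAL_COLUMNS]


def write_trials_csv(df: pd.DataFrame, path) -> None:
    df[TRIAL_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_fits_csv(df: pd.DataFrame, path) -> None:
    df[FIT_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_fits_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_group_biases_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GROUP_BIAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_prior_fit_json(fit: PriorModelFit, path) -> None:
    payload = {
        "policy": fit.config.policy,
        "sigma_p_deg": fit.config.sigma_p_deg,
        "a0_deg": fit.params.a0_deg,
        "a1_deg_per_year": fit.params.a1_deg_per_year,
        "epsilon_deg": fit.params.epsilon_deg,
        "sse": fit.sse,
        "r_squared": fit.r_squared,
        "predicted_bias_by_age": {str(k): v for k, v in fit.predicted_bias_by_age.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"cannot serialise {type(obj)}")
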