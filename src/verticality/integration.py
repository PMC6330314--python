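"""Maximum-likelihood visual-haptic cue combination.

Under optimal (inverse-variance weighted) fusion of two unimodal estimates,
the bimodal precision and bias are

    sigma_VH^2 = sigma_V^2 sigma_H^2 / (sigma_V^2 + sigma_H^2)
    S_VH       = w_V S_V + w_H S_H,   w_m = (1/sigma_m^2) / (1/sigma_V^2 + 1/sigma_H^2)

These predictions are computed from per-subject unimodal psychometric fits
and compared with the observed bimodal fits per age group.  A failure of the
prediction (observed bimodal JND above the predicted one) is the signature of
absent multisensory integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .psychometric import PsychometricFit

__all__ = [
    "ADULT_AGE_YEARS",
    "UnimodalPair",
    "BimodalPrediction",
    "predict_bimodal_sigma",
    "compute_weights",
    "predict_bimodal_pse",
    "compare_groups",
]

#: Age (years) at and above which a subject counts as an adult.
ADULT_AGE_YEARS = 18.0

#: Minimum matched subjects required per group for a comparison.
MIN_GROUP_SIZE = 3


@dataclass(frozen=True)
class UnimodalPair:
    """Converged visual and haptic fits of the same subject."""

    subject_id: str
    visual: PsychometricFit
    haptic: PsychometricFit


@dataclass(frozen=True)
class BimodalPrediction:
    """MLE-optimal bimodal prediction derived from a :class:`UnimodalPair`."""

    subject_id: str
    sigma_vh_deg: float
    pse_vh_deg: float
    w_v: float
    w_h: float


def predict_bimodal_sigma(sigma_v: float, sigma_h: float) -> float:
    """Optimal bimodal JND: sqrt(sv^2 sh^2 / (sv^2 + sh^2)); never exceeds
    the better unimodal JND."""
    if sigma_v <= 0 or sigma_h <= 0:
        raise ValueError("sigmas must be strictly positive")
    sv2, sh2 = sigma_v * sigma_v, sigma_h * sigma_h
    return math.sqrt(sv2 * sh2 / (sv2 + sh2))


def compute_weights(sigma_v: float, sigma_h: float) -> tuple[float, float]:
    """Inverse-variance cue weights (w_v, w_h); they sum to one."""
    if sigma_v <= 0 or sigma_h <= 0:
        raise ValueError("sigmas must be strictly positive")
    rv, rh = 1.0 / (sigma_v * sigma_v), 1.0 / (sigma_h * sigma_h)
    total = rv + rh
    return rv / total, rh / total


def predict_bimodal_pse(pair: UnimodalPair) -> BimodalPrediction:
    """Weighted-sum bimodal PSE and pooled JND for one subject.

    Refuses pairs containing a non-converged fit: those subjects are excluded
    from the integration analysis.
    """
    if not pair.visual.converged or not pair.haptic.converged:
        raise ValueError(
            f"subject {pair.subject_id!r}: both unimodal fits must be "
            "converged for an integration prediction"
        )
    w_v, w_h = compute_weights(pair.visual.jnd_deg, pair.haptic.jnd_deg)
    return BimodalPrediction(
        subject_id=pair.subject_id,
        sigma_vh_deg=predict_bimodal_sigma(pair.visual.jnd_deg, pair.haptic.jnd_deg),
        pse_vh_deg=w_v * pair.visual.pse_deg + w_h * pair.haptic.pse_deg,
        w_v=w_v,
        w_h=w_h,
    )


def compare_groups(
    predictions: Mapping[str, BimodalPrediction],
    observed: Mapping[str, PsychometricFit],
    ages: Mapping[str, float],
) -> pd.DataFrame:
    """Predicted vs observed bimodal PSE/JND, summarised per age group.

    Only subjects present in all three mappings with a converged observed
    bimodal fit are used.  Subjects split into ``children`` (< 18 y) and
    ``adults``.  Each non-empty group must contain at least three matched
    subjects.  Returns one row per group with means, mean paired differences
    (observed - predicted) and two-sided paired t statistics with Bonferroni
    correction across the groups present.  The table is descriptive; it draws
    no conclusion itself.
    """
    ids = sorted(
        s
        for s in predictions
        if s in observed and s in ages and observed[s].converged
    )
    rows: dict[str, list[str]] = {"children": [], "adults": []}
    for s in ids:
        rows["adults" if ages[s] >= ADULT_AGE_YEARS else "children"].append(s)
    groups = {g: members for g, members in rows.items() if members}
    for g, members in groups.items():
        if len(members) < MIN_GROUP_SIZE:
            raise ValueError(
                f"group {g!r} has only {len(members)} matched subjects; "
                f"at least {MIN_GROUP_SIZE} are required"
            )
    n_tests = len(groups)
    out = []
    for g, members in groups.items():
        pred_jnd = np.array([predictions[s].sigma_vh_deg for s in members])
        obs_jnd = np.array([observed[s].jnd_deg for s in members])
        pred_pse = np.array([predictions[s].pse_vh_deg for s in members])
        obs_pse = np.array([observed[s].pse_deg for s in members])
        jnd_t, jnd_p = _paired_t(obs_jnd, pred_jnd)
        pse_t, pse_p = _paired_t(obs_pse, pred_pse)
        out.append(
            {
                "group": g,
                "n": len(members),
                "jnd_pred_mean": pred_jnd.mean(),
                "jnd_obs_mean": obs_jnd.mean(),
                "jnd_diff_mean": (obs_jnd - pred_jnd).mean(),
                "jnd_t": jnd_t,
                "jnd_p_bonf": min(1.0, jnd_p * n_tests) if math.isfinite(jnd_p) else jnd_p,
                "pse_pred_mean": pred_pse.mean(),
                "pse_obs_mean": obs_pse.mean(),
                "pse_diff_mean": (obs_pse - pred_pse).mean(),
                "pse_t": pse_t,
                "pse_p_bonf": min(1.0, pse_p * n_tests) if math.isfinite(pse_p) else pse_p,
            }
        )
    return pd.DataFrame(out).set_index("group")


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    d = a - b
    if np.allclose(d, d[0]):
        # zero-variance differences: t undefined
        return math.nan, math.nan
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
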