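"""Synthetic study generator: cohort, ground-truth observers, PSI trials.

Emulates the structure of a developmental verticality study: seven age groups
(6-11 years and adults), three conditions per subject (visual, haptic,
bimodal), 50 trials per condition for children and 100 for adults, stimuli
chosen by the PSI adaptive procedure.  Ground-truth biases follow the prior
observer model (visual A-effects at all ages; haptic A-effect in the youngest
shifting toward zero/positive with age), with Gaussian between-subject
scatter on the PSE and log-normal JNDs that shrink with age.  The bimodal
ground truth depends on the chosen integration regime, which makes cohorts
with and without multisensory integration directly comparable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import prior
from .prior import LikelihoodAgeParams, PriorConfig, forward_predict
from .integration import compute_weights, predict_bimodal_sigma
from .psi import gaussian_observer, run_session
from .psychometric import DEFAULT_LAPSE

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "default_groups",
    "make_truth",
    "generate_study",
    "TRUTH_COLUMNS",
    "TRIAL_COLUMNS",
]

TRUTH_COLUMNS = [
    "subject_id",
    "group_label",
    "age_years",
    "condition",
    "true_pse_deg",
    "true_jnd_deg",
]
TRIAL_COLUMNS = ["subject_id", "age_years", "condition", "stimulus_deg", "response"]

FROM_PRIOR_MODEL = "from_prior_model"
EXPLICIT_TRUTH = "explicit_truth"
MLE_INTEGRATOR = "mle_integrator"
VISUAL_CAPTURE = "visual_capture"
NO_INTEGRATION = "no_integration"


@dataclass(frozen=True)
class GroupSpec:
    """One age group: label, size and the age interval subjects are drawn
    from (uniformly)."""

    label: str
    n_subjects: int
    age_low: float
    age_high: float

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 < self.age_low <= self.age_high):
            raise ValueError("invalid age interval")


def default_groups() -> list[GroupSpec]:
    """The study's cohort structure: groups of 6, 7, 10, 8, 15, 7 children at
    nominal ages 6-11 plus 8 adults aged 22-37 (61 subjects)."""
    return [
        GroupSpec("6", 6, 5.5, 6.5),
        GroupSpec("7", 7, 6.5, 7.5),
        GroupSpec("8", 10, 7.5, 8.5),
        GroupSpec("9", 8, 8.5, 9.5),
        GroupSpec("10", 15, 9.5, 10.5),
        GroupSpec("11", 7, 10.5, 11.5),
        GroupSpec("adult", 8, 22.0, 37.0),
    ]


@dataclass
class CohortSpec:
    """Full specification of a synthetic study.

    ``generative_mode`` is either ``from_prior_model`` (unimodal ground-truth
    biases from :func:`verticality.prior.forward_predict` plus subject noise)
    or ``explicit_truth`` (a supplied truth table is used verbatim).
    ``integration_mode`` selects the bimodal ground truth: ``mle_integrator``
    applies optimal cue fusion to the subject's unimodal truths,
    ``visual_capture`` copies the visual truth, ``no_integration`` copies the
    more reliable (lower-JND) modality.
    """

    groups: list[GroupSpec] = field(default_factory=default_groups)
    trials_children: int = 50
    trials_adults: int = 100
    generative_mode: str = FROM_PRIOR_MODEL
    integration_mode: str = MLE_INTEGRATOR
    #: Between-subject SD of the true PSE around the group prediction (deg).
    inter_subject_bias_sd: float = 4.0
    #: Median true JND at age 6 (deg); declines linearly with age to a floor.
    jnd_median_youngest: float = 8.0
    jnd_decline_per_year: float = 0.25
    jnd_floor: float = 3.0
    #: SD of the log-normal JND scatter (log units).
    jnd_log_sd: float = 0.25
    lapse_rate: float = DEFAULT_LAPSE
    seed: int = 0
    visual_prior: PriorConfig = field(default_factory=lambda: prior.DEFAULT_VISUAL_PRIOR_FIT[0])
    visual_likelihood: LikelihoodAgeParams = field(
        default_factory=lambda: prior.DEFAULT_VISUAL_PRIOR_FIT[1]
    )
    haptic_prior: PriorConfig = field(default_factory=lambda: prior.DEFAULT_HAPTIC_PRIOR_FIT[0])
    haptic_likelihood: LikelihoodAgeParams = field(
        default_factory=lambda: prior.DEFAULT_HAPTIC_PRIOR_FIT[1]
    )
    truth_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.generative_mode not in (FROM_PRIOR_MODEL, EXPLICIT_TRUTH):
            raise ValueError(f"unknown generative_mode {self.generative_mode!r}")
        if self.integration_mode not in (MLE_INTEGRATOR, VISUAL_CAPTURE, NO_INTEGRATION):
            raise ValueError(f"unknown integration_mode {self.integration_mode!r}")
        if self.generative_mode == EXPLICIT_TRUTH and self.truth_table is None:
            raise ValueError("explicit_truth mode requires a truth_table")


def _median_jnd(spec: CohortSpec, age: float) -> float:
    return max(
        spec.jnd_floor,
        spec.jnd_median_youngest - spec.jnd_decline_per_year * (age - 6.0),
    )


def make_truth(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-subject true (PSE, JND) per condition.

    In ``from_prior_model`` mode the unimodal group-level biases come from
    the forward prior model evaluated over the whole cohort's ages at once
    (the rectification of the likelihood width depends on the evaluated age
    set), with independent Gaussian subject scatter added per modality.
    """
    if spec.generative_mode == EXPLICIT_TRUTH:
        t = spec.truth_table.copy()
        missing = set(TRUTH_COLUMNS) - set(t.columns)
        if missing:
            raise ValueError(f"truth_table lacks columns {sorted(missing)}")
        return t[TRUTH_COLUMNS].reset_index(drop=True)

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])

    subjects: list[tuple[str, str, float]] = []
    for g in spec.groups:
        for i in range(g.n_subjects):
            age = float(rng.uniform(g.age_low, g.age_high))
            subjects.append((f"{g.label}_s{i + 1:02d}", g.label, age))

    ages = np.array([s[2] for s in subjects])
    base = {
        "visual": forward_predict(spec.visual_prior, spec.visual_likelihood, ages),
        "haptic": forward_predict(spec.haptic_prior, spec.haptic_likelihood, ages),
    }

    rows = []
    for k, (sid, label, age) in enumerate(subjects):
        uni = {}
        for cond in ("visual", "haptic"):
            pse = float(base[cond][k] + rng.normal(0.0, spec.inter_subject_bias_sd))
            jnd = float(_median_jnd(spec, age) * np.exp(rng.normal(0.0, spec.jnd_log_sd)))
            uni[cond] = (pse, jnd)
            rows.append((sid, label, age, cond, pse, jnd))
        rows.append((sid, label, age, "bimodal", *_bimodal_truth(spec, uni)))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def _bimodal_truth(spec: CohortSpec, uni: dict) -> tuple[float, float]:
    (pse_v, jnd_v), (pse_h, jnd_h) = uni["visual"], uni["haptic"]
    if spec.integration_mode == MLE_INTEGRATOR:
        w_v, w_h = compute_weights(jnd_v, jnd_h)
        return w_v * pse_v + w_h * pse_h, predict_bimodal_sigma(jnd_v, jnd_h)
    if spec.integration_mode == VISUAL_CAPTURE:
        return pse_v, jnd_v
    # no_integration: the more reliable modality wins outright
    return (pse_v, jnd_v) if jnd_v <= jnd_h else (pse_h, jnd_h)


def generate_study(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one PSI session per subject per condition; returns
    ``(trials, truth)`` data frames.

    Children (age < 18) get ``trials_children`` trials per condition, adults
    ``trials_adults``.  Fully deterministic for a fixed ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    truth_ss, session_ss = root.spawn(2)
    truth = make_truth(spec, rng=np.random.default_rng(truth_ss))

    n_sessions = len(truth)
    seeds = session_ss.spawn(n_sessions)
    frames = []
    for k, row in enumerate(truth.itertuples(index=False)):
        n_trials = spec.trials_children if row.age_years < 18.0 else spec.trials_adults
        observer = gaussian_observer(row.true_pse_deg, row.true_jnd_deg, spec.lapse_rate)
        records = run_session(
            observer,
            n_trials,
            rng=np.random.default_rng(seeds[k]),
            lapse_rate=spec.lapse_rate,
            subject_id=row.subject_id,
            age_years=row.age_years,
            condition=row.condition,
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [t.subject_id for t in records],
                    "age_years": [t.age_years for t in records],
                    "condition": [t.condition for t in records],
                    "stimulus_deg": [t.stimulus_deg for t in records],
                    "response": [t.response for t in records],
                }
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    return trials, truth
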