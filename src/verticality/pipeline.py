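"""End-to-end orchestration: generate/load trials, fit, integrate, model-fit.

The pipeline mirrors the analysis flow of a tilted-verticality study: trial
records are fit per subject and condition, non-converging fits are excluded
and counted, converged fits are summarised per age group, unimodal fits feed
the cue-integration predictions, and group-level mean biases feed the prior
observer model, fit separately for the visual and haptic modalities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .integration import (
    ADULT_AGE_YEARS,
    BimodalPrediction,
    UnimodalPair,
    compare_groups,
    predict_bimodal_pse,
)
from .prior import (
    DEFAULT_EPSILON_DEG,
    POLICIES,
    PriorModelSearch,
)
from .psychometric import DEFAULT_LAPSE, PsychometricFit, fit_pse_jnd
from .synth import CohortSpec, GroupSpec, generate_study

logger = logging.getLogger("verticality")

__all__ = [
    "RunConfig",
    "age_group_label",
    "fit_all_trials",
    "summarize_groups",
    "integration_analysis",
    "prior_fit_from_summary",
    "run_all",
]


def age_group_label(age_years: float) -> str:
    """Default age-group labelling: 'adult' from 18 years, otherwise the
    nearest integer year clipped into 6-11."""
    if age_years >= ADULT_AGE_YEARS:
        return "adult"
    return str(int(np.clip(round(age_years), 6, 11)))


def fit_all_trials(trials: pd.DataFrame, lapse_rate: float = DEFAULT_LAPSE) -> pd.DataFrame:
    """Fit every (subject, condition) block; one row per fit."""
    rows = []
    for (sid, cond), block in trials.groupby(["subject_id", "condition"], sort=True):
        fit = fit_pse_jnd(
            block["stimulus_deg"].to_numpy(),
            block["response"].to_numpy(),
            lapse_rate=lapse_rate,
        )
        logger.info(
            "fit subject=%s condition=%s pse=%.2f jnd=%.2f converged=%s",
            sid,
            cond,
            fit.pse_deg,
            fit.jnd_deg,
            fit.converged,
        )
        rows.append(
            {
                "subject_id": sid,
                "age_years": float(block["age_years"].iloc[0]),
                "condition": cond,
                "pse_deg": fit.pse_deg,
                "jnd_deg": fit.jnd_deg,
                "lapse_rate": fit.lapse_rate,
                "log_likelihood": fit.log_likelihood,
                "converged": fit.converged,
                "n_trials": fit.n_trials,
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(fits: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-(modality, age group) summary of converged fits.

    Columns: n, mean age, mean bias with SEM, mean JND with SEM, and a
    one-sample t statistic of the bias against 0.  SEMs of single-subject
    groups are reported as missing.  Non-converged fits are excluded before
    aggregation; empty groups are simply absent.
    """
    conv = fits[fits["converged"].astype(bool)].copy()
    if "group_label" not in conv.columns:
        conv["group_label"] = conv["age_years"].map(age_group_label)
    out = []
    for (cond, label), g in conv.groupby(["condition", "group_label"], sort=True):
        n = len(g)
        bias = g["pse_deg"].to_numpy()
        jnd = g["jnd_deg"].to_numpy()
        sem_bias = bias.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        sem_jnd = jnd.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        t_stat = bias.mean() / sem_bias if n > 1 and sem_bias > 0 else np.nan
        out.append(
            {
                "condition": cond,
                "group_label": label,
                "n": n,
                "mean_age_years": g["age_years"].mean(),
                "mean_bias_deg": bias.mean(),
                "sem_bias_deg": sem_bias,
                "mean_jnd_deg": jnd.mean(),
                "sem_jnd_deg": sem_jnd,
                "t_vs_zero": t_stat,
            }
        )
    return pd.DataFrame(out)


def _fit_from_row(row) -> PsychometricFit:
    return PsychometricFit(
        pse_deg=row.pse_deg,
        jnd_deg=row.jnd_deg,
        lapse_rate=row.lapse_rate,
        log_likelihood=row.log_likelihood,
        converged=bool(row.converged),
        n_trials=int(row.n_trials),
    )


def integration_analysis(fits: pd.DataFrame):
    """Bimodal predictions and the group comparison table.

    Uses only subjects with converged fits in all three conditions.  Returns
    ``(predictions_df, comparison_df)``; the comparison is None when a group
    is too small to compare.
    """
    by_subject: dict[str, dict[str, PsychometricFit]] = {}
    ages: dict[str, float] = {}
    for row in fits.itertuples(index=False):
        by_subject.setdefault(row.subject_id, {})[row.condition] = _fit_from_row(row)
        ages[row.subject_id] = row.age_years

    predictions: dict[str, BimodalPrediction] = {}
    observed: dict[str, PsychometricFit] = {}
    for sid, conds in sorted(by_subject.items()):
        if set(conds) != {"visual", "haptic", "bimodal"}:
            continue
        if not all(conds[c].converged for c in conds):
            continue
        pair = UnimodalPair(subject_id=sid, visual=conds["visual"], haptic=conds["haptic"])
        predictions[sid] = predict_bimodal_pse(pair)
        observed[sid] = conds["bimodal"]

    pred_df = pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "age_years": ages[p.subject_id],
                "sigma_vh_deg": p.sigma_vh_deg,
                "pse_vh_deg": p.pse_vh_deg,
                "w_v": p.w_v,
                "w_h": p.w_h,
            }
            for p in predictions.values()
        ]
    )
    try:
        comparison = compare_groups(predictions, observed, ages)
    except ValueError as exc:
        logger.warning("group comparison skipped: %s", exc)
        comparison = None
    return pred_df, comparison


def prior_fit_from_summary(
    summary: pd.DataFrame,
    modality: str,
    *,
    search: PriorModelSearch | None = None,
    **search_kwargs,
):
    """Fit the prior observer model to one modality's group mean biases."""
    sub = summary[summary["condition"] == modality].sort_values("mean_age_years")
    ages = sub["mean_age_years"].to_numpy()
    biases = sub["mean_bias_deg"].to_numpy()
    if search is None:
        search = PriorModelSearch(ages, **search_kwargs)
    return search.fit(biases), ages


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run.

    Exactly one of ``trials_csv`` / ``synthesis`` must be given; the latter
    is a :class:`verticality.synth.CohortSpec`.
    """

    out_dir: str
    seed: int = 0
    trials_csv: str | None = None
    synthesis: CohortSpec | None = None
    lapse_rate: float = DEFAULT_LAPSE
    policies: tuple = POLICIES
    sigma_p_grid: np.ndarray | None = None
    a0_grid: np.ndarray | None = None
    a1_grid: np.ndarray | None = None
    epsilon_deg: float = DEFAULT_EPSILON_DEG
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.trials_csv is None) == (self.synthesis is None):
            raise ValueError("exactly one of trials_csv / synthesis must be set")

    @classmethod
    def from_json(cls, path, **overrides) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        synthesis = None
        if "synthesis" in raw:
            s = dict(raw["synthesis"])
            if "groups" in s:
                s["groups"] = [GroupSpec(*g) for g in s["groups"]]
            synthesis = CohortSpec(**s)
        kwargs = {
            "out_dir": raw.get("out_dir", "."),
            "seed": raw.get("seed", 0),
            "trials_csv": raw.get("trials_csv"),
            "synthesis": synthesis,
            "lapse_rate": raw.get("lapse_rate", DEFAULT_LAPSE),
            "epsilon_deg": raw.get("epsilon_deg", DEFAULT_EPSILON_DEG),
            "make_plots": raw.get("make_plots", False),
        }
        if "policies" in raw:
            kwargs["policies"] = tuple(raw["policies"])
        for key in ("sigma_p_grid", "a0_grid", "a1_grid"):
            if key in raw:
                lo, hi, step = raw[key]
                kwargs[key] = np.round(np.arange(lo, hi + 1e-9, step), 10)
        kwargs.update(overrides)
        return cls(**kwargs)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write the result bundle.

    Artifacts: ``trials.csv`` (when synthesised, with ``truth.csv``),
    ``fits.csv``, ``group_summary.csv``, ``bimodal_predictions.csv``,
    ``integration_comparison.csv``, ``prior_fit_visual.json``,
    ``prior_fit_haptic.json``, ``manifest.json`` and optional plots.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthesis is not None:
        spec = config.synthesis
        if config.seed is not None:
            from dataclasses import replace as dc_replace

            spec = dc_replace(spec, seed=config.seed)
        trials, truth = generate_study(spec)
        io.write_trials_csv(trials, out / "trials.csv")
        truth.to_csv(out / "truth.csv", index=False, float_format="%.6f")
    else:
        trials = io.read_trials_csv(config.trials_csv)

    fits = fit_all_trials(trials, lapse_rate=config.lapse_rate)
    io.write_fits_csv(fits, out / "fits.csv")
    n_total = fits["subject_id"].nunique()
    bad = fits[~fits["converged"].astype(bool)]
    excluded_subjects = sorted(bad["subject_id"].unique())
    logger.info(
        "%d subjects, %d non-converged fits across %d subjects",
        n_total,
        len(bad),
        len(excluded_subjects),
    )

    summary = summarize_groups(fits)
    summary.to_csv(out / "group_summary.csv", index=False, float_format="%.6f")

    pred_df, comparison = integration_analysis(fits)
    pred_df.to_csv(out / "bimodal_predictions.csv", index=False, float_format="%.6f")
    if comparison is not None:
        comparison.to_csv(out / "integration_comparison.csv", float_format="%.6f")

    prior_fits = {}
    for modality in ("visual", "haptic"):
        if not (summary["condition"] == modality).any():
            continue
        fit, _ages = prior_fit_from_summary(
            summary,
            modality,
            policies=config.policies,
            sigma_p_grid=config.sigma_p_grid,
            a0_grid=config.a0_grid,
            a1_grid=config.a1_grid,
            epsilon_deg=config.epsilon_deg,
        )
        io.write_prior_fit_json(fit, out / f"prior_fit_{modality}.json")
        prior_fits[modality] = fit

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "lapse_rate": config.lapse_rate,
        "n_subjects": int(n_total),
        "n_nonconverged_fits": int(len(bad)),
        "excluded_subjects": excluded_subjects,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    io.write_json(manifest, out / "manifest.json")

    if config.make_plots:
        from . import plots

        plots.bias_vs_age(summary, out / "bias_vs_age.png")
        if "visual" in prior_fits:
            plots.observer_triptych(
                prior_fits["visual"].config,
                prior_fits["visual"].params,
                sorted({round(a) for a in summary["mean_age_years"]}),
                out / "prior_model_visual.png",
            )

    return {
        "trials": trials,
        "fits": fits,
        "summary": summary,
        "predictions": pred_df,
        "comparison": comparison,
        "prior_fits": prior_fits,
        "manifest": manifest,
        "out_dir": str(out),
    }
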