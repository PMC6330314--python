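"""Diagnostic figures: group bias trajectories and the observer triptych."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import norm

from .prior import (
    LikelihoodAgeParams,
    PriorConfig,
    TRUE_TILT_DEG,
    prior_center_for_age,
    rectify_sigma,
    sigma_age,
)

__all__ = ["bias_vs_age", "observer_triptych"]


def bias_vs_age(summary, path) -> None:
    """Mean bias vs mean age per modality, with +/- SEM bands."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, g in summary.groupby("condition"):
        g = g.sort_values("mean_age_years")
        x = g["mean_age_years"].to_numpy()
        y = g["mean_bias_deg"].to_numpy()
        sem = np.nan_to_num(g["sem_bias_deg"].to_numpy())
        ax.plot(x, y, marker="o", label=cond)
        ax.fill_between(x, y - sem, y + sem, alpha=0.2)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("bias (deg)  [negative = A-effect]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def observer_triptych(
    config: PriorConfig,
    params: LikelihoodAgeParams,
    ages,
    path,
) -> None:
    """Prior, likelihood and posterior rows for a set of age groups.

    The posterior is the pointwise product of prior and likelihood; its peak
    position relative to the true tilt (-90 deg) shows whether the model
    predicts under- or overcompensation of body tilt.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    theta = np.linspace(-200.0, 20.0, 2201)
    sigma_b = rectify_sigma(sigma_age(ages, params), params.epsilon_deg)

    fig, axes = plt.subplots(3, 1, figsize=(6, 8), sharex=True)
    for k, age in enumerate(ages):
        center = prior_center_for_age(config.policy, age)
        if center is None:
            prior_pdf = np.full_like(theta, 1.0 / (theta[-1] - theta[0]))
        else:
            prior_pdf = norm.pdf(theta, loc=center, scale=config.sigma_p_deg)
        like_pdf = norm.pdf(theta, loc=TRUE_TILT_DEG, scale=sigma_b[k])
        post = prior_pdf * like_pdf
        post /= np.trapezoid(post, theta)
        label = f"{age:.0f} y"
        axes[0].plot(theta, prior_pdf, label=label)
        axes[1].plot(theta, like_pdf, label=label)
        axes[2].plot(theta, post, label=label)
    for ax, title in zip(axes, ("prior", "likelihood", "posterior")):
        ax.axvline(TRUE_TILT_DEG, color="k", lw=0.8, ls="--")
        ax.set_ylabel(title)
    axes[2].set_xlabel("body orientation (deg)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
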