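"""Cumulative-Gaussian psychometric observer for 2AFC verticality judgments.

A subject tilted 90° counterclockwise (left-ear down) judges whether a bar is
tilted toward or away from their body tilt.  The probability of an "away"
response as a function of bar orientation is modelled as a cumulative Gaussian
whose mean is the point of subjective equality (PSE, the bias) and whose
standard deviation is the just noticeable difference (JND, inverse precision).
A negative PSE means the bar must be rotated toward the body to appear
vertical — the Aubert (A-) effect; a positive PSE is the E-effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

__all__ = [
    "CONDITIONS",
    "STIMULUS_RANGE_DEG",
    "DEFAULT_LAPSE",
    "A_EFFECT",
    "E_EFFECT",
    "UNBIASED",
    "TrialRecord",
    "PsychometricFit",
    "pf_eval",
    "fit_psychometric",
    "fit_pse_jnd",
    "classify_bias",
]

CONDITIONS = ("visual", "haptic", "bimodal")
STIMULUS_RANGE_DEG = (-45.0, 45.0)

#: Fixed symmetric lapse rate, split evenly across both asymptotes.  A free
#: lapse is not identifiable from 50-trial blocks, so it is held constant for
#: both fitting and the simulated observers inside the adaptive procedure.
DEFAULT_LAPSE = 0.02

A_EFFECT = "A_effect"
E_EFFECT = "E_effect"
UNBIASED = "unbiased"

#: JND bounds (deg) outside which a fit is flagged non-converged.
JND_BOUNDS_DEG = (0.2, 40.0)
#: |PSE| bound (deg) outside which a fit is flagged non-converged.
PSE_BOUND_DEG = 45.0
#: Minimum number of trials required for a fit.
MIN_TRIALS = 20

_P_FLOOR = 1e-12


@dataclass(frozen=True)
class TrialRecord:
    """One two-alternative forced-choice trial.

    Attributes
    ----------
    subject_id : str
        Opaque subject token.
    age_years : float
        Subject age in years (> 0).
    condition : str
        One of ``visual``, ``haptic``, ``bimodal``.
    stimulus_deg : float
        Bar orientation in degrees, within [-45, 45]; negative values are
        tilted toward the body tilt.
    response : int
        1 = judged "tilted away from body tilt", 0 = toward.
    """

    subject_id: str
    age_years: float
    condition: str
    stimulus_deg: float
    response: int

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValueError(f"age_years must be positive, got {self.age_years}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        lo, hi = STIMULUS_RANGE_DEG
        if not (lo <= self.stimulus_deg <= hi):
            raise ValueError(
                f"stimulus_deg {self.stimulus_deg} outside [{lo}, {hi}]"
            )
        if self.response not in (0, 1):
            raise ValueError(f"response must be 0 or 1, got {self.response}")


@dataclass
class PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit of one subject/condition.

    ``pse_deg`` is the bias (negative = A-effect), ``jnd_deg`` the standard
    deviation of the fitted cumulative Gaussian.  Non-converged fits carry
    ``converged=False`` and are excluded from group-level aggregation.
    """

    pse_deg: float
    jnd_deg: float
    lapse_rate: float
    log_likelihood: float
    converged: bool
    n_trials: int


def pf_eval(stimulus_deg, pse_deg, jnd_deg, lapse_rate=DEFAULT_LAPSE):
    """Probability of an "away" response at a given bar orientation.

    P(response = 1 | x) = lapse/2 + (1 - lapse) * Phi((x - pse) / jnd)

    All arguments broadcast; returns a float or ndarray in
    [lapse/2, 1 - lapse/2].
    """
    jnd = np.asarray(jnd_deg, dtype=float)
    if np.any(jnd <= 0):
        raise ValueError("jnd_deg must be strictly positive")
    lam = float(lapse_rate)
    if not (0.0 <= lam <= 0.1):
        raise ValueError(f"lapse_rate must lie in [0, 0.1], got {lam}")
    z = (np.asarray(stimulus_deg, dtype=float) - np.asarray(pse_deg, dtype=float)) / jnd
    out = lam / 2.0 + (1.0 - lam) * ndtr(z)
    if out.ndim == 0:
        return float(out)
    return out


def _neg_log_likelihood(stimuli, responses, pse, jnd, lapse):
    """Bernoulli negative log-likelihood; pse/jnd may be arrays (grid eval)."""
    p = pf_eval(stimuli, pse, jnd, lapse)
    p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    return -(responses * np.log(p) + (1.0 - responses) * np.log1p(-p)).sum(axis=0)


def fit_pse_jnd(
    stimuli,
    responses,
    lapse_rate: float = DEFAULT_LAPSE,
    min_trials: int = MIN_TRIALS,
) -> PsychometricFit:
    """Fit (PSE, JND) by maximum likelihood from raw stimulus/response arrays.

    The JND is optimised on a log scale to avoid boundary pathologies.  The
    optimiser is seeded from a coarse grid scan and polished with Nelder-Mead.
    A fit is marked non-converged when the optimiser fails, the JND leaves
    (0.2, 40) deg, |PSE| reaches 45 deg, or the local Hessian of the negative
    log-likelihood is not positive definite.

    Degenerate data (a single response class) return a non-converged fit
    rather than raising; fewer than ``min_trials`` trials is a contract
    violation.
    """
    x = np.asarray(stimuli, dtype=float)
    r = np.asarray(responses, dtype=float)
    n = x.size
    if n < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {n}")
    if r.min() == r.max():
        return PsychometricFit(
            pse_deg=math.nan,
            jnd_deg=math.nan,
            lapse_rate=lapse_rate,
            log_likelihood=math.nan,
            converged=False,
            n_trials=n,
        )

    # Coarse grid start, then simplex polish on (pse, log jnd).
    a_grid = np.arange(-40.0, 40.0 + 1e-9, 2.0)
    ls_grid = np.linspace(np.log(0.4), np.log(35.0), 9)
    aa, ll = np.meshgrid(a_grid, ls_grid, indexing="ij")
    nll_grid = _neg_log_likelihood(
        x[:, None], r[:, None], aa.ravel()[None, :], np.exp(ll.ravel())[None, :], lapse_rate
    )
    k = int(np.argmin(nll_grid))
    theta0 = np.array([aa.ravel()[k], ll.ravel()[k]])

    def objective(theta):
        return _neg_log_likelihood(x, r, theta[0], np.exp(theta[1]), lapse_rate)

    res = minimize(
        objective,
        theta0,
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 800},
    )
    pse = float(res.x[0])
    jnd = float(np.exp(res.x[1]))
    converged = bool(res.success)
    converged &= JND_BOUNDS_DEG[0] < jnd < JND_BOUNDS_DEG[1]
    converged &= abs(pse) < PSE_BOUND_DEG
    if converged:
        converged = _hessian_positive_definite(objective, res.x)
    return PsychometricFit(
        pse_deg=pse,
        jnd_deg=jnd,
        lapse_rate=lapse_rate,
        log_likelihood=float(-res.fun),
        converged=converged,
        n_trials=n,
    )


def _hessian_positive_definite(f, theta, h: float = 1e-3) -> bool:
    """Finite-difference Hessian check at the optimum (2 parameters)."""
    t = np.asarray(theta, dtype=float)
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = h
            ej[j] = h
            hess[i, j] = (
                f(t + ei + ej) - f(t + ei - ej) - f(t - ei + ej) + f(t - ei - ej)
            ) / (4.0 * h * h)
    if not np.all(np.isfinite(hess)):
        return False
    eig = np.linalg.eigvalsh((hess + hess.T) / 2.0)
    return bool(np.all(eig > 0))


def fit_psychometric(trials, lapse_rate: float = DEFAULT_LAPSE) -> PsychometricFit:
    """Fit a cumulative Gaussian to a list of :class:`TrialRecord`."""
    x = np.array([t.stimulus_deg for t in trials], dtype=float)
    r = np.array([t.response for t in trials], dtype=float)
    return fit_pse_jnd(x, r, lapse_rate=lapse_rate)


def classify_bias(pse_deg: float, threshold_deg: float = 0.0) -> str:
    """Classify a bias as A-effect (toward tilt), E-effect (away) or unbiased.

    ``threshold_deg`` sets a dead zone around zero; with the default 0 any
    strictly negative PSE is an A-effect and any strictly positive one an
    E-effect.
    """
    if threshold_deg < 0:
        raise ValueError("threshold_deg must be nonnegative")
    if pse_deg < -threshold_deg:
        return A_EFFECT
    if pse_deg > threshold_deg:
        return E_EFFECT
    return UNBIASED
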