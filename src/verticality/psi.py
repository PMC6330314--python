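"""Entropy-minimising PSI adaptive procedure for 2AFC threshold estimation.

The procedure keeps a discrete posterior over candidate (PSE, JND) pairs and,
on every trial, presents the stimulus orientation that minimises the expected
Shannon entropy of that posterior, averaged over the two possible responses
weighted by their predictive probabilities.  The posterior is updated by
Bayes' rule after each response.  Final PSE/JND estimates are obtained by a
separate maximum-likelihood refit of the collected trials
(:func:`verticality.psychometric.fit_pse_jnd`), not from the PSI posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import xlogy

from .psychometric import DEFAULT_LAPSE, STIMULUS_RANGE_DEG, TrialRecord, pf_eval

__all__ = [
    "PsiState",
    "default_alpha_grid",
    "default_sigma_grid",
    "default_stimulus_grid",
    "init_psi",
    "select_stimulus",
    "expected_entropies",
    "update_posterior",
    "gaussian_observer",
    "run_session",
]

_NORM_TOL = 1e-10


def default_alpha_grid() -> np.ndarray:
    """Candidate PSE values: -40 to 40 deg in 1 deg steps (symmetric about 0,
    so the initial marginal mode sits at 0 deg under the tie-break)."""
    return np.arange(-40.0, 40.0 + 1e-9, 1.0)


def default_sigma_grid() -> np.ndarray:
    """Candidate JND values: 25 log-spaced points from 0.5 to 30 deg."""
    return np.geomspace(0.5, 30.0, 25)


def default_stimulus_grid() -> np.ndarray:
    """Candidate stimulus orientations: -45 to 45 deg in 1.5 deg steps."""
    return np.arange(-45.0, 45.0 + 1e-9, 1.5)


class _Tables:
    """Per-grid constant lookup tables shared by all states of a session."""

    def __init__(self, alpha, sigma, stimulus, lapse):
        aa, ss = np.meshgrid(alpha, sigma, indexing="ij")
        self.alpha_flat = aa.ravel()
        self.sigma_flat = ss.ravel()
        # P(response=1 | x, theta), shape (n_stimuli, n_theta)
        self.p1 = pf_eval(
            stimulus[:, None], self.alpha_flat[None, :], self.sigma_flat[None, :], lapse
        )
        self.q1 = 1.0 - self.p1
        self.p1_xlog = xlogy(self.p1, self.p1)
        self.q1_xlog = xlogy(self.q1, self.q1)
        # Deterministic tie-break: smallest |x| first, negative before positive.
        self.tie_order = np.array(
            sorted(range(stimulus.size), key=lambda i: (abs(stimulus[i]), stimulus[i] >= 0))
        )


@dataclass
class PsiState:
    """State of one PSI run: grids plus the posterior over (PSE, JND)."""

    alpha_grid: np.ndarray
    sigma_grid: np.ndarray
    stimulus_grid: np.ndarray
    posterior: np.ndarray  # flat over alpha x sigma, sums to 1
    trial_count: int
    lapse_rate: float
    tables: _Tables = field(repr=False, compare=False, default=None)

    def posterior_2d(self) -> np.ndarray:
        return self.posterior.reshape(self.alpha_grid.size, self.sigma_grid.size)

    def alpha_marginal(self) -> np.ndarray:
        return self.posterior_2d().sum(axis=1)

    def sigma_marginal(self) -> np.ndarray:
        return self.posterior_2d().sum(axis=0)

    def pse_mode(self) -> float:
        """Mode of the PSE marginal; ties go to smallest |alpha|, negative first."""
        marg = self.alpha_marginal()
        best = marg.max()
        ties = np.flatnonzero(marg >= best - 1e-15)
        key = sorted(ties, key=lambda i: (abs(self.alpha_grid[i]), self.alpha_grid[i] >= 0))
        return float(self.alpha_grid[key[0]])

    def entropy(self) -> float:
        return float(-xlogy(self.posterior, self.posterior).sum())


def init_psi(
    alpha_grid=None,
    sigma_grid=None,
    stimulus_grid=None,
    lapse_rate: float = DEFAULT_LAPSE,
) -> PsiState:
    """Initialise a PSI run with a uniform posterior over the parameter grid.

    The grids default to :func:`default_alpha_grid` etc.  Grid symmetry about
    0 deg realises the conventional unbiased starting estimate: the initial
    PSE-marginal mode is 0 deg.
    """
    alpha = np.asarray(alpha_grid if alpha_grid is not None else default_alpha_grid(), float)
    sigma = np.asarray(sigma_grid if sigma_grid is not None else default_sigma_grid(), float)
    stim = np.asarray(
        stimulus_grid if stimulus_grid is not None else default_stimulus_grid(), float
    )
    if alpha.size == 0 or sigma.size == 0 or stim.size == 0:
        raise ValueError("grids must be nonempty")
    if np.any(sigma <= 0):
        raise ValueError("sigma_grid must be strictly positive")
    lo, hi = STIMULUS_RANGE_DEG
    if stim.min() < lo or stim.max() > hi:
        raise ValueError(f"stimulus_grid must lie within [{lo}, {hi}]")
    n = alpha.size * sigma.size
    posterior = np.full(n, 1.0 / n)
    tables = _Tables(alpha, sigma, stim, lapse_rate)
    return PsiState(
        alpha_grid=alpha,
        sigma_grid=sigma,
        stimulus_grid=stim,
        posterior=posterior,
        trial_count=0,
        lapse_rate=lapse_rate,
        tables=tables,
    )


def expected_entropies(state: PsiState) -> np.ndarray:
    """Expected posterior entropy after each candidate stimulus.

    For stimulus x with predictive probability s1 = P(r=1 | x) under the
    current posterior p, the entropy of the response-conditional posterior is
    H_r = log s_r - (sum_theta p * L_r * log(p * L_r)) / s_r, and the expected
    entropy is s1*H1 + s0*H0.
    """
    t = state.tables
    p = state.posterior
    u = xlogy(p, p)  # p log p, with 0 log 0 = 0
    s1 = t.p1 @ p
    s0 = 1.0 - s1
    w1 = t.p1 @ u + t.p1_xlog @ p  # sum_theta (p * p1) log(p * p1)
    w0 = t.q1 @ u + t.q1_xlog @ p
    with np.errstate(divide="ignore", invalid="ignore"):
        h1 = np.where(s1 > 1e-300, np.log(np.maximum(s1, 1e-300)) - w1 / np.maximum(s1, 1e-300), 0.0)
        h0 = np.where(s0 > 1e-300, np.log(np.maximum(s0, 1e-300)) - w0 / np.maximum(s0, 1e-300), 0.0)
    return s1 * h1 + s0 * h0


def select_stimulus(state: PsiState) -> float:
    """Stimulus orientation minimising expected posterior entropy.

    Ties (within 1e-12 nats) are broken by smallest absolute orientation,
    negative before positive, so runs are deterministic.
    """
    eh = expected_entropies(state)
    best = eh.min()
    for i in state.tables.tie_order:
        if eh[i] <= best + 1e-12:
            return float(state.stimulus_grid[i])
    return float(state.stimulus_grid[int(np.argmin(eh))])  # pragma: no cover


def update_posterior(state: PsiState, stimulus_deg: float, response: int) -> PsiState:
    """Bayes-rule update of the posterior after one observed response."""
    lo, hi = STIMULUS_RANGE_DEG
    if not (lo <= stimulus_deg <= hi):
        raise ValueError(f"stimulus_deg {stimulus_deg} outside [{lo}, {hi}]")
    if response not in (0, 1):
        raise ValueError(f"response must be 0 or 1, got {response}")
    t = state.tables
    like = pf_eval(stimulus_deg, t.alpha_flat, t.sigma_flat, state.lapse_rate)
    if response == 0:
        like = 1.0 - like
    new = state.posterior * like
    total = new.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise ValueError(
            "posterior update produced zero total mass "
            f"(stimulus={stimulus_deg}, response={response}): the observed "
            "response has vanishing likelihood everywhere on the grid"
        )
    new /= total
    return replace(state, posterior=new, trial_count=state.trial_count + 1)


def gaussian_observer(
    pse_deg: float, jnd_deg: float, lapse_rate: float = DEFAULT_LAPSE
) -> Callable[[float, np.random.Generator], int]:
    """Simulated observer drawing Bernoulli responses from a cumulative
    Gaussian psychometric function."""

    def observer(stimulus_deg: float, rng: np.random.Generator) -> int:
        p = pf_eval(stimulus_deg, pse_deg, jnd_deg, lapse_rate)
        return int(rng.random() < p)

    return observer


def run_session(
    observer: Callable[[float, np.random.Generator], int],
    n_trials: int,
    *,
    seed=None,
    rng: np.random.Generator | None = None,
    alpha_grid=None,
    sigma_grid=None,
    stimulus_grid=None,
    lapse_rate: float = DEFAULT_LAPSE,
    subject_id: str = "sim",
    age_years: float = 30.0,
    condition: str = "visual",
    return_state: bool = False,
):
    """Run one adaptive session against a response-generating observer.

    Alternates stimulus selection, observer response and posterior update for
    ``n_trials`` trials.  Reproducible for a fixed ``seed``.  Returns the list
    of :class:`TrialRecord`; with ``return_state=True`` returns
    ``(records, final_state)``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    state = init_psi(alpha_grid, sigma_grid, stimulus_grid, lapse_rate)
    records: list[TrialRecord] = []
    for _ in range(n_trials):
        x = select_stimulus(state)
        r = int(observer(x, rng))
        records.append(
            TrialRecord(
                subject_id=subject_id,
                age_years=age_years,
                condition=condition,
                stimulus_deg=x,
                response=r,
            )
        )
        state = update_posterior(state, x, r)
    if return_state:
        return records, state
    return records
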