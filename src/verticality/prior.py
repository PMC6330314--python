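"""Bayesian prior observer model of perceived verticality under 90° tilt.

The tilted observer's estimate of body orientation is the peak of a posterior
formed by multiplying a Gaussian likelihood centred at the true tilt (-90 deg,
left-ear down; assumed unbiased) with a Gaussian prior over body orientations.
The prior can be flat (no influence), peaked at upright (0 deg, the idiotropic
vector, producing A-effects) or peaked at upside-down (-180 deg, producing
E-effects), and its placement may differ between children and adults.  The
likelihood width grows or shrinks linearly with age,

    sigma_a(age) = a0 + a1 * age,

rectified to stay positive (see :func:`rectify_sigma`).  The signed bias of
perceived vertical is (true tilt - posterior peak): a posterior peak between
-90 and 0 deg is undercompensation of tilt (negative bias, A-effect), between
-180 and -90 deg overcompensation (positive bias, E-effect).

The model is fit to observed mean biases per age group by exhaustive grid
search over (prior policy, sigma_p, a0, a1), minimising the unweighted sum of
squared errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TRUE_TILT_DEG",
    "PRIOR_UPRIGHT_DEG",
    "PRIOR_UPSIDEDOWN_DEG",
    "ADULT_AGE_YEARS",
    "POLICIES",
    "FLAT_ALL",
    "UPRIGHT_ALL",
    "UPRIGHT_CHILDREN_FLAT_ADULTS",
    "UPRIGHT_CHILDREN_UPSIDEDOWN_ADULTS",
    "PriorConfig",
    "LikelihoodAgeParams",
    "PriorModelFit",
    "sigma_age",
    "rectify_sigma",
    "posterior_peak",
    "predicted_bias",
    "prior_center_for_age",
    "forward_predict",
    "PriorModelSearch",
    "fit_prior_model",
    "default_sigma_p_grid",
    "default_a0_grid",
    "default_a1_grid",
    "DEFAULT_VISUAL_PRIOR_FIT",
    "DEFAULT_HAPTIC_PRIOR_FIT",
]

TRUE_TILT_DEG = -90.0
PRIOR_UPRIGHT_DEG = 0.0
PRIOR_UPSIDEDOWN_DEG = -180.0
#: Age (years) at and above which the "adult" component of a policy applies.
ADULT_AGE_YEARS = 18.0

FLAT_ALL = "flat_all"
UPRIGHT_ALL = "upright_all"
UPRIGHT_CHILDREN_FLAT_ADULTS = "upright_children_flat_adults"
UPRIGHT_CHILDREN_UPSIDEDOWN_ADULTS = "upright_children_upsidedown_adults"

#: Prior-placement policies, in tie-break order (flat before peaked).
POLICIES = (
    FLAT_ALL,
    UPRIGHT_ALL,
    UPRIGHT_CHILDREN_FLAT_ADULTS,
    UPRIGHT_CHILDREN_UPSIDEDOWN_ADULTS,
)

DEFAULT_EPSILON_DEG = 0.1


@dataclass(frozen=True)
class PriorConfig:
    """Prior placement policy plus the prior spread sigma_p (deg).

    ``sigma_p_deg`` is ignored for flat components but must be positive
    whenever any non-flat component is active.
    """

    policy: str
    sigma_p_deg: float

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.policy != FLAT_ALL and not self.sigma_p_deg > 0:
            raise ValueError("sigma_p_deg must be positive for a peaked prior")


@dataclass(frozen=True)
class LikelihoodAgeParams:
    """Age-dependence of the likelihood width: sigma_a = a0 + a1 * age,
    rectified with floor constant epsilon."""

    a0_deg: float
    a1_deg_per_year: float
    epsilon_deg: float = DEFAULT_EPSILON_DEG

    def __post_init__(self) -> None:
        if not self.epsilon_deg > 0:
            raise ValueError("epsilon_deg must be positive")


@dataclass
class PriorModelFit:
    """Best-fitting prior model over age-group biases."""

    config: PriorConfig
    params: LikelihoodAgeParams
    sse: float
    r_squared: float
    predicted_bias_by_age: dict = field(default_factory=dict)


#: Reference visual-modality configuration (upright prior at all ages,
#: slightly increasing likelihood width with age).  Used as the default
#: generative truth for the visual condition of synthetic cohorts.
DEFAULT_VISUAL_PRIOR_FIT = (
    PriorConfig(UPRIGHT_ALL, 24.7),
    LikelihoodAgeParams(5.3, 0.16),
)

#: Reference haptic-modality configuration (upright prior in children,
#: upside-down prior in adults, likelihood width decreasing with age).
DEFAULT_HAPTIC_PRIOR_FIT = (
    PriorConfig(UPRIGHT_CHILDREN_UPSIDEDOWN_ADULTS, 28.3),
    LikelihoodAgeParams(0.3, -0.16),
)


def sigma_age(age_years, params: LikelihoodAgeParams):
    """Raw (possibly negative) likelihood width a0 + a1 * age."""
    return params.a0_deg + params.a1_deg_per_year * np.asarray(age_years, dtype=float)


def rectify_sigma(raw_sigmas, epsilon_deg: float = DEFAULT_EPSILON_DEG) -> np.ndarray:
    """Map raw widths over the evaluated age set onto strictly positive ones.

    If every raw value is positive, each is shifted by +epsilon only.
    Otherwise the minimum over the age set is subtracted before adding
    epsilon, so the youngest-to-oldest ordering is preserved and the smallest
    width maps to epsilon.  (A literal min-*addition* cannot keep widths
    positive when the slope is negative enough; the subtraction realises the
    stated intent of keeping the age trend while staying positive.)

    Operates on the last axis, so parameter-grid tensors with a trailing age
    axis rectify each parameter combination independently.
    """
    if not epsilon_deg > 0:
        raise ValueError("epsilon_deg must be positive")
    raw = np.asarray(raw_sigmas, dtype=float)
    if raw.size == 0:
        raise ValueError("age set must be nonempty")
    mn = raw.min(axis=-1, keepdims=True)
    return np.where(mn > 0, raw + epsilon_deg, raw - mn + epsilon_deg)


def posterior_peak(
    prior_center_deg,
    sigma_p_deg: float,
    likelihood_center_deg: float,
    sigma_b_deg: float,
) -> float:
    """Peak of the (Gaussian x Gaussian) posterior on a linear angle axis.

    ``prior_center_deg=None`` denotes a flat prior, for which the peak is the
    likelihood centre.  Otherwise the product of two Gaussians peaks at the
    precision-weighted mean (mu_L sigma_p^2 + mu_p sigma_b^2) /
    (sigma_p^2 + sigma_b^2).
    """
    if sigma_b_deg <= 0:
        raise ValueError("sigma_b_deg must be positive")
    if prior_center_deg is None:
        return float(likelihood_center_deg)
    if sigma_p_deg <= 0:
        raise ValueError("sigma_p_deg must be positive")
    sp2 = sigma_p_deg * sigma_p_deg
    sb2 = sigma_b_deg * sigma_b_deg
    return float((likelihood_center_deg * sp2 + prior_center_deg * sb2) / (sp2 + sb2))


def predicted_bias(posterior_peak_deg: float, true_tilt_deg: float = TRUE_TILT_DEG):
    """Signed bias of perceived vertical: true tilt minus posterior peak.

    Peaks in (-90, 0] give negative biases (A-effect, undercompensation);
    peaks in [-180, -90) give positive biases (E-effect, overcompensation).
    """
    return true_tilt_deg - posterior_peak_deg


def prior_center_for_age(policy: str, age_years: float):
    """Prior centre (deg) for one age under a policy; None means flat."""
    adult = age_years >= ADULT_AGE_YEARS
    if policy == FLAT_ALL:
        return None
    if policy == UPRIGHT_ALL:
        return PRIOR_UPRIGHT_DEG
    if policy == UPRIGHT_CHILDREN_FLAT_ADULTS:
        return None if adult else PRIOR_UPRIGHT_DEG
    if policy == UPRIGHT_CHILDREN_UPSIDEDOWN_ADULTS:
        return PRIOR_UPSIDEDOWN_DEG if adult else PRIOR_UPRIGHT_DEG
    raise ValueError(f"unknown policy {policy!r}")


def _bias_given(centers, flat_mask, sp2, sb2):
    """Vectorised bias for broadcastable centre/width arrays.

    Shared by :func:`forward_predict` and the grid search so both paths use
    bitwise-identical arithmetic.
    """
    safe_centers = np.where(flat_mask, 0.0, centers)
    peak = (TRUE_TILT_DEG * sp2 + safe_centers * sb2) / (sp2 + sb2)
    return np.where(flat_mask, 0.0, TRUE_TILT_DEG - peak)


def forward_predict(
    config: PriorConfig, params: LikelihoodAgeParams, age_groups
) -> np.ndarray:
    """Predicted bias (deg) for each age group under one configuration.

    The rectification of the likelihood width is computed over the supplied
    age set as a whole, so the same ages must be passed together when
    predictions are to be compared.
    """
    ages = np.atleast_1d(np.asarray(age_groups, dtype=float))
    sigma_b = rectify_sigma(sigma_age(ages, params), params.epsilon_deg)
    centers = np.array(
        [
            c if (c := prior_center_for_age(config.policy, a)) is not None else np.nan
            for a in ages
        ]
    )
    flat_mask = np.isnan(centers)
    sp2 = config.sigma_p_deg * config.sigma_p_deg
    return _bias_given(centers, flat_mask, sp2, sigma_b * sigma_b)


def default_sigma_p_grid() -> np.ndarray:
    """Prior-width grid: 1 to 60 deg, step 0.3."""
    return np.round(np.arange(1.0, 60.0 + 1e-9, 0.3), 10)


def default_a0_grid() -> np.ndarray:
    """Likelihood offset grid: -5 to 15 deg, step 0.1."""
    return np.round(np.arange(-5.0, 15.0 + 1e-9, 0.1), 10)


def default_a1_grid() -> np.ndarray:
    """Likelihood slope grid: -0.5 to 0.5 deg/year, step 0.02."""
    return np.round(np.arange(-0.5, 0.5 + 1e-9, 0.02), 10)


class PriorModelSearch:
    """Exhaustive least-squares search over policy x sigma_p x a0 x a1.

    Precomputes the forward-predicted bias for every grid combination at the
    given age groups, so repeated fits (e.g. Monte-Carlo replicates) reuse the
    tables.  Ties in SSE are broken deterministically: flat before peaked
    policies, then smaller sigma_p, smaller |a1|, smaller a0.
    """

    def __init__(
        self,
        age_groups,
        *,
        policies=POLICIES,
        sigma_p_grid=None,
        a0_grid=None,
        a1_grid=None,
        epsilon_deg: float = DEFAULT_EPSILON_DEG,
    ):
        self.ages = np.atleast_1d(np.asarray(age_groups, dtype=float))
        if self.ages.size < 3:
            raise ValueError("need at least 3 age groups")
        self.policies = tuple(policies)
        if not self.policies:
            raise ValueError("policy list must be nonempty")
        for p in self.policies:
            if p not in POLICIES:
                raise ValueError(f"unknown policy {p!r}")
        self.sigma_p = np.asarray(
            sigma_p_grid if sigma_p_grid is not None else default_sigma_p_grid(), float
        )
        self.a0 = np.asarray(a0_grid if a0_grid is not None else default_a0_grid(), float)
        self.a1 = np.asarray(a1_grid if a1_grid is not None else default_a1_grid(), float)
        if self.sigma_p.size == 0 or self.a0.size == 0 or self.a1.size == 0:
            raise ValueError("parameter grids must be nonempty")
        if np.any(self.sigma_p <= 0):
            raise ValueError("sigma_p grid must be strictly positive")
        self.epsilon = float(epsilon_deg)

        # sigma_b tensor, shape (n_a0, n_a1, n_ages); rectified per (a0, a1).
        raw = (
            self.a0[:, None, None]
            + self.a1[None, :, None] * self.ages[None, None, :]
        )
        sigma_b = rectify_sigma(raw, self.epsilon)
        sb2 = sigma_b * sigma_b
        sp2 = (self.sigma_p * self.sigma_p)[:, None, None, None]

        # Predicted-bias tensors per peaked policy: (n_sp, n_a0, n_a1, n_ages).
        self._bias: dict[str, np.ndarray] = {}
        for policy in self.policies:
            if policy == FLAT_ALL:
                continue
            centers = np.array(
                [
                    c if (c := prior_center_for_age(policy, a)) is not None else np.nan
                    for a in self.ages
                ]
            )
            flat_mask = np.isnan(centers)
            self._bias[policy] = _bias_given(centers, flat_mask, sp2, sb2[None])

    def fit(self, observed_biases) -> PriorModelFit:
        """Least-squares fit of observed mean biases per age group."""
        obs = np.asarray(observed_biases, dtype=float)
        if obs.shape != self.ages.shape:
            raise ValueError("observed biases must match the age groups")

        candidates: list[tuple] = []  # (rank, sigma_p, |a1|, a0, a1, policy, sse)
        best_sse = math.inf
        per_policy: dict[str, np.ndarray | float] = {}
        for rank, policy in enumerate(self.policies):
            if policy == FLAT_ALL:
                sse = float((obs * obs).sum())
            else:
                d = self._bias[policy] - obs
                sse = (d * d).sum(axis=-1)
            per_policy[policy] = sse
            m = sse if policy == FLAT_ALL else float(np.min(sse))
            best_sse = min(best_sse, m)

        atol = 1e-9 * max(1.0, best_sse)
        for rank, policy in enumerate(self.policies):
            sse = per_policy[policy]
            if policy == FLAT_ALL:
                if sse <= best_sse + atol:
                    # flat ignores all parameters; tie-break picks the
                    # smallest grid values
                    candidates.append(
                        (
                            rank,
                            float(self.sigma_p[0]),
                            float(np.min(np.abs(self.a1))),
                            float(self.a0[0]),
                            float(self.a1[int(np.argmin(np.abs(self.a1)))]),
                            policy,
                            float(sse),
                        )
                    )
                continue
            idx = np.flatnonzero(sse <= best_sse + atol)
            if idx.size == 0:
                continue
            isp, i0, i1 = np.unravel_index(idx, sse.shape)
            for k in range(idx.size):
                sp = float(self.sigma_p[isp[k]])
                a0 = float(self.a0[i0[k]])
                a1 = float(self.a1[i1[k]])
                candidates.append(
                    (rank, sp, abs(a1), a0, a1, policy, float(sse.flat[idx[k]]))
                )

        rank, sp, _, a0, a1, policy, sse = min(candidates)
        config = PriorConfig(policy, sp)
        params = LikelihoodAgeParams(a0, a1, self.epsilon)
        predicted = forward_predict(config, params, self.ages)
        sst = float(((obs - obs.mean()) ** 2).sum())
        if sst > 0:
            r2 = 1.0 - sse / sst
        else:
            r2 = 1.0 if sse <= atol else math.nan
        return PriorModelFit(
            config=config,
            params=params,
            sse=sse,
            r_squared=r2,
            predicted_bias_by_age={
                float(a): float(b) for a, b in zip(self.ages, predicted)
            },
        )


def fit_prior_model(
    age_groups,
    observed_biases,
    *,
    policies=POLICIES,
    sigma_p_grid=None,
    a0_grid=None,
    a1_grid=None,
    epsilon_deg: float = DEFAULT_EPSILON_DEG,
) -> PriorModelFit:
    """One-shot convenience wrapper around :class:`PriorModelSearch`."""
    search = PriorModelSearch(
        age_groups,
        policies=policies,
        sigma_p_grid=sigma_p_grid,
        a0_grid=a0_grid,
        a1_grid=a1_grid,
        epsilon_deg=epsilon_deg,
    )
    return search.fit(observed_biases)
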