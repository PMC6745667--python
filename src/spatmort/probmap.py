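"""Leave-one-out Gaussian-kernel survival probability maps.

Given a marked point pattern (dead = 0, alive = 1), each individual's
survival probability is estimated from the *other* individuals only:

    D1_i = sum_{j alive, j != i} g(d_ij, sigma)
    D0_i = sum_{j dead,  j != i} g(d_ij, sigma)
    p_i  = D1_i / (D1_i + D0_i)

with g the Gaussian kernel profile of inter-point distance,
g(d, sigma) = exp(-d^2 / (2 sigma^2)).  Only the ratio of the two
densities matters, so the kernel's normalization constant cancels and
the unnormalized profile is used.  Excluding the focal individual keeps
the map strictly smoother than the raw observations and prevents it
from memorizing its own outcome.

The raw probabilities are then clamped away from exactly 0 and 1
(defaults 0.0001 and 0.9999) and rescaled by a scalar shift on the
logit scale until the mode of the implied Poisson binomial distribution
equals the observed survivor count, so that the central mortality
estimate built from the map matches the one built from the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .poibin import pb_mode
from .spatstats import PointPattern

__all__ = [
    "KernelDensities",
    "SurvivalProbVector",
    "gaussian_kernel",
    "kernel_densities",
    "survival_probabilities",
    "clamp",
    "rescale_to_mode",
]

DEFAULT_CLAMP_LO = 0.0001
DEFAULT_CLAMP_HI = 0.9999

# Below this total density a point is effectively isolated from both
# status groups and the leave-one-out global rate is used instead.
_ISOLATION_EPS = 1e-300


@dataclass
class KernelDensities:
    """Per-individual kernel densities of surviving and dead neighbours."""

    d_surv: np.ndarray  # D(x_i = 1), survivor density at each point
    d_dead: np.ndarray  # D(x_i = 0), dead density at each point
    sigma: float
    status: np.ndarray  # focal statuses, needed for the isolation fallback


@dataclass
class SurvivalProbVector:
    """Clamped, optionally mode-rescaled survival probabilities.

    ``scale_param`` is the additive logit shift c applied during
    rescaling (0 means identity); ``mode`` is the Poisson binomial mode
    actually achieved, which equals the rescaling target except in the
    rare case where clamping makes the target unreachable.
    """

    p_hat: np.ndarray
    clamp_lo: float = DEFAULT_CLAMP_LO
    clamp_hi: float = DEFAULT_CLAMP_HI
    rescaled: bool = False
    scale_param: float = 0.0
    mode: int | None = None

    def __len__(self) -> int:
        return self.p_hat.size


def gaussian_kernel(d, sigma: float) -> np.ndarray:
    """Unnormalized Gaussian profile exp(-d^2 / (2 sigma^2))."""
    d = np.asarray(d, dtype=float)
    return np.exp(-0.5 * (d / sigma) ** 2)


def kernel_densities(pattern: PointPattern, sigma: float) -> KernelDensities:
    """Leave-one-out kernel densities of survivors and dead at each point.

    Direct O(n^2) pairwise summation; the focal individual j = i is
    always excluded from both sums.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if pattern.n < 2:
        raise ValueError("kernel densities require at least 2 points")
    d = np.hypot(
        pattern.x[:, None] - pattern.x[None, :],
        pattern.y[:, None] - pattern.y[None, :],
    )
    g = gaussian_kernel(d, sigma)
    np.fill_diagonal(g, 0.0)
    alive = (pattern.status == 1).astype(float)
    return KernelDensities(
        d_surv=g @ alive,
        d_dead=g @ (1.0 - alive),
        sigma=float(sigma),
        status=pattern.status.copy(),
    )


def survival_probabilities(dens: KernelDensities) -> np.ndarray:
    """Raw per-individual survival probabilities D1 / (D1 + D0).

    A point isolated from every neighbour (total density ~ 0, which is
    the sigma -> 0 limit) falls back to the leave-one-out global
    survivor fraction: the count of survivors among the other n - 1
    individuals divided by n - 1.
    """
    total = dens.d_surv + dens.d_dead
    n = dens.status.size
    k = int(dens.status.sum())
    fallback = (k - dens.status) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > _ISOLATION_EPS, dens.d_surv / np.maximum(total, _ISOLATION_EPS), fallback)
    return p


def clamp(p, lo: float = DEFAULT_CLAMP_LO, hi: float = DEFAULT_CLAMP_HI) -> np.ndarray:
    """Replace probabilities below ``lo`` by ``lo`` and above ``hi`` by ``hi``."""
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("clamp bounds must satisfy 0 < lo < hi < 1")
    return np.clip(np.asarray(p, dtype=float), lo, hi)


def _shifted(logits: np.ndarray, c: float, lo: float, hi: float) -> np.ndarray:
    return np.clip(expit(logits + c), lo, hi)


def rescale_to_mode(
    p,
    k_obs: int,
    lo: float = DEFAULT_CLAMP_LO,
    hi: float = DEFAULT_CLAMP_HI,
    c_bound: float = 50.0,
    tol: float = 1e-10,
) -> SurvivalProbVector:
    """Shift the map on the logit scale until its mode equals ``k_obs``.

    The one-parameter family p_i(c) = logistic(logit(p_i) + c) preserves
    the ordering and spatial structure of the map while moving the
    Poisson binomial mode monotonically with c; the shift is found by
    bisection on c in [-c_bound, c_bound] and the result re-clamped to
    [lo, hi].  If clamping makes the exact target unattainable, the
    closest achievable mode is returned with a warning.

    Raises
    ------
    ValueError
        If ``k_obs`` is 0 or n (degenerate species: no realistic
        probability map exists) or the input is not clamped.
    """
    p = np.asarray(p, dtype=float).ravel()
    n = p.size
    if not (0 < k_obs < n):
        raise ValueError(
            "observed survivor count must be strictly between 0 and n; "
            "species with k = 0 or k = n have no realistic probability map"
        )
    if np.any(p < lo) or np.any(p > hi):
        raise ValueError("probabilities must be clamped to [lo, hi] before rescaling")
    logits = logit(p)

    def mode_at(c: float) -> int:
        return pb_mode(_shifted(logits, c, lo, hi))

    if mode_at(0.0) == k_obs:
        return SurvivalProbVector(
            p_hat=_shifted(logits, 0.0, lo, hi),
            clamp_lo=lo, clamp_hi=hi, rescaled=True, scale_param=0.0, mode=k_obs,
        )

    c_lo, c_hi = -c_bound, c_bound
    m_lo, m_hi = mode_at(c_lo), mode_at(c_hi)
    if m_lo >= k_obs or m_hi < k_obs:
        # Target outside the reachable range (can only happen under clamping).
        c = c_lo if abs(m_lo - k_obs) <= abs(m_hi - k_obs) else c_hi
        achieved = mode_at(c)
        warnings.warn(
            f"mode {k_obs} unreachable under clamping; returning closest "
            f"achievable mode {achieved}",
            stacklevel=2,
        )
        return SurvivalProbVector(
            p_hat=_shifted(logits, c, lo, hi),
            clamp_lo=lo, clamp_hi=hi, rescaled=True, scale_param=c, mode=achieved,
        )

    # Bisection on the monotone predicate mode(c) >= k_obs.
    while c_hi - c_lo > tol:
        c_mid = 0.5 * (c_lo + c_hi)
        if mode_at(c_mid) >= k_obs:
            c_hi = c_mid
        else:
            c_lo = c_mid
    c = c_hi
    achieved = mode_at(c)
    if achieved != k_obs:
        # The mode jumped past the target at the transition point.
        warnings.warn(
            f"mode {k_obs} skipped at the rescaling transition; returning "
            f"closest achievable mode {achieved}",
            stacklevel=2,
        )
    return SurvivalProbVector(
        p_hat=_shifted(logits, c, lo, hi),
        clamp_lo=lo, clamp_hi=hi, rescaled=True, scale_param=float(c), mode=achieved,
    )
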