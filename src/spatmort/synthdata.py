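"""Synthetic data with known truth: coin mixes, coin tables, landscapes.

Three generators, all seed-deterministic:

* :func:`coin_mixes` — mixes of biased coins sharing the same expected
  number of heads but differing in heterogeneity, used to demonstrate
  that heterogeneity *narrows* the spread of the outcome.
* :func:`coin_table` — coins on a regular grid whose head-probabilities
  carry a chosen spatial structure (none / patchy / gradient), the
  minimal spatial setting in which the binomial and Poisson binomial
  predictions separate.
* :func:`species_landscape` — a synthetic tree species: uniformly
  placed individuals over a rectangular plot, survival probability
  constant within square habitat patches of a known scale, statuses
  drawn as independent Bernoulli outcomes.  The recorded truth (p_true,
  patch labels, true mortality rate) supports parameter-recovery and
  coverage experiments that real census data cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spatstats import PointPattern, Window

__all__ = [
    "TruthLandscape",
    "coin_mixes",
    "coin_table",
    "species_landscape",
    "true_lambda",
]

_MAX_STATUS_RETRIES = 10


@dataclass
class TruthLandscape:
    """A generated pattern together with its generative truth."""

    pattern: PointPattern
    p_true: np.ndarray  # per-individual true survival probability
    patch_map: np.ndarray  # per-individual regime/patch label
    params: dict = field(default_factory=dict)
    degenerate: bool = False  # all-dead/all-alive even after status redraws


def _two_point_mix(n: int, mean_p: float, p_low: float, p_high: float) -> np.ndarray:
    """n probabilities taking two values, with sum(p) = n * mean_p exactly.

    One coin takes an intermediate value when the counts cannot hit the
    target mean on their own.
    """
    if not 0.0 <= p_low <= p_high <= 1.0:
        raise ValueError("regime probabilities must satisfy 0 <= p_low <= p_high <= 1")
    if not p_low <= mean_p <= p_high:
        raise ValueError(
            f"mean {mean_p} is infeasible for a mix of p={p_low} and p={p_high}"
        )
    target = n * mean_p
    if p_high == p_low:
        return np.full(n, mean_p)
    n_high = int(math.floor((target - n * p_low) / (p_high - p_low)))
    p = np.full(n, p_low)
    p[:n_high] = p_high
    residual = target - p.sum()
    if residual > 1e-12:  # 0 <= residual < p_high - p_low by construction
        p[n_high] = p_low + residual
    return p


def coin_mixes(
    n: int = 300,
    mean_p: float = 0.45,
    regimes: tuple[tuple[float, float], ...] | None = None,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Coin mixes of increasing heterogeneity but identical mean.

    Each regime is a two-point mixture (p_low, p_high); all mixes are
    constrained to the same expected head count ``n * mean_p`` (135 for
    the defaults).  The default regimes are homogeneous, moderate and
    extreme (coins nearly two-tailed or two-headed), so the Poisson
    binomial variance sum(p(1-p)) strictly decreases across them.

    Parameters
    ----------
    seed
        When given, each mix is independently shuffled (composition is
        unchanged; only the ordering is randomized).
    """
    if n < 1:
        raise ValueError("need at least one coin")
    if regimes is None:
        regimes = (
            (mean_p, mean_p),
            (max(0.05, mean_p - 0.2), min(0.95, mean_p + 0.2)),
            (0.02, 0.98),
        )
    mixes = [_two_point_mix(n, mean_p, lo, hi) for lo, hi in regimes]
    if seed is not None:
        rng = np.random.default_rng(seed)
        mixes = [rng.permutation(m) for m in mixes]
    return mixes


def coin_table(
    nx: int = 20,
    ny: int = 15,
    structure: str = "patchy",
    seed: int = 0,
    p_levels: tuple[float, float] = (0.2, 0.8),
    p_const: float = 0.45,
    block: int = 5,
) -> TruthLandscape:
    """Coins on an ``nx`` x ``ny`` unit grid with a spatial p structure.

    structure:
      * ``"random"``  — constant p everywhere (no spatial pattern);
      * ``"patchy"``  — ``block`` x ``block`` squares alternate between
        the low and high ``p_levels`` (strong pattern);
      * ``"gradient"`` — p ramps smoothly across the x axis (weak
        pattern).

    Outcomes are independent Bernoulli draws from the true map.
    """
    rng = np.random.default_rng(seed)
    jx, jy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x = (jx + 0.5).ravel()
    y = (jy + 0.5).ravel()
    if structure == "random":
        p_true = np.full(x.size, p_const)
        labels = np.zeros(x.size, dtype=int)
    elif structure == "patchy":
        bx = (x // block).astype(int)
        by = (y // block).astype(int)
        labels = (bx + by) % 2
        p_true = np.asarray(p_levels, dtype=float)[labels]
    elif structure == "gradient":
        lo, hi = min(p_levels), max(p_levels)
        p_true = lo + (hi - lo) * x / nx
        labels = np.zeros(x.size, dtype=int)
    else:
        raise ValueError("structure must be one of random, patchy, gradient")
    status = (rng.random(x.size) < p_true).astype(int)
    pattern = PointPattern(x, y, status, Window(0.0, float(nx), 0.0, float(ny)))
    return TruthLandscape(
        pattern=pattern,
        p_true=p_true,
        patch_map=labels,
        params={"nx": nx, "ny": ny, "structure": structure, "seed": seed},
    )


def species_landscape(
    n: int,
    window: Window,
    patch_scale: float,
    p_regimes,
    frac_per_regime,
    seed: int = 0,
) -> TruthLandscape:
    """One synthetic species over a patchwork survival landscape.

    Individuals are placed uniformly in the window.  The window is tiled
    into square blocks of side ``patch_scale``; each block is assigned a
    survival regime by a seeded draw with probabilities
    ``frac_per_regime``, and every individual inherits its block's
    regime probability.  Statuses are independent Bernoulli(p_true)
    draws; a draw leaving no dead or no survivors is redrawn (statuses
    only) up to 10 times, after which the landscape is returned with
    ``degenerate=True``.
    """
    p_regimes = np.asarray(p_regimes, dtype=float).ravel()
    frac = np.asarray(frac_per_regime, dtype=float).ravel()
    if p_regimes.size != frac.size:
        raise ValueError("need one fraction per regime")
    if abs(frac.sum() - 1.0) > 1e-9:
        raise ValueError("regime fractions must sum to 1")
    if not 0 < patch_scale < window.shorter_side:
        raise ValueError("patch_scale must be positive and smaller than the window")
    rng = np.random.default_rng(seed)
    x = rng.uniform(window.xmin, window.xmax, n)
    y = rng.uniform(window.ymin, window.ymax, n)
    nbx = int(math.ceil(window.width / patch_scale))
    nby = int(math.ceil(window.height / patch_scale))
    block_labels = rng.choice(p_regimes.size, size=(nbx, nby), p=frac)
    bx = np.minimum(((x - window.xmin) // patch_scale).astype(int), nbx - 1)
    by = np.minimum(((y - window.ymin) // patch_scale).astype(int), nby - 1)
    labels = block_labels[bx, by]
    p_true = p_regimes[labels]
    degenerate = True
    status = np.zeros(n, dtype=int)
    for _ in range(_MAX_STATUS_RETRIES + 1):
        status = (rng.random(n) < p_true).astype(int)
        if 0 < status.sum() < n:
            degenerate = False
            break
    pattern = PointPattern(x, y, status, window)
    return TruthLandscape(
        pattern=pattern,
        p_true=p_true,
        patch_map=labels,
        params={
            "n": n,
            "patch_scale": patch_scale,
            "p_regimes": tuple(p_regimes),
            "frac_per_regime": tuple(frac),
            "seed": seed,
        },
        degenerate=degenerate,
    )


def true_lambda(landscape: TruthLandscape, dt: float) -> float:
    """True mortality rate implied by the expected survivor count."""
    n = landscape.p_true.size
    return (math.log(n) - math.log(landscape.p_true.sum())) / dt
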