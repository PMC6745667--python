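"""Second-order point-pattern statistics and bandwidth selection.

Implements Ripley's K function with the isotropic (Ripley) edge
correction for rectangular windows, Besag's variance-stabilizing
transform L(r) = sqrt(K(r) / pi), and the *relative aggregation* curves

    A_dead(r) = (L_dead(r) - L_all(r)) / L_all(r)
    A_surv(r) = (L_surv(r) - L_all(r)) / L_all(r)

which compare the spatial aggregation of the dead (or surviving) subset
of a marked pattern with the aggregation of the full pattern.  The full
pattern's L curve acts as the expectation for an unmarked individual, so
positive A means the subset is more clumped than the species as a whole.

The distance r* at which A_dead peaks is the scale at which mortality
has been concentrated over the census interval; the distance at which
A_surv is most negative is the scale at which survivors repel each other
(long-term thinning).  The shorter of the two is used as the species
bandwidth sigma for the kernel survival-probability map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Window",
    "PointPattern",
    "LProfile",
    "default_r_grid",
    "k_function",
    "l_function",
    "relative_aggregation",
    "l_profile",
    "select_sigma",
]

DEFAULT_R_GRID_SIZE = 513


@dataclass(frozen=True)
class Window:
    """Rectangular observation window, in the same units as coordinates."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("window must have positive width and height")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def shorter_side(self) -> float:
        return min(self.width, self.height)

    @property
    def diameter(self) -> float:
        return float(np.hypot(self.width, self.height))


@dataclass
class PointPattern:
    """Planar points with a binary survival status (0 = dead, 1 = alive)."""

    x: np.ndarray
    y: np.ndarray
    status: np.ndarray
    window: Window

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.status = np.asarray(self.status).ravel().astype(np.int64)
        if not (self.x.size == self.y.size == self.status.size):
            raise ValueError("x, y and status must have equal length")
        if self.x.size < 1:
            raise ValueError("pattern must contain at least one point")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status values must be 0 (dead) or 1 (alive)")
        w = self.window
        inside = (
            (self.x >= w.xmin)
            & (self.x <= w.xmax)
            & (self.y >= w.ymin)
            & (self.y <= w.ymax)
        )
        if not inside.all():
            raise ValueError("all points must lie inside the window")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def k(self) -> int:
        """Number of survivors."""
        return int(self.status.sum())

    def subset(self, mask) -> "PointPattern":
        mask = np.asarray(mask, dtype=bool)
        return PointPattern(self.x[mask], self.y[mask], self.status[mask], self.window)

    @property
    def dead(self) -> "PointPattern":
        return self.subset(self.status == 0)

    @property
    def surviving(self) -> "PointPattern":
        return self.subset(self.status == 1)


@dataclass
class LProfile:
    """L curves for the full pattern and its status subsets on a shared grid.

    A curves are NaN wherever they are undefined (L_all = 0, or a subset
    with fewer than two points).
    """

    r: np.ndarray
    L_all: np.ndarray
    L_dead: np.ndarray
    L_surv: np.ndarray
    A_dead: np.ndarray
    A_surv: np.ndarray


def default_r_grid(window: Window, num: int = DEFAULT_R_GRID_SIZE) -> np.ndarray:
    """Equally spaced distances from 0 to a quarter of the shorter side."""
    return np.linspace(0.0, window.shorter_side / 4.0, num)


def _ripley_weights(
    x: np.ndarray, y: np.ndarray, d: np.ndarray, window: Window
) -> np.ndarray:
    """Isotropic edge-correction weight for circles centred at (x, y).

    The weight is the reciprocal of the fraction of the circle of radius
    ``d`` centred at the focal point that lies inside the rectangular
    window.  Closed form valid while the circle can cross at most the
    two nearest (adjacent) edges, i.e. for d below half the shorter
    side.
    """
    dx = np.minimum(x - window.xmin, window.xmax - x)
    dy = np.minimum(y - window.ymin, window.ymax - y)
    with np.errstate(divide="ignore", invalid="ignore"):
        ax = np.arccos(np.clip(np.where(d > 0, dx / d, 1.0), 0.0, 1.0))
        ay = np.arccos(np.clip(np.where(d > 0, dy / d, 1.0), 0.0, 1.0))
    # Exterior arcs from the two near edges overlap when the near corner
    # falls inside the circle (ax + ay > pi/2).
    exterior = 2.0 * ax + 2.0 * ay - np.maximum(0.0, ax + ay - np.pi / 2.0)
    return 1.0 / (1.0 - exterior / (2.0 * np.pi))


def k_function(points: PointPattern, r: np.ndarray | None = None) -> np.ndarray:
    """Ripley's K with isotropic edge correction on a rectangular window.

    K_hat(r) = area / (m (m - 1)) * sum_{i != j} e_ij 1(d_ij <= r)

    where ``e_ij`` is the edge-correction weight of the circle through
    point j centred at point i.  Under complete spatial randomness
    E[K(r)] = pi r^2.

    Parameters
    ----------
    points
        The pattern (or status subset) whose K is wanted; needs >= 2
        points.
    r
        Increasing distance grid starting at 0; defaults to
        :func:`default_r_grid` of the pattern's window.
    """
    if points.n < 2:
        raise ValueError("K function requires at least 2 points")
    w = points.window
    if r is None:
        r = default_r_grid(w)
    r = np.asarray(r, dtype=float)
    if r.max() > w.shorter_side / 2.0:
        raise ValueError(
            "edge correction is only valid for r below half the shorter window side"
        )
    m = points.n
    d = np.hypot(
        points.x[:, None] - points.x[None, :], points.y[:, None] - points.y[None, :]
    )
    mask = d <= r[-1]
    np.fill_diagonal(mask, False)
    ii, _ = np.nonzero(mask)
    dd = d[mask]
    weights = _ripley_weights(points.x[ii], points.y[ii], dd, w)
    order = np.argsort(dd, kind="stable")
    cumw = np.concatenate(([0.0], np.cumsum(weights[order])))
    idx = np.searchsorted(dd[order], r, side="right")
    return w.area / (m * (m - 1)) * cumw[idx]


def l_function(K: np.ndarray) -> np.ndarray:
    """Besag's transform L(r) = sqrt(K(r) / pi); CSR gives L(r) = r."""
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise ValueError("K values must be non-negative")
    return np.sqrt(K / np.pi)


def relative_aggregation(L_sub: np.ndarray, L_all: np.ndarray) -> np.ndarray:
    """Relative aggregation A(r) = (L_sub - L_all) / L_all.

    NaN where L_all = 0 (the statistic is undefined there and such
    distances are excluded from extrema searches).
    """
    L_sub = np.asarray(L_sub, dtype=float)
    L_all = np.asarray(L_all, dtype=float)
    if L_sub.shape != L_all.shape:
        raise ValueError("L curves must share the same distance grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(L_all > 0, (L_sub - L_all) / L_all, np.nan)


def l_profile(pattern: PointPattern, r: np.ndarray | None = None) -> LProfile:
    """Compute L_all, L_dead, L_surv and both A curves for one species.

    Subsets with fewer than two points yield all-NaN L and A curves
    (their second-order structure is undefined) rather than an error, so
    that species with a single death or single survivor can still select
    a bandwidth from the other curve.
    """
    if r is None:
        r = default_r_grid(pattern.window)
    r = np.asarray(r, dtype=float)
    L_all = l_function(k_function(pattern, r))
    nan = np.full_like(r, np.nan)

    def sub_l(sub: PointPattern) -> np.ndarray:
        if sub.n < 2:
            return nan.copy()
        return l_function(k_function(sub, r))

    L_dead = sub_l(pattern.dead)
    L_surv = sub_l(pattern.surviving)
    A_dead = relative_aggregation(L_dead, L_all)
    A_surv = relative_aggregation(L_surv, L_all)
    return LProfile(r=r, L_all=L_all, L_dead=L_dead, L_surv=L_surv,
                    A_dead=A_dead, A_surv=A_surv)


def select_sigma(profile: LProfile) -> float:
    """Species-level kernel bandwidth from the relative-aggregation curves.

    sigma = min( argmax_r A_dead(r), argmin_r A_surv(r) ), searching only
    distances r > 0 where the curve is defined; ties break toward the
    smaller r.  The result is floored at half the grid spacing so a
    degenerate zero bandwidth can never be returned.
    """
    r = profile.r
    candidates = []
    searchable = r > 0
    vd = searchable & np.isfinite(profile.A_dead)
    if vd.any():
        a = np.where(vd, profile.A_dead, -np.inf)
        candidates.append(r[int(np.argmax(a))])
    vs = searchable & np.isfinite(profile.A_surv)
    if vs.any():
        a = np.where(vs, profile.A_surv, np.inf)
        candidates.append(r[int(np.argmin(a))])
    if not candidates:
        raise ValueError(
            "both relative-aggregation curves are undefined; "
            "cannot select a bandwidth for a degenerate species"
        )
    spacing = r[1] - r[0]
    return float(max(min(candidates), spacing / 2.0))
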