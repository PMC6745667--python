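"""Ripley/Besag statistics, relative aggregation and bandwidth selection."""

import numpy as np
import pytest

from spatmort.spatstats import (
    LProfile,
    PointPattern,
    Window,
    default_r_grid,
    k_function,
    l_function,
    l_profile,
    relative_aggregation,
    select_sigma,
)


def csr_pattern(n, window, rng, status=None):
    x = rng.uniform(window.xmin, window.xmax, n)
    y = rng.uniform(window.ymin, window.ymax, n)
    if status is None:
        status = np.ones(n, dtype=int)
    return PointPattern(x, y, status, window)


class TestPatternValidation:
    def test_rejects_points_outside_window(self):
        with pytest.raises(ValueError, match="inside the window"):
            PointPattern([0.5, 2.0], [0.5, 0.5], [1, 0], Window(0, 1, 0, 1))

    def test_rejects_non_binary_status(self):
        with pytest.raises(ValueError, match="status"):
            PointPattern([0.5], [0.5], [2], Window(0, 1, 0, 1))

    def test_window_must_have_positive_area(self):
        with pytest.raises(ValueError):
            Window(0, 0, 0, 1)


class TestKFunction:
    def test_two_isolated_points_hand_value(self):
        # Distance 3 in a huge window: edge weights are 1, so
        # K(r >= 3) = area * 2 / (2 * 1) = area.
        w = Window(0, 1000, 0, 1000)
        pat = PointPattern([500, 503], [500, 500], [1, 0], w)
        K = k_function(pat, np.array([0.0, 2.0, 4.0]))
        np.testing.assert_allclose(K, [0.0, 0.0, w.area], rtol=1e-12)

    def test_k_at_zero_is_zero(self, rng):
        pat = csr_pattern(50, Window(0, 10, 0, 10), rng)
        assert k_function(pat)[0] == 0.0

    def test_k_is_non_decreasing(self, rng):
        for _ in range(5):
            pat = csr_pattern(80, Window(0, 10, 0, 20), rng)
            assert (np.diff(k_function(pat)) >= 0).all()

    def test_needs_two_points(self):
        pat = PointPattern([1.0], [1.0], [1], Window(0, 10, 0, 10))
        with pytest.raises(ValueError, match="at least 2"):
            k_function(pat)

    def test_interior_pattern_matches_uncorrected_estimator(self, rng):
        # All points far from every edge: each correction weight is 1,
        # so K must equal the plain pair-counting estimator.
        w = Window(0, 100, 0, 100)
        x = rng.uniform(45, 55, 40)
        y = rng.uniform(45, 55, 40)
        pat = PointPattern(x, y, np.ones(40), w)
        r = np.linspace(0, 25, 51)
        d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
        np.fill_diagonal(d, np.inf)
        uncorrected = w.area / (40 * 39) * (d[None] <= r[:, None, None]).sum((1, 2))
        np.testing.assert_allclose(k_function(pat, r), uncorrected, rtol=1e-12)

    def test_csr_expectation_is_pi_r_squared(self, rng):
        # Mean of the edge-corrected estimator over CSR replicates.
        w = Window(0, 1, 0, 1)
        r = np.array([0.05, 0.125, 0.25])
        reps = 200
        Ks = np.array([k_function(csr_pattern(500, w, rng), r) for _ in range(reps)])
        se = Ks.std(axis=0, ddof=1) / np.sqrt(reps)
        assert (np.abs(Ks.mean(axis=0) - np.pi * r**2) < 4 * se).all()


class TestLFunction:
    def test_closed_forms(self):
        np.testing.assert_allclose(l_function([0.0, np.pi]), [0.0, 1.0])

    def test_rejects_negative_k(self):
        with pytest.raises(ValueError):
            l_function([-1.0])

    def test_csr_l_is_identity(self, rng):
        w = Window(0, 1, 0, 1)
        r = np.linspace(0, 0.25, 26)
        Ls = np.array(
            [l_function(k_function(csr_pattern(400, w, rng), r)) for _ in range(50)]
        )
        np.testing.assert_allclose(Ls.mean(axis=0)[1:], r[1:], atol=0.01)


class TestRelativeAggregation:
    def test_identical_curves_give_zero(self):
        L = np.array([0.0, 1.0, 2.0])
        A = relative_aggregation(L, L)
        assert np.isnan(A[0])  # L_all = 0 there
        np.testing.assert_allclose(A[1:], 0.0)

    def test_half_more_aggregated(self):
        np.testing.assert_allclose(
            relative_aggregation(np.array([1.5]), np.array([1.0])), [0.5]
        )

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError, match="grid"):
            relative_aggregation(np.zeros(3), np.zeros(4))

    def test_csr_statuses_fluctuate_around_zero(self, rng):
        # Random dead/alive labels on CSR points carry no spatial signal.
        w = Window(0, 1, 0, 1)
        mids = []
        for _ in range(100):
            status = rng.integers(0, 2, 200)
            pat = csr_pattern(200, w, rng, status=status)
            prof = l_profile(pat)
            mids.append(prof.A_dead[len(prof.r) // 2])
        mids = np.array(mids)
        se = mids.std(ddof=1) / np.sqrt(len(mids))
        assert abs(mids.mean()) < 3 * se


class TestSelectSigma:
    @staticmethod
    def profile_with(r, r_dead_peak, r_surv_trough):
        A_dead = -((r - r_dead_peak) ** 2)
        A_surv = (r - r_surv_trough) ** 2
        L = np.where(r > 0, r, 0.0)
        return LProfile(r=r, L_all=L, L_dead=L, L_surv=L,
                        A_dead=A_dead, A_surv=A_surv)

    def test_shortest_of_the_two_extrema_wins(self):
        r = np.linspace(0, 25, 513)
        prof = self.profile_with(r, r_dead_peak=10.0, r_surv_trough=15.0)
        assert select_sigma(prof) == pytest.approx(10.0, abs=r[1])
        prof = self.profile_with(r, r_dead_peak=18.0, r_surv_trough=6.0)
        assert select_sigma(prof) == pytest.approx(6.0, abs=r[1])

    def test_r_zero_excluded_and_sigma_floored(self):
        # Extrema exactly at r = 0 are excluded: the first positive grid
        # distance is chosen instead, and sigma can never fall below
        # half the grid spacing.
        r = np.linspace(0, 25, 513)
        prof = self.profile_with(r, r_dead_peak=0.0, r_surv_trough=0.0)
        sigma = select_sigma(prof)
        assert sigma == pytest.approx(r[1])
        assert sigma >= r[1] / 2

    def test_degenerate_species_error(self):
        r = np.linspace(0, 25, 513)
        nan = np.full_like(r, np.nan)
        prof = LProfile(r=r, L_all=r, L_dead=nan, L_surv=nan,
                        A_dead=nan, A_surv=nan)
        with pytest.raises(ValueError, match="degenerate"):
            select_sigma(prof)

    def test_dead_cluster_argmax_tracks_cluster_scale(self):
        # Deaths confined to one compact 3x3 cluster (spacing 4, diameter
        # ~11) among grid survivors: the dead-aggregation maximum falls
        # inside the cluster's internal scale band, far below the window
        # scale.
        gx, gy = np.meshgrid(np.arange(5.0, 100, 10), np.arange(5.0, 100, 10))
        dx, dy = np.meshgrid([46.3, 50.3, 54.3], [46.3, 50.3, 54.3])
        x = np.concatenate([gx.ravel(), dx.ravel()])
        y = np.concatenate([gy.ravel(), dy.ravel()])
        status = np.concatenate([np.ones(gx.size, int), np.zeros(9, int)])
        prof = l_profile(PointPattern(x, y, status, Window(0, 100, 0, 100)))
        valid = (prof.r > 0) & np.isfinite(prof.A_dead)
        r_peak = prof.r[np.argmax(np.where(valid, prof.A_dead, -np.inf))]
        assert 2.0 <= r_peak <= 12.0


def test_default_grid_follows_window(rng):
    r = default_r_grid(Window(0, 100, 0, 400))
    assert r.size == 513
    assert r[0] == 0.0
    assert r[-1] == pytest.approx(25.0)
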