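"""Colvar evaluation, PMF integration/stitching, ABF errors, blocking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import junctionmd as jm
from junctionmd.sampling import DEFAULT_WINDOWS
from junctionmd.synth import _helical_mean, _rigid_body_basis
from conftest import ar1_series


@pytest.fixture(scope="module")
def colvar_def():
    rng = np.random.default_rng(60)
    ref = _helical_mean(25)
    rigid = _rigid_body_basis(ref)
    v = rng.standard_normal(75)
    v -= rigid @ (rigid.T @ v)
    v /= np.linalg.norm(v)
    return jm.ColvarDefinition(ref, v)


class TestEvalColvar:
    def test_reference_maps_to_zero(self, colvar_def):
        assert jm.eval_colvar(colvar_def.reference, colvar_def) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_unit_displacement_along_mode(self, colvar_def):
        a = 3.7
        frame = colvar_def.reference + a * colvar_def.vector.reshape(-1, 3)
        assert jm.eval_colvar(frame, colvar_def) == pytest.approx(a, abs=1e-8)

    def test_rigid_motion_of_frame_gives_zero(self, colvar_def):
        rng = np.random.default_rng(61)
        Q = Rotation.random(random_state=rng).as_matrix()
        frame = colvar_def.reference @ Q.T + rng.normal(0, 10, 3)
        assert abs(jm.eval_colvar(frame, colvar_def)) < 1e-8

    def test_common_rigid_motion_invariance(self, colvar_def):
        rng = np.random.default_rng(62)
        a = -2.1
        frame = colvar_def.reference + a * colvar_def.vector.reshape(-1, 3)
        Q = Rotation.random(random_state=rng).as_matrix()
        t = rng.normal(0, 5, 3)
        moved = frame @ Q.T + t
        assert jm.eval_colvar(moved, colvar_def) == pytest.approx(a, abs=1e-6)

    def test_selection_mismatch(self, colvar_def):
        with pytest.raises(ValueError, match="atoms"):
            jm.eval_colvar(np.zeros((10, 3)), colvar_def)

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValueError, match="unit norm"):
            jm.ColvarDefinition(np.zeros((4, 3)), np.ones(12))


class TestIntegratePMF:
    def test_constant_force_linear_pmf(self):
        centers = np.linspace(0, 5, 15)
        w = jm.WindowForceData(
            (0, 5), centers, np.full(15, -2.0), np.zeros(15),
            np.full(15, 100.0), np.zeros(15), "w0",
        )
        pmf = jm.integrate_pmf([w])
        slope = np.polyfit(pmf.xi, pmf.A, 1)[0]
        assert slope == pytest.approx(2.0, rel=1e-9)
        assert pmf.A.min() == 0.0

    def test_harmonic_recovery(self):
        spec = jm.AbfForceSpec(force_sigma=0.0)
        pmf = jm.integrate_pmf(jm.gen_abf_forces(spec, seed=63))
        kappa = 2 * np.polyfit(pmf.xi, pmf.A, 2)[0]
        assert kappa == pytest.approx(1.0, rel=0.02)

    def test_stitching_matches_single_window(self):
        # two overlapping windows over the same harmonic forces must agree
        # with the single full window after gauge fixing
        kappa = 1.3

        def window(a, b, wid):
            c = np.linspace(a + (b - a) / 30, b - (b - a) / 30, 15)
            return jm.WindowForceData(
                (a, b), c, -kappa * c, np.zeros(15), np.full(15, 100.0),
                np.zeros(15), wid,
            )

        split = jm.integrate_pmf([window(-2, 1, "a"), window(0, 3, "b")])
        exact = 0.5 * kappa * split.xi**2
        exact -= exact.min()
        np.testing.assert_allclose(split.A, exact, atol=1e-6)

    def test_disconnected_coverage_names_gap(self):
        def window(a, b):
            c = np.linspace(a, b, 5)
            return jm.WindowForceData((a, b), c, -c, np.zeros(5),
                                      np.full(5, 10.0), np.zeros(5))

        with pytest.raises(ValueError, match="gap"):
            jm.integrate_pmf([window(0, 1), window(2, 3)])

    def test_empty_bin_interpolated_with_warning(self):
        c = np.linspace(0, 5, 15)
        k = np.full(15, 100.0)
        k[7] = 0.0
        w = jm.WindowForceData((0, 5), c, -c, np.zeros(15), k, np.zeros(15))
        with pytest.warns(UserWarning, match="empty bin"):
            jm.integrate_pmf([w])

    def test_convergence_with_bin_refinement(self):
        # quartic double well: integration error shrinks as bins refine
        a, b = 0.05, 2.0

        def pot(x):
            return a * (x**2 - b**2) ** 2

        def grad(x):
            return 4 * a * x * (x**2 - b**2)

        errs = []
        for bins in (8, 16, 32):
            spec = jm.AbfForceSpec(
                potential=pot, grad=grad, windows=((-3.0, 3.0),),
                bins_per_window=bins, force_sigma=0.0,
            )
            pmf = jm.integrate_pmf(jm.gen_abf_forces(spec, seed=0))
            exact = pot(pmf.xi)
            exact -= exact.min()
            errs.append(np.abs(pmf.A - exact).max())
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 0.05


class TestAbfError:
    def _window(self, sigma2, K, tau):
        c = np.linspace(0, 4, 15)
        return jm.WindowForceData(
            (0, 4), c, np.zeros(15), np.full(15, sigma2), np.full(15, K),
            np.full(15, tau),
        )

    def test_uncorrelated_limit(self):
        # tau = 0: bound reduces to (xi_b - xi_a) sigma / sqrt(K) with K
        # the per-bin force-evaluation count
        w = self._window(0.25, 100.0, 0.0)
        expected = 4.0 * 0.5 / np.sqrt(100.0)
        assert jm.abf_error(w) == pytest.approx(expected, rel=1e-12)

    def test_quadrupling_samples_halves_bound(self):
        b1 = jm.abf_error(self._window(0.25, 100.0, 1.0))
        b2 = jm.abf_error(self._window(0.25, 400.0, 1.0))
        assert b1 / b2 == pytest.approx(2.0, rel=1e-12)

    @given(
        sigma=st.floats(0.01, 2.0),
        tau=st.floats(0.0, 20.0),
        K=st.integers(10, 10000),
        span=st.floats(0.5, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, sigma, tau, K, span):
        c = np.linspace(0, span, 5)

        def bound(s, t, k, xb):
            w = jm.WindowForceData(
                (0, xb), c * xb / span, np.zeros(5), np.full(5, s**2),
                np.full(5, float(k)), np.full(5, t),
            )
            return jm.abf_error(w, (0, xb))

        b = bound(sigma, tau, K, span)
        assert bound(sigma * 1.5, tau, K, span) >= b
        assert bound(sigma, tau + 1, K, span) >= b
        assert bound(sigma, tau, K * 2, span) <= b
        assert bound(sigma, tau, K, span * 1.5) >= b

    def test_no_samples_rejected(self):
        w = self._window(0.25, 0.0, 0.0)
        with pytest.raises(ValueError, match="no force samples"):
            jm.abf_error(w)

    def test_bound_covers_empirical_error(self):
        # repeated noisy harmonic PMFs: the realized error at the far end
        # stays below the printed bound in >= 90% of replicates
        kappa, sigma, K = 1.0, 0.4, 400.0
        c = np.linspace(-2, 2, 15)
        hits = 0
        n_rep = 100
        rng = np.random.default_rng(64)
        for _ in range(n_rep):
            noise = rng.normal(0, sigma / np.sqrt(K), c.shape)
            w = jm.WindowForceData(
                (-2, 2), c, -kappa * c + noise, np.full(15, sigma**2),
                np.full(15, K), np.zeros(15),
            )
            pmf = jm.integrate_pmf([w])
            exact = 0.5 * kappa * pmf.xi**2
            exact -= exact.min()
            err = abs((pmf.A[-1] - pmf.A[0]) - (exact[-1] - exact[0]))
            if err <= jm.abf_error(w):
                hits += 1
        assert hits / n_rep >= 0.9


class TestBlocking:
    def test_white_noise_flat_se(self):
        rng = np.random.default_rng(65)
        res = jm.blocking_analysis(rng.normal(0, 1, 2**14), dt=1.0)
        assert res.plateau_found
        assert res.tau_c < 0.5
        assert res.se_plateau / res.se_naive < 1.2

    def test_ar1_integrated_time(self):
        rng = np.random.default_rng(66)
        phi = 0.9
        x = ar1_series(rng, phi, 100000)
        res = jm.blocking_analysis(x, dt=1.0)
        expected = phi / (1 - phi)  # = 9 samples
        assert res.tau_c == pytest.approx(expected, rel=0.25)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            jm.blocking_analysis(np.zeros(32))

    def test_minimum_sampling_rule_flags_bins(self):
        # the 5-ns floor: with 10 ps samples a bin needs >= 500 samples
        c = np.linspace(0, 4, 5)
        w = jm.WindowForceData(
            (0, 4), c, np.zeros(5), np.zeros(5),
            np.array([600.0, 499.0, 500.0, 100.0, 1200.0]), np.zeros(5), "w0",
        )
        flags = jm.minimum_sampling_flags([w], min_time=5000.0, dt=10.0)
        assert flags["undersampled"].tolist() == [False, True, False, True, False]

    def test_decorrelation_rule_end_to_end(self):
        # an AR(1) twist series with tau ~ 400 samples (4 ns at 10 ps) is
        # what motivates the 5 ns minimum; blocking must recover tau in
        # that regime so the rule can be applied
        rng = np.random.default_rng(67)
        phi = 400.0 / 401.0  # tau = phi/(1-phi) = 400 samples
        x = ar1_series(rng, phi, 2**17)
        res = jm.blocking_analysis(x, dt=10.0)  # ps units
        assert res.tau_c == pytest.approx(4000.0, rel=0.45)
        min_time = 5000.0
        assert res.tau_c < min_time  # the 5-ns floor exceeds the decorrelation time


class TestColvarCalibration:
    def test_affine_anchors(self):
        assert jm.colvar_to_jtwist(-5.0) == pytest.approx(-90.0)
        assert jm.colvar_to_jtwist(10.0) == pytest.approx(90.0)

    def test_default_windows_cover_range(self):
        lo = min(w[0] for w in DEFAULT_WINDOWS)
        hi = max(w[1] for w in DEFAULT_WINDOWS)
        assert (lo, hi) == (-5.0, 10.0)
        ws = sorted(DEFAULT_WINDOWS)
        assert all(b[0] < a[1] for a, b in zip(ws, ws[1:]))  # overlaps
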