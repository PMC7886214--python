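"""Viscous energy dissipation operator, series, TVED, peaks, ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from mitralflow import FlowSpec, FluidProps, VEDSeries, VelocityField
from mitralflow import synthetic
from mitralflow.energetics import (
    anova_recordings,
    detect_peaks,
    dissipation_density,
    tved,
    ved_instant,
    ved_series,
)


def grid_field(u, v, spacing=1e-3):
    rows, cols = u.shape
    return VelocityField(u=u, v=v, x=np.arange(cols) * spacing,
                         y=np.arange(rows) * spacing, spacing=spacing)


class TestVedInstant:
    def test_solid_rotation_dissipates_nothing(self, fluid):
        spec = FlowSpec(model="solid_rotation", params={"omega": 10.0},
                        grid_shape=(41, 41), grid_spacing=1e-3)
        f = synthetic.make_flow_field(spec)
        assert ved_instant(f, fluid) == pytest.approx(0.0, abs=1e-12)

    def test_pure_shear_closed_form(self, fluid):
        """For u = gamma*y the dissipation density is exactly mu*gamma^2,
        and linear fields are exact under central differences."""
        gamma = 5.0
        n, h = 41, 1e-3
        spec = FlowSpec(model="pure_shear", params={"gamma": gamma},
                        grid_shape=(n, n), grid_spacing=h)
        f = synthetic.make_flow_field(spec)
        area = (n - 1) ** 2 * h**2
        expected = fluid.dynamic_viscosity * gamma**2 * area
        assert ved_instant(f, fluid) == pytest.approx(expected, rel=1e-10)

    def test_galilean_invariance_example(self, fluid, rng):
        u = rng.standard_normal((15, 15))
        v = rng.standard_normal((15, 15))
        f0 = grid_field(u, v)
        f1 = grid_field(u + 0.7, v - 0.2)
        assert ved_instant(f1, fluid) == pytest.approx(
            ved_instant(f0, fluid), rel=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(cu=st.floats(-5, 5), cv=st.floats(-5, 5), seed=st.integers(0, 100))
    def test_galilean_invariance_property(self, cu, cv, seed):
        fl = FluidProps()
        r = np.random.default_rng(seed)
        u = r.standard_normal((9, 9))
        v = r.standard_normal((9, 9))
        base = ved_instant(grid_field(u, v), fl)
        shifted = ved_instant(grid_field(u + cu, v + cv), fl)
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_nonnegative_for_any_field(self, seed):
        r = np.random.default_rng(seed)
        f = grid_field(r.standard_normal((8, 8)), r.standard_normal((8, 8)))
        assert ved_instant(f, FluidProps()) >= 0.0

    def test_pair_sum_identity_on_random_fields(self, fluid, rng):
        """The ordered-pair sum over (i,j) of (du_i/dx_j + du_j/dx_i)^2
        equals 2(u_x^2 + v_y^2) + (u_y + v_x)^2 times 2, algebraically."""
        u = rng.standard_normal((12, 12))
        v = rng.standard_normal((12, 12))
        h = 1e-3
        f = grid_field(u, v, spacing=h)
        # independent route: explicit i,j sum from numpy gradients
        ux = np.gradient(u, h, axis=1, edge_order=2)
        uy = np.gradient(u, h, axis=0, edge_order=2)
        vx = np.gradient(v, h, axis=1, edge_order=2)
        vy = np.gradient(v, h, axis=0, edge_order=2)
        grads = {(0, 0): ux, (0, 1): uy, (1, 0): vx, (1, 1): vy}
        mu = fluid.dynamic_viscosity
        pair_sum = sum((grads[(i, j)] + grads[(j, i)]) ** 2
                       for i in (0, 1) for j in (0, 1))
        phi_pairs = 0.5 * mu * pair_sum
        phi_lib = dissipation_density(f, fluid)
        assert np.allclose(phi_pairs, phi_lib, rtol=1e-12, atol=0)

    def test_lamb_oseen_second_order_convergence(self, fluid):
        """Grid refinement converges to the analytic dissipation integral
        with observed order ~2 (central differences + trapezoid)."""
        circ, rc, L = 0.01, 5e-3, 0.02  # domain [-L, L]^2
        mu = fluid.dynamic_viscosity

        # dissipation density of an axisymmetric swirl u_t(r):
        #   Phi = mu * (du_t/dr - u_t/r)^2 = mu * (Gamma/2pi)^2 *
        #         (2 e^{-r^2/rc^2} / rc^2 - 2 (1 - e^{-r^2/rc^2}) / r^2)^2
        # quadrature over one quadrant (the density is even in x and y)
        def phi_xy(y, x):
            r2 = x * x + y * y
            if r2 < 1e-24:
                return 0.0
            e = np.exp(-r2 / rc**2)
            shear = 2.0 * e / rc**2 - 2.0 * (1.0 - e) / r2
            return mu * (circ / (2 * np.pi)) ** 2 * shear**2

        quad_val, _ = integrate.dblquad(phi_xy, 0, L, 0, L,
                                        epsabs=1e-14, epsrel=1e-10)
        exact = 4.0 * quad_val

        errs = []
        for n in (33, 65, 129):
            h = 2 * L / (n - 1)
            spec = FlowSpec(model="lamb_oseen",
                            params={"circulation": circ, "core_radius": rc,
                                    "center": (L, L)},
                            grid_shape=(n, n), grid_spacing=h)
            f = synthetic.make_flow_field(spec)
            errs.append(abs(ved_instant(f, fluid) - exact))
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(len(errs) - 1)]
        assert min(orders) > 1.6
        assert max(orders) < 2.8

    def test_too_small_grid_rejected(self, fluid):
        f = grid_field(np.zeros((2, 5)), np.zeros((2, 5)))
        with pytest.raises(ValueError):
            ved_instant(f, fluid)

    def test_all_masked_returns_zero_with_warning(self, fluid):
        f = grid_field(np.ones((5, 5)), np.ones((5, 5)))
        f.mask[:] = False
        with pytest.warns(UserWarning):
            assert ved_instant(f, fluid) == 0.0

    def test_masked_nodes_excluded_from_integral(self, fluid):
        gamma, n, h = 3.0, 21, 1e-3
        spec = FlowSpec(model="pure_shear", params={"gamma": gamma},
                        grid_shape=(n, n), grid_spacing=h)
        f = synthetic.make_flow_field(spec)
        full = ved_instant(f, fluid)
        f.u[5, 5] = 1e6  # corrupt one node, then mask it out
        f.mask[5, 5] = False
        masked = ved_instant(f, fluid)
        # masking removes the node and its stencils; result stays near the
        # uncorrupted value, far below the corrupted one
        assert masked < 1.5 * full


class TestVedSeries:
    def test_constant_field_gives_constant_series(self, fluid):
        spec = FlowSpec(model="pure_shear", params={"gamma": 2.0},
                        grid_shape=(9, 9), grid_spacing=1e-3)
        f = synthetic.make_flow_field(spec)
        fields = [f.copy() for _ in range(5)]
        s = ved_series(fields, fluid, np.linspace(0, 0.8, 5), cycle_period=1.0)
        assert np.allclose(s.ved, s.ved[0])

    def test_amplitude_scaling_is_quadratic(self, fluid):
        spec = FlowSpec(model="pure_shear", params={"gamma": 2.0},
                        grid_shape=(9, 9), grid_spacing=1e-3)
        f = synthetic.make_flow_field(spec)
        amps = np.array([0.5, 1.0, 2.0])
        fields = [VelocityField(a * f.u, a * f.v, f.x, f.y, f.spacing)
                  for a in amps]
        s = ved_series(fields, fluid, np.arange(3) * 0.1, cycle_period=0.3)
        assert np.allclose(s.ved / s.ved[1], amps**2)

    def test_ea_jet_series_has_two_maxima(self, fluid, jet_spec, rest_beat):
        fields = synthetic.make_flow_series(jet_spec, rest_beat, 128)
        t = np.arange(128) * rest_beat.period_s / 128
        s = ved_series(fields, fluid, t, cycle_period=rest_beat.period_s)
        ext = np.r_[s.ved[-1], s.ved, s.ved[0]]
        n_max = int(np.sum((ext[1:-1] > ext[:-2]) & (ext[1:-1] >= ext[2:])
                           & (ext[1:-1] > 1e-9 * s.ved.max())))
        assert n_max == 2

    def test_grid_mismatch_rejected(self, fluid):
        f1 = grid_field(np.zeros((5, 5)), np.zeros((5, 5)))
        f2 = grid_field(np.zeros((6, 6)), np.zeros((6, 6)))
        with pytest.raises(ValueError):
            ved_series([f1, f2], fluid, np.array([0.0, 0.1]), cycle_period=0.2)


class TestTved:
    def test_constant_series_integrates_exactly(self):
        t = np.linspace(0, 1, 251)
        s = VEDSeries(t=t, ved=np.ones_like(t), cycle_period=1.0)
        assert tved(s, duration=1.0) == pytest.approx(1.0, rel=1e-12)

    def test_linear_in_viscosity(self, jet_spec, rest_beat):
        fields = synthetic.make_flow_series(jet_spec, rest_beat, 64)
        t = np.arange(64) * rest_beat.period_s / 64
        s1 = ved_series(fields, FluidProps(dynamic_viscosity=0.0042), t,
                        cycle_period=rest_beat.period_s)
        s2 = ved_series(fields, FluidProps(dynamic_viscosity=0.0084), t,
                        cycle_period=rest_beat.period_s)
        assert tved(s2) == pytest.approx(2.0 * tved(s1), rel=1e-9)

    def test_periodic_tiling_matches_scaled_cycle_integral(self):
        """A one-cycle rest-period series whose modulation completes an
        integer number of periods inside the tiled remainder satisfies
        integral(0..1s) = (1/T) * cycle integral analytically."""
        T = 60.0 / 70.0  # rest cycle, s
        t = np.arange(0, T, T / 256)
        ved = 1.0 + 0.8 * np.sin(2 * np.pi * 7 * t / T) ** 2
        s = VEDSeries(t=t, ved=ved, cycle_period=T)
        cycle_integral = np.trapezoid(np.r_[ved, ved[0]], np.r_[t, T])
        assert tved(s, duration=1.0) == pytest.approx(
            cycle_integral / T, rel=0.005)

    def test_tiling_agrees_with_explicit_concatenation(self, fluid, jet_spec,
                                                       rest_beat):
        """Independent oracle: tile the series explicitly and integrate."""
        fields = synthetic.make_flow_series(jet_spec, rest_beat, 96)
        T = rest_beat.period_s
        t = np.arange(96) * T / 96
        s = ved_series(fields, fluid, t, cycle_period=T)
        t3 = np.concatenate([t, t + T, t + 2 * T])
        v3 = np.tile(s.ved, 3)
        grid = np.linspace(0, 1.0, 4001)
        explicit = np.trapezoid(np.interp(grid, t3, v3), grid)
        assert tved(s, duration=1.0) == pytest.approx(explicit, rel=0.005)

    def test_duration_must_be_positive(self):
        t = np.linspace(0, 1, 11)
        s = VEDSeries(t=t, ved=np.ones_like(t), cycle_period=1.0)
        with pytest.raises(ValueError):
            tved(s, duration=0.0)

    def test_partial_cycle_rejected(self):
        t = np.linspace(0, 0.4, 11)
        s = VEDSeries(t=t, ved=np.ones_like(t), cycle_period=1.0)
        with pytest.raises(ValueError):
            tved(s)


class TestDetectPeaks:
    def _two_lobe_series(self, v1=0.3, v2=0.2):
        T = 1.0
        t = np.linspace(0, T, 400, endpoint=False)
        ved = (v1 * np.exp(-((t - 0.05) ** 2) / 2e-4)
               + v2 * np.exp(-((t - 0.55) ** 2) / 2e-4))
        return VEDSeries(t=t, ved=ved, cycle_period=T)

    def test_reports_lobe_maxima_and_times(self):
        s = self._two_lobe_series(0.3, 0.2)
        pk = detect_peaks(s)
        assert pk.first_peak_value == pytest.approx(0.3, rel=1e-3)
        assert pk.first_peak_time == pytest.approx(0.05, abs=0.01)
        assert pk.second_peak_value == pytest.approx(0.2, rel=1e-3)
        assert pk.second_peak_time == pytest.approx(0.55, abs=0.01)

    def test_swapped_windows_swap_peaks(self):
        s = self._two_lobe_series(0.3, 0.2)
        pk = detect_peaks(s, first_window=(0.45, 0.65), second_window=(0.0, 0.15))
        assert pk.first_peak_value == pytest.approx(0.2, rel=1e-3)
        assert pk.second_peak_value == pytest.approx(0.3, rel=1e-3)

    def test_monotone_window_warns_and_returns_endpoint(self):
        t = np.linspace(0, 1, 101, endpoint=False)
        s = VEDSeries(t=t, ved=t + 0.01, cycle_period=1.0)
        with pytest.warns(UserWarning):
            pk = detect_peaks(s)
        assert pk.first_peak_time == pytest.approx(0.15, abs=0.02)

    def test_empty_window_rejected(self):
        t = np.linspace(0.2, 1.0, 81)
        s = VEDSeries(t=t, ved=np.ones_like(t), cycle_period=2.0)
        with pytest.raises(ValueError):
            detect_peaks(s, first_window=(0.9, 0.95))


class TestAnova:
    def _series(self, values):
        t = np.arange(len(values), dtype=float)
        return VEDSeries(t=t, ved=np.asarray(values, float),
                         cycle_period=float(len(values)))

    def test_identical_recordings_give_zero_f(self):
        recs = [self._series([1.0, 2.0, 3.0])] * 5
        f, p = anova_recordings(recs)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        """Groups {1,2,3} and {2,3,4}: SSB=1.5, SSW=4, df=(1,4) -> F=1.5."""
        f, p = anova_recordings([self._series([1, 2, 3]),
                                 self._series([2, 3, 4])])
        assert f == pytest.approx(1.5, rel=1e-12)

    def test_permutation_within_groups_invariant(self):
        f1, _ = anova_recordings([self._series([1, 2, 3]),
                                  self._series([2, 3, 4])])
        f2, _ = anova_recordings([self._series([3, 1, 2]),
                                  self._series([4, 2, 3])])
        assert f1 == pytest.approx(f2)

    def test_single_recording_rejected(self):
        with pytest.raises(ValueError):
            anova_recordings([self._series([1, 2, 3])])
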