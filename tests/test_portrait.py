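"""Tests for mass-balance portrait reconstruction."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

import cortexflux as cf
from cortexflux.errors import (
    DomainError,
    EmptyFieldError,
    EmptySliceError,
    NoNullclineError,
)
from cortexflux.model import DEFAULT_PARAMS as P
from cortexflux.model import DEFAULT_VOLUME as V
from cortexflux.portrait import (
    conditional_rate_slices,
    growth_vs_stoichiometry,
    intensivity_slopes,
    occupancy_contours,
    phi_V_field,
    preferred_concentration_pair,
    volume_nullcline_phi,
    zero_crossing_stoichiometry,
)
from cortexflux.volume import VolumeModel


def _track(t, w, a):
    return pd.DataFrame(
        {
            "condition": "x", "oocyte_id": "o", "condensate_id": "c0",
            "t": t, "w_iu": w, "a_iu": a, "area_um2": np.nan,
        }
    )


def _exact_rate_points(params=P, s_grid=None, n_mag=8):
    """Points sampled on rays of fixed stoichiometry with exact growth-law
    rates — the analytic reference for portrait statistics."""
    if s_grid is None:
        s_grid = np.linspace(0.05, 0.97, 60)
    rows = []
    for k, s in enumerate(s_grid):
        mags = np.geomspace(2.0, 500.0, n_mag)
        A, W = mags * s, mags * (1.0 - s)
        dW, dA = cf.growth_rates(A, W, params, V)
        rows.append(
            pd.DataFrame(
                {
                    "condition": "exact", "oocyte_id": "o",
                    "condensate_id": f"r{k:03d}", "t": np.arange(n_mag) * 0.5,
                    "w_iu": W, "a_iu": A, "dw": dW, "da": dA,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestDerivatives:
    def test_linear_ramp_exact(self):
        t = np.arange(10) * 0.5
        out = cf.estimate_derivatives(_track(t, 2.0 * t, 5.0 + 0.0 * t))
        assert np.allclose(out["dw"], 2.0, atol=1e-12)
        assert np.allclose(out["da"], 0.0, atol=1e-12)

    def test_quadratic_no_bias(self):
        t = np.arange(12) * 0.5
        out = cf.estimate_derivatives(_track(t, 1.0 + 0.0 * t, t**2))
        assert np.allclose(out["da"], 2.0 * out["t"], atol=1e-12)

    def test_endpoints_dropped(self):
        t = np.arange(5) * 0.5
        out = cf.estimate_derivatives(_track(t, t, t))
        assert len(out) == 3

    def test_irregular_spacing_rejected(self):
        t = np.array([0.0, 0.5, 1.2, 1.5])
        with pytest.raises(DomainError):
            cf.estimate_derivatives(_track(t, t, t))

    def test_short_track_rejected(self):
        t = np.array([0.0, 0.5])
        with pytest.raises(DomainError):
            cf.estimate_derivatives(_track(t, t, t))

    @staticmethod
    def _orbit_error(dt):
        orbit = cf.integrate_orbit(P, V, (1.0, 5.0), 40.0, dt)
        out = cf.estimate_derivatives(_track(orbit.t, orbit.W, orbit.A))
        dW_true, _ = cf.growth_rates(out["a_iu"].to_numpy(), out["w_iu"].to_numpy(), P, V)
        scale = np.maximum(np.abs(dW_true), 1e-2)
        return np.max(np.abs(out["dw"].to_numpy() - dW_true) / scale)

    def test_second_order_convergence_on_deterministic_orbit(self):
        errs = {dt: self._orbit_error(dt) for dt in (0.25, 0.5, 1.0)}
        assert errs[0.5] < 0.01  # sub-percent at the reference frame interval
        assert errs[0.25] < errs[0.5] < errs[1.0]
        # halving dt cuts the error by roughly 4 (second order)
        assert errs[0.5] / errs[0.25] > 2.5

    def test_savgol_option_on_smooth_data(self):
        orbit = cf.integrate_orbit(P, V, (1.0, 5.0), 30.0, 0.5)
        out = cf.estimate_derivatives(_track(orbit.t, orbit.W, orbit.A), smooth=True)
        dW_true, _ = cf.growth_rates(out["a_iu"].to_numpy(), out["w_iu"].to_numpy(), P, V)
        assert np.corrcoef(out["dw"], dW_true)[0, 1] > 0.999


class TestBinnedField:
    def test_single_repeated_point(self):
        pts = pd.DataFrame(
            {
                "a_iu": np.full(100, 50.0), "w_iu": np.full(100, 10.0),
                "dw": np.full(100, 1.5), "da": np.full(100, -2.5),
            }
        )
        fld = cf.bin_vector_field(pts, n_bins=4, min_count=20)
        occ = fld.count > 0
        assert occ.sum() == 1
        assert fld.mean_dW[occ][0] == pytest.approx(1.5)
        assert fld.mean_dA[occ][0] == pytest.approx(-2.5)
        assert fld.n_points == 100

    def test_permutation_invariance(self, bounded_points):
        sub = bounded_points.head(20000)
        f1 = cf.bin_vector_field(sub)
        f2 = cf.bin_vector_field(sub.sample(frac=1.0, random_state=3))
        assert np.array_equal(f1.count, f2.count)
        assert np.allclose(f1.mean_dW, f2.mean_dW, equal_nan=True)

    def test_all_bins_under_min_count(self):
        pts = pd.DataFrame(
            {"a_iu": [1.0, 2.0], "w_iu": [1.0, 2.0], "dw": [0.1, 0.1], "da": [0.1, 0.1]}
        )
        with pytest.raises(EmptyFieldError):
            cf.bin_vector_field(pts, n_bins=4, min_count=20)

    def test_three_regime_signs(self, bounded_points):
        """Above the WSP-1 nullcline ray condensates grow in WSP-1; between
        the rays they lose WSP-1 while still gaining F-actin."""
        fld = cf.bin_vector_field(bounded_points)
        s_W, s_A = cf.nullcline_stoichiometries(P, V)
        AA, WW = np.meshgrid(fld.A_centres, fld.W_centres, indexing="ij")
        s_bin = AA / (AA + WW)
        ok = ~fld.masked & (fld.count > 200)
        grow = ok & (s_bin < s_W - 0.05)
        # keep clear of the F-actin nullcline, where the true dA signal
        # passes through zero and bin signs are pure noise
        trans = ok & (s_bin > s_W + 0.01) & (s_bin < s_A - 0.02)
        assert grow.sum() > 10 and trans.sum() > 3
        assert np.mean(fld.mean_dW[grow] > 0) > 0.9
        assert np.mean(fld.mean_dW[trans] < 0) > 0.8
        assert np.mean(fld.mean_dA[trans] > 0) > 0.8


class TestNullclineExtraction:
    def test_recovery_from_bounded_ensemble(self, bounded_points):
        fld = cf.bin_vector_field(bounded_points)
        ncW = cf.extract_nullcline(fld, "W", n_boot=50, rng_seed=1)
        ncA = cf.extract_nullcline(fld, "A", n_boot=50, rng_seed=1)
        s_W, s_A = cf.nullcline_stoichiometries(P, V)
        assert abs(ncW.fitted_stoichiometry - s_W) < 0.02
        assert abs(ncA.fitted_stoichiometry - s_A) < 0.02
        assert ncW.stoichiometry_se >= 0

    def test_exact_field_recovery(self):
        nodes = np.geomspace(1.0, 1000.0, 60)
        fld = cf.predict_flux_field(P, V, nodes, nodes)
        s_W, s_A = cf.nullcline_stoichiometries(P, V)
        got_W = cf.extract_nullcline(fld, "W", n_boot=0).fitted_stoichiometry
        got_A = cf.extract_nullcline(fld, "A", n_boot=0).fitted_stoichiometry
        assert abs(got_W - s_W) < 1e-3
        assert abs(got_A - s_A) < 1e-3

    def test_unbounded_ensemble_has_no_w_nullcline(self):
        cfg = cf.GeneratorConfig(params=cf.rnai_preset("strong"), rng_seed=9)
        table, _ = cf.generate_ensemble(cfg, n_condensates=300)
        fld = cf.bin_vector_field(cf.derivatives_table(table))
        with pytest.raises(NoNullclineError):
            cf.extract_nullcline(fld, "W", n_boot=0)

    def test_unknown_component(self, bounded_points):
        fld = cf.bin_vector_field(bounded_points.head(30000))
        with pytest.raises(DomainError):
            cf.extract_nullcline(fld, "V")


class TestGrowthVsStoichiometry:
    def test_crossing_order_bounded(self, bounded_points):
        curve = growth_vs_stoichiometry(bounded_points)
        z_W = zero_crossing_stoichiometry(curve, "mean_dw")
        z_A = zero_crossing_stoichiometry(curve, "mean_da")
        assert z_W < z_A
        assert z_W == pytest.approx(0.85, abs=0.03)
        assert z_A == pytest.approx(0.90, abs=0.03)

    def test_exact_ray_samples_reproduce_analytic_rates(self):
        pts = _exact_rate_points()
        curve = growth_vs_stoichiometry(pts, n_bins=60, min_count=5)
        for _, row in curve.iterrows():
            s = row["s_centre"]
            dW, dA = cf.growth_rates(100 * s, 100 * (1 - s), P, V)
            # bin means mix magnitudes on the same ray; compare sign and scale
            assert np.sign(row["mean_dw"]) == np.sign(dW) or abs(dW) < 1e-3

    def test_theory_rates_swap_crossing_order_when_unbounded(self):
        pts = _exact_rate_points(params=cf.rnai_preset("strong"))
        curve = growth_vs_stoichiometry(pts, n_bins=60, min_count=5)
        z_W = zero_crossing_stoichiometry(curve, "mean_dw")
        z_A = zero_crossing_stoichiometry(curve, "mean_da")
        assert z_A < z_W  # nullclines switched


class TestOccupancyContours:
    def test_gaussian_cloud_calibration_and_nesting(self):
        rng = np.random.default_rng(0)
        pts = pd.DataFrame(
            {"c_a": rng.normal(0, 1, 15000), "c_w": rng.normal(5, 2, 15000)}
        )
        c68, c25 = occupancy_contours(pts, levels=(0.68, 0.25))
        assert c68.enclosed_fraction == pytest.approx(0.68, abs=0.02)
        assert c25.enclosed_fraction == pytest.approx(0.25, abs=0.02)
        # the 25% highest-density region is strictly inside the 68% region
        assert c25.threshold > c68.threshold

    def test_degenerate_cloud_rejected(self):
        pts = pd.DataFrame({"c_a": np.ones(200), "c_w": np.ones(200)})
        with pytest.raises(DomainError):
            occupancy_contours(pts)

    def test_ensemble_contour_centroid_on_density_line(self, bounded_table):
        vm = VolumeModel(coefficients=V)
        conc = cf.concentrations(bounded_table, vm, "relation")
        c68, _ = occupancy_contours(conc, levels=(0.68, 0.25))
        resid = (
            V.v_A * c68.centroid[0] + V.v_W * c68.centroid[1] - 1.0
        )
        assert abs(resid) < 0.02  # within histogram bin width of the line


class TestPreferredPair:
    def test_point_mass_returns_the_pair(self):
        pts = pd.DataFrame({"c_a": np.full(200, 3.0e6), "c_w": np.full(200, 1.0e6)})
        pair = preferred_concentration_pair(pts, n_boot=0)
        assert pair.c_A == 3.0e6 and pair.c_W == 1.0e6

    def test_pair_at_density_line_dominant_ray_intersection(self, bounded_table):
        vm = VolumeModel(coefficients=V)
        conc = cf.concentrations(bounded_table, vm, "relation")
        pair = preferred_concentration_pair(conc, n_boot=0)
        _, s_star = cf.fixed_point_phi(P, V)
        resid = V.v_A * pair.c_A + V.v_W * pair.c_W - 1.0
        s_pair = pair.c_A / (pair.c_A + pair.c_W)
        assert abs(resid) < 0.02
        assert abs(s_pair - s_star) < 0.01

    def test_rnai_shifts_along_density_line(self, bounded_table, mild_table, moderate_table):
        """Knockdown shifts the maintained pair toward higher WSP-1 and
        lower F-actin concentration, along the constant-density line."""
        vm = VolumeModel(coefficients=V)
        pairs = {}
        for name, tbl in (
            ("control", bounded_table), ("mild", mild_table), ("moderate", moderate_table)
        ):
            conc = cf.concentrations(tbl, vm, "relation")
            pairs[name] = preferred_concentration_pair(conc, n_boot=0)
        for name in ("mild", "moderate"):
            assert pairs[name].c_A < pairs["control"].c_A
            assert pairs[name].c_W > pairs["control"].c_W
        # moderate shifts further than mild
        assert pairs["moderate"].c_A < pairs["mild"].c_A


class TestPhiVPlane:
    def test_noise_free_volume_nullcline_matches_root_finder(self, clean_points):
        vm = VolumeModel(coefficients=V)
        fld = phi_V_field(clean_points, vm)
        got = volume_nullcline_phi(fld)

        def rel_volume_rate(phi):
            s = cf.phi_to_stoichiometry(phi, V)
            A, W = 100 * s, 100 * (1 - s)
            dW, dA = cf.growth_rates(A, W, P, V)
            return (V.v_A * dA + V.v_W * dW) / (V.v_A * A + V.v_W * W)

        phi_oracle = brentq(rel_volume_rate, 0.6, 0.95, xtol=1e-12)
        assert phi_oracle == pytest.approx(0.8542, abs=1e-4)
        bin_width = np.diff(fld.phi_centres).mean()
        assert abs(got - phi_oracle) < bin_width

    def test_intensive_dynamics_no_volume_trend(self, bounded_points):
        """The composition rate dphi/dt does not depend on condensate
        volume: any residual V-trend is a small fraction of the phi-driven
        dynamic range, and most phi columns are statistically flat."""
        vm = VolumeModel(coefficients=V)
        fld = phi_V_field(bounded_points, vm)
        sl = intensivity_slopes(fld)
        ok = ~fld.masked
        dyn_range = np.ptp(fld.mean_dphi[ok])
        v_span = np.log(fld.V_centres.max() / fld.V_centres.min())
        effect = np.average(
            np.abs(sl["slope"]) * v_span, weights=sl["n_bins"]
        )
        assert effect < 0.10 * dyn_range
        z = (sl["slope"] / sl["slope_se"]).abs()
        assert (z < 2).mean() > 0.6

    def test_low_phi_limit_volume_rate_is_k_r(self):
        # condensates of almost pure WSP-1 grow in volume at rate k_r
        s = 1e-6
        A, W = 100 * s, 100 * (1 - s)
        dW, dA = cf.growth_rates(A, W, P, V)
        relV = (V.v_A * dA + V.v_W * dW) / (V.v_A * A + V.v_W * W)
        assert relV == pytest.approx(P.k_r, rel=1e-3)


class TestSlices:
    def test_exact_field_slice_matches_growth_rates(self):
        nodes = np.geomspace(1.0, 1000.0, 30)
        fld = cf.predict_flux_field(P, V, nodes, nodes)
        a0 = float(nodes[12])
        sl = conditional_rate_slices(fld, "A", a0)
        dW, _ = cf.growth_rates(a0, sl["centre"].to_numpy(), P, V)
        assert np.allclose(sl["mean_dw"], dW, rtol=1e-12)

    def test_dw_increases_with_w_below_crossing(self, bounded_points):
        fld = cf.bin_vector_field(bounded_points)
        a0 = float(np.median(bounded_points["a_iu"]))
        sl = conditional_rate_slices(fld, "A", a0)
        # in the growth regime (large W at fixed A) dW grows with W
        top = sl.nlargest(4, "centre").sort_values("centre")
        assert top["mean_dw"].is_monotonic_increasing or (
            top["mean_dw"].iloc[-1] > top["mean_dw"].iloc[0]
        )

    def test_out_of_range_slice_rejected(self, bounded_points):
        fld = cf.bin_vector_field(bounded_points.head(30000))
        with pytest.raises(EmptySliceError):
            conditional_rate_slices(fld, "A", 1e9)
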