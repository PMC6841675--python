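"""Radial profiling, central-window statistics, gating, normalization and
kernel regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from samquant.errors import DegenerateNormalizationError, ValidationError
from samquant.geometry import Axis, estimate_center
from samquant.radial import (
    ProfileConfig,
    RadialProfile,
    SurfaceGrid,
    center_and_align,
    central_window_test,
    central_zone_timecourse,
    cross_section_profiles,
    gate_stem_cells,
    kernel_profile,
    minmax_normalize,
    threshold_distance,
)


def radial_grid(func, extent=40.0, px=0.5):
    """Grid of a radially symmetric intensity field I(x, y) = func(r)."""
    n = int(2 * extent / px) + 1
    xs = -extent + np.arange(n) * px
    gx, gy = np.meshgrid(xs, xs)
    return SurfaceGrid(data=func(np.hypot(gx, gy)), pixel_size=px, origin=(-extent, -extent))


def make_profile(distances, values, px=1.0):
    vals = np.asarray(values, float)
    return RadialProfile(
        distances=np.asarray(distances, float),
        mean_intensity=vals,
        per_section=vals[None, :],
        pixel_size=px,
    )


class TestCrossSections:
    def test_constant_grid_gives_flat_profile(self):
        grid = radial_grid(lambda r: np.full_like(r, 7.0))
        p = cross_section_profiles(grid, np.array([0.0, 0.0]))
        inner = p.distances <= 35  # beyond that some sections exit the grid corner
        assert np.allclose(p.mean_intensity[inner], 7.0, atol=1e-9)
        assert np.nanmax(np.abs(p.per_section - 7.0)) < 1e-9

    def test_symmetric_grid_sections_agree(self):
        # wide Gaussian on fine pixels: bilinear interpolation error < 1e-6 of scale
        grid = radial_grid(lambda r: 100.0 * np.exp(-(r**2) / (2 * 100.0**2)), px=0.1)
        p = cross_section_profiles(grid, np.array([0.0, 0.0]))
        inner = p.distances <= 35
        spread = np.nanmax(p.per_section[:, inner], axis=0) - np.nanmin(
            p.per_section[:, inner], axis=0
        )
        assert np.max(spread) < 1e-6 * 100.0
        expected = 100.0 * np.exp(-(p.distances[inner] ** 2) / (2 * 100.0**2))
        assert np.allclose(p.mean_intensity[inner], expected, atol=1e-3)

    def test_wedge_mean_matches_pixel_oracle(self):
        base = 10.0
        px = 0.5

        def field(gx, gy):
            # doubled wedge offset so no section ray lies on its boundary
            az = (np.degrees(np.arctan2(gy, gx)) - 0.9) % 360.0
            return np.where(az < 36.0, 2 * base, base)

        n = int(2 * 40 / px) + 1
        xs = -40 + np.arange(n) * px
        gx, gy = np.meshgrid(xs, xs)
        grid = SurfaceGrid(data=field(gx, gy), pixel_size=px, origin=(-40, -40))
        p = cross_section_profiles(grid, np.array([0.0, 0.0]))
        mid = (p.distances > 10) & (p.distances < 30)
        # 36/360 of the (section, side) rays hit the doubled wedge
        assert np.allclose(p.mean_intensity[mid], base * 1.1, atol=0.1)

        # independent pixel-space oracle: manual bilinear sampling of the
        # same rays, averaged the same way
        def bilinear(data, row, col):
            r0, c0 = int(np.floor(row)), int(np.floor(col))
            fr, fc = row - r0, col - c0
            return (
                data[r0, c0] * (1 - fr) * (1 - fc)
                + data[r0 + 1, c0] * fr * (1 - fc)
                + data[r0, c0 + 1] * (1 - fr) * fc
                + data[r0 + 1, c0 + 1] * fr * fc
            )

        center_px = (40 / px, 40 / px)
        for j in np.flatnonzero(mid)[:5]:
            d_px = p.distances[j] / px
            samples = []
            for k in range(100):
                ang = np.radians(k * 3.6)
                for sign in (1, -1):
                    col = center_px[0] + sign * d_px * np.cos(ang)
                    row = center_px[1] + sign * d_px * np.sin(ang)
                    samples.append(bilinear(grid.data, row, col))
            assert p.mean_intensity[j] == pytest.approx(np.mean(samples), rel=1e-9)

    def test_center_outside_grid_rejected(self):
        grid = radial_grid(lambda r: np.ones_like(r), extent=10)
        with pytest.raises(ValidationError):
            cross_section_profiles(grid, np.array([50.0, 0.0]))


class TestAlign:
    def test_single_profile_unchanged(self):
        p = make_profile([0, 1, 2], [5, 6, 7])
        (out,) = center_and_align([p])
        assert np.array_equal(out.distances, p.distances)
        assert np.array_equal(out.mean_intensity, p.mean_intensity)

    def test_padding_with_missing_markers(self):
        p30 = make_profile(np.arange(30), np.ones(30))
        p40 = make_profile(np.arange(40), np.ones(40))
        a30, a40 = center_and_align([p30, p40])
        assert len(a30.distances) == 40
        assert np.isnan(a30.mean_intensity[30:]).all()
        assert not np.isnan(a40.mean_intensity).any()

    def test_mixed_pixel_sizes_rejected(self):
        with pytest.raises(ValidationError):
            center_and_align(
                [make_profile([0, 1], [1, 1], px=1.0), make_profile([0, 0.5], [1, 1], px=0.5)]
            )


class TestCentralWindow:
    def test_identical_groups_null(self):
        g = [make_profile(np.arange(20), np.full(20, 5.0)) for _ in range(3)]
        res = central_window_test(g, g)
        assert res.t == 0.0 and res.p == 1.0

    def test_textbook_means(self):
        def flat(v):
            return make_profile(np.arange(20), np.full(20, float(v)))

        res = central_window_test([flat(1), flat(2), flat(3)], [flat(4), flat(5), flat(6)])
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.p == pytest.approx(0.0214, abs=2e-4)
        assert (res.mean_a, res.mean_b) == (2.0, 5.0)

    def test_shift_linearity(self):
        rng = np.random.default_rng(3)
        base = [make_profile(np.arange(20), rng.uniform(1, 2, 20)) for _ in range(3)]
        other = [make_profile(np.arange(20), rng.uniform(1, 2, 20)) for _ in range(3)]
        r1 = central_window_test(base, other)
        shifted = [
            make_profile(p.distances, p.mean_intensity + 2.5) for p in base
        ]
        r2 = central_window_test(shifted, other)
        assert r2.mean_a == pytest.approx(r1.mean_a + 2.5)

    def test_group_size_minimum(self):
        g = [make_profile(np.arange(5), np.ones(5))]
        with pytest.raises(ValidationError):
            central_window_test(g, g)


class TestThresholdDistance:
    def test_linear_ramp_closed_form(self):
        d = np.arange(0, 101, dtype=float)
        p = make_profile(d, 10.0 * (1 + d / 100.0))
        res = threshold_distance(p)
        assert not res.censored
        assert res.distance == pytest.approx(20.0, abs=1e-9)

    def test_constant_profile_censored(self):
        p = make_profile(np.arange(30), np.full(30, 4.0))
        res = threshold_distance(p)
        assert res.censored and res.distance == 29.0

    def test_inverted_gaussian_well_closed_form(self):
        d = np.arange(0, 60, 0.5)
        p = make_profile(d, 50.0 * (2 - np.exp(-(d**2) / (2 * 20.0**2))), px=0.5)
        res = threshold_distance(p)
        expected = 20.0 * np.sqrt(2 * np.log(1.25))
        assert res.distance == pytest.approx(expected, abs=0.05)

    def test_zero_background_rejected(self):
        p = make_profile([0, 1, 2], [0.0, 1, 2])
        with pytest.raises(ValidationError):
            threshold_distance(p)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_in_threshold_factor(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.abs(rng.normal(5, 2, 40)) + 0.5
        p = make_profile(np.arange(40), vals)
        prev = -np.inf
        for factor in (1.05, 1.2, 1.5, 2.0):
            res = threshold_distance(p, ProfileConfig(background_threshold_factor=factor))
            assert res.distance >= prev - 1e-12
            prev = res.distance


class TestPipelineRecovery:
    """The 120%-threshold readout recovers the planted central-minimum
    radius through the full generate -> profile -> threshold chain."""

    CFG = ProfileConfig(background_halfwidth=2.5)  # noise-robust background

    @staticmethod
    def _one(spec):
        from samquant.synthetic import generate_sam

        _, grid, _ = generate_sam(spec)
        p = cross_section_profiles(grid, np.array([0.0, 0.0]), TestPipelineRecovery.CFG)
        return threshold_distance(p, TestPipelineRecovery.CFG).distance

    def test_noise_free_recovery_within_one_pixel(self):
        from samquant.synthetic import SamSpec

        spec = SamSpec(seed=0, noise_mult_sigma=0.0, noise_add_sigma=0.0)
        got = self._one(spec)
        assert abs(got - spec.dr5_central_min_radius) <= spec.grid_pixel_size

    def test_default_noise_median_within_one_pixel(self):
        from samquant.synthetic import SamSpec

        rng = np.random.default_rng(20240917)
        vals = [self._one(SamSpec(seed=int(s))) for s in rng.integers(0, 2**31 - 1, 51)]
        spec = SamSpec()
        assert abs(np.median(vals) - spec.dr5_central_min_radius) <= spec.grid_pixel_size


class TestStemCellGate:
    def test_boundary_inclusive(self):
        from samquant.geometry import SphereFit

        fit = SphereFit(center=np.zeros(3), radius=40.0, rms_residual=0.0, n_points=10)
        axis = Axis(anchor=np.zeros(3), direction=np.array([0.0, 0, 1]))
        cells = pd.DataFrame(
            {
                "cell_id": ["a", "b"],
                "x_um": [10.0, 10.001],
                "y_um": [0.0, 0.0],
                "z_um": [38.0, 38.0],
                "layer": ["L1", "L1"],
            }
        )
        out = gate_stem_cells(cells, fit, axis)
        assert out["is_stem_cell"].tolist() == [True, False]

    def test_matches_refilter_oracle(self, default_sam):
        table, _, truth = default_sam
        fit, mc = estimate_center(table, np.array(truth.primordium_seeds))
        out = gate_stem_cells(table, fit, mc.axis)
        oracle = (out["dist"] <= fit.radius / 4).sum()
        assert out["is_stem_cell"].sum() == oracle
        assert out["is_stem_cell"].any() and not out["is_stem_cell"].all()


class TestMinMax:
    def test_simple_scaling(self):
        df = pd.DataFrame({"dist": [0.0, 5.0, 10.0]})
        out = minmax_normalize(df, ["dist"], by=None)
        assert out["dist_norm"].tolist() == [0.0, 0.5, 1.0]

    def test_idempotent_on_unit_range(self):
        df = pd.DataFrame({"v": [0.0, 0.3, 1.0]})
        out = minmax_normalize(df, ["v"], by=None)
        assert np.allclose(out["v_norm"], df["v"])

    def test_per_meristem_independent(self, rng):
        df = pd.DataFrame(
            {
                "meristem_id": ["m1"] * 10 + ["m2"] * 10,
                "sig": np.concatenate([rng.uniform(0, 10, 10), rng.uniform(100, 300, 10)]),
            }
        )
        out = minmax_normalize(df, ["sig"])
        for _, sub in out.groupby("meristem_id"):
            assert sub["sig_norm"].min() == 0.0 and sub["sig_norm"].max() == 1.0

    def test_constant_field_rejected(self):
        df = pd.DataFrame({"v": [2.0, 2.0, 2.0]})
        with pytest.raises(DegenerateNormalizationError):
            minmax_normalize(df, ["v"], by=None)


class TestKernelProfile:
    def test_constant_signal(self, rng):
        x = rng.uniform(0, 20, 40)
        res = kernel_profile(x, np.full(40, 3.0), np.array([5.0, 10.0]), seed=0)
        assert np.allclose(res.estimate, 3.0)
        assert np.allclose(res.upper - res.lower, 0.0, atol=1e-12)

    def test_linear_signal_small_bandwidth(self, rng):
        x = np.linspace(0, 20, 200)
        y = 2.0 * x
        ev = np.array([5.0, 10.0, 15.0])
        cfg = ProfileConfig(kernel_bandwidth=0.3, bootstrap_iterations=100)
        res = kernel_profile(x, y, ev, cfg, seed=0)
        assert np.allclose(res.estimate, 2 * ev, rtol=0.01)
        # direct kernel-sum oracle on the same data
        for j, e in enumerate(ev):
            w = np.exp(-0.5 * ((x - e) / 0.3) ** 2)
            assert res.estimate[j] == pytest.approx((w @ y) / w.sum(), rel=1e-12)

    def test_matches_statsmodels_local_constant(self, rng):
        from statsmodels.nonparametric.kernel_regression import KernelReg

        x = rng.uniform(0, 10, 60)
        y = np.sin(x) + rng.normal(0, 0.1, 60)
        ev = np.linspace(1, 9, 7)
        cfg = ProfileConfig(kernel_bandwidth=0.8, bootstrap_iterations=10)
        res = kernel_profile(x, y, ev, cfg, seed=0)
        kr = KernelReg(y, x, var_type="c", reg_type="lc", bw=[0.8])
        sm_fit, _ = kr.fit(ev)
        assert np.allclose(res.estimate, sm_fit, rtol=1e-8)

    def test_bandwidth_to_zero_recovers_point_means(self):
        x = np.repeat([1.0, 2.0, 3.0, 4.0], 3)
        y = np.concatenate([[1, 2, 3], [4, 4, 4], [7, 8, 9], [0, 0, 3]]).astype(float)
        cfg = ProfileConfig(kernel_bandwidth=0.01, bootstrap_iterations=10)
        res = kernel_profile(x, y, np.array([1.0, 2.0, 3.0, 4.0]), cfg, seed=0)
        assert np.allclose(res.estimate, [2.0, 4.0, 8.0, 1.0])

    def test_seeded_reproducibility_and_degenerate_input(self, rng):
        x = rng.uniform(0, 5, 30)
        y = rng.normal(size=30)
        cfg = ProfileConfig(bootstrap_iterations=200)
        r1 = kernel_profile(x, y, np.array([2.0]), cfg, seed=11)
        r2 = kernel_profile(x, y, np.array([2.0]), cfg, seed=11)
        assert np.array_equal(r1.lower, r2.lower)
        with pytest.raises(ValidationError):
            kernel_profile(np.ones(30), y, np.array([1.0]), cfg, seed=0)


class TestAnovaTukey:
    def test_identical_groups(self):
        res = central_zone_timecourse({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_anova_decomposition(self):
        # SSB = 2*(9+4+25) = 76 on 2 df; SSW = 1.5 on 3 df -> F = 76
        res = central_zone_timecourse({"a": [1, 2], "b": [2, 3], "c": [9, 10]})
        assert res.f == pytest.approx(76.0, rel=1e-12)
        assert len(res.tukey) == 3
        assert set(res.tukey.columns) >= {"group_a", "group_b", "mean_diff", "p_adj"}

    def test_location_invariance(self):
        g1 = {"a": [1.0, 2, 4], "b": [2.0, 5, 6], "c": [9.0, 10, 12]}
        g2 = {k: [v + 100 for v in vals] for k, vals in g1.items()}
        r1, r2 = central_zone_timecourse(g1), central_zone_timecourse(g2)
        assert r1.f == pytest.approx(r2.f)
        assert np.allclose(r1.tukey["p_adj"], r2.tukey["p_adj"])
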