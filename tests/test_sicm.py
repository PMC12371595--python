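"""Inverse pipeline: slope fits, contact extraction, modulus maps, masks."""

import math

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings
from hypothesis import strategies as st

from storemetrics.containers import AcquisitionParams, ApproachCurve
from storemetrics.sicm import (
    RIGID,
    build_maps,
    cell_region_stats,
    extract_contact_z,
    fit_window_slope,
    modulus_distribution,
    modulus_from_slope,
    reference_slope,
    segment_cells,
)
from storemetrics.synthetic import (
    generate_phantom,
    synthesize_scan,
    uniform_modulus,
)

from conftest import single_cell_phantom


def line_curve(slope, z0=10.0, z_step=0.05, stop=2.1):
    """Exact linear approach curve with window slope ``slope`` (%/µm)."""
    n = int(np.ceil((stop / slope + 0.1) / z_step)) + 1
    z = z0 - z_step * np.arange(n)
    d = np.maximum(0.0, slope * (z0 - z))
    hit = np.nonzero(d >= stop)[0]
    k = hit[0] if hit.size else n - 1
    return ApproachCurve(z[: k + 1], d[: k + 1])


class TestFitWindowSlope:
    def test_exact_line_recovered(self):
        z0 = 10.0
        z = z0 - 0.1 * np.arange(35)
        d = 2.0 - 1.0 * (z - (z0 - 3.0))  # unit slope, crosses window
        curve = ApproachCurve(z, d)
        s, r2, n = fit_window_slope(curve, 1.0, 2.0)
        assert s == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert n >= 10

    def test_two_in_window_points_flag_undefined(self):
        curve = line_curve(10.0, z_step=0.06)  # window 1-2% spans 0.1 µm
        in_window = ((curve.drop_pct >= 1.0) & (curve.drop_pct <= 2.0)).sum()
        assert in_window < 3
        s, r2, n = fit_window_slope(curve)
        assert math.isnan(s) and math.isnan(r2)

    def test_noisy_slope_within_ols_sampling_bound(self):
        # oracle: closed-form OLS slope variance sigma^2 / sum (z - zbar)^2
        rng = np.random.default_rng(5)
        z = 10.0 - 0.02 * np.arange(120)
        true = 0.5
        d = 1.5 - true * (z - 9.0)
        sel = (d >= 1.0) & (d <= 2.0)
        sd = 0.01
        noisy = ApproachCurve(z, d + rng.normal(0, sd, z.size))
        s, _, n = fit_window_slope(noisy)
        zc = z[sel] - z[sel].mean()
        slope_sd = sd / math.sqrt(float(zc @ zc))
        assert abs(s - true) < 3 * slope_sd


class TestExtractContact:
    def test_interpolates_between_brackets(self):
        curve = ApproachCurve(np.array([10.0, 9.0]), np.array([1.9, 2.3]))
        assert extract_contact_z(curve, 2.1) == pytest.approx(9.5)

    def test_exact_sample_at_threshold(self):
        curve = ApproachCurve(np.array([10.0, 9.5, 9.0]),
                              np.array([1.0, 2.1, 3.0]))
        assert extract_contact_z(curve, 2.1) == 9.5

    def test_translation_equivariance(self):
        curve = line_curve(2.0)
        shifted = ApproachCurve(curve.z_um + 1.0, curve.drop_pct)
        assert extract_contact_z(shifted) == pytest.approx(
            extract_contact_z(curve) + 1.0)

    def test_unreached_threshold_is_error(self):
        curve = ApproachCurve(np.array([10.0, 9.0]), np.array([0.5, 1.0]))
        with pytest.raises(ValueError, match="never reaches"):
            extract_contact_z(curve, 2.1)


class TestReferenceSlope:
    def test_identical_curves(self):
        ref = reference_slope([line_curve(2.0, z_step=0.02)] * 200)
        assert ref.s_inf == pytest.approx(2.0)
        assert ref.n_curves == 200

    def test_median_robust_to_49_pct_outliers(self):
        # sort-based oracle: 101 slopes of 2 and 99 of 50 -> median 2
        curves = [line_curve(2.0, z_step=0.02)] * 101 + \
                 [line_curve(50.0, z_step=0.002)] * 99
        assert reference_slope(curves).s_inf == pytest.approx(2.0)

    def test_even_count_median_is_central_pair_mean(self):
        curves = [line_curve(s, z_step=0.01) for s in (1.0, 2.0, 3.0, 4.0)]
        assert reference_slope(curves).s_inf == pytest.approx(2.5, rel=1e-9)

    def test_all_undefined_is_error(self):
        flat = ApproachCurve(np.array([10.0, 9.0, 8.0]),
                             np.array([0.0, 0.0, 2.2]))
        with pytest.raises(ValueError, match="no reference curve"):
            reference_slope([flat])


class TestModulusFromSlope:
    def test_half_slope_gives_a_p0(self):
        assert modulus_from_slope(12.5, 25.0, 0.1617, 2000.0) == pytest.approx(323.4)

    def test_slope_at_reference_is_rigid(self):
        assert modulus_from_slope(25.0, 25.0) == RIGID
        assert modulus_from_slope(30.0, 25.0) == RIGID

    def test_algebraic_inverse_round_trip(self):
        # s chosen as s_inf/(1 + A*P0/300) must map back to E = 300
        s = 25.0 / (1.0 + 0.1617 * 2000.0 / 300.0)
        assert modulus_from_slope(s, 25.0, 0.1617, 2000.0) == pytest.approx(300.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            modulus_from_slope(-1.0, 25.0)
        with pytest.raises(ValueError):
            modulus_from_slope(1.0, 25.0, a_geom=0.0)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing_in_slope(self, f1, f2):
        s_inf = 25.0
        e1 = modulus_from_slope(min(f1, f2) * s_inf, s_inf)
        e2 = modulus_from_slope(max(f1, f2) * s_inf, s_inf)
        if f1 != f2:
            assert e1 < e2

    @given(st.floats(0.05, 0.95), st.floats(0.5, 4.0))
    @settings(deadline=None, max_examples=50)
    def test_p0_linearity(self, frac, scale):
        # multiplying P0 by c multiplies every finite modulus by c
        s, s_inf = frac * 25.0, 25.0
        e1 = modulus_from_slope(s, s_inf, pressure_pa=2000.0)
        e2 = modulus_from_slope(s, s_inf, pressure_pa=2000.0 * scale)
        assert e2 == pytest.approx(scale * e1, rel=1e-12)


class TestBuildMaps:
    def test_stiff_phantom_topography_within_one_step(self, stiff_scan,
                                                      noise_free_acq):
        phantom, scan = stiff_scan
        topo, _, _ = build_maps(scan)
        err = np.abs(topo.height_um - phantom.topography_um)
        assert err.max() < noise_free_acq.z_step_um

    def test_uniform_cell_recovered_within_1_pct(self, uniform_300_scan):
        phantom, scan = uniform_300_scan
        _, _, modulus = build_maps(scan)
        cell = ~np.isnan(phantom.modulus_pa)
        rec = modulus.e_pa[cell]
        assert np.all(np.isfinite(rec))
        assert np.max(np.abs(rec - 300.0) / 300.0) < 0.01

    @pytest.mark.parametrize("e_true", [50.0, 100.0, 300.0, 1000.0])
    def test_forward_inverse_consistency(self, e_true, noise_free_acq):
        phantom = single_cell_phantom(uniform_modulus(e_true), grid=16,
                                      pixel_um=2.0, radius_um=10.0)
        scan = synthesize_scan(phantom, noise_free_acq)
        _, _, modulus = build_maps(scan)
        cell = ~np.isnan(phantom.modulus_pa)
        assert np.max(np.abs(modulus.e_pa[cell] - e_true) / e_true) < 0.01

    def test_all_substrate_scan_is_all_sentinel(self, noise_free_acq):
        phantom = generate_phantom([], (8, 8), 1.0)
        scan = synthesize_scan(phantom, noise_free_acq)
        _, _, modulus = build_maps(scan)
        assert not np.any(np.isfinite(modulus.e_pa))

    def test_missing_reference_curves_is_error(self, uniform_300_scan):
        _, scan = uniform_300_scan
        stripped = type(scan)(curves=scan.curves, reference_curves=[],
                              params=scan.params, pixel_size_um=scan.pixel_size_um)
        with pytest.raises(ValueError, match="reference"):
            build_maps(stripped)


def disc(shape, center, radius, height):
    yy, xx = np.indices(shape, dtype=float)
    return np.where(np.hypot(xx - center[1], yy - center[0]) <= radius,
                    height, 0.0)


class TestSegmentCells:
    def test_two_disjoint_discs_two_labels(self):
        topo = disc((64, 64), (32, 16), 8, 2.0) + disc((64, 64), (32, 48), 8, 2.0)
        mask = segment_cells(topo)
        assert mask.n_cells == 2

    def test_flat_topography_no_labels(self):
        mask = segment_cells(np.zeros((32, 32)))
        assert mask.n_cells == 0
        assert np.all(mask.labels == 0)

    def test_fused_discs_split_at_neck(self):
        # two domes joined by a bridge lower than both peaks
        yy, xx = np.indices((48, 80), dtype=float)
        peak_a = 2.0 * np.exp(-((xx - 25) ** 2 + (yy - 24) ** 2) / (2 * 7.0**2))
        peak_b = 2.0 * np.exp(-((xx - 55) ** 2 + (yy - 24) ** 2) / (2 * 7.0**2))
        topo = peak_a + peak_b
        assert topo[24, 40] > 0.2  # the neck is above the foreground cutoff
        mask = segment_cells(topo)
        assert mask.n_cells == 2
        # flood-fill oracle from the two peaks: symmetric construction means
        # each peak's core belongs to the label of its own side
        la, lb = mask.labels[24, 25], mask.labels[24, 55]
        assert la != lb and la > 0 and lb > 0
        left = mask.labels[:, :38]
        right = mask.labels[:, 43:]
        assert set(np.unique(left[left > 0])) == {la}
        assert set(np.unique(right[right > 0])) == {lb}

    def test_dimpled_cell_stays_single_label(self, center_edge_scan):
        _, scan = center_edge_scan
        topo, _, _ = build_maps(scan)
        assert segment_cells(topo).n_cells == 1


class TestModulusDistribution:
    @staticmethod
    def _uniform_map(value=300.0, shape=(16, 16)):
        from storemetrics.containers import CellMask, ModulusMap
        e = np.full(shape, np.nan)
        labels = np.zeros(shape, dtype=np.int32)
        labels[4:12, 4:12] = 1
        e[labels == 1] = value
        return ModulusMap(e, 0.1617, 2000.0), CellMask(labels)

    def test_uniform_region_occupies_single_bin(self):
        modulus, mask = self._uniform_map()
        hist = modulus_distribution(modulus, mask, bins=10,
                                    value_range=(0.0, 600.0))
        assert (hist.mass > 0).sum() == 1

    def test_normalized_masses_sum_to_one(self):
        modulus, mask = self._uniform_map()
        hist = modulus_distribution(modulus, mask, bins=20,
                                    value_range=(0.0, 600.0), normalize=True)
        assert hist.mass.sum() == pytest.approx(1.0, abs=1e-12)

    def test_histogram_additive_over_merged_masks(self, center_edge_scan):
        from storemetrics.containers import CellMask
        _, scan = center_edge_scan
        topo, _, modulus = build_maps(scan)
        mask = segment_cells(topo)
        labels = mask.labels
        half_a = np.where(np.indices(labels.shape)[1] < 16, labels, 0)
        half_b = np.where(np.indices(labels.shape)[1] >= 16, labels, 0)
        kw = dict(bins=25, value_range=(0.0, 400.0))
        h_all = modulus_distribution(modulus, mask, **kw)
        h_a = modulus_distribution(modulus, CellMask(half_a), **kw)
        h_b = modulus_distribution(modulus, CellMask(half_b), **kw)
        assert np.allclose(h_all.mass, h_a.mass + h_b.mass)

    def test_no_cell_pixels_is_error(self):
        from storemetrics.containers import CellMask, ModulusMap
        modulus = ModulusMap(np.full((8, 8), np.nan), 0.1617, 2000.0)
        with pytest.raises(ValueError, match="no finite-modulus"):
            modulus_distribution(modulus, CellMask(np.zeros((8, 8), np.int32)))

    def test_substrate_pixels_never_counted(self, center_edge_scan):
        # exclusion invariant: histogram mass equals the finite cell-pixel count
        _, scan = center_edge_scan
        topo, _, modulus = build_maps(scan)
        mask = segment_cells(topo)
        hist = modulus_distribution(modulus, mask, bins=30,
                                    value_range=(0.0, 500.0))
        n_cell = int(((mask.labels > 0) & np.isfinite(modulus.e_pa)).sum())
        assert hist.mass.sum() == n_cell


class TestCellRegionStats:
    def test_uniform_region_center_equals_edge(self):
        modulus, mask = TestModulusDistribution._uniform_map(300.0)
        center, edge = cell_region_stats(modulus, mask, 1)
        assert center == pytest.approx(300.0)
        assert edge == pytest.approx(300.0)

    def test_center_edge_recovery_from_phantom(self, center_edge_scan):
        _, scan = center_edge_scan
        topo, _, modulus = build_maps(scan)
        mask = segment_cells(topo)
        center, edge = cell_region_stats(modulus, mask, 1)
        assert abs(center - 300.0) / 300.0 < 0.05
        assert edge <= 100.0

    def test_translation_invariance(self):
        from storemetrics.containers import CellMask, ModulusMap
        rng = np.random.default_rng(2)
        patch = rng.uniform(50.0, 400.0, size=(9, 9))
        e1 = np.full((32, 32), np.nan)
        e2 = np.full((32, 32), np.nan)
        l1 = np.zeros((32, 32), np.int32)
        l2 = np.zeros((32, 32), np.int32)
        e1[3:12, 3:12] = patch
        l1[3:12, 3:12] = 1
        e2[15:24, 18:27] = patch
        l2[15:24, 18:27] = 1
        s1 = cell_region_stats(ModulusMap(e1, 0.1617, 2000.0), CellMask(l1), 1)
        s2 = cell_region_stats(ModulusMap(e2, 0.1617, 2000.0), CellMask(l2), 1)
        assert s1 == pytest.approx(s2)

    def test_tiny_region_is_error(self):
        from storemetrics.containers import CellMask, ModulusMap
        e = np.full((8, 8), 100.0)
        labels = np.zeros((8, 8), np.int32)
        labels[0, :4] = 1
        with pytest.raises(ValueError, match="pixels"):
            cell_region_stats(ModulusMap(e, 0.1617, 2000.0), CellMask(labels), 1)
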