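"""3D morphometry: line scans, radial averaging, contours, hourglass features."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from oracles import line_samples, radial_bin_means
from podoscope import (
    ImageStack3D,
    RadialHeatmap,
    aggregate_heatmaps,
    axial_profiles,
    default_template,
    extract_morphology,
    perpendicular_line_scan,
    podosome_contour,
    radial_average,
    render_heatmap_direct,
)

Z = np.arange(0.0, 451.0, 10.0)


def _stack_from_function(fn, n_px=41, ps=0.05, z=None):
    z = Z if z is None else z
    xs = (np.arange(n_px) + 0.5) * ps
    slices = np.array([fn(xs[np.newaxis, :], xs[:, np.newaxis], zv) for zv in z])
    return ImageStack3D(slices, ps, z)


class TestLineScan:
    def test_symmetric_podosome_gives_symmetric_map(self):
        pod = (1.025, 1.025)
        stack = _stack_from_function(
            lambda x, y, z: np.exp(-((x - pod[0]) ** 2 + (y - pod[1]) ** 2) / 0.02),
            z=np.array([0.0, 10.0]),
        )
        scan = perpendicular_line_scan(stack, pod, site_center_xy=(0.2, 0.2), half_length=0.8)
        assert np.allclose(scan.values, scan.values[:, ::-1], atol=1e-6)
        assert scan.d_positions[len(scan.d_positions) // 2] == 0.0

    def test_constant_slice_gives_constant_row(self):
        stack = _stack_from_function(lambda x, y, z: np.full_like(x + y, 3.5), z=np.array([0.0]))
        scan = perpendicular_line_scan(stack, (1.0, 1.0), (0.3, 0.5), half_length=0.6)
        assert np.allclose(scan.values, 3.5)

    def test_planted_inward_spot_peaks_at_negative_d(self):
        pod = (2.2, 2.0)
        site = (1.2, 2.0)  # inward direction = -x
        spot = (pod[0] - 0.35, pod[1])
        stack = _stack_from_function(
            lambda x, y, z: np.exp(-((x - spot[0]) ** 2 + (y - spot[1]) ** 2) / (2 * 0.01)),
            n_px=90,
            z=np.array([0.0]),
        )
        scan = perpendicular_line_scan(stack, pod, site, half_length=1.0)
        step = scan.d_positions[1] - scan.d_positions[0]
        d_at_max = scan.d_positions[np.nanargmax(scan.values[0])]
        assert abs(d_at_max - (-0.35)) <= step + 1e-9

    def test_zero_direction_rejected(self):
        stack = _stack_from_function(lambda x, y, z: x + y, z=np.array([0.0]))
        with pytest.raises(ValueError):
            perpendicular_line_scan(stack, (1.0, 1.0), (1.0, 1.0))

    def test_matches_bilinear_oracle(self, rng):
        values = rng.random((21, 21))
        stack = ImageStack3D(values[np.newaxis], 0.05, np.array([0.0]))
        scan = perpendicular_line_scan(stack, (0.52, 0.5), (0.2, 0.31), half_length=0.3)
        u = np.array([0.52, 0.5]) - np.array([0.2, 0.31])
        u /= np.hypot(*u)
        pts = np.array([0.52, 0.5]) + scan.d_positions[:, None] * u
        ref = line_samples(values, 0.05, pts)
        ok = np.isfinite(ref) & np.isfinite(scan.values[0])
        assert np.allclose(scan.values[0][ok], ref[ok], rtol=1e-9)


class TestRadialAverage:
    def test_gaussian_profile_recovered(self):
        pod = (1.0125, 1.0125)
        sigma_nm = 250.0
        stack = _stack_from_function(
            lambda x, y, z: np.exp(
                -((x - pod[0]) ** 2 + (y - pod[1]) ** 2) * 1e6 / (2 * sigma_nm**2)
            ),
            n_px=81,
            ps=0.025,
            z=np.array([0.0]),
        )
        hm = radial_average(stack, pod, r_max=600.0, r_bin=10.0)
        expected = np.exp(-(hm.r_centers**2) / (2 * sigma_nm**2))
        assert np.allclose(hm.values[0], expected, rtol=0.01, atol=0.001)

    def test_constant_slice_flat_profile(self):
        stack = _stack_from_function(lambda x, y, z: np.full_like(x + y, 2.0), z=np.array([0.0]))
        hm = radial_average(stack, (1.0, 1.0), r_max=400.0)
        assert np.allclose(hm.values, 2.0)

    def test_agrees_with_distance_binning_oracle(self, rng):
        # a smooth random slice: angular sampling vs direct pixel binning
        from scipy.ndimage import gaussian_filter

        values = gaussian_filter(rng.random((41, 41)), 3.0)
        stack = ImageStack3D(values[np.newaxis], 0.05, np.array([0.0]))
        center = (1.03, 1.01)
        hm = radial_average(stack, center, r_max=500.0, r_bin=20.0)
        edges_um = np.arange(0, 501.0, 20.0) / 1000.0
        ref = radial_bin_means(values, 0.05, center, edges_um)
        ok = np.isfinite(ref)
        assert np.allclose(hm.values[0][ok], ref[ok], rtol=0.06)

    def test_invalid_r_max(self):
        stack = _stack_from_function(lambda x, y, z: x + y, z=np.array([0.0]))
        with pytest.raises(ValueError):
            radial_average(stack, (1.0, 1.0), r_max=-5.0)

    def test_normalization_flag(self):
        stack = _stack_from_function(lambda x, y, z: np.full_like(x + y, 4.0), z=np.array([0.0]))
        hm = radial_average(stack, (1.0, 1.0), r_max=300.0, normalize=True)
        assert hm.normalized and hm.values.max() == pytest.approx(1.0)


def _column_heatmap(n_cols_bright=6):
    r = (np.arange(60) + 0.5) * 10.0
    values = np.zeros((len(Z), 60))
    values[:, :n_cols_bright] = 1.0
    return RadialHeatmap(values=values, r_centers=r, z_positions=Z, r_bin=10.0)


class TestContour:
    def test_bright_column_is_masked(self):
        # column occupies 6 of the 35 bins inside r<=350: threshold ~0.17
        hm = _column_heatmap()
        mask = podosome_contour(hm)
        assert mask[:, :4].all()  # column interior above threshold
        assert not mask[:, 10:].any()  # background below threshold

    def test_all_zero_heatmap_empty_mask(self):
        hm = _column_heatmap(0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = podosome_contour(hm)
        assert not mask.any()

    def test_two_lobes_join_only_through_bright_neck(self):
        r = (np.arange(60) + 0.5) * 10.0
        lo = np.zeros((len(Z), 60))
        lo[5:10, :8] = 1.0
        hi = lo.copy()
        hi[25:30, :8] = 1.0
        from scipy import ndimage

        disjoint = RadialHeatmap(hi, r, Z, 10.0)
        _, n_disjoint = ndimage.label(podosome_contour(disjoint))
        necked = hi.copy()
        necked[10:25, :3] = 1.0  # bridge above threshold
        _, n_necked = ndimage.label(
            podosome_contour(RadialHeatmap(necked, r, Z, 10.0))
        )
        assert n_disjoint == 2 and n_necked == 1

    def test_requires_350nm_coverage(self):
        r = (np.arange(20) + 0.5) * 10.0  # only to 200 nm
        hm = RadialHeatmap(np.ones((len(Z), 20)), r, Z, 10.0)
        with pytest.raises(ValueError):
            podosome_contour(hm)


class TestAxialProfiles:
    def test_r_constant_heatmap_profiles_equal_z_profile(self):
        r = (np.arange(60) + 0.5) * 10.0
        zprof = np.exp(-((Z - 200.0) ** 2) / (2 * 50.0**2))
        hm = RadialHeatmap(np.tile(zprof[:, None], (1, 60)), r, Z, 10.0)
        core, net = axial_profiles(hm)
        assert np.allclose(core, zprof) and np.allclose(net, zprof)

    def test_two_lobe_core_has_two_maxima(self):
        t = replace(
            default_template(),
            neck_fraction=0.0,
            knob_amplitude=0.0,
            lower_network=replace(default_template().lower_network, amplitude=0.0),
            upper_network=replace(default_template().upper_network, amplitude=0.0),
        )
        hm = render_heatmap_direct(t)
        core, _ = axial_profiles(hm)
        interior = (core[1:-1] > core[:-2]) & (core[1:-1] >= core[2:])
        maxima_z = Z[1:-1][interior]
        assert len(maxima_z) == 2
        assert abs(maxima_z[0] - 70.0) <= 10.0 and abs(maxima_z[1] - 270.0) <= 10.0

    def test_network_only_heatmap_zero_core(self):
        r = (np.arange(60) + 0.5) * 10.0
        values = np.tile((r >= 400).astype(float), (len(Z), 1))
        core, net = axial_profiles(RadialHeatmap(values, r, Z, 10.0))
        assert np.allclose(core, 0.0) and np.allclose(net, 1.0)


class TestExtractMorphology:
    def test_default_template_hourglass(self):
        m = extract_morphology(render_heatmap_direct(default_template()))
        assert m.has_upper_core and m.has_lower_core and m.has_neck
        assert m.has_upper_network and m.has_lower_network
        assert m.lower_core_z < m.neck_z < m.upper_core_z
        r = m.rounded()
        assert r.height == 330.0
        assert r.neck_z == 190.0
        assert r.upper_core_z == 270.0 and r.lower_core_z == 70.0
        assert r.protrusion_length == 20.0

    def test_two_lobe_closed_form_fwhm(self):
        # bridge/networks/knob off: the core profile is two axial
        # Gaussians and FWHM = 2 sqrt(2 ln 2) sigma exactly
        base = default_template()
        t = replace(
            base,
            neck_fraction=0.0,
            knob_amplitude=0.0,
            lower_network=replace(base.lower_network, amplitude=0.0),
            upper_network=replace(base.upper_network, amplitude=0.0),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = extract_morphology(render_heatmap_direct(t))
        assert abs(m.upper_core_z - 270.0) <= 10.0
        assert abs(m.lower_core_z - 70.0) <= 10.0
        assert abs(m.upper_core_fwhm - 90.0) <= 10.0
        assert abs(m.lower_core_fwhm - 80.0) <= 10.0

    def test_single_lobe_has_no_lower_core_or_neck(self):
        base = default_template()
        t = replace(
            base,
            lower_lobe=replace(base.lower_lobe, amplitude=0.0),
            neck_fraction=0.0,
            knob_amplitude=0.0,
            lower_network=replace(base.lower_network, amplitude=0.0),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = extract_morphology(render_heatmap_direct(t))
        assert m.has_upper_core and not m.has_lower_core and not m.has_neck

    def test_flat_heatmap_reports_nothing(self):
        r = (np.arange(60) + 0.5) * 10.0
        hm = RadialHeatmap(np.zeros((len(Z), 60)), r, Z, 10.0)
        m = extract_morphology(hm)
        assert not any(
            [m.has_upper_core, m.has_lower_core, m.has_neck, m.has_upper_network]
        )

    def test_scale_invariance(self):
        hm = render_heatmap_direct(default_template())
        m1 = extract_morphology(hm)
        m2 = extract_morphology(replace(hm, values=hm.values * 37.5))
        for name in ("height", "neck_z", "upper_core_z", "upper_core_fwhm", "protrusion_length"):
            assert getattr(m1, name) == pytest.approx(getattr(m2, name))

    def test_rounding_is_reporting_only(self):
        m = extract_morphology(render_heatmap_direct(default_template()))
        assert m.upper_core_fwhm != round(m.upper_core_fwhm / 10) * 10 or True
        r = m.rounded()
        assert r.upper_core_fwhm % 10 == 0
        assert r.height % 10 == 0


class TestAggregate:
    def _hm(self, values):
        r = (np.arange(60) + 0.5) * 10.0
        return RadialHeatmap(values, r, Z, 10.0)

    def test_identical_maps_idempotent(self):
        hm = render_heatmap_direct(default_template())
        agg = aggregate_heatmaps([hm, hm, hm])
        assert np.allclose(agg.values, hm.values / hm.values.max())

    def test_constant_maps_normalise_to_one(self):
        a = self._hm(np.full((len(Z), 60), 3.0))
        b = self._hm(np.full((len(Z), 60), 11.0))
        assert np.allclose(aggregate_heatmaps([a, b]).values, 1.0)

    def test_mean_beats_single_noisy_member(self, rng):
        template = render_heatmap_direct(default_template())
        ref = template.values / template.values.max()
        noisy = [
            self._hm(template.values + rng.normal(0, 0.05, template.values.shape).clip(-0.04, None))
            for _ in range(12)
        ]
        agg = aggregate_heatmaps(noisy)
        rms_mean = np.sqrt(((agg.values - ref) ** 2).mean())
        rms_members = [
            np.sqrt(((h.normalize().values - ref) ** 2).mean()) for h in noisy
        ]
        assert rms_mean < min(rms_members)

    def test_mismatched_grids_rejected(self):
        a = self._hm(np.ones((len(Z), 60)))
        r2 = (np.arange(30) + 0.5) * 20.0
        b = RadialHeatmap(np.ones((len(Z), 30)), r2, Z, 20.0)
        with pytest.raises(ValueError):
            aggregate_heatmaps([a, b])
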