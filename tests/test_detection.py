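"""Podosome/site detection: preprocessing, significance, refinement."""

import numpy as np
import pytest

from podoscope import (
    DetectionParams,
    Image2D,
    PodosomeSet,
    detect_features,
    preprocess,
    refine,
    split_significant,
)
from podoscope.detect import smoothing_width


def _gaussian_spot(canvas, pixel_size, x, y, sigma_um, amplitude):
    rows, cols = canvas.shape
    xs = (np.arange(cols) + 0.5) * pixel_size
    ys = (np.arange(rows) + 0.5) * pixel_size
    canvas += amplitude * np.exp(
        -((xs[np.newaxis, :] - x) ** 2 + (ys[:, np.newaxis] - y) ** 2)
        / (2 * sigma_um**2)
    )


class TestPreprocess:
    def test_constant_image_zero_variance_rejected(self):
        img = Image2D(np.full((10, 10), 2.0), 0.1)
        with pytest.raises(ValueError):
            preprocess(img, 0.3, noise_variance=0.0)
        out = preprocess(img, 0.3, noise_variance=0.01, rng_seed=3)
        assert np.unique(out.values).size == out.values.size

    def test_box_filter_spreads_single_pixel(self):
        a = np.zeros((9, 9))
        a[4, 4] = 9.0
        out = preprocess(
            Image2D(a, 0.1), feature_size=0.3, noise_variance=1e-10, rng_seed=0
        )
        # kernel width 3: the (normalised) unit peak averages over 3x3,
        # up to the (tiny) uniqueness noise
        assert out.values[4, 4] == pytest.approx(1 / 9, abs=1e-4)
        assert out.values[3, 4] == pytest.approx(1 / 9, abs=1e-4)
        assert out.values[0, 0] == pytest.approx(0.0, abs=1e-4)

    def test_seeded_determinism(self, rng):
        img = Image2D(rng.random((20, 20)), 0.1)
        a = preprocess(img, 0.3, 0.01, rng_seed=7)
        b = preprocess(img, 0.3, 0.01, rng_seed=7)
        assert np.array_equal(a.values, b.values)
        c = preprocess(img, 0.3, 0.01, rng_seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_subpixel_feature_size_rejected(self):
        img = Image2D(np.arange(16.0).reshape(4, 4), 0.1)
        with pytest.raises(ValueError):
            preprocess(img, 0.05)

    @pytest.mark.parametrize(
        "feature,pixel,width", [(0.3, 0.05, 7), (1.5, 0.05, 31), (0.3, 0.1, 3), (0.3, 0.08, 5)]
    )
    def test_smoothing_width_is_odd(self, feature, pixel, width):
        assert smoothing_width(feature, pixel) == width


class TestSplitSignificant:
    def test_symmetric_two_group_split(self):
        mask = split_significant([10.0, 9.0, 0.5, 0.4])
        assert mask.tolist() == [True, True, False, False]

    def test_two_values(self):
        assert split_significant([5.0, 1.0]).tolist() == [True, False]

    def test_optimal_contiguous_split(self):
        # within-cluster SS 0.5 + 0.38 at the {8,7.5,7}|{1,0.9,0.2} split
        # beats every other contiguous split (checked exhaustively)
        vals = [8.0, 7.5, 7.0, 1.0, 0.9, 0.2]
        s = np.sort(vals)
        best = min(
            range(1, len(s)),
            key=lambda k: np.var(s[:k]) * k + np.var(s[k:]) * (len(s) - k),
        )
        assert s[best] == 7.0
        assert split_significant(vals).tolist() == [True, True, True, False, False, False]

    def test_degenerate_inputs_empty(self):
        assert split_significant([3.0]).sum() == 0
        assert split_significant([2.0, 2.0, 2.0]).sum() == 0
        assert split_significant([]).size == 0

    def test_floor_suppresses_weak_clusters(self):
        vals = [0.03, 0.025, 0.001, 0.002]
        assert split_significant(vals).sum() == 2
        assert split_significant(vals, floor_value=0.05).sum() == 0


class TestDetectFeatures:
    def test_three_planted_spots_recovered(self):
        ps = 0.05
        canvas = np.zeros((120, 120))
        truth = [(1.5, 1.5), (4.0, 2.0), (2.5, 4.5)]
        for x, y in truth:
            _gaussian_spot(canvas, ps, x, y, sigma_um=0.127, amplitude=1.0)
        pods = detect_features(
            Image2D(canvas, ps), DetectionParams(rng_seed=0), mode="podosome"
        )
        assert len(pods) == 3
        for x, y in truth:
            d = np.hypot(pods.positions[:, 0] - x, pods.positions[:, 1] - y).min()
            assert d <= ps * 1.5  # within one pixel (diagonal)

    def test_constant_image_yields_empty(self):
        pods = detect_features(
            Image2D(np.full((80, 80), 5.0), 0.05), DetectionParams(rng_seed=0), "podosome"
        )
        assert len(pods) == 0

    def test_ring_of_spots_yields_site_candidate(self):
        ps = 0.05
        canvas = np.zeros((160, 160))
        center = (4.0, 4.0)
        for k in range(8):
            ang = 2 * np.pi * k / 8
            _gaussian_spot(
                canvas,
                ps,
                center[0] + 1.8 * np.cos(ang),
                center[1] + 1.8 * np.sin(ang),
                sigma_um=0.2,
                amplitude=1.0,
            )
        cands = detect_features(
            Image2D(canvas, ps), DetectionParams(rng_seed=0), mode="site"
        )
        assert len(cands) >= 1
        d = np.hypot(cands[:, 0] - center[0], cands[:, 1] - center[1]).min()
        assert d <= 1.5 / 2  # within half the site feature size

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            detect_features(Image2D(np.eye(4) + 1, 0.1), DetectionParams(), "blob")


def _pod_set(positions):
    positions = np.asarray(positions, dtype=float)
    return PodosomeSet(
        positions=positions,
        persistence=np.ones(len(positions)),
        loci=np.zeros((len(positions), 2), dtype=int),
    )


class TestRefine:
    def test_site_with_two_podosomes_dropped(self):
        pods = _pod_set([(0.0, 0.1), (0.1, 0.0)])
        refined, sites = refine(pods, np.array([[0.0, 0.0]]), DetectionParams())
        assert len(refined) == 0 and len(sites) == 0

    def test_recentering_by_symmetry(self):
        ring = [
            (np.cos(a), np.sin(a)) for a in 2 * np.pi * np.arange(6) / 6
        ]
        refined, sites = refine(_pod_set(ring), np.array([[0.2, 0.0]]), DetectionParams())
        assert len(refined) == 6
        assert np.allclose(sites.centers[0], (0.0, 0.0), atol=1e-12)

    def test_stray_podosome_dropped(self):
        ring = [
            (3 + 1.8 * np.cos(a), 3 + 1.8 * np.sin(a))
            for a in 2 * np.pi * np.arange(8) / 8
        ]
        pods = _pod_set(ring + [(12.0, 12.0)])  # stray, far from everything
        refined, sites = refine(pods, np.array([[3.0, 3.0]]), DetectionParams())
        assert len(refined) == 8
        assert len(sites) == 1 and len(sites.members[0]) == 8

    def test_empty_inputs(self):
        refined, sites = refine(_pod_set([]), np.empty((0, 2)), DetectionParams())
        assert len(refined) == 0 and len(sites) == 0

    def test_refinement_contracts(self, rng):
        pods = _pod_set(rng.uniform(0, 10, size=(40, 2)))
        cands = rng.uniform(0, 10, size=(6, 2))
        refined, sites = refine(pods, cands, DetectionParams())
        assert len(refined) <= 40
        assert len(sites) <= 6
        # every surviving podosome has a surviving site and is close to it
        if len(refined):
            assert refined.site_id.min() >= 0
            d = np.hypot(
                *(refined.positions - sites.centers[refined.site_id]).T
            )
            assert (d <= DetectionParams().max_podosome_site_distance).all()


def test_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(podosome_feature_size=2.0, site_feature_size=1.5)
    with pytest.raises(ValueError):
        DetectionParams(min_podosomes_per_site=0)
    with pytest.raises(ValueError):
        DetectionParams(noise_variance=-1.0)


def test_detection_translation_equivariance(rng):
    """Shifting the image by whole pixels shifts detections accordingly."""
    ps = 0.05
    canvas = np.zeros((100, 100))
    for x, y in [(1.6, 1.4), (3.3, 3.7)]:
        _gaussian_spot(canvas, ps, x, y, 0.127, 1.0)
    shifted = np.roll(canvas, (6, 4), axis=(0, 1))
    params = DetectionParams(rng_seed=5)
    a = detect_features(Image2D(canvas, ps), params, "podosome")
    b = detect_features(Image2D(shifted, ps), params, "podosome")
    assert len(a) == len(b) == 2
    delta = np.array([4 * ps, 6 * ps])  # (x, y) shift
    # the uniqueness-noise field does not translate with the image, so
    # loci may wander by one pixel at most
    assert np.allclose(
        sorted(map(tuple, a.positions + delta)),
        sorted(map(tuple, b.positions)),
        atol=ps + 1e-9,
    )
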