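"""Fibre segmentation, minimum Feret diameter and summary statistics."""

import numpy as np
import pytest
from skimage.draw import disk

from dystromark import fibre_morphometry as fm
from dystromark import synthetic_data as syn

from conftest import brute_force_min_feret, random_convex_polygon


def rot(points, deg):
    th = np.deg2rad(deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return np.asarray(points, float) @ R.T


class TestMinFeret:
    @pytest.mark.parametrize(
        "polygon, expected",
        [
            ([(0, 0), (10, 0), (10, 10), (0, 10)], 10.0),  # square
            (rot([(0, 0), (8, 0), (8, 3), (0, 3)], 37.0), 3.0),  # rotated rectangle
            ([(0, 0), (3, 0), (0, 4)], 2.4),  # right triangle: altitude 12/5
        ],
    )
    def test_closed_forms(self, polygon, expected):
        assert fm.min_feret(polygon) == pytest.approx(expected, abs=1e-9)

    def test_rotation_invariance(self, rng):
        poly = random_convex_polygon(rng)
        base = fm.min_feret(poly)
        for deg in rng.uniform(0, 360, 10):
            assert fm.min_feret(rot(poly, deg)) == pytest.approx(base, rel=5e-3)

    def test_brute_force_oracle(self, rng):
        # fibre-scale polygons: the 0.01-degree grid bounds the scan error
        # by diameter * step/2, well below 1e-3 um at this size
        for _ in range(25):
            poly = random_convex_polygon(rng, scale=10.0)
            assert fm.min_feret(poly) == pytest.approx(
                brute_force_min_feret(poly, step_deg=0.01), abs=1e-3
            )

    def test_equals_convex_hull_value(self, rng):
        # star-shaped (concave) polygon: width is a hull property
        angles = np.sort(rng.uniform(0, 2 * np.pi, 14))
        radii = np.where(np.arange(14) % 2 == 0, 30.0, rng.uniform(10, 28, 14))
        star = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        from scipy.spatial import ConvexHull

        hv = star[ConvexHull(star).vertices]
        assert fm.min_feret(star) == pytest.approx(fm.min_feret(hv), abs=1e-12)

    def test_degenerate_polygon_raises(self):
        with pytest.raises(ValueError):
            fm.min_feret([(0, 0), (1, 1), (2, 2)])  # collinear
        with pytest.raises(ValueError):
            fm.min_feret([(0, 0), (1, 1)])

    def test_mfd_bounded_by_max_feret(self, rng):
        poly = random_convex_polygon(rng)
        assert fm.min_feret(poly) <= fm.max_feret(poly)


class TestSegmentation:
    def test_single_dark_disc(self):
        img = np.full((100, 100), 200, np.uint8)
        rr, cc = disk((50, 50), 20)
        img[rr, cc] = 30
        labels = fm.segment_fibres(img)
        assert labels.max() == 1

    def test_watershed_seals_one_pixel_gap(self):
        # two dark discs whose dividing wall has a 1-px hole
        img = np.full((120, 200), 220, np.uint8)
        rr, cc = disk((60, 60), 28)
        img[rr, cc] = 30
        rr, cc = disk((60, 130), 28)
        img[rr, cc] = 30
        img[:, 93:97] = 220  # wall between the discs
        img[60, 93:97] = 30  # ... breached by a small gap
        labels = fm.segment_fibres(img, min_distance=10)
        rois = fm.fibre_metrics(labels, pixel_size=1.0)  # drops the gap sliver
        assert len(rois) == 2
        assert labels[60, 60] != labels[60, 130]  # discs kept apart

    def test_elongated_fibre_not_oversplit(self):
        # a 30x80 dark rectangle has a distance-transform ridge with many
        # peaks; the boundary-evidence merge must keep it as one fibre
        img = np.full((120, 160), 220, np.uint8)
        img[45:75, 40:120] = 30
        labels = fm.segment_fibres(img, min_distance=7)
        assert labels.max() == 1

    def test_uniform_image_raises(self):
        with pytest.raises(fm.EmptyFieldError):
            fm.segment_fibres(np.full((64, 64), 200, np.uint8), threshold=100)

    def test_correction_mask_splits(self):
        img = np.full((100, 180), 220, np.uint8)
        img[30:70, 30:150] = 30
        mask = np.zeros_like(img)
        mask[:, 88:92] = 1  # painted boundary
        labels = fm.segment_fibres(img, correction_mask=mask)
        assert labels.max() == 2


class TestFibreMetrics:
    def test_square_label_metrics(self):
        labels = np.zeros((40, 40), int)
        labels[10:30, 10:30] = 1
        rois = fm.fibre_metrics(labels, pixel_size=0.5)
        assert len(rois) == 1
        assert rois[0].mfd == pytest.approx(10.0, abs=1e-6)
        assert rois[0].csa == pytest.approx(100.0, rel=0.01)  # chamfered corners
        assert rois[0].csa <= np.pi / 4 * fm.max_feret(rois[0].polygon) ** 2

    def test_pixel_size_scale_equivariance(self):
        labels = np.zeros((50, 50), int)
        labels[10:30, 15:40] = 1
        r1 = fm.fibre_metrics(labels, pixel_size=0.5)[0]
        r2 = fm.fibre_metrics(labels, pixel_size=1.0)[0]
        assert r2.mfd == pytest.approx(2 * r1.mfd)
        assert r2.csa == pytest.approx(4 * r1.csa)

    def test_border_exclusion_and_min_area(self):
        labels = np.zeros((60, 60), int)
        labels[0:20, 0:20] = 1  # touches border
        labels[30:50, 30:50] = 2
        labels[25, 25] = 3  # sub-minimum speck
        rois = fm.fibre_metrics(labels, pixel_size=1.0)
        assert [r.fibre_id for r in rois] == [2]
        rois_all = fm.fibre_metrics(labels, pixel_size=1.0, exclude_border=False)
        assert sorted(r.fibre_id for r in rois_all) == [1, 2]

    def test_roundtrip_on_synthetic_map(self):
        fmap = syn.make_fibre_map(150, 40.0, 0.25, 0.5, seed=11)
        labels = fm.segment_fibres(fmap.boundary_image)
        rois = fm.fibre_metrics(labels, fmap.pixel_size)
        assert abs(len(rois) - 150) <= 0.05 * 150
        measured = np.median([r.mfd for r in rois])
        assert measured == pytest.approx(np.median(fmap.true_mfd), abs=1.0)


class TestRout:
    def test_single_spike_flagged(self):
        x = np.zeros(100)
        x[42] = 100.0
        flags = fm.rout_outliers(x)
        assert flags[42] and flags.sum() == 1

    def test_constant_sample_no_flags(self):
        assert fm.rout_outliers(np.ones(50)).sum() == 0

    def test_false_positive_control_on_clean_normal(self):
        z = np.random.default_rng(7).normal(0, 1, 1000)
        assert fm.rout_outliers(z, q=0.01).mean() <= 0.02

    def test_small_sample_warns_and_passes(self):
        with pytest.warns(UserWarning):
            flags = fm.rout_outliers([1.0, 2.0, 3.0])
        assert not flags.any()

    def test_contaminated_sample(self, rng):
        x = np.concatenate([rng.normal(40, 4, 500), [400.0, -300.0]])
        flags = fm.rout_outliers(x)
        assert flags[-1] and flags[-2]


class TestMfdSummary:
    def test_constant_values(self):
        s = fm.mfd_summary(np.full(100, 40.0))
        assert s.median_mfd == 40.0 and s.cov == 0.0
        assert s.histogram.sum() == pytest.approx(1.0)
        # 40 falls in the left-closed [40, 45) bin
        assert s.bin_edges[np.argmax(s.histogram)] == 40.0

    def test_bodyweight_normalisation(self):
        s = fm.mfd_summary([30.0, 40.0, 50.0], bodyweight_kg=10.0, min_n=3)
        assert s.median_mfd == 40.0
        assert s.normalised_median_bw == pytest.approx(4.0)
        assert s.normalised_median_femur is None  # absent covariate: absent field

    def test_cov_estimate_from_lognormal(self):
        g = np.random.default_rng(5)
        vals = g.lognormal(np.log(40), np.sqrt(np.log1p(0.25 ** 2)), 5000)
        s = fm.mfd_summary(vals)
        assert 0.23 <= s.cov <= 0.27
        assert s.n_fibres_plausible

    def test_cov_scale_invariance(self):
        g = np.random.default_rng(2)
        vals = g.lognormal(np.log(40), 0.2, 200)
        s1 = fm.mfd_summary(vals)
        s2 = fm.mfd_summary(vals * 3.7)
        assert s2.cov == pytest.approx(s1.cov, rel=1e-12)
        assert s2.median_mfd == pytest.approx(3.7 * s1.median_mfd, rel=1e-12)

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            fm.mfd_summary([40.0] * 10)


class TestRevertants:
    @pytest.mark.parametrize(
        "n_rev, n_total, expected",
        [(3, 3000, 0.1), (0, 2500, 0.0), (1, 1000, 0.1)],
    )
    def test_percentages(self, n_rev, n_total, expected):
        assert fm.revertant_fraction(n_rev, n_total).percent == pytest.approx(expected)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            fm.revertant_fraction(1, 0)
        with pytest.raises(ValueError):
            fm.revertant_fraction(5, 3)
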