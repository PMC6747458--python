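"""Counting-chain semantics, with brute-force oracles for segmentation
and de-duplication."""

import numpy as np
import pytest

from gliaquant.detect import (
    DetectionParams,
    EmptyFieldError,
    SPOT_PARAMS,
    area_fraction,
    count_cells,
    count_spots,
    dedupe_centroids,
    normalize_peak,
    project,
    segment,
    threshold_floor,
)
from gliaquant.synthetic import generate_layer_field, generate_vertical_spots
from gliaquant.types import CellTruth, Field, FieldGeometry, ZStack
from gliaquant.synthetic import render_cell


def F(pixels, px=1.0, **kw):
    return Field(np.asarray(pixels, dtype=float), px, **kw)


# ---------------------------------------------------------------------------
# independent oracles

def flood_fill_count(mask: np.ndarray, connectivity: int) -> int:
    """Brute-force BFS flood fill, independent of scipy labelling."""
    mask = mask.copy()
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    n = 0
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                n += 1
                stack = [(r, c)]
                mask[r, c] = False
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc]:
                            mask[nr, nc] = False
                            stack.append((nr, nc))
    return n


def union_find_clusters(points: np.ndarray, min_distance: float) -> int:
    """O(n²) union-find over the strict-distance graph."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) < min_distance:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


# ---------------------------------------------------------------------------

class TestProject:
    def test_identical_sections_mean_is_section(self):
        s = F(np.arange(16).reshape(4, 4))
        st = ZStack([s, F(s.pixels), F(s.pixels)])
        np.testing.assert_array_equal(project(st, "mean").pixels, s.pixels)

    def test_mean_of_zero_and_ten(self):
        st = ZStack([F(np.zeros((3, 3))), F(np.full((3, 3), 10.0))])
        np.testing.assert_allclose(project(st).pixels, 5.0)

    def test_mean_matches_arithmetic_oracle(self, rng):
        secs = [F(rng.uniform(0, 1, (8, 8))) for _ in range(3)]
        st = ZStack(secs)
        oracle = (secs[0].pixels + secs[1].pixels + secs[2].pixels) / 3.0
        np.testing.assert_allclose(project(st, "mean").pixels, oracle, rtol=1e-12)

    def test_max_mode(self, rng):
        secs = [F(rng.uniform(0, 1, (6, 6))) for _ in range(4)]
        oracle = np.max([s.pixels for s in secs], axis=0)
        np.testing.assert_array_equal(project(ZStack(secs), "max").pixels, oracle)

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            project(ZStack([F(np.ones((2, 2)))]), "median")


class TestNormalizePeak:
    def test_peak_becomes_one(self):
        f = F([[0, 250], [500, 100]])
        out = normalize_peak(f)
        assert out.pixels.max() == 1.0
        assert out.pixels[1, 0] == 1.0

    def test_identity_when_already_normalized(self):
        f = F([[0.2, 1.0], [0.5, 0.0]])
        np.testing.assert_array_equal(normalize_peak(f).pixels, f.pixels)

    def test_scale_invariance(self, rng):
        pix = rng.uniform(0, 3, (10, 10))
        a = normalize_peak(F(pix)).pixels
        b = normalize_peak(F(pix * 17.3)).pixels
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_all_zero_field_rejected(self):
        with pytest.raises(EmptyFieldError):
            normalize_peak(F(np.zeros((4, 4))))


class TestThresholdFloor:
    def test_values_below_zeroed_at_boundary_retained(self):
        f = F([[0.19, 0.20], [0.21, 1.0]])
        out = threshold_floor(f, 0.2)
        np.testing.assert_array_equal(out.pixels, [[0.0, 0.20], [0.21, 1.0]])

    def test_threshold_zero_is_identity(self, rng):
        pix = rng.uniform(0, 1, (6, 6))
        np.testing.assert_array_equal(threshold_floor(F(pix), 0.0).pixels, pix)

    def test_constant_below_threshold_goes_dark(self):
        out = threshold_floor(F(np.full((5, 5), 0.5)), 0.6)
        assert not out.pixels.any()

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 2.0])
    def test_invalid_threshold(self, bad):
        with pytest.raises(ValueError):
            threshold_floor(F(np.ones((2, 2)) * 0.5), bad)

    def test_retains_values_not_binarized(self, rng):
        pix = rng.uniform(0, 1, (12, 12))
        out = threshold_floor(F(pix), 0.3).pixels
        kept = out > 0
        np.testing.assert_array_equal(out[kept], pix[pix >= 0.3])


class TestSegment:
    def test_two_blobs_split_by_zero_row(self):
        pix = np.zeros((5, 5))
        pix[0, :2] = 1.0
        pix[3:, 3:] = 1.0
        assert len(segment(F(pix), 8)) == 2

    def test_diagonal_touch_depends_on_connectivity(self):
        pix = np.zeros((4, 4))
        pix[1, 1] = pix[2, 2] = 1.0
        assert len(segment(F(pix), 8)) == 1
        assert len(segment(F(pix), 4)) == 2

    def test_empty_support_no_segments(self):
        assert segment(F(np.zeros((4, 4)))) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(25):
            pix = (rng.random((24, 24)) < 0.25).astype(float) * rng.uniform(
                0.5, 1.0, (24, 24)
            )
            got = len(segment(F(pix), connectivity))
            assert got == flood_fill_count(pix > 0, connectivity)

    def test_center_of_mass_is_intensity_weighted(self):
        pix = np.zeros((1, 4))
        pix[0, 0] = 3.0
        pix[0, 1] = 1.0
        (seg,) = segment(F(pix, px=1.0), 8)
        # COM column = (0*3 + 1*1)/4 = 0.25 → physical x = 0.75
        assert seg.center_um[0] == pytest.approx(0.75)
        assert seg.n_pixels == 2


class TestDedupe:
    def test_close_pair_merges(self):
        assert len(dedupe_centroids([(0, 0), (5, 0)], 10)) == 1

    def test_far_pair_kept(self):
        assert len(dedupe_centroids([(0, 0), (15, 0)], 10)) == 2

    def test_exact_min_distance_not_merged(self):
        # the rule merges strictly closer pairs only
        assert len(dedupe_centroids([(0, 0), (10, 0)], 10)) == 2

    def test_chain_is_transitively_merged(self):
        reps = dedupe_centroids([(0, 0), (8, 0), (16, 0)], 10)
        assert len(reps) == 1
        assert reps[0] == pytest.approx((8.0, 0.0))

    def test_matches_union_find_oracle(self, rng):
        for _ in range(30):
            pts = rng.uniform(0, 100, size=(50, 2))
            got = len(dedupe_centroids([tuple(p) for p in pts], 12.0))
            assert got == union_find_clusters(pts, 12.0)

    def test_representative_is_cluster_centroid(self):
        reps = dedupe_centroids([(0, 0), (4, 0), (2, 3)], 10)
        assert reps == [pytest.approx((2.0, 1.0))]


class TestCountCells:
    def _three_cell_field(self):
        geo = FieldGeometry(n_pixels=512)
        f = Field(np.zeros(geo.shape), geo.pixel_size)
        centers = [(100.0, 100.0), (140.0, 100.0), (100.0, 140.0)]
        for c in centers:
            f = render_cell(CellTruth(c, 3.5, peak_intensity=0.9), f)
        return f, centers

    def test_three_planted_cells_counted_and_located(self):
        f, centers = self._three_cell_field()
        res = count_cells(f, DetectionParams(min_distance=12))
        assert res.count == 3
        for cx, cy in centers:
            nearest = min(np.hypot(gx - cx, gy - cy) for gx, gy in res.centroids)
            assert nearest < 1.0

    def test_dim_cell_below_relative_threshold_removed(self):
        geo = FieldGeometry(n_pixels=256)
        f = Field(np.zeros(geo.shape), geo.pixel_size)
        f = render_cell(CellTruth((100, 100), 3.5, peak_intensity=1.0), f)
        f = render_cell(CellTruth((250, 250), 3.5, peak_intensity=0.15), f)
        res = count_cells(f)
        assert res.count == 1

    def test_noise_floor_guard_reports_blank(self, rng):
        geo = FieldGeometry(n_pixels=128)
        pix = np.clip(rng.normal(0.01, 0.005, geo.shape), 0, None)
        res = count_cells(Field(pix, geo.pixel_size))
        assert res.blank and res.count == 0

    def test_count_non_increasing_in_min_distance(self, rng, small_geometry):
        f, _ = generate_layer_field(20, rng=rng, geometry=small_geometry)
        counts = [
            count_cells(f, DetectionParams(min_distance=md)).count
            for md in (4, 8, 12, 20, 40, 80)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_count_non_increasing_in_low_threshold(self, rng, small_geometry):
        f, _ = generate_layer_field(20, rng=rng, geometry=small_geometry)
        counts = [
            count_cells(f, DetectionParams(low_threshold=t)).count
            for t in (0.05, 0.2, 0.4, 0.6, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_stack_input_projected_then_counted(self, rng, small_geometry):
        from gliaquant.synthetic import generate_layer_stack

        stack, truths = generate_layer_stack(
            10, rng=rng, geometry=small_geometry
        )
        res = count_cells(stack)
        assert res.count == len(truths)


class TestCountSpots:
    def test_planted_spots_recovered(self, small_geometry):
        field, truths = generate_vertical_spots(
            12, small_geometry, rng=np.random.default_rng(5)
        )
        assert count_spots(field).count == 12

    def test_two_close_spots_merge(self):
        geo = FieldGeometry(n_pixels=256)
        f = Field(np.zeros(geo.shape), geo.pixel_size)
        for c in [(100.0, 100.0), (102.5, 100.0)]:
            f = render_cell(
                CellTruth(c, 1.4, peak_intensity=0.9, kind="vertical_spot"), f
            )
        assert count_spots(f, SPOT_PARAMS).count == 1

    def test_blank_plane_counts_zero(self, rng, small_geometry):
        field, _ = generate_vertical_spots(0, small_geometry, rng=rng)
        assert count_spots(field).count == 0


class TestAreaFraction:
    def test_zero_field_zero_percent(self):
        res = area_fraction(F(np.zeros((8, 8))), 0.5)
        assert res.percent_area == 0.0

    def test_binary_half_set_is_fifty_percent(self):
        pix = np.zeros((10, 10))
        pix[:5] = 1.0
        res = area_fraction(F(pix), 0.5)
        assert res.percent_area == 50.0
        assert res.n_pixels_above == 50

    def test_matches_pixel_count_oracle(self, rng):
        pix = rng.uniform(0, 1, (32, 32))
        res = area_fraction(F(pix), 0.37)
        assert res.percent_area == 100.0 * np.count_nonzero(pix >= 0.37) / pix.size

    def test_invariant_under_monotone_rescale(self, rng):
        pix = rng.uniform(0, 1, (16, 16))
        a = area_fraction(F(pix), 0.4).percent_area
        b = area_fraction(F(pix * 5 + 2), 0.4 * 5 + 2).percent_area
        assert a == b

    def test_otsu_threshold_reported(self, rng, small_geometry):
        f, _ = generate_layer_field(10, rng=rng, geometry=small_geometry)
        res = area_fraction(f, "otsu")
        assert 0 < res.threshold_used < f.pixels.max()
        assert res.percent_area == 100.0 * res.n_pixels_above / res.n_pixels_total
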