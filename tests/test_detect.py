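from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pasturediff import (
    DifferenceImage,
    GeoTransform,
    SpatialThreshold,
    SpectralThreshold,
    TruthSet,
    extract_polygons,
    filter_by_area,
    read_polygons_geojson,
    suggest_threshold,
    threshold_mask,
    write_polygons_geojson,
)
from pasturediff.errors import EmptySampleError, ThresholdError
from pasturediff.evaluate import Animal

T = GeoTransform(0.0, 100.0, 0.25)


def diff_of(values, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return DifferenceImage(values=values, transform=T, mask=mask)


def flood_fill_components(mask, connectivity):
    """Independent BFS component counter/labeller (the oracle)."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and not seen[r, c]:
                comp = []
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    rr, cc = q.popleft()
                    comp.append((rr, cc))
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if (
                            0 <= nr < mask.shape[0]
                            and 0 <= nc < mask.shape[1]
                            and mask[nr, nc]
                            and not seen[nr, nc]
                        ):
                            seen[nr, nc] = True
                            q.append((nr, nc))
                comps.append(frozenset(comp))
    return comps


class TestThresholdMask:
    def test_zero_threshold_selects_everything_unmasked(self):
        d = diff_of(np.random.default_rng(0).random((5, 5)))
        d.mask[1, 1] = True
        m = threshold_mask(d, SpectralThreshold(t_low=0.0))
        assert m.sum() == 24 and not m[1, 1]

    def test_threshold_above_maximum_selects_nothing(self):
        d = diff_of([[0.1, 0.2], [0.3, 0.4]])
        assert threshold_mask(d, SpectralThreshold(t_low=0.5)).sum() == 0

    def test_lower_bound_is_inclusive(self):
        d = diff_of([[0.1, 0.5, 0.9]])
        m = threshold_mask(d, SpectralThreshold(t_low=0.5))
        np.testing.assert_array_equal(m, [[False, True, True]])

    def test_upper_bound_is_inclusive(self):
        d = diff_of([[0.1, 0.5, 0.9]])
        m = threshold_mask(d, SpectralThreshold(t_low=0.2, t_high=0.5))
        np.testing.assert_array_equal(m, [[False, True, False]])

    def test_raising_t_low_is_monotone(self):
        d = diff_of(np.random.default_rng(1).random((20, 20)))
        counts = [
            threshold_mask(d, SpectralThreshold(t_low=t)).sum()
            for t in (0.0, 0.2, 0.4, 0.6, 0.8)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_interval_rejected(self):
        with pytest.raises(ThresholdError):
            SpectralThreshold(t_low=2.0, t_high=1.0)


class TestSuggestThreshold:
    def truth_at(self, *points):
        return TruthSet(
            animals=[
                Animal(id=f"a{i}", pos_t1=p, pos_t2=p) for i, p in enumerate(points)
            ]
        )

    def test_constant_sample_returns_constant(self):
        d = diff_of(np.full((9, 9), 0.42))
        st_ = suggest_threshold(d, self.truth_at((1.0, 99.0)))
        assert st_.t_low == pytest.approx(0.42)

    def test_matches_order_statistic_oracle(self):
        # values 1..100 laid out in a 10x10 grid; one animal window covers
        # a known subset -> compare to a sort-based quantile computation
        vals = np.arange(1, 101, dtype=float).reshape(10, 10)
        d = DifferenceImage(values=vals, transform=GeoTransform(0, 2.5, 0.25), mask=np.zeros((10, 10), bool))
        truth = self.truth_at((1.25, 1.25))  # pixel (5, 5), window rows/cols 4..6
        st_ = suggest_threshold(d, truth, percentile=0.05)
        window = vals[4:7, 4:7].ravel()
        pooled = np.sort(np.concatenate([window, window]))  # t1 and t2 windows
        h = 0.05 * (len(pooled) - 1)
        lo = int(np.floor(h))
        oracle = pooled[lo] + (h - lo) * (pooled[lo + 1] - pooled[lo])
        assert st_.t_low == pytest.approx(oracle, rel=1e-12)

    def test_fully_masked_truth_rejected(self):
        d = diff_of(np.ones((9, 9)), mask=np.ones((9, 9), bool))
        d.mask[0, 0] = False
        d.values[:] = 1.0
        with pytest.raises(EmptySampleError):
            suggest_threshold(d, self.truth_at((1.0, 98.0)))

    def test_percentile_outside_unit_interval_rejected(self):
        d = diff_of(np.ones((9, 9)))
        with pytest.raises(ThresholdError):
            suggest_threshold(d, self.truth_at((1.0, 99.0)), percentile=1.5)


class TestExtractPolygons:
    def test_single_pixel_square(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 3] = True
        (poly,) = extract_polygons(mask, T)
        assert poly.area_m2 == pytest.approx(0.0625)
        assert poly.pixel_count == 1
        # boundary is the exact 0.25 m pixel square
        assert poly.geometry.area == pytest.approx(0.0625)
        assert poly.geometry.length == pytest.approx(1.0)
        assert poly.centroid == pytest.approx(T.pixel_to_map(2, 3))

    def test_diagonal_pixels_joined_under_8_connectivity(self):
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(extract_polygons(mask, T, connectivity=8)) == 1
        assert len(extract_polygons(mask, T, connectivity=4)) == 2

    def test_empty_mask_gives_empty_list(self):
        assert extract_polygons(np.zeros((4, 4), bool), T) == []

    def test_deterministic_ordering_by_min_row_col(self):
        mask = np.zeros((10, 10), bool)
        mask[8, 1] = mask[0, 5] = mask[4, 2] = True
        tops = [tuple(p.pixels[0]) for p in extract_polygons(mask, T)]
        assert tops == [(0, 5), (4, 2), (8, 1)]

    @given(st.integers(0, 2**31 - 1), st.sampled_from([4, 8]))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_components_match_flood_fill_oracle(self, seed, connectivity):
        mask = np.random.default_rng(seed).random((30, 30)) < 0.35
        polys = extract_polygons(mask, T, connectivity=connectivity)
        oracle = flood_fill_components(mask, connectivity)
        got = {frozenset(map(tuple, p.pixels)) for p in polys}
        assert got == set(oracle)

    def test_partition_property(self):
        mask = np.random.default_rng(5).random((50, 50)) < 0.4
        polys = extract_polygons(mask, T)
        assert sum(p.pixel_count for p in polys) == mask.sum()
        all_pixels = [tuple(px) for p in polys for px in p.pixels]
        assert len(all_pixels) == len(set(all_pixels))

    def test_boundary_traces_pixel_edges(self):
        # an L-shape: union area equals pixel count x cell area, no smoothing
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = mask[2, 1] = mask[2, 2] = True
        (poly,) = extract_polygons(mask, T)
        assert poly.geometry.area == pytest.approx(3 * 0.0625)
        assert poly.geometry.length == pytest.approx(8 * 0.25)


class TestFilterByArea:
    def poly_of(self, n_pixels):
        mask = np.zeros((100, 100), bool)
        mask.ravel()[:n_pixels] = True  # first rows: one connected run
        (poly,) = extract_polygons(mask, T)
        return poly

    @pytest.mark.parametrize(
        "n_pixels,kept",
        [(15, False), (16, True), (160, True), (161, False)],
        ids=["0.9375m2", "1.0m2", "10.0m2", "10.0625m2"],
    )
    def test_area_boundaries(self, n_pixels, kept):
        poly = self.poly_of(n_pixels)
        result = filter_by_area([poly], SpatialThreshold())
        assert (len(result) == 1) == kept

    def test_idempotent_and_monotone(self):
        polys = [self.poly_of(n) for n in (10, 16, 40, 120, 160, 200)]
        st1 = SpatialThreshold(0.99, 10.0)
        once = filter_by_area(polys, st1)
        assert filter_by_area(once, st1) == once
        narrower = filter_by_area(polys, SpatialThreshold(2.0, 8.0))
        assert set(id(p) for p in narrower) <= set(id(p) for p in once)

    def test_order_preserved(self):
        polys = [self.poly_of(n) for n in (160, 16, 40)]
        kept = filter_by_area(polys, SpatialThreshold())
        assert [p.pixel_count for p in kept] == [160, 16, 40]

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ThresholdError):
            SpatialThreshold(min_area=5.0, max_area=1.0)


class TestGeoJSONRoundTrip:
    def test_polygons_round_trip(self, tmp_path):
        mask = np.zeros((20, 20), bool)
        mask[2:6, 2:6] = True
        mask[10:14, 10:13] = True
        polys = extract_polygons(mask, T)
        path = tmp_path / "polys.geojson"
        write_polygons_geojson(polys, path)
        back = read_polygons_geojson(path)
        assert len(back) == 2
        for orig, loaded in zip(polys, back):
            assert loaded.area_m2 == pytest.approx(orig.area_m2)
            assert loaded.pixel_count == orig.pixel_count
            assert loaded.geometry.equals(orig.geometry)
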