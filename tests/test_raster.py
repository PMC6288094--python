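"""Patch extraction: thresholding, Moore labelling, censuses and file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragcrit.raster import (
    DEFAULT_THRESHOLDS,
    BinaryLandscape,
    CoverRaster,
    binarize,
    census_sweep,
    label_patches,
    parse_patch_file_name,
    read_ascii_grid,
    read_geotiff,
    read_patch_sizes,
    write_patch_sizes,
)


def flood_fill_sizes(mask):
    """Independent brute-force 8-connected component sizes (stack flood fill)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    sizes = []
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and not seen[r0, c0]:
                stack = [(r0, c0)]
                seen[r0, c0] = True
                count = 0
                while stack:
                    r, c = stack.pop()
                    count += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < rows
                                and 0 <= cc < cols
                                and mask[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                sizes.append(count)
    return sorted(sizes, reverse=True)


class TestBinarize:
    def test_direct_comparison(self):
        cov = CoverRaster(values=[[50, 10], [30, 30]])
        land = binarize(cov, 30)
        assert land.mask.tolist() == [[True, False], [True, True]]

    def test_all_zero_grid(self):
        cov = CoverRaster(values=np.zeros((5, 5)))
        assert not binarize(cov, 20).mask.any()

    def test_missing_is_non_forest(self, small_cover):
        land = binarize(small_cover, 20)
        assert not land.mask[2, 0]

    @pytest.mark.parametrize("bad", [0, -5, 101])
    def test_threshold_range(self, small_cover, bad):
        with pytest.raises(ValueError):
            binarize(small_cover, bad)

    def test_higher_threshold_is_subset(self, rng):
        cov = CoverRaster(values=rng.integers(0, 101, size=(30, 30)))
        m40 = binarize(cov, 40).mask
        m20 = binarize(cov, 20).mask
        assert not (m40 & ~m20).any()

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            CoverRaster(values=[[120, 10]])


class TestLabelPatches:
    def test_diagonal_adjacency_counts(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = mask[1, 1] = True
        census = label_patches(BinaryLandscape(mask=mask))
        assert census.sizes.tolist() == [2.0]

    def test_checkerboard_is_one_patch(self):
        mask = np.indices((4, 4)).sum(axis=0) % 2 == 0
        census = label_patches(BinaryLandscape(mask=mask))
        assert census.n_patches == 1
        assert census.s_max == 8
        assert flood_fill_sizes(mask) == [8]

    def test_empty_grid(self):
        census = label_patches(BinaryLandscape(mask=np.zeros((4, 4), bool)))
        assert census.n_patches == 0
        assert census.total_forest == 0
        assert np.isnan(census.rs_max)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 20), st.floats(0.2, 0.8))
    def test_matches_flood_fill_oracle(self, seed, side, density):
        mask = np.random.default_rng(seed).random((side, side)) < density
        census = label_patches(BinaryLandscape(mask=mask))
        assert census.sizes.tolist() == flood_fill_sizes(mask)

    def test_conservation(self, rng):
        mask = rng.random((40, 40)) < 0.5
        census = label_patches(BinaryLandscape(mask=mask))
        assert census.total_forest == mask.sum()

    def test_cell_area_scales_sizes(self):
        mask = np.ones((2, 2), bool)
        census = label_patches(BinaryLandscape(mask=mask, cell_area=0.0534))
        assert census.s_max == pytest.approx(4 * 0.0534)


class TestCensusSweep:
    def test_default_sweep_has_five_censuses(self, small_cover):
        censuses = census_sweep(small_cover)
        assert len(censuses) == 5
        assert [c.threshold for c in censuses] == list(DEFAULT_THRESHOLDS)

    def test_monotone_in_threshold(self, rng):
        cov = CoverRaster(values=rng.integers(0, 101, size=(50, 50)))
        censuses = census_sweep(cov)
        totals = [c.total_forest for c in censuses]
        smaxes = [c.s_max for c in censuses]
        assert totals == sorted(totals, reverse=True)
        assert smaxes == sorted(smaxes, reverse=True)

    def test_nestedness(self, rng):
        """Every patch at the higher threshold lies inside one lower-threshold patch."""
        from scipy import ndimage

        cov = CoverRaster(values=rng.integers(0, 101, size=(40, 40)))
        lo = ndimage.label(binarize(cov, 20).mask, structure=np.ones((3, 3)))[0]
        hi_mask = binarize(cov, 40).mask
        hi, n_hi = ndimage.label(hi_mask, structure=np.ones((3, 3)))
        for patch_id in range(1, n_hi + 1):
            parents = np.unique(lo[hi == patch_id])
            assert parents.size == 1 and parents[0] > 0

    def test_empty_thresholds_rejected(self, small_cover):
        with pytest.raises(ValueError):
            census_sweep(small_cover, [])


class TestIO:
    def test_ascii_grid_roundtrip(self, tmp_path):
        path = tmp_path / "cov.asc"
        path.write_text(
            "ncols 3\nnrows 2\nNODATA_value -9\n# comment\n10 -9 30\n55 80 0\n"
        )
        cov = read_ascii_grid(path, year=2001)
        assert cov.shape == (2, 3)
        assert np.isnan(cov.values[0, 1])
        assert cov.values[1, 1] == 80

    def test_geotiff_reader(self, tmp_path):
        import tifffile

        arr = np.array([[10, 50], [200, 80]], dtype=np.uint8)
        path = tmp_path / "cov.tif"
        tifffile.imwrite(path, arr)
        cov = read_geotiff(path)
        assert np.isnan(cov.values[1, 0])  # 200 = water fill
        assert cov.values[1, 1] == 80

    def test_patch_file_roundtrip(self, tmp_path):
        mask = np.zeros((6, 6), bool)
        mask[:2, :2] = True
        mask[4, 4] = True
        census = label_patches(
            BinaryLandscape(mask=mask, threshold=30.0, region_id="AF1", year=2005)
        )
        path = write_patch_sizes(census, tmp_path)
        assert path.name == "AF1_2005_30.csv"
        back = read_patch_sizes(path)
        assert back.sizes.tolist() == census.sizes.tolist()
        assert (back.region_id, back.year, back.threshold) == ("AF1", 2005, 30.0)

    def test_parse_patch_file_name(self):
        assert parse_patch_file_name("SEAS1_2014_25.csv") == ("SEAS1", 2014, 25.0)
        with pytest.raises(ValueError):
            parse_patch_file_name("notaname.csv")
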