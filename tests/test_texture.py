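"""Quantization, co-occurrence counting and GLCM homogeneity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scarpol.polarimetry import CylinderROI
from scarpol.texture import (
    MISSING,
    BirefringenceMap,
    CooccurrenceMatrix,
    QuantizedMap,
    glcm,
    homogeneity,
    homogeneity_feature,
    quantize,
)

COVER_ALL = CylinderROI(center_x=0.0, center_y=0.0, diameter=1e9,
                        z_top=0.0, z_bottom=1e9)


def qmap(codes, L=12):
    return QuantizedMap(levels=np.asarray(codes), L=L,
                        bin_edges=np.linspace(0, 1, L + 1))


class TestQuantize:
    @pytest.mark.parametrize(
        "value,expected_level",
        [
            (0.04, 1),      # first bin, width 1/12
            (0.0, 1),
            (0.95, 12),
            (1.0, 12),      # right edge closes into the top bin
            (1.3, 12),      # above-range clipping
            (1.0 / 12 + 1e-9, 2),
        ],
    )
    def test_binning_arithmetic(self, value, expected_level):
        bmap = BirefringenceMap(values=np.full((6, 6), value))
        q = quantize(bmap, L=12, lo=0.0, hi=1.0)
        assert q.levels[0, 0] == expected_level

    def test_below_range_clips_into_first_bin(self):
        bmap = BirefringenceMap(values=np.full((4, 4), 0.1))
        q = quantize(bmap, L=12, lo=0.2, hi=1.2)
        assert q.levels[0, 0] == 1

    def test_roi_voxels_marked_missing(self):
        bmap = BirefringenceMap(values=np.full((4, 8), 0.5),
                                spacing_z=10.0, spacing_x=10.0)
        roi = CylinderROI(center_x=0.0, center_y=0.0, diameter=25.0,
                          z_top=0.0, z_bottom=15.0)
        q = quantize(bmap, roi=roi)
        # lateral centers 0 and 10 um are within radius 12.5; depths 0, 10
        assert np.sum(q.levels != MISSING) == 2 * 2
        assert q.levels[0, 3] == MISSING

    def test_all_missing_raises(self):
        bmap = BirefringenceMap(values=np.full((4, 4), 0.5))
        roi = CylinderROI(center_x=1e6, center_y=0.0, diameter=1.0,
                          z_top=0.0, z_bottom=1.0)
        with pytest.raises(ValueError, match="all-missing"):
            quantize(bmap, roi=roi)

    def test_invalid_parameters_rejected(self):
        bmap = BirefringenceMap(values=np.full((4, 4), 0.5))
        with pytest.raises(ValueError):
            quantize(bmap, L=1)
        with pytest.raises(ValueError):
            quantize(bmap, lo=1.0, hi=1.0)


def loop_glcm(codes, dz, dx, L):
    """Exhaustive double-loop oracle for directed pair counting."""
    codes = np.asarray(codes)
    if codes.ndim == 2:
        codes = codes[:, :, None]
    counts = np.zeros((L, L))
    n_z, n_x, n_y = codes.shape
    for y in range(n_y):
        for z in range(n_z):
            for x in range(n_x):
                z2, x2 = z + dz, x + dx
                if not (0 <= z2 < n_z and 0 <= x2 < n_x):
                    continue
                a, b = codes[z, x, y], codes[z2, x2, y]
                if a != MISSING and b != MISSING:
                    counts[a - 1, b - 1] += 1
    return counts / counts.sum()


class TestGlcm:
    def test_constant_image_all_mass_on_diagonal(self):
        q = qmap(np.full((10, 4), 5))
        P = glcm(q, offset=(5, 0)).P
        assert P[4, 4] == 1.0
        assert P.sum() == 1.0

    def test_ten_voxel_column_all_pairs_cross_level(self):
        codes = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2]).reshape(10, 1)
        P = glcm(qmap(codes, L=2), offset=(5, 0)).P
        assert P[0, 1] == 1.0  # all 5 pairs are (1, 2)

    def test_disjoint_regions_weighted_by_pair_count(self):
        # column A: 8 voxels of level 1 -> 3 pairs; column B: 6 voxels of
        # level 2 (then missing) -> 1 pair
        codes = np.zeros((8, 2), dtype=int)
        codes[:, 0] = 1
        codes[:6, 1] = 2
        P = glcm(qmap(codes, L=2), offset=(5, 0)).P
        assert P[0, 0] == pytest.approx(0.75)
        assert P[1, 1] == pytest.approx(0.25)

    def test_counting_is_directed(self):
        codes = np.array([1, 2]).reshape(2, 1)
        P = glcm(qmap(codes, L=2), offset=(1, 0)).P
        assert P[0, 1] == 1.0 and P[1, 0] == 0.0

    def test_matches_loop_oracle_on_random_grids(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            L = int(rng.integers(2, 13))
            nz, nx = rng.integers(2, 20, 2)
            codes = rng.integers(0, L + 1, (nz, nx))
            dz = int(rng.integers(0, min(nz, 6)))
            dx = int(rng.integers(0, min(nx, 4)))
            if dz == 0 and dx == 0:
                dz = 1
            codes[0, 0] = L  # guarantee at least some non-missing
            codes[min(dz, nz - 1), min(dx, nx - 1)] = L
            try:
                P = glcm(qmap(codes, L=L), offset=(dz, dx)).P
            except ValueError:
                continue
            np.testing.assert_allclose(P, loop_glcm(codes, dz, dx, L), atol=1e-12)

    def test_matches_skimage_graycomatrix(self):
        skimage_feature = pytest.importorskip("skimage.feature")
        rng = np.random.default_rng(3)
        for _ in range(10):
            L = 8
            img = rng.integers(0, L, (16, 16))
            # skimage: angle +pi/2 with distance d pairs (r, c) -> (r+d, c)
            ref = skimage_feature.graycomatrix(
                img.astype(np.uint8), distances=[5], angles=[np.pi / 2],
                levels=L, symmetric=False, normed=True,
            )[:, :, 0, 0]
            P = glcm(qmap(img + 1, L=L), offset=(5, 0)).P
            np.testing.assert_allclose(P, ref, atol=1e-12)

    def test_zero_valid_pairs_raises(self):
        q = qmap(np.full((3, 2), 4))
        with pytest.raises(ValueError):
            glcm(q, offset=(5, 0))
        codes = np.zeros((10, 2), dtype=int)
        codes[0, 0] = 1  # lone voxel: no partner at the offset
        with pytest.raises(ValueError, match="no valid voxel pairs"):
            glcm(qmap(codes, L=2), offset=(5, 0))


class TestHomogeneity:
    def test_diagonal_mass_gives_one(self):
        P = np.zeros((12, 12))
        P[3, 3] = 0.4
        P[7, 7] = 0.6
        assert homogeneity(CooccurrenceMatrix(P=P, offset=(5, 0), normalized=True)) == 1.0

    def test_adjacent_level_mass_gives_half(self):
        P = np.zeros((12, 12))
        P[0, 1] = 0.5
        P[4, 3] = 0.5
        assert homogeneity(
            CooccurrenceMatrix(P=P, offset=(5, 0), normalized=True)
        ) == pytest.approx(0.5)

    def test_extreme_level_distance(self):
        P = np.zeros((12, 12))
        P[0, 11] = 1.0
        assert homogeneity(
            CooccurrenceMatrix(P=P, offset=(5, 0), normalized=True)
        ) == pytest.approx(1.0 / 12.0)

    def test_unnormalized_matrix_rejected(self):
        P = np.zeros((4, 4))
        P[0, 0] = 3.0
        with pytest.raises(ValueError):
            homogeneity(CooccurrenceMatrix(P=P, offset=(5, 0), normalized=False))

    def test_transpose_invariance(self):
        rng = np.random.default_rng(8)
        P = rng.uniform(0, 1, (12, 12))
        P /= P.sum()
        a = homogeneity(CooccurrenceMatrix(P=P, offset=(5, 0), normalized=True))
        b = homogeneity(CooccurrenceMatrix(P=P.T, offset=(5, 0), normalized=True))
        assert a == pytest.approx(b, abs=1e-14)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounded_between_zero_and_one(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 13))
        P = rng.uniform(0, 1, (L, L))
        P /= P.sum()
        h = homogeneity(CooccurrenceMatrix(P=P, offset=(5, 0), normalized=True))
        assert 0.0 <= h <= 1.0
        # 1 iff all mass on the diagonal
        assert (h == 1.0) == np.allclose(P, np.diag(np.diag(P)))


class TestHomogeneityFeature:
    def test_uniform_map_gives_one(self):
        bmap = BirefringenceMap(values=np.full((40, 40), 0.5))
        assert homogeneity_feature(bmap, roi=COVER_ALL) == 1.0

    def test_five_pixel_alternation_gives_half(self):
        # blocks of 5 axial pixels alternating between bin-1 and bin-2
        # values: at offset 5 every pair differs by exactly one level
        z = np.arange(40)
        col = np.where((z // 5) % 2 == 0, 0.04, 0.12)
        bmap = BirefringenceMap(values=np.tile(col[:, None], (1, 8)))
        assert homogeneity_feature(bmap) == pytest.approx(0.5)

    def test_widening_range_drives_hom_to_one(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.0, 1.0, (30, 30))
        bmap = BirefringenceMap(values=vals)
        homs = [homogeneity_feature(bmap, hi=hi) for hi in (1.0, 4.0, 1000.0)]
        assert homs[0] < homs[1] < homs[2]
        assert homs[2] == 1.0  # single occupied level in the limit

    def test_spot_field_less_homogeneous_than_uniform(self):
        from scarpol.synthetic_data import BirefFieldSpec, synth_biref_map

        spec = BirefFieldSpec(n_z=64, n_x=64, amplitude=0.5, density=80.0)
        uniform_hom = homogeneity_feature(
            BirefringenceMap(values=np.full((64, 64), spec.base))
        )
        for seed in range(20):
            bmap = synth_biref_map(spec, seed=seed)
            assert homogeneity_feature(bmap) < uniform_hom
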