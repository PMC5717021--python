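"""Birefringence texture: quantization, co-occurrence matrix, homogeneity.

Mature scar collagen is uniformly aligned, so its birefringence map is
spatially smooth; normal dermis shows a spot-like, heterogeneous pattern.
The texture feature used to separate the two is the gray-level
co-occurrence matrix (GLCM) *homogeneity*: the birefringence inside the
lesion ROI is quantized into L equal-width levels (default 12 over
0-1 deg/um), pairs of voxels at a fixed axial offset (default 5 pixels)
are counted into an L x L joint frequency matrix P, and

    Hom = sum_{i,j} P(i, j) / (1 + |i - j|)

which is 1 when co-occurring levels are always identical and approaches
0 as they diverge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .polarimetry import CylinderROI, cylinder_mask

__all__ = [
    "BirefringenceMap",
    "QuantizedMap",
    "CooccurrenceMatrix",
    "quantize",
    "glcm",
    "homogeneity",
    "homogeneity_feature",
]

#: integer code for voxels outside the ROI
MISSING = 0


@dataclass
class BirefringenceMap:
    """Birefringence field in deg/um on a (z, x) or (z, x, y) grid."""

    values: np.ndarray
    spacing_z: float = 1.0
    spacing_x: float = 1.0
    spacing_y: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("birefringence map must be 2-D (z, x) or 3-D (z, x, y)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite birefringence values")
        if self.values.min() < 0:
            raise ValueError("birefringence must be >= 0")


@dataclass
class QuantizedMap:
    """Integer level codes 1..L; 0 marks out-of-ROI (missing) voxels."""

    levels: np.ndarray
    L: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.levels.min() < 0 or self.levels.max() > self.L:
            raise ValueError("codes must lie in {0 (missing), 1..L}")
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")


@dataclass
class CooccurrenceMatrix:
    """L x L joint frequency of level pairs at a fixed (dz, dx) offset."""

    P: np.ndarray
    offset: tuple
    normalized: bool

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("P must be square")
        if self.P.min() < 0:
            raise ValueError("P must be nonnegative")
        if self.normalized and abs(self.P.sum() - 1.0) > 1e-12:
            raise ValueError("normalized P must sum to 1")


def quantize(
    bmap: BirefringenceMap,
    L: int = 12,
    lo: float = 0.0,
    hi: float = 1.0,
    roi: CylinderROI | None = None,
) -> QuantizedMap:
    """Equal-width quantization of birefringence into levels 1..L.

    Bins partition [lo, hi); values below lo clip into level 1 and values
    at or above hi clip into level L (the right edge closes into the top
    bin).  Voxels outside the ROI receive the missing code.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if not (lo < hi):
        raise ValueError("lo must be < hi")
    v = bmap.values
    width = (hi - lo) / L
    codes = np.floor((v - lo) / width).astype(int) + 1
    codes = np.clip(codes, 1, L)
    if roi is not None:
        if v.ndim == 2:
            n_z, n_x = v.shape
            mask = cylinder_mask(n_x, 1, bmap.spacing_x, 1.0, roi)[:, 0]
            lateral = np.broadcast_to(mask[None, :], v.shape)
        else:
            n_z, n_x, n_y = v.shape
            mask = cylinder_mask(n_x, n_y, bmap.spacing_x, bmap.spacing_y, roi)
            lateral = np.broadcast_to(mask[None, :, :], v.shape)
        zs = np.arange(v.shape[0]) * bmap.spacing_z
        axial = (zs >= roi.z_top) & (zs <= roi.z_bottom)
        inside = lateral & axial.reshape((-1,) + (1,) * (v.ndim - 1))
        codes = np.where(inside, codes, MISSING)
    if not np.any(codes != MISSING):
        raise ValueError("ROI excludes every voxel (all-missing quantization)")
    edges = lo + width * np.arange(L + 1)
    return QuantizedMap(levels=codes, L=L, bin_edges=edges)


def _pair_slices(n: int, d: int) -> tuple:
    """Source/target slices along one axis for an integer offset d."""
    if d >= 0:
        return slice(0, n - d), slice(d, n)
    return slice(-d, n), slice(0, n + d)


def glcm(q: QuantizedMap, offset: tuple = (5, 0)) -> CooccurrenceMatrix:
    """Directed co-occurrence matrix at offset (dz, dx), in pixels.

    Pairs (v, v + offset) with both members inside the ROI are counted
    source -> target without symmetrization; the counts are normalized to
    sum to 1.  For 3-D maps, pairs are accumulated over all frames into a
    single matrix.  Raises if no valid pair exists.
    """
    dz, dx = int(offset[0]), int(offset[1])
    codes = q.levels
    if codes.ndim == 2:
        frames = codes[:, :, None]
    else:
        frames = codes
    n_z, n_x, n_y = frames.shape
    if abs(dz) >= n_z or abs(dx) >= n_x:
        raise ValueError("offset exceeds grid extent: no voxel pairs")
    sz, tz = _pair_slices(n_z, dz)
    sx, tx = _pair_slices(n_x, dx)
    src = frames[sz, sx, :]
    tgt = frames[tz, tx, :]
    valid = (src != MISSING) & (tgt != MISSING)
    total = int(valid.sum())
    if total == 0:
        raise ValueError("no valid voxel pairs inside the ROI at this offset")
    L = q.L
    flat = (src[valid] - 1) * L + (tgt[valid] - 1)
    counts = np.bincount(flat, minlength=L * L).reshape(L, L).astype(float)
    return CooccurrenceMatrix(P=counts / total, offset=(dz, dx), normalized=True)


def homogeneity(P: CooccurrenceMatrix) -> float:
    """GLCM homogeneity sum_{ij} P(i,j) / (1 + |i-j|), in [0, 1]."""
    if not P.normalized:
        raise ValueError("homogeneity requires a normalized co-occurrence matrix")
    if abs(P.P.sum() - 1.0) > 1e-9:
        raise ValueError("co-occurrence matrix entries must sum to 1")
    L = P.P.shape[0]
    i = np.arange(L)
    w = 1.0 / (1.0 + np.abs(i[:, None] - i[None, :]))
    return float(np.sum(P.P * w))


def homogeneity_feature(
    bmap: BirefringenceMap,
    roi: CylinderROI | None = None,
    L: int = 12,
    lo: float = 0.0,
    hi: float = 1.0,
    offset: tuple = (5, 0),
) -> float:
    """Single lesion-level Hom: quantize -> glcm -> homogeneity."""
    q = quantize(bmap, L=L, lo=lo, hi=hi, roi=roi)
    return homogeneity(glcm(q, offset=offset))
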