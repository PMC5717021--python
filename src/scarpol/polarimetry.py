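"""Degree-of-polarization (DOP) metrics from Stokes-vector tomograms.

Polarization-sensitive OCT measures, for every voxel, the Stokes vector
(I, Q, U, V) of the backscattered light, independently for each spectral
bin ``n`` and input polarization state ``p``.  Tissue that scrambles the
polarization state on a scale below the focal volume (e.g. the collagen
mesh of normal dermis) depolarizes the signal; organized scar collagen
maintains it.  The DOP quantifies this:

    DOP = 1/(P*N) * sum_{p,n} sqrt(Qbar^2 + Ubar^2 + Vbar^2) / Ibar

where the bar denotes spatial (lateral Gaussian) averaging of each Stokes
component before taking the norm.  The DOP of the *averaged* components is
1 for locally uniform states and decreases toward 0 as the states within
the averaging kernel decorrelate.

This module computes DOP volumes, depth profiles within a cylindrical
region of interest, and the per-millimeter slope of the depth-averaged
DOP (``DOPSlope``), reported *positive* for a downward (decreasing) DOP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "StokesVolume",
    "SmoothingSpec",
    "ScalarVolume",
    "CylinderROI",
    "DepthProfile",
    "compute_dop",
    "dop_depth_profile",
    "fit_dop_slope",
    "cylinder_mask",
]

#: tolerance for float overshoot of the physical DOP <= 1 bound
DOP_OVERSHOOT_TOL = 1e-9

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SmoothingSpec:
    """Lateral Gaussian averaging kernel.

    Parameters
    ----------
    lateral_fwhm : float
        Full width at half maximum of the Gaussian, in units of adjacent
        A-lines (lateral pixels). Default 12.
    truncate : float
        Kernel truncation radius in multiples of sigma. Default 3.
    """

    lateral_fwhm: float = 12.0
    truncate: float = 3.0

    def __post_init__(self) -> None:
        if not (self.lateral_fwhm > 0):
            raise ValueError("lateral_fwhm must be > 0")
        if not (self.truncate > 0):
            raise ValueError("truncate must be > 0")

    @property
    def sigma(self) -> float:
        """Gaussian sigma in lateral pixels."""
        return self.lateral_fwhm * _FWHM_TO_SIGMA

    def kernel(self, n_lateral: int) -> np.ndarray:
        """Unit-sum 1-D kernel, truncated to the lateral support.

        Offsets beyond ``n_lateral - 1`` can never overlap the volume, so
        the radius is capped there; combined with renormalized-truncation
        edge handling this is exact.
        """
        radius = int(np.ceil(self.truncate * self.sigma))
        radius = max(0, min(radius, n_lateral - 1))
        if radius == 0:
            return np.ones(1)
        offsets = np.arange(-radius, radius + 1, dtype=float)
        with np.errstate(under="ignore"):
            k = np.exp(-0.5 * (offsets / self.sigma) ** 2)
        return k / k.sum()


@dataclass
class StokesVolume:
    """Stokes-vector tomogram.

    The four component grids are indexed ``(z, x, y, n, p)``: axial depth,
    lateral A-line within a frame, frame, spectral bin, input polarization
    state.  Spacings are micrometres per voxel.
    """

    I: np.ndarray
    Q: np.ndarray
    U: np.ndarray
    V: np.ndarray
    spacing_z: float = 1.0
    spacing_x: float = 1.0
    spacing_y: float = 1.0

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.I.ndim != 5:
            raise ValueError(
                f"Stokes grids must be 5-D (z, x, y, bin, state); got ndim={self.I.ndim}"
            )
        for name in ("Q", "U", "V"):
            if getattr(self, name).shape != self.I.shape:
                raise ValueError(
                    f"shape mismatch: {name} has {getattr(self, name).shape}, "
                    f"I has {self.I.shape}"
                )
        if not np.all(np.isfinite(self.I)):
            raise ValueError("non-finite intensity values")
        if np.any(self.I <= 0):
            idx = tuple(int(i) for i in np.argwhere(self.I <= 0)[0])
            raise ValueError(f"non-positive intensity at voxel {idx}")
        norm = np.sqrt(self.Q**2 + self.U**2 + self.V**2)
        bad = norm > self.I * (1.0 + DOP_OVERSHOOT_TOL)
        if np.any(bad):
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(
                f"unphysical Stokes vector (|QUV| > I) at voxel {idx}"
            )
        for s in (self.spacing_z, self.spacing_x, self.spacing_y):
            if not (s > 0):
                raise ValueError("voxel spacings must be > 0")

    @property
    def shape(self) -> tuple:
        return self.I.shape

    @property
    def n_bins(self) -> int:
        return self.I.shape[3]

    @property
    def n_states(self) -> int:
        return self.I.shape[4]


@dataclass
class ScalarVolume:
    """A scalar field on the ``(z, x, y)`` grid.

    ``kind`` declares the semantic range: ``"dop"`` is unitless in [0, 1],
    ``"birefringence"`` is nonnegative (deg/um).
    """

    values: np.ndarray
    spacing_z: float = 1.0
    spacing_x: float = 1.0
    spacing_y: float = 1.0
    kind: str = "dop"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ScalarVolume values must be 3-D (z, x, y)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values")
        if self.kind == "dop":
            if self.values.min() < 0 or self.values.max() > 1:
                raise ValueError("DOP values must lie in [0, 1]")
        elif self.kind == "birefringence":
            if self.values.min() < 0:
                raise ValueError("birefringence must be >= 0")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")


@dataclass(frozen=True)
class CylinderROI:
    """Cylindrical region of interest, axis along depth.

    All coordinates in micrometres; physical coordinate of voxel index i
    is ``i * spacing``.  Lateral membership: distance of the voxel center
    from (center_x, center_y) <= diameter/2 (inclusive).  Axial bounds are
    inclusive.
    """

    center_x: float
    center_y: float
    z_top: float
    z_bottom: float
    diameter: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise ValueError("diameter must be > 0")
        if not (self.z_top < self.z_bottom):
            raise ValueError("z_top must be < z_bottom")


@dataclass
class DepthProfile:
    """Depth-resolved lateral mean of a scalar field within an ROI."""

    depth_mm: np.ndarray
    mean_dop: np.ndarray
    voxel_count: np.ndarray

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.mean_dop = np.asarray(self.mean_dop, dtype=float)
        self.voxel_count = np.asarray(self.voxel_count, dtype=int)
        if not (len(self.depth_mm) == len(self.mean_dop) == len(self.voxel_count)):
            raise ValueError("profile arrays must have equal length")
        if np.any(np.diff(self.depth_mm) <= 0):
            raise ValueError("depth must be strictly increasing")
        if np.any(self.voxel_count <= 0):
            raise ValueError("voxel_count must be > 0 at every retained depth")


def _smooth_lateral(grid: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Gaussian smoothing along axis 1 with renormalized truncation.

    Convolving with zero padding and dividing by the in-support kernel
    weight is equivalent to renormalizing the truncated kernel at the
    edges, which avoids any padding bias.
    """
    if kernel.size == 1:
        return grid
    num = ndimage.convolve1d(grid, kernel, axis=1, mode="constant", cval=0.0)
    weight = ndimage.convolve1d(
        np.ones(grid.shape[1]), kernel, mode="constant", cval=0.0
    )
    shape = [1] * grid.ndim
    shape[1] = grid.shape[1]
    return num / weight.reshape(shape)


def compute_dop(stokes: StokesVolume, kernel: SmoothingSpec | None = None) -> ScalarVolume:
    """DOP volume from Stokes data.

    Each component is smoothed laterally (within a frame, across adjacent
    A-lines) with a Gaussian kernel, independently for every spectral bin
    and input state; the norm-over-intensity ratio is then averaged with
    equal weight 1/(P*N) over the bins and states.

    Returns a ``ScalarVolume`` with values in [0, 1] on the (z, x, y)
    grid.  Raises if a smoothed intensity is non-positive or if the
    averaged DOP exceeds 1 beyond float tolerance (unphysical input).
    """
    if kernel is None:
        kernel = SmoothingSpec()
    k = kernel.kernel(stokes.shape[1])
    i_bar = _smooth_lateral(stokes.I, k)
    if np.any(i_bar <= 0):
        idx = tuple(int(i) for i in np.argwhere(i_bar <= 0)[0])
        raise ValueError(f"non-positive smoothed intensity at voxel {idx}")
    q_bar = _smooth_lateral(stokes.Q, k)
    u_bar = _smooth_lateral(stokes.U, k)
    v_bar = _smooth_lateral(stokes.V, k)
    dop_np = np.sqrt(q_bar**2 + u_bar**2 + v_bar**2) / i_bar
    dop = dop_np.mean(axis=(3, 4))
    overshoot = dop.max() - 1.0
    if overshoot > DOP_OVERSHOOT_TOL:
        raise ValueError(
            f"DOP exceeds 1 by {overshoot:.3g}: unphysical input Stokes data"
        )
    dop = np.clip(dop, 0.0, 1.0)
    return ScalarVolume(
        values=dop,
        spacing_z=stokes.spacing_z,
        spacing_x=stokes.spacing_x,
        spacing_y=stokes.spacing_y,
        kind="dop",
    )


def cylinder_mask(
    n_x: int, n_y: int, spacing_x: float, spacing_y: float, roi: CylinderROI
) -> np.ndarray:
    """Boolean lateral membership mask of shape (n_x, n_y)."""
    xs = np.arange(n_x) * spacing_x
    ys = np.arange(n_y) * spacing_y
    d2 = (xs[:, None] - roi.center_x) ** 2 + (ys[None, :] - roi.center_y) ** 2
    return d2 <= (roi.diameter / 2.0) ** 2


def _axial_indices(n_z: int, spacing_z: float, roi: CylinderROI) -> np.ndarray:
    zs = np.arange(n_z) * spacing_z
    return np.nonzero((zs >= roi.z_top) & (zs <= roi.z_bottom))[0]


def dop_depth_profile(dop: ScalarVolume, roi: CylinderROI) -> DepthProfile:
    """Average the DOP at each depth across the ROI cylinder.

    Depths whose lateral mask is empty are dropped (not zero-filled); an
    entirely empty ROI raises.
    """
    n_z, n_x, n_y = dop.values.shape
    mask = cylinder_mask(n_x, n_y, dop.spacing_x, dop.spacing_y, roi)
    z_idx = _axial_indices(n_z, dop.spacing_z, roi)
    count = int(mask.sum())
    if count == 0 or z_idx.size == 0:
        raise ValueError("ROI does not intersect the volume")
    means = dop.values[z_idx][:, mask].mean(axis=1)
    depth_mm = z_idx * dop.spacing_z / 1000.0
    counts = np.full(z_idx.size, count)
    return DepthProfile(depth_mm=depth_mm, mean_dop=means, voxel_count=counts)


def fit_dop_slope(profile: DepthProfile) -> float:
    """DOPSlope: negated OLS slope of mean DOP vs depth (1/mm).

    Fitted by ordinary least squares over the full profile.  The sign is
    flipped so that DOP *decreasing* with depth yields a positive slope,
    the convention in which scar severity metrics are tabulated.
    """
    if len(profile.depth_mm) < 2:
        raise ValueError("at least 2 depth points are required to fit a slope")
    slope, _ = np.polyfit(profile.depth_mm, profile.mean_dop, 1)
    return float(-slope)
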