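"""Synthetic study data with known ground truth.

Three generators let every pipeline stage be exercised end to end without
any measured data:

* ``synth_cohort`` draws longitudinal wound cohorts whose marginal
  feature moments match the published calibration table (mean/std per
  feature and month) and whose dependence structure is a single latent
  "severity" factor: each feature loads on it with a tunable weight, and
  the month-6 scar area loads with ``outcome_loading`` (the signal dial).
  The population correlation between a feature and the outcome is the
  product of their loadings.  A shared animal-level component (variance
  share 0.2) makes wounds on one animal mildly correlated.

* ``synth_stokes_volume`` builds Stokes tomograms whose expected
  post-averaging DOP follows a prescribed depth profile
  ``f(z) = f0 - slope * z`` (slope in 1/mm), so the DOP-slope extraction
  can be validated against a known ground truth.

* ``synth_biref_map`` builds birefringence maps as a base level plus a
  Gaussian-blob spot field, emulating the heterogeneous, spot-like
  appearance of normal dermis (amplitude 0 gives the perfectly uniform,
  scar-like limit with homogeneity 1).

All generators take an explicit seed; none touch global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import yaml

from .cohort import ALL_MONTHS, Cohort, FeatureTriple, WoundRecord, write_cohort
from .polarimetry import StokesVolume
from .texture import BirefringenceMap

__all__ = [
    "TABLE_CALIBRATION",
    "CohortCalibration",
    "BirefFieldSpec",
    "TomogramSpec",
    "synth_cohort",
    "synth_stokes_volume",
    "synth_biref_map",
    "make_fixture_bundle",
]

#: calibration moments (mean, std) per feature and month, from the
#: published rat burn-scar summary table
TABLE_CALIBRATION: Dict[str, Dict[int, Tuple[float, float]]] = {
    "scar_area": {
        1: (76.13, 25.22),
        2: (48.07, 12.36),
        3: (33.77, 7.65),
        5: (34.72, 11.01),
        6: (36.09, 12.79),
    },
    "hom": {
        1: (0.734, 0.071),
        2: (0.700, 0.055),
        3: (0.593, 0.189),
        5: (0.573, 0.040),
        6: (0.539, 0.100),
    },
    "dop_slope": {
        1: (0.281, 0.100),
        2: (0.185, 0.067),
        3: (0.195, 0.090),
        5: (0.256, 0.054),
        6: (0.295, 0.087),
    },
}

#: clip bounds (lo, hi) enforcing the feature invariants after sampling
CLIP_BOUNDS: Dict[str, Tuple[float, float]] = {
    "scar_area": (1e-3, np.inf),
    "hom": (0.0, 1.0),
    "dop_slope": (0.0, np.inf),
}


def _default_loadings() -> Dict[Tuple[str, int], float]:
    # month 1 is weakly coupled to the latent severity, later months more
    # strongly -- mirroring the finding that month-1 features are poor
    # predictors while months 2-3 carry signal
    w = {}
    for feat in TABLE_CALIBRATION:
        for month in ALL_MONTHS:
            w[(feat, month)] = 0.2 if month == 1 else 0.5
    return w


@dataclass
class CohortCalibration:
    """Moments, loadings and shape of the synthetic cohort.

    ``outcome_loading`` couples the month-6 scar area to the latent
    severity; 0 gives a no-signal cohort, 1 a deterministic outcome.
    """

    moments: Dict[str, Dict[int, Tuple[float, float]]] = field(
        default_factory=lambda: {
            f: dict(m) for f, m in TABLE_CALIBRATION.items()
        }
    )
    feature_loadings: Dict[Tuple[str, int], float] = field(
        default_factory=_default_loadings
    )
    outcome_loading: float = 0.8
    animal_share: float = 0.2
    n_animals: int = 9
    wounds_per_animal: int = 4
    clip_bounds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(CLIP_BOUNDS)
    )

    def __post_init__(self) -> None:
        for feat, months in self.moments.items():
            for month, (mu, sigma) in months.items():
                if not sigma > 0:
                    raise ValueError(f"sigma must be > 0 for ({feat}, {month})")
        for key, w in self.feature_loadings.items():
            if abs(w) > 1:
                raise ValueError(f"|loading| must be <= 1 for {key}")
        if not (0.0 <= self.outcome_loading <= 1.0):
            raise ValueError("outcome_loading must lie in [0, 1]")
        if not (0.0 <= self.animal_share < 1.0):
            raise ValueError("animal_share must lie in [0, 1)")
        if self.n_animals < 1 or self.wounds_per_animal < 1:
            raise ValueError("cohort shape must be positive")

    @property
    def n_wounds(self) -> int:
        return self.n_animals * self.wounds_per_animal

    def with_coupling(self, outcome_loading: float) -> "CohortCalibration":
        return replace(self, outcome_loading=outcome_loading)


def synth_cohort(calib: CohortCalibration | None = None, seed: int = 0) -> Cohort:
    """Draw one synthetic cohort.

    Per wound, a latent severity ``u = sqrt(a) * animal + sqrt(1-a) *
    wound`` (standard normal overall, ``a`` the animal variance share).
    Each feature value is ``mu + sigma * (w*u + sqrt(1-w^2)*eps)`` with
    independent standard-normal ``eps``; the month-6 scar area uses the
    outcome loading.  Values are clipped into their physical bounds.
    """
    if calib is None:
        calib = CohortCalibration()
    rng = np.random.default_rng(seed)
    n = calib.n_wounds
    animal_idx = np.repeat(np.arange(calib.n_animals), calib.wounds_per_animal)
    a = rng.standard_normal(calib.n_animals)
    e = rng.standard_normal(n)
    u = np.sqrt(calib.animal_share) * a[animal_idx] + np.sqrt(
        1.0 - calib.animal_share
    ) * e

    keys = [(feat, month) for month in ALL_MONTHS for feat in TABLE_CALIBRATION]
    eps = rng.standard_normal((n, len(keys)))
    values: Dict[Tuple[str, int], np.ndarray] = {}
    for j, (feat, month) in enumerate(keys):
        mu, sigma = calib.moments[feat][month]
        if feat == "scar_area" and month == 6:
            w = calib.outcome_loading
        else:
            w = calib.feature_loadings[(feat, month)]
        v = mu + sigma * (w * u + np.sqrt(1.0 - w**2) * eps[:, j])
        lo, hi = calib.clip_bounds[feat]
        values[(feat, month)] = np.clip(v, lo, hi)

    records = []
    for i in range(n):
        wound_in_animal = i % calib.wounds_per_animal
        treatment = "control" if wound_in_animal == 0 else f"pIRE{wound_in_animal}"
        meas = {
            month: FeatureTriple(
                scar_area=float(values[("scar_area", month)][i]),
                hom=float(values[("hom", month)][i]),
                dop_slope=float(values[("dop_slope", month)][i]),
            )
            for month in ALL_MONTHS
        }
        records.append(
            WoundRecord(
                wound_id=f"A{animal_idx[i] + 1:03d}-W{wound_in_animal + 1}",
                animal_id=f"A{animal_idx[i] + 1:03d}",
                treatment=treatment,
                measurements=meas,
            )
        )
    return Cohort(records)


@dataclass
class TomogramSpec:
    """Geometry and signal model of a synthetic Stokes tomogram.

    The polarized fraction decays linearly with depth,
    ``f(z) = surface_fraction - slope * z(mm)``; ``slope`` is the
    ground-truth DOPSlope.  The polarized component lies along a unit
    Stokes direction that rotates smoothly with depth (emulating
    birefringence); the unpolarized remainder appears as zero-mean
    isotropic (Q, U, V) fluctuation with per-component standard deviation
    ``noise_scale * (1 - f(z)) * I / sqrt(3)``, which keeps the physical
    bound |QUV| <= I essentially surely (rare violators are rescaled).
    """

    n_z: int = 400
    n_x: int = 2048
    n_y: int = 1
    spacing_z: float = 2.5  # um: 400 depths span 1 mm
    spacing_x: float = 4.9  # um: ~10 mm / 2048 A-lines
    spacing_y: float = 19.5  # um
    surface_fraction: float = 0.95
    slope: float = 0.25  # 1/mm
    intensity: float = 1.0
    noise_scale: float = 0.5
    n_bins: int = 5
    n_states: int = 2
    rotation_period_mm: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_z, self.n_x, self.n_y, self.n_bins, self.n_states) < 1:
            raise ValueError("grid shape and bin/state counts must be >= 1")
        if not self.intensity > 0:
            raise ValueError("intensity must be > 0")
        if not (0.0 <= self.noise_scale <= 1.0):
            raise ValueError("noise_scale must lie in [0, 1]")
        z_max_mm = (self.n_z - 1) * self.spacing_z / 1000.0
        f_ends = (self.surface_fraction, self.surface_fraction - self.slope * z_max_mm)
        if min(f_ends) < 0.0 or max(f_ends) > 1.0:
            raise ValueError(
                f"polarized fraction leaves [0, 1] over the grid: {f_ends}"
            )


def synth_stokes_volume(spec: TomogramSpec | None = None, seed: int = 0) -> StokesVolume:
    """Stokes tomogram with known ground-truth DOP depth profile."""
    if spec is None:
        spec = TomogramSpec()
    rng = np.random.default_rng(seed)
    z_mm = np.arange(spec.n_z) * spec.spacing_z / 1000.0
    f = spec.surface_fraction - spec.slope * z_mm  # (n_z,)

    shape = (spec.n_z, spec.n_x, spec.n_y, spec.n_bins, spec.n_states)
    theta = 2.0 * np.pi * z_mm / spec.rotation_period_mm
    # distinct direction per bin/state: phase offsets across n and p
    n_off = (np.pi / max(spec.n_bins, 1)) * np.arange(spec.n_bins)
    p_off = (np.pi / 2.0) * np.arange(spec.n_states)
    phase = (
        theta[:, None, None]
        + n_off[None, :, None]
        + p_off[None, None, :]
    )  # (n_z, n_bins, n_states)
    # unit direction with a fixed circular component: 0.8^2 + 0.6^2 = 1
    d_q = 0.8 * np.cos(phase)
    d_u = 0.8 * np.sin(phase)
    d_v = np.full_like(d_q, 0.6)

    fI = (f * spec.intensity)[:, None, None]  # (n_z, 1, 1) over (z, n, p)
    sigma = (spec.noise_scale * (1.0 - f) * spec.intensity / np.sqrt(3.0))
    sigma5 = sigma[:, None, None, None, None]

    def component(d: np.ndarray) -> np.ndarray:
        base = (fI * d)[:, None, None, :, :]  # -> (n_z, 1, 1, n_bins, n_states)
        out = np.broadcast_to(base, shape).copy()
        out += rng.standard_normal(shape) * sigma5
        return out

    Q = component(d_q)
    U = component(d_u)
    V = component(d_v)
    I = np.full(shape, spec.intensity)

    norm = np.sqrt(Q**2 + U**2 + V**2)
    bad = norm > spec.intensity
    if np.any(bad):
        scale = np.where(bad, spec.intensity / np.maximum(norm, 1e-300), 1.0)
        Q *= scale
        U *= scale
        V *= scale
    return StokesVolume(
        I=I,
        Q=Q,
        U=U,
        V=V,
        spacing_z=spec.spacing_z,
        spacing_x=spec.spacing_x,
        spacing_y=spec.spacing_y,
    )


@dataclass
class BirefFieldSpec:
    """Spot-field birefringence map parameters.

    ``density`` is the expected spot count per mm^2; ``corr_length`` the
    Gaussian blob radius (um).  Amplitude 0 gives a perfectly uniform
    (scar-like) map.
    """

    n_z: int = 200
    n_x: int = 200
    spacing_z: float = 5.0  # um
    spacing_x: float = 5.0  # um
    base: float = 0.3  # deg/um
    amplitude: float = 0.4  # deg/um
    density: float = 50.0  # spots per mm^2
    corr_length: float = 30.0  # um

    def __post_init__(self) -> None:
        if self.base < 0 or self.amplitude < 0:
            raise ValueError("base and amplitude must be >= 0")
        if self.density < 0 or self.corr_length <= 0:
            raise ValueError("density must be >= 0 and corr_length > 0")
        if self.n_z < 1 or self.n_x < 1:
            raise ValueError("grid shape must be positive")


def synth_biref_map(spec: BirefFieldSpec | None = None, seed: int = 0) -> BirefringenceMap:
    """Base level plus Gaussian-blob spots, clipped at 0."""
    if spec is None:
        spec = BirefFieldSpec()
    rng = np.random.default_rng(seed)
    extent_z = spec.n_z * spec.spacing_z
    extent_x = spec.n_x * spec.spacing_x
    area_mm2 = (extent_z / 1000.0) * (extent_x / 1000.0)
    n_spots = int(rng.poisson(spec.density * area_mm2))
    zz = (np.arange(spec.n_z) * spec.spacing_z)[:, None]
    xx = (np.arange(spec.n_x) * spec.spacing_x)[None, :]
    field = np.full((spec.n_z, spec.n_x), spec.base)
    for _ in range(n_spots):
        cz = rng.uniform(0, extent_z)
        cx = rng.uniform(0, extent_x)
        r2 = (zz - cz) ** 2 + (xx - cx) ** 2
        field += spec.amplitude * np.exp(-0.5 * r2 / spec.corr_length**2)
    return BirefringenceMap(
        values=np.clip(field, 0.0, None),
        spacing_z=spec.spacing_z,
        spacing_x=spec.spacing_x,
    )


def make_fixture_bundle(out_dir: str | Path, seed: int = 0) -> Dict[str, str]:
    """Write a default cohort CSV, a small Stokes volume, a birefringence
    map and a YAML manifest with seeds and ground truths.

    The manifest is byte-identical for a given seed.  Returns the file
    paths keyed by role.
    """
    from . import io as scario

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_cohort, s_vol, s_map = (int(s) & 0x7FFFFFFF for s in ss.generate_state(3))

    calib = CohortCalibration()
    cohort = synth_cohort(calib, seed=s_cohort)
    cohort_path = out / "cohort.csv"
    write_cohort(cohort, cohort_path)

    vol_spec = TomogramSpec(
        n_z=60, n_x=64, n_y=2, spacing_z=5.0, spacing_x=10.0, spacing_y=20.0,
        surface_fraction=0.9, slope=0.25, n_bins=2, n_states=2,
    )
    vol = synth_stokes_volume(vol_spec, seed=s_vol)
    vol_path = out / "stokes.npz"
    scario.save_stokes(vol_path, vol)

    map_spec = BirefFieldSpec(n_z=64, n_x=64)
    bmap = synth_biref_map(map_spec, seed=s_map)
    map_path = out / "biref.tiff"
    scario.save_biref_tiff(map_path, bmap)

    manifest = {
        "seed": int(seed),
        "seeds": {"cohort": s_cohort, "stokes": s_vol, "biref": s_map},
        "files": {
            "cohort": cohort_path.name,
            "stokes": vol_path.name,
            "biref": map_path.name,
        },
        "ground_truth": {
            "cohort": {
                "n_wounds": calib.n_wounds,
                "outcome_loading": calib.outcome_loading,
                "animal_share": calib.animal_share,
            },
            "stokes": {
                "dop_slope_per_mm": vol_spec.slope,
                "surface_polarized_fraction": vol_spec.surface_fraction,
            },
            "biref": {
                "base_deg_per_um": map_spec.base,
                "spot_amplitude_deg_per_um": map_spec.amplitude,
                "spot_density_per_mm2": map_spec.density,
            },
        },
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return {
        "cohort": str(cohort_path),
        "stokes": str(vol_path),
        "biref": str(map_path),
        "manifest": str(manifest_path),
    }
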