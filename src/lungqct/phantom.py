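"""Synthetic thoracic CT phantom generation.

Builds paired inspiratory/expiratory attenuation volumes containing a
soft-tissue thorax, an ellipsoidal lung with clustered emphysema and
air-trapping regions, and one straight airway of known annular geometry,
then renders them at configurable reconstruction noise levels.

The phantom stands in for patient scans in sensitivity studies of
quantitative CT measures: all pathology masks and the airway geometry are
known exactly, so every downstream measurement can be checked against
ground truth.

Geometry is defined in physical millimetres; volumes are indexed (x, y, z)
with the z axis axial (larger index = more superior) so axial slices are
perpendicular cross-sections of the embedded airway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

HU_AIR = -1000.0
HU_SOFT_TISSUE = 40.0

__all__ = [
    "PhantomParams",
    "ReconParams",
    "CTVolume",
    "PhantomTruth",
    "CohortRanges",
    "CohortSubject",
    "generate_phantom",
    "apply_reconstruction",
    "generate_cohort",
    "draw_cohort_params",
    "make_annulus_slice",
]


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of one synthetic subject.

    Hounsfield defaults follow typical parenchymal attenuation: normal lung
    near -880 HU at full inspiration, rising to about -790 HU at expiration
    except in air-trapping regions, which retain near-inspiratory density.
    Emphysematous tissue sits at -1000 HU, below the -950 HU density-mask
    threshold.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_spacing_mm: tuple[float, float, float] = (0.7, 0.7, 1.0)
    emphysema_fraction: float = 0.08
    trapping_fraction: float = 0.18
    hu_normal_insp: float = -880.0
    hu_normal_exp: float = -790.0
    hu_emphysema: float = -1000.0
    hu_trapped_exp: float = -880.0
    airway_inner_radius_mm: float = 1.8
    airway_outer_radius_mm: float = 3.8
    airway_wall_hu: float = 0.0
    texture_sigma_hu: float = 20.0
    cluster_scale_mm: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3-D with at least 16 voxels per axis")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacings must be positive")
        if not (0.0 <= self.emphysema_fraction <= 1.0):
            raise ValueError("emphysema_fraction must lie in [0, 1]")
        if not (0.0 <= self.trapping_fraction <= 1.0):
            raise ValueError("trapping_fraction must lie in [0, 1]")
        if self.emphysema_fraction + self.trapping_fraction > 1.0:
            raise ValueError("emphysema_fraction + trapping_fraction must not exceed 1")
        if not (0.0 < self.airway_inner_radius_mm < self.airway_outer_radius_mm):
            raise ValueError("require 0 < inner radius < outer radius")
        if not (self.hu_emphysema < -950.0 < self.hu_normal_insp):
            raise ValueError("require hu_emphysema < -950 < hu_normal_insp")
        if self.texture_sigma_hu < 0:
            raise ValueError("texture_sigma_hu must be non-negative")


@dataclass(frozen=True)
class ReconParams:
    """Noise rendering of a reconstruction algorithm.

    Filtered back-projection (FBP) carries the full image noise
    ``noise_sigma_hu``; hybrid iterative reconstruction (IR) is modelled as
    a pure scaling of that noise by ``1 - noise_reduction`` without any
    change to the underlying image, so the effective standard deviation is
    ``noise_sigma_hu * (1 - noise_reduction)``.
    """

    label: str = "FBP"
    noise_sigma_hu: float = 80.0
    noise_reduction: float = 0.0

    def validate(self) -> None:
        if self.noise_sigma_hu < 0:
            raise ValueError("noise_sigma_hu must be non-negative")
        if not (0.0 <= self.noise_reduction < 1.0):
            raise ValueError("noise_reduction must lie in [0, 1)")

    @property
    def effective_sigma_hu(self) -> float:
        return self.noise_sigma_hu * (1.0 - self.noise_reduction)

    @classmethod
    def fbp(cls, noise_sigma_hu: float = 80.0) -> "ReconParams":
        return cls(label="FBP", noise_sigma_hu=noise_sigma_hu, noise_reduction=0.0)

    @classmethod
    def idose(cls, noise_sigma_hu: float = 80.0, noise_reduction: float = 0.45) -> "ReconParams":
        return cls(label="IR", noise_sigma_hu=noise_sigma_hu, noise_reduction=noise_reduction)


@dataclass
class CTVolume:
    """3-D attenuation grid in Hounsfield units with physical spacing."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    recon_label: str = "clean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("CTVolume requires a 3-D array")
        if len(self.spacing_mm) != 3:
            raise ValueError("spacing_mm must have 3 entries")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def axial_slice(self, z_index: int) -> tuple[np.ndarray, tuple[float, float]]:
        """Return one axial cross-section and its in-plane spacing."""
        return self.values[:, :, z_index], self.spacing_mm[:2]


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: masks, airway geometry, analytic areas."""

    lung_mask: np.ndarray
    emphysema_mask: np.ndarray
    trapping_mask: np.ndarray
    airway_lumen_mask: np.ndarray
    airway_center_xy_mm: tuple[float, float]
    airway_axis: str
    airway_inner_radius_mm: float
    airway_outer_radius_mm: float
    airway_slice_index: int
    true_LA_mm2: float
    true_WA_mm2: float
    true_Pi_mm: float

    def to_geometry_dict(self) -> dict:
        return {
            "airway_center_xy_mm": list(self.airway_center_xy_mm),
            "airway_axis": self.airway_axis,
            "airway_inner_radius_mm": self.airway_inner_radius_mm,
            "airway_outer_radius_mm": self.airway_outer_radius_mm,
            "airway_slice_index": self.airway_slice_index,
            "true_LA_mm2": self.true_LA_mm2,
            "true_WA_mm2": self.true_WA_mm2,
            "true_Pi_mm": self.true_Pi_mm,
        }


def _coordinate_grids(params: PhantomParams):
    """Physical coordinates (mm) of voxel centres, origin at grid centre."""
    axes = [
        (np.arange(n, dtype=np.float32) - (n - 1) / 2.0) * s
        for n, s in zip(params.grid_shape, params.voxel_spacing_mm)
    ]
    return axes  # broadcastable 1-D axes


# Proportions of the field of view occupied by body and lung ellipsoids.
_BODY_SEMI = (0.44, 0.44, 0.48)
_LUNG_SEMI = (0.30, 0.32, 0.35)
_AIRWAY_X_OFFSET = 0.35  # of the lung x semi-axis
_AIRWAY_Z_LOW = -0.05    # of FOV z, tube bottom (capped)
_AIRWAY_Z_HIGH = 0.40    # of FOV z, tube top (open, inside mediastinum,
                         # comfortably below the body surface even on
                         # coarse desk-scale grids)
_AIRWAY_MARGIN_MM = 3.0  # pathology exclusion margin around the airway


def generate_phantom(params: PhantomParams) -> tuple[CTVolume, CTVolume, PhantomTruth]:
    """Generate paired clean inspiratory/expiratory volumes plus ground truth.

    The thorax is a soft-tissue ellipsoid in background air; the lung is a
    smaller ellipsoid of parenchymal attenuation. Emphysema and air-trapping
    masks are carved from thresholded smooth Gaussian random fields so they
    form spatially coherent clusters whose voxel counts hit the requested
    fractions of the lung to within one voxel. A straight airway tube runs
    along z through the lung, extending superiorly into the mediastinum with
    an open top and a capped bottom, so its lumen is an air column enclosed
    by wall everywhere except at its superior opening.

    Identical parameters (including seed) give bit-identical outputs.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = params.grid_shape
    spacing = params.voxel_spacing_mm
    fov = tuple(n * s for n, s in zip(shape, spacing))
    xs, ys, zs = _coordinate_grids(params)
    x = xs[:, None, None]
    y = ys[None, :, None]
    z = zs[None, None, :]

    body = (
        (x / (_BODY_SEMI[0] * fov[0])) ** 2
        + (y / (_BODY_SEMI[1] * fov[1])) ** 2
        + (z / (_BODY_SEMI[2] * fov[2])) ** 2
    ) <= 1.0
    lung_semi = tuple(p * f for p, f in zip(_LUNG_SEMI, fov))
    lung_ellipsoid = (
        (x / lung_semi[0]) ** 2 + (y / lung_semi[1]) ** 2 + (z / lung_semi[2]) ** 2
    ) <= 1.0

    # Airway tube parallel to z, offset from the lung centre.
    cx = _AIRWAY_X_OFFSET * lung_semi[0]
    cy = 0.0
    r_i = params.airway_inner_radius_mm
    r_o = params.airway_outer_radius_mm
    rho2 = (x - cx) ** 2 + (y - cy) ** 2
    z_low = _AIRWAY_Z_LOW * fov[2]
    z_high = _AIRWAY_Z_HIGH * fov[2]
    cap_mm = r_o - r_i
    tube_z = (z >= z_low) & (z <= z_high)
    in_outer = tube_z & (rho2 <= r_o**2)
    lumen = in_outer & (rho2 <= r_i**2) & (z >= z_low + cap_mm)
    wall = in_outer & ~lumen

    # The tube must stay clear of the lung boundary in-plane and inside the
    # body superiorly, otherwise the lumen would open into parenchyma or
    # outside air.
    if cx + r_o + _AIRWAY_MARGIN_MM >= lung_semi[0]:
        raise ValueError("airway outer radius too large for the lung cross-section")
    body_top_at_axis = _BODY_SEMI[2] * fov[2] * math.sqrt(
        max(0.0, 1.0 - (cx / (_BODY_SEMI[0] * fov[0])) ** 2)
    )
    if z_high >= body_top_at_axis:
        raise ValueError("airway tube would exit the body superiorly")

    lung_mask = lung_ellipsoid & ~in_outer
    n_lung = int(lung_mask.sum())
    if n_lung == 0:
        raise ValueError("degenerate geometry: empty lung")

    # Pathology placement: exclude a margin around the airway so clustered
    # emphysema cannot merge with the lumen air column.
    near_airway = tube_z & (rho2 <= (r_o + _AIRWAY_MARGIN_MM) ** 2)
    eligible = lung_mask & ~near_airway

    k_emph = int(round(params.emphysema_fraction * n_lung))
    k_trap = int(round(params.trapping_fraction * n_lung))
    if k_emph + k_trap > int(eligible.sum()):
        raise ValueError(
            "emphysema_fraction + trapping_fraction exceed the capacity of the "
            "lung region available for pathology placement"
        )

    cluster_sigma_vox = [params.cluster_scale_mm / s for s in spacing]
    emphysema_mask = _top_k_cluster_mask(rng, shape, cluster_sigma_vox, eligible, k_emph)
    trapping_mask = _top_k_cluster_mask(
        rng, shape, cluster_sigma_vox, eligible & ~emphysema_mask, k_trap
    )

    normal_insp = lung_mask & ~emphysema_mask
    normal_exp = lung_mask & ~emphysema_mask & ~trapping_mask

    def _render(hu_normal: float, trapped: bool) -> np.ndarray:
        vol = np.full(shape, HU_AIR, dtype=np.float32)
        vol[body] = HU_SOFT_TISSUE
        if trapped:
            vol[normal_exp] = hu_normal
            vol[trapping_mask] = params.hu_trapped_exp
        else:
            vol[normal_insp] = hu_normal
        vol[emphysema_mask] = params.hu_emphysema
        if params.texture_sigma_hu > 0:
            texture = rng.normal(0.0, params.texture_sigma_hu, size=shape).astype(np.float32)
            vol[lung_mask] += texture[lung_mask]
        vol[wall] = params.airway_wall_hu
        vol[lumen] = HU_AIR
        return vol

    insp = CTVolume(_render(params.hu_normal_insp, trapped=False), spacing, "clean")
    exp = CTVolume(_render(params.hu_normal_exp, trapped=True), spacing, "clean")

    # Recommended measurement slice: mid-lung, well away from the tube cap.
    slice_z_mm = 0.10 * fov[2]
    slice_index = int(round(slice_z_mm / spacing[2] + (shape[2] - 1) / 2.0))

    # Truth centre in image coordinates (origin at the centre of voxel 0).
    cx_img = cx + (shape[0] - 1) / 2.0 * spacing[0]
    cy_img = cy + (shape[1] - 1) / 2.0 * spacing[1]
    truth = PhantomTruth(
        lung_mask=lung_mask,
        emphysema_mask=emphysema_mask,
        trapping_mask=trapping_mask,
        airway_lumen_mask=lumen,
        airway_center_xy_mm=(float(cx_img), float(cy_img)),
        airway_axis="z",
        airway_inner_radius_mm=r_i,
        airway_outer_radius_mm=r_o,
        airway_slice_index=slice_index,
        true_LA_mm2=math.pi * r_i**2,
        true_WA_mm2=math.pi * (r_o**2 - r_i**2),
        true_Pi_mm=2.0 * math.pi * r_i,
    )
    return insp, exp, truth


def _top_k_cluster_mask(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    sigma_vox: Sequence[float],
    eligible: np.ndarray,
    k: int,
) -> np.ndarray:
    """Select the k eligible voxels with the highest smoothed-noise value.

    Thresholding a smooth Gaussian random field at a quantile produces
    spatially coherent blobs; selecting exactly k voxels makes the achieved
    fraction exact to one voxel.
    """
    mask = np.zeros(shape, dtype=bool)
    if k <= 0:
        return mask
    field_ = ndimage.gaussian_filter(
        rng.standard_normal(shape).astype(np.float32), sigma=sigma_vox
    )
    values = field_[eligible]
    # k-th largest value as threshold; ties broken by selection order.
    idx = np.argpartition(values, -k)[-k:]
    flat_eligible = np.flatnonzero(eligible.ravel())
    mask.ravel()[flat_eligible[idx]] = True
    return mask


def apply_reconstruction(
    clean: CTVolume, recon: ReconParams, seed: int | np.random.Generator = 0
) -> CTVolume:
    """Render a clean volume at a reconstruction's noise level.

    Adds independent zero-mean Gaussian noise with standard deviation
    ``noise_sigma_hu * (1 - noise_reduction)``. Passing the same seed for
    two reconstructions of the same clean volume yields scaled versions of
    the same noise field, emulating two reconstructions of one raw
    acquisition.
    """
    recon.validate()
    if not np.all(np.isfinite(clean.values)):
        raise ValueError("clean volume contains non-finite values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = recon.effective_sigma_hu
    if sigma == 0.0:
        values = clean.values.copy()
    else:
        noise = rng.standard_normal(clean.values.shape).astype(np.float32)
        values = clean.values + sigma * noise
    return CTVolume(values, clean.spacing_mm, recon.label)


@dataclass(frozen=True)
class CohortRanges:
    """Uniform sampling ranges for per-subject phantom parameters.

    Defaults emulate a heavy-smoker screening cohort: mild-to-moderate
    emphysema, a broad spread of air trapping, and segmental-bronchus
    calibre airways (lumen radius 1.4-2.4 mm, wall thickness 1.6-2.4 mm).
    """

    emphysema_fraction: tuple[float, float] = (0.02, 0.15)
    trapping_fraction: tuple[float, float] = (0.05, 0.30)
    hu_normal_insp: tuple[float, float] = (-900.0, -860.0)
    hu_normal_exp: tuple[float, float] = (-810.0, -770.0)
    airway_inner_radius_mm: tuple[float, float] = (1.4, 2.4)
    airway_wall_thickness_mm: tuple[float, float] = (1.6, 2.4)

    def validate(self) -> None:
        for name in (
            "emphysema_fraction",
            "trapping_fraction",
            "hu_normal_insp",
            "hu_normal_exp",
            "airway_inner_radius_mm",
            "airway_wall_thickness_mm",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"range {name} has min > max")


@dataclass
class CohortSubject:
    subject_id: str
    params: PhantomParams
    insp: CTVolume
    exp: CTVolume
    truth: PhantomTruth


def draw_cohort_params(
    n_subjects: int,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    base: PhantomParams | None = None,
) -> list[PhantomParams]:
    """Draw per-subject parameters from uniform ranges, reproducibly.

    Per-subject seeds are derived from independent substreams of the master
    seed, so subject k is identical no matter how many subjects are drawn.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    ranges = ranges or CohortRanges()
    ranges.validate()
    base = base or PhantomParams()
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        r_i = rng.uniform(*ranges.airway_inner_radius_mm)
        wall_t = rng.uniform(*ranges.airway_wall_thickness_mm)
        out.append(
            replace(
                base,
                emphysema_fraction=rng.uniform(*ranges.emphysema_fraction),
                trapping_fraction=rng.uniform(*ranges.trapping_fraction),
                hu_normal_insp=rng.uniform(*ranges.hu_normal_insp),
                hu_normal_exp=rng.uniform(*ranges.hu_normal_exp),
                airway_inner_radius_mm=r_i,
                airway_outer_radius_mm=r_i + wall_t,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out


def generate_cohort(
    n_subjects: int,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    base: PhantomParams | None = None,
) -> Iterator[CohortSubject]:
    """Yield phantom subjects one at a time (volumes are large)."""
    for i, params in enumerate(draw_cohort_params(n_subjects, ranges, seed, base)):
        insp, exp, truth = generate_phantom(params)
        yield CohortSubject(f"S{i + 1:03d}", params, insp, exp, truth)


def make_annulus_slice(
    inner_radius_mm: float = 1.8,
    outer_radius_mm: float = 3.8,
    pixel_mm: float = 0.25,
    size: int = 96,
    lumen_hu: float = -1000.0,
    wall_hu: float = 0.0,
    parenchyma_hu: float = -880.0,
) -> tuple[np.ndarray, tuple[float, float], tuple[float, float]]:
    """Ideal airway cross-section: lumen disc, annular wall, parenchyma.

    Returns (image, (sx, sy) spacing, centre in mm). The centre falls on the
    pixel grid's symmetry point so the discretised annulus is symmetric.
    """
    if not (0 < inner_radius_mm < outer_radius_mm):
        raise ValueError("require 0 < inner radius < outer radius")
    coords = (np.arange(size, dtype=np.float64) - (size - 1) / 2.0) * pixel_mm
    xx = coords[:, None]
    yy = coords[None, :]
    r2 = xx**2 + yy**2
    img = np.full((size, size), parenchyma_hu, dtype=np.float32)
    img[r2 <= outer_radius_mm**2] = wall_hu
    img[r2 <= inner_radius_mm**2] = lumen_hu
    centre = ((size - 1) / 2.0 * pixel_mm, (size - 1) / 2.0 * pixel_mm)
    return img, (pixel_mm, pixel_mm), centre
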