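"""Lung segmentation by thresholding, connected components and airway removal.

The segmenter labels air-like voxels inside the body, keeps the large
connected components as lung, and removes the airway air column by growing
a strict-air region from its most superior opening. Implausible results
raise :class:`SegmentationFailure` — a typed signal rather than a silent
empty mask — so a cohort pipeline can exclude the subject and account for
the exclusion, the way visual quality control would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import CTVolume

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationFailure",
    "SegmentationConfig",
    "LungMask",
    "QCReport",
    "segment_lungs",
    "check_segmentation",
    "dice_coefficient",
]

# 26-connectivity for 3-D components.
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationFailure(Exception):
    """Raised when no plausible lung mask can be produced."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the threshold/region segmenter.

    ``air_threshold_hu`` separates aerated lung from chest wall and
    mediastinum; -320 HU sits comfortably between parenchyma (about
    -900 HU) and soft tissue (about +40 HU). A light Gaussian pre-smooth
    makes the threshold decisions robust to reconstruction noise.
    Plausibility bounds are expressed as fractions of the field of view so
    the same defaults serve both desk-scale phantoms and human-scale grids
    (human lungs of 2-9 L occupy roughly 5-25 % of a chest CT field of
    view).
    """

    air_threshold_hu: float = -320.0
    # The final lung surface is taken this far below the air threshold,
    # near the midpoint of the parenchyma/chest-wall edge profile. This
    # keeps partial-volume chest-wall voxels out of the histogram and makes
    # the boundary second-order insensitive to image noise (the iso-contour
    # of a noisy smoothed field drifts with noise level wherever the edge
    # profile is curved, which would otherwise couple mean lung density to
    # the reconstruction algorithm).
    boundary_margin_hu: float = 150.0
    smooth_sigma_vox: float = 1.0
    min_component_fraction: float = 0.005  # of FOV, to qualify as lung
    strict_air_hu: float = -950.0          # airway lumen after smoothing
    min_airway_component_voxels: int = 30
    max_airway_fraction: float = 0.02      # of FOV; growth cap
    airway_dilation_vox: int = 2
    min_lung_fraction: float = 0.02        # plausibility bounds, of FOV
    max_lung_fraction: float = 0.60
    max_border_fraction: float = 0.01      # QC: mask voxels on grid faces


@dataclass
class LungMask:
    """Binary lung mask aligned to a CT volume."""

    mask: np.ndarray
    spacing_mm: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing_mm)) / 1000.0


@dataclass
class QCReport:
    passed: bool
    reasons: list[str]
    volume_ml: float
    border_fraction: float


def _remove_border_components(mask: np.ndarray) -> np.ndarray:
    """Drop connected components touching any face of the grid (outside air)."""
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    if n == 0:
        return mask
    border = np.zeros(mask.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        border[tuple(sl)] = True
        sl[ax] = -1
        border[tuple(sl)] = True
    touching = np.unique(labels[border & mask])
    touching = touching[touching > 0]
    if touching.size:
        mask = mask & ~np.isin(labels, touching)
    return mask


def segment_lungs(vol: CTVolume, config: SegmentationConfig | None = None) -> LungMask:
    """Segment the lungs, excluding the airway air column.

    Steps: smooth; threshold at ``air_threshold_hu``; discard air connected
    to the grid border (outside the body); keep components larger than
    ``min_component_fraction`` of the field of view; fill internal holes;
    refine the surface to ``air_threshold_hu - boundary_margin_hu`` on the
    smoothed volume; remove the airway by taking the strict-air (< ``strict_air_hu``)
    component with the most superior extent — the trachea-like opening —
    and subtracting its slightly dilated footprint; finally check the lung
    volume against plausibility bounds.

    Deterministic: identical volumes give identical masks.

    Raises
    ------
    SegmentationFailure
        If no lung-like component exists or the segmented volume falls
        outside the configured plausibility bounds.
    """
    config = config or SegmentationConfig()
    values = vol.values
    n_fov = values.size

    smoothed = ndimage.gaussian_filter(values, sigma=config.smooth_sigma_vox)
    air = smoothed < config.air_threshold_hu
    air = _remove_border_components(air)

    labels, n = ndimage.label(air, structure=_STRUCT26)
    if n == 0:
        raise SegmentationFailure("no air-like component inside the body")
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= config.min_component_fraction * n_fov) + 1
    if keep.size == 0:
        raise SegmentationFailure("no lung-like component found")
    lung = np.isin(labels, keep)
    lung = ndimage.binary_fill_holes(lung)
    lung &= smoothed < (config.air_threshold_hu - config.boundary_margin_hu)

    # Airway removal uses the unsmoothed volume: smoothing a narrow lumen
    # against its high-attenuation wall pulls it above the strict-air
    # threshold, whereas in the raw volume the lumen stays a connected air
    # column isolated from parenchymal noise by the wall ring.
    lung = _remove_airway(values, lung, config)

    lung_fraction = lung.sum() / n_fov
    if not (config.min_lung_fraction <= lung_fraction <= config.max_lung_fraction):
        raise SegmentationFailure(
            f"segmented lung occupies {lung_fraction:.1%} of the field of view, "
            f"outside plausibility bounds "
            f"[{config.min_lung_fraction:.0%}, {config.max_lung_fraction:.0%}]"
        )
    return LungMask(mask=lung, spacing_mm=vol.spacing_mm)


def _remove_airway(
    values: np.ndarray, lung: np.ndarray, config: SegmentationConfig
) -> np.ndarray:
    """Subtract the airway lumen column from the lung mask.

    Among strict-air components of sufficient size, the one reaching
    highest along z is taken as the airway (its superior opening sits above
    the lung apex). Growth is capped at ``max_airway_fraction`` of the
    field of view to stop leakage into emphysematous parenchyma.
    """
    strict_air = values < config.strict_air_hu
    strict_air = _remove_border_components(strict_air)
    labels, n = ndimage.label(strict_air, structure=_STRUCT26)
    if n == 0:
        return lung
    cap = int(config.max_airway_fraction * values.size)
    best_label, best_top = 0, -1
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        size = int((labels[sl] == lab).sum())
        if size < config.min_airway_component_voxels:
            continue
        top = sl[2].stop - 1
        if top > best_top:
            best_top, best_label = top, lab
    if best_label == 0:
        return lung
    airway = labels == best_label
    n_airway = int(airway.sum())
    if n_airway > cap:
        # Geodesic growth from the most superior voxel, capped.
        zs = np.nonzero(airway)
        top_idx = np.argmax(zs[2])
        seed = np.zeros_like(airway)
        seed[zs[0][top_idx], zs[1][top_idx], zs[2][top_idx]] = True
        grown = seed
        while grown.sum() <= cap:
            nxt = ndimage.binary_dilation(grown, structure=_STRUCT26) & airway
            if nxt.sum() == grown.sum():
                break
            grown = nxt
        airway = grown
        logger.warning("airway region growth capped at %d voxels", cap)
    airway = ndimage.binary_dilation(
        airway, structure=_STRUCT26, iterations=config.airway_dilation_vox
    )
    return lung & ~airway


def check_segmentation(
    mask: LungMask, vol: CTVolume, config: SegmentationConfig | None = None
) -> QCReport:
    """Automated surrogate for visual quality control of a lung mask.

    Fails when the mask is empty, its volume falls outside the plausibility
    bounds, or too many mask voxels lie on the grid boundary faces (a sign
    the segmentation leaked out of the body).
    """
    config = config or SegmentationConfig()
    reasons: list[str] = []
    n = mask.n_voxels
    n_fov = vol.values.size
    if n == 0:
        return QCReport(False, ["empty mask"], 0.0, 0.0)
    fraction = n / n_fov
    if not (config.min_lung_fraction <= fraction <= config.max_lung_fraction):
        reasons.append(
            f"lung volume {mask.volume_ml:.0f} ml ({fraction:.1%} of FOV) outside bounds"
        )
    border = np.zeros(mask.mask.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        border[tuple(sl)] = True
        sl[ax] = -1
        border[tuple(sl)] = True
    border_fraction = float((mask.mask & border).sum()) / n
    if border_fraction > config.max_border_fraction:
        reasons.append(f"{border_fraction:.1%} of mask voxels on the grid boundary")
    return QCReport(not reasons, reasons, mask.volume_ml, border_fraction)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
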