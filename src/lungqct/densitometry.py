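"""Histogram-based densitometry of emphysema and air trapping.

Five standard indices are computed from the attenuation histogram of the
segmented lung:

* ``IN-950`` — percentage of inspiratory lung voxels below -950 HU
  (the density mask for emphysema),
* ``Perc15`` — HU value at the 15th percentile of the inspiratory
  attenuation histogram,
* ``EXP-856`` — percentage of expiratory lung voxels below -856 HU
  (air trapping),
* ``RVC(-860..-950)`` — change (expiration minus inspiration) in the
  relative lung volume with attenuation between -860 and -950 HU,
* ``E/I-ratio(MLD)`` — 100 x expiratory / inspiratory mean lung density.

Conventions, stated because they differ between tools: "below" thresholds
are strict (<); the RVC band is inclusive at both ends and voxels below
-950 HU lie outside it; percentiles interpolate linearly between closest
order statistics at position (n-1)*p. HU values are treated as real
numbers throughout — no integer quantisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import CTVolume
from .segmentation import LungMask

__all__ = [
    "DensitometryResult",
    "compute_in950",
    "compute_perc15",
    "compute_exp856",
    "compute_rvc",
    "compute_ei_ratio",
    "compute_all",
]

EMPHYSEMA_THRESHOLD_HU = -950.0
AIR_TRAPPING_THRESHOLD_HU = -856.0
RVC_BAND_HU = (-950.0, -860.0)
PERC15_PERCENTILE = 15.0


@dataclass
class DensitometryResult:
    """The five indices plus mean lung density and lung volumes for one
    subject under one reconstruction."""

    in950_pct: float
    perc15_hu: float
    exp856_pct: float
    rvc_pct: float
    ei_ratio_pct: float
    mld_insp_hu: float
    mld_exp_hu: float
    lung_volume_insp_ml: float
    lung_volume_exp_ml: float

    def as_dict(self) -> dict[str, float]:
        return {
            "IN950": self.in950_pct,
            "Perc15": self.perc15_hu,
            "EXP856": self.exp856_pct,
            "RVC": self.rvc_pct,
            "EIratioMLD": self.ei_ratio_pct,
            "MLD_insp": self.mld_insp_hu,
            "MLD_exp": self.mld_exp_hu,
            "LungVolume_insp_ml": self.lung_volume_insp_ml,
            "LungVolume_exp_ml": self.lung_volume_exp_ml,
        }


def _masked_values(vol: CTVolume, mask: LungMask) -> np.ndarray:
    m = mask.mask
    if m.shape != vol.values.shape:
        raise ValueError("mask shape does not match volume shape")
    values = vol.values[m]
    if values.size == 0:
        raise ValueError("empty lung mask")
    return values


def compute_in950(insp: CTVolume, mask: LungMask) -> float:
    """Density-mask emphysema index: % of lung voxels strictly below -950 HU."""
    values = _masked_values(insp, mask)
    return 100.0 * float(np.count_nonzero(values < EMPHYSEMA_THRESHOLD_HU)) / values.size


def compute_perc15(insp: CTVolume, mask: LungMask) -> float:
    """HU at the 15th percentile of the lung attenuation histogram.

    Linear interpolation between closest order statistics, i.e. the value
    at fractional position (n-1) * 0.15 of the sorted sample.
    """
    values = _masked_values(insp, mask)
    return float(np.percentile(values.astype(np.float64), PERC15_PERCENTILE))


def compute_exp856(exp: CTVolume, mask: LungMask) -> float:
    """Air-trapping index: % of expiratory lung voxels strictly below -856 HU."""
    values = _masked_values(exp, mask)
    return 100.0 * float(np.count_nonzero(values < AIR_TRAPPING_THRESHOLD_HU)) / values.size


def _band_share_pct(values: np.ndarray) -> float:
    lo, hi = RVC_BAND_HU
    in_band = (values >= lo) & (values <= hi)
    return 100.0 * float(np.count_nonzero(in_band)) / values.size


def compute_rvc(
    insp: CTVolume, insp_mask: LungMask, exp: CTVolume, exp_mask: LungMask
) -> float:
    """Relative volume change in the -860 to -950 HU band, in percentage
    points (expiratory share minus inspiratory share)."""
    insp_values = _masked_values(insp, insp_mask)
    exp_values = _masked_values(exp, exp_mask)
    return _band_share_pct(exp_values) - _band_share_pct(insp_values)


def compute_ei_ratio(
    insp: CTVolume, insp_mask: LungMask, exp: CTVolume, exp_mask: LungMask
) -> float:
    """Expiratory-to-inspiratory mean-lung-density ratio, x100."""
    mld_insp = float(np.mean(_masked_values(insp, insp_mask), dtype=np.float64))
    mld_exp = float(np.mean(_masked_values(exp, exp_mask), dtype=np.float64))
    if mld_insp == 0.0:
        raise ValueError("inspiratory mean lung density is zero; ratio undefined")
    return 100.0 * mld_exp / mld_insp


def compute_all(
    insp: CTVolume, exp: CTVolume, insp_mask: LungMask, exp_mask: LungMask
) -> DensitometryResult:
    """All indices for one inspiratory/expiratory pair."""
    insp_values = _masked_values(insp, insp_mask).astype(np.float64)
    exp_values = _masked_values(exp, exp_mask).astype(np.float64)
    mld_insp = float(insp_values.mean())
    mld_exp = float(exp_values.mean())
    if mld_insp == 0.0:
        raise ValueError("inspiratory mean lung density is zero; ratio undefined")
    return DensitometryResult(
        in950_pct=100.0
        * float(np.count_nonzero(insp_values < EMPHYSEMA_THRESHOLD_HU))
        / insp_values.size,
        perc15_hu=float(np.percentile(insp_values, PERC15_PERCENTILE)),
        exp856_pct=100.0
        * float(np.count_nonzero(exp_values < AIR_TRAPPING_THRESHOLD_HU))
        / exp_values.size,
        rvc_pct=_band_share_pct(exp_values) - _band_share_pct(insp_values),
        ei_ratio_pct=100.0 * mld_exp / mld_insp,
        mld_insp_hu=mld_insp,
        mld_exp_hu=mld_exp,
        lung_volume_insp_ml=insp_mask.volume_ml,
        lung_volume_exp_ml=exp_mask.volume_ml,
    )
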