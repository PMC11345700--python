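"""Volume-wise Gaussian spatial smoothing with mask renormalization."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SmoothSpec", "FWHM_TO_SIGMA", "gaussian_smooth"]

#: FWHM = sigma * 2 sqrt(2 ln 2)
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: The three kernel presets, mm FWHM.  The conventional size labels (1x,
#: 1.5x, 2.5x the 1.5 mm voxel) are kept with the preset names even though
#: 2.5/1.5 and 3.5/1.5 are not exactly those multiples.
PRESETS_MM = {"g1x": 1.5, "g15x": 2.5, "g25x": 3.5}


@dataclass(frozen=True)
class SmoothSpec:
    """Gaussian kernel size; build from a preset with :meth:`from_preset`."""

    fwhm_mm: float

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ValueError("FWHM must be positive")

    @classmethod
    def from_preset(cls, name: str) -> "SmoothSpec":
        return cls(fwhm_mm=PRESETS_MM[name])

    def sigma_voxels(self, voxel_size_mm: float) -> float:
        return self.fwhm_mm / (voxel_size_mm * FWHM_TO_SIGMA)


def gaussian_smooth(
    series: np.ndarray,
    spec: SmoothSpec,
    brain_mask: np.ndarray,
    voxel_size_mm: float = 1.5,
) -> np.ndarray:
    """Smooth each volume of a 3D/4D array inside the brain mask.

    The convolution is mask-renormalized — data-times-mask and the mask are
    convolved separately and divided — so intensity does not bleed in from
    outside the brain and a constant in-mask field is left unchanged.
    The temporal axis is untouched.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    sigma = spec.sigma_voxels(voxel_size_mm)
    if spec.fwhm_mm < voxel_size_mm / 4.0:
        warnings.warn(
            f"FWHM {spec.fwhm_mm} mm is below a quarter voxel; smoothing is "
            "effectively the identity", stacklevel=2)
    norm = gaussian_filter(brain_mask.astype(np.float64), sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_norm = np.where(norm > 1e-12, 1.0 / norm, 0.0)

    def _one(vol: np.ndarray) -> np.ndarray:
        sm = gaussian_filter(np.where(brain_mask, vol, 0.0).astype(np.float64), sigma)
        return np.where(brain_mask, sm * inv_norm, 0.0)

    if series.ndim == 3:
        return _one(series)
    if series.ndim != 4:
        raise ValueError("series must be 3D or 4D")
    out_dtype = np.float64 if series.dtype == np.float64 else np.float32
    out = np.empty(series.shape, dtype=out_dtype)
    for t in range(series.shape[-1]):
        out[..., t] = _one(series[..., t])
    return out
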