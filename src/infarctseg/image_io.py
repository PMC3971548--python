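"""Reading, writing and normalizing co-registered DWI / ADC / mask volumes.

The segmentation pipeline operates on three co-registered, brain-masked 3-D
volumes: a diffusion-weighted image (DWI), an apparent-diffusion-coefficient
(ADC) map, and a binary brain mask.  Registration and skull stripping are
assumed to have been done upstream; this module only loads NIfTI volumes,
rescales intensities to the standard (0, 1) range, and enforces geometric
consistency across the triple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "RawVolume",
    "NormalizedVolume",
    "BrainMask",
    "read_volume",
    "read_mask",
    "normalize_intensity",
    "check_geometry",
    "write_label_map",
    "write_volume",
]

logger = logging.getLogger(__name__)

#: spacing agreement tolerance, in mm
SPACING_TOL = 1e-3


@dataclass
class RawVolume:
    """A 3-D scalar image in arbitrary scanner units.

    Parameters
    ----------
    data
        3-D array of voxel intensities; axial slices along the third axis.
    spacing
        Voxel size ``(dx, dy, dz)`` in millimetres, strictly positive.
    affine
        Optional NIfTI affine carried through for round-tripping.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.data.ndim}-D data")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class NormalizedVolume(RawVolume):
    """A 3-D scalar image with intensities rescaled into [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        dmin, dmax = float(np.min(self.data)), float(np.max(self.data))
        if dmin < 0.0 or dmax > 1.0:
            raise ValueError(
                f"normalized volume out of range: min={dmin:g}, max={dmax:g}"
            )


@dataclass
class BrainMask(RawVolume):
    """A 3-D binary brain mask (1 = inside brain)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("brain mask must be binary (values in {0, 1})")
        self.data = self.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.data.sum())


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # corrupt header / not a NIfTI
        raise OSError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D volume, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, img.affine


def read_volume(path: str | Path) -> RawVolume:
    """Read a 3-D NIfTI volume; no intensity rescaling is applied."""
    data, spacing, affine = _load_nifti(path)
    return RawVolume(data=np.asarray(data, dtype=np.float64), spacing=spacing, affine=affine)


def read_mask(path: str | Path) -> BrainMask:
    """Read a 3-D NIfTI binary mask."""
    data, spacing, affine = _load_nifti(path)
    return BrainMask(data=data, spacing=spacing, affine=affine)


def normalize_intensity(
    vol: RawVolume, clip_percentiles: tuple[float, float] | None = None
) -> NormalizedVolume:
    """Min–max rescale a volume so its intensities span the range (0, 1).

    ``x' = (x - min) / (max - min)`` over the whole volume (mask-free, since
    normalization precedes masking in the processing chain).  NaN voxels are
    treated as outside-brain and set to 0 before rescaling, with a warning.
    ``clip_percentiles`` (off by default) winsorizes to the given percentile
    pair first, for data whose global extrema are outliers.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if np.isnan(data).any():
        logger.warning(
            "volume contains %d NaN voxels; treating them as 0 (outside brain)",
            int(np.isnan(data).sum()),
        )
        data = np.nan_to_num(data, nan=0.0)
    if clip_percentiles is not None:
        lo, hi = np.percentile(data, clip_percentiles)
        data = np.clip(data, lo, hi)
    dmin, dmax = float(data.min()), float(data.max())
    if dmax == dmin:
        raise ValueError("cannot normalize a constant volume (zero dynamic range)")
    scaled = (data - dmin) / (dmax - dmin)
    return NormalizedVolume(data=scaled, spacing=vol.spacing, affine=vol.affine)


def check_geometry(
    dwi: RawVolume, adc: RawVolume, mask: BrainMask
) -> tuple[RawVolume, RawVolume, BrainMask]:
    """Verify that DWI, ADC and mask share shape and voxel spacing.

    Spacing must agree within ``SPACING_TOL`` mm.  Returns the validated
    triple unchanged; raises ``ValueError`` naming the offending volume.
    """
    ref_shape, ref_spacing = dwi.shape, dwi.spacing
    for name, vol in (("ADC", adc), ("mask", mask)):
        if vol.shape != ref_shape:
            raise ValueError(
                f"{name} shape {vol.shape} does not match DWI shape {ref_shape}"
            )
        if any(abs(a - b) > SPACING_TOL for a, b in zip(vol.spacing, ref_spacing)):
            raise ValueError(
                f"{name} spacing {vol.spacing} does not match DWI spacing "
                f"{ref_spacing} within {SPACING_TOL} mm"
            )
    return dwi, adc, mask


def _affine_for(spacing: tuple, affine: np.ndarray | None) -> np.ndarray:
    if affine is not None:
        return affine
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(vol: RawVolume, path: str | Path) -> None:
    """Write a scalar volume as NIfTI, preserving spacing."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), _affine_for(vol.spacing, vol.affine))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_label_map(
    labels: np.ndarray,
    path: str | Path,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    affine: np.ndarray | None = None,
) -> None:
    """Write an integer label map (background = 0) as NIfTI."""
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("label map must be 3-D")
    img = nib.Nifti1Image(labels.astype(np.int32), _affine_for(spacing, affine))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))
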