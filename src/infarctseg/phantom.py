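"""Synthetic DWI/ADC phantoms with ground truth for testing the pipeline.

The phantom emulates exactly the statistical features the segmentation
decisions rely on, not brain anatomy: an ellipsoidal "brain" whose in-mask
DWI histogram is unimodal with an identifiable peak; spherical lesion blobs
of four kinds, each built to trip (or pass) exactly one filter:

- ``infarct``       DWI-bright, sharp-edged, ADC-dark: the only blobs that
                    should survive to the final mask (they are the truth).
- ``faint_decoy``   DWI offset at most 0.2 above the background mode, so the
                    intensity screen (I_peak + 0.2) must remove it.
- ``blurred_decoy`` as bright as an infarct but heavily Gaussian-blurred
                    in-plane before noise, so only the weak-edge filter can
                    remove it; its ADC is dark like an infarct so the ADC
                    screen cannot be the eliminator.
- ``adc_artifact``  DWI-bright and sharp like an infarct but ADC-bright,
                    mimicking a susceptibility artifact; only the ADC
                    darker-half ratio rule can remove it.

Volumes are emitted with intensities in [0, 1] and air at 0; consumers are
expected to min-max normalize them as they would scanner data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage as ndi

from .image_io import BrainMask, NormalizedVolume, write_volume, write_label_map

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomBundle",
    "generate_phantom",
    "write_phantom_bundle",
    "read_phantom_spec",
]

KINDS = ("infarct", "faint_decoy", "blurred_decoy", "adc_artifact")


@dataclass
class LesionSpec:
    """One spherical blob.

    ``dwi_offset`` is the DWI intensity above the background mode;
    ``adc_level`` the blob's ADC intensity (None keeps the ADC background,
    for decoys that are mere DWI noise).  ``blur_sigma`` (voxels, in-plane)
    applies only to blurred decoys.
    """

    center: tuple[int, int, int]
    radius_mm: float
    kind: str
    dwi_offset: float
    adc_level: float | None = None
    blur_sigma: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}; expected one of {KINDS}")
        if self.kind == "infarct" and self.dwi_offset < 0.25:
            raise ValueError("infarct blobs need dwi_offset >= 0.25")
        if self.kind == "faint_decoy" and not 0.0 < self.dwi_offset <= 0.2:
            raise ValueError("faint decoys need 0 < dwi_offset <= 0.2")
        if self.kind in ("blurred_decoy", "adc_artifact") and self.dwi_offset < 0.25:
            raise ValueError(f"{self.kind} blobs need dwi_offset >= 0.25")


def _default_lesions() -> list[LesionSpec]:
    """The standard four-blob layout on the default 64x64x16 grid.

    All bright blobs share the central slices so every slice containing a
    blurred decoy also contains a sharp gradient reference, as skull and CSF
    interfaces provide in real data.  ADC levels: infarct and blurred decoy
    dark (0.15 = 0.375 of the ADC background mode 0.4, safely below the 0.5
    artifact ratio), artifact bright (0.55 = 1.375 of the mode, above it).
    """
    return [
        LesionSpec(center=(19, 32, 8), radius_mm=11.0, kind="infarct",
                   dwi_offset=0.45, adc_level=0.15),
        LesionSpec(center=(32, 15, 8), radius_mm=9.0, kind="faint_decoy",
                   dwi_offset=0.12, adc_level=None),
        LesionSpec(center=(45, 32, 8), radius_mm=11.0, kind="blurred_decoy",
                   dwi_offset=0.45, adc_level=0.15, blur_sigma=4.0),
        LesionSpec(center=(32, 49, 8), radius_mm=9.0, kind="adc_artifact",
                   dwi_offset=0.45, adc_level=0.55),
    ]


@dataclass
class PhantomSpec:
    """Geometry, background modes, noise level and lesion layout."""

    shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.79, 1.79, 5.0)
    background_mode: float = 0.3
    adc_background_mode: float = 0.4
    noise_sd: float = 0.02
    lesions: list[LesionSpec] = field(default_factory=_default_lesions)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.background_mode < 1.0:
            raise ValueError("background_mode must lie in (0, 1)")
        if not 0.0 < self.adc_background_mode < 1.0:
            raise ValueError("adc_background_mode must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.lesions = [
            l if isinstance(l, LesionSpec) else LesionSpec(**l) for l in self.lesions
        ]


@dataclass
class PhantomBundle:
    dwi: NormalizedVolume
    adc: NormalizedVolume
    mask: BrainMask
    truth: np.ndarray           # union of infarct blobs
    artifact_truth: np.ndarray  # union of adc_artifact blobs
    lesion_masks: list          # per-lesion binary grids, aligned with spec.lesions
    spec: PhantomSpec = None


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.44 * nx, 0.44 * ny, 0.48 * nz
    x, y, z = np.ogrid[:nx, :ny, :nz]
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _sphere_mask(shape, spacing, center, radius_mm) -> np.ndarray:
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        ((x - center[0]) * spacing[0]) ** 2
        + ((y - center[1]) * spacing[1]) ** 2
        + ((z - center[2]) * spacing[2]) ** 2
    )
    return d2 <= radius_mm**2


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build the DWI, ADC, mask, truth and per-lesion masks for ``spec``.

    Deterministic given ``spec.seed``.  Lesions of different kinds must not
    overlap (the ground truth would be ambiguous).
    """
    shape, spacing = tuple(spec.shape), tuple(spec.spacing)
    brain = _ellipsoid_mask(shape)

    lesion_masks = []
    for les in spec.lesions:
        region = _sphere_mask(shape, spacing, les.center, les.radius_mm)
        if not (region & brain).sum() == region.sum():
            raise ValueError(f"lesion at {les.center} does not fit inside the brain")
        lesion_masks.append(region)
    for i, (li, mi) in enumerate(zip(spec.lesions, lesion_masks)):
        for lj, mj in zip(spec.lesions[i + 1:], lesion_masks[i + 1:]):
            if li.kind != lj.kind and (mi & mj).any():
                raise ValueError(
                    f"overlapping lesions of different kinds ({li.kind}, {lj.kind})"
                )

    dwi = np.zeros(shape)
    adc = np.zeros(shape)
    dwi[brain] = spec.background_mode
    adc[brain] = spec.adc_background_mode

    for les, region in zip(spec.lesions, lesion_masks):
        if les.kind == "blurred_decoy":
            # blur the DWI contribution in-plane before noise: same brightness
            # as an infarct but without a sharp margin
            bump = np.where(region, les.dwi_offset, 0.0)
            bump = ndi.gaussian_filter(bump, sigma=(les.blur_sigma, les.blur_sigma, 0))
            dwi += np.where(brain, bump, 0.0)
        else:
            dwi[region] = spec.background_mode + les.dwi_offset
        if les.adc_level is not None:
            adc[region] = les.adc_level

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        dwi[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
        adc[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
    np.clip(dwi, 0.0, 1.0, out=dwi)
    np.clip(adc, 0.0, 1.0, out=adc)

    truth = np.zeros(shape, dtype=bool)
    artifact_truth = np.zeros(shape, dtype=bool)
    for les, region in zip(spec.lesions, lesion_masks):
        if les.kind == "infarct":
            truth |= region
        elif les.kind == "adc_artifact":
            artifact_truth |= region

    return PhantomBundle(
        dwi=NormalizedVolume(data=dwi, spacing=spacing),
        adc=NormalizedVolume(data=adc, spacing=spacing),
        mask=BrainMask(data=brain.astype(np.uint8), spacing=spacing),
        truth=truth,
        artifact_truth=artifact_truth,
        lesion_masks=lesion_masks,
        spec=spec,
    )


def write_phantom_bundle(spec: PhantomSpec, out_dir: str | Path) -> dict:
    """Generate and write dwi/adc/mask/truth/artifact_truth NIfTIs + the spec.

    Returns the mapping of component name to written path.  The recorded
    spec regenerates the identical phantom.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = generate_phantom(spec)
    paths = {}
    for name, vol in (("dwi", bundle.dwi), ("adc", bundle.adc)):
        paths[name] = out_dir / f"{name}.nii.gz"
        write_volume(vol, paths[name])
    for name, grid in (
        ("mask", bundle.mask.data),
        ("truth", bundle.truth),
        ("artifact_truth", bundle.artifact_truth),
    ):
        paths[name] = out_dir / f"{name}.nii.gz"
        write_label_map(grid.astype(np.int32), paths[name], spacing=spec.spacing)
    record = asdict(spec)
    record["shape"] = list(spec.shape)
    record["spacing"] = [float(s) for s in spec.spacing]
    paths["spec"] = out_dir / "phantom_spec.yaml"
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=False)
    return paths


def read_phantom_spec(path: str | Path) -> PhantomSpec:
    """Load a phantom spec record written by :func:`write_phantom_bundle`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["shape"] = tuple(raw["shape"])
    raw["spacing"] = tuple(raw["spacing"])
    raw["lesions"] = [
        LesionSpec(**{**l, "center": tuple(l["center"])}) for l in raw["lesions"]
    ]
    return PhantomSpec(**raw)
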