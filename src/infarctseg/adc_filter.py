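"""ADC-based rejection of magnetic-inhomogeneity artifacts.

Susceptibility (echo-planar) artifacts near air/tissue interfaces mimic
infarct brightness on DWI but, unlike true acute infarcts (restricted
diffusion, ADC-dark), they stay relatively bright on the ADC map.  A
candidate label is declared an artifact when the mean ADC intensity of its
lower-intensity half reaches at least half the ADC map's histographic peak
intensity:

    I_lower_mean,ADC / I_peak,ADC  >=  artifact_ratio   (default 0.5)

The ratio is scale-invariant, so it is unaffected by how the ADC map was
normalized.  All labels surviving this screen constitute the final infarct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histogram import compute_histogram, DEFAULT_N_BINS
from .image_io import BrainMask, NormalizedVolume
from .screening import LesionLabel

__all__ = [
    "AdcScreenResult",
    "DEFAULT_ARTIFACT_RATIO",
    "adc_peak",
    "lower_half_mean",
    "screen_labels_by_adc",
]

DEFAULT_ARTIFACT_RATIO = 0.5


@dataclass
class AdcScreenResult:
    label_id: int
    lower_half_mean: float  # mean ADC intensity of the label's darker half
    ratio: float            # lower_half_mean / I_peak,ADC
    is_artifact: bool


def adc_peak(adc: NormalizedVolume, mask: BrainMask, n_bins: int = DEFAULT_N_BINS) -> float:
    """Histographic peak intensity of the ADC map, ``I_peak,ADC``.

    Uses the same binning, smoothing and tie-break as the DWI histogram.
    """
    return compute_histogram(adc, mask, n_bins=n_bins).peak_intensity


def lower_half_mean(label: LesionLabel, adc: NormalizedVolume) -> float:
    """Mean ADC intensity of the lower-intensity half of the label's voxels.

    The half is the first ``ceil(n/2)`` values in ascending order, so it is
    nonempty even for a single-voxel label.
    """
    vals = np.sort(adc.data[tuple(label.voxels.T)])
    if vals.size == 0:
        raise ValueError("empty label")
    half = (vals.size + 1) // 2
    return float(vals[:half].mean())


def screen_labels_by_adc(
    labels: list[LesionLabel],
    adc: NormalizedVolume,
    peak_adc: float,
    artifact_ratio: float = DEFAULT_ARTIFACT_RATIO,
) -> tuple[list[LesionLabel], list[LesionLabel], list[AdcScreenResult]]:
    """Eliminate labels whose darker-half ADC intensity is too high.

    A label with ``lower_half_mean / peak_adc >= artifact_ratio`` gets
    verdict ``adc_artifact`` (the inequality is inclusive).  Returns
    ``(retained, eliminated, screen_results)``; the retained labels are the
    final infarct set.
    """
    if peak_adc <= 0:
        raise ValueError("peak_adc must be > 0 (degenerate ADC normalization)")
    retained, eliminated, results = [], [], []
    for lab in labels:
        lhm = lower_half_mean(lab, adc)
        ratio = lhm / peak_adc
        is_artifact = ratio >= artifact_ratio
        results.append(
            AdcScreenResult(
                label_id=lab.label_id,
                lower_half_mean=lhm,
                ratio=ratio,
                is_artifact=is_artifact,
            )
        )
        if is_artifact:
            lab.verdict = "adc_artifact"
            eliminated.append(lab)
        else:
            retained.append(lab)
    return retained, eliminated, results
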