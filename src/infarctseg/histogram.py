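"""In-mask intensity histogram, its smoothed peak, and preclustering elimination.

Acute infarcts are hyperintense on DWI, so the bulk of normal brain tissue
forms a single dominant mode in the in-mask intensity histogram.  The
intensity at that mode, ``I_peak``, is a self-adaptive lower bound: voxels at
or below it are almost certainly not infarct and are eliminated before
clustering, which both removes obvious non-lesion tissue and shrinks the
clustering problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import BrainMask, NormalizedVolume

__all__ = [
    "HistogramProfile",
    "CandidateVoxelSet",
    "compute_histogram",
    "precluster_eliminate",
]

DEFAULT_N_BINS = 256


@dataclass
class HistogramProfile:
    """Binned in-mask intensity distribution with a smoothed peak.

    ``smoothed_counts`` is the 3-point centered moving average of ``counts``
    (the window shrinks to the available bins at the ends).  ``peak_intensity``
    is the bin-center intensity at the argmax of the smoothed counts; among
    tied smoothed maxima the bin with the highest raw count wins (smoothing a
    single-bin spike produces a flat 3-bin plateau whose true mode is the
    middle), and remaining ties break toward the lower-intensity bin so the
    downstream threshold stays conservative.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed_counts: np.ndarray
    peak_intensity: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class CandidateVoxelSet:
    """Voxels surviving preclustering elimination (intensity > I_peak)."""

    coordinates: np.ndarray  # (n, 3) int voxel indices
    intensities: np.ndarray  # (n,) normalized DWI values

    def __len__(self) -> int:
        return len(self.intensities)


def moving_average3(counts: np.ndarray) -> np.ndarray:
    """3-point centered moving average; the window shrinks at the ends."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.size == 0:
        return counts
    csum = np.cumsum(np.concatenate(([0.0], counts)))
    n = counts.size
    lo = np.maximum(np.arange(n) - 1, 0)
    hi = np.minimum(np.arange(n) + 2, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def peak_bin(counts: np.ndarray, smoothed: np.ndarray) -> int:
    """Index of the histographic peak on the smoothed curve.

    Ties between smoothed maxima are broken by the higher raw count, then by
    the lower bin index.
    """
    tied = np.flatnonzero(smoothed == smoothed.max())
    return int(tied[np.argmax(counts[tied])])  # argmax keeps the first on ties


def compute_histogram(
    vol: NormalizedVolume, mask: BrainMask, n_bins: int = DEFAULT_N_BINS
) -> HistogramProfile:
    """Histogram the in-mask intensities over uniform bins on [0, 1].

    The raw counts are smoothed with a third-order (3-point) moving-average
    filter and the peak intensity is read off the smoothed curve.
    """
    if n_bins < 8:
        raise ValueError(f"n_bins must be >= 8, got {n_bins}")
    in_mask = vol.data[mask.data]
    if in_mask.size == 0:
        raise ValueError("empty brain mask: no voxels to histogram")
    counts, edges = np.histogram(in_mask, bins=n_bins, range=(0.0, 1.0))
    smoothed = moving_average3(counts)
    pk = peak_bin(counts, smoothed)
    peak_intensity = float(0.5 * (edges[pk] + edges[pk + 1]))
    return HistogramProfile(
        bin_edges=edges,
        counts=counts,
        smoothed_counts=smoothed,
        peak_intensity=peak_intensity,
    )


def precluster_eliminate(
    vol: NormalizedVolume, mask: BrainMask, peak: float
) -> CandidateVoxelSet:
    """Keep exactly the in-mask voxels with intensity strictly above ``peak``.

    Voxels at or below the histographic peak are eliminated from all further
    processing.
    """
    if not 0.0 <= peak <= 1.0:
        raise ValueError(f"peak intensity must lie in [0, 1], got {peak}")
    survivors = mask.data & (vol.data > peak)
    coords = np.argwhere(survivors)
    return CandidateVoxelSet(
        coordinates=coords,
        intensities=vol.data[survivors.nonzero()],
    )
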