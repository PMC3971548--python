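"""Candidate-label screening: cluster skimming, connected components,
intensity filtering, and weak-edge elimination.

After clustering, only clusters whose mean intensity clears the adaptive
threshold ``I_peak + offset`` are kept ("skimming").  Their voxels are split
into connected components ("labels"); labels that are faint on average are
dropped, and labels whose boundaries find no support in a Canny edge map of
the DWI are dropped as weak-edge false positives (real acute infarcts have
sharp margins on DWI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny

from .fcm import FCMResult
from .image_io import NormalizedVolume

__all__ = [
    "LesionLabel",
    "EdgeMap",
    "VERDICTS",
    "skim_clusters",
    "label_components",
    "filter_labels_by_intensity",
    "canny_edge_map",
    "filter_labels_by_edge",
]

VERDICTS = ("retained", "low_intensity", "weak_edge", "adc_artifact")

DEFAULT_THRESHOLD_OFFSET = 0.2
DEFAULT_CANNY_SIGMA = 1.0
DEFAULT_CANNY_LOW = 0.0
DEFAULT_CANNY_HIGH = 0.3
DEFAULT_EDGE_SUPPORT_MIN = 0.5

#: 26-connectivity in 3-D (faces, edges, corners)
STRUCT_3D26 = np.ones((3, 3, 3), dtype=bool)
#: 8-connectivity within each axial slice, no inter-slice links
STRUCT_8_PER_SLICE = np.zeros((3, 3, 3), dtype=bool)
STRUCT_8_PER_SLICE[:, :, 1] = True

_CONNECTIVITY = {"3d26": STRUCT_3D26, "8-per-slice": STRUCT_8_PER_SLICE}


@dataclass
class LesionLabel:
    """One connected component of candidate voxels with screening verdicts."""

    label_id: int
    voxels: np.ndarray          # (n, 3) int voxel indices
    mean_dwi: float
    source_cluster: int = -1    # majority cluster of the component's voxels
    edge_support: float | None = None
    verdict: str = "retained"

    @property
    def size(self) -> int:
        return len(self.voxels)

    def as_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


@dataclass
class EdgeMap:
    """Binary edge-voxel grid with the Canny parameters that produced it."""

    data: np.ndarray
    params: tuple[float, float, float]  # (low_threshold, high_threshold, sigma)


def skim_clusters(result: FCMResult, peak: float, offset: float = DEFAULT_THRESHOLD_OFFSET) -> np.ndarray:
    """Indices of clusters with mean intensity strictly above ``peak + offset``."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    return np.flatnonzero(result.cluster_means > peak + offset)


def label_components(
    voxels: np.ndarray,
    dwi: NormalizedVolume,
    connectivity: str = "3d26",
    cluster_of_voxel: np.ndarray | None = None,
) -> list[LesionLabel]:
    """Partition a voxel set into maximal connected components.

    Components are taken over the full candidate voxel set (the union of the
    skimmed clusters), under 26-connectivity by default so a lesion spanning
    slices forms a single label; ``"8-per-slice"`` restricts connectivity to
    within axial slices.  ``cluster_of_voxel``, aligned with ``voxels``,
    records each component's majority source cluster.
    """
    voxels = np.asarray(voxels)
    if voxels.size == 0:
        return []
    structure = _CONNECTIVITY[connectivity]
    grid = np.zeros(dwi.shape, dtype=bool)
    grid[tuple(voxels.T)] = True
    labeled, n = ndi.label(grid, structure=structure)
    out: list[LesionLabel] = []
    cluster_grid = None
    if cluster_of_voxel is not None:
        cluster_grid = np.full(dwi.shape, -1, dtype=np.int64)
        cluster_grid[tuple(voxels.T)] = np.asarray(cluster_of_voxel)
    for lid in range(1, n + 1):
        coords = np.argwhere(labeled == lid)
        vals = dwi.data[tuple(coords.T)]
        source = -1
        if cluster_grid is not None:
            members = cluster_grid[tuple(coords.T)]
            source = int(np.bincount(members).argmax())
        out.append(
            LesionLabel(
                label_id=lid,
                voxels=coords,
                mean_dwi=float(vals.mean()),
                source_cluster=source,
            )
        )
    return out


def filter_labels_by_intensity(
    labels: list[LesionLabel], peak: float, offset: float = DEFAULT_THRESHOLD_OFFSET
) -> tuple[list[LesionLabel], list[LesionLabel]]:
    """Keep labels with mean DWI intensity strictly above ``peak + offset``.

    Labels at or below the threshold get verdict ``low_intensity``.  Returns
    ``(retained, eliminated)``.
    """
    retained, eliminated = [], []
    thr = peak + offset
    for lab in labels:
        if lab.mean_dwi > thr:
            retained.append(lab)
        else:
            lab.verdict = "low_intensity"
            eliminated.append(lab)
    return retained, eliminated


def _slice_gradient_max(img: np.ndarray, sigma: float) -> float:
    """Max Sobel gradient magnitude of the Gaussian-smoothed slice.

    Mirrors the operators the Canny implementation applies internally, so
    that fractional hysteresis thresholds can be expressed on its scale.
    """
    sm = ndi.gaussian_filter(img, sigma, mode="constant")
    g = np.hypot(ndi.sobel(sm, axis=0, mode="constant"), ndi.sobel(sm, axis=1, mode="constant"))
    return float(g.max())


def canny_edge_map(
    dwi: NormalizedVolume,
    sigma: float = DEFAULT_CANNY_SIGMA,
    low: float = DEFAULT_CANNY_LOW,
    high: float = DEFAULT_CANNY_HIGH,
) -> EdgeMap:
    """Per-axial-slice 2-D Canny edge detection on the normalized DWI.

    The hysteresis thresholds ``(low, high)`` are fractions of each slice's
    maximum smoothed gradient magnitude, so ``high = 0.3`` means "at least
    30 % of the strongest gradient in the slice".  Slices are processed in
    2-D because the thick, gapped axial slices make through-plane gradients
    unreliable.  A gradient-free (constant) slice yields no edges.
    """
    edges = np.zeros(dwi.shape, dtype=bool)
    for z in range(dwi.shape[2]):
        sl = dwi.data[:, :, z]
        gmax = _slice_gradient_max(sl, sigma)
        if gmax <= 0:
            continue
        edges[:, :, z] = canny(
            sl,
            sigma=sigma,
            low_threshold=low * gmax,
            high_threshold=high * gmax,
        )
    return EdgeMap(data=edges, params=(low, high, sigma))


_STRUCT_2D8 = np.ones((3, 3), dtype=bool)


def _boundary_2d(mask3d: np.ndarray) -> np.ndarray:
    """Per-slice 8-neighborhood boundary of a 3-D binary region."""
    boundary = np.zeros_like(mask3d)
    for z in range(mask3d.shape[2]):
        sl = mask3d[:, :, z]
        if not sl.any():
            continue
        eroded = ndi.binary_erosion(sl, structure=_STRUCT_2D8, border_value=0)
        boundary[:, :, z] = sl & ~eroded
    return boundary


def filter_labels_by_edge(
    labels: list[LesionLabel],
    edges: EdgeMap,
    support_min: float = DEFAULT_EDGE_SUPPORT_MIN,
) -> tuple[list[LesionLabel], list[LesionLabel]]:
    """Eliminate labels whose boundaries lack Canny edge support.

    For each label, ``edge_support`` is the fraction of its per-slice
    8-neighborhood boundary voxels lying within 1 voxel (in-plane) of an edge
    voxel.  Labels with support below ``support_min`` get verdict
    ``weak_edge``.  Returns ``(retained, eliminated)``.
    """
    if not 0.0 <= support_min <= 1.0:
        raise ValueError("support_min must lie in [0, 1]")
    shape = edges.data.shape
    dilated = np.zeros(shape, dtype=bool)
    for z in range(shape[2]):
        if edges.data[:, :, z].any():
            dilated[:, :, z] = ndi.binary_dilation(edges.data[:, :, z], structure=_STRUCT_2D8)
    retained, eliminated = [], []
    for lab in labels:
        region = lab.as_mask(shape)
        boundary = _boundary_2d(region)
        n_boundary = int(boundary.sum())
        support = float((boundary & dilated).sum() / n_boundary) if n_boundary else 0.0
        lab.edge_support = support
        if support >= support_min:
            retained.append(lab)
        else:
            lab.verdict = "weak_edge"
            eliminated.append(lab)
    return retained, eliminated
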