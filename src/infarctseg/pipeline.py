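"""End-to-end infarct segmentation pipeline.

Runs the full chain on a normalized DWI / ADC / mask triple:

    histogram peak -> preclustering elimination -> FCM clustering ->
    cluster skimming -> connected-component labeling ->
    label intensity filter -> weak-edge filter -> ADC artifact filter

Each stage can only remove candidate voxels, never add any, and the whole
run is deterministic given the seed.  Stage-by-stage voxel masks and counts
are recorded so the shrinkage can be audited and eliminations attributed to
the filter responsible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import adc_filter, fcm, histogram, screening
from .image_io import BrainMask, NormalizedVolume, check_geometry

__all__ = [
    "PipelineConfig",
    "SegmentationResult",
    "RepeatedRunSummary",
    "segment_infarct",
    "compute_volume",
    "repeat_runs",
    "classify_region",
]

logger = logging.getLogger(__name__)

#: pipeline stages in execution order (keys of SegmentationResult.stage_masks)
STAGES = ("in_mask", "precluster", "skim", "intensity", "edge", "final")


@dataclass
class PipelineConfig:
    """All tunable knobs of the segmentation chain.

    Defaults are the published operating point: 50 clusters, intensity
    threshold offset 0.2 above the histographic peak, per-slice Canny with
    sigma 1 and relative hysteresis thresholds (0, 0.3), and ADC artifact
    ratio 0.5.
    """

    n_bins: int = histogram.DEFAULT_N_BINS
    n_clusters: int = 50
    fuzzifier_m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    threshold_offset: float = screening.DEFAULT_THRESHOLD_OFFSET
    connectivity: str = "3d26"
    canny_sigma: float = screening.DEFAULT_CANNY_SIGMA
    canny_low: float = screening.DEFAULT_CANNY_LOW
    canny_high: float = screening.DEFAULT_CANNY_HIGH
    edge_support_min: float = screening.DEFAULT_EDGE_SUPPORT_MIN
    artifact_ratio: float = adc_filter.DEFAULT_ARTIFACT_RATIO
    seed: int = 0
    n_repeats: int = 1
    #: use this thickness (mm) instead of the header dz when computing volume,
    #: for acquisitions where slice thickness differs from slice spacing
    slice_thickness_override: float | None = None

    def fcm_config(self) -> fcm.FCMConfig:
        return fcm.FCMConfig(
            n_clusters=self.n_clusters,
            fuzzifier_m=self.fuzzifier_m,
            tol=self.tol,
            max_iter=self.max_iter,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SegmentationResult:
    infarct_mask: np.ndarray                      # final binary infarct grid
    labels: list                                  # all LesionLabels with verdicts
    dwi_histogram: histogram.HistogramProfile
    adc_histogram: histogram.HistogramProfile
    peak_dwi: float
    peak_adc: float
    adc_screens: list
    volume_ml: float
    stage_masks: dict                             # stage name -> bool grid
    stage_counts: dict                            # stage name -> voxel count
    config: PipelineConfig
    seed: int

    @property
    def retained_labels(self) -> list:
        return [l for l in self.labels if l.verdict == "retained"]


@dataclass
class RepeatedRunSummary:
    results: list
    volumes_ml: np.ndarray
    mean_volume_ml: float
    sd_volume_ml: float
    seeds: list
    sd_is_degenerate: bool = False  # flagged when n_repeats == 1


def compute_volume(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    slice_thickness: float | None = None,
) -> float:
    """Infarct volume in mL: voxel count x in-plane area x slice thickness.

    ``slice_thickness`` defaults to the through-plane spacing ``dz``; pass an
    override when the acquisition's slice thickness differs from the slice
    spacing (e.g. gapped slices).
    """
    dx, dy, dz = spacing
    if min(dx, dy, dz) <= 0:
        raise ValueError("spacing must be positive")
    thickness = dz if slice_thickness is None else float(slice_thickness)
    return float(np.count_nonzero(mask) * dx * dy * thickness / 1000.0)


def _voxel_mask(shape, coords: np.ndarray) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    if len(coords):
        m[tuple(np.asarray(coords).T)] = True
    return m


def _labels_mask(shape, labels) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    for lab in labels:
        m[tuple(lab.voxels.T)] = True
    return m


def segment_infarct(
    dwi: NormalizedVolume,
    adc: NormalizedVolume,
    mask: BrainMask,
    config: PipelineConfig | None = None,
) -> SegmentationResult:
    """Segment acute infarct from a co-registered, normalized DWI/ADC/mask triple."""
    config = config or PipelineConfig()
    check_geometry(dwi, adc, mask)
    shape = dwi.shape

    # adaptive threshold from the in-mask DWI histogram
    dwi_hist = histogram.compute_histogram(dwi, mask, config.n_bins)
    peak = dwi_hist.peak_intensity
    adc_hist = histogram.compute_histogram(adc, mask, config.n_bins)
    peak_adc = adc_hist.peak_intensity

    stage_masks = {"in_mask": mask.data.copy()}

    # preclustering elimination: drop voxels at or below the peak
    candidates = histogram.precluster_eliminate(dwi, mask, peak)
    stage_masks["precluster"] = _voxel_mask(shape, candidates.coordinates)

    empty = SegmentationResult(
        infarct_mask=np.zeros(shape, dtype=bool),
        labels=[],
        dwi_histogram=dwi_hist,
        adc_histogram=adc_hist,
        peak_dwi=peak,
        peak_adc=peak_adc,
        adc_screens=[],
        volume_ml=0.0,
        stage_masks=stage_masks,
        stage_counts={},
        config=config,
        seed=config.seed,
    )

    if len(candidates) == 0:
        logger.info("no voxels above the histographic peak; empty segmentation")
        for s in ("skim", "intensity", "edge", "final"):
            empty.stage_masks[s] = np.zeros(shape, dtype=bool)
        empty.stage_counts = {s: int(m.sum()) for s, m in empty.stage_masks.items()}
        return empty

    # fuzzy clustering of candidate intensities (1-D feature space)
    fcm_result = fcm.fcm_cluster(candidates.intensities, config.fcm_config())

    # cluster skimming: keep clusters with mean above peak + offset
    skimmed = screening.skim_clusters(fcm_result, peak, config.threshold_offset)
    in_skimmed = np.isin(fcm_result.hard_assignment, skimmed)
    skim_coords = candidates.coordinates[in_skimmed]
    stage_masks["skim"] = _voxel_mask(shape, skim_coords)

    # connected-component labels over the skimmed voxels
    labels = screening.label_components(
        skim_coords,
        dwi,
        connectivity=config.connectivity,
        cluster_of_voxel=fcm_result.hard_assignment[in_skimmed],
    )

    # label-level intensity screen (same threshold as the skim)
    bright, faint = screening.filter_labels_by_intensity(
        labels, peak, config.threshold_offset
    )
    stage_masks["intensity"] = _labels_mask(shape, bright)

    # weak-edge elimination against the per-slice Canny map
    edges = screening.canny_edge_map(
        dwi, sigma=config.canny_sigma, low=config.canny_low, high=config.canny_high
    )
    strong, weak = screening.filter_labels_by_edge(
        bright, edges, config.edge_support_min
    )
    stage_masks["edge"] = _labels_mask(shape, strong)

    # ADC screen for magnetic-inhomogeneity artifacts
    retained, artifacts, adc_screens = adc_filter.screen_labels_by_adc(
        strong, adc, peak_adc, config.artifact_ratio
    )
    infarct_mask = _labels_mask(shape, retained)
    stage_masks["final"] = infarct_mask

    all_labels = retained + faint + weak + artifacts
    all_labels.sort(key=lambda l: l.label_id)
    stage_counts = {s: int(stage_masks[s].sum()) for s in STAGES}
    logger.info("stage voxel counts: %s", stage_counts)

    return SegmentationResult(
        infarct_mask=infarct_mask,
        labels=all_labels,
        dwi_histogram=dwi_hist,
        adc_histogram=adc_hist,
        peak_dwi=peak,
        peak_adc=peak_adc,
        adc_screens=adc_screens,
        volume_ml=compute_volume(
            infarct_mask, dwi.spacing, config.slice_thickness_override
        ),
        stage_masks=stage_masks,
        stage_counts=stage_counts,
        config=config,
        seed=config.seed,
    )


def repeat_runs(
    dwi: NormalizedVolume,
    adc: NormalizedVolume,
    mask: BrainMask,
    config: PipelineConfig | None = None,
    n_repeats: int | None = None,
) -> RepeatedRunSummary:
    """Run the pipeline repeatedly with seeds ``base_seed + i``.

    The only stochastic element is the FCM center initialization, so the
    spread of the per-run volumes measures clustering stability.  The SD is
    the sample standard deviation; with a single run it is reported as 0 and
    flagged degenerate.
    """
    import dataclasses

    config = config or PipelineConfig()
    n = n_repeats if n_repeats is not None else config.n_repeats
    if n < 1:
        raise ValueError("n_repeats must be >= 1")
    results, seeds = [], []
    for i in range(n):
        run_cfg = dataclasses.replace(config, seed=config.seed + i)
        results.append(segment_infarct(dwi, adc, mask, run_cfg))
        seeds.append(run_cfg.seed)
    volumes = np.array([r.volume_ml for r in results])
    degenerate = n == 1
    if degenerate:
        logger.warning("n_repeats == 1: volume SD reported as 0 by convention")
    return RepeatedRunSummary(
        results=results,
        volumes_ml=volumes,
        mean_volume_ml=float(volumes.mean()),
        sd_volume_ml=0.0 if degenerate else float(volumes.std(ddof=1)),
        seeds=seeds,
        sd_is_degenerate=degenerate,
    )


def classify_region(
    result: SegmentationResult, region: np.ndarray, min_fraction: float = 0.5
) -> str:
    """Attribute a region's fate to the pipeline stage that eliminated it.

    Follows the fraction of the region's voxels surviving each stage and
    reports the first stage at which the surviving fraction (relative to the
    region's in-mask size) drops below ``min_fraction``:

    - ``"retained"``: the majority of the region is in the final mask;
    - ``"preclustering"``: removed by the histographic-peak threshold;
    - ``"intensity"``: removed by the ``I_peak + offset`` screen, whether at
      the cluster-skim or the label level (the two share one threshold);
    - ``"weak_edge"``: removed by the Canny edge-support filter;
    - ``"adc_artifact"``: removed by the ADC darker-half ratio rule;
    - ``"outside_mask"``: the region does not meaningfully intersect the brain.
    """
    region = np.asarray(region, dtype=bool)
    base = int((region & result.stage_masks["in_mask"]).sum())
    if base == 0:
        return "outside_mask"

    def frac(stage: str) -> float:
        return float((region & result.stage_masks[stage]).sum() / base)

    if frac("final") >= min_fraction:
        return "retained"
    if frac("precluster") < min_fraction:
        return "preclustering"
    if frac("intensity") < min_fraction:
        return "intensity"
    if frac("edge") < min_fraction:
        return "weak_edge"
    return "adc_artifact"
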