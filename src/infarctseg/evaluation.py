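"""Agreement metrics between automatic and reference segmentations.

Voxelwise confusion counts within the brain mask feed the similarity index
(SI, identical to the Dice coefficient), Cohen's kappa, and the four
predictive metrics (sensitivity, specificity, PPV, NPV).  Volume agreement
over a cohort is summarized by the intraclass correlation coefficient
(two-way random effects, absolute agreement, single measures) and by the
signed relative volume difference.  A cluster-number calibration sweep
re-runs the front half of the pipeline for a range of K and scores each
against a reference mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import fcm, histogram, screening
from .image_io import BrainMask, NormalizedVolume
from .pipeline import PipelineConfig, compute_volume

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion",
    "similarity_index",
    "cohen_kappa",
    "predictive_metrics",
    "delta_vol",
    "icc_volumes",
    "evaluate_masks",
    "sweep_cluster_number",
]


@dataclass
class ConfusionCounts:
    """Voxelwise TP/TN/FP/FN within the brain mask."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvaluationReport:
    counts: ConfusionCounts
    si: float
    kappa: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    vol_auto: float
    vol_ref: float
    delta_vol: float

    def as_percent_row(self) -> dict:
        """Metrics x100, rounded to 3 decimals as agreement tables print them."""
        pct = lambda v: round(100.0 * v, 3) if not math.isnan(v) else float("nan")
        return {
            "SI (%)": pct(self.si),
            "Kappa (%)": pct(self.kappa),
            "Sen. (%)": pct(self.sensitivity),
            "Spe. (%)": pct(self.specificity),
            "PPV (%)": pct(self.ppv),
            "NPV (%)": pct(self.npv),
            "Auto vol (mL)": round(self.vol_auto, 3),
            "Ref vol (mL)": round(self.vol_ref, 3),
            "dVol (%)": round(100.0 * self.delta_vol, 1),
        }


def confusion(auto: np.ndarray, ref: np.ndarray, mask: BrainMask) -> ConfusionCounts:
    """Confusion counts restricted to in-mask voxels."""
    auto = np.asarray(auto, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if auto.shape != ref.shape or auto.shape != mask.data.shape:
        raise ValueError(
            f"shape mismatch: auto {auto.shape}, ref {ref.shape}, mask {mask.data.shape}"
        )
    a = auto[mask.data]
    r = ref[mask.data]
    return ConfusionCounts(
        tp=int((a & r).sum()),
        tn=int((~a & ~r).sum()),
        fp=int((a & ~r).sum()),
        fn=int((~a & r).sum()),
    )


def similarity_index(c: ConfusionCounts) -> float:
    """SI = 2 TP / (2 TP + FP + FN); NaN when both masks are empty."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return float("nan")
    return 2.0 * c.tp / denom


def cohen_kappa(c: ConfusionCounts) -> float:
    """Chance-corrected voxelwise agreement; NaN when expected agreement is 1."""
    n = c.total
    if n == 0:
        raise ValueError("empty confusion table")
    po = (c.tp + c.tn) / n
    pe = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / n**2
    if pe == 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def predictive_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, PPV, NPV); zero-denominator entries are NaN."""

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return (
        ratio(c.tp, c.tp + c.fn),
        ratio(c.tn, c.tn + c.fp),
        ratio(c.tp, c.tp + c.fp),
        ratio(c.tn, c.tn + c.fn),
    )


def delta_vol(vol_ref: float, vol_auto: float, printed_convention: bool = True) -> float:
    """Signed relative volume difference.

    With ``printed_convention`` (default) the value is
    ``(vol_auto - vol_ref) / vol_ref``, the sign convention of the published
    per-patient table; the alternative is its negation
    ``(vol_ref - vol_auto) / vol_ref``.
    """
    if vol_ref <= 0:
        raise ValueError("reference volume must be > 0")
    d = (vol_auto - vol_ref) / vol_ref
    return d if printed_convention else -d


def icc_volumes(ref_volumes, auto_volumes, variant: str = "ICC2") -> float:
    """Intraclass correlation between two volume series.

    Default is ICC(2,1): two-way random effects, absolute agreement, single
    measures — the form that penalizes systematic offsets between methods.
    """
    import pandas as pd
    import pingouin as pg

    ref = np.asarray(ref_volumes, dtype=float)
    auto = np.asarray(auto_volumes, dtype=float)
    if ref.shape != auto.shape:
        raise ValueError("volume series must have equal length")
    n = ref.size
    if n < 3:
        raise ValueError("need at least 3 subjects for the ICC")
    data = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["ref", "auto"], n),
            "volume": np.concatenate([ref, auto]),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        # perfectly agreeing columns make pingouin's F statistics divide by zero
        table = pg.intraclass_corr(
            data=data, targets="subject", raters="rater", ratings="volume"
        ).set_index("Type")
    # pingouin labels rows by either the Shrout-Fleiss ("ICC2") or the
    # McGraw-Wong ("ICC(A,1)") convention depending on version
    aliases = {
        "ICC1": ["ICC1", "ICC(1,1)"],
        "ICC2": ["ICC2", "ICC(A,1)"],
        "ICC3": ["ICC3", "ICC(C,1)"],
        "ICC1k": ["ICC1k", "ICC(1,k)"],
        "ICC2k": ["ICC2k", "ICC(A,k)"],
        "ICC3k": ["ICC3k", "ICC(C,k)"],
    }
    for label in aliases.get(variant, [variant]):
        if label in table.index:
            return float(table.loc[label, "ICC"])
    raise KeyError(f"ICC variant {variant!r} not in {list(table.index)}")


def evaluate_masks(
    auto: np.ndarray,
    ref: np.ndarray,
    mask: BrainMask,
    spacing: tuple[float, float, float] | None = None,
    slice_thickness: float | None = None,
) -> EvaluationReport:
    """Full agreement report between an automatic and a reference mask."""
    spacing = spacing if spacing is not None else mask.spacing
    c = confusion(auto, ref, mask)
    sen, spe, ppv, npv = predictive_metrics(c)
    vol_auto = compute_volume(auto, spacing, slice_thickness)
    vol_ref = compute_volume(ref, spacing, slice_thickness)
    dv = delta_vol(vol_ref, vol_auto) if vol_ref > 0 else float("nan")
    return EvaluationReport(
        counts=c,
        si=similarity_index(c),
        kappa=cohen_kappa(c),
        sensitivity=sen,
        specificity=spe,
        ppv=ppv,
        npv=npv,
        vol_auto=vol_auto,
        vol_ref=vol_ref,
        delta_vol=dv,
    )


def sweep_cluster_number(
    dwi: NormalizedVolume,
    mask: BrainMask,
    ref_mask: np.ndarray,
    k_values,
    config: PipelineConfig | None = None,
) -> list[tuple[int, float]]:
    """Calibration sweep over the FCM cluster number K.

    For each K the front half of the pipeline runs (histogram peak,
    preclustering, FCM, cluster skimming, component labeling); the labels
    containing at least one reference voxel are selected as infarct labels
    and their union is scored with the SI against the reference mask.  The
    later screening filters are deliberately excluded so the score isolates
    the effect of K.
    """
    config = config or PipelineConfig()
    ref_mask = np.asarray(ref_mask, dtype=bool)
    if not ref_mask.any():
        raise ValueError("reference mask is empty")

    hist = histogram.compute_histogram(dwi, mask, config.n_bins)
    candidates = histogram.precluster_eliminate(dwi, mask, hist.peak_intensity)
    curve: list[tuple[int, float]] = []
    for k in k_values:
        if not 2 <= k <= len(candidates):
            raise ValueError(f"k={k} outside [2, {len(candidates)}]")
        cfg = fcm.FCMConfig(
            n_clusters=int(k),
            fuzzifier_m=config.fuzzifier_m,
            tol=config.tol,
            max_iter=config.max_iter,
            seed=config.seed,
        )
        res = fcm.fcm_cluster(candidates.intensities, cfg)
        skimmed = screening.skim_clusters(res, hist.peak_intensity, config.threshold_offset)
        in_skim = np.isin(res.hard_assignment, skimmed)
        labels = screening.label_components(
            candidates.coordinates[in_skim], dwi, connectivity=config.connectivity
        )
        selected = np.zeros(dwi.shape, dtype=bool)
        for lab in labels:
            idx = tuple(lab.voxels.T)
            if ref_mask[idx].any():
                selected[idx] = True
        c = confusion(selected, ref_mask, mask)
        curve.append((int(k), similarity_index(c)))
    return curve
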