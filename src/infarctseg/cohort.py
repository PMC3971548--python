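"""Published per-patient results of the 22-patient acute-stroke reference cohort.

The clinical MRIs behind this method are not publicly deposited, so the
per-patient agreement statistics published for the 22-patient validation
cohort (semiautomatic vs automatic segmentation) are shipped as a small
table.  It supports two reproducible computations: recomputing the cohort
summary rows (mean / sample SD of each column) from the per-patient values,
and recomputing the relative volume differences from the printed volumes.

Columns
-------
patient, sex, age
    demographics.
demar_offset
    the neurologist's demarcation threshold, expressed as the offset above
    the histographic peak ``I_peak`` (its cohort mean, 0.20, is the origin
    of the pipeline's default ``threshold_offset``).
vol_semi_ml, vol_auto_ml
    semiautomatic (reference) and automatic infarct volumes in mL.
delta_vol_pct
    published signed relative volume difference (%, automatic relative to
    semiautomatic).
si_pct, kappa_pct, sen_pct, spe_pct, ppv_pct, npv_pct
    published agreement metrics, in percent.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_cohort", "summarize_cohort"]

_NUMERIC = [
    "age", "demar_offset", "vol_semi_ml", "vol_auto_ml", "delta_vol_pct",
    "si_pct", "kappa_pct", "sen_pct", "spe_pct", "ppv_pct", "npv_pct",
]


def load_reference_cohort() -> pd.DataFrame:
    """Load the 22-patient reference cohort table."""
    with resources.files("infarctseg.data").joinpath("reference_cohort.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def summarize_cohort(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean and sample SD of each numeric cohort column."""
    if df is None:
        df = load_reference_cohort()
    num = df[_NUMERIC]
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})
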