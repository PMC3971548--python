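"""Recompute the published 22-patient cohort summaries from the per-patient rows.

The clinical MRIs are not public, but the per-patient agreement table is:
recomputing its summary statistics (and the volume ICC) from the per-patient
values checks the arithmetic end to end and shows how the evaluation module
is used on cohort data.
"""

import infarctseg as iseg
from infarctseg.evaluation import delta_vol, icc_volumes

df = iseg.load_reference_cohort()
print(f"{len(df)} patients, infarct volumes "
      f"{df.vol_semi_ml.min():.3f}-{df.vol_semi_ml.max():.3f} mL (reference)")
print(f"SI:          {df.si_pct.mean():.3f} +/- {df.si_pct.std(ddof=1):.3f} %")
print(f"sensitivity: {df.sen_pct.mean():.3f} +/- {df.sen_pct.std(ddof=1):.3f} %")
print(f"demarcation offset above I_peak: {df.demar_offset.mean():.2f} "
      f"(the origin of the +0.2 screening threshold)")
print(f"relative volume difference: {df.delta_vol_pct.mean():.1f} % on average")
print(f"volume ICC(2,1): {icc_volumes(df.vol_semi_ml, df.vol_auto_ml):.3f}")

for patient in (20, 22):
    row = df.set_index("patient").loc[patient]
    dv = 100 * delta_vol(row.vol_semi_ml, row.vol_auto_ml)
    print(f"patient {patient}: dVol recomputed from volumes = {dv:+.1f} % "
          f"(published {row.delta_vol_pct:+.1f} %)")
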