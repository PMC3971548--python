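"""Score a segmentation against a reference mask.

Segments a phantom, then compares the result with the ground truth the way
an automatic mask is compared with a neurologist's demarcation: voxelwise
confusion counts, similarity index (Dice), Cohen's kappa, the four
predictive metrics and the volume difference.
"""

import infarctseg as iseg

bundle = iseg.generate_phantom(iseg.PhantomSpec(seed=2))
dwi = iseg.normalize_intensity(bundle.dwi)
adc = iseg.normalize_intensity(bundle.adc)
result = iseg.segment_infarct(dwi, adc, bundle.mask, iseg.PipelineConfig(seed=2))

report = iseg.evaluate_masks(result.infarct_mask, bundle.truth, bundle.mask)
c = report.counts
print(f"confusion (in-mask): TP={c.tp} TN={c.tn} FP={c.fp} FN={c.fn}")
for name, value in report.as_percent_row().items():
    print(f"  {name:>14}: {value}")
# SI = 100% means the final mask reproduces the ground-truth blob exactly;
# dVol is the signed volume error relative to the reference.
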