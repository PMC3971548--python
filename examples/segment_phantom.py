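"""Segment a synthetic phantom end-to-end and attribute every blob's fate.

Builds the standard four-blob phantom (one true infarct, one faint decoy,
one blurred decoy, one ADC-bright artifact), runs the full screening chain,
and prints the stage-by-stage candidate counts, the per-label verdicts and
the infarct volume.
"""

import infarctseg as iseg

bundle = iseg.generate_phantom(iseg.PhantomSpec(seed=1))
dwi = iseg.normalize_intensity(bundle.dwi)
adc = iseg.normalize_intensity(bundle.adc)
result = iseg.segment_infarct(dwi, adc, bundle.mask, iseg.PipelineConfig(seed=1))

print(f"DWI histographic peak I_peak = {result.peak_dwi:.3f} "
      f"(screening threshold {result.peak_dwi + 0.2:.3f})")
print("candidate voxels per stage:")
for stage, count in result.stage_counts.items():
    print(f"  {stage:>10}: {count}")
print("labels:")
for lab in result.labels:
    support = "-" if lab.edge_support is None else f"{lab.edge_support:.2f}"
    print(f"  label {lab.label_id}: {lab.size} voxels, mean DWI {lab.mean_dwi:.3f}, "
          f"edge support {support} -> {lab.verdict}")
print(f"infarct volume: {result.volume_ml:.3f} mL")
print("ground-truth attribution:")
for les, region in zip(bundle.spec.lesions, bundle.lesion_masks):
    print(f"  {les.kind:>14} -> {iseg.classify_region(result, region)}")
# Each decoy is removed by exactly the filter aimed at it; only the true
# infarct survives to the final mask.
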