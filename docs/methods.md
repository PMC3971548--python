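# Methods

## Problem and approach

Acute cerebral infarcts restrict water diffusion: they appear hyperintense
on diffusion-weighted imaging (DWI) and hypointense on the apparent
diffusion coefficient (ADC) map. `infarctseg` segments them fully
automatically from a co-registered, brain-masked DWI/ADC pair using only
histographic intensity structure — no training data, atlas or anatomy
model. The chain:

1. **Normalization.** Both volumes are min–max rescaled to [0, 1] over the
   whole volume, `x' = (x − min)/(max − min)`. The mapping to (0, 1) is the
   one assumption isolated in `image_io.normalize_intensity`; percentile
   clipping is deliberately not applied by default.
2. **Histographic peak.** The in-mask DWI histogram (256 uniform bins on
   [0, 1]) is smoothed with a 3-point centered moving average (window
   shrinking at the ends). The bin-center intensity at the smoothed maximum
   is `I_peak`, the mode of normal brain tissue. Because infarcts are
   hyperintense, every voxel with intensity ≤ `I_peak` is eliminated before
   clustering ("preclustering elimination"): this is safe for lesions and
   roughly halves the problem.
3. **Fuzzy C-means.** The surviving intensities (a 1-D feature space —
   intensity only, no spatial coordinates) are partitioned into K = 50
   clusters by conventional FCM: objective
   `J = Σ_i Σ_k u_ik^m (x_k − c_i)²`, fuzzifier m = 2, alternating
   membership/center updates, convergence when the maximum center shift
   drops below 1e−5 (max 300 sweeps). Centers are initialized by drawing K
   distinct observed values with the run seed; drawing from the *unique*
   values avoids duplicate initial centers, which could never separate
   afterwards. The seed is the pipeline's only stochastic element.
4. **Cluster skimming.** Clusters whose hard-member mean intensity exceeds
   `I_peak + 0.2` are selected. The 0.2 offset is the average margin by
   which expert demarcation thresholds exceeded `I_peak` in the reference
   cohort (`demar_offset` column, mean 0.20); it is a config knob
   (`threshold_offset`) so it can be re-estimated for other scanners or
   raters.
5. **Labeling and intensity screen.** The union of the skimmed clusters'
   voxels is split into connected components ("labels") under
   26-connectivity (per-slice 8-connectivity available). Labels whose mean
   intensity is ≤ `I_peak + 0.2` are eliminated (`low_intensity`).
6. **Weak-edge screen.** True acute infarcts have sharp DWI margins. A
   per-axial-slice 2-D Canny map is computed (Gaussian σ = 1; hysteresis
   thresholds 0 and 0.3 expressed as fractions of each slice's maximum
   smoothed gradient magnitude — the relative-threshold convention of the
   classic MATLAB detector). A label's `edge_support` is the fraction of
   its per-slice 8-neighborhood boundary voxels within 1 in-plane voxel of
   an edge voxel; labels below `edge_support_min = 0.5` are eliminated
   (`weak_edge`). The support statistic and its 0.5 default are this
   package's operationalization of "weak edge", which has no standard
   numeric definition; both are config-exposed.
7. **ADC artifact screen.** Susceptibility artifacts mimic infarct
   brightness on DWI but stay bright on ADC. With `I_peak,ADC` the ADC
   histogram's peak (same binning/smoothing) and `I_lower_mean,ADC` the mean
   of the darker half (first ⌈n/2⌉ sorted values) of a label's ADC
   intensities, a label is eliminated as `adc_artifact` when
   `I_lower_mean,ADC / I_peak,ADC ≥ 0.5` (inclusive). The ratio is invariant
   to affine rescaling of the ADC map. Survivors are the final infarct.

Volume is voxel count × in-plane area × slice thickness (mL); for gapped
acquisitions where thickness ≠ slice spacing, `slice_thickness_override`
substitutes the nominal thickness for the header `dz`.

## Design choices where the procedure was genuinely open

- **Labels over the union of skimmed clusters.** Components could be formed
  per cluster instead. With many narrow 1-D intensity clusters, per-cluster
  components shatter a homogeneous lesion into noise speckles whose
  boundaries carry no edge information; union labeling keeps a lesion one
  label regardless of how many bright clusters span it, and reduces to the
  per-cluster reading in the typical regime where a single cluster passes
  the skim. Each label records the majority cluster as `source_cluster`.
- **Histogram peak tie-breaks.** Among tied smoothed maxima the bin with
  the higher raw count wins (smoothing a single-bin spike yields a flat
  3-bin plateau whose true mode is the middle bin); remaining ties go to
  the lower-intensity bin, which is the conservative direction (lower
  threshold keeps more candidates).
- **Strict vs inclusive comparisons.** Skimming and the label screen retain
  on strictly-greater-than `I_peak + 0.2`; the ADC artifact rule eliminates
  on ≥ 0.5. Equality at a screening threshold therefore always removes.
- **Attribution.** `classify_region` reports which stage removed (the
  majority of) a region. Eliminations by the cluster skim and the label
  intensity screen are reported as one category, `intensity`: both apply
  the identical threshold, and which of the two fires for a given faint
  region is an artifact of cluster geometry, not a scientific distinction.
- **Empty clusters** keep their center as the recorded mean (warning
  logged); hard-assignment ties resolve to the lowest cluster index.
- **Metrics.** SI = 2TP/(2TP+FP+FN) (the Dice coefficient); Cohen's κ from
  the closed-form p_o/p_e expression on confusion counts; confusion counts
  (and hence specificity) are restricted to in-mask voxels, since counting
  air as true negatives would inflate TN. Volume agreement uses ICC(2,1) —
  two-way random effects, absolute agreement, single measures (via
  pingouin; variant config-exposed). Undefined metrics (zero denominators)
  are NaN, never silently 0. The relative volume difference is reported as
  `(vol_auto − vol_ref)/vol_ref`, the sign convention of the published
  per-patient table; the opposite convention is available via a flag.
- **Cluster-number sweep.** The calibration semiprocedure stops after
  labeling: labels overlapping the reference by ≥ 1 voxel are selected and
  their union scored with SI. The later screens are excluded so the curve
  isolates the effect of K. The ADC map is not consulted, so the sweep
  function does not take one.

## The phantom: what it emulates and what it does not

Patient MRIs are not redistributable, so testing uses a synthetic phantom
(64×64×16 voxels at 1.79×1.79×5 mm — the acquisition geometry of the
reference cohort at reduced matrix size, keeping runtimes at seconds while
leaving ≥ 10⁴ candidate voxels for the 50-cluster FCM). It reproduces the
*decision-relevant statistics*, not anatomy:

- an ellipsoidal brain with constant background plus truncated Gaussian
  noise (sd 0.02), giving the unimodal in-mask histogram with an
  identifiable peak (background mode 0.3 DWI, 0.4 ADC);
- spherical blobs placed so each trips exactly one filter:
  **infarct** (DWI offset +0.45, sharp, ADC 0.15 = 0.375× the ADC mode —
  below the 0.5 ratio), **faint decoy** (offset +0.12 ≤ 0.2 margin),
  **blurred decoy** (offset +0.45 but blurred in-plane with σ = 4 voxels
  before noise, so its gradient falls below 30 % of the slice maximum;
  ADC-dark so the ADC screen cannot be its eliminator), and
  **ADC-bright artifact** (offset +0.45, sharp, ADC 0.55 = 1.375× mode).
  The bright blobs share axial slices so every slice with a blurred decoy
  contains a sharp gradient reference, as skull/CSF interfaces do in real
  images (the brain/air boundary provides a second reference on all
  slices);
- voxels outside the brain are 0 and noise is clipped to [0, 1], so the
  pipeline's min–max normalization acts realistically (a ≈1.2× stretch on
  the default phantom); all decision margins above were chosen to survive
  that stretch with slack.

Not emulated: gyral/CSF anatomy, Rician noise statistics, partial-volume
boundaries, EPI geometric distortion, multi-focal or heterogeneous lesion
texture. Passing phantom suites therefore demonstrates that each screening
rule removes exactly the false-positive class it targets under controlled
separation, and that the chain is deterministic and monotone — not that
clinical-grade accuracy transfers to patient data, which requires the
original acquisition context.

## Numerical notes

- FCM memberships for a voxel coinciding exactly with c centers split
  evenly over those centers; the objective trace is recorded once per sweep
  (after the membership update) and is non-increasing by construction.
- Geometry checks tolerate 1e−3 mm spacing disagreement.
- NaN voxels are zeroed (with a warning) before normalization; constant
  volumes are rejected rather than normalized.
- Deduplication of intensities is *not* performed inside FCM; the
  initialization draws from unique values but the updates weight every
  voxel.

## Known limitations

- The +0.2 skimming offset is rater- and scanner-calibrated; transferring
  it to other acquisition protocols without re-estimation is the method's
  main fragility.
- The weak-edge operationalization (boundary/edge coincidence ≥ 0.5 with
  1-voxel dilation) is one reasonable choice among several; labels a few
  voxels large have unstable support fractions.
- Min–max normalization ties all thresholds to the volume's global extrema;
  a single hot voxel compresses the usable range (percentile clipping is
  available as a config knob for such data).
- The artifact screen assumes artifacts stay ADC-bright; artifacts with
  genuinely low ADC would pass it.
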