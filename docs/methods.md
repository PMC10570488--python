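# Methods

## Model and pipeline

The pipeline estimates, for each of four default-mode-network (DMN)
pathways, the adjusted linear association between white-matter-
hyperintensity (WMH) burden inside a fiber tract and amyloid-PET SUVr in
the cortical region the tract projects to:

    SUVr_region = b0 + b1 * log10(V_tract) + bX . (age, sex, apoe_e4, icv) + e

with `V_tract` the WMH volume (mL) inside the tract. The pairs are fixed by
the DMN anatomy: SLF→IPL, IFOF→MPFC, CING→PCC, CING_Hippo→MTL. The family
of four tests is Bonferroni-controlled: at alpha = .05 the per-test
significance threshold is .05/4 = .0125.

### WMH segmentation

FLAIR intensities inside a supplied white-matter (WM) mask are modelled as
a dominant normal-appearing-WM (NAWM) Gaussian mode plus a hyperintense
lesion tail. The default fit (`histogram_ls`) least-squares fits a
three-parameter Gaussian (amplitude, mu, sigma) to the Freedman–Diaconis-
binned intensity density, initialized at the median and IQR/1.349 so the
optimizer locks onto the main mode; this keeps mu within ~1 intensity unit
under a 5% bright-tail contamination where plain sample moments (the
`moments` fallback) are biased by >1 unit. The lesion threshold is
`mu + k*sigma` with k = 3. The threshold inequality is strict (`>`); this
is arbitrary but fixed. Components are defined by 26-connectivity;
components smaller than `min_component_size` voxels (default 3) are
removed — a deterministic replacement for manual artifact editing. Total
WMH volume is voxel count × voxel volume, in mL.

Degenerate inputs: a constant-intensity WM mask raises a
degenerate-distribution error (no Gaussian is identifiable); masks under
100 voxels are refused; if the histogram least-squares fit fails to
converge the sample moments are used.

The NAWM mean+3SD rule is implemented literally as `mu + 3*sigma`; no
p-value interpretation of the threshold enters any computation.

### Tract volumetrics

WMH volume in a tract is the voxelwise AND of the WMH and tract masks
times the voxel volume; probabilistic tract maps are binarized at
`p > prob_threshold` with default threshold 0 (any nonzero membership),
configurable because published probabilistic atlases do not fix a value.
Per-tract volumes are log-transformed, base 10 by default (natural log via
config): on the mL scale this gives predictor magnitudes near 1, matching
how such burdens are conventionally reported. Zero-volume records are
excluded by default — log10(0) is undefined and real cohorts show smaller
per-tract Ns for exactly this reason — with an epsilon-offset mode
(`log10(V + eps)`) for sensitivity analyses.

### SUVr quantification

Regional SUVr is the unweighted arithmetic mean uptake over the region's
voxels divided by the mean over the whole-cerebellum reference mask (no
partial-volume weighting). Composite regions are unions of parcellation
labels (MTL = entorhinal + parahippocampal; MPFC = rostral anterior
cingulate + caudal anterior cingulate + medial orbitofrontal; PCC and IPL
are single labels). An amyloid-positivity floor (default 1.17) excludes
below-floor records *per region* — per-region application is chosen
because per-region Ns legitimately differ — with the boundary value kept
(non-strict). SUVr is invariant under global positive rescaling of the PET
image, which the tests assert to 1e-12.

### Association analysis

Each pair is fit by ordinary least squares on
`[1, log10 V, age, sex, apoe_e4_count, icv]` with listwise deletion of
rows excluded upstream. Inference on b1 is two-sided t with n−p−1 degrees
of freedom; the 95% CI likewise. Reported statistics:

- standardized beta `b1 * sd(x)/sd(y)` over analyzed rows (algebraically
  identical to refitting on z-scored data for OLS);
- adjusted R² `1 − (1−R²)(n−1)/(n−p−1)`, reported as-is when negative;
- Cohen's `f = sqrt(R2adj / (1 − R2adj))`, with negative adjusted R²
  clamped to 0 first so f stays real on null data, and f = ∞ reported for
  a perfect (noise-free) fit where adjusted R² = 1 exactly.

ApoE enters as e4 allele count (0/1/2); sex as a 0/1 indicator;
intracranial volume in mL. CI limits always satisfy ci_low ≤ ci_high. A
pair that cannot be estimated (rank deficiency, too few subjects, constant
outcome) is reported with NaN statistics and a warning; other pairs are
unaffected.

## The synthetic phantom

The phantom replaces atlas registration and cortical parcellation with
parametric solids in one shared grid (default 64³ voxels at 1×1×1.2 mm,
the voxel geometry of a 3D FLAIR acquisition): a central WM slab, four
disjoint rectangular tract tubes inside it occupying separate z-bands,
four GM blocks each sharing a face with the WM exactly where its tract
terminates, and a cerebellum block below. Co-registration therefore holds
by construction, and every mask invariant (tracts ⊆ WM, pairwise-disjoint
tissue compartments, tract–region adjacency) is asserted at build time.

Lesions are connected blobs of exactly `round(target/voxel_volume)` tract
voxels — the voxels nearest a jittered anchor at the tract centroid — so
inserted volume is known to half a voxel and containment is exact. FLAIR
rendering draws NAWM voxels from Normal(mu, sigma·noise_scale) and lesion
voxels offset by `k·sigma` (k default 6, comfortably above the 3-sigma
threshold; k ≤ 3 produces designed-to-fail fixtures). `noise_scale=0`
yields a noise-free image that keeps the nominal contrast, which is what
makes voxel-exact recovery checks possible; `nawm_sigma=0` itself is
flagged as degenerate since the contrast offset collapses. PET rendering
sets each region constant at its linear predictor plus one regional noise
draw and the cerebellum at the reference value, so computed SUVr equals
the generative predictor exactly in the noiseless case.

Covariates are drawn from the reference cohort's marginals: age
Normal(74.96, 8.13) years, ICV Normal(1455.26, 132.46) mL, sex
Bernoulli(.493), ApoE e4 count with P(1)=.099, P(2)=.366. Covariate
effects bX default to 0 so calibration studies isolate b1; confounding
tests set them nonzero.

Two simulation levels are deliberate: the **tabular** simulator draws
(log V, SUVr) pairs directly from the coupling model using the reference
cohort's per-tract log10-volume marginals (SLF 1.12±.66 etc.) and serves
all replicate-based statistical checks; the **image-level** cohort uses
scaled-down volume marginals (log10 V ~ Normal(−0.45, 0.20) mL) because a
64³ phantom tract holds only ~3 mL — the reference marginals imply ~13 mL
tracts and are in any case inconsistent with the same table's 4.43 mL mean
total burden. The coupling structure, not the volume scale, is what the
image-level path validates.

Noise calibration is closed-form: to target an expected adjusted R² of t
with slope b1 and predictor SD s, `noise_sd = |b1|·s·sqrt((1−t)/t)`
(`calibrate_noise_sd`); the covariates are null in calibration runs, and
the adjusted-R² correction cancels their overfitting contribution in
expectation (verified at n=20,000 to ±.02).

## What the phantom does and does not show

Passing tests demonstrate algorithmic correctness — exact volumetrics,
correct thresholding arithmetic, unbiased slope recovery, nominal CI
coverage and type-I error under the assumed generative model. The phantom
has none of real data's difficulties: no registration error, bias fields,
partial-volume mixing, non-Gaussian NAWM intensity, scanner effects, or
anatomically realistic lesion shapes. Results on real cohorts additionally
depend on those factors.

## Reproducibility and problem sizes

All randomness flows through explicit integer seeds (numpy SeedSequence
spawning per subject); identical configuration + seed reproduces cohorts
and pipeline outputs byte-identically, and the run manifest records the
SHA-256 of the canonical configuration JSON. Stochastic checks use 200
replicate cohorts of n=60 for slope recovery and CI coverage and 500 for
type-I error — sizes at which the binomial noise on the checked rates is
well inside the asserted bands; image-level demonstrations use 10–40
subjects on 40–64³ grids, which keeps a full pipeline run under a minute
on one CPU.
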