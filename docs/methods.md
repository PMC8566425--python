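# Methods

This note documents the models, parameter choices and numerical
conventions behind `mammilieu`, and what the synthetic-data validation
does and does not establish about real tissue.

## Scene model

A scene is a simulated brightfield scan of an FFPE breast section at
0.465 µm/pixel. Stains combine linearly in optical density (Beer–Lambert):
for stain concentrations `c_s` and unit OD vectors `v_s` (RGB),
`OD = Σ c_s v_s`, and the 8-bit image is `I = 256·10^(−OD) − 1`, clipped
and rounded. The OD transform used throughout is
`OD = −log10((I+1)/256)`, so blank background (I = 255) is exactly OD 0
and the transform is finite at I = 0.

Stain vectors (normalized; RGB order) ship in a YAML registry:
hematoxylin (0.650, 0.700, 0.290); purple/CD3 (0.250, 0.930, 0.260);
teal/CD20 or CD163 (0.930, 0.260, 0.260); yellow/CD68
(0.150, 0.250, 0.960). They are shared by the generator and the
deconvolution stage, which makes recovery well-posed; no vector estimation
from images is attempted. Each marker is unmixed in its own pass against
hematoxylin plus a residual vector orthogonal to both. With these vectors
the positive cross-talk of off-panel chromogens into a marker channel is
at most ≈ 0.14 of the source concentration (most leakage is negative and
clipped), far below the positivity threshold.

**Geometry.** EER is a Gaussian random field (correlation length ≈ 1/10 of
the image side) thresholded at the quantile matching `eer_fraction`; the
field is drawn on a coarse grid and bilinearly upsampled, which is
statistically equivalent and much faster at large correlation lengths.
PE is modeled as filled duct/alveolar foci (disks, radius 30–60 µm) grown
inside EER until the requested PE share of EER is reached; ILS is the
remainder of EER. Filled foci rather than thin annular bands were chosen
so that `pe_fraction_of_eer` is controlled monotonically and no stray ILS
islands appear inside duct lumina; the downstream pipeline consumes only
the label map, so this choice does not affect any operation's contract.
Labels: 0 = FSR, 1 = PE, 2 = ILS.

**Cells.** A cell is a hematoxylin nucleus disk (equivalent diameter
8 ± 1.5 µm, clipped to 6–12 µm, OD amplitude 1.2 above background) plus a
flat chromogen halo (20 ± 1.5 µm, floored at 16 µm, amplitude 1.3 ± 0.08,
floored at 1.0). The halo floor sits above the 15 µm detection cutoff so
genuine cells survive the size filter, while a configurable debris
population (< 15 µm) and nucleus-free CD68 "speckles" (fragments of
sliced macrophages) exercise the size and nucleus-association filters
respectively. Background hematoxylin is compartment-dependent (PE 0.55,
ILS 0.18, FSR 0.05 OD) — epithelium is nucleus-dense — which is also what
makes the compartments learnable by the segmenter. Optical-density noise
(sd 0.02 per channel by default) is added before quantization.

**Placement.** Counts per class × compartment are Poisson(density × area);
positions are drawn by dart throwing over compartment pixels with a
hard-core minimum separation of one mean halo diameter (20 µm) shared
across all classes, so rendered blobs rarely merge; exhausting the
candidate list raises an "overcrowded scene" error rather than silently
under-planting. Realized counts and count/area densities are recorded in
the ground truth. Two small biases are accepted and documented: cells
whose halo is clipped by the image border can fall under the 15 µm filter
(≲ 1–2% at the scene sizes used), and hard-core repulsion makes the point
process slightly sub-Poisson.

## Detection

Per marker channel: concentrations map to a 0–255 intensity
(`I = 255·10^(−c/scale)`, scale 1.0; 0 = strongest stain), mean filter of
radius 2 µm, binarization at intensity < 128, connected components,
Euclidean distance transform, watershed from peaks separated by at least
0.4 × the 33 µm blob scale. Object filters: equivalent-circle diameter
≥ 15 µm (the "< 15 µm" removal is read as exclusive, so 15.0 µm is kept)
and per-object mean intensity < 50 (exclusive: a mean of exactly 50 is
not positive). Positivity is per-object mean, not per-pixel — the
threshold's reference implementation is proprietary and does not state
which; per-object mean is the stabler reading and is fixed in config.
The hematoxylin nucleus pass reuses the same machinery with its own
cutoffs (1 µm mean filter, binarize < 40, minimum 4 µm): nuclei are
smaller and darker than chromogen halos, and the gentler filter keeps the
6 µm tail of the nucleus size distribution detectable. CD68 objects must
overlap a nucleus object by ≥ 1% of their area; speckles fail this and
are excluded.

Objects from different markers merge into one cell when they overlap by
≥ 30% of the smaller object. Triple panel: exactly one positive marker
classifies (T/B/Mac); multi-positives are collisions and are excluded as
unclassified. Double panel: CD163⁺ is M2 whether or not CD68 co-stains;
CD68⁺/CD163⁻ is M1.

## Segmentation

Both stages use one encoder–decoder family implemented in numpy with
manual backpropagation: 3×3 convolutions + ReLU, 2×2 average pooling,
nearest-neighbour upsampling with skip concatenation, 1×1 head, softmax
cross-entropy with a per-pixel weight mask, Adam (lr 3·10⁻³). The
desk-scale default is depth 2, base width 8, 64×64 tiles (the
architecture family supports 512×512 tiles; narrow width keeps CPU
training in seconds–minutes). Stage B's loss and validation error are
computed on EER pixels only, so fat/stroma never influences the PE/ILS
decision. "Validation error" is the fraction of misclassified held-out
pixels; training stops when it drops below 0.10 (configurable) or at the
epoch budget (default 60), in which case the model is returned
non-converged with a warning. Augmentation: flips, right-angle rotations,
multiplicative intensity jitter (±8%), all seeded. Inference tiles with
50% overlap and averages class scores; stage A output gets small-object
removal and hole filling. An oracle segmenter returns generator truth
verbatim, used to bound detection error independently of model quality.

## Densities and statistics

Density is count/area (cells/mm²) with area = pixel count ×
(0.465·10⁻³)² mm². Donor-level records pool counts and areas across
images before dividing, so `EER_total = (n_PE + n_ILS)/(A_PE + A_ILS)`
exactly — never a mean of per-image densities. The statistics layer uses
classical two-sided tests at α = 0.05: OLS/Pearson for age trends, plain
(equal-variance) t-tests with Welch behind a flag, one-way ANOVA with
Tukey HSD, and Tukey boxplot whiskers at 1.5 IQR with
linear-interpolation quartiles (conventions differ between packages; this
one is fixed and tested against a hand-computed fixture). A paired test
on perfectly equal compartments returns t = 0, p = 1 rather than NaN.

## Cohort truth model

Per-donor densities are linear in age with Gaussian between-donor noise,
truncated at zero (the analysis layer fits simple linear regressions, so
the truth model matches the inference family). Defaults anchor at the
reported compartment means: PE T cells fall from ≈ 849 (≤ 41 y) toward
≈ 477 cells/mm² (≥ 58 y) (slope −11.1/y), ILS T mean 259, B cells
ILS-enriched and declining (140 − 2.0·age; PE B ≈ 11), macrophages
age-flat at 313 (PE) and 101 (ILS) cells/mm². The double-panel M1/M2
defaults are age-flat with M2 > M1 in ILS; their magnitudes are free
choices since only the qualitative pattern is reported. Cohort
composition: 67 average-risk + 36 high-risk donors (103 total), ages
uniform on 24–74 y, BMI ≈ N(27, 4.5²) with classes normal [18.5, 25),
overweight [25, 30), obese ≥ 30, menopause assigned at 51 y.

## Flow and signature arms

Flow events are mixtures of truth-labeled populations with log-normal
channel intensities (negatives at 10¹, positives at 10³); gates are
rectangular per-channel thresholds with an ambiguity band (10^1.8–10^2.2)
standing in for manual 2-D gating; events in a band, or positive for more
than one subset marker, are excluded, so subset percentages sum below
100%. Dead (7-AAD⁺) events are removed first; fewer than 10,000 viable
events rejects the sample. Compensation is not modeled — the generator
emits compensated intensities.

Signature scoring: per gene keep the probe with maximal mean across all
samples (ties by probe identifier), z-score each gene row ("mean center
scaled" is read as center + unit variance; plain centering is behind a
flag), score = mean of member-gene scaled values (the simplest scoring
consistent with scaled inputs; the source procedure is not stated),
two-sided Wilcoxon rank-sum between young (≤ 35 y) and older (≥ 50 y)
samples with 35 < age < 50 excluded, Holm–Bonferroni across all tested
signatures. Real-array ingestion (series-matrix TSV) is possible through
the same functions but is not exercised by tests; reproducing published
adjusted p-values would require the real accession and exact signature
gene lists.

## Validation scale and scope

The acceptance benchmarks plant macrophages at the reported ILS
(101 cells/mm², plus 20% speckles) and PE (313 cells/mm²) mean densities
over ≥ 10 mm² of synthetic tissue (sixteen to twenty 1792² scenes,
pooled) and recover them through oracle segmentation + detection +
quantification; the stage-B segmenter trains on ~40 annotated 64×64 tiles
from four seeded scenes. These sizes were chosen so each benchmark
completes in about a minute or two on one CPU while keeping Poisson
counting error near 3%.

Passing these benchmarks shows the pipeline's operators implement their
stated contracts and compose without bias — it does not certify
performance on real FFPE tissue, where stain vectors vary between
batches, compartment boundaries are ambiguous, chromogens co-localize in
folds and debris, and cell morphology departs from disks. Folds, tears,
out-of-focus regions, fat vacuole texture and scanner artifacts are
deliberately not modeled. Hard-core placement is a simplification of real
clustering; the M1–M2 polarization continuum is reduced to a binary rule.
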