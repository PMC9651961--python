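# Methods

This note documents the models, numerical choices and limitations of
`transfc`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The analysis model

The pipeline characterises the functional organisation of the
entorhinal–hippocampal circuitry in two steps. First, entorhinal cortex
(EC) voxels are attributed to the cortical source region — retrosplenial
cortex (RSC), parahippocampal cortex (PHC), perirhinal Area 35 (A35) or
Area 36 (A36) — whose activity they uniquely track; second, the
connectivity of the resulting EC seed regions is profiled along the
transversal (proximal→distal) axis of hippocampal subiculum (SUB) and CA1
and compared across seeds, and scene/object task responses are compared
across the same subregions.

### GLM

Runs are smoothed with a 1.5 mm FWHM Gaussian kernel (σ = FWHM/(2√(2 ln 2))
voxels; deliberately below twice the voxel size to limit spatial
leakage between adjacent subregions). Outlier volumes are detected by
scan-to-scan change of the global mean intensity exceeding 1.3% of the
run-mean intensity, or framewise displacement — the sum of absolute
scan-to-scan translation differences — exceeding 0.3 mm. Rotations are
ignored in the displacement measure because the threshold is specified in
millimetres; this is a documented simplification. The design matrix holds
one HRF-convolved boxcar per condition (scene, object, and an explicit
baseline, since the contrasts of interest are versus baseline), six motion
columns, a one-hot column per outlier volume, and an intercept. The HRF is
the conventional double gamma (response peak shape 6, undershoot shape 16,
both scale 1 s, undershoot ratio 1/6), sampled at a tenth of the TR during
convolution so event onsets need not align with volume boundaries, and
sum-normalised. The fit is voxelwise OLS without prewhitening; slice-time,
motion and distortion correction are upstream concerns and out of scope.
Residuals — the data with task, motion and spike effects removed — behave
like resting-state data and feed the connectivity analysis; with more than
one run, runs are voxelwise standardized per run and concatenated.

### Semipartial connectivity

Seed masks are first cleaned of signal-dropout voxels: ROI voxels whose
temporal-mean intensity falls more than 2 sample SDs below the mean of the
ROI's voxel means are excluded. The reference population for this rule is
the ROI itself (the plausible alternative, the whole brain, would make the
threshold depend on arbitrary phantom tissue proportions); `k_sd=inf`
disables the rule.

All series — seed means, competing-seed means, nuisance columns (motion,
spike indicators, white-matter and CSF mean series) and voxel series — are
band-pass filtered to 0.01–0.1 Hz with a zero-phase FFT mask. The mask is
exact at the discrete Fourier frequencies, which makes the filter
deterministic and testable against an FFT amplitude-ratio oracle; an IIR
filter would introduce phase/edge behaviour with no benefit here.

The semipartial correlation is computed with the *seed* residualized
against the other seeds plus nuisance, while the voxel side is cleaned of
nuisance only. This asymmetry implements "variance in a voxel uniquely
explained by the seed" and is stated prominently because toolboxes differ
in which side they partial. Correlations are clipped to ±(1 − 10⁻⁷) before
the Fisher z-transform so perfectly correlated voxels stay finite.

### Winner-take-all parcellation

Per-source one-sample T maps are computed across subjects (t = mean /
(sd/√n), df = n − 1; zero-SD voxels get a signed-infinity sentinel and are
logged). Each EC voxel is assigned to the source with maximal T provided
that T strictly exceeds 3.1 — a one-directional threshold on positive
connectivity. Ties are broken by the fixed source order (RSC, PHC, A35,
A36) and logged; ties are measure-zero on real data but determinism is
required. Across hemispheres, each source keeps only the N
highest-winning-T voxels, N being the smaller hemisphere's count; with one
hemisphere the operation is the identity and still runs.

### Transversal segmentation

Within each coronal slice, subiculum voxels are cut into five equal-width
bins over the medial–lateral extent: label = 1 + ⌊n·(x − min)/(max − min
+ 1)⌋, oriented so label 1 is proximal (the lateral end, adjacent to CA1).
CA1 is cut into three 60° sectors: the two "outer borders" are
operationalised as the voxel pair at maximum in-plane distance
(lexicographic tie-break, since no operational definition is standard);
each voxel's unsigned angle to the chord direction, measured from the
chord midpoint, is binned in half-open 60° sectors (the last closed at
180°), label 1 anchored at the proximal endpoint. The sector reading of
the 60° construction — three roughly equal sectors — is implemented, as
opposed to two rays each at 60° to the chord; the two readings coincide
for the default angle. Slices with too few distinct coordinates are
skipped with a warning.

Segment profiles are means per segment per slice, then averaged across
slices with equal slice weight regardless of voxel count ("averaged along
all coronal slices"); a voxel-weighted alternative is available behind a
flag defaulting off.

### Statistics

The repeated-measures ANOVA is the classical univariate within-subject
decomposition: each effect is tested against its subject × effect
interaction stratum, giving interaction df = (a−1)(b−1) over
(a−1)(b−1)(n−1). No sphericity correction is applied by default — the
reference degrees of freedom in this design are the uncorrected ones —
but Greenhouse–Geisser correction is available (`gg_correction=True`).
Duplicated factor levels would otherwise produce F as a ratio of rounding
residues, so sums of squares below 10⁻¹² of the total are treated as
exactly zero.

The gradient hierarchy: stage 1 tests the seed × segment interaction in
every target region, Benjamini–Hochberg-corrected across regions; stage 2
runs only in significant regions and tests each seed's one-way segment
effect, BH-corrected within region; stage 3 runs only when at least two
seeds survive and tests the pairwise seed × segment interactions. Stage-3
p-values are reported uncorrected (no established family is defined for
them); this is logged in the decision trail that every fitted report
carries. The content cascade tests the condition × region (or segment)
interaction at the nominal level and, if significant, scene-vs-object
paired t-tests per unit with BH-FDR; directional claims come from the sign
of the mean difference, p-values are two-sided throughout.

BH-FDR is the step-up rule — reject the k smallest p-values with
k = max{i : p(i) ≤ i·q/m} — with adjusted p-values from the backward
cumulative-minimum pass.

## The phantom

The generator emulates the study design at configurable scale. Geometry on
a 24×24×12 default grid (axis 0 medial→lateral, axis 1 coronal, axis 2
inferior→superior, recorded in the label-map metadata so segmentation
never guesses): four 36-voxel cortical source blocks; a 128-voxel EC block
hiddenly partitioned into four 32-voxel source-driven subregions; an
8-slice, 10-voxel-wide subiculum sheet; an 8-slice, 9-voxel CA1 arc. Every
SUB/CA1 voxel carries a transversal coordinate t ∈ [0, 1] (0 proximal,
1 distal); the subiculum's proximal end is lateral (adjacent to CA1), the
CA1 arc's proximal end medial.

Latent source signals are white Gaussian series band-limited to
0.01–0.1 Hz by FFT masking and standardized — simple and spectrum-exact.
Voxel signals are baseline intensity (100) + Σₖ wₖ·latentₖ + task response
+ white noise (default SD 1). Connectivity weights interpolate linearly in
t between configured proximal/distal endpoints; the defaults impose the
qualitative pattern under study — in SUB, PHC-driven signal rises
distally (0.2→0.8) while RSC (0.7→0.3) and A35 (0.7→0.2) fall and A36 is
flat; in CA1, RSC rises distally (0.3→0.7) with a weaker opposing A35
trend (0.5→0.3). Task amplitudes are compartmental rather than graded: the
"distal" amplitude applies where t > 0.6, which confines the default
scene bias (amplitude 1.2 vs 0.5, in noise-SD units) to the distal
subiculum segments and the PHC-driven EC subregion. Events are 3-s
stimuli: ten baseline (scrambled) stimuli at each end of the run and
alternating scene/object mini-blocks of two stimuli in between. Spikes are
global offsets of +3% of the baseline intensity on randomly chosen volumes
(rate 0.02), exceeding the 1.3% detection threshold by design. Motion is
a slow Gaussian random walk (0.02 mm / 0.002 rad steps).

Defaults are desk scale — 16 subjects, one 240-volume run at TR 2.4 s —
chosen so a full group analysis runs in seconds; the full-scale values
(32 subjects, two 332-volume runs) are valid configuration. Subject seeds
are spawned deterministically from the group seed, so identical
(config, seed) reproduce every artifact bit for bit.

What the phantom does **not** emulate: vascular/physiological noise,
spatial autocorrelation of noise (noise is iid white), multi-band
artifacts, between-subject anatomical variability (all subjects share one
grid, so co-registration is out of scope), and the event-related
old/similar-lure microstructure of the recognition task (only
condition-level regressors matter downstream). Passing tests therefore
demonstrate the correctness of the analysis chain under known ground
truth, not robustness to realistic noise structure.

## Problem sizes used in tests and the acceptance script

Parameter-recovery checks run 20 replicate groups at n = 16 subjects,
240 volumes, unit noise; type-I-error checks run 100 replicate null groups
(flat gradients, no content bias) at the reduced size n = 8, 120 volumes
on a 22×20×12 grid, which leaves the test of the inference cascade intact
while keeping a hundred full pipeline replicates cheap. The acceptance
script runs one full experiment at the study sample size (n = 32) and 50
null replicates. The zero-noise parcellation check disables smoothing:
with no noise there is nothing to suppress, and smoothing across the
(deliberately adjacent) hidden EC subregion boundaries would only blur the
exact attribution the check is about.

## Known limitations

- Framewise displacement ignores rotations.
- The GLM assumes iid errors (no prewhitening); fine for the white-noise
  phantom, anticonservative on real autocorrelated BOLD data.
- Stage-3 pairwise interactions are uncorrected.
- The CA1 "outer borders" definition (max-distance voxel pair) is one of
  several defensible readings; it is deterministic and matches the sector
  construction on convex arcs.
- One-sided thresholding (T > 3.1) means anticorrelated voxels are never
  assigned.
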