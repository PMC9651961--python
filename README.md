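# transfc

Transversal functional connectivity of the human entorhinal–hippocampal
circuitry: a tested, reusable Python pipeline from 4D BOLD runs and ROI
label maps to the statistics that characterise how cortical information
streams map onto the entorhinal cortex (EC) and continue along the
transversal (proximal→distal) axis of hippocampal subiculum and CA1.

## Who this is for

Researchers analysing high-resolution task or resting-state fMRI of the
medial temporal lobe who want a transparent, scriptable implementation of
the seed-to-voxel semipartial-correlation / winner-take-all parcellation /
transversal-segmentation workflow — and a synthetic phantom with known
ground truth to validate every stage of it.

## What it computes

1. **Task GLM** (`transfc.glm`) — spike/outlier detection (global-intensity
   change > 1.3% of the run mean, or framewise displacement > 0.3 mm),
   double-gamma HRF condition regressors, motion and spike nuisance
   columns, voxelwise OLS. Residuals feed the connectivity analysis;
   condition betas yield scene>baseline and object>baseline contrasts.
2. **Semipartial seed-to-voxel connectivity** (`transfc.connectivity`) —
   after 0.01–0.1 Hz zero-phase band-pass filtering, the seed time series
   is residualized against the *other* seeds plus nuisance (white matter,
   CSF, motion, spikes), isolating the variance a voxel shares uniquely
   with that seed:

   r_sp(v, s) = corr( v ⊥ N ,  s ⊥ [S₋ₛ, N] ),   z = atanh(r_sp)

   where N are nuisance regressors and S₋ₛ the competing seed series.
3. **Winner-take-all parcellation** (`transfc.parcellation`) — per-source
   one-sample T maps over subjects' z-maps; each EC voxel is attributed to
   the source (RSC, PHC, Area 35, Area 36) with the maximum T, provided
   T > 3.1; seed sizes are equalized across hemispheres.
4. **Transversal segmentation** (`transfc.segmentation`) — per coronal
   slice, five equal-width subiculum bins along the medial–lateral axis
   and three 60° CA1 sectors about the midpoint of the longest chord;
   segment means are averaged along the longitudinal axis into
   subjects × (seed × segment) estimate tables.
5. **Hierarchical RM-ANOVA cascade** (`transfc.stats`) — stage 1:
   seed × segment interaction per target region (Benjamini–Hochberg FDR
   across regions); stage 2: per-seed one-way segment effects (FDR within
   region); stage 3: pairwise seed × segment interactions among surviving
   seeds. A parallel cascade tests condition × region/segment interactions
   for scene-vs-object content bias with FDR-corrected paired t-tests.
   The within-subject ANOVA uses the classical sums-of-squares
   decomposition (interaction df = (a−1)(b−1), error df = (a−1)(b−1)(n−1)).
6. **Synthetic phantom** (`transfc.phantom`) — four cortical sources emit
   band-limited latent signals; hidden EC subregions are each driven by
   one source; subiculum/CA1 voxels mix the latents with weights varying
   linearly along a known transversal coordinate; a scene-specific
   response is confined to the PHC-driven EC subregion and the distal
   subiculum. White noise, motion traces and global-intensity spikes
   complete the simulation.

## Worked example

```python
import transfc as tf

config = tf.PipelineConfig(phantom=tf.PhantomConfig(n_subjects=16, rng_seed=0))
result = tf.run_pipeline(config, write_artifacts=False)

print(f"parcellation accuracy: {result.parcellation_accuracy:.3f}")
print(f"seed sizes: {result.seed_counts}")
sub = result.gradient_report.regions["SUB"]
print(sub.interaction)
print(f"slope signs: {sub.seed_slope_signs}")
print(result.content_reports["EC"].summary())
```

prints

```
parcellation accuracy: 0.992
seed sizes: {'RSC': 31, 'PHC': 33, 'A35': 32, 'A36': 32}
measure:segment: F(12,180) = 860.938, p = 5.643e-152
slope signs: {'EC_A35': -1, 'EC_A36': 1, 'EC_PHC': 1, 'EC_RSC': -1}
Content-bias test (q=0.05): condition:region: F(3,45) = 26.159, p = 6.011e-10
   EC_A35: t(15)=1.416 p_FDR=0.3544 (scene>object)
   EC_A36: t(15)=0.315 p_FDR=0.9954 (scene>object)
 * EC_PHC: t(15)=10.538 p_FDR=9.993e-08 (scene>object)
   EC_RSC: t(15)=-0.006 p_FDR=0.9954 (object>=scene)
```

Reading this: 99.2% of EC voxels were attributed to the cortical source
that actually drives them in the phantom; the four seeds end up nearly
equal in size. The subiculum seed × segment interaction is significant
with the expected degrees of freedom (12 and 12·(n−1)), and the recovered
profile slopes match the imposed gradients — the PHC-based seed's
connectivity rises towards the distal subiculum while the RSC- and
A35-based seeds' connectivity rises towards the proximal end. In the
content analysis only the PHC-based EC seed shows significantly higher
scene than object activity, exactly where the phantom put the bias.

The same stages are exposed on the command line:

```bash
tfc simulate --out data/ --seed 0        # phantom dataset (NIfTI + TSV)
tfc glm --bold data/sub-01_run-1_bold.nii.gz --events data/events.tsv \
        --motion data/sub-01_run-1_motion.tsv --out glm/
tfc run --out results/                   # whole experiment, all artifacts
tfc gradient --tables SUB.tsv --tables CA1.tsv
tfc content --table content_EC.tsv --unit-col region
```

Segment-level estimate tables are plain TSV (`subject`, `measure`,
`segment`, `value`); `transfc.read_table` accepts a column mapping so
externally produced segment estimates can be fed straight into the stats
cascade.

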