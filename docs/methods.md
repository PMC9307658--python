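# Methods

This note describes the statistical model implemented by `myelinpath`, the
assumptions behind each stage, the default parameters and why they were
chosen, what the synthetic-cohort generator does and does not emulate, and
the numerical choices that matter for reproducibility.

## Scientific setting

The package analyses a within-subject motor-neuroscience design in which
each participant contributes:

1. **Skeletonised microstructural maps** — four voxelwise markers sensitive
   to myelin: magnetisation transfer (MT), longitudinal relaxation rate
   (R1), effective transverse relaxation rate (R2\*), and fractional
   anisotropy (FA) — sampled on a common white-matter skeleton.
2. **Paired-pulse TMS physiology** during an action-reprogramming task:
   motor evoked potentials (MEPs) recorded under single-pulse (SP) and
   paired-pulse (PP) stimulation on *stay* and *switch* trials.
3. **Behaviour** — reaction times on the same trials.

Three subject-level ratio metrics summarise the physiology and behaviour:

- **switch PP/SP ratio** = median(PP-switch MEP) / median(SP-switch MEP):
  an index of interhemispheric/premotor influence on M1 during reprogramming
  (lower = stronger conditioning effect);
- **switch M1 inhibition** = median(SP-switch MEP) / median(SP-stay MEP):
  corticospinal suppression during reprogramming relative to stay trials;
- **switch RT cost** = mean(switch RT) / mean(stay RT): the behavioural
  cost of reprogramming.

The scientific chain under study is: more myelinated tracts → stronger
paired-pulse conditioning (lower PP/SP) → … → reaction-time cost. The
package tests each link and the serial mediation of the whole chain.

## Stage 1 — MEP preprocessing

Trials are excluded, in fixed order of attribution, when:

| rule | criterion | default |
|---|---|---|
| small MEP | amplitude below threshold | `< 0.2 mV` |
| large MEP | amplitude above threshold | `> 9 mV` |
| incorrect | wrong response | — |
| premature | RT below window | `< 150 ms` |
| slow | RT above window | `> 800 ms` |
| precontraction | pre-TMS EMG above threshold | `> 0.4 mV` |

All comparisons are strict inequalities, so boundary values are retained.
Each excluded trial is attributed to the *first* matching rule, which makes
the per-reason accounting reproducible. After rule-based filtering, an
iterative two-sided Grubbs test (α = 0.05) removes amplitude outliers
within each (trial type × condition) cell; the critical value is built from
the Student-t quantile, G = ((n−1)/√n)·√(t²/(n−2+t²)) with
t = t₁₋α/(2n), n−2. Subjects with fewer than 9 MEPs in any condition are
excluded from all further stages.

A Wilcoxon matched-pairs test compares SP-switch and SP-stay medians across
subjects; the point estimate is the Hodges–Lehmann median of Walsh averages
with a distribution-free confidence interval from the normal-approximation
critical rank.

## Stage 2 — voxelwise joint inference

At each skeleton voxel and for each of the K = 4 modalities, the
association between the voxel values and the subject-level regressor (the
switch PP/SP ratio) is scored by the Pearson correlation after a Blom
rank-based inverse-normal transform of the regressor,
Φ⁻¹((rank − 3/8)/(n + 1/4)), which makes the permutation distribution
depend only on ranks. Per-modality one-sided p-values come from a common
pool of P random subject permutations (identity included; p = (b+1)/(P+1)
counting). The four p-values are combined per voxel with Fisher's
statistic F = −2·Σ ln p. Family-wise error is controlled by the
max-statistic method: the same permutations, synchronised across voxels and
modalities, yield the null distribution of the skeleton-wide maximum of F,
and each voxel's FWE p-value is the tail share of that distribution at its
observed F. Synchronising permutations preserves both the spatial
correlation of the skeleton and the cross-modal correlation of the markers,
which is what makes Fisher's combination valid here without an independence
assumption.

Default direction is `negative` (more myelin-like marker values predicting
*lower* PP/SP ratios); `positive` and `two-sided` are available.

## Stage 3 — myelin composite

Per-modality means over the significant voxel mask are standardized and
decomposed by SVD; the composite is the first principal component score,
sign-oriented so that it correlates positively with the across-modality
mean (higher composite = more myelin-like). Constant modality columns are
dropped with a warning. Spearman correlations link the composite to the
physiology metrics, and Steiger's Z̄\* test for dependent overlapping
correlations compares correlation strengths that share a variable.

## Stage 4 — serial mediation

The serial two-mediator path system is fitted by OLS:

    M1 ~ X            (a)
    M2 ~ X + M1       (d21)
    Y  ~ X + M1 + M2  (b1, b2, c′)
    Y  ~ X            (c_total)

with X the myelin composite, M1 the switch PP/SP ratio, M2 switch M1
inhibition, and Y the switch RT cost. The headline estimand is the serial
indirect effect a·d21·b2. Inference is by subject-level bootstrap
(default 10,000 resamples): percentile 95% CI (BCa available by flag) and a
sign-based two-sided p-value, 2·min(share ≤ 0, share ≥ 0), floored at
1/n_boot. Degenerate resamples (any constant variable) are redrawn and
counted. Variables are standardized by default; raw-scale fits by flag.

For OLS these fits satisfy the exact decomposition
c_total = c′ + a·b1 + (a·d21 + x→M2)·b2, which the test suite checks to
1e−10.

## Synthetic-cohort generator

The generator produces a full study-scale cohort: the default configuration
*is* the study condition — 56 subjects, 500 skeleton voxels with a 10%
contiguous signal block, 28 trials per (trial type × condition) cell.

Structure: a standard-normal latent myelin factor x per subject drives a
linear-Gaussian chain z_M1 = a·x + ε, z_M2 = d21·z_M1 + ε,
z_Y = b2·z_M2 + c·x + ε. Each latent z maps to a positive subject-level
ratio through a lognormal link, ratio = base·exp(scale·z̃). Skeleton voxels
in the signal block equal loading·x plus independent Gaussian noise; null
voxels are pure noise. Trial-level MEPs are lognormal around the condition
medians implied by the subject's true ratios, and RTs are Gaussian around
condition means; both are median-preservingly clipped inside the filter
windows so that the contamination labels are exact. Contaminated trials are
drawn from a single categorical distribution (premature, slow, incorrect,
precontraction, extreme amplitude), making the kinds mutually exclusive.

**Calibration.** The default path coefficients (a = −0.655, d21 = −0.620,
b2 = −0.355, c′ = −0.0891), loadings (1.5, 1.5, 1.2, 0.9) and voxel noise
sd 0.5 were chosen so that the correlations among the *measured* metrics —
after trial sampling noise and the full preprocessing cascade — land near
the field-reported values (marker ↔ PP/SP ≈ −0.40, PP/SP ↔ M1 inhibition
≈ −0.52, M1 inhibition ↔ RT cost ≈ −0.31). Median-based metrics attenuate
latent correlations by roughly √(1/(1+(π/2)σ²/m)) per metric, so the latent
paths are deliberately stronger than the target correlations.

**What the generator does not emulate.**

- Voxel noise is independent across voxels, so averaging over a significant
  mask nearly removes it and the PC1 of the four modality means explains
  ≈ 99% of variance — higher than the ≈ 70% typical of empirical maps,
  where modality-specific (voxel-shared) variance persists. Correlations
  *between* the composite and physiology are calibrated and realistic; the
  PC1 variance share is not a calibrated quantity.
- Clean-trial values are truncated inside the filter windows, so the filter
  has recall and precision 1 on labelled data; empirical data would show
  borderline clean trials.
- The two shared-median metrics (PP/SP and M1 inhibition both use the
  SP-switch median) acquire extra negative correlation from shared sampling
  noise (~−0.2 at 28 trials); this is a real property of the metric design,
  not an artifact.
- At the default n = 56 the standardized mediation estimate is attenuated
  by mediator measurement noise (proportion mediated ≈ 0.15–0.25 rather
  than the latent ≈ 0.6) and the bootstrap CI frequently spans zero; the
  mediation machinery is validated on larger simulated cohorts where the
  planted effect is recovered to ±0.02.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.SeedSequence` spawning: one
  master seed deterministically derives the simulate / inference /
  mediation stage seeds, all recorded in the run report. The same config
  and seed reproduce every output byte.
- Permutation p-values use (b+1)/(P+1) counting with the identity
  permutation in the pool, so p = 0 is impossible and the FWE p-value floor
  is 1/(P+1).
- Bootstrap path fits use batched normal equations
  (`einsum` + `numpy.linalg.solve`) across all resamples at once; the test
  suite cross-checks the per-fit route against `statsmodels` OLS to 1e−10.
- JSON artifacts are written with sorted keys and fixed float handling, so
  determinism is byte-level, not merely numerical.

## Limitations

No spatial cluster-level inference (voxel-level max-statistic FWE only), no
causal-identification machinery beyond the serial OLS system, no MRI or EMG
preprocessing — the package starts from skeletonised values and trial
tables. The generator is a calibration and validation instrument, not a
biophysical simulation.
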