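# Methods note

This document records the quantification model implemented by `hcrquant`,
the synthetic phantom used to validate it, the numerical conventions, and
the known limitations. It makes no empirical claims beyond what the code in
this repository computes.

## Quantification model

`hcrquant` quantifies whole-mount HCR in situ hybridization signal in
cleared, light-sheet-imaged regenerating limb volumes. One biological
sample (one blastema) is a 4-channel 3D stack: a nuclear channel (DAPI), a
488 nm autofluorescence channel containing no HCR probe, and two HCR
channels (546 nm and 647 nm; here Fgf8 and Axin2 probes). Axes are ordered
`(channel, z, y, x)`; physical triples are `(z, y, x)` micrometres; crop
boxes are 0-based and half-open.

Per sample the pipeline applies, in order:

1. **Isolation** — optional rigid rotation about the stack center (Euler
   angles about z, y, x; linear interpolation, shape preserved) followed by
   a half-open crop box, used to exclude mature stump tissue.
2. **Background estimation and subtraction** — per HCR channel, the
   background is the unweighted mean of the mean intensities of small
   in-plane square ROIs (default 5 µm × 5 µm) placed in epidermis free of
   HCR signal. It is subtracted from that channel only, clamped at zero.
   The nuclear and autofluorescence channels are left untouched.
3. **Smoothing for segmentation only** — a separable 3D Gaussian with an
   isotropic physical sigma (default 3.84 µm; at the original acquisition
   spacing of 0.64 × 0.64 × 2.207 µm this equals pixel sigmas x = 6.0,
   y = 6.0, z ≈ 1.74). Boundaries are handled by edge-repeating reflection.
4. **Fixed thresholds** — a mask is all voxels with blurred intensity
   `>= t`. One threshold per channel is shared by every sample of an
   experiment; thresholds are configuration inputs recorded in the log.
5. **Autofluorescence removal** — the thresholded 488 nm mask (bright
   structures such as blood cells, visible in all channels) is subtracted
   from every expression mask: `expr AND NOT af`.
6. **Compartment split** — for Axin2, a low-threshold Fgf8 mask that covers
   the whole mesenchyme (Fgf8 is weakly present throughout the blastema
   mesenchyme) splits the Axin2 domain: epidermal = Axin2 minus the low
   mask; mesenchymal = the remainder. The two parts are disjoint and union
   to the input (a checked invariant).
7. **Measurement** — the arithmetic mean intensity of the *unblurred*,
   background-subtracted channel inside each final mask, accumulated in
   float64. One blastema yields one value per (domain, channel). An empty
   mask is an error or an explicitly flagged record, never a silent zero.
8. **Normalization** — every value is divided by the mean of the vehicle
   (DMSO) controls of the same domain, channel and staining round, so
   controls average to 1 per stratum and between-round staining-efficiency
   differences cancel.
9. **Statistics** — treated vs control groups are compared with the
   two-sided Wilcoxon rank-sum test: the exact permutation null when the
   pooled sample size is ≤ 20 without ties, otherwise the normal
   approximation with tie and continuity corrections. The fold change is
   the ratio of group means of normalized values. Stars follow
   *p < 0.05, **p < 0.01, ***p < 0.001, ns otherwise. No multiple-testing
   correction is applied.

Failures are quarantined per sample with their stage and message; a batch
never aborts, and nothing is excluded silently. A JSON-lines log records
per sample the background values, all thresholds, the resolved pixel
sigmas, and every mask's voxel count — the complete set of analyst degrees
of freedom.

## Synthetic phantom

The generator (`hcrquant.synthetic`) builds blastema-shaped volumes with
exactly known ground truth, used for validation and parameter-recovery
experiments.

**Geometry.** Tissue is a capped elliptic cylinder continued by a
half-ellipsoid dome along +y (the proximal cut face open at y = 0). An
epidermal shell of fixed physical thickness (default 24 µm) surrounds the
mesenchymal core (radii shrunk by the thickness). The shell splits into an
HCR-free outer layer (default 8 µm — where background ROIs are placed) and
a basal layer carrying the weak epidermal Axin2 expression, matching the
basal-epidermal localization of Wnt activity. The Fgf8 domain is anterior
(x below the midline), confined to a subepidermal band (default 40 µm below
the shell), with a distal y-quantile cut sized so it occupies ~15% of the
mesenchyme.

**Intensities.** Channels: DAPI 80 in tissue; 488 nm dark except
autofluorescent inclusions; Fgf8-546 with a weak pan-mesenchymal floor
(0.25 × base 100) plus the bright anterior domain (total 100 inside it);
Axin2-647 100 throughout the mesenchyme and 50 in the basal epidermis.
Fifteen blood-cell spheres (radius 8 µm, +300 in *all* channels) model
autofluorescent inclusions. Per-channel additive background (20) and
additive Gaussian sensor noise (sd 5, clipped at zero, float32) complete
the image. The weak pan-mesenchymal Fgf8 floor is what makes the
low-threshold mesenchyme mask of the compartment split work, mirroring the
published analysis' use of a permissive Fgf8 threshold to cover the
mesenchyme.

**Condition presets.** Treatment arms inject known fold changes into
mesenchymal Axin2, epidermal Axin2 and Fgf8 (CHIR 3 h: 2.6 / 1.8 / 1.5;
CHIR 6 h: 4.4 / 1.7 / 1.0; CHIR 12 h: 2.0 / 1.5 / 0.6; IWR 12 h: 0.5 / 0.5
/ 0.5; DMSO: all 1.0). Per-sample variability is multiplicative lognormal
jitter on intensity (σ = 0.10) and size (σ = 0.05); staining rounds apply
multiplicative efficiency factors (1.0, 1.2) in contiguous blocks, with
both arms of an experiment following the treated preset's round structure
(samples of the same experiment are stained in the same batches). Jitter
and noise for sample *i* depend only on `(seed, i)`, never on the preset,
so same-seed arms are sample-wise paired and the ratio of arm-mean true
intensities equals the injected fold exactly. All derived seeds are
reduced modulo 2³¹.

**What the generator does and does not emulate.** It emulates compartment
geometry, uniform-mean expression domains, autofluorescent inclusions,
additive background, sensor noise, staining-round efficiency and animal
variability. It does **not** emulate a light-sheet PSF, depth-dependent
attenuation or scattering, spatially varying background, textured
(per-cell granular) expression, segmentation-relevant anatomy beyond the
shell/core split, or registration error. Domain interiors are uniform, so
mean-intensity recovery is exact by construction in the noise-free limit;
what the recovery experiments actually stress is edge placement by the
blur-and-threshold step, background estimation, autofluorescence removal,
compartment splitting, round normalization and the statistics.

**Phantom scale.** Default phantoms are 64 × 128 × 128 voxels at 4.0 × 1.6
× 1.6 µm (≈ 256 × 205 × 205 µm). A real blastema at acquisition resolution
is orders of magnitude larger; at desk scale the spacing was chosen so the
3.84 µm blur stays small relative to compartment sizes, keeping
edge-effect biases second-order, while the z-anisotropy (2.5×) still
exercises anisotropic code paths.

**A-priori thresholds for synthetic experiments.** A fixed threshold at
half the blurred edge height places the mask boundary on the true domain
boundary (half-height edge recovery). With a single threshold shared by
both arms and an injected fold ≠ 1 no threshold is exactly half-height for
both arms, so for uniform-interior domains (Axin2, low Fgf8) the geometric
mean of the two arms' half-heights is used, balancing the two arms' edge
displacements; for the bright Fgf8 domain, which sits on the weak
mesenchymal floor, the threshold is the midpoint between the highest floor
and the lowest domain level across arms. The autofluorescence threshold is
the 488 nm background plus 30% of the blood-cell brightness. These rules
were fixed before the recovery experiments and are not tuned per run.

## Numerical conventions

- Voxel data is float32 on disk (ImageJ-hyperstack TIFF, axes ZCYX, with
  voxel size stored in the resolution tags and `spacing`); masks are 8-bit
  0/255 TIFFs. All mean/sum accumulation is float64.
- Thresholding uses `>=` (inclusive).
- Gaussian blur uses separable correlation with truncation at 4σ and
  edge-repeating reflective boundaries (`scipy.ndimage.gaussian_filter`,
  `mode="reflect"`).
- Rotation uses linear interpolation with zero fill, clamped at zero.
- The rank-sum statistic W is the rank-sum of the treated group with
  mid-ranks for ties; p-values come from `scipy.stats.mannwhitneyu`
  (exact when pooled n ≤ 20 and tie-free, else asymptotic with continuity
  correction).
- Randomness: `numpy.random.Generator` (PCG64) with `SeedSequence`-derived
  child seeds, all reduced modulo 2³¹. Every stochastic routine takes an
  explicit seed; there is no global random state.

## Validation design

- **Null calibration** uses n = 8 per arm because the exact two-sided
  rank-sum test at 8/8 has attainable size 0.0499 (at 4/4 the smallest
  attainable two-sided level is 2/70 ≈ 0.029, making a 0.05-level
  calibration check meaningless). Over 400 seeded DMSO-vs-DMSO
  experiments the rejection rate must fall inside the exact binomial 95%
  interval around 0.05.
- **Fold-change recovery** runs the treated presets against DMSO (n = 8
  per arm, 20 seeds) through the full file-based pipeline and requires the
  mean estimated mesenchymal and epidermal Axin2 fold changes within 15%
  of the injected values.
- **Known residual bias.** With a single fixed threshold per experiment
  the brighter (treated) arm's Axin2 mask extends ~0.5σ past the basal
  epidermal layer into the HCR-free outer epidermis, adding near-zero
  voxels to the treated mean only. This depresses the estimated epidermal
  fold by roughly 8–12% (within the 15% acceptance band; mesenchymal folds
  are recovered within ~2%). This is a property of the fixed-threshold
  protocol being modeled, not of the implementation; it is visible in the
  per-sample mask voxel counts in the run log.

## Limitations

- No PSF, attenuation, or depth-dependent degradation is simulated, so
  the recovery experiments do not probe deconvolution or depth bias.
- Uniform-intensity domains make mean recovery easy; textured expression
  would interact with blur-and-threshold segmentation differently.
- Whole-mask mean intensity is the only readout — no per-cell or
  per-component statistics.
- Thresholds are configuration inputs; the package does not choose them
  from the data (by design, matching the manual protocol — the log makes
  the choice auditable).
- The compartment split relies on the weak pan-mesenchymal Fgf8 floor
  exceeding the low threshold everywhere in the mesenchyme; in tissue
  where that floor is absent the split would misassign epidermal voxels.
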