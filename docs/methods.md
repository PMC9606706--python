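# Methods

## Problem

When EEG activity is mapped to the cortex, the forward model — head
geometry, tissue conductivities, electrode positions — is often only
approximately known: many studies substitute a template anatomy (no MRI) or
a template electrode cap (no 3-D digitization). `pacsim` quantifies what
those substitutions cost for a small, deep-ish target, the primary auditory
cortex (PAC), by simulating a cohort whose true geometry is known exactly
and re-analyzing each subject under the four combinations of
template/individual anatomy × template/individual electrodes.

## Head model and forward solution

Each head is three concentric spherical shells: inner skull, outer skull
(inner + 4 mm) and scalp (default radii 83 / 87 / 92 mm), with relative
conductivities (1, 0.0125, 1). The scalp potential of a current dipole
inside the innermost region separates into spherical harmonics; per degree
n the boundary conditions (continuity of potential and radial current at
the two skull interfaces, zero current through the scalp surface) are
eliminated analytically, leaving a dimensionless transfer factor τₙ. The
potential is the series

V = 1/(4π σ₁ R²) Σₙ τₙ xⁿ⁻¹ [ n q_r Pₙ(u) + (q·ê − u q_r) Pₙ′(u) ],

with x the dipole eccentricity (distance/scalp radius), u the cosine
between dipole position and electrode, q_r the radial moment component.
For equal conductivities τₙ = (2n+1)/n and the series has a closed form
(via Legendre generating functions); that closed form is the package's
independent forward oracle and the two agree to better than 1e−8 relative.

Numerics: the series is truncated when the last term's relative
contribution falls below 1e−8 (at least 60, at most 2000 terms); leadfield
assembly fixes the term count from the most eccentric source and evaluates
all sensor×vertex pairs by vectorized Legendre recurrences (a 128 × 2000
gain takes well under a second). Dipoles are unit (1 A·m), oriented along
the source normal (constrained orientation), and the gain is
average-referenced so forward and inverse share one reference.

This analytic model is the single largest deviation from a realistic
(boundary-element) head model. It preserves exactly the physics the study
design manipulates — layered conductivity, source depth, and geometric
mismatch between assumed and true sensor/anatomy configurations — but has
no cortical folding, so orientation errors from misestimated sulci are out
of reach.

## Anatomy and electrode individuality

*Individual anatomy* is the template sphere scaled by a subject factor
~Normal(1, 0.04), truncated to [0.85, 1.15], plus a centre offset uniform
in a 4 mm ball. This reproduces the mechanism that matters for the
comparison (the assumed conductor boundary is in the wrong place at the
wrong scale) without MRI data.

*Individual electrode positions* displace the template cap (128 quasi-
uniform Fibonacci-lattice electrodes within 120° of the vertex) along the
scalp: a per-subject smooth tangential direction field (affine field
projected to the sphere, i.e. degree ≤ 1 harmonics, so neighbouring
electrodes err coherently the way a shifted cap does), a linear
anterior→posterior magnitude gradient (default strength 0.5, giving
roughly 2:1 posterior:frontal displacement), and re-projection onto the
scalp. Each subject's mean displacement is drawn from Normal(17, 3.3) mm —
the statistic is read as mean ± SD of the per-subject mean across the
cohort — and a short fixed-point rescaling makes the realized mean match
the draw despite the projection shortening. Mismatched analysis
configurations radially project the foreign montage onto the chosen scalp,
mirroring the "project to surface" co-registration step.

## Source space and ROIs

Sources sit on a sphere at 0.9 × inner-skull radius with radial normals
(default 2000 vertices; 15000 available via configuration). Two lateral
seeds (±x, the left/right temporal positions) anchor concentric geodesic
discs: PAC (right 4.56 cm², left 6.16 cm²) inside an extended ROI (right
24.67 cm², left 28.03 cm², area factors 5.4 and 4.6). Areas are scaled to
the model sphere by the ratio of model area to a reference cortical
surface of 1800 cm² (factor recorded in the metadata). Vertex counts are
rounded, and the extended-ROI count is chosen to minimize the area-ratio
error, bounding the ratio deviation by 0.5/(k_PAC · ratio) < 5 % for any
grid of ≥ 1000 vertices; the individual ROI areas themselves are only
matched to one-vertex granularity at coarse resolutions.

## Evoked model and noise

The PAC source time course is two Gaussian deflections: P1 (+40 nA·m
total patch moment, 55 ms, σ = 20 ms) and N1 (−60 nA·m, 100 ms, σ = 30 ms),
each truncated at ±4σ. The template amplitude is the *total* dipole moment
of a hemisphere's PAC patch, divided uniformly over its vertices — this
keeps sensor amplitudes (~1 µV evoked peak) independent of grid resolution
and within the physiological range implied by the ±200/800 µV artifact
thresholds. Trials jitter in amplitude (lognormal, σ = 0.2) and latency
(Gaussian, σ = 5 ms). Truth is confined to the PAC patches by design, so
the power ratio of the true source pattern is exactly 1 and any deficit in
an estimate is attributable to the inverse operator — the operational
definition of spatial leakage used throughout.

Noise is sensor-space: unit-variance AR(1) in time (coefficient 0.95 at
1 kHz) mixed across channels by a Gaussian kernel over electrode distances
(bandwidth 40 mm, rows normalized to preserve marginal variance), scaled
so the single-trial peak SNR (max |clean evoked| / noise SD) is 0.3 — i.e.
≈ 3 after averaging 100 trials. Brain-noise (projected dipole) backgrounds
are not modelled.

Seeds: every subject quantity derives from
`SeedSequence([master_seed, subject_index, purpose_tag])` with tags for
anatomy, montage and trials, so partial re-runs are stable. Epochs are
generated on demand per subject (a 20 × 600-trial cohort is never held in
memory at once).

## Preprocessing

Band-pass 0.5–100 Hz, linear-phase Kaiser FIR (β = 7.2, order 462) applied
as a centred single-pass convolution (group delay compensated; the
magnitude response is exactly the designed one, and the first/last 231
samples of an epoch are edge-contaminated). Note the printed order gives a
~10 Hz transition band: very slow drift (< 0.5 Hz) is attenuated by only
~2 dB by design. Trials containing any sample outside [−200, 800] µV are
rejected. Average reference subtracts the instantaneous channel mean.
Trial equalization takes evenly spaced indices round(k·N/target)
(duplicates pushed forward), a deterministic formalization of
pseudo-selection that preserves temporal spread. Channel interpolation and
ICA have no synthetic counterpart and are omitted; the chain marks where
they would sit.

## Inverse solutions

The noise covariance is estimated from the pooled per-trial-demeaned
[−200, 0] ms baselines and loaded as C′ = C + 0.1·mean(diag C)·I. The
paper-style parameter pair ("regularization 0.1", "SNR 3") is disentangled
the way Brainstorm does: 0.1 is covariance diagonal loading; the Tikhonov
parameter is λ² = 1/SNR² = 1/9, with SNR read as an amplitude ratio of 3
(not 10^(3/20); configurable). After whitening (W = C′^(−1/2), symmetric
eigendecomposition) and depth weighting
R = diag(‖g̃ⱼ‖^(−2γ)), γ = 0.5, rescaled so trace(G̃RG̃ᵀ) equals the
sensor count, the kernel is K = R G̃ᵀ (G̃RG̃ᵀ + λ²I)⁻¹ W. Standardization
divisors: dSPM uses the noise-propagated SD (row norms of R G̃ᵀ M⁻¹; unit
variance under model-consistent noise — measured 0.92 with the 0.1
loading), sLORETA the model data-covariance diagonal
diag(R G̃ᵀ M⁻¹ G̃ R)^(1/2). A Cauchy-Schwarz argument shows the sLORETA
peak sits exactly at a noiseless single source for any λ and any diagonal
R, which the tests verify by brute force; raw MNE on the same test set
shows the superficial bias that motivates standardization. Estimates are
computed on the trial average (the kernels are linear, so per-trial
averaging would give the identical point estimate).

## Metrics

ROI time courses are plain means over ROI vertices (radial, coherently
oriented normals need no sign flipping; a `signs` hook marks where folded
cortices would). They are low-passed at 20 Hz (Hamming FIR, order 150,
delay-compensated) and baseline-corrected over [−100, 0] ms. P1 is the
largest strict local maximum in [10, 90] ms, N1 the largest local minimum
in [50, 150] ms; ties break earlier, and a window without an interior
extremum yields a missing value (the synthetic counterpart of subjects
lost to template configurations). The ROI power ratio is Σv² over PAC
divided by Σv² over the extended ROI at the single sample nearest the
component's peak latency ("squared sum" is read as sum of squares,
matching the name *power* ratio; the literal (Σ|v|)² is available via an
option), computed on per-vertex baseline-corrected, unfiltered source
scores. Localization error is the great-circle distance between the true
patch seed and the hemisphere-restricted absolute peak at the measured P1
latency (hemisphere restriction keeps the bilateral-source simulation
interpretable).

## Statistics

Per metric × hemisphere × method: subjects with any missing cell are
excluded listwise for that metric (every exclusion is logged). Values are
z-scored within subject over the four cells, Box-Cox transformed
(grid-search MLE over λ ∈ [−2, 2] step 0.01; data are shifted by 1 − min
only when non-positive, since shifting already-positive data distorts the
likelihood), then tested with a fully-within-subject 2×2 repeated-measures
ANOVA (both factors within-subject, one value per cell, so the
"mixed-model" design reduces to the classical blocked ANOVA; partial η²
from F·df₁/(F·df₁+df₂)). Levene (centre = median, across the four cells)
and Shapiro on the additive-model residuals gate a fallback to the
aligned-rank-transform ANOVA (align per effect on the balanced means
decomposition, rank, re-run the ANOVA on ranks, keep the aligned effect)
with Bonferroni-corrected paired Wilcoxon post-hocs; effect sizes are
reported only on the parametric branch. A degenerate Wilcoxon (all
differences zero) reports p = 1.

With zero anatomy and montage perturbation the four configurations are
identical by construction, so paired contrasts are exactly zero and the
directional tests cannot reject — the pipeline's null behaviour. Type-I
calibration is checked at the statistics level (aligned-rank ANOVA null
rejection rate over 500 simulated tables within [0.02, 0.08] at α = 0.05;
Levene null/power checks).

## Problem sizes and defaults

Cohort defaults follow the emulated recording (20 subjects, 600 trials,
128 channels, 1 kHz, epochs −200…1500 ms). The package's own evaluation
runs use a desk-scale grid of 2000 source vertices and 100 trials per
subject (trial-average SNR ≈ 3), which keeps a full 20-subject 2×2 dSPM
design in a few minutes on one CPU; grid size and trial count are
configuration values, and 15000 vertices reproduces the paper-scale
resolution.

## Known limitations

- Spherical shells: no cortical folding, no orientation errors from
  misestimated sulci, no skull-thickness variation across the head.
- ROIs are geodesic discs; real atlas parcels are irregular and split
  across gyri, so absolute power-ratio levels are not comparable to real
  data — only their ordering across configurations is meaningful.
- Sensor-space noise only; no brain-noise sources, no ocular or muscle
  artifacts (hence no ICA stage).
- Ground truth confined to PAC; real generators include contributions the
  leakage metric would attribute differently.
- The anatomy perturbation (global scale + offset) spans a narrower
  mismatch family than real inter-individual anatomy; effect sizes for the
  anatomy factor are therefore conservative relative to electrode effects.
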