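# Methods

`oscmem` reimplements, as a tested pipeline on synthetic data, an EEG
analysis chain for a 2x2 memory-encoding experiment: two encoding
strategies (a spatial mnemonic vs. a nonspatial associative mnemonic)
crossed with subsequent memory (items later recalled in the correct
relative order vs. forgotten). The chain runs: cohort simulation →
serial-recall scoring → Morlet wavelet power with pooled z-normalization
→ first-level cell averages → factorial contrasts → cluster-based
permutation statistics (3D sensor, sliding-window, 2D virtual-electrode)
→ LCMV beamformer source analysis.

## Synthetic cohort

The generator is the pipeline's ground truth, not a fixture. Its
defaults encode the reference study conditions: 21 subjects, 63
equidistant scalp channels, 500 Hz sampling, epochs −2.5..3.5 s around
item onset, and per-cell trial counts drawn from a truncated normal
around means 62.9 (spatial/remembered), 34.7 (spatial/forgotten), 45.7
(nonspatial/remembered), 49.7 (nonspatial/forgotten) with SD 12 and a
floor of 15 trials (the cohort-exclusion rule).

**Head model.** A single homogeneous conducting sphere (radius 0.09 m,
σ = 0.33 S/m) with the classic Legendre-series surface-potential
solution: the n-th infinite-medium multipole coefficient is boosted by
(2n+1)/n to satisfy the insulating boundary; the series is truncated at
n = 80 and sources kept at |r| ≤ R − spacing/2, where it converges to
~1e−8. The simplification is deliberate: simulation and inversion use
the *same* forward model, so beamformer claims are tested
self-consistently without any template download. Gains are
average-referenced. Anatomical ROIs (left/right medial temporal,
posterior parietal) are coordinate boxes in the sphere — stand-ins for
atlas masks, with the same nonempty-mask contract.

**Background noise.** 60 dipoles (half deep, half superficial), each
emitting independent Gaussian noise with a 1/f power spectrum
(log-log slope −1 over 2–30 Hz, flattened below 0.5 Hz), mixed through
the leadfield; plus white sensor noise (RMS 0.2 of a unit noise
component). This produces a realistically structured sensor covariance,
which the beamformer stage needs; it contains no ocular/muscle
artifacts, no line noise, and no non-stationarities, so passing tests
demonstrate statistical correctness of the chain, not robustness to
real-world artifacts.

**Effects.** Each effect is amplitude-modulated narrowband Gaussian
noise (not a phase-locked sinusoid) placed coherently on the grid points
of a ROI, present in *every* trial at base amplitude (2x a single noise
dipole's RMS) and scaled by `1 + amplitude_delta` inside its time window
for the affected cells. The default effect set mirrors the reference
findings qualitatively: a theta (3–7 Hz) decrease of 30% amplitude for
the spatial condition (bilateral MTL, −1..3 s), a theta memory decrease
(left MTL, 0.5..3 s), and alpha/beta increases late in the trial (10–15
Hz condition / 15–30 Hz memory, posterior parietal, 1–3 s; +30%, a value
chosen once as a plausible mirror of the decreases — the magnitudes of
the increases are not quantified in the source material). Condition and
memory effects live on different sources and therefore combine
additively: the design contains no interaction, which the interaction
contrast must (and does) report as null.

**Recall transcripts.** Each subject also gets synthetic recall
sequences per condition whose relative-order scoring reproduces exactly
the drawn remembered counts; out-of-sequence recalls (Poisson, mean 1.5
per condition) are constructed provably out of order (late items
recalled first in decreasing order). This exercises the scoring module
inside the pipeline rather than beside it.

**Determinism.** One master seed spawns per-subject `SeedSequence`
children; identical (config, seed) reproduces a cohort bit for bit.
Noise synthesis is single precision (complex64 spectra) — a deliberate
numerical choice that halves simulation cost with no statistical
consequence at the SNRs involved.

## Recall scoring

The relative-order rule is formalized as a maximum-cardinality
increasing subsequence of presented indices in recall order: items in
the subsequence are remembered, recalled items outside it are
out-of-sequence (discarded from the design cells), unrecalled items are
forgotten. A shifted whole run therefore counts fully remembered, while
a swapped pair loses exactly one item — the two canonical boundary
cases. Ties between equal-length subsequences are broken toward the
earliest output positions (computed by a start-length DP plus greedy
scan), making labels deterministic. Whether a globally maximal or a
greedy run-based rule was originally used is undecidable from the stated
examples (both agree on them); the maximal-subsequence reading is the
one under which both examples follow from a single principle.

## Time-frequency analysis

Complex Morlet wavelets with a fixed 5-cycle width (Gaussian envelope
SD `n_cycles/(2πf)`), default grid 2–10 Hz in 1 Hz steps for the
theta-band analyses and 2–30 Hz in 0.5 Hz steps for the sliding
statistic. Implementation notes:

* Signals are resampled to 100 Hz before convolution (power envelopes at
  ≤30 Hz have bandwidth f/n_cycles ≤ 6 Hz, so nothing is lost) and power
  is read out on 50 Hz frames aligned to t = 0 — the 100 ms sliding step
  implies ≤10 Hz effective resolution, so finer frames only cost
  permutation time.
* **Edge validity.** A 5-cycle wavelet at 2 Hz has a half-support of
  ~1.25 s, which does not fit between the −1..3 s statistics window and
  the −2.5..3.5 s epoch edges. Rather than letting edge attenuation leak
  into statistics, each (frequency, frame) bin carries a validity flag
  (frame at least 2 envelope SDs from both epoch edges); invalid bins
  are excluded from the z-scoring moments and can never join a cluster.
* z-transform per subject: for each channel x frequency, mean and SD are
  pooled over all trials and valid frames (SD with ddof = 1, in double
  precision), then every sample is transformed. A zero SD raises a
  degenerate-distribution error.
* First-level averages per design cell guard against trial-count bias in
  the main effects (cells enter contrasts unweighted).
* Gaussian smoothing (FWHM 200 ms x 2 Hz) is separable, truncated at
  4 SD, and renormalized by the smoothed validity mask, so constants are
  preserved exactly and invalid bins do not bleed inward.

## Factorial contrasts and group statistic

`main_condition` = mean(spatial) − mean(nonspatial), `main_memory` =
mean(remembered) − mean(forgotten), `interaction` = difference of
SMEs, `simple_remembered` = spatial/remembered − nonspatial/remembered.
The bin-wise one-sample t of each contrast across subjects satisfies
t² = F of the matching 2x2 repeated-measures ANOVA effect (tested to
1e−8 against statsmodels). Zero-variance bins yield t = 0 with a warning
instead of ±inf, so degenerate bins cannot seed clusters.

## Cluster-based permutation inference

Suprathreshold bins (|t| above the two-tailed p < 0.05 critical value of
t(df), configurable) are grouped by connectivity — ±1 neighbours along
frequency and time (no wraparound), explicit graph neighbours across
electrodes or grid voxels (Euclidean ≤ 1.5x spacing for source grids) —
and each cluster is scored by its summed t. The null distribution of the
per-permutation extreme cluster sum is built by randomly sign-flipping
subjects' contrast maps (the paired-design label permutation); all
observed clusters are compared against that same extreme-statistic null,
giving strong familywise control.

Numerical/design choices:

* Positive and negative clusters keep separate nulls; the reported
  `p_corr` doubles the per-tail p (capped at 1), making `p_corr ≤ α` a
  valid two-tailed decision. This is what calibrates the familywise rate
  at α = 0.05 (measured 3.3–7.1% over 500 null cohorts) and matches the
  convention under which a 1000-permutation test bottoms out at
  p = 0.002.
* Monte-Carlo p = (1 + #{null ≥ obs})/(n_perm + 1); when n_perm reaches
  the 2^n distinct sign patterns the test enumerates them all and p is
  exact (floor 2/2^n two-sided; the identity pattern's tie is enforced
  against floating-point rounding). Default n_perm = 1000.
* The bin adjacency is the Kronecker sum of per-axis adjacencies, built
  once per geometry; component labelling is a union-find over the masked
  subgraph (numba-compiled, with a scipy connected-components fallback),
  which is what makes 500-cohort calibration runs desk-scale.

## Sliding-window statistic

For every 300 ms x 1 Hz tile (steps 100 ms / 0.5 Hz) the contrast is
averaged over the tile per subject and a 1D electrode-cluster
permutation test is run; each tile stores its best cluster p per
polarity, with a deterministic per-tile seed schedule so any tile can be
reproduced standalone. Tiles are deliberately uncorrected across the
grid (the screen is exploratory); the coherence filter then keeps only
4-connected regions of significant tiles whose bounding extent spans at
least 3 time x 4 frequency bins (500 ms and 2 Hz at the default steps).
Extent is measured as the bounding-box span; an area mode (minimum 8
tiles) reproduces the stricter interaction screen. The filter is
idempotent and monotone in alpha, and with minimum extent (1,1) it
degenerates to plain thresholding.

## LCMV beamformer

Sensor covariance is pooled over the whole length of all trials
(average-referenced, mean-removed) and diagonally loaded with
λ·mean(diag) (default λ = 5%). Filters W = (LᵀC⁻¹L)⁻¹LᵀC⁻¹ satisfy
unit gain W·L = I at every grid point (1e−8); the scalar filter per
point takes the orientation of maximal output power (eigenvector of the
smallest eigenvalue of LᵀC⁻¹L). Localization scans noise-normalized
output power (wᵀCw / wᵀw). Virtual electrodes sign-align orientations
within a ROI (nearby orientation flips would cancel a coherent source)
and average the scalar time courses; the result re-enters the spectral
chain as a one-channel recording and is tested with 2D (time x
frequency) clustering. Source power maps band-pass, project, and
z-score the squared analytic-signal envelope across trials and time —
the source-level analogue of the sensor z-transform (chosen over a
separate noise normalization; z-scoring across time is applied the same
way at both levels).

Two properties of EEG beamforming shape the validation design:
output power at the true source *grows* with added sensor noise (the
unit-gain constraint passes the noise floor), so the monotone quantity
checked is the localization contrast against the background; and
bilateral medial-temporal virtual electrodes leak ~25% of an injected
amplitude change into the contralateral side at any regularization.
Lateralized recovery is therefore validated with light loading
(λ = 0.001, sharper filters from a well-estimated covariance) on a
cohort sized (8 subjects x 16 trials/cell, full 63-channel montage) so
the leaked effect sits below the detection threshold while the injected
one sits well above it — the same regime in which a lateralized finding
is interpretable in real recordings.

## Problem sizes used in validation

The statistical criteria are never relaxed, but simulations are scaled
to desk size as the package's own choice of validation conditions:

* Familywise calibration: 500 null cohorts of 12 subjects on a
  16-channel x 10-frequency x 40-frame grid, 500 permutations each.
* Effect recovery: 50 cohorts of 21 subjects at 16 channels, 250 Hz,
  half the default trial-count means (floor 15), 24 noise dipoles,
  200 permutations; recovery requires a significant negative cluster
  overlapping the injected band x window for both theta effects and a
  null interaction, each in ≥90% of runs.
* Localization: 100 random interior dipoles at SNR 10 on a 12 mm grid.
* Lateralization: 50 cohorts of the 8-subject configuration above.

## Known limitations

* The spherical head model and box ROIs are self-consistent stand-ins;
  absolute localization accuracy on real heads is out of scope.
* The generator's effects are stationary narrowband amplitude changes;
  evoked (phase-locked) activity, artifacts, and inter-subject
  anatomical variability are not modelled.
* The sliding statistic inherits its liberal, tile-uncorrected character
  by design; the coherence filter documents rather than fixes it.
* Out-of-sequence recalls are constructed, not behaviourally modelled;
  their rate matters only to the scoring stage's bookkeeping.
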