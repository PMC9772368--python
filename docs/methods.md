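# Methods

This note documents the models, conventions and design choices behind
`segdosim`, in the order the pipeline applies them.

## Study structure

The unit of data is a *read*: one contouring event identified by
(lesion, reader, round), carrying a binary voxel mask on a regular grid with
physical spacing. The reference design has three readers, two contributing
three rounds and one a single round — 7 reads per lesion, 140 for a 20-lesion
cohort. All analyses assume masks and dose maps are co-registered; masks on a
different lattice are resampled to the dose grid by nearest neighbour.
Registration itself is out of scope.

## Geometric metrics

- **Volume** = occupied voxels × voxel volume / 1000 (mL). An empty mask has
  volume 0 and is excluded (with a warning) from pairing and summaries.
- **Dice** = 2|A∩B|/(|A|+|B|), defined only on a shared grid and only when at
  least one mask is non-empty.
- **RECIST diameter** = the maximum, over axial slices, of the largest
  pairwise distance between occupied-voxel centers within that slice. The
  production path takes the per-slice convex hull first and scans hull
  vertices; tests compare against the all-pairs oracle. Distances are
  center-to-center: a caliper (edge-to-edge) measurement would read up to
  about one voxel larger, a deliberate, documented convention because it is
  unambiguous and exactly oracle-checkable. The axial plane is the third
  array axis by default and is configurable, since NIfTI orientation varies.

## Dose metrics

Mean dose is the arithmetic mean of voxel doses inside the mask; equal voxel
volumes within a grid are assumed (true for the supported formats).
D_x (the minimum dose delivered to x% of the contoured volume) supports two
conventions:

- `linear` (default): linear interpolation between closest ranks of the
  (100−x)th percentile of voxel doses — standard smooth-DVH practice;
- `step`: the largest sampled dose t with fraction(dose ≥ t) ≥ x%, the
  step-function reading of the cumulative DVH.

Both are oracle-tested; which convention an existing analysis used is rarely
stated, so both are exposed and the choice is recorded in the run manifest.

**Partial-volume correction.** The recovery coefficient curve
RC(v) = −0.934·v^(−0.573) + 0.883 (v in mL) comes from a sphere-phantom
calibration of a Y-90 PET/CT chain. RC crosses zero at v ≈ 1.104 mL and the
correction 1/RC blows up near the root, so PVC requires
v ≥ `min_valid_volume_ml` (default 1.5 mL; hard floor at the root). The
correction is applied **per read** with that read's own volume and then
summarized per lesion — correcting the lesion-mean volume instead would
understate the variance inflation that PVC causes for small, variable
contours (the curve is convex there). Corrected dose is always larger than
measured (RC < 0.883 < 1 for all finite volumes).

## Observer variability

Inter-observer Dice pairs: different readers, same lesion, same round
(readers absent from a round contribute nothing to it). Intra-observer pairs:
same reader, same lesion, different rounds. Under the reference design each
lesion gives 5 inter and 6 intra pairs. The group means are compared with a
Welch (unequal-variance) two-sample t-test on the raw Dice values; Welch was
chosen over the pooled test as the robust default — at these group sizes the
difference is negligible. Per-lesion uncertainty is CV% = 100·SD/mean with
the sample (n−1) SD.

## Variance decomposition

Measurements are modelled as y = μ + lesion + reader-within-lesion +
residual, all random and mean-zero, with variances σ²_lesion, σ²_inter,
σ²_intra summing to σ²_total. The reader effect is **nested within lesion**
(equivalently a lesion×reader interaction) rather than a crossed reader main
effect: with three readers a crossed main effect is barely identifiable, and
the quantity of interest is between-reader disagreement per lesion.
Estimation is REML (statsmodels MixedLM: lesion random intercept plus a
reader variance component), which handles the unbalanced single-round reader
natively; a closed-form expected-mean-squares estimator is provided for
balanced designs and agrees with REML to ~1% there (tested). Negative
moment estimates are truncated at zero and flagged. The analysis runs on the
raw measurement scale by default (no transform is assumed); a log-scale flag
exists for sensitivity checks.

Reliability: ρ_inter = σ²_lesion/σ²_total and
ρ_intra = (σ²_lesion+σ²_inter)/σ²_total, with the observer variance split
100·σ²_inter/(σ²_inter+σ²_intra) (undefined, reported as NaN, when the
observer variance is zero). The identity
inter_share = 100·(ρ_intra−ρ_inter)/(1−ρ_inter) recovers the split from an
ICC pair alone and is exposed as `reliability_to_shares`.

Subgroup fits (small ≤ 8 mL vs large; well- vs poorly-defined margins; named
lesion exclusions) are pure row filters followed by the same fit; they never
alter the global fit.

## Uncertainty as a function of volume

CV is regressed on the per-lesion mean contour volume as CV = α·v^β via OLS
of log CV on log v — multiplicative error is the natural scale for CVs and
keeps predictions positive; nonlinear least squares on the raw scale is
deliberately not the default. The slope t-test gives p for β = 0; Spearman
rank correlation between v and CV is reported alongside. Two fits are
produced per run: volume CV vs v and PVC mean-dose CV vs v. Noiseless
power-law data are recovered to machine precision, and the slope CI covers
the truth in ≥ 90% of seeded log-normal-noise replicates (tested).

## TCP propagation

TCP(d) = 1/(1+exp(−(b0+b1·d))). The coefficients are **user inputs**: they
come from a separately fitted dose-response analysis and this package does
not refit them (nor does it model their own uncertainty — reported Δ_TCP is
a lower bound in that sense). For a lesion of volume v and measured PVC mean
dose d: SD = predict_cv(v)/100·d, and Δ_TCP = TCP(d+2SD) − TCP(d−2SD), with
the lower bound floored at 0 Gy (warned). Deltas are reported in percentage
points; cohort summaries give mean, max, and the fraction of lesions at or
above a threshold (default 25 points). Δ_TCP peaks for lesions near the
logistic midpoint and vanishes for very low/high doses or SD → 0 (tested by
grid scan). A demo model (b0 = −2, b1 = 0.01/Gy; midpoint 200 Gy) ships for
examples only.

## Synthetic cohort generator

The generator emulates the structure of a multi-reader MRI contouring study
feeding Y-90 PET/CT dosimetry; it defines the study conditions under which
the pipeline is validated.

- **Lesions** are star-shaped bodies: an ellipsoid with mildly random axis
  ratios times 1 + irregularity·h(u), where h is a random band-limited
  spherical-harmonic field (degrees 1–3, RMS 1). The overall scale is set
  analytically from the target volume and corrected once against the voxel
  count; voxelized volume lands within ~2% of target for adequately resolved
  lesions (≳100 voxels). Volumes are sampled log-uniformly over 2–200 mL,
  matching the right-skewed spread of hepatic lesions selected above a
  ~2 mL visibility floor.
- **Observer disagreement** is a radial displacement of the true surface
  about the centroid: a per-(lesion, reader) bias field (degrees 1–4, RMS
  `sigma_inter`, fixed across that reader's rounds) plus fresh per-read
  session noise (RMS `sigma_intra`). This separable structure is exactly
  what the downstream variance decomposition assumes, and it is a modelling
  assumption: real disagreement may concentrate at ambiguous boundary
  segments rather than spreading smoothly over the surface. Defaults
  sigma_inter = 2.0 mm, sigma_intra = 1.25 mm put intra-pair Dice above
  inter-pair Dice at levels comparable to experienced abdominal readers
  (means ≈ 0.85 vs ≈ 0.7 on the default cohort, individual pairs mostly
  0.5–0.95 with a lower tail from the smallest poorly-defined lesions).
  Fields are mean-zero (degree 0 excluded), so read volumes are unbiased to
  first order; with both sigmas ≤ 1 mm the mean read volume stays within
  10% of truth (tested).
- **Margin classes.** A configurable fraction of lesions (default 40%,
  matching the rough proportion of poorly-defined margins among HCC lesions)
  receives a 2× perturbation multiplier and is labelled "poor"; size classes
  use the ≤ 8 mL convention.
- **Dose maps**: dose_peak (log-normal lesion-to-lesion spread, default
  150 Gy scale) inside the true lesion with multiplicative log-normal voxel
  texture (log-SD 0.3, mean 1, so D10 > mean > D90 generically), a 10%
  background outside, convolved with an isotropic Gaussian (default 5 mm,
  the post-filter width of the emulated Y-90 PET chain). Convolution
  conserves the dose integral away from grid edges (tested to 0.1%).
- **Determinism**: one master seed, expanded into per-(lesion),
  per-(lesion, reader) and per-(lesion, reader, round) substreams keyed by
  index — identical configs are bit-identical, and appending lesions leaves
  existing ones unchanged. Surfaces are voxelized by tabulating the
  (band-limited) radius field on a 128×256 angular lattice with a cached
  harmonic basis and bilinearly interpolating at voxel directions; the
  interpolation error is far below a voxel.

What passing on synthetic cohorts does **not** show: the generator contains
no imaging appearance, no registration error, no boundary-localized
disagreement, and no reader skill differences beyond the bias-field RMS, so
absolute agreement levels on real data may differ; the validated claims are
structural (orderings, identities, parameter recovery, propagation
arithmetic).

## Problem sizes in the test suite

Monte-Carlo style checks run on reduced conditions chosen as the smallest
that exercise the property cleanly: Welch-power replication uses 50 cohorts
of 4 lesions on a 2.5×2.5×3 mm grid (sigma_inter = 2 > sigma_intra = 1 mm);
variance-component recovery simulates 150 lesions × 7 reads from the
random-effects model directly, over 20 seeds, recovering the observer
components within 30% relative error; the full 20-lesion default cohort is
generated once per session for design-count and ordering checks.

## Known limitations

- RC curves from sphere phantoms carry their own transferability error for
  irregular, non-uniform lesions; this is not modelled.
- No voxel-level partial-volume correction (only the mean-value RC scaling).
- No confidence intervals on ICCs; no Bayesian variance estimation.
- TCP coefficients are treated as known; their sampling uncertainty is not
  propagated.
- Star-shaped geometry cannot represent lesions that are concave about their
  centroid.
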