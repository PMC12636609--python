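# Methods

This note documents the models, numerical choices and synthetic-data
conditions behind `rg4fus`, and what the test suite does and does not
establish about real data.

## rG4 motif scanning (`g4scan`)

A quadruplex candidate is a placement of four G-runs of equal length
*g* ≥ `min_group` (default 2) separated by three loops, each of length
`loop_min`–`loop_max` (default 0–36 nt), with total span ≤ `max_length`
(default 30 nt). Enumeration is exhaustive over (start, g, l1, l2, l3)
tuples: overlapping candidates are all reported and G-runs longer than *g*
appear at every register, deduplicated only on identical tuples, because the
consumed signal downstream is presence/absence per sequence, not a
non-overlapping tiling. Loops accept any base (the scanner is
alphabet-agnostic outside the G-runs), so DNA and RNA inputs classify
identically.

The G-score used for ranking is a surrogate:
`10·(g − min_group) + (max_length − L) − (max(loops) − min(loops))`.
It encodes the standard ordering principles — more stacked tetrads dominate,
then shorter spans, then more equal loops — without claiming the constants
of any particular published scorer, which are not needed for
presence/absence classification. The weight 10 on the tetrad term simply
guarantees tetrad count dominates the other two terms within the default
constraints (span surplus ≤ 22, loop spread ≤ 22 only in extremes).

## Interval enrichment (`enrichment`)

Coordinates are BED-convention throughout: 0-based, half-open, overlap
meaning `a.start < b.end and b.start < a.end`. Strand is carried by the I/O
layer but ignored by all enrichment arithmetic. "Occurrence" of a region in
an interactome is the **count of overlapping interactome intervals**
(`bedtools intersect -c` semantics, ≥ 1 bp by default), not base-pair
coverage; the per-region enrichment score is
`count_soluble / count_droplet`, defined only when both are positive.
Regions found in one phase only are labelled `soluble_only`/`droplet_only`;
candidate ranking puts soluble-exclusive regions first, then shared regions
by descending enrichment with region-id tie-breaks, reflecting that an RNA
found exclusively in the soluble FUS phase is the strongest possible
candidate inhibitor.

Tertile stratification sorts regions ascending by G4 Probability with stable
tie order and splits into "low"/"medium"/"high" groups whose sizes differ by
at most one (extras assigned to the lower strata: n = 7 gives 3/2/2).

Shuffling re-places each interval independently and uniformly across the
genome: chromosome drawn with probability proportional to length among the
chromosomes the interval fits, start uniform on the feasible range. Lengths
are preserved; shuffled intervals may overlap each other (the defaults of
the canonical shuffle tool). The permutation test statistic is the number of
query intervals with ≥ 1 bp of overlap in the subject set; the null is built
from `n_shuffles` (default 100) re-placements of either set ("both
directions"), and the empirical p-value uses the (r+1)/(N+1) pseudocount
estimator — conservative, never zero, with minimum attainable value
1/(N+1). The test addresses the enrichment (upper) tail.

## Binding isotherm (`binding`)

The anisotropy signal is modelled by the exact ligand-depletion quadratic:
the bound-complex concentration is the smaller root of
`c² − c(x + Lt + Kd) + x·Lt = 0`, giving a bound fraction in [0, 1] that is
nondecreasing in protein concentration. Lt is the total labeled RNA (8 nM in
the titrations this package targets); Kd is in nM. An additive offset a₀ is
fitted by default so the routine works on raw anisotropy as well as
baseline-subtracted data; `fit_offset=False` pins a₀ = 0. Fitting is
trust-region least squares with positivity bounds on ΔA_max and Kd,
parameter/function tolerances 1e-10 and 10,000 evaluation cap. Initial
guesses: Kd at the x of half-maximal signal (linear interpolation), ΔA_max
as the signal span, a₀ as the minimum. Replicates are pooled before fitting
rather than averaged. Flat curves are returned with `converged=False`
(amplitude below 1e-8) instead of raising, so batch pipelines can continue.

## CD preprocessing and melt fit (`melt`)

Means-movement smoothing is a centered moving average (default width 15
points, odd widths only); at the edges the window shrinks symmetrically to
the largest centered window that fits, avoiding phantom padding. Buffer
subtraction is pointwise on matching X grids (1e-9 tolerance).

The melt model uses absolute temperature in the exponential (the only
physically meaningful reading of 1/X), with ΔH constrained positive so the
unfolded population grows with temperature. The fitted output always lies
between the two baselines, and the fraction unfolded is exactly ½ at T_m.
Initialization: T_m at the temperature of steepest change of the smoothed
curve, ΔH = 150 kJ/mol, baselines from straight-line fits to the first and
last 20% of points; T_m is bounded to the data range ± 20 K. Two degeneracy
guards flag non-convergence rather than returning a spurious T_m: a T_m
pinned at its bound, and a fitted transition amplitude below
max(3·residual s.d., 0.001·data range) — the latter catches monotone
baselines with no sigmoid. A helper `is_parallel_g4` reproduces the
qualitative topology call from a spectrum: positive band at 265 ± 5 nm with
a negative band at 240 ± 5 nm.

## Turbidity (`turbidity`)

Traces are A395 sampled in 1-minute cycles. Inhibition preprocessing
subtracts the pointwise mean of the buffer blanks and divides by the maximum
of the trial's zero-RNA control; reversal preprocessing divides each trace
by its own pre-RNA anchor, taken as the mean of the last 5 points before RNA
addition (a single final point would be hostage to one noisy read). The
pause at RNA addition is metadata, never gap-filled. AUC is trapezoidal on
the native grid (no resampling; endpoints interpolated linearly), which is
exact for piecewise-linear traces and additive over adjacent windows to
1e-9. Sedimentation fractions are intensity shares normalized to sum to 1.

## Imaging (`imaging`)

Droplet segmentation thresholds at a lower bound (Otsu by default, manual
override for parity with interactive analysis), labels 8-connected
components and discards those under 4 px. "Size" is the equivalent-area
diameter. The imaging enrichment score divides each droplet's mean intensity
by the mean of the background, where background excludes all droplets
dilated by a 2-px halo so rim pixels do not dilute the partition estimate.
Speckle enhancement is a white top-hat with a disk footprint whose diameter
is the feature size (default 20 px). Cytoplasmic foci masks combine
thresholded enhanced foci with the complement of the nuclei mask eroded by
5 px (so peri-nuclear foci survive). Colocalization is the Pearson
correlation of raw intensities over the **union** of the two channels'
cytoplasmic foci masks — the symmetric choice among the plausible pixel
populations (per-object or whole-cytoplasm correlation would also be
defensible); it requires ≥ 10 pixels and nonzero variance in both channels.
Enrichment is invariant under multiplicative intensity rescaling and Pearson
r under any affine rescaling.

## Synthetic data (`simulate`)

All generators take a seed and are bit-reproducible. They define the study
conditions under which the pipeline is validated:

- **Enrichment dataset** — 300 non-overlapping 30-bp regions on a
  2 × 1 Mbp genome, G4 Probability ~ Uniform(0, 1); each region receives a
  100-bp soluble-interactome fragment with probability 0.8 (high stratum) /
  0.3 (low; medium midway) and a droplet fragment with probability 0.3. One
  region is planted soluble-exclusive (score 1.0, soluble always, droplet
  never), the ground truth for candidate selection. The 100-bp fragment
  length against 30-bp regions mimics interactome fragments overlapping
  short rG4-seq windows.
- **Curves** — generative inverses of the fit models plus homoscedastic
  Gaussian noise (the simplest model consistent with plate-reader/CCD noise;
  none is otherwise specified). Melt fixtures use T_m = 50.64 °C (K⁺) and
  36.98 °C (Na⁺) with ΔH = 180 kJ/mol, flat baselines at 6 and 1 mdeg,
  15–85 °C at 1 °C pitch, σ = 0.1 mdeg. Titrations default to ΔA_max = 0.1,
  Kd = 50 nM, Lt = 8 nM, 12 log-spaced points, σ = 0.002. Turbidity is a
  logistic rise (plateau 0.5 A395, half-time 30 min) with post-addition
  decay toward a floor of (1 − inhibitor strength), making normalized AUC
  exactly nonincreasing in strength, and an optional enhancement multiplier
  for the low-concentration turbidity increase.
- **Images** — non-overlapping planted disks (droplets: intensity 200 on
  background 100; foci radius 3 at intensity 200 on background 10), nuclei
  as large disks in a separate channel, a controllable shared-foci fraction
  between the two foci channels, and returned truth masks.

What the generators deliberately do **not** emulate: read-level rG4-seq
counts, transcript annotation structure, heteroscedastic or correlated
instrument noise, droplet coalescence/ripening dynamics, out-of-focus light
and uneven illumination. Passing tests therefore demonstrate correctness of
the arithmetic and estimators under idealized conditions and calibrated
statistics under the stated nulls — not robustness to every artifact of real
microscopy or sequencing data.

## Problem sizes and determinism

The validation suite uses desk-scale problem sizes chosen to exercise the
statistics meaningfully: brute-force oracle comparisons at 200 × 200
intervals, type-I calibration over 200 null permutation tests (19 shuffles
each, sets of 20 intervals on a 100-kb genome), planted-enrichment detection
over 100 seeds at 99 shuffles, and parameter-recovery distributions over 50
seeded simulations per fit. Every stochastic routine accepts either a seed
or a `numpy.random.Generator`; identical seeds give identical results on any
platform.

## Known limitations

- The surrogate G-score ranks candidates plausibly but is not a calibrated
  stability predictor; two-tetrad motifs at long loops are reported even
  though many will not fold.
- Interval "occurrence" counts intervals, not reads; analyses whose
  interactomes carry read-count weights need upstream aggregation.
- The melt fit assumes a single two-state transition; multiphasic melts will
  be flagged converged with an averaged T_m rather than rejected.
- Shuffling places intervals anywhere in the genome; restricting the null to
  transcribed regions would sharpen it for transcriptome-derived sets.
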