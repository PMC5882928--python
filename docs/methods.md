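# Methods

## The discrimination value and its permutation test

The package treats every observation as a point in n-dimensional Euclidean
space carrying one of L condition labels. All statistics derive from the
M×M matrix of pairwise Euclidean distances; no other feature of the data
enters. Block means of that matrix form the L×L proximity matrix: the
diagonal entry for cluster A is the mean over all unordered within-A pairs
(self-distances excluded — a point's zero distance to itself is not a pair
and would bias cluster density downward), the off-diagonal entry for (A,B)
is the mean over all |A|·|B| cross pairs. The discrimination value

    Δ(A,B) = d(A,A) + d(B,B) − 2 d(A,B)

is negative for disjoint clusters, positive for overlapping ones, and zero
when all points coincide. With unequal cluster sizes the block means are
plain (unweighted) means; the factor 2 already compensates for there being
one inter-cluster term against two intra-cluster terms. For L > 2 the
global discrimination value is the sum of Δ over all unordered label
pairs; it reduces to the two-cluster value at L = 2, keeps the per-pair
factor-2 balance, and is isolated behind a single function
(`core.global_discrimination`) so an alternative aggregate can be swapped
in. The metric is fixed to Euclidean distance throughout.

Significance is assessed by re-labeling: class-size-preserving label
permutations leave the distance matrix untouched, so the null distribution
of Δ is computed from block means of a fixed matrix. Implementation-wise
the permuted one-hot label matrices are evaluated in batched matrix
products (chunks of 2048 permutations), which makes N = 10⁴ permutations
on M ≈ 200–400 points a sub-second operation. Each chunk's permutations
come from one batched draw of uniform sort keys, so permutation i is a
fixed function of the seed regardless of evaluation order, and results are
bit-identical across runs for a fixed seed.

Two p-value estimators are available:

* `add_one_leq` (default): p = (1 + #{Δᵢ ≤ Δ₀})/(N + 1). This is the
  standard finite-sample permutation estimator; it cannot return 0 and is
  exact-level under exchangeability.
* `paper_literal_strict`: the plain empirical Pr(X < Δ₀) over the sampled
  null. It can return exactly 0 and is kept for replication of analyses
  that report the raw empirical CDF value.

When the number of distinct count-preserving labelings M!/(∏ nₗ!) does not
exceed N, the null is enumerated exhaustively instead of sampled (the
estimators then become exact counts over all labelings, without the +1).
`exhaustive="never"/"always"` force either branch; forcing is mainly
useful for validating the sampler against the enumeration.

The pairwise p-value matrix reports raw mutual p-values by default, which
mirrors standard practice of quoting each pairwise comparison directly; a
Holm–Bonferroni option (`correction="holm"`, via statsmodels) is available
but off by default. Pairwise tests permute labels within the two clusters
being compared only.

## Preprocessing of multichannel recordings

A recording is a channels × time matrix per condition block with a
sampling rate and a condition schedule (half-open [start, end) intervals
in seconds). The pipeline per block:

1. **Onset exclusion** (default 0.2 s): the transient evoked response at
   each stimulus onset is removed once per block, not per window.
2. **Sliding RMS** (default 20 s windows, 5 s steps): per channel, the
   root-mean-square amplitude in each window; windows are closed-open
   sample intervals [t, t + window), only full windows inside the block
   are emitted, and windows never span condition boundaries. A 180 s
   block therefore yields ⌊(180 − 20)/5⌋ + 1 = 33 windows, and a session
   of 8 blocks ≈ 264 state vectors (256 with the 0.2 s exclusion).
   Implemented with cumulative sums of squares, so cost is independent of
   the overlap.
3. **z-score across channels** (default): each state vector is
   standardized across its channels (mean 0, sd 1, population convention).
   This removes activity common to all channels — the component that
   carries overall amplitude rather than spatial pattern. The alternative
   orientation (each channel standardized over time within a block) is
   available via `zscore_mode="channel"` since both readings occur in
   practice; only the across-channel version removes common-mode activity.

Concatenating blocks gives the labeled point set (with per-point
timestamps and block ids for trajectory plots).

## Exchangeability and overlapping windows — known limitation

Windows that overlap by 75 % produce strongly autocorrelated successive
state vectors, while conditions occupy contiguous blocks. The full-shuffle
permutation null assumes exchangeable points, and on *null* data (no
condition information whatsoever) this combination is badly
anticonservative: in our surrogate-null experiments the default pipeline
rejected essentially always at α = 0.05, because within-block
autocorrelation alone makes the observed labeling look "better" than
random re-labelings. Consequences drawn here:

* The default pipeline replicates the established practice (overlapping
  windows, full shuffle) and is appropriate when the question is whether
  a strong pattern effect exists on top of the autocorrelation — but its
  p-values on autocorrelated data should not be read as calibrated.
* `scheme="block_shuffle"` permutes contiguous label blocks as units and
  is the conservative option; at the block lengths matching these window
  overlaps it reduces but does not eliminate the inflation.
* Non-overlapping windows (step = window length) restore calibration: in
  a 100-replicate null experiment the rejection rate at α = 0.05 was
  0.06. The null-calibration tests in this package therefore use
  non-overlapping windows.
* The type-I calibration of the permutation test itself is checked on
  i.i.d. Gaussian clusters, where exchangeability holds exactly.

## Classical MDS (visualization only)

Torgerson scaling: square the distances, double-center, eigendecompose,
keep the `target_dim` largest nonnegative eigenvalues (negative
eigenvalues — non-Euclidean residue — are truncated to zero). Classical
scaling was chosen over SMACOF-style stress majorization because it is
deterministic, has no initialization, and is exact for configurations of
rank ≤ target_dim; "distance preservation" holds only for such low-rank
data, so the relative residual distortion is reported as a stress value.
Reflection indeterminacy is removed by fixing each axis's sign so that its
largest-magnitude coordinate is positive; axes are ordered by descending
eigenvalue. Cluster-centroid ("attractor basin") layouts embed the
proximity off-diagonals as exact centroid distances (diagonal zeroed);
basin disk diameters equal the proximity diagonal exactly. Figures are
written with a fixed SVG hash salt and no date metadata so identical
inputs give identical bytes. Statistics never read anything the MDS
produces.

## Assignment of new points

A query x is tentatively appended to each cluster i; the tentative point
participates in cluster i's intra-cluster distances and all its
inter-cluster distances; the predicted label minimizes the resulting
global discrimination value, and the margin to the runner-up is reported.
The update is incremental — O(M) per candidate from precomputed block
sums — and agrees with full recomputation to 1e-10 (tested). Exact ties
(within 1e-12 relative) are broken by canonical label order with an
explicit warning. At large separation this rule essentially reproduces
nearest-centroid classification (≥ 99 % agreement in tests), which is the
expected geometric behaviour for balanced spherical clusters.

## Synthetic data: what it emulates and what it does not

`make_gaussian_clusters` places k centroids on a regular simplex so all
pairwise centroid distances equal `separation · σ` — a single
interpretable knob; points are i.i.d. Gaussian (spherical σ = 1 by
default, full covariance optional). `separation=0` gives exchangeable
null data. `make_attractor_trajectory` is a discrete mean-reverting walk
toward the active condition's centroid (relaxation rate per step, white
process noise), visiting each attractor twice by default so repeated
visits land in the same basin.

`make_recording` emulates a sustained-stimulation session. Defaults are
the study conditions used throughout the tests: 16 channels at 1 kHz,
180 s blocks, four conditions (silence at modulation depth 0 plus three
stimuli at depth 3, patterns random orthonormal unit vectors over
channels), presented twice each; common-mode amplitude 1, channel noise
sd 1, carrier band 5–45 Hz. Depth 3 was chosen to produce clearly
separated attractors, the regime the method targets. Each block's channel
signals are common_mode(t) + depth · pattern · carrier(t) + white noise;
carrier and common mode are band-limited Gaussian noise drawn fresh per
block (unit RMS), so condition identity lives **only** in the spatial
pattern. The carrier is noise rather than a pure tone so windowed RMS
estimates a stationary amplitude instead of locking to carrier phase.
With `power_matched` (default on) the per-condition channel-noise
variance is adjusted so the expected total power is identical across
conditions — overall amplitude then carries no condition information,
the premise the method is designed around. One second-order caveat:
"overall amplitude" measured as the mean across channels of per-channel
RMS retains a slight sensitivity to how pattern power spreads across
channels (concavity of the square root), so a rank test on that summary
runs marginally above its nominal level (~10 % at α = 0.05 in our
experiments) even though total power is matched exactly.

Not emulated: 1/f spectra, volume conduction, nonstationarity, artifacts,
biophysical forward models. Passing tests on these surrogates show that
the pipeline detects spatial-pattern information under power matching and
stays calibrated under exchangeable nulls; they do not certify behaviour
on real recordings with richer temporal structure.

## Problem sizes and numerical choices

The calibration experiments use 1000 replicates with N = 199 permutations
each (the add-one estimator's granularity 1/200 is exact at α = 0.05) for
the type-I check, N = 10⁴ for single-test p-values (floor 1/(N+1) = 10⁻⁴),
and 100 end-to-end recording replicates with N = 999 (floor 10⁻³, the
level quoted for clearly separated conditions). The z-score uses the
population (ddof = 0) convention. Delimited-text IO writes floats at %.17g
and reads with round-trip float parsing, so point sets survive a
write/read cycle bit-exactly. Degenerate inputs raise typed errors:
clusters with fewer than two members, zero-variance windows, onset
exclusion consuming a whole segment, overlapping schedules, non-finite
coordinates (named by row).
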