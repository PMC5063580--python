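# Methods

## Data model and conventions

All analyses operate on contiguous annual series over a closed study period
`[start_year, end_year]` (`n = end − start + 1` years; the seven-region
western spruce budworm compilation shares 1700–1990, n = 291).  Outbreak
episodes are maximal runs of 1s; durations are inclusive (`end − start +
1`), which is the only convention consistent with a two-year episode
spanning consecutive calendar years such as 1702–1703.  Quiescent gaps are
counted strictly between consecutive episodes (`next.start − prev.end −
1`); margins before the first and after the last episode are not gaps, and
the mean gap is undefined for fewer than two episodes.  Matrix readers trim
leading/trailing missing cells per region (records of unequal length) but
reject internal gaps: every downstream statistic assumes uninterrupted
annual coverage.

Stand-to-region conversion labels a year a regional outbreak year iff it
belongs to a run of at least `min_run = 2` consecutive years in which at
least `threshold = 40%` of the region's sampled trees record outbreak
conditions, with tree-weighted pooling across sites (summed outbreak trees
over summed sampled trees, not a mean of site fractions).  The threshold is
a weak inequality applied to the pooled series; whether the original
reconstructions applied it before or after pooling is not documented, so
pooling-first is this package's documented choice.

## Synchronous periods

A synchronous period is a maximal run of years in which at least
`min_regions = 3` regions are simultaneously in outbreak, discarded if
shorter than `min_run = 2` years.  `max_bridge` (default 0) optionally
merges runs separated by that many sub-threshold years, counting bridge
years inside the merged span; it exists because published period tables of
this kind can contain a small number of bridged years, but no merging is
performed unless requested.  Participants are the regions with at least one
outbreak year anywhere in the (merged) span.  Periods touching the study
boundary are flagged truncated rather than dropped.

## One-dimensional multivariate Ripley's K

For event sets `a`, `b` (outbreak years, episode initiations, or episode
cessations) the bivariate estimator is

    K̂_ab(t) = n / (n_a · n_b) · #{(u, v) ∈ a × b : |u − v| ≤ t},

with symmetric inclusive windows (t = 0 means same-year co-occurrence), and
the pooled estimator sums pair counts and `n_i n_j` over all ordered region
pairs.  Pair counts are computed from lagged cross-products of event
indicator vectors (a length-2n−1 convolution per pair), which is exactly
the brute-force double loop; the test suite asserts equality against that
loop on random instances.

Under temporal independence a discrete window of `2t + 1` years gives
`E[K̂(t)] ≈ 2t + 1`, so the affine standardization `L(t) = (K̂(t) − (2t +
1)) / 2` has expectation ≈ 0 with positive values indicating synchrony.
Any affine transform applied identically to observed and surrogate K leaves
the envelope decision unchanged, so the choice is presentational.

**No analytic edge correction is applied.**  Observed and surrogate
statistics are computed on the same finite record, so the finite-window
bias is common to both and cancels in the envelope comparison; classical
1-D K implementations offer explicit corrections, which matter only when K
is interpreted against its analytic expectation rather than a
randomization band.

**Circular-shift null.**  Each surrogate independently rotates every
region's full binary record by a uniform offset in `{1, …, n−1}` with
wraparound (offset 0 excluded so no surrogate equals the observed
arrangement), then re-extracts events.  Rotation preserves each region's
episode count and duration multiset up to one episode possibly split at the
wrap seam — re-extracting events after rotating the binary record, rather
than rotating event lists, is deliberate: the rotated record is the
surrogate observable.  The envelope is the per-window empirical (α/2, 1 −
α/2) percentile band of surrogate L over `n_sim = 1000` draws (α = 0.05);
windows where observed L falls outside are flagged.  With 26 windows per
analysis this is a pointwise, not simultaneous, test — calibrated at ≈ 5%
per window on unforced synthetic scenarios (measured 4.9–5.1% at n_sim =
200 over 200 replicates).

## Similarity, distance decay, Mantel

Outbreak similarity is the simple matching fraction `(a + b) / n` (joint
presences plus joint absences over years); the index is sometimes labelled
"Jaccard" in the source literature, but the formula used and printed there
includes joint absences, and that formula is what is implemented.  Climate
similarity is `−(1/n) Σ_t |x_t − y_t|` (≤ 0, zero iff identical): the
negated mean annual distance in one-dimensional climate space.  Distances
are centroid-to-centroid Euclidean km on the projected plane.

Distance-decay regressions are ordinary least squares of upper-triangle
similarity on distance.  The Mantel statistic is the Pearson correlation
over upper triangles; its null distribution comes from simultaneous
row/column relabelings of one matrix, with the identity permutation
included in numerator and denominator, so `p ∈ [1/(n_perm + 1), 1]`.  The
default test is two-tailed on |r|; a one-tailed option exists for
directional hypotheses (and is the appropriate choice when the question is
specifically whether outbreak similarity *increases* with climate
similarity).  The partial Mantel residualizes both matrices on the control
matrix over upper triangles and permutes the residualized first matrix,
reassembled as a symmetric matrix, by relabeling.  With only 4 regions the
24 possible relabelings can be enumerated; the test suite checks the Monte
Carlo p against that enumeration.  A control matrix that explains the
second matrix exactly leaves nothing to correlate; this degenerate case
returns r = 0, p = 1 explicitly.

## Superposed epoch analysis

Anomalies are index values minus the full-period mean (no detrending or
windowed baseline: the reference is the long-term average).  The composite
at lag ℓ is the mean anomaly at `event_year + ℓ` over events, using only
lags that fall inside the period (an event near the boundary contributes
its in-period lags; a strict mode that rejects such events is available).
The null draws `n_boot = 1000` sets of as many random years, uniformly
without replacement within a draw, composited identically; a lag is
significant outside the (α/2, 1 − α/2) percentiles.  Uniform resampling is
a deliberate, simple choice — it tests "are these event years special"
against "any years", not against a phase-randomized climate.  For
cessation analyses only lags ≤ 0 are scientifically interpretable (later
climate cannot cause an earlier collapse); the pipeline reports all lags
and leaves the restriction to the reader.

Group contrasts use Welch's unequal-variance t with Welch–Satterthwaite
degrees of freedom, two-tailed.  Pre-initiation years are the union of the
five years before each period start, clipped to the study period and
deduplicated; pre-initiation years that fall inside another synchronous
period are kept in the pre-initiation group by default (switchable), since
excluding them changes the question from "years before starts" to "years
before starts that were otherwise quiet".

## Synthetic scenarios

The generator emulates the statistical structure the analysis assumes, not
budworm biology.

**Climate.**  Per-year draws from a zero-mean multivariate normal with
correlation `exp(−d_ij / λ)`; for `dipole > 0` the cross-group
(northwest/southwest) correlations are multiplied by `1 − 2·dipole`
(dipole 1 negates them; any value in [0, 1] keeps the matrix positive
definite because the result is a convex combination of the base matrix and
its sign-flipped similarity transform).  Optional AR(1) persistence with
the marginal variance held fixed.  Years are otherwise independent.

**Outbreaks.**  Per region, a two-state renewal process.  Episode lengths
are negative binomial (a sum of `duration_shape` geometric stages, support
≥ `duration_shape` years) with the configured mean; shape 1 is the
memoryless geometric regime.  In quiescence, the initiation probability in
year t is proportional to `exp(β · trigger_t)`, where `trigger_t =
max(0, −mean(climate[t−k..t−1]))` when the current year's climate is ≥ 0
and 0 otherwise — a drought-then-release signal whose weight grows with
the severity of the preceding drought.  The weights are normalized (by a
bisection that accounts for the cap at probability 1) so the *marginal*
initiation rate equals `1 / mean_quiescent` at every β: forcing
redistributes initiations into shared severe-drought-release years without
changing the calibrated mean gap.  A region cannot re-initiate in the year
immediately after an episode ends, which keeps episodes maximal runs and
makes the mean gap exactly `mean_quiescent`.  Each region runs through a
300-year unforced burn-in before the study period so regions enter it in
independent stationary phases; without this, the shared all-quiescent
initial condition itself synchronizes early episodes and inflates the
envelope's null flag rate.

**Seven-region preset** (`paper_layout`).  Regions on a ~2,000 km
north–south transect (five northwestern, two southwestern), 291 years,
per-region mean durations (7.8–28.7 yr) and quiescent gaps (8.8–28.3 yr)
taken from the published per-region reconstruction summaries, climate sd
2.0 index units.  The remaining defaults define the deliberately *strong*
Moran-forcing regime used as the positive control: β = 8, λ = 5,000 km,
full dipole, AR(1) = 0.6, duration shape 5, and a k = 5 drought-memory
window (matching the five-pre-initiation-years contrast).  Under these
conditions the scenario reproduces the published regime's gross structure
(≈ 14 synchronous periods; ≈ 55–65% of years with ≥ 3 regions in outbreak)
while making the synchrony statistics reliably detectable: zero-window
initiation clustering is flagged in ~100% of replicates, and the one-tailed
partial Mantel of outbreak vs climate similarity controlling distance is
significant in ~98%.  `beta = 0` with the same layout is the null
scenario: regions independent of climate and of each other.  The SEA
positive control uses the `dipole = 0` variant, because with a full dipole
the all-region index averages opposite-signed north/south anomalies at
initiation and dilutes the composite; the dipole-free variant isolates the
SEA contract itself.

**What the generator does not emulate:** observation lag between
defoliation and ring-width response (reconstructed dates can trail true
population events by 1–3 years), spatially varying climate variance and
seasonality, non-stationarity (e.g. land-use-driven changes in outbreak
frequency), dispersal, and trophic interactions.  Passing tests therefore
demonstrate that the statistics detect (and correctly fail to detect)
Moran-type climate forcing in a well-specified renewal world — not that the
real records satisfy these assumptions.

## Numerical choices and degenerate inputs

- Percentiles use NumPy's linear-interpolation empirical quantiles; with
  the observed statistic exchangeable among surrogates this yields a
  per-window flag rate slightly above α/ties may pull it below — measured
  ≈ 5% at n_sim = 200.
- Permutation tie comparisons use a 1e-12 slack so the identity permutation
  always counts as at least as extreme as itself.
- Constant similarity vectors make the decay regression's R² a 0/0; the
  package defines it as 0 (distance explains nothing).
- Zero-variance upper triangles are an error for Mantel; a control matrix
  that reproduces the comparison matrix exactly short-circuits the partial
  Mantel to r = 0, p = 1.
- Welch's t on two zero-variance samples errors unless the means are equal
  (then t = 0, p = 1).
- All stochastic routines take explicit seeds and are bit-reproducible for
  a fixed seed; the pipeline derives all stage seeds from one run seed.
- CSV round-trips use full-precision float repr and round-trip parsing, so
  write-then-read reproduces values exactly.

## Problem sizes

Default analysis sizes follow the compiled-record setting: n = 291 years, 7
regions, t_max = 25 windows, 1,000 circular surrogates, 10,000 Mantel
permutations, 1,000 SEA Monte-Carlo draws.  Calibration and power checks in
the test suite use 100–200 scenario replicates with 200 surrogates and
1,000–2,000 permutations per replicate, sizes at which the binomial error
of the measured rates is comfortably inside the asserted bands.

## Known limitations

- The envelope test is pointwise per window; no family-wise correction
  across the 26 windows is attempted (matching standard practice for
  randomization envelopes, but worth remembering when reading flags at
  many windows).
- The partial Mantel's residual-permutation scheme is the classical one;
  its type-I behaviour is known to degrade with very strong confounding
  structure and tiny region counts.
- The per-region published summary statistics (episode counts, durations,
  gaps) are encoded as reference calibration values; the underlying annual
  records are not public, so region-level results cannot be recomputed,
  only emulated.
- Climate forcing acts on initiation only; episode lengths are
  climate-independent, so the generator cannot produce climate-driven
  synchronous collapses (deliberately: collapse synchrony is not part of
  the tested hypothesis set).
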