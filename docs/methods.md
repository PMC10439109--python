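# Methods

## Model

Two MS/MS spectra are compared by spectral cosine similarity: fragments
are matched across spectra within an m/z tolerance, and the score is the
dot product of the two unit-normalized intensity vectors restricted to
matched fragments. `blink` computes this quantity — plus the number of
matching ions — for all query × reference pairs simultaneously.

Each spectrum set becomes a pair of sparse matrices over integer m/z bins
(rows) × spectra (columns): one holds normalized fragment intensities, the
other fragment counts (ones). Fragment m/z is floor-binned,
`bin = floor(mz / bin_width)`, with a relative epsilon of 1e-9 inside the
floor so values intended as exact multiples of the bin width land in the
upper bin deterministically. One side is then blurred: each occupied bin
is copied across a uniform window of `2h + 1` bins, where the kernel
half-width is

    h = round(tolerance / bin_width) − 1.

Scores are `Qᵀ·R` over intensities and matching-ion counts are `Qᵀ·R` over
counts (rounded to the nearest integer to guard float drift; they are
integral in exact arithmetic under the ones-kernel). Two fragments are
linked exactly when their bins differ by at most `h`, which gives the
effective-tolerance identity: pairs closer than `h · bin_width =
tolerance − bin_width` are always linked, pairs further apart than
`tolerance` never are, and pairs in the band in between link or not
depending on bin phase. Floor binning (rather than rounding) is what makes
this identity exact; at the defaults (0.01 / 0.001 Da) the method is
equivalent to a 0.009 Da alignment tolerance.

The kernel is symmetric, so which side is blurred does not change the
result; the library blurs the side with fewer stored fragments (cheaper)
and transposes if needed. Bin width may equal the tolerance (the kernel
degenerates to the identity, effective tolerance 0) but may not exceed it.

### Deviation from alignment-based scoring

A loop-based aligned cosine (the `oracle` module: enumerate in-tolerance
fragment pairs, sort by intensity product descending — ties by smaller
Δm/z, then lower query index — and accept greedily with each fragment used
once) selects at most one partner per fragment. The blur-and-link score
instead sums **every** in-tolerance product, so it is never lower than the
greedy score (one-sided deviation) and exceeds it exactly when several
fragments of one spectrum fall within tolerance of one fragment of the
other. When all within-spectrum fragment spacings exceed the tolerance and
all cross-spectrum distances avoid the ambiguous band, the two scores are
identical. The practical remedy for workflows requiring exact conventional
scores is `rescore_hits`: recompute only the thresholded hit list with the
aligned cosine (run at `tolerance − bin_width`) and re-filter.

## Preprocessing

Fixed order: noise filter → square-root scaling → unit normalization
(normalization must come last or scores change scale). The filter removes
fragments strictly below 1 % of the base peak (a fragment at exactly 1 %
is kept), fragments with m/z strictly above the precursor (one exactly at
the precursor is kept), and zero-intensity fragments. Spectra left empty
are dropped from the set with their ids logged rather than scored as zero
vectors. Defaults: `base_peak_fraction = 0.01`, `apply_sqrt = true`,
`remove_above_precursor = true`.

## Analog search

`discretize` can shift the bin coordinate: `precursor` mode bins
`precursor_mz − mz` (neutral-loss coordinate) on both sets, so homologs
whose fragments and precursor share a constant offset align; `fixed` mode
bins `mz + delta` on the query side only. The sign convention for the
precursor shift is a design choice of this package — the neutral-loss form
was chosen because it makes equal losses align across different
precursors, and the fixed-delta mode covers any other convention.
`analog_score_all` returns the regular and shifted results plus a combined
matrix taking the element-wise maximum score (ties favor the regular
channel, whose match count is then reported); both raw matrices are
returned so other combination rules can be applied downstream.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `bin_width` | 0.001 Da | discretization step; guaranteed tolerance is `tolerance − bin_width` |
| `tolerance` | 0.01 Da | kernel window; must be ≥ bin_width |
| `base_peak_fraction` | 0.01 | noise floor relative to the base peak |
| `min_score` | 0.7 | similarity-call threshold on the cosine (inclusive) |
| `min_matches` | 6 | similarity-call threshold on matching ions (inclusive) |

## Numerical choices

- Floor binning with a 1e-9 relative epsilon (see above); validated
  against exact rational arithmetic in the tests.
- Matrices are stored as COO triplets with int64 *global* bin coordinates
  instead of 2-D sparse matrices spanning the whole bin space: at
  bin width 1e-6 the bin space has ~2×10⁹ rows and a CSR index alone
  would need ~16 GB. Scoring intersects the occupied-bin sets of the two
  operands first (only shared bins contribute to the product) and builds
  compact CSR matrices for the multiplication — mathematically identical
  to padding both matrices to a common row count and multiplying.
- Hit lists are written in TSV sorted by descending score, ties broken by
  (query_id, ref_id), with scores at 9 decimal places, making repeated
  runs byte-identical.

## Synthetic data

`random_library` emulates high-resolution centroided spectra: fragment
m/z uniform over 50–2000 Da, intensities exponential with mean 100 (a
heavy-tailed stand-in for real fragment-intensity distributions; the
validation properties are distribution-free, so the exact law is not
critical), precursor a uniform 5–50 Da margin above the largest fragment.
Two structural controls matter for validation:

- `min_spacing` enforces within-spectrum fragment separation; above twice
  the tolerance it removes the multi-link mechanism, so fast and precise
  scores must coincide.
- `grid_spacing` locks fragments onto a coarse global grid (0.05 Da in
  the validation suites), so cross-spectrum distances are either within
  the jitter (≤ tolerance − bin_width) or at least one grid step (> the
  tolerance) — never inside the ambiguous band.

`perturb_pair` derives a partner keeping `ceil(shared_fraction · n)`
fragments (uniform m/z jitter, lognormal intensity noise), replacing the
rest with fresh fragments outside an exclusion radius of the originals,
and optionally mass-shifting everything for analog tests.

What the generator does *not* emulate: chemically realistic fragmentation,
isotope patterns, adducts, correlated noise, or the precursor-mass
clustering of real libraries. Passing validation therefore demonstrates
the algebraic correctness and tolerance behavior of the scorer, not
identification performance on real data.

## Validation problem sizes

The test suite validates exact oracle equivalence on 200 × 200
grid-locked spectra (40,000 pairs, 100 % required at |Δscore| < 1e-9 with
identical match counts), an agreement rate of ≥ 99 % (score within 0.001,
identical matches) on 1,000 × 1,000 unconstrained spectra with 200
planted related pairs whose jitter spans the ambiguous band, monotonicity
sweeps (score non-decreasing in tolerance; oracle agreement
non-increasing in bin width from 1e-6 to 0.01 Da, evaluated in chunks to
bound blur memory at the smallest widths), brute-force linkage bounds
over 1e5 random fragment pairs, and the rescoring path on both regimes.
The aligned cosine is additionally cross-checked against an independent
greedy-pairing implementation (matchms) on 1,000 random pairs at 1e-6
agreement.

## Known limitations

- Tolerances are absolute (Da); ppm-relative tolerance is out of scope.
- The blurred count matrix approximates matching-ion counts: it counts
  all in-tolerance fragment pairs, so counts (like scores) can exceed the
  greedy-alignment values and are not capped at
  `min(n_frag_query, n_frag_ref)`.
- Wide tolerance windows (low-resolution instruments) inflate the
  deviation from alignment-based scores; loop-based scoring or hit
  rescoring is more appropriate there.
- Dense result matrices are materialized, so very large query × reference
  products should be processed in chunks by the caller.
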