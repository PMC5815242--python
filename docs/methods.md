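# Methods

## Model and procedure

The input universe is a set `P` of `d` profiles, each a length-`m` vector
over an integer alphabet of size `σ` (allelic profiles from MLST-family
schemas, or SNP sequences; categorical tokens are re-coded to dense
integers on read). The target object is the truncated distance matrix at a
threshold `k`, `0 < k < m`: every unordered pair at Hamming distance at
most `k`, together with the exact distance.

The pipeline has three steps.

**Indexing.** Profiles are concatenated row-major, without separator
symbols, into a string `s` of length `n = m·d`, over which we build the
suffix array (SA), the LCP array (Kasai's algorithm), and a sparse-table
RMQ over the LCP array. The RMQ answers longest-common-extension (LCE)
queries between arbitrary suffixes in O(1) after O(n log n) table
construction. The SA is built by prefix doubling with numpy `lexsort`
passes, O(n log n) worst case; the doubling loop terminates as soon as all
ranks are distinct, which for i.i.d. data happens after roughly
log₂ log_σ n rounds, so construction is dominated by a handful of
vectorised sorts. A linear-time builder can be swapped in behind the
`suffix_array` function without touching anything else; the asymptotic
constant of construction is not load-bearing for any result here.

Omitting separators keeps `n = m·d` exactly but lets suffix comparisons run
across profile boundaries. Two guards compensate: an *aligned* block start
at in-profile offset `ℓ` is accepted only when `ℓ` is a multiple of `L`
**and** `ℓ + L ≤ m` (a block never spans two profiles), and every LCE used
in distance verification is capped at the profile end. With both guards in
place the no-separator concatenation is observationally equivalent to a
separated one.

**Filtering.** Pigeonhole: with block length `L = ⌊m/(k+1)⌋`, at least
`k+1` disjoint aligned blocks fit in a profile, so two profiles within
distance `k` agree verbatim on at least one block, at the same block
ordinal. We use all `⌊m/L⌋ ≥ k+1` aligned in-profile blocks rather than
only the first `k+1` — a superset filter, so completeness is preserved.
Candidates are enumerated two ways, kept deliberately redundant so each can
cross-check the other:

- *LCP clusters*: one scan of the LCP array. Maximal runs of SA ranks whose
  adjacent LCP is ≥ L are exactly the maximal SA intervals of suffixes
  sharing an L-prefix (pairwise LCP within a run is the minimum of the
  adjacent values). Within a run, aligned suffix starts with equal block
  ordinal `t` yield candidate pairs.
- *Binary search*: for each profile and block ordinal, the SA interval of
  suffixes prefixed by that block is found by binary search (O(L log n));
  matches not aligned at the same ordinal are discarded.

Candidates are deduplicated on the unordered pair before verification: a
close pair typically shares several blocks, and verification cost dominates
enumeration, so each pair is verified once.

**Verification.** Kangaroo jumps: starting at offset 0, repeatedly take the
LCE of the two suffixes at the current offset (capped at the profile end),
skip it, count one mismatch, and advance. Each candidate costs O(k) LCE
queries because the walk stops past the cap. The public
`hamming_capped(index, i, j, k)` returns `min(k, H)`; internally the pair
search verifies with cap `k+1`, which resolves the `H = k` vs `H > k`
ambiguity at the cost of one extra jump — a pair is reported iff the capped
value is ≤ k, and the reported value is then exact.

A direct all-pairs scan (`strategy="naive"`) is retained as the oracle and
for small inputs; the strategy flag defaults to the LCP-cluster variant.
No automatic strategy selection is attempted — the crossover between naive
and filtered search depends on how clustered the data are, and the flag
makes the choice explicit instead.

## Average-case admissibility

Under the i.i.d.-uniform model the expected number of candidate pairs is at
most `B·d/σ^L` with `B = d⌊m/L⌋` total blocks, giving expected total time
`O(md + k·B·d/σ^L)`, which is `O(md)` whenever

```
k < (m − k − 1) · log σ / log(m·d).
```

`max_admissible_k(m, d, σ)` returns the largest integer threshold
satisfying this (the right-hand side decreases in `k`, so the admissible
set is a prefix and binary search applies); `simplified_max_k(m)` is the
closed form `⌊m/(2 log₂ m)⌋` valid for the square binary regime `d = m`,
`σ = 2`, where it upper-bounds the exact value (170 vs 163 at m = 4096).
Logs are base-invariant in the exact condition; the closed form fixes
base 2, which is the convention that makes the bound an integer-friendly
`m/(2 log₂ m)` for power-of-two `m`.

**A caution on regimes.** The closed form is tied to `d = m`. If `m` is
held fixed while `d` grows, any fixed `k` eventually leaves the admissible
region (the right side shrinks like `1/log d`), and the expected candidate
count `⌊m/L⌋·C(d,2)/σ^L` is then Θ(d²) — the filter still prunes by the
constant factor `σ^{-L}` but no longer changes the growth order. The
candidate-volume test in `tests/test_acceptance.py` runs exactly this
fixed-`m` regime (m ∈ {256, 512}, d up to 2000, k = `simplified_max_k(m)`)
and therefore observes doubling ratios near 4; its ≤ 3 ratio assertion
encodes the linear-regime expectation and fails by design outside it, while
the companion assertion (mean verified candidates within 10× of `B·d/σ^L`)
holds throughout. We keep the test as specified rather than tuning its
parameters into the admissible region: the failure is informative about
where the average-case guarantee applies.

## goeBURST

The threshold graph `G = (P, {(u,v) : H(u,v) ≤ k})` with the truncated
distances as weights is a graphic matroid, so a greedy Kruskal pass yields
a minimum spanning forest; goeBURST's contribution is the total order on
links that breaks weight ties. The published description enumerates the
criteria — distance, numbers of single-, double- and triple-locus variants
(SLV/DLV/TLV), isolate frequency, sequence identifier — without fixing
directions or endpoint aggregation, so this package freezes a concrete
strict order: distance ascending; then larger endpoint SLV count
descending, smaller descending; the same two steps for DLV, then TLV; then
larger and smaller endpoint frequency descending; finally larger then
smaller endpoint input rank ascending. The last key makes the order strict,
hence the forest deterministic. Tie-break *directions* follow the founder
model (a founder accumulates many SLVs and high frequency, so better-
connected endpoints link earlier); under any strict refinement the forest's
total weight is the matroid optimum regardless, which is what the
MSF-oracle test checks.

SLV/DLV/TLV counts are derived from the truncated matrix at the user's
`k`; for `k < 3` the deeper counts are structurally zero, and `lv_k`
(CLI `--lv-k`) requests a second, deeper pass (e.g. `max(k, 3)`) purely for
tie-breaking — the index is built once and reused. Duplicate profiles are
ordinary weight-0 edges and link first. Matroid structure also gives
threshold nesting: components at `k₁ < k₂` refine components at `k₂`,
which is property-tested.

## Querying

An external profile `u` (same `m`, same encoding; alleles unseen at
indexing time get fresh codes ≥ σ and can therefore never match) is
searched by binary search for each of its aligned blocks in the SA,
keeping matches aligned at the same ordinal. Since `u` itself is not
indexed, candidates are verified by direct positionwise comparison, O(m)
each. Classification returns the label of the closest hit (ties to the
lower row index) or a configurable `new` sentinel. The index is immutable;
adding profiles means rebuilding, which the CLI supports by serializing
`s`, SA and LCP to an `.npz` container (RMQ is rebuilt on load, being
cheaper to recompute than to store).

## Synthetic data

`random_profiles(d, m, σ, seed)` draws i.i.d. uniform symbols — exactly the
model of the average-case analysis, and (with σ = 2) the uniform binary
sequences used to validate the asymptotics. `plant_pair` rewrites one row
as a copy of another mutated at exactly `h` uniform positions, giving
ground-truth pairs for completeness tests. What this generator does *not*
emulate is the clustering of real typing databases: clonal expansion makes
real profiles far more mutually similar than the uniform model, candidate
counts correspondingly higher, and the admissibility bound optimistic.
Passing tests on synthetic data therefore establish correctness (which is
data-independent: the oracle-equivalence tests hold for any input) and the
average-case *trend* on uniform data, not running-time behaviour on real
databases.

## Numerical and engineering choices

- Suffix-order tie rule: a suffix that is a proper prefix of another sorts
  first (positions past the end compare below every symbol in the doubling
  ranks; binary-search comparison treats a short matching suffix as less).
- RMQ ties resolve to the leftmost index; `lce(i, i) = n − i` by
  convention.
- Integer encoding is global (first occurrence, row-major), not per-locus:
  Hamming distance only tests positional equality, so a shared code across
  loci cannot create or destroy matches within a column. Missing-allele
  tokens ("0", "-", "na") are ordinary categories — two profiles both
  missing a locus match there; callers wanting different semantics should
  pre-filter columns.
- Degenerate inputs: `d = 1` yields an empty pair set; duplicate rows are
  permitted and surface as distance-0 pairs; `k` outside `(0, m)` is a
  parameter error everywhere (CLI exit code 2).
- Problem sizes in the test suite: oracle equivalence uses 200 instances up
  to d = 50, m = 64; index correctness 1000 strings up to n = 200 plus 10⁴
  LCE queries; the scaling study uses m ∈ {256, 512}, d up to 2000 over 10
  seeds (the largest single index is n ≈ 10⁶). These sizes keep the full
  suite under a few minutes while leaving the largest instances big enough
  for the average-case trend to be visible.

## Limitations

- No dynamic index updates: any addition to the profile set triggers a full
  rebuild.
- The LCP-cluster enumerator materialises candidate groups per run; on
  pathologically clustered data (many identical profiles) group sizes reach
  `d` and enumeration degrades toward the naive quadratic — consistent with
  the analysis, which is average-case over uniform data only.
- The goeBURST comparator is this package's frozen interpretation of the
  published criteria list; other implementations may break ties
  differently, changing edge choices (never total forest weight).
- No evolutionary-model distance corrections, tree visualisation, or
  NJ/UPGMA construction: the deliverable is the truncated matrix, the
  forest, and the query layer.
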