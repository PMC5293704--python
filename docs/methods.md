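# Methods

## The database fingerprint

A library of *n* molecules, each represented by a length-*L* binary
fingerprint, is reduced to its per-bit probability profile
*p*ᵢ = cᵢ/*n*, where cᵢ counts the molecules setting bit *i*. No
smoothing or pseudocounts are applied: the profile is the plain
empirical frequency, and all downstream quantities are exact functions
of it. Consequently the DFP is invariant to duplicating the library
(it depends on probabilities, not on *n*) and reduces to the molecule's
own fingerprint for a single-molecule library.

The DFP at threshold *t* is the indicator vector [*p*ᵢ > *t*]. The
inequality is strict: a bit whose probability equals the threshold
exactly is set to 0. Because the rule is a pointwise threshold, DFP
support is monotone in *t* — raising the threshold can only clear bits,
never set new ones — and the popcount is non-increasing in *t*.
Thresholds ≥ 1 are rejected rather than silently producing the all-zero
vector, which carries no information and almost certainly indicates a
user error. *t* = 0 is allowed (the DFP becomes the support of the
profile).

### Threshold strategies

- **fixed** (default *t* = 0.5): the conventional cutoff for the
  881-bit PubChem workflow; higher cutoffs discard informative bits and
  reduce the resolution between libraries.
- **random_reference_mean**: *t* is the grand mean per-bit probability
  of a freshly generated random reference (defaults: 1500 vectors,
  Bernoulli(0.5) bits, the scheme's length). For fair bits this
  concentrates tightly around 0.5 (standard error
  0.5/√(1500·L) ≈ 0.001 at L = 166); the seed makes it exactly
  reproducible. A physical random source would not be reproducible,
  which is why a seeded PCG64 generator is used instead.
- **mean_plus_sd**: the library's mean bit probability plus one
  *sample* standard deviation over the L bit positions (denominator
  L−1; the population/sample choice is a convention, made explicit
  here), clipped into [0, 1) so it remains a usable strict threshold.
  Needs L ≥ 2.

## Entropy metrics

Per-bit Shannon entropy uses base-2 logarithms (units: bits) with the
standard convention 0·log₂0 = 0. Two variants are exposed:

- **binary** (default): H(p) = −p log₂ p − (1−p) log₂(1−p), the entropy
  of the Bernoulli bit. Bounded by 1 per position, maximal at p = 0.5,
  symmetric under p ↔ 1−p; the total over L bits lies in [0, L] and is
  0 iff every p ∈ {0, 1}.
- **ones_term**: −p log₂ p only. Bounded by log₂(e)/e ≈ 0.5307 per
  position, maximal at p = 1/e. Included because library SE totals are
  conventionally reported on this halved scale (a 166-bit random
  library totals ≈ 83 rather than ≈ 166); both variants clear the
  random-reference calibration bound of 80.

The total SE of a library is a diversity metric: random-like bit usage
maximizes it, homogeneous libraries drive it toward 0. The relationship
with mean pairwise Tanimoto similarity is inverse but not linear, and
it is a population-level summary — pairwise structure (e.g. two distinct
tight clusters) can depress similarity without raising SE much, so SE
complements rather than replaces pairwise analysis.

### Differential Shannon entropy

For two libraries a, b with profiles p_a, p_b, the per-bit DSE is

  DSE_i = H(pooled_i) − (H(p_{a,i}) + H(p_{b,i})) / 2,

with binary-mode H. Two pooling weightings are provided:

- **size_weighted** (default): pooled_i = (c_{a,i}+c_{b,i})/(n_a+n_b),
  the profile of the concatenated libraries. Faithful to the data, but
  a large library dominates the pool and DSE can be (slightly) negative
  when sizes differ.
- **equal**: pooled_i = (p_{a,i}+p_{b,i})/2, weighting both libraries
  equally regardless of size. By concavity of H this is ≥ the average
  of the component entropies, so DSE ≥ 0 bitwise (Jensen). Equal
  weighting is implemented as exact probability averaging rather than
  by subsampling the larger library to the smaller size: averaging is
  the deterministic limit of that subsampling, requires no access to
  the raw rows, and keeps the non-negativity guarantee without
  introducing a sampling seed.

DSE is 0 exactly where the two profiles agree and reaches 1 bit for a
position fully set in one library and fully clear in the other (equal
weighting); it is the discrimination signal behind significant-bit
selection.

## Similarity and distance

Tanimoto similarity |a∧b|/|a∨b| and city-block distance Σ|aᵢ−bᵢ|
(identical to Hamming distance on binary vectors) are the two
comparison primitives. Tanimoto of two all-zero vectors is defined as
0, the dominant fingerprint-toolkit convention; the alternative (1)
would report perfect similarity for featureless inputs. City-block is a
true metric; the DFP-vs-DFP inter-library matrix uses it by default,
with 1 − Tanimoto as a secondary option. Internally all pairwise
computations are popcount/matrix-product accelerated; the test suite
pins them against naive per-bit loops.

Intra-library similarity is summarized two ways:

- **pairwise**: exact mean/SD over all n(n−1)/2 pairs up to
  `max_exact_n` = 3000 molecules (≈ 4.5 M pairs, well within memory);
  beyond that, the mean is estimated from `sample_pairs` = 100,000
  uniformly drawn distinct pairs with a recorded seed, and the result
  is flagged as sampled. The sampling standard error is available from
  the reported SD.
- **vs-DFP**: mean Tanimoto of every molecule against the library's
  own DFP — a linear-cost proxy for the quadratic pairwise mean. On a
  ladder of libraries of increasing homogeneity the two move together
  (rank correlation 1 in the test suite), which is the property that
  makes the DFP a usable stand-in for full pairwise analysis.

## Significant-bit selection

Across several libraries, three explicit rules select the
informationally significant bit positions:

- **union_of_dfps** (default): a bit is kept iff it survives at least
  one library's DFP at the given threshold. Fully determined by the
  thresholding rule; the selection shrinks (weakly) as the threshold
  rises.
- **pooled_entropy_cutoff**: binary entropy of the size-weighted pooled
  profile ≥ cutoff — keeps bits that are globally informative.
- **dse_cutoff**: maximum pairwise equal-weighted DSE over all library
  pairs ≥ cutoff — keeps bits that discriminate between at least one
  pair of libraries. (Pairwise maximum was chosen over pooled-vs-each
  alternatives as the most sensitive of the defensible variants; the
  choice is a flag, not a constant.)

The entropy/DSE rules can additionally be intersected with the DFP
union (`combine_with_dfp`). Since DSE ≥ 0 everywhere under equal
weighting, a cutoff of exactly 0 selects every bit; use a small
positive cutoff to select strictly discriminating positions.

## Library summaries and k-means

Each library is mapped to a point (mean per-bit binary entropy, mean
vs-DFP Tanimoto), optionally restricted to a bit selection — restriction
changes the columns analyzed, never the library size. Libraries are
grouped by k-means (default k = 5, a flag) on these two axes. Both axes
are z-scored by default so entropy and similarity contribute on
comparable scales; centroids and inertia are then reported in the
standardized space. Clustering is Lloyd's algorithm with seeded random
initialization and the best inertia over 10 restarts (scikit-learn's
`KMeans` with `algorithm="lloyd"`, `init="random"`), giving bit-exact
determinism for a fixed seed. Expect the random reference in the
high-entropy/low-similarity corner and near-clonal libraries in the
opposite corner.

## Synthetic data

Generators are pure functions of (parameters, seed) using NumPy's PCG64
(`default_rng`), so outputs are identical across runs and platforms.

- **Random reference**: n × L independent Bernoulli(p) bits; defaults
  n = 1500, L = 166, p = 0.5. This is the calibration object: its total
  ones-term SE is ≈ 83 (> 80) and its exact mean pairwise Tanimoto is
  ≈ 1/3 — the expected value for independent fair bits, since
  E|a∧b| = L/4 and E|a∨b| = 3L/4.
- **Profiled libraries**: independent bits following a target per-bit
  profile, plus optional disjoint correlated blocks. Within a block,
  each bit copies a shared per-molecule latent uniform with probability
  √ρ (otherwise using its own draw), which yields pairwise within-block
  correlation ρ for equal-probability bits while preserving every
  marginal exactly. Empirical profiles converge to the target (max
  deviation < 0.03 at n = 10,000 in the tests).
- **Homogeneity ladder**: k levels whose profiles are drawn uniformly
  from [0.5−d, 0.5+d] with d rising linearly from 0 to 0.4. Level 0
  matches the random reference statistically; increasing d pushes bit
  probabilities toward 0/1, monotonically raising mean pairwise
  Tanimoto (analytically, E[p²]/E[2p−p²] = (¼+d²/3)/(¾−d²/3)) and
  lowering total SE. Ladder defaults (3 levels × 500 molecules) keep
  the trend tests comfortably significant at negligible cost.

What the generators do **not** emulate: real MACCS/PubChem bit
marginals (which are far from exchangeable), scaffold-driven
correlation structure beyond simple blocks, and bit-bit dependencies
induced by substructure nesting. Passing trend tests therefore
demonstrate the *directional* entropy/similarity relationships and the
correctness of the computations, not quantitative agreement with any
real compound collection.

## Numerical and interface conventions

- Entropies in bits (log base 2) everywhere; 0·log 0 = 0 handled
  explicitly, no epsilons added to probabilities.
- Strict inequality at the DFP threshold; ties go to 0.
- Sample SD (ddof = 1) for similarity summaries and the mean+SD
  threshold; population SD (ddof = 0) for k-means axis standardization
  (a fixed transform, not an estimate).
- FPS v1 hex records are little-endian within bytes (bit k in byte
  k≫3, mask 1≪(k&7)); set pad bits beyond `num_bits` are rejected on
  read. MACCS key k (1-based, backend position 0 unused) maps to
  column k−1, so stored vectors have exactly 166 columns.
- Unparseable structures are skipped with a logged warning instead of
  aborting; an input with zero parseable molecules is an error.
- TSV is used for matrices (labels may contain commas); JSON sidecars
  record every CLI run's resolved configuration.

## Problem sizes

The default verification workloads are desk-scale by construction: the
1500 × 166 random reference (1.12 M exact pairs, < 1 s via the
matrix-product path), 5000-molecule synthetic libraries for threshold
parameter recovery (Hoeffding: with a 0.05 margin the per-bit error
probability is ≤ e^(−25)), and 300–500-molecule ladder levels for the
trend tests.

## Known limitations

- The DFP discards all inter-bit correlation: libraries with identical
  marginals but different joint structure share a DFP.
- The vs-DFP similarity is a proxy; its absolute level differs from the
  pairwise mean (it is systematically higher on homogeneous synthetic
  libraries), so comparisons should stay relative, across libraries
  summarized the same way.
- Thresholds near the bulk of the probability profile make DFP bits
  sensitive to sampling noise for small n (binomial fluctuation around
  the cutoff); the parameter-recovery analysis quantifies the safe
  margin (|p − t| ≥ 0.05 at n = 5000).
- PubChem fingerprints are ingested only as precomputed FPS/CSV input;
  generating them from structures is out of scope (MACCS via RDKit is
  the only structure backend).
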