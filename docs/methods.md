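# Methods

## Model

The package treats a training set as a formal context `K = (G, M, I)`
over binary attributes obtained by bucketing, and its concept lattice as
a complete inventory of the attribute combinations the data supports:
each concept `(A, B)` is a maximal rectangle — the objects `A` are
exactly those holding all of `B`, and `B` is exactly what all of `A`
share. A new instance is scored by how strongly its profile is witnessed
in that inventory, combining *how often* (support) with *how closely*
(F-measure of intent vs. profile). The underlying assumption is that a
classifier trained on `G` is most reliable where the lattice is densely
populated; the evaluation workflow exists to test that assumption on any
given dataset rather than take it on faith.

### Scoring conventions

Several small conventions are forced by internal consistency and are
fixed throughout:

- **Intervals are lower-inclusive / upper-exclusive.** "Adult below 60"
  means `[0, 60)`; BMI 25.0 is Overweight under `[25, 30)`. This is the
  only convention that assigns every record of the worked example
  consistently, including the boundary cases (age 59, BMI 25).
- **Support counts own objects, not the extent.** `S(C)` asks how many
  training items have *exactly* the concept's intent as their profile
  (intersected with the candidate set `G′`). A concept that exists only
  as a generalization of several distinct profiles — non-empty extent,
  empty own-object set — has support 0: the exact combination was never
  observed. In the worked example this is visible in the concept
  {Adult, Female}, whose extent has two objects but whose support is 0.
- **The matching threshold is a strict majority**: shared attributes
  `> |Attr(X)|/2`, so a 3-attribute instance needs at least 2. Concepts
  with empty extent (in particular the bottom concept, whose intent
  contains everything) never match — they describe no data.
- **The exact case uses only the exact concept.** At most one concept
  can have intent equal to `Attr(X)` (closure uniqueness), its F-measure
  is 1, and other matching concepts are ignored.
- **Instance attributes outside M** stay in `Attr(X)` for the recall
  denominator and the matching threshold but can never be shared; an
  instance fully disjoint from M scores 0 with case `none`. An empty
  attribute set is rejected (the threshold is undefined).

### Arithmetic modes

`full` (library default) carries exact floating point. `printed` mimics
hand-computation on two-decimal printed tables: support and F-measure are
rounded to 2 decimals before combining and the final score to 3, with
ties away from zero (`decimal.Decimal`, `ROUND_HALF_UP`: 0.9125 → 0.913).
The two modes agree within 0.01 on the worked example; `printed` exists so
published reference values are reproduced digit-for-digit, and is also
what `scripts/acceptance.py` reports.

## Lattice construction

Concepts are enumerated with Ganter's NextClosure over attribute sets,
implemented on integer bitmasks; the enumeration's correctness is defined
(and tested) against brute-force closure of every attribute subset, not
by the algorithm choice. Concept ids are canonical — sorted by
`(|intent|, lexicographic intent)` — so serialization is byte-stable
across runs; id 0 is always the top concept and the last id the bottom.
Only the cover (Hasse) relation is stored; general order queries use
extent inclusion directly. An inverted index (attribute → concepts
containing it in the intent) supports retrieval-style matching without
scanning the lattice; it is an in-memory stand-in for a search-index
deployment.

Complexity is the usual FCA bound (worst case exponential in
`min(|G|, |M|)`); the intended regime is bucketized tabular data with
tens of attributes, where the number of distinct object profiles — not
the number of records — bounds the lattice size in practice.

## Evaluation workflow

`evaluate()` scores a labelled test set, sorts the scores, groups them
into `k` equal-frequency bins (default `k = 10`; the granularity is a
free parameter of the method), computes accuracy per bin, and correlates
per-bin **mean** score with per-bin accuracy using Pearson's r,
Kendall's τ-b (tie-corrected), and Spearman's ρ (scipy implementations).
Per-instance values are kept in the report so alternative x-variables
(bin midpoint, bin index) or unbinned correlations can be recomputed.

Binning details that matter in practice:

- Runs of identical scores are atomic — a bin boundary can only fall
  between distinct values — because splitting a tie would make bin
  membership depend on input order. Bin sizes are rebalanced greedily
  after each tie run (each remaining bin targets an equal share of the
  remaining items), so a heavily repeated score (common when many test
  items share one training profile) inflates one bin instead of starving
  the last. If there are fewer distinct values than bins the binning
  fails with advice to lower `k`.
- A constant series (e.g. accuracy 1.0 in every bin under a perfect
  classifier) makes the correlations undefined; they are reported as
  null with a reason, never silently as 0.
- The cosine baseline vectorizes profiles as binary indicators over M,
  scores each test instance by its mean cosine similarity to all
  training vectors, and reuses the identical binning-and-correlation
  code path, so the comparison isolates the score definition.

## Synthetic data generator

`generate_synthetic()` emulates the setting the score is designed for.
Defaults, chosen once as the package's study conditions: 500 training and
500 test records over 6 binary features (profile space 64), training
profiles drawn with Dirichlet-skewed weights from a 60% subset of the
space, `novelty_rate = 0.3` (fraction of test items that are 1–2-feature
perturbations of training profiles rather than resampled ones), and
`noise_slope = 0.9`: the simulated classifier flips the true label with
probability `0.9 · d/6`, where `d` is the Hamming distance to the
nearest training profile. Test sizes and rates are configurable;
numeric-feature variants exercise the interval-bucketing path.

The generator couples score and accuracy *by construction* — seen
profiles are always classified correctly, novel ones err in proportion to
their novelty. Passing the workflow test (positive binned Spearman
correlation in ≥ 95 of 100 seeds at the defaults) therefore shows that
the pipeline detects a representativeness–accuracy link when one exists;
it says nothing about whether real classifiers on real tabular data
exhibit such a link, which must be established per dataset with the same
workflow. Real data also differ in ways the generator does not model:
correlated features, label noise independent of novelty, class imbalance,
and attribute spaces large enough that most test profiles are novel.

## Numerical and degenerate-input choices

- Bucketing rejects missing values rather than imputing; imputation is a
  pre-processing concern with dataset-specific answers.
- Attributes supported by no object are retained in M (schema stability
  between train and test); they index only the bottom concept.
- Convexity of the weights (`α₁, α₂ ≥ 0`, `α₁ + α₂ = 1`, tolerance 1e-9)
  is validated at construction, which is what keeps every score in
  [0, 1] without clipping.
- `support` with an empty candidate set, `precision` of an empty intent,
  and correlation of series shorter than 2 raise typed errors rather
  than returning sentinels.
- Correlating two bins (`k = 2`) is allowed though degenerate: the rank
  coefficients can only be ±1.

## Known limitations

- Lattice construction is exact and in-memory; no incremental updates,
  attribute-reduction, or approximate variants are provided for very
  wide contexts.
- Only crisp binary contexts are supported — no fuzzy or many-valued
  scaling beyond interval/one-hot bucketing; text vectorization into a
  context is an explicit, unimplemented extension hook.
- The weights α₁/α₂ are taken as given, not learned, and the score is
  not a calibrated probability.
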