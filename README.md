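# congruity

**Training-set representativeness scoring for classifier inputs, via
formal concept analysis.**

A trained classifier reports one overall accuracy, but its reliability on
a *particular* input depends on how much experience it has with inputs
like it. `congruity` quantifies that experience: it organizes the
training data into a concept lattice (formal concept analysis) and scores
each new instance by how strongly its attribute profile — and close
generalizations of it — occurred in training. The score lives in [0, 1]:
high values mean the model has seen this kind of input many times; low
values flag out-of-distribution inputs whose predictions deserve less
trust. The package targets practitioners of clinical and other tabular
risk models who consume models they did not train, and researchers
auditing whether a training set represents its problem domain.

## The measure

Training records are *bucketized* into binary attributes (one attribute
per categorical value; named half-open intervals for numeric features),
giving a formal context `K = (G, M, I)`. Its concept lattice `L` consists
of all closed pairs `(A, B)` with extent `A ⊆ G` and intent `B ⊆ M`.

For a new instance `X` with attribute set `Attr(X)`:

- the candidate set `G′` holds every training object sharing ≥ 1
  attribute with `X`;
- the matching concepts `C̃` are those with non-empty extent whose intent
  shares **strictly more than** `|Attr(X)|/2` attributes with `X`;
- per concept: support `S(C) = |own objects of C ∩ G′| / |G′|` (own
  objects = training items whose complete profile equals the intent), and
  the F-measure `F = 2PR/(P+R)` of precision
  `P = |Attr(X) ∩ B| / |B|` and recall `R = |Attr(X) ∩ B| / |Attr(X)|`.

The score is the convex combination `α₁S + α₂F` (defaults
`α₁ = 0.1, α₂ = 0.9`):

| case | condition | value |
|---|---|---|
| exact | some matching intent equals `Attr(X)` | `α₁·S(C̃*) + α₂` |
| partial | matches exist, none exact | mean of `α₁·S + α₂·F` over `C̃` |
| none | no matching concept | `0` |

The evaluation workflow then checks that the score means what it claims:
score a labelled test set, sort and group the scores into equal-frequency
bins, compute classifier accuracy per bin, and correlate per-bin mean
score with accuracy (Pearson r, Kendall τ-b, Spearman ρ). A
mean-cosine-similarity baseline runs through the identical binning path
for comparison.

## Worked example

The built-in example bucketizes ten people by age (Adult < 60 ≤ Elderly),
gender, and BMI (WHO cut points 18.5 / 25 / 30), then scores two new
people:

```text
$ congruity demo
context: 10 objects, 8 attributes
lattice: 22 concepts
Person11 {Elderly, Male, Underweight}: congruity = 0.913 (exact case, |G'| = 8)
  concept {Elderly, Male, Underweight}: S = 0.13, P = 1.00, R = 1.00, F = 1.00
Person12 {Adult, Female, Overweight}: congruity = 0.643 (partial case, |G'| = 9)
  concept {Adult, Female}: S = 0.00, P = 1.00, R = 0.67, F = 0.80
  concept {Adult, Female, Normal}: S = 0.11, P = 0.67, R = 0.67, F = 0.67
  concept {Adult, Female, Obese}: S = 0.11, P = 0.67, R = 0.67, F = 0.67
  concept {Adult, Male, Overweight}: S = 0.22, P = 0.67, R = 0.67, F = 0.67
```

Person11's exact profile occurred in training (once among the 8
candidate objects, so S = 1/8), giving the high exact-case score
`0.1·S + 0.9 ≈ 0.913`. Person12's combination was never seen together:
four concepts each share 2 of the 3 attributes, and averaging their
`0.1·S + 0.9·F` terms gives 0.643 — decent coverage, low direct support.

The same toolchain runs from the shell on your own data:

```sh
congruity synth --seed 1 --out-dir data/                 # or bring your own CSVs
congruity build-lattice --context data/train.csv --schema data/schema.yaml --out lattice.json
congruity score --lattice lattice.json --instances data/test.csv \
    --schema data/schema.yaml --out scores.json
congruity evaluate --scores scores.json --predictions data/predictions.csv \
    --bins 10 --baseline cosine --lattice lattice.json --out report.json
```

`report.json` contains the bins (range, size, mean score, accuracy) and
the three correlation coefficients for the congruity score and for the
cosine baseline.

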