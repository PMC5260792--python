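# Methods

## Rank weights

All seven tests start from per-sample abundance ranks. Within a sample, only
proteins with a positive value compete for ranks (a spectral count of zero
means the protein was not observed; ranking unobserved proteins into the top
percentiles would be meaningless), and the percentile of a protein is its
ordinal rank from the most abundant divided by the number of positive
proteins, so "top 10%" means percentile ≤ 0.10. Ties are broken by protein ID
(ascending). This tie-break is arbitrary but deterministic — reproducibility
claims about the methods are only testable if the weight matrix is a pure
function of the input — and it is applied identically everywhere, so no
method is favoured.

Three weight schemes map percentiles to weights:

| scheme | top region [0, α₁] | fuzzy band (α₁, α₂], 4 bins | beyond α₂ |
|---|---|---|---|
| `binary` | 1 | 0 | 0 |
| `fuzzy_fractional` | 1 | 0.8, 0.6, 0.4, 0.2 | 0 |
| `fuzzy_integer` | 5 | 4, 3, 2, 1 | 0 |

Defaults α₁ = 0.10, α₂ = 0.20, 4 bins. The bands are half-open, `(α₁ + (j−1)w,
α₁ + jw]` with `w = (α₂−α₁)/n_bins`, so the six weight levels partition
[0, 1]; boundary comparisons carry a 1e-9 tolerance because percentiles are
ratios of small integers. With the defaults the fractional scheme equals the
integer scheme divided by 5. α₁ = α₂ is allowed and collapses the fuzzy band,
which reduces FSNET to SNET — useful for testing, and the natural way to
express "no fuzzification". The integer units of the `fuzzy_integer` scheme
are part of the Fuzzy-FishNET definition: its exact test treats pooled weight
sums as pseudo-counts, so rescaling the weights changes p-values. Fractional
weights are therefore rejected by the contingency builder rather than
rounded.

## The tests

**Fuzzy-FishNET** (`ffishnet`) pools integer weights per class into a 2×2
table (in-complex vs out-of-complex mass for each class) and computes the
one-sided Fisher exact tail P(first cell ≥ a | marginals) by summing
hypergeometric point probabilities in log-gamma space. Both class
orientations are tested; a complex is selected when either one-sided p < α,
with the reported direction taken from the smaller p. The p-value is
per-direction and uncorrected, matching the uniform 0.05 convention used
throughout. The cell `b` is the total weight mass of proteins *outside* the
complex (the "not in complex" column of the table); the alternative reading —
maximum possible in-complex mass minus `a` — would break the marginal
structure of the table and is rejected.

**FishNET** (`fishnet`), the unweighted ablation, assigns uniform weight 1
across the *whole* considered region (top α₂) and 0 elsewhere, sharing the
Fuzzy-FishNET code path. Two readings of "unweighted" are possible: weight 1
over the top α₁ only (a SNET-style cutoff), or weight 1 over the same top-α₂
coverage as the fuzzy scheme with the tiers removed. This package uses the
coverage-fixed reading because it is the actual ablation of the rank tiers —
both variants then see exactly the same proteins and differ only in the
grading — and because it reproduces the stabilising effect of fuzzification
that motivates the comparison. Under the top-α₁ reading the ablation has a
seven-fold smaller weight budget, is extremely conservative on simulated
data, and degenerates into repeatedly selecting the one or two strongest
complexes, which makes its Jaccard stability trivially high and the
comparison uninformative.

**Hypergeometric enrichment** (`he`) runs a per-protein two-sample t-test
(Welch by default; the equal-variance form is available via `equal_var=True`)
and forms the differential list at p < 0.05, then computes the upper
hypergeometric tail of each complex's overlap with that list (universe = all
matrix proteins). No multiple-testing correction is applied at either stage
by default, matching the uncorrected convention; Benjamini–Hochberg on the
complex p-values is available (`fdr="bh"`).

**KS direct-group test** (`gsea`) needs a per-protein ranking score that the
formulation leaves unstated; the signed Welch t statistic (class1 − class2)
is used, rank 1 = largest. Each complex is tested by the two-sample KS
statistic between in-complex and out-of-complex ranks, with normalized ECDFs
(the printed rejection threshold `c(α)·√((|D|+|D′|)/(|D|·|D′|))` is the
classical two-sample form for normalized ECDFs), and selected when
KS ≥ threshold with c(0.05) = 1.36. Because the threshold rule, not a p-value
cut, defines selection, the stored p-value (asymptotic Kolmogorov tail) is
reference-only and `selected` can disagree with `p_value < 0.05` in a narrow
band (the threshold corresponds to an asymptotic p of ≈ 0.049).

**QPSP** (`qpsp`) computes per-sample hit-rates H(S,C) = (weight sum of
measured members) / (number of measured members) with fractional weights and
compares classes per complex with the pooled-variance two-sample t, two-sided
(the formulation does not state a direction). The pooled-variance form is
kept for QPSP while SNET/FSNET use Welch degrees of freedom — the
inconsistency between the two printed t forms is preserved deliberately for
fidelity. (The printed pooled-SD formula has a minus sign between the two
variance terms, which would be negative for equal-sized classes; the standard
plus is used.)

**SNET / FSNET** (`snet`, `fsnet`) compute β(g, C) = class-mean weight of g,
score(S, p, C) = Σ_{g∈S} fs(g,p)·β(g,C), and per weighting direction a Welch
t between the weighting class's scores and the other class's scores,
significant in the upper 5% tail (Welch–Satterthwaite df). FSNET's β uses the
fuzzy weights (the mean of fuzzy memberships), the natural generalization of
"proportion of tissues with g in the top α". The result set is the union of
both directions.

**PFSNET** (`pfsnet`) computes delta(S,p) = score(S,p,X) − score(S,p,Y) over
*all* samples p ∈ X ∪ Y (the printed statistic iterates over Z = X ∪ Y; no
tissue pairing is imposed, although the name suggests it) and tests
mean/standard-error against the upper 5% tail of t with |Z|−1 df, per
direction.

Degenerate variance cases are handled uniformly: zero variance with zero mean
difference gives t = 0, p = 1; zero variance with a non-zero difference gives
the smallest positive double as p. All directional methods carry both
one-sided p-values (`p_up_class1`, `p_up_class2`) in their result tables;
`class1` is always the lexicographically smaller label, so label-swap
symmetry is exact.

## Null calibration, measured

The calibration experiment (500 independent rounds of a no-effect
simulation — fresh 1000×12 count matrix and fresh 60-complex set per round,
balanced 6+6 labelling) is computed by `fishnet_kit.experiments.
null_calibration` and re-run by both the test suite and the acceptance
script. The behaviour it shows is a property of the methods, not of the
implementation:

- the t-based tests sit slightly below nominal (per-direction rates ≈ 0.04
  for QPSP, ≈ 0.048 for FSNET): small-sample t-tests on discrete
  rank-derived scores are mildly conservative;
- the exact and threshold tests are clearly conservative (≈ 0.02 for
  Fuzzy-FishNET — Fisher's exact test under stable between-sample ranks —
  and ≈ 0.03 for the KS rule, whose asymptotic threshold over-covers at
  small complex sizes);
- PFSNET rejects far above nominal (≈ 0.34 per direction). This is inherent
  to the printed statistic: the per-sample deltas all share the realized
  β_X − β_Y vector, so they are strongly correlated observations centred on
  a non-zero random constant, and a one-sample t that treats them as
  independent detects that constant. A direct simulation of the bare formula
  with independent weights reproduces the inflation, and it is consistent
  with the method's documented hyper-sensitivity (it selects far more
  complexes than the exact tests).

## Synthetic data

`synthesize_base_matrix` draws per-protein expected counts from a lognormal
(log-mean 2.0, log-sd 1.0 — median ≈ 7 counts, long right tail, natural zeros
for low-abundance proteins, roughly the shape of spectral-count data) and
per-cell Poisson counts. An optional `dispersion` parameter multiplies each
cell's rate by lognormal noise (sigma on the log scale), emulating the
technical overdispersion of real spectral counts; 0.5 (≈ 50% CV) is used for
the "noisy" stability experiments because between-sample rank instability is
exactly the noise the fuzzification claim concerns — with pure Poisson noise
ranks are nearly deterministic and every method looks stable.

Spike-in multiplies a seeded random 20% of proteins by (1 + p), p drawn per
protein from {0.2, 0.5, 0.8, 1.0, 2.0}, in one class only; spiked values stay
real-valued (all downstream methods are rank- or weight-based, so re-rounding
would only coarsen ties). Pseudo-class datasets split an even set of
same-condition samples randomly in half and spike one half.

Pseudo-complexes: differential proteins are ordered by the leaf order of
Ward-linkage hierarchical clustering on Euclidean distances over all samples
(raw, unstandardized expression vectors), so co-expressed proteins are
adjacent, then split into contiguous chunks whose sizes differ by at most one.
An equal number of non-differential proteins is sampled, ordered and chunked
the same way. Purity dilution keeps `round_half_up(purity × size)` true
members per differential complex and replaces the rest with non-differential
proteins *not* used by the non-differential complexes (no truth leakage), the
replaced positions chosen uniformly. The replacement pool is re-drawn per
dataset.

What passing these benchmarks does **not** show about real data: the
generator has no batch structure, no missingness mechanism beyond Poisson
zeros, no correlated protein blocks outside the constructed pseudo-complexes,
and pseudo-complex sizes (≈ 3–4 members at the standard 200-truth/62-complex
setting) are smaller than typical curated complexes. Real-data properties
that depend on those features — absolute selection counts, replicate overlap
values — are not reproduced here, only the qualitative contrasts between
methods.

## Benchmarks

Precision = TP/(TP+FP), recall = TP/(TP+FN) against complex-level truth, and
F is their harmonic mean, with 0/0 ratios defined as 0. Set overlap is
offered as Jaccard |∩|/|∪| and as |∩|/min(|A|,|B|); two empty sets overlap
perfectly by convention. (The two modes disagree in general — the min-
normalized form is the only one that can reach values like 0.96 for sets of
sizes 78 and 87, which Jaccard cannot.)

Stability resampling draws `size` samples **per class** (sizes 4/6/8 mean
4+4, 6+6, 8+8 — per-class keeps the classes balanced at every level) without
replacement, re-runs the method, and records a binary selection vector; the
headline scalar is the mean pairwise Jaccard between rounds' selection sets,
with row sums (selections per round) and column sums (per-complex selection
frequency) as secondary summaries.

Cross-validation repeats, per repetition: optional label shuffling, a
stratified split into one validation quarter, one training quarter and a
selection half (per class: q = n//4 samples to validation, q to training, the
rest to selection), method on the selection part, features = expressions of
all proteins inside selected complexes, deterministic Gaussian naive Bayes on
the training quarter, accuracy on the validation quarter; with zero selected
complexes the majority training class is predicted and the repetition is
flagged. The standard design uses 12 samples per class — the size of a
six-pair, two-batch clinical screen — which gives 6/3/3 splits.

The naive Bayes is Gaussian with per-class ML means and variances, a variance
floor of `var_smoothing × (global feature variance + 1)` with
`var_smoothing = 1e-2`, features constant across training skipped, and exact
posterior ties broken toward the lexicographically smaller label. The floor
is deliberately large: with two or three training samples per class, discrete
count features are frequently constant-within-class, and with a negligible
floor (the usual 1e-9) a single such feature dominates the log-posterior and
drives accuracy to chance even on perfectly separable data. 1e-2 regularizes
those features while leaving genuinely informative ones decisive.

False-positive evaluation splits the samples of a single condition into two
random pseudo-classes per round (an odd sample count drops the last column)
and records the fraction of complexes selected.

## Numerical and interface choices

- Exact tails (hypergeometric and Fisher) are summed in log-gamma space with
  a max-shifted `fsum`; relative accuracy against exact integer enumeration
  is better than 1e-9 over all tables with n ≤ 40, and the two
  implementations agree to 1e-12 where they coincide mathematically.
- Every random draw flows through `numpy.random.default_rng` seeded from a
  `SeedSequence` tree, so all simulators, resamplers and experiment recipes
  are bit-reproducible from one integer seed across platforms.
- Complexes need ≥ 3 members identified in the matrix (rows present,
  regardless of zero counts) to be tested; absent members simply contribute
  nothing — no imputation.
- Input formats: proteins × samples TSV, two-column label TSV, GMT complex
  sets; results are six-column TSVs. The CLI writes a JSON manifest (method,
  parameters, seed, input MD5s) next to every output.

## Known limitations

- PFSNET's nominal significance level is not meaningful (see the calibration
  section); its results should be read as a ranking, which is how it is
  benchmarked here.
- The GSEA-style per-protein ranking score (signed Welch t) is a choice the
  formulation leaves open; a different contrast score would change its
  selections.
- The Fisher test's calibration depends on the between-sample stability of
  abundance ranks: with very noisy ranks the pooled weight sums are
  overdispersed relative to the hypergeometric model and the test can become
  anti-conservative. On count-like data with a stable abundance hierarchy it
  is conservative.
- Resampling benchmarks assume at least `size` samples per class; the CV
  protocol needs at least four per class.
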