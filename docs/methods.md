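# Methods

## Profiles

Input is two tab-separated edge lists: miRNA–gene interactions and
miRNA–disease associations (`mirna_id<TAB>feature_id`, `#` comments,
UTF-8).  Records are de-duplicated after identifier normalization
(lowercase + trim by default).  Two opt-in normalizations mirror common
curation steps whose exact merge tables vary between database releases and
are therefore left to the user: collapsing precursor-copy suffixes
(`mir-21-1`/`mir-21-2` → `mir-21`; a single trailing `-digits` group is
stripped when the remaining stem still contains a digit) and a two-column
alias→canonical synonym map, typically for disease names.

The miRNA universe is the **intersection** of the two lists' miRNA sets: a
miRNA lacking either profile carries no cross-view signal and cannot inform
the canonical correlation.  Features incident only to excluded miRNAs are
dropped (they would be all-zero columns, which degenerate the correlation).
Rows and columns are sorted lexicographically, making every matrix and all
downstream output deterministic.  Dataset statistics report exact counts,
unrounded means (mean × n equals the edge count to machine precision) plus a
one-decimal rendering, and per-matrix degree histograms.

## Sparse CCA by penalized matrix decomposition

The optimization is run on `Z = XᵀY`.  On raw binary profiles `Z[g, d]`
counts the miRNAs that both target gene *g* and associate with disease *d*,
which keeps components directly interpretable; this is the default.
`center=true` column-centers X and Y before forming Z for users who prefer
fully centered canonical variates (the training column means are stored and
re-applied to queries).  Either way, the reported canonical correlation ρ is
always the Pearson correlation of the *centered* variates `Xα`, `Yβ`
(defined as 0 when either variate is constant).

**Single component.**  With β fixed, the constrained maximizer of `αᵀZβ`
over `‖α‖₂ ≤ 1, ‖α‖₁ ≤ c₁√p` is the soft-thresholded, L2-normalized vector
`S(Zβ, δ*)/‖S(Zβ, δ*)‖₂`, with δ* the smallest threshold meeting the L1
budget; δ* is found by bisection (150 iterations or interval width
< 1e−10).  The two sides alternate until the maximum componentwise change
of α and β falls below `tol = 1e−6`, capped at `max_iter = 1000`.

**Feasibility clamp.**  Any L2-unit vector has `1 ≤ ‖u‖₁ ≤ √m`, so the
nominal budget `c√m` is clamped to `[1, √m]`.  In particular very small
sparsity fractions at large *m* (nominal budget < 1) are infeasible as
written; the clamp to 1 selects maximally sparse components and is logged.
When the budget is exactly 1 but the leading magnitudes of the update are
tied, even the limit vector (uniform over the tied entries, L1 = √#ties)
exceeds the budget; it is returned with a warning rather than failing.

**Initialization and multi-start.**  Under binding budgets the problem is
non-convex and alternation can stall in local optima.  Starts are
deterministic: the leading right singular vectors of the working matrix
(with non-binding budgets the first is already the global optimum, so the
fit reduces exactly to the SVD), plus — when the budget binds — the
coordinate axes of the largest-norm columns, which seed maximally sparse
solutions.  `n_starts = 5` per family by default; the best objective wins,
with the earlier (more canonical) start preferred on ties.  `config.seed`
exists for an explicit random-init mode but no default path consumes
randomness: fits are bit-reproducible from the data alone.

**Deflation and bookkeeping.**  `Zᵏ⁺¹ = Zᵏ − d_k α_k β_kᵀ` for k = 1..K,
stopping early (with a warning) when the residual's Frobenius norm drops
below `tol` — requesting more components than the matrix's rank truncates K
rather than erroring.  Signs are fixed by flipping (α, β) jointly so α's
largest-magnitude entry is positive.  Each component records its nonzero
weights as named gene/disease sets (|weight| descending, lexicographic
tie-break) and its contributing miRNAs — training rows whose gene profile
has nonzero inner product with α *and* disease profile nonzero inner
product with β.  Set membership is "nonzero weight": soft-thresholding
already zeroes non-selected features, so no secondary cutoff is introduced.
Models serialize to JSON with hex-encoded floats for bit-exact round-trips.

## Prediction

`y_new = Σₖ ρ_k (α_kᵀ x_new) β_k`.  Query genes absent from the training
vocabulary are dropped, counted (`n_unknown_genes`) and logged — the
new-miRNA scenario guarantees vocabulary mismatch, so this is a warning,
not an error; a query with no known genes yields all-zero scores.  Rankings
sort by score descending with lexicographic disease-id tie-breaks, making
output deterministic.  The score is linear in the query profile and
invariant to component order.

## Cross-validation

miRNAs are shuffled into `n_folds` folds whose sizes differ by at most one
(repeat *r* uses derived seed `seed + r`; no global random state).  Per
fold, both profile matrices are subset to the training miRNAs, columns that
become all-zero are dropped for that fold (logged), the model is refit and
every test miRNA scored from its gene profile only — its disease row never
reaches training.  Per repeat, all (test miRNA, disease) pairs are pooled:
positives are the held-out known associations, negatives all other pairs
(the standard choice for this protocol, since ranked association lists are
scored threshold-free).  AUC is trapezoidal over the threshold sweep on
unique scores, identical to the Mann–Whitney statistic with mid-rank ties.
The headline number is the mean AUC over repeats; the pooled-over-repeats
AUC is also reported.  `tune_parameters` exhaustively evaluates a
(c₁, c₂, K) grid and flags the best row.

## Synthetic data

The generator plants L latent factors: disjoint (by default) groups of
miRNAs, genes and diseases; within-factor pairs link with probability
`pi_in`, all others with `pi_bg`.  Mixing factor membership with background
links yields sparse matrices with right-skewed degrees.  Defaults are
calibrated analytically to the scale of curated human data — 404 miRNAs ×
2796 genes × 362 diseases, 10 factors of 40 miRNAs / 40 genes / 31 diseases,
`pi_in = 0.4`, `pi_bg = 0.0015` — giving expected per-miRNA degrees of
~20.0 genes and ~12.8 diseases, near the observed 19.8 and 12.7.  An
`overlap` mode lets factors share miRNAs (miRNA families share targets);
it is off by default so recovery experiments have clean truth sets.

What the generator does *not* emulate: the exact long-tail shape of real
degree distributions (only its skew), correlated gene co-targeting outside
factors, database ascertainment bias, and disease-ontology structure.
Passing recovery tests therefore show the estimator recovers planted
low-rank co-occurrence structure at realistic sparsity — not that curated
databases contain such structure.

`recovery_score` reports, per planted factor, the best Jaccard index
between its gene (disease) set and any component's extracted set.

## Recovery experiment design

The headline synthetic experiment uses n = 300 miRNAs, 5 factors of
60 miRNAs / 20 genes / 10 diseases over 200 genes and 100 diseases,
`pi_in = 0.9`, `pi_bg = 0.02`, K = 5, and sparsity fractions
`c₁ = c₂ = 0.3`.  The fractions were set so the L1 budget `c√p ≈ √s` sits
at the scale of the planted cardinality *s* (0.3·√200 ≈ √18 for 20 genes;
0.3·√100 = √9 for 10 diseases): soft-thresholding then retains roughly one
planted set per component.  Under these conditions the planted sets are
recovered with Jaccard ≈ 1 and 5×5-fold cross-validated mean AUC ≈ 0.91,
while a matched pure-noise generator (`pi_in = pi_bg`) stays at chance.
Problem sizes were chosen so the full suite and the acceptance script each
run in about one to two minutes on a single CPU.

## Numerical choices and limitations

- Bisection tolerance 1e−10 on the threshold interval; zero tolerance
  1e−12 for "nonzero weight" and "nonzero inner product".
- Degenerate inputs: all-zero Z errors; all-zero residual truncates K;
  constant canonical variates give ρ = 0; one-class ROC labels error.
- Components are extracted greedily with deflation; unlike a full SVD the
  sparse factors are not orthogonal, and strongly overlapping planted
  factors may merge into one component.
- The L1-ball geometry means equal-magnitude ties cannot be split below
  budget 1; such components carry a logged warning.
- Binary profiles weight every interaction equally; evidence strength and
  prediction confidence from the source databases are out of scope.
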