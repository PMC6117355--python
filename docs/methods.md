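# Methods

## Problem setting and statistical model

Given a universe of genes `U`, an active list `U_G` (with complement
`U_O = U \ U_G`) and candidate term gene sets `S_1..S_m`, a term
combination `X` is reduced to its *pseudo composite term* `∪_{i∈X} S_i` and
tested for over-representation exactly like a single term: the p-value is
the hypergeometric upper tail `P(overlap ≥ t(X))` with population `N = |U|`,
`K = S(X)` annotated genes and `n = |U_G|` draws, i.e. the one-sided
Fisher's exact test on the 2×2 table of the union. Combination p-values are
reported raw; only the single-term baseline scan carries a
Benjamini–Hochberg adjustment (the conventional FDR procedure for that
setting), because combination p-values arise from a search, not from a
fixed family of hypotheses, and any fixed multiplicity correction over the
searched space would be arbitrary.

The tail is computed in log space: log-pmf terms from a cached
log-factorial table, combined with a max-shifted log-sum-exp. Two reasons:
(a) numerical safety — the test grid certifies ≤1e-10 relative error
against exact rational summation; (b) strong combinations on realistic
instances have p-values around `1e-300 … 1e-1000`, below float64, so every
`TermCombination` carries an exact `neg_log10_p` next to the (possibly
underflowed) `p_value`, and all orderings use the log value.

## The optimization model

Good combinations trade off two conflicting objectives: maximize covered
active genes `t(X)`, minimize the annotated-inactive penalty
`S(X) − t(X)`. The minimum-p combination is Pareto-optimal for this pair
(verified empirically by enumeration in the test suite), and because
`0 ≤ t(X) ≤ |U_G|` the front holds at most `|U_G| + 1` points. Fixing
coverage yields the constrained form `min S(X) − t(X)  s.t.
t(X) ≥ α|U_G|` (ESCP; the constraint is discretized to
`t(X) ≥ ceil(α|U_G|)` since `t` is integral, with a 1e-9 guard against
float fuzz at exact multiples). There is deliberately no size constraint in
the model; size selection happens only when filtering the pooled solutions.

## The randomized greedy search

Per step, every candidate term is scored by cost-effectiveness
`w(S_i)/|(S_i ∩ U_G) \ C|` where `C` is the set of already covered
*active* genes (the denominator's definition forces this reading of `C`),
`w(S) = Σ_{e∈S∩U_O} 1/|N_e|` and `N_e` is the number of candidate terms
annotating gene `e`. One term is picked uniformly at random among those
with cost-effectiveness at most `(1+d)·σ`, `σ` the minimum over terms that
still add an uncovered active gene; the band boundary is inclusive, and
when `σ = 0` (a candidate with zero weight, i.e. fully active membership)
the eligible set is exactly the zero-cost terms since `(1+d)·0 = 0`. Terms
adding no new active gene get `ce = +∞` and are never selectable; terms
never overlapping `U_G` are pruned up front (pure speedup — they can never
enter). The run stops when no finite cost-effectiveness remains; active
genes no term covers are simply never covered (real lists always contain
noise genes that no annotation explains), optionally earlier at a coverage
target.

Every prefix of every run is recorded with its `(S, t, C, p)` — that is
what produces solutions at every size and the characteristic landscape in
which `−log10 p` against size rises while informative terms are added and
falls once coverage is being bought with unenriched terms. `T` restarts
(default `d = 1`, `T = 500`) are pooled and deduplicated by member set,
keeping first-seen provenance `(repeat, step)`.

Randomness: repeat `r` uses `SeedSequence(entropy=seed, spawn_key=(r,))`,
so the pool is a pure function of the master seed and independent of
execution order; the same seed gives bit-identical output.

Known limitation: the `(1+d)σ` band cannot reach optima that require
skipping a locally cheap term whose active gene is later re-covered by an
expensive term — on adversarial random instances (active genes uncorrelated
with terms) a few percent of cases have an exhaustive optimum outside the
reachable set for every `T`. The exact oracle exists precisely to measure
this gap; increasing `d` widens the band at the cost of more repeats.

Implementation: the greedy engine precomputes per-candidate active/full
incidence matrices and weights once per `(db, active)` pair and does one
matrix–vector product per step; instances of 300 terms × 500 restarts run
in about a second.

## Exact oracles

Brute-force certification on small instances uses integer bitmasks over the
annotated genes: exhaustive minimum-p search over subsets (size-capped,
with a subset-count budget guard, default 2×10⁶), exact ESCP by full
subset enumeration, and the exact Pareto front by sweeping the integral
coverage requirement and removing dominated points. Tie-breaks everywhere:
smaller objective, then smaller combination, then lexicographically
smallest member tuple — fixed so results are reproducible under term
relabeling. These are test instruments, not competitive solvers.

## Redundancy and specificity evaluation

Pairwise similarity is Wang's (2007) graph-based measure on the is_a DAG
with contribution weight 0.8 per edge (the default of the standard GO
semantic-similarity tooling; the DAG-free Jaccard overlap of annotated gene
sets is provided as a fallback and the method used is recorded in output
metadata). The redundancy of a reported term set is its averaged pairwise
score `ASS = mean over C(n,2) pairs`; it is compared against the ASS
distribution of randomly drawn term sets of the same size from the whole
candidate pool, 100,000 draws by default (tests and the bundled pipeline
use 200–2000 draws; the estimate is a simple mean whose standard error
shrinks as `reps^-1/2`, and cross-seed stability at 2000 draws is asserted
within 3 standard errors). Pairs whose similarity is undefined because a
term is missing from the DAG are dropped with a logged count rather than
scored zero. Specificity uses the annotated-gene count and the ontology
level — the longest is_a path to the root, root = 0 — computed by
longest-path dynamic programming over a topological order.

## Deriving active lists from expression data

Per-gene two-sample t-test between the two groups (Welch by default —
robust to unequal variances; the pooled-variance flavor is a flag since the
choice is conventional), two-sided; genes sorted by ascending p with ties
broken by gene id (stable, reproducible cut); top 100 by default; then the
annotation filter keeps genes with at least one term, so `|U_G| ≤ 100`.
Genes with undefined statistics (constant in both groups) get p = 1 and
sort last. Identifier matching is exact-string throughout; no alias
resolution.

## Synthetic data

`make_synthetic_db` emulates the shape of GO-BP-style annotation: term
sizes log-uniform on [5, 200] (mean ≈ 53 — many specific terms, few general
ones), a 2000-gene universe, and an `overlap` knob that resamples a
fraction (default 0.3) of each new term's members from previously generated
terms; fresh members come from so-far-unused genes, so `overlap = 0` yields
disjoint terms. `make_planted_instance` plants `k` mutually disjoint terms
(default 10), sets the active list to their union plus `noise_active`
(default 5) genes outside it, and records per-gene provenance. Because
planted terms contain only active genes they have zero weight, and with no
noise the planted set is the unique zero-penalty cover — certified by the
exact oracle on small instances in the tests.

What the generator does *not* emulate: the DAG-correlated nesting of real
GO terms (parents containing children), annotation bias toward
well-studied genes, and inter-gene expression correlation. Planted-recovery
results therefore demonstrate the search machinery, not robustness to
hierarchically redundant annotations; on real GO data the landscape and
Pareto filters are doing the de-redundancy work.

## Problem sizes in the bundled checks

The exhaustive hypergeometric certification covers the full grid `N ≤ 60`;
greedy-vs-oracle uses 100 instances with `m ∈ [8,15]`, `|U| = 40`,
`|U_G| ∈ [4,8]`; Pareto certificates use 50 such instances (`m ≤ 12` where
full-power enumeration of p-values is needed); planted recovery and
landscape shape use 20 instances at the full default scale (2000 genes,
300 terms, 10 planted, 5 noise genes, `d = 1`, `T = 500`). These sizes keep
every certificate exhaustive or near-exhaustive while the whole suite runs
in well under a minute.
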