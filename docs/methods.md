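# Methods

## Problem and transformation model

`anonlattice` anonymizes tabular microdata — survey responses, registry
extracts, clinical tables — in which no single attribute identifies a person
but combinations of *quasi-identifiers* (age, sex, postal code, diagnosis
codes, ...) can.  Each quasi-identifier carries a user-supplied
*generalization hierarchy*: level 0 holds the raw values, and each higher
level merges them into coarser categories up to a single root (`34 → 30-39 →
*`).  A *generalization scheme* `g = (g_1, ..., g_m)` picks one level per
quasi-identifier; under global recoding every record is transformed with the
same scheme.  The solution space is the lattice of all level vectors, of size
`Π (L_i + 1)`; it grows exponentially with the number of attributes, which is
why heuristic search matters beyond ~15 attributes.

Records that still violate the privacy model after generalization are
*suppressed*: their quasi-identifier cells are replaced by the suppression
token (default `*`) and they are excluded from privacy evaluation, though the
rows remain in the output file.  There is no suppression limit; suppression
is penalized only through the quality score.  Cells are compared as exact
strings (no trimming or case folding) for determinism, and the empty string
is an ordinary value that must appear in the hierarchy like any other.

## Privacy models

**k-anonymity.**  Every equivalence class — a maximal set of non-suppressed
records identical on all (generalized) quasi-identifiers — must contain at
least `k` records.  `k = 5` is the conventional default exposed by the CLI
examples.  Suppression under this model is exact: precisely the records in
classes smaller than `k` are removed.

**Population uniqueness.**  The dataset is treated as a sampling fraction
`π ∈ (0, 1]` of a larger population, and the model bounds the estimated
fraction of *population* records that are unique on the quasi-identifiers
(e.g. threshold 0.01 = 1%).  Class sizes are modeled with the two-parameter
Poisson–Dirichlet distribution PD(α, θ) (Pitman's sampling formula), the
standard model for the long-tailed class-size distributions of census-like
data.  With `(x)_m` the rising factorial, the sequential
(Chinese-restaurant) construction gives

    E[K_n]     = (θ/α) ((θ+α)_n / (θ)_n − 1)          (α > 0)
    E[K_n]     = θ (ψ(θ+n) − ψ(θ))                    (α = 0)
    E[K_{n,1}] = n (θ+α)_{n−1} / (θ+1)_{n−1}

for the expected number of classes and of singleton classes in a sample of
size `n`.  The fit matches these expectations to the observed class count `u`
and singleton count `u₁` (method of moments), then extrapolates the fitted
model to the population size `N = round(n/π)`; the uniqueness estimate is
`E[K_{N,1}] / N`.  Two short-circuits are exact by construction: `π = 1`
returns `u₁/n`, and `u₁ = 0` returns 0.

Numerics: the two-equation system is solved by a nested bracketed Brent
search — for each candidate `α` the class-count equation is solved for `θ`
(it is strictly increasing in `θ`), and the singleton residual is driven to
zero over `α ∈ [0, 1)`; residual tolerance 1e−9, at most 200 iterations per
solve, box `θ ∈ (1e−8, 1e9]`.  A derivative-free bracketed solve was chosen
over Newton iteration because it cannot leave the parameter box and has no
step-size failure modes.  Rising-factorial ratios are computed as
`Σ log1p((a−b)/(b+i))` rather than log-gamma differences, which cancel
catastrophically when `θ` is large relative to `n`.  Degenerate histograms
(all singletons, no singletons, a single class, or no sign change in the
box) never raise: the fit falls back to `α = 0` with `θ` matched to the
class count alone and is flagged `converged=False`.  This matters because
the search algorithms evaluate thousands of candidate schemes and must
always receive a defined estimate.  The moment equations are validated by
simulation against a sequential Chinese-restaurant sampler (parameter
recovery within 20% median relative error at n = 5,000) and against
brute-force population counting on a Zipf population (mean absolute error
≈ 0.03 at a 10% sample), since no closed-form reference exists for the full
pipeline.

Suppression under population uniqueness removes whole classes in ascending
size order (ties by first occurrence) and re-estimates after each removal
until the threshold is met.  Smallest-first is a design choice: small classes
contribute most to uniqueness risk and least to quality.  Whether a union of
independently safe batches (local recoding) is itself safe is not a theorem
under this model, so the run report states both the per-batch guarantee and
the recomputed combined-output estimate.

## Quality model (granularity)

Each quasi-identifier cell incurs a loss in `[0, 1]`: a cell generalized to
value `v` loses `(leaves(v) − 1) / (D − 1)`, where `leaves(v)` is the number
of distinct level-0 values covered by `v` and `D` the attribute's total leaf
count (loss 0 when `D = 1`); suppressed cells lose 1.  The score is
`100 × (1 − mean loss over all QI cells)`, so 100% is an unmodified dataset
and 0% one from which all information has been removed.  Suppressed records
stay in the denominator: quality measures the published table against the
original, and a suppressed record is information lost.  Empty datasets and
datasets without quasi-identifiers score 100 by convention.

## Search algorithms

All searches maximize post-suppression quality, memoize evaluations per run,
break ties by the lexicographically smallest level vector, and record a
trace of (elapsed, evaluations, best quality, best scheme).  Budgets
(seconds and/or evaluations) are checked between evaluations; a single
evaluation is never interrupted.

- **Exhaustive** enumerates the lattice in lexicographic order (refused above
  a configurable cap, default 100,000 schemes) and is the oracle for the
  other three.
- **Greedy best-first** starts at the bottom (no generalization) or top
  (full generalization) and repeatedly expands the best not-yet-expanded
  scheme by evaluating its immediate up- (resp. down-) neighbors.  Run to
  exhaustion it visits every scheme and provably returns the exhaustive
  optimum; under a budget it returns the incumbent.  Bottom-up favors the
  low-generalization region and stalls on high-dimensional data where
  everything near the bottom is fully suppressed; top-down is its mirror
  image and reaches usable solutions quickly there.
- **Genetic** maintains two subpopulations of schemes ("individuals" whose
  genes are the per-attribute levels).  Subpopulation 1 is seeded with a
  deterministic triangle pattern — row `j` raises the first `j` attributes to
  their maximum level — and filled with uniform-random schemes; subpopulation
  2 is fully random.  Each generation: sort by fitness (descending, lex
  tie-break); copy the elite fraction unchanged; breed the crossover fraction
  from two distinct parents drawn from the production fraction with
  rank-linear weights (`p − rank + 1`), each gene inherited from a uniformly
  chosen parent; fill the remainder with mutants of uniformly chosen
  individuals, resampling between 1 and `max(1, round(0.05·m))` genes
  uniformly over their full level range (a mutation may be a no-op on a
  gene).  Every 10 iterations the top 20% of each subpopulation (pre-swap
  state, simultaneous exchange) replace the weakest of the other.  Defaults:
  fractions 0.2/0.4/0.2/0.2, 50 iterations, subpopulations of 50.
  Fraction-derived counts use round-half-up with floors of 1 elite and 2
  producers so small subpopulations stay well-formed.  A single seeded
  generator drives the whole run; the seed is part of the configuration.

Implementation note: the evaluation context pre-encodes, per attribute and
level, each record's generalized value as an integer code plus its
granularity loss; an evaluation is then a product-encoding of code columns
(with compaction before 63-bit overflow), a `bincount`, and a masked sum.
The string-level transform layer (`apply_scheme`, `suppress_to_satisfy`,
`quality_granularity`) is the reference implementation; the tests assert the
two routes agree exactly on random instances under both privacy models.

## Local recoding

The iterative partition loop (default 100 iterations): run the inner search
on the current records, emit the non-suppressed ones with that iteration's
scheme, and feed the suppressed remainder — with original values — into the
next iteration, where a coarser scheme can often rescue them.  The loop stops
when nothing remains, when an iteration rescues zero records, or at the
iteration cap; leftovers are suppressed.  Each batch satisfies the privacy
model on its own; for k-anonymity the union does too, because records from
different batches that coincide on all generalized values only enlarge
classes.  With one iteration the procedure reduces exactly to global
recoding.  The "suppressed remainder becomes the next input" rule is the
simplest partitioning consistent with applying different schemes to
different record subsets; per-record schemes are retained in the output so
the transformation is fully auditable.

## Synthetic data

The generator draws categorical attributes with configurable domain size,
hierarchy branching factor `b`, and marginal distribution (uniform or Zipf
with exponent `s`, default 1).  Leaves are zero-padded integer codes; level
`ℓ` groups `b^ℓ` consecutive codes; heights are `⌈log_b(domain)⌉` with root
`*`.  Zipf skew is the default for benchmarks because it yields the mix of
common and rare attribute combinations that makes suppression behavior
non-trivial — uniform marginals make nearly every record unique at low
generalization and the problem degenerates.  What the generator does *not*
emulate: correlated attributes, semantically meaningful hierarchies of
uneven fan-out, missing-data patterns, and numeric attributes.  Passing
tests therefore demonstrate algorithmic correctness and the qualitative
behavior of the searches, not quality levels to expect on real microdata.

## Benchmark conditions

The in-tree high-dimensional comparison uses 20 attributes with domain sizes
cycling through 8/16/32, Zipf(1) marginals, 1,000 records, k = 5, and an
equal budget of 250 evaluations per run, averaged over 10 seeds.  Budgets
are expressed in evaluations rather than seconds so results are
hardware-independent; the harness also accepts time limits.  Under these
conditions top-down and genetic each meet or beat bottom-up's mean final
quality — the qualitative high-dimensional finding the algorithms were
built around (bottom-up spends its entire budget in the fully-suppressed
bottom region).  Wall-clock timings are recorded in the results table but
never asserted.

## Known limitations

- The exhaustive search is a plain enumeration; it has none of the pruning
  machinery of optimal anonymization algorithms and is only intended as an
  oracle on small lattices.
- Only record-level suppression and full-domain global/local generalization
  are implemented; no cell-level suppression, sub-tree generalization,
  microaggregation, or attribute-type inference.
- Granularity is the only built-in quality model (the context accepts the
  transform-layer functions as extension points).
- The population-uniqueness estimator assumes the Poisson–Dirichlet
  class-size model; heavily structured real populations can violate it, and
  the combined-output estimate under local recoding is reported rather than
  guaranteed.
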