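# Methods

## Model and procedure

The package implements similarity-based clustering for cohorts described by
one or more mixed-type attribute tables ("layers") over the same ordered
example set.  It makes no metric assumption about the attributes; instead it
*learns* similarity from the data and then partitions examples by a
variability criterion with an intrinsic stopping rule.  The pipeline is:

1. **Artificial task** (per layer).  Positives are the original examples;
   negatives are a copy in which every attribute column has been permuted
   independently and uniformly at random.  Missing cells are permuted along
   with values, so each column's value multiset — including its missingness
   rate — is preserved exactly, while all between-attribute co-occurrence is
   destroyed.  One shuffled copy per original example is the default
   (`neg_ratio = 1`), which makes "better than a random classifier"
   equivalent to precision above 0.5.

2. **Rule ensemble.**  Candidate rules are conjunctions of 1 to
   `max_conditions_per_rule` (default 3) conditions on distinct attributes:
   the condition count is uniform, attributes are uniform over those with at
   least one observed value, numeric conditions compare against the value of
   a uniformly drawn example (direction uniform in {≤, >}), categorical
   conditions test equality with an observed category.  A candidate is
   retained iff its precision on the artificial task strictly exceeds
   `min_rule_precision` (default 0.5) *and* it covers at least one positive;
   sampling repeats until `n_rules` are retained (production default 50,000;
   the simulation studies here use 2,000, which suffices at n ≤ ~100).  If
   200 × `n_rules` candidates fail to fill the quota the layer is declared
   structure-free and the run aborts with a diagnostic.  Duplicates may be
   retained; normalization absorbs multiplicity.  An example missing a value
   on any conditioned attribute is *not* covered — similarity is only
   asserted where evidence exists, and no imputation is performed.

3. **Example similarity table (EST).**  Entry (i, j) counts the retained
   rules covering both i and j (the Gram matrix of the boolean coverage
   matrix; the diagonal counts rules covering each example).  The whole
   matrix is divided by its single global maximum — the diagonal included,
   as the maximum typically is a diagonal count — giving similarities in
   [0, 1], kept at full floating precision.

4. **CRV score.**  For example i in cluster C, the within-cluster component
   is the sum of squared deviates of row i's entries over columns in C
   (diagonal included; a singleton therefore has component exactly 0), the
   outside component the same over columns not in C (defined as 0 for an
   all-inclusive cluster, a case the score otherwise never meets).  A
   cluster's CRV sums its members' totals, and the merge gain is
   DIFF(a, b) = CRV_a + CRV_b − CRV_{a∪b}.

5. **Merge engine.**  From singletons, each iteration recomputes the gain of
   every cluster pair in every layer, takes the per-pair minimum over
   layers, and merges the single pair with the largest minimum if it is
   strictly positive; otherwise the algorithm stops.  Ties are broken by the
   lexicographically smallest pair of minimal member indices, making runs
   deterministic.  With one layer this is exactly the single-layer
   algorithm.

## Numerical choices

- **Strict positivity with a round-off guard.**  "Merging must reduce
  variability" is a strict inequality; gains are compared against
  `DIFF_EPS = 1e-12` rather than 0.0 because a mathematically zero gain
  (e.g. on a constant similarity table) otherwise surfaces as ±1e-16 of
  floating noise and could trigger spurious merges.  Genuine gains in
  practice are orders of magnitude above this guard.
- **Vectorized pair scoring.**  The per-iteration scorer prices all pairs at
  once using the sum/sum-of-squares identity
  Σ(v−v̄)² = Σv² − (Σv)²/m over per-cluster column aggregates; this is an
  O(N·K) pass per cluster instead of an O(K²·N) pair loop.  It is a pure
  recomputation from the current partition — no stale caching — and the test
  suite asserts agreement with the definitional mean-and-deviates
  implementation to 1e-12 on random partitions, plus bitwise-equal traces
  for duplicated layers versus the single-layer path.
- **Rounding convention.**  All internal arithmetic is full precision.  The
  reference walk-through prints per-example CRV components rounded to three
  decimals and sums the rounded components (merged-pair CRV 0.030,
  DIFF 0.948, where full precision gives 0.031 and 0.947); the
  `round_components=True` reporting option reproduces that convention.  The
  singleton outside-component value 0.484 only arises from *unrounded*
  similarity values (e.g. 118/140), not from their two-decimal display
  (which would give 0.479) — hence the insistence on unrounded ESTs.
- **Determinism.**  One master seed; per-layer generators are derived at
  fixed offsets (seed + 100003·layer_index), so runs are bit-reproducible
  and adding a layer does not perturb the others' randomness.

## Synthetic cohorts: what they emulate, and what not

`generate_cohort` plants k subpopulations expressed in *every* layer (the
multi-layer criterion requires cross-layer coherence, so this is the regime
the method is designed for; a `group_layer_only` flag confines a group's
signal to one layer to exercise the no-merge behaviour).  Per layer, half
the attributes are numeric and half categorical (n_categories = 4).  Group
prototypes assign each numeric attribute a center — a per-group offset on a
spread-3 scale, multiplied by the signal strength s — and each categorical
attribute a modal category.  Members draw numeric values around the center
with residual spread (1−s) and adopt the modal category with probability s
(uniform otherwise).  Background-noise examples draw every attribute
independently from the pooled mixture marginal, so at s = 0 group members
are indistinguishable from noise by construction.  Missing cells are
inserted uniformly at the stated rate.  Defaults — n = 90, k = 3, two
layers of 10 attributes, s = 0.9, 20 % noise, 5 % missing — describe a
small, strongly structured cohort on which full pipeline runs take on the
order of a second with 2,000 rules per layer.

What the generator does **not** emulate: realistic marginal shapes or effect
sizes of any particular clinical cohort, correlated attributes within a
group beyond the planted prototype, informative missingness, or noise
examples forming their own weak structure.  Passing the recovery tests
therefore shows the method finds clean planted co-occurrence structure at
moderate sample size; it does not certify performance on real clinical data,
where signals are weaker and attribute redundancy (to which the score is
sensitive) is common.

## Evaluation conventions

Recovery on synthetic cohorts is scored by the adjusted Rand index between
planted labels and found clusters, computed on non-singleton examples only:
leaving a noise example unclustered is the desired outcome, and the
unclustered pool is judged separately (at signal 0 the expected modal
outcome is all-singletons, and the suite asserts a predominantly singleton
result).  Cluster profiling reports descriptive statistics only — per-cluster
means of numeric attributes over non-missing member values, category
frequencies, and contingency counts against a held-out label; significance
testing across clusters is deliberately out of scope.

## Known limitations

- Cost per iteration is quadratic in the number of clusters (cubic overall
  in the worst case); suitable up to a few thousand examples, not beyond.
- Narrow layers (< 5 attributes) give unreliable similarity estimates; the
  reader warns but does not refuse.
- Duplicated attributes (or near-copies) inflate co-coverage and hence
  similarity; the layer mechanism is the intended mitigation, not an
  automatic defence.
- The EST is a stochastic estimate; very small ensembles produce noisy
  similarities and unstable small clusters.  Ensemble size trades compute
  for stability.
- The merge path is greedy; it commits to the best immediate gain and never
  revisits, so it explores one branch of the merge hierarchy only.
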