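# Methods

## The harmonization model

A study variable is represented by the concatenation of three vectors:

* two semantic embeddings of its cleaned description (`VAR_coder`,
  `VAR_sapbert`), produced by interchangeable backends satisfying a
  determinism contract (same text → same vector, fixed dimension);
* a distribution vector `VAR_dist`: for each anchor subgroup populated in
  the cohort, the 25th/50th/75th percentiles of the variable's patient-level
  values, stacked in a canonical order (age bucket ascending, then race,
  then sex, in schema order).

Before concatenation each segment is divided by its own maximum absolute
component, bounding all entries to [−1, 1] so no segment dominates by scale
alone. The working assumption is that variables encoding the same concept
have both similar wording and similar patient-value distributions, and that
the two signals fail in different places: wording collides across distinct
concepts (or diverges across aliases of one concept), while distributions
are insensitive to wording but blur when concepts share similar values.

Similarity between two variables is the cosine of their fused vectors. For
intercohort tasks `VAR_dist` is first restricted to the subgroups populated
in both cohorts so the vectors align positionally; intracohort tasks keep
all populated subgroups. The fused dimension *d* therefore varies by cohort
pair, and all fused objects (and the supervised matrix below) are scoped to
one comparison task.

### Supervised alignment

A *d×d* matrix **M** refines the fused space using gold-standard pairs. It
is identity-initialized — so zero training epochs reproduce the unsupervised
method exactly — and applied with the row-vector convention `x·M`. Training
minimizes a margin contrastive loss: for each positive pair (i, j) and each
of `n_negatives` sampled partners k of the anchor i,

    loss = mean over positives of Σ_k max(0, cos(x_iM, x_kM) − cos(x_iM, x_jM) + margin)

by full-batch gradient descent with analytic gradients (verified against
finite differences in the test suite). Negative partners are sampled once
per run (seeded) from the anchor's candidate scope — the opposite cohort for
intercohort tasks, all variables for intracohort tasks — excluding gold
partners, so the descent runs on a fixed deterministic objective and the
loss trace is monotone for a stable step size. "Alignment matrix" here means
an unconstrained linear map; an optional orthogonality penalty
λ‖MᵀM − I‖²_F is available and off by default, since nothing in the scoring
requires orthogonality and the unconstrained map trains more freely.

Defaults: 100 epochs, learning rate 0.5 (the loss is averaged over positive
pairs, making the gradient scale insensitive to the number of gold pairs;
0.5 gives a steadily decreasing trace without oscillation on benchmark-sized
tasks), margin 0.2, 5 negatives per positive. All are exposed in
`TrainingConfig`.

Evaluation of the supervised method uses 2-fold cross-validation split **by
concept** (never by pair, so no concept leaks across folds; the split is
seeded). The matrix trained on one fold scores the other fold's positive
pairs, so every positive pair is scored exactly once by a matrix that never
saw its concept; non-gold pairs take the average of the two matrices'
scores. The matrix is trained per comparison task because *d* varies with
the shared-subgroup restriction.

## Preprocessing

Filters run in a fixed order for deterministic audit logs (the survivor set
itself is order-invariant for the per-variable value filters):

1. **continuous flag** — only variables marked continuous in the metadata;
2. **subgroup completeness** — a variable must have ≥1 observed value in
   every subgroup populated in its cohort (subgroups with no patients are
   ignored, so sparse cohorts are not penalised for cells they lack);
3. **non-zero values** — variables whose observed values are uniformly zero
   carry no distributional information and are dropped;
4. **consolidation** — same-cohort variables with identical cleaned
   descriptions (case-folded, whitespace-collapsed) merge into one entity
   keyed by the smallest accession, with the element-wise mean of their
   distribution vectors. Cross-cohort duplicates are never merged. Gold
   labels are re-keyed onto the representatives.

Description cleaning removes temporal measurement phrases: occurrences of
`<term> <number|ordinal>` or `<number|ordinal> <term>` with surrounding
punctuation, for the configurable term list {visit, exam, year, baseline,
follow-up, day}. The matching grammar accepts digits, `1st`-style ordinals
and the word ordinals/cardinals up to ten. Only spans are removed and
whitespace is collapsed, so cleaning never lengthens a description.

## Numerical choices

* Quantiles use linear interpolation between closest order statistics
  (numpy's default, "type 7"); a single observation yields (v, v, v).
* Ages are floored to whole years before bucketing; the default buckets are
  ≤59, 60–69, 70–79, ≥80. Negative ages are rejected.
* A subgroup counts as populated with ≥1 patient (configurable).
* Max-abs normalization leaves the all-zero vector unchanged (relevant for
  empty descriptions under the fallback backend; after fusion the other
  segments keep the vector informative).
* Cosine of a zero-norm vector is defined as 0.
* Top-k ranking breaks score ties by ascending accession, making reports
  deterministic; for intracohort mappings the query itself is excluded from
  its candidate list (with exact duplicates already consolidated, including
  the query would only inflate self-retrieval).
* In the evaluation pipeline k is capped at the number of available
  candidates (small synthetic cohorts can have fewer than 20 candidates);
  the metric-level function instead rejects an out-of-range k.
* Concept-level AUC is the rank-based (Mann–Whitney) estimator with ties
  counted ½; negatives are drawn without replacement, per concept, from
  pairs joining a gold variable of the concept to a non-partner candidate
  within the comparison's scope. Three samplings are averaged. Hard concepts
  are those with benchmark semantic AUC strictly below 0.900.
* Every random draw (simulation, negative sampling, fold split, training)
  flows from one root seed through named substreams, so whole runs are
  bit-reproducible with the built-in backend.

## The synthetic generator

`sonar.simulate` generates the study conditions the pipeline is tested
under: 3 cohorts, 40 shared concepts realised as 1–3 variables per cohort,
30 singleton distractor variables per cohort, 500 patients per cohort, and a
populated-subgroup pattern of 12/16/6 cells with a single-sex third cohort
(so the shared-subgroup restriction and single-sex arithmetic are exercised,
mirroring the coverage heterogeneity of real cohort collections).

Values for a concept follow a Gaussian per (subgroup, cohort): concept
levels are log-uniform over (0.5, 500) — lab-style quantities span orders of
magnitude — with a coefficient of variation drawn from (0.2, 1.2) and
age/race/sex effects, cohort shifts and per-variable assay offsets all
proportional to the level (defaults 0.30, 0.08, 0.08, 0.05, 0.15). The
per-variable offset reflects that same-concept variables measured with
different assays or units do not share identical raw values; it is what
keeps distribution learning imperfect, as in real data. A log-normal
heavy-tail option exists for robustness experiments. Missingness is 2%
completely at random, plus structurally absent subgroups from the cohort
masks.

Descriptions are built from a (context, root, measure) template per concept
with synonym swaps (rate 0.5), abbreviation (0.2), token reordering (0.3)
and appended temporal phrases (0.5). `make_hard_concepts(config, fraction)`
designates concept *pairs* that share a near-identical template (roots
differing in one character) while each member is additionally known under an
unrelated alias used by about half its variables — the "CRP vs C-reactive
protein" situation. Their value distributions are pushed ≥4 pooled-SD apart.
This makes purely semantic AUC degrade on those concepts while
distribution-based AUC is unaffected, which is exactly the regime where
fusing the signals pays off.

What the generator does **not** emulate: real dbGaP vocabulary and
questionnaire phrasing, informative missingness, categorical variables,
unit conversions that change distribution *shape* (only location offsets are
modelled), and correlations between concepts. Passing tests therefore show
that the pipeline recovers structure of this kind when present; they do not
certify performance numbers on any real cohort collection.

## Scale of the shipped experiments

The default benchmark (10 replicates of the 3×40×500 configuration) and the
in-repo lexical backends at dimension 256 keep the full test suite under two
minutes and the acceptance script under ten seconds on one CPU, while
preserving the segment-weight proportions of production-size semantic
embeddings (two 768-dim model segments vs a ≤48-dim distribution segment):
after max-abs normalization a segment's norm grows like √(d / 2 ln d), so a
256-dim semantic segment relates to the distribution segment roughly as the
full-size models would.

## Known limitations

* The supervised step assumes gold pairs exist for at least two concepts in
  scope; with a single labelled concept cross-validation refuses to run.
* Variables missing an entire populated subgroup are dropped rather than
  compared on partial vectors (distribution vectors of differing lengths
  within one cohort are not supported).
* Only continuous variables are handled; categorical distribution encodings
  are out of scope.
* The deterministic lexical backend measures surface similarity only; true
  synonymy without character overlap is invisible to it. Plugging in
  transformer backends changes that but breaks bit-reproducibility across
  hardware.
* With very small candidate pools the negative sampler for the concept AUC
  requires the pool to be at least as large as the positive set and errors
  otherwise.
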