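# sonar-harmonize

Semantic and distribution-based harmonization of study variables across
cohort studies.

Multicohort epidemiological studies need to know which variables in different
(or the same) cohorts encode the same underlying concept — "LDL cholesterol,
visit 2" in one study and "Exam 3: serum LDL" in another. Manual curation of
thousands of dbGaP-style variables is slow and error-prone. This package
scores candidate variable pairs automatically by fusing two complementary
signals:

1. **Semantic learning** — embedding vectors of the cleaned variable
   descriptions (`VAR_coder`, `VAR_sapbert`) from pluggable text-embedding
   backends. A deterministic character n-gram backend ships in-repo so the
   whole pipeline runs without model weights or downloads; adapters for
   transformer models can be plugged in through the same interface.
2. **Distribution learning** — a quartile distribution vector (`VAR_dist`)
   built from patient-level values: patients are partitioned into anchor
   subgroups (4 age buckets × 2 races × 2 sexes by default, 16 cells) and the
   per-subgroup (q25, q50, q75) are stacked, giving up to 48 dimensions. For
   intercohort comparisons only subgroups populated in *both* cohorts are
   kept, so vectors stay positionally aligned.

Each segment is max-abs normalized (every component in [−1, 1]) and
concatenated into `VAR_concat` of dimension *d*. The similarity of two
variables is the cosine of their fused vectors. Optionally a supervised
*d×d* alignment matrix **M** (identity-initialized, applied as `x·M`) is
trained by gradient descent on a margin contrastive loss over gold-standard
pairs, evaluated with 2-fold cross-validation split by concept.

Evaluation follows the concept-level protocol: per-concept AUC against an
equal number of sampled negative pairs (3 samplings averaged), "hard"
concepts defined by a benchmark semantic AUC strictly below 0.900, and
directional top-k accuracy (acc@k for k ∈ {1, 3, 5, 10, 20}) aggregated per
concept, then per mapping level (intracohort / intercohort / overall).

A first-class synthetic multi-cohort generator (`sonar.simulate`) emulates
the relevant structure of real cohort collections — shared latent concepts,
cohort-specific lexical variants and temporal phrases, subgroup-structured
value distributions with cohort shifts, missing subgroups, single-sex
cohorts, and lexically colliding "hard" concept pairs — so every claim is
testable end to end.

## Worked example

```python
from sonar import SimulationConfig, make_hard_concepts, simulate
from sonar import pipeline

config = make_hard_concepts(SimulationConfig(seed=1), 0.3)
dataset = simulate(config)
cohorts = {
    cid: pipeline.prepare_cohort(
        dataset.records(cid), dataset.patient_table(cid), config.schema
    )
    for cid in dataset.cohort_ids
}
report = pipeline.run_benchmark(
    cohorts, dataset.gold,
    methods=("sapbert", "dist", "concat", "supervised"), seed=1,
)
for method in ("sapbert", "dist", "concat", "supervised"):
    print(
        f"{method:<11} AUC={report.auc_overall(method):.3f} "
        f"hard={report.auc_hard(method):.3f} "
        f"acc@10={report.acc[method].aggregate('overall', 10):.3f}"
    )
```

prints

```
sapbert     AUC=0.960 hard=0.673 acc@10=0.924
dist        AUC=0.951 hard=0.931 acc@10=0.898
concat      AUC=0.974 hard=0.913 acc@10=0.941
supervised  AUC=0.980 hard=0.891 acc@10=0.956
```

Reading: a single semantic backend collapses on hard concepts (AUC 0.673) —
concepts whose descriptions collide lexically with a different concept or use
unrelated aliases. Distribution vectors barely notice (0.931), because the
colliding concepts have distinct value distributions. Fusing both signals
(`concat`) beats either component overall, and supervised alignment improves
the overall AUC and top-k retrieval further.

The same workflow is available from the shell:

```bash
sonar simulate --seed 1 --hard-fraction 0.3 --out data/
sonar preprocess --dictionary data/STUDY1_dictionary.csv \
    --patients data/STUDY1_patients.csv --cohort-id STUDY1 --out prep/
sonar harmonize --data-dir data/ --seed 1 --out run/
sonar evaluate --scores run/similarities/STUDY1__STUDY2__concat.csv \
    --gold data/gold_standard.csv --intercohort --out eval.json
```

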