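"""End-to-end harmonization pipeline.

Wires the modules into the method's workflow: preprocess each cohort (filters,
distribution vectors, consolidation), embed descriptions, fuse segments per
comparison, score variable pairs by cosine similarity (optionally through the
cross-validated supervised alignment), and evaluate concept AUC and acc@k over
all intracohort and intercohort comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import cohort_io, distribution, evaluation, fusion, semantic
from .cohort_io import GoldStandard, PatientTable, VariableRecord
from .distribution import DistributionVector, SubgroupSchema
from .errors import ValidationError
from .fusion import TaskEmbeddings, TrainingConfig, derive_seed

log = logging.getLogger(__name__)

#: Method variants: single semantic backends, distribution only, the fused
#: semantic pair, the unsupervised concatenation, and the supervised method.
METHODS = ("coder", "sapbert", "biobert", "dist", "semantic", "concat", "supervised")

_METHOD_ALIASES = {"sonar-supervised": "supervised", "sonar": "concat"}


def canonical_method(name: str) -> str:
    method = _METHOD_ALIASES.get(name, name)
    if method not in METHODS:
        raise ValidationError(f"unknown method {name!r}; choose from {METHODS}")
    return method


@dataclass
class CohortData:
    """One cohort after preprocessing."""

    cohort_id: str
    records: list[VariableRecord]
    dist_vectors: dict[str, DistributionVector]
    populated: tuple
    merge_map: dict[str, str]
    audit: dict[str, int]

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(sorted(r.variable_accession for r in self.records))


def prepare_cohort(
    records: Sequence[VariableRecord],
    table: PatientTable,
    schema: SubgroupSchema,
    min_patients: int = 1,
) -> CohortData:
    """Apply the filter pipeline and build distribution vectors.

    Order: continuous flag -> subgroup completeness -> non-zero values ->
    consolidation of identical descriptions.  The audit dict counts variables
    removed by each rule (the survivor set itself is order-invariant for the
    two per-variable value filters).
    """
    audit: dict[str, int] = {"input": len(records)}
    continuous = cohort_io.filter_continuous(records)
    audit["not_continuous"] = len(records) - len(continuous)

    in_table = [
        r for r in continuous if r.variable_accession in set(table.variable_columns)
    ]
    audit["no_patient_data"] = len(continuous) - len(in_table)

    complete = cohort_io.filter_complete_subgroups(table, schema, min_patients)
    after_complete = [r for r in in_table if r.variable_accession in complete]
    audit["incomplete_subgroups"] = len(in_table) - len(after_complete)

    nonzero = cohort_io.filter_nonzero(
        table, [r.variable_accession for r in after_complete]
    )
    after_nonzero = [r for r in after_complete if r.variable_accession in nonzero]
    audit["uniformly_zero"] = len(after_complete) - len(after_nonzero)

    vectors, populated = distribution.build_distribution_vectors(
        table,
        [r.variable_accession for r in after_nonzero],
        schema,
        min_patients,
    )
    merged = cohort_io.consolidate_identical(after_nonzero, vectors)
    audit["consolidated"] = len(after_nonzero) - len(merged.records)
    audit["output"] = len(merged.records)

    return CohortData(
        cohort_id=table.cohort_id,
        records=merged.records,
        dist_vectors=merged.dist_vectors,
        populated=tuple(populated),
        merge_map=merged.merge_map,
        audit=audit,
    )


def load_cohort(
    dictionary_path, patients_path, cohort_id: str, schema: SubgroupSchema
) -> CohortData:
    records = cohort_io.read_dictionary(dictionary_path, cohort_id)
    table = cohort_io.read_patient_table(patients_path, cohort_id)
    return prepare_cohort(records, table, schema)


def remap_gold(gold: GoldStandard, cohorts: Mapping[str, CohortData]) -> GoldStandard:
    """Re-key gold labels onto consolidation representatives."""
    merge_map: dict[str, str] = {}
    for cohort in cohorts.values():
        merge_map.update(cohort.merge_map)
    return gold.remapped(merge_map)


def compute_semantic_embeddings(
    cohorts: Mapping[str, CohortData],
    backends: Mapping[str, semantic.EmbeddingBackend] | None = None,
) -> dict[str, dict[str, semantic.EmbeddingSet]]:
    """Per-cohort, per-backend semantic embeddings of the cleaned descriptions."""
    backends = backends if backends is not None else semantic.default_backends()
    out: dict[str, dict[str, semantic.EmbeddingSet]] = {}
    for cohort_id in sorted(cohorts):
        out[cohort_id] = {
            role: semantic.embed_descriptions(cohorts[cohort_id].records, backend)
            for role, backend in backends.items()
        }
    return out


def _method_segments(method: str) -> tuple[list[str], bool]:
    """Semantic backend roles and whether the distribution segment is used."""
    if method in ("coder", "sapbert", "biobert"):
        return [method], False
    if method == "dist":
        return [], True
    if method == "semantic":
        return ["coder", "sapbert"], False
    if method in ("concat", "supervised"):
        return ["coder", "sapbert"], True
    raise ValidationError(f"unknown method {method!r}")


def comparison_embeddings(
    coh_a: CohortData,
    coh_b: CohortData,
    embeddings: Mapping[str, Mapping[str, semantic.EmbeddingSet]],
    method: str,
) -> tuple[TaskEmbeddings, TaskEmbeddings]:
    """Task-scoped fused embeddings for both sides of a comparison.

    For intercohort comparisons the distribution segment is restricted to the
    subgroups populated in both cohorts; intracohort comparisons keep all of
    the cohort's populated subgroups.
    """
    roles, use_dist = _method_segments(canonical_method(method))
    intracohort = coh_a.cohort_id == coh_b.cohort_id
    if use_dist and not intracohort:
        shared = distribution.shared_labels(coh_a.populated, coh_b.populated)
    else:
        shared = None

    def build(cohort: CohortData) -> TaskEmbeddings:
        accessions = cohort.accessions
        segments: list[tuple[str, Mapping[str, np.ndarray]]] = []
        for role in roles:
            segments.append(
                (role, embeddings[cohort.cohort_id][role].vectors)
            )
        if use_dist:
            vectors = {}
            for acc in accessions:
                vec = cohort.dist_vectors[acc]
                if shared is not None:
                    vec = distribution._restrict(vec, shared)
                vectors[acc] = vec.flat
            segments.append(("dist", vectors))
        return fusion.build_task_embeddings(accessions, segments)

    emb_a = build(coh_a)
    emb_b = emb_a if intracohort else build(coh_b)
    return emb_a, emb_b


def comparison_scores(
    coh_a: CohortData,
    coh_b: CohortData,
    embeddings,
    gold: GoldStandard,
    method: str,
    training: TrainingConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, TaskEmbeddings, TaskEmbeddings]:
    """Similarity matrix for one comparison under one method variant."""
    method = canonical_method(method)
    emb_a, emb_b = comparison_embeddings(coh_a, coh_b, embeddings, method)
    intracohort = coh_a.cohort_id == coh_b.cohort_id
    if method != "supervised":
        scores = fusion.cosine_matrix(emb_a.X, emb_b.X)
    else:
        training = training if training is not None else TrainingConfig()
        pairs = gold.positive_pairs(emb_a.accessions, emb_b.accessions, intracohort)
        config = TrainingConfig(
            epochs=training.epochs,
            learning_rate=training.learning_rate,
            margin=training.margin,
            n_negatives=training.n_negatives,
            seed=derive_seed(seed, "cv", coh_a.cohort_id, coh_b.cohort_id),
            ortho_penalty=training.ortho_penalty,
            n_folds=training.n_folds,
        )
        result = fusion.crossval_scores(emb_a, emb_b, pairs, config, intracohort)
        scores = result.scores
    return scores, emb_a, emb_b


def negative_pools(
    gold: GoldStandard,
    accessions_a: Sequence[str],
    accessions_b: Sequence[str],
    intracohort: bool,
) -> dict[str, list[tuple[int, int]]]:
    """Per-concept negative candidate pairs (index pairs into the score matrix).

    A negative joins a gold variable of the concept to any in-scope candidate
    that is not one of its gold partners (i.e. not of the same concept).
    """
    index_a = {a: i for i, a in enumerate(accessions_a)}
    index_b = {b: i for i, b in enumerate(accessions_b)}
    pools: dict[str, list[tuple[int, int]]] = {}
    for concept in sorted(gold.assignments):
        members = gold.assignments[concept]
        pool: list[tuple[int, int]] = []
        for a in sorted(members & set(accessions_a)):
            ia = index_a[a]
            for b in accessions_b:
                if b == a or b in members:
                    continue
                pool.append((ia, index_b[b]))
        if not intracohort:
            # queries anchored on the B side, scored through the same matrix
            for b in sorted(members & set(accessions_b)):
                ib = index_b[b]
                for a in accessions_a:
                    if a == b or a in members:
                        continue
                    pool.append((index_a[a], ib))
        if pool:
            pools[concept] = pool
    return pools


@dataclass
class ComparisonResult:
    cohort_a: str
    cohort_b: str
    method: str
    scores: np.ndarray
    accessions_a: tuple[str, ...]
    accessions_b: tuple[str, ...]
    auc: evaluation.ConceptAUCReport


@dataclass
class BenchmarkReport:
    """All comparisons x methods: AUC reports and acc@k tables."""

    comparisons: dict[tuple[str, str, str], ComparisonResult] = field(
        default_factory=dict
    )
    acc: dict[str, evaluation.AccAtKReport] = field(default_factory=dict)
    hard_sets: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def auc_overall(self, method: str) -> float:
        values = [
            r.auc.overall
            for (a, b, m), r in sorted(self.comparisons.items())
            if m == method
        ]
        return float(np.mean(values))

    def auc_mean_over_concepts(self, method: str, concepts) -> float | None:
        values = []
        for (_a, _b, m), r in sorted(self.comparisons.items()):
            if m != method:
                continue
            mean = r.auc.mean_over(concepts)
            if mean is not None:
                values.append(mean)
        return float(np.mean(values)) if values else None

    def auc_hard(self, method: str) -> float | None:
        """Mean over comparisons of the hard-concept AUC (benchmark-defined)."""
        values = []
        for (a, b, m), r in sorted(self.comparisons.items()):
            if m != method:
                continue
            hard = self.hard_sets.get((a, b), frozenset())
            mean = r.auc.mean_over(hard)
            if mean is not None:
                values.append(mean)
        return float(np.mean(values)) if values else None


def run_benchmark(
    cohorts: Mapping[str, CohortData],
    gold: GoldStandard,
    methods: Sequence[str] = ("sapbert", "dist", "semantic", "concat", "supervised"),
    seed: int = 0,
    ks: Sequence[int] = (1, 3, 5, 10, 20),
    auc_repeats: int = 3,
    hard_threshold: float = 0.900,
    training: TrainingConfig | None = None,
    backends: Mapping[str, semantic.EmbeddingBackend] | None = None,
    benchmark_method: str = "sapbert",
) -> BenchmarkReport:
    """Run every comparison and mapping for the requested method variants.

    Comparisons are the 3 intracohort and 3 unordered intercohort pairs (for
    3 cohorts); acc@k mappings additionally include both directions of each
    intercohort pair.  Hard concepts are defined per comparison from the
    benchmark method's concept AUCs (strictly below ``hard_threshold``), so
    the benchmark method is always evaluated even if not requested.
    """
    methods = [canonical_method(m) for m in methods]
    eval_methods = list(dict.fromkeys([benchmark_method, *methods]))
    gold = remap_gold(gold, cohorts)
    embeddings = compute_semantic_embeddings(cohorts, backends)

    ids = sorted(cohorts)
    comparison_pairs = [(c, c) for c in ids] + [
        (a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]
    ]

    report = BenchmarkReport()
    acc_reports = {
        m: evaluation.AccAtKReport(
            per_mapping={}, intracohort_mappings=tuple((c, c) for c in ids), ks=tuple(ks)
        )
        for m in methods
    }

    for cohort_a, cohort_b in comparison_pairs:
        coh_a, coh_b = cohorts[cohort_a], cohorts[cohort_b]
        intracohort = cohort_a == cohort_b
        for method in eval_methods:
            scores, emb_a, emb_b = comparison_scores(
                coh_a,
                coh_b,
                embeddings,
                gold,
                method,
                training=training,
                seed=seed,
            )
            pairs = gold.positive_pairs(
                emb_a.accessions, emb_b.accessions, intracohort
            )
            index_a = {a: i for i, a in enumerate(emb_a.accessions)}
            index_b = {b: i for i, b in enumerate(emb_b.accessions)}
            pair_idx = {
                c: [(index_a[a], index_b[b]) for a, b in ps]
                for c, ps in pairs.items()
            }
            pools = negative_pools(
                gold, emb_a.accessions, emb_b.accessions, intracohort
            )
            auc = evaluation.evaluate_concept_auc(
                scores,
                pair_idx,
                pools,
                n_repeats=auc_repeats,
                seed=derive_seed(seed, "auc", cohort_a, cohort_b, method),
            )
            if method in methods:
                report.comparisons[(cohort_a, cohort_b, method)] = ComparisonResult(
                    cohort_a,
                    cohort_b,
                    method,
                    scores,
                    emb_a.accessions,
                    emb_b.accessions,
                    auc,
                )
            if method == benchmark_method:
                report.hard_sets[(cohort_a, cohort_b)] = evaluation.hard_concepts(
                    auc.concept_auc, hard_threshold
                )
            if method in methods:
                mappings = [(cohort_a, cohort_b, scores, emb_a, emb_b)]
                if not intracohort:
                    mappings.append((cohort_b, cohort_a, scores.T, emb_b, emb_a))
                for m_a, m_b, m_scores, m_emb_a, m_emb_b in mappings:
                    for k in ks:
                        per_concept = evaluation.acc_at_k(
                            m_scores,
                            m_emb_a.accessions,
                            m_emb_b.accessions,
                            gold,
                            k=min(
                                k,
                                len(m_emb_b.accessions) - (1 if intracohort else 0),
                            ),
                            intracohort=intracohort,
                        )
                        acc_reports[method].per_mapping[(m_a, m_b, k)] = per_concept

    # attach hard sets to AUC reports for convenience
    for (a, b, m), result in report.comparisons.items():
        result.auc.hard_set = report.hard_sets.get((a, b))
    report.acc = acc_reports
    return report
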