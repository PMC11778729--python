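"""Concept-level AUC, hard-concept AUC, and directional top-k accuracy.

AUC: for each underlying concept, the gold pairs in the comparison's scope are
the positives; an equal number of negatives is sampled (without replacement,
seeded) from pairs joining a gold variable of the concept to a non-partner
candidate, and the rank-based (Mann-Whitney, ties counted 1/2) AUC is computed.
This is repeated for 3 negative samplings and averaged, then concept AUCs are
averaged into the overall AUC.  Hard concepts are those whose benchmark
(SapBERT-role) AUC falls strictly below 0.900.

acc@k: for a directed mapping A -> B, a gold query variable ``a`` scores a hit
when its top-k most-similar candidates in B (ties broken by accession; the
query itself excluded for intracohort mappings) intersect its gold partners.
Per-concept acc@k divides hits by the concept's gold variable count in A.
Aggregation is two-stage: per concept, mean over the mappings where the
concept has gold pairs; then mean over concepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError


def mann_whitney_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Rank-based AUC of positives vs negatives; ties count one half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("AUC requires at least one positive and one negative")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def concept_auc(
    pos_scores: Sequence[float],
    negative_pool: Sequence[float],
    n_repeats: int = 3,
    seed: int = 0,
) -> float:
    """Mean AUC over ``n_repeats`` equal-size negative samplings.

    Each repeat samples ``len(pos_scores)`` negatives without replacement
    from the pool; sampling is seeded so reports are reproducible.
    """
    pos = np.asarray(pos_scores, dtype=float)
    pool = np.asarray(negative_pool, dtype=float)
    if pos.size == 0:
        raise ValidationError("concept has no positive pairs")
    if pool.size < pos.size:
        raise ValidationError(
            f"negative pool ({pool.size}) smaller than positives ({pos.size})"
        )
    rng = np.random.default_rng(seed)
    aucs = [
        mann_whitney_auc(pos, rng.choice(pool, size=pos.size, replace=False))
        for _ in range(n_repeats)
    ]
    return float(np.mean(aucs))


@dataclass
class ConceptAUCReport:
    """Concept-level and aggregate AUCs for one comparison."""

    concept_auc: dict[str, float]
    seed: int
    n_repeats: int
    hard_set: frozenset[str] | None = None

    @property
    def overall(self) -> float:
        return float(np.mean(list(self.concept_auc.values())))

    def mean_over(self, concepts) -> float | None:
        values = [self.concept_auc[c] for c in concepts if c in self.concept_auc]
        return float(np.mean(values)) if values else None

    @property
    def hard(self) -> float | None:
        if not self.hard_set:
            return None
        return self.mean_over(self.hard_set)


def evaluate_concept_auc(
    scores: np.ndarray,
    pairs_by_concept: Mapping[str, Sequence[tuple[int, int]]],
    negatives_by_concept: Mapping[str, Sequence[tuple[int, int]]],
    n_repeats: int = 3,
    seed: int = 0,
) -> ConceptAUCReport:
    """Concept AUC report from a score matrix and index-pair scopes."""
    per_concept: dict[str, float] = {}
    for concept in sorted(pairs_by_concept):
        positives = pairs_by_concept[concept]
        pool = negatives_by_concept.get(concept, ())
        pos_scores = [scores[i, j] for i, j in positives]
        pool_scores = [scores[i, j] for i, j in pool]
        per_concept[concept] = concept_auc(
            pos_scores,
            pool_scores,
            n_repeats=n_repeats,
            seed=_concept_seed(seed, concept),
        )
    return ConceptAUCReport(per_concept, seed=seed, n_repeats=n_repeats)


def _concept_seed(seed: int, concept: str) -> int:
    import zlib

    return int((seed * 0x9E3779B1 + zlib.crc32(concept.encode())) % (2**31 - 1))


def hard_concepts(
    benchmark_auc: Mapping[str, float], threshold: float = 0.900
) -> frozenset[str]:
    """Concepts whose benchmark AUC is strictly below the threshold."""
    return frozenset(c for c, auc in benchmark_auc.items() if auc < threshold)


def acc_at_k(
    scores: np.ndarray,
    accessions_a: Sequence[str],
    accessions_b: Sequence[str],
    gold,
    k: int,
    intracohort: bool,
) -> dict[str, float]:
    """Per-concept top-k accuracy for the directed mapping A -> B.

    ``scores[i, j]`` is the similarity between ``accessions_a[i]`` and
    ``accessions_b[j]``.  The query itself is excluded from its candidate
    ranking for intracohort mappings.  Concepts without gold pairs in this
    mapping are omitted.
    """
    n_candidates = len(accessions_b) - (1 if intracohort else 0)
    if k < 1 or k > n_candidates:
        raise ValidationError(
            f"k={k} outside the valid range 1..{n_candidates} for this mapping"
        )
    index_a = {a: i for i, a in enumerate(accessions_a)}
    set_a = set(accessions_a)
    set_b = set(accessions_b)
    result: dict[str, float] = {}
    for concept in sorted(gold.assignments):
        members = gold.assignments[concept]
        queries = sorted(members & set_a)
        partners_b = members & set_b
        if not queries:
            continue
        hits = 0
        any_pair = False
        for a in queries:
            ia = index_a[a]
            gold_partners = {b for b in partners_b if b != a}
            if not gold_partners:
                continue
            any_pair = True
            row = scores[ia]
            ranked = sorted(
                range(len(accessions_b)),
                key=lambda j: (-row[j], accessions_b[j]),
            )
            top: list[str] = []
            for j in ranked:
                b = accessions_b[j]
                if intracohort and b == a:
                    continue
                top.append(b)
                if len(top) == k:
                    break
            if gold_partners & set(top):
                hits += 1
        if any_pair:
            result[concept] = hits / len(queries)
    return result


def aggregate_acc(
    per_mapping_concept: Mapping[str, Mapping[str, float]]
) -> float | None:
    """Two-stage mean: per concept over its relevant mappings, then over concepts."""
    concepts: dict[str, list[float]] = {}
    for _mapping, per_concept in sorted(per_mapping_concept.items()):
        for concept, value in per_concept.items():
            concepts.setdefault(concept, []).append(value)
    if not concepts:
        return None
    return float(
        np.mean([np.mean(values) for _, values in sorted(concepts.items())])
    )


@dataclass
class AccAtKReport:
    """acc@k per (mapping, concept, k) plus the three-level aggregates."""

    per_mapping: dict[tuple[str, str, int], dict[str, float]] = field(
        default_factory=dict
    )
    intracohort_mappings: tuple = ()
    ks: tuple[int, ...] = (1, 3, 5, 10, 20)

    def aggregate(self, level: str, k: int) -> float | None:
        """``level`` is 'intracohort', 'intercohort' or 'overall'."""
        selected = {}
        for (a, b, kk), per_concept in self.per_mapping.items():
            if kk != k:
                continue
            intra = (a, b) in self.intracohort_mappings or a == b
            if level == "intracohort" and not intra:
                continue
            if level == "intercohort" and intra:
                continue
            selected[f"{a}->{b}"] = per_concept
        return aggregate_acc(selected)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b, k), per_concept in sorted(self.per_mapping.items()):
            for concept, value in sorted(per_concept.items()):
                rows.append(
                    {
                        "cohort_a": a,
                        "cohort_b": b,
                        "k": k,
                        "concept_id": concept,
                        "acc_at_k": value,
                    }
                )
        return pd.DataFrame(
            rows, columns=["cohort_a", "cohort_b", "k", "concept_id", "acc_at_k"]
        )
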