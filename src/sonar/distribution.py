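"""Anchor subgroups and quartile distribution vectors.

Patients are partitioned into subgroups by the anchor covariates age, race and
sex (default: 4 age buckets x 2 races x 2 sexes = 16 cells).  A variable's
distribution vector stacks the within-subgroup quartiles (25th, 50th, 75th
percentiles) over the cohort's populated subgroups in a canonical order, giving
a vector of length ``3 * n_subgroups`` (up to 48 under the default schema).
For an intercohort comparison both cohorts' vectors are restricted to the
subgroups populated in both, so they stay positionally aligned.

Quartiles use linear interpolation between closest order statistics (numpy's
default, the "type 7" convention); ages are floored to integer years before
bucketing.  Neither choice is dictated by the data model — both are fixed here
for reproducibility.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

SubgroupLabel = tuple[str, str, str]  # (age bucket, race, sex)


@dataclass(frozen=True)
class SubgroupSchema:
    """Partition of patients by age bucket x race x sex.

    ``age_edges`` are the lower bounds of every bucket after the first: the
    default ``(60, 70, 80)`` yields buckets <=59, 60-69, 70-79, >=80.
    """

    age_edges: tuple[int, ...] = (60, 70, 80)
    race_categories: tuple[str, ...] = ("White", "Black")
    sex_categories: tuple[str, ...] = ("female", "male")

    def __post_init__(self):
        if not self.age_edges or list(self.age_edges) != sorted(set(self.age_edges)):
            raise ValidationError("age_edges must be strictly increasing and non-empty")
        if not self.race_categories or not self.sex_categories:
            raise ValidationError("race and sex categories must be non-empty")

    @property
    def age_labels(self) -> tuple[str, ...]:
        labels = [f"<={self.age_edges[0] - 1}"]
        for low, high in zip(self.age_edges, self.age_edges[1:]):
            labels.append(f"{low}-{high - 1}")
        labels.append(f">={self.age_edges[-1]}")
        return tuple(labels)

    @property
    def n_subgroups(self) -> int:
        return len(self.age_labels) * len(self.race_categories) * len(self.sex_categories)

    def labels(self) -> list[SubgroupLabel]:
        """All subgroup labels in canonical order (age, then race, then sex)."""
        return [
            (age, race, sex)
            for age in self.age_labels
            for race in self.race_categories
            for sex in self.sex_categories
        ]

    def assign(self, age: float, race: str, sex: str) -> SubgroupLabel | None:
        """Deterministically place one patient; None if race/sex is unknown."""
        return assign_subgroup(age, race, sex, self)


def assign_subgroup(
    age: float, race: str, sex: str, schema: SubgroupSchema
) -> SubgroupLabel | None:
    """Map one patient's anchors to a subgroup label.

    Ages are floored to whole years.  Patients whose race or sex is outside
    the schema's categories return ``None`` and are excluded upstream (the
    schema is a closed partition only over its own categories).
    """
    if age < 0 or not math.isfinite(age):
        raise ValidationError(f"age must be a finite non-negative number, got {age!r}")
    if race not in schema.race_categories or sex not in schema.sex_categories:
        return None
    bucket = bisect_right(schema.age_edges, math.floor(age))
    return (schema.age_labels[bucket], race, sex)


@dataclass(frozen=True)
class DistributionVector:
    """Ordered subgroup quartiles for one variable.

    ``quantiles`` has shape ``(n_subgroups, 3)`` holding (q25, q50, q75) per
    populated subgroup, rows following ``labels`` which follow the schema's
    canonical product order.
    """

    labels: tuple[SubgroupLabel, ...]
    quantiles: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.quantiles, dtype=float)
        object.__setattr__(self, "quantiles", q)
        if q.shape != (len(self.labels), 3):
            raise ValidationError(
                f"quantiles shape {q.shape} does not match {len(self.labels)} labels"
            )
        if np.any(np.diff(q, axis=1) < 0):
            raise ValidationError("quartiles must be non-decreasing within a subgroup")

    @property
    def flat(self) -> np.ndarray:
        """Flattened vector, length ``3 * n_subgroups``."""
        return self.quantiles.reshape(-1)


def compute_dist_vector(
    values_by_subgroup: Mapping[SubgroupLabel, Sequence[float]],
    populated_subgroups: Sequence[SubgroupLabel],
) -> DistributionVector:
    """Quartile distribution vector over the cohort's populated subgroups.

    Every populated subgroup must contribute at least one observed value
    (guaranteed upstream by the subgroup-completeness filter).
    """
    if not populated_subgroups:
        raise ValidationError("populated subgroup list is empty")
    rows = []
    for label in populated_subgroups:
        values = np.asarray(values_by_subgroup.get(label, ()), dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise ValidationError(f"no observed values in populated subgroup {label}")
        rows.append(np.quantile(values, (0.25, 0.5, 0.75), method="linear"))
    return DistributionVector(tuple(populated_subgroups), np.asarray(rows))


def shared_subgroup_restrict(
    vec_a: DistributionVector, vec_b: DistributionVector
) -> tuple[DistributionVector, DistributionVector]:
    """Restrict two cohorts' vectors to the subgroups present in both.

    Both inputs must already follow the schema's canonical order, so the
    intersection preserves it.  When the label sets coincide the inputs are
    returned unchanged (intracohort restriction is the identity).
    """
    if vec_a.labels == vec_b.labels:
        return vec_a, vec_b
    shared = shared_labels(vec_a.labels, vec_b.labels)
    return (
        _restrict(vec_a, shared),
        _restrict(vec_b, shared),
    )


def shared_labels(
    labels_a: Sequence[SubgroupLabel], labels_b: Sequence[SubgroupLabel]
) -> tuple[SubgroupLabel, ...]:
    set_b = set(labels_b)
    shared = tuple(label for label in labels_a if label in set_b)
    if not shared:
        raise ValidationError("cohorts share no populated subgroup")
    return shared


def _restrict(
    vec: DistributionVector, labels: Sequence[SubgroupLabel]
) -> DistributionVector:
    index = {label: i for i, label in enumerate(vec.labels)}
    rows = [index[label] for label in labels]
    return DistributionVector(tuple(labels), vec.quantiles[rows])


def populated_subgroups(
    table, schema: SubgroupSchema, min_patients: int = 1
) -> list[SubgroupLabel]:
    """Subgroups of a patient table with at least ``min_patients`` members."""
    counts: dict[SubgroupLabel, int] = {}
    for age, race, sex in zip(
        table.frame["age"], table.frame["race"], table.frame["sex"]
    ):
        label = assign_subgroup(age, race, sex, schema)
        if label is not None:
            counts[label] = counts.get(label, 0) + 1
    return [
        label for label in schema.labels() if counts.get(label, 0) >= min_patients
    ]


def build_distribution_vectors(
    table,
    accessions: Iterable[str],
    schema: SubgroupSchema,
    min_patients: int = 1,
) -> tuple[dict[str, DistributionVector], list[SubgroupLabel]]:
    """Distribution vectors for every accession of one cohort.

    Returns the vectors and the cohort's populated subgroup labels (canonical
    order).  Accessions must already have passed the completeness filter.
    """
    populated = populated_subgroups(table, schema, min_patients)
    if not populated:
        raise ValidationError(
            f"cohort {table.cohort_id!r} has no populated subgroup"
        )
    member_rows: dict[SubgroupLabel, np.ndarray] = {}
    assigned = [
        assign_subgroup(age, race, sex, schema)
        for age, race, sex in zip(
            table.frame["age"], table.frame["race"], table.frame["sex"]
        )
    ]
    assigned_arr = np.array(
        ["|".join(a) if a is not None else "" for a in assigned], dtype=object
    )
    for label in populated:
        member_rows[label] = np.flatnonzero(assigned_arr == "|".join(label))
    vectors: dict[str, DistributionVector] = {}
    for accession in sorted(accessions):
        column = table.frame[accession].to_numpy(dtype=float)
        values_by_subgroup = {
            label: column[rows] for label, rows in member_rows.items()
        }
        vectors[accession] = compute_dist_vector(values_by_subgroup, populated)
    return vectors, populated
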