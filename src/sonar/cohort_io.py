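"""Reading, cleaning and filtering of cohort variable metadata and patient tables.

A cohort ships two tabular text files: a *data dictionary* describing each study
variable (accession, name, free-text description, dataset accession, continuous
flag) and a *patient table* holding one row per participant with the anchor
covariates ``age``, ``race`` and ``sex`` plus one column per variable accession.
A third file assigns variables to underlying concepts (the gold standard).

Descriptions are cleaned by removing temporal measurement phrases ("visit 2",
"Exam 5:") so that the same concept measured at different visits compares equal.
Variables are then filtered (continuous flag, subgroup completeness, non-zero
values) and same-description variables within a cohort are consolidated into a
single entity whose distribution vector is the element-wise mean.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

log = logging.getLogger(__name__)

#: Terms that introduce a temporal measurement phrase when adjacent to a number
#: or ordinal.  Configurable; the matching grammar is documented in
#: :func:`strip_temporal`.
DEFAULT_TEMPORAL_TERMS = ("visit", "exam", "year", "baseline", "follow-up", "day")

_ORDINAL_WORDS = (
    "first|second|third|fourth|fifth|sixth|seventh|eighth|ninth|tenth"
)
_NUMBER = rf"(?:\d+(?:st|nd|rd|th)?|{_ORDINAL_WORDS})"

_DICTIONARY_COLUMNS = (
    "variable_accession",
    "variable_name",
    "description",
    "dataset_accession",
    "is_continuous",
)

ANCHOR_COLUMNS = ("age", "race", "sex")

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


@dataclass(frozen=True)
class VariableRecord:
    """One study variable's metadata after description cleaning."""

    variable_accession: str
    variable_name: str
    description_raw: str
    description_clean: str
    dataset_accession: str
    cohort_id: str
    is_continuous: bool

    def canonical_description(self) -> str:
        """Case-folded, whitespace-collapsed clean description (merge key)."""
        return " ".join(self.description_clean.lower().split())


@dataclass
class PatientTable:
    """Patient-level values for one cohort.

    ``frame`` is indexed by patient id with the anchor columns ``age``,
    ``race``, ``sex`` first, then one numeric column per variable accession.
    Rows missing any anchor have been dropped at read time.
    """

    cohort_id: str
    frame: pd.DataFrame

    @property
    def variable_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ANCHOR_COLUMNS]

    @property
    def n_patients(self) -> int:
        return len(self.frame)


class GoldStandard:
    """Concept -> variable assignments inducing gold-standard positive pairs."""

    def __init__(self, assignments: Mapping[str, Iterable[str]]):
        self.assignments: dict[str, frozenset[str]] = {
            c: frozenset(v) for c, v in assignments.items()
        }
        concept_of: dict[str, str] = {}
        for concept, accs in self.assignments.items():
            for acc in accs:
                if acc in concept_of and concept_of[acc] != concept:
                    raise ValidationError(
                        f"variable {acc!r} assigned to both concept "
                        f"{concept_of[acc]!r} and {concept!r}"
                    )
                concept_of[acc] = concept
        self.concept_of = concept_of

    @property
    def concepts(self) -> list[str]:
        return sorted(self.assignments)

    def remapped(self, merge_map: Mapping[str, str]) -> "GoldStandard":
        """Re-key assignments after consolidation merged accessions.

        Merged members inherit their representative's accession.  If a merge
        group spans two concepts the representative keeps whichever concept
        claims it directly (or the lexicographically first claim) and the
        conflict is logged; the alternative would silently double-label.
        """
        new: dict[str, set[str]] = {}
        claimed: dict[str, str] = {}
        for concept in sorted(self.assignments):
            for acc in sorted(self.assignments[concept]):
                rep = merge_map.get(acc, acc)
                if rep in claimed and claimed[rep] != concept:
                    log.warning(
                        "consolidated variable %s claimed by concepts %s and %s; "
                        "keeping %s",
                        rep,
                        claimed[rep],
                        concept,
                        claimed[rep],
                    )
                    continue
                claimed[rep] = concept
                new.setdefault(concept, set()).add(rep)
        return GoldStandard(new)

    def positive_pairs(
        self,
        accessions_a: Iterable[str],
        accessions_b: Iterable[str],
        intracohort: bool,
    ) -> dict[str, list[tuple[str, str]]]:
        """Gold pairs per concept within a comparison scope.

        Intracohort pairs are unordered combinations (identical accessions
        excluded); intercohort pairs are all cross products of the concept's
        variables on each side.
        """
        set_a = set(accessions_a)
        set_b = set(accessions_b)
        pairs: dict[str, list[tuple[str, str]]] = {}
        for concept in sorted(self.assignments):
            members = self.assignments[concept]
            side_a = sorted(members & set_a)
            side_b = sorted(members & set_b)
            if intracohort:
                combos = [
                    (a, b) for a, b in itertools.combinations(side_a, 2)
                ]
            else:
                combos = [(a, b) for a in side_a for b in side_b if a != b]
            if combos:
                pairs[concept] = combos
        return pairs


@dataclass
class ConsolidationResult:
    """Output of :func:`consolidate_identical`."""

    records: list[VariableRecord]
    dist_vectors: dict
    merge_map: dict[str, str] = field(default_factory=dict)


def _temporal_regex(terms: Sequence[str]) -> re.Pattern:
    if not terms:
        raise ValidationError("temporal_terms must be non-empty")
    alts = "|".join(
        re.escape(t).replace("\\-", "[\\s-]")
        for t in sorted(set(terms), key=len, reverse=True)
    )
    phrase = rf"(?:(?:{alts})\s+{_NUMBER}|{_NUMBER}\s+(?:{alts}))"
    return re.compile(
        rf"[\s,;:\-()]*\b{phrase}\b\s*[,;:\-]*", re.IGNORECASE
    )


def strip_temporal(
    description: str, temporal_terms: Sequence[str] = DEFAULT_TEMPORAL_TERMS
) -> str:
    """Remove temporal measurement phrases from a variable description.

    A phrase is ``<term> <number-or-ordinal>`` or ``<number-or-ordinal>
    <term>`` (case-insensitive) together with immediately surrounding
    punctuation; residual whitespace is collapsed.  Only spans are removed,
    never inserted, so the output is a subsequence of the input (modulo
    whitespace collapse) and never longer than it.

    >>> strip_temporal("LDL cholesterol, visit 2")
    'LDL cholesterol'
    """
    pattern = _temporal_regex(temporal_terms)
    cleaned = pattern.sub(" ", description)
    cleaned = re.sub(r"\s+", " ", cleaned).strip()
    return cleaned.strip(" ,;:-")


def _parse_bool(value: str, accession: str) -> bool:
    token = str(value).strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ValidationError(
        f"unparseable is_continuous value {value!r} for variable {accession!r}"
    )


def records_from_frame(
    frame: pd.DataFrame,
    cohort_id: str,
    temporal_terms: Sequence[str] = DEFAULT_TEMPORAL_TERMS,
) -> list[VariableRecord]:
    """Build :class:`VariableRecord` objects from a dictionary table."""
    for column in _DICTIONARY_COLUMNS:
        if column not in frame.columns:
            raise ConfigurationError(
                f"data dictionary is missing required column {column!r}"
            )
    records: list[VariableRecord] = []
    seen: set[str] = set()
    for row in frame.itertuples(index=False):
        acc = str(getattr(row, "variable_accession")).strip()
        if acc in seen:
            raise ValidationError(f"duplicate variable accession {acc!r}")
        seen.add(acc)
        description = str(getattr(row, "description"))
        if description == "nan":  # empty cell read as float NaN
            description = ""
        records.append(
            VariableRecord(
                variable_accession=acc,
                variable_name=str(getattr(row, "variable_name")),
                description_raw=description,
                description_clean=strip_temporal(description, temporal_terms),
                dataset_accession=str(getattr(row, "dataset_accession")),
                cohort_id=cohort_id,
                is_continuous=_parse_bool(getattr(row, "is_continuous"), acc),
            )
        )
    return records


def read_dictionary(
    path,
    cohort_id: str,
    temporal_terms: Sequence[str] = DEFAULT_TEMPORAL_TERMS,
) -> list[VariableRecord]:
    """Read a tab- or comma-delimited data dictionary file."""
    frame = pd.read_csv(
        path, sep=None, engine="python", dtype=str, keep_default_na=False
    )
    if frame.empty and len(frame.columns) == 0:
        raise ConfigurationError(f"data dictionary {path} is empty")
    return records_from_frame(frame, cohort_id, temporal_terms)


def patient_table_from_frame(frame: pd.DataFrame, cohort_id: str) -> PatientTable:
    for column in ANCHOR_COLUMNS:
        if column not in frame.columns:
            raise ConfigurationError(
                f"patient table is missing required anchor column {column!r}"
            )
    frame = frame.copy()
    frame["age"] = pd.to_numeric(frame["age"], errors="coerce")
    complete = frame[list(ANCHOR_COLUMNS)].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info(
            "%s: dropped %d patient rows with missing anchors", cohort_id, n_dropped
        )
    frame = frame.loc[complete]
    value_cols = [c for c in frame.columns if c not in ANCHOR_COLUMNS]
    frame[value_cols] = frame[value_cols].apply(pd.to_numeric, errors="coerce")
    return PatientTable(cohort_id=cohort_id, frame=frame)


def read_patient_table(path, cohort_id: str) -> PatientTable:
    """Read a wide-layout patient table (one row per patient).

    Missing values may be empty cells or the sentinel ``NA``.
    """
    frame = pd.read_csv(
        path,
        sep=None,
        engine="python",
        index_col="patient_id",
        na_values=["", "NA"],
        keep_default_na=True,
    )
    return patient_table_from_frame(frame, cohort_id)


def read_gold_standard(path) -> GoldStandard:
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for column in ("concept_id", "variable_accession"):
        if column not in frame.columns:
            raise ConfigurationError(
                f"gold standard file is missing required column {column!r}"
            )
    assignments: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        assignments.setdefault(str(row.concept_id), set()).add(
            str(row.variable_accession)
        )
    return GoldStandard(assignments)


def write_gold_standard(gold: GoldStandard, path) -> None:
    rows = [
        {"concept_id": c, "variable_accession": a}
        for c in sorted(gold.assignments)
        for a in sorted(gold.assignments[c])
    ]
    pd.DataFrame(rows, columns=["concept_id", "variable_accession"]).to_csv(
        path, index=False
    )


def filter_continuous(records: Sequence[VariableRecord]) -> list[VariableRecord]:
    """Keep only variables flagged continuous in the metadata; order preserved."""
    kept = [r for r in records if r.is_continuous]
    if records and not kept:
        log.warning("no continuous variables survive the metadata filter")
    return kept


def filter_complete_subgroups(
    table: PatientTable, schema, min_patients: int = 1
) -> set[str]:
    """Accessions with at least one observed value in every populated subgroup.

    A subgroup is *populated* when the cohort has at least ``min_patients``
    patients in it; subgroups absent from the cohort are ignored, so a cohort
    covering only some of the schema's cells is not penalised for the rest.
    """
    labels, populated = _patient_subgroups(table, schema, min_patients)
    if not populated:
        return set()
    kept: set[str] = set()
    observed = table.frame[table.variable_columns].notna()
    observed = observed.loc[labels.notna()]
    groups = observed.groupby(labels.dropna(), observed=True).any()
    for accession in table.variable_columns:
        if bool(groups.loc[list(populated), accession].all()):
            kept.add(accession)
    return kept


def filter_nonzero(table: PatientTable, accessions: Iterable[str]) -> set[str]:
    """Drop accessions whose observed values are uniformly zero (or absent)."""
    kept: set[str] = set()
    for accession in accessions:
        values = table.frame[accession].dropna()
        if len(values) and bool((values != 0).any()):
            kept.add(accession)
    return kept


def consolidate_identical(
    records: Sequence[VariableRecord],
    dist_vectors: Mapping[str, "object"],
) -> ConsolidationResult:
    """Merge same-cohort variables whose cleaned descriptions are identical.

    Identity is case-insensitive with collapsed whitespace.  The merged entity
    is keyed by the lexicographically smallest accession and its distribution
    vector is the element-wise mean of the group's vectors.  Variables from
    different cohorts are never merged.  Idempotent.
    """
    groups: dict[tuple[str, str], list[VariableRecord]] = {}
    for record in records:
        key = (record.cohort_id, record.canonical_description())
        groups.setdefault(key, []).append(record)

    out_records: list[VariableRecord] = []
    out_vectors: dict[str, object] = {}
    merge_map: dict[str, str] = {}
    consumed: set[str] = set()
    for record in records:
        if record.variable_accession in consumed:
            continue
        group = groups[(record.cohort_id, record.canonical_description())]
        if len(group) == 1:
            out_records.append(record)
            if record.variable_accession in dist_vectors:
                out_vectors[record.variable_accession] = dist_vectors[
                    record.variable_accession
                ]
            continue
        representative = min(g.variable_accession for g in group)
        members = sorted(g.variable_accession for g in group)
        consumed.update(members)
        for member in members:
            if member != representative:
                merge_map[member] = representative
        rep_record = next(
            g for g in group if g.variable_accession == representative
        )
        out_records.append(rep_record)
        vectors = [dist_vectors[m] for m in members if m in dist_vectors]
        if vectors:
            first = vectors[0]
            for other in vectors[1:]:
                if tuple(other.labels) != tuple(first.labels):
                    raise ValidationError(
                        "cannot consolidate variables with mismatched subgroup "
                        f"labels (representative {representative!r})"
                    )
            merged = replace(
                first,
                quantiles=np.mean([v.quantiles for v in vectors], axis=0),
            )
            out_vectors[representative] = merged
    return ConsolidationResult(out_records, out_vectors, merge_map)


def _patient_subgroups(table: PatientTable, schema, min_patients: int):
    """Per-patient subgroup labels (as strings) and the populated label set."""
    assigned = []
    for age, race, sex in zip(
        table.frame["age"], table.frame["race"], table.frame["sex"]
    ):
        label = schema.assign(age, race, sex)
        assigned.append("|".join(label) if label is not None else None)
    labels = pd.Series(assigned, index=table.frame.index, dtype=object)
    n_unassigned = int(labels.isna().sum())
    if n_unassigned:
        log.info(
            "%s: %d patients outside the subgroup schema were ignored",
            table.cohort_id,
            n_unassigned,
        )
    counts = labels.value_counts()
    populated = [
        "|".join(label)
        for label in schema.labels()
        if counts.get("|".join(label), 0) >= min_patients
    ]
    return labels, populated
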