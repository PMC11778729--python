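"""Synthetic multi-cohort data generator.

Emits data dictionaries, patient tables and a gold standard in exactly the
formats the readers consume, with the statistical structure the harmonization
method assumes:

* latent concepts shared across cohorts, each realised as 1-3 variables per
  cohort plus singleton distractor concepts;
* cohort-specific lexical variants of a concept's description (synonym swaps,
  token reordering, abbreviation, appended temporal phrases such as
  "visit 3");
* Gaussian patient values per (concept, subgroup, cohort): a concept-level
  location/scale plus additive age/race/sex effects and a cohort-level shift
  (a log-normal heavy-tail option exists for robustness experiments);
* per-cohort populated-subgroup masks defaulting to a 12/16/6 pattern with a
  single-sex third cohort, mirroring the kind of coverage heterogeneity seen
  in real multi-cohort studies;
* optional "hard" concept pairs sharing near-identical wording but distinct
  value distributions, which degrade purely semantic matching while leaving
  distribution-based matching intact.

Everything is driven by one seed; identical configs produce byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import (
    GoldStandard,
    patient_table_from_frame,
    records_from_frame,
    write_gold_standard,
)
from .distribution import SubgroupSchema
from .errors import ValidationError

_CONTEXT_GROUPS = (
    ("serum", "blood serum"),
    ("plasma", "circulating"),
    ("urinary", "urine"),
    ("dietary", "diet"),
    ("fasting", "fasted"),
    ("total", "overall"),
)
_MEASURE_GROUPS = (
    ("level", "lvl"),
    ("concentration", "conc"),
    ("count", "cnt"),
    ("index", "idx"),
    ("ratio", "quotient"),
    ("score", "value"),
)
_SYLLABLES = (
    "al", "bro", "cor", "den", "fer", "gly", "hep", "lip", "mon", "nat",
    "pro", "ren", "sta", "tri", "vas", "zym", "cal", "myo", "ost", "neu",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults describe the benchmark regime: 3 cohorts, 40 shared concepts,
    500 patients per cohort, moderate lexical heterogeneity, no hard concept
    pairs (enable them with :func:`make_hard_concepts`).
    """

    n_cohorts: int = 3
    n_concepts: int = 40
    variables_per_concept: tuple[int, int] = (1, 3)
    n_distractors: int = 30
    patients_per_cohort: int = 500
    schema: SubgroupSchema = field(default_factory=SubgroupSchema)
    populated_masks: tuple | None = None  # default 12/16/6 pattern, see below
    concept_mean_range: tuple[float, float] = (0.5, 500.0)  # log-uniform
    concept_cv_range: tuple[float, float] = (0.2, 1.2)
    age_effect_sd: float = 0.3  # relative to the concept mean
    race_effect_sd: float = 0.08
    sex_effect_sd: float = 0.08
    cohort_shift_sd: float = 0.05
    variable_shift_sd: float = 0.15
    value_noise_scale: float = 1.0
    heavy_tail: bool = False
    synonym_rate: float = 0.5
    abbreviation_rate: float = 0.2
    token_shuffle_rate: float = 0.3
    temporal_rate: float = 0.5
    hard_concept_fraction: float = 0.0
    hard_separation: float = 4.0
    missing_rate: float = 0.02
    n_zero_variables: int = 1
    n_noncontinuous: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in (
            "synonym_rate",
            "abbreviation_rate",
            "token_shuffle_rate",
            "temporal_rate",
            "hard_concept_fraction",
            "missing_rate",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {rate}")
        for name in (
            "age_effect_sd",
            "race_effect_sd",
            "sex_effect_sd",
            "cohort_shift_sd",
            "variable_shift_sd",
            "value_noise_scale",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


def make_hard_concepts(config: SimulationConfig, fraction: float) -> SimulationConfig:
    """Flag a fraction of concepts as lexically colliding hard pairs.

    Hard concepts come in pairs sharing near-identical description templates
    while their value distributions are pushed apart, so semantic-only AUC
    degrades on them but distribution-only AUC does not.
    """
    if fraction > 1:
        raise ValidationError("hard-concept fraction cannot exceed 1")
    if fraction > 0 and config.n_concepts < 4:
        raise ValidationError("hard concepts need at least 4 concepts")
    if fraction == config.hard_concept_fraction:
        return config
    return dataclasses.replace(config, hard_concept_fraction=fraction)


def default_populated_masks(schema: SubgroupSchema, n_cohorts: int) -> tuple:
    """Per-cohort populated subgroup masks.

    For 3 cohorts: cohort 1 lacks the oldest age bucket (12 subgroups),
    cohort 2 covers all 16, cohort 3 is female-only over the three oldest
    buckets (6 subgroups).  Additional cohorts cover everything.
    """
    all_labels = schema.labels()
    masks = []
    age_labels = schema.age_labels
    for c in range(n_cohorts):
        if c == 0:
            mask = [l for l in all_labels if l[0] != age_labels[-1]]
        elif c == 2:
            mask = [
                l
                for l in all_labels
                if l[2] == schema.sex_categories[0] and l[0] in age_labels[1:]
            ]
        else:
            mask = list(all_labels)
        masks.append(tuple(mask))
    return tuple(masks)


@dataclass
class SyntheticDataset:
    """In-memory result of :func:`simulate`, writable to the on-disk formats."""

    config: SimulationConfig
    cohort_ids: tuple[str, ...]
    dictionaries: dict[str, pd.DataFrame]
    patients: dict[str, pd.DataFrame]
    gold: GoldStandard
    hard_concepts: tuple[str, ...]

    def records(self, cohort_id: str):
        return records_from_frame(self.dictionaries[cohort_id], cohort_id)

    def patient_table(self, cohort_id: str):
        frame = self.patients[cohort_id].set_index("patient_id")
        return patient_table_from_frame(frame, cohort_id)

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for cohort in self.cohort_ids:
            dpath = out / f"{cohort}_dictionary.csv"
            self.dictionaries[cohort].to_csv(dpath, index=False)
            ppath = out / f"{cohort}_patients.csv"
            self.patients[cohort].to_csv(
                ppath, index=False, float_format="%.6g", na_rep=""
            )
            paths[f"{cohort}_dictionary"] = dpath
            paths[f"{cohort}_patients"] = ppath
        gpath = out / "gold_standard.csv"
        write_gold_standard(self.gold, gpath)
        paths["gold_standard"] = gpath
        manifest = {
            "cohorts": list(self.cohort_ids),
            "hard_concepts": list(self.hard_concepts),
            "seed": self.config.seed,
            "config": _config_dict(self.config),
        }
        mpath = out / "simulation_manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest"] = mpath
        return paths


def _config_dict(config: SimulationConfig) -> dict:
    out = dataclasses.asdict(config)
    out["schema"] = {
        "age_edges": list(config.schema.age_edges),
        "race_categories": list(config.schema.race_categories),
        "sex_categories": list(config.schema.sex_categories),
    }
    if config.populated_masks is not None:
        out["populated_masks"] = [
            ["|".join(l) for l in mask] for mask in config.populated_masks
        ]
    return out


def _unique_roots(rng: np.random.Generator, n: int) -> list[str]:
    roots: list[str] = []
    seen: set[str] = set()
    while len(roots) < n:
        root = "".join(rng.choice(_SYLLABLES, size=3))
        if root not in seen:
            seen.add(root)
            roots.append(root)
    return roots


def _perturb_root(root: str) -> str:
    """A lexically close but distinct root (second character cycled)."""
    replacement = "z" if root[1] != "z" else "q"
    return root[0] + replacement + root[2:]


def _describe(
    rng: np.random.Generator,
    template: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]],
    config: SimulationConfig,
) -> str:
    context_group, root_variants, measure_group = template
    root = str(rng.choice(root_variants))
    context = (
        rng.choice(context_group[1:])
        if len(context_group) > 1 and rng.random() < config.synonym_rate
        else context_group[0]
    )
    measure = (
        rng.choice(measure_group[1:])
        if len(measure_group) > 1 and rng.random() < config.synonym_rate
        else measure_group[0]
    )
    token = root
    if rng.random() < config.abbreviation_rate and len(root) > 4:
        token = root[:4] + "."
    tokens = [str(context), token, str(measure)]
    if rng.random() < config.token_shuffle_rate:
        tokens = [tokens[1], tokens[0], tokens[2]]
    text = " ".join(tokens)
    if rng.random() < config.temporal_rate:
        n = int(rng.integers(1, 7))
        if rng.random() < 0.5:
            text = f"{text}, visit {n}"
        else:
            text = f"Exam {n}: {text}"
    return text[0].upper() + text[1:]


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full multi-cohort dataset under ``config``.

    Same-concept variables share a description template (independently
    perturbed per variable) and a latent value distribution (per-subgroup
    means, shifted per cohort).  Distractors are singleton concepts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x50A]))
    schema = config.schema
    masks = (
        config.populated_masks
        if config.populated_masks is not None
        else default_populated_masks(schema, config.n_cohorts)
    )
    if len(masks) != config.n_cohorts:
        raise ValidationError(
            f"{len(masks)} populated masks for {config.n_cohorts} cohorts"
        )
    if any(len(mask) == 0 for mask in masks):
        raise ValidationError("every cohort needs at least one populated subgroup")

    cohort_ids = tuple(f"STUDY{c + 1}" for c in range(config.n_cohorts))

    # --- concepts -----------------------------------------------------------
    # aliases of hard concepts draw extra roots, hence the 2x headroom
    n_total = 2 * config.n_concepts + config.n_cohorts * config.n_distractors
    roots = _unique_roots(rng, n_total)
    concept_ids = [f"C{i:03d}" for i in range(config.n_concepts)]

    n_hard = int(round(config.n_concepts * config.hard_concept_fraction))
    n_hard -= n_hard % 2
    hard_ids = tuple(concept_ids[:n_hard])

    templates: dict[str, tuple] = {}
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    age_slope: dict[str, float] = {}
    race_eff: dict[str, np.ndarray] = {}
    sex_eff: dict[str, np.ndarray] = {}

    def _draw_concept_params(cid: str):
        # levels span orders of magnitude (lab values do); spread and
        # demographic effects scale with the level
        lo_m, hi_m = config.concept_mean_range
        mean = float(np.exp(rng.uniform(np.log(lo_m), np.log(hi_m))))
        means[cid] = mean
        sds[cid] = mean * float(rng.uniform(*config.concept_cv_range))
        age_slope[cid] = mean * float(rng.normal(0, config.age_effect_sd))
        race_eff[cid] = mean * rng.normal(
            0, config.race_effect_sd, len(schema.race_categories)
        )
        sex_eff[cid] = mean * rng.normal(
            0, config.sex_effect_sd, len(schema.sex_categories)
        )

    root_iter = iter(roots)
    i = 0
    while i < config.n_concepts:
        cid = concept_ids[i]
        context = _CONTEXT_GROUPS[int(rng.integers(len(_CONTEXT_GROUPS)))]
        measure = _MEASURE_GROUPS[int(rng.integers(len(_MEASURE_GROUPS)))]
        root = next(root_iter)
        if i + 1 < n_hard:  # pair this hard concept with a lexical twin
            # hard concepts are doubly unreliable lexically: the pair shares a
            # near-identical template (root differs by one character) and each
            # concept is also known under an unrelated alias (as with
            # "C-reactive protein" vs "CRP"), used by about half its variables
            twin = concept_ids[i + 1]
            templates[cid] = (context, (root, next(root_iter)), measure)
            templates[twin] = (context, (_perturb_root(root), next(root_iter)), measure)
            _draw_concept_params(cid)
            _draw_concept_params(twin)
            # force the twin's distribution well away from its partner's
            means[twin] = means[cid] + config.hard_separation * max(
                sds[cid], sds[twin]
            )
            i += 2
        else:
            templates[cid] = (context, (root,), measure)
            _draw_concept_params(cid)
            i += 1

    # --- variables ----------------------------------------------------------
    accession_counter = 0

    def next_accession() -> str:
        nonlocal accession_counter
        accession_counter += 1
        return f"phv{accession_counter:07d}"

    dictionaries: dict[str, pd.DataFrame] = {}
    patients: dict[str, pd.DataFrame] = {}
    assignments: dict[str, set[str]] = {}
    lo, hi = config.variables_per_concept

    for c, cohort in enumerate(cohort_ids):
        mask = list(masks[c])
        rows = []

        def add_variable(description: str, concept: str | None, continuous=True):
            acc = next_accession()
            rows.append(
                {
                    "variable_accession": acc,
                    "variable_name": f"VAR_{acc[-5:]}",
                    "description": description,
                    "dataset_accession": f"pht{c + 1:04d}",
                    "is_continuous": "true" if continuous else "false",
                }
            )
            if concept is not None:
                assignments.setdefault(concept, set()).add(acc)
            return acc

        var_concept: dict[str, str] = {}
        for cid in concept_ids:
            n_vars = int(rng.integers(lo, hi + 1))
            for _ in range(n_vars):
                acc = add_variable(_describe(rng, templates[cid], config), cid)
                var_concept[acc] = cid
        for dix in range(config.n_distractors):
            did = f"D{c:02d}{dix:03d}"
            context = _CONTEXT_GROUPS[int(rng.integers(len(_CONTEXT_GROUPS)))]
            measure = _MEASURE_GROUPS[int(rng.integers(len(_MEASURE_GROUPS)))]
            templates[did] = (context, (next(root_iter),), measure)
            _draw_concept_params(did)
            acc = add_variable(_describe(rng, templates[did], config), did)
            var_concept[acc] = did
        zero_accs = [
            add_variable(f"Calibration offset channel {z + 1}", None)
            for z in range(config.n_zero_variables)
        ]
        for z in range(config.n_noncontinuous):
            add_variable(f"Questionnaire item {z + 1} category", None, continuous=False)

        dictionaries[cohort] = pd.DataFrame(rows)

        # --- patients -------------------------------------------------------
        n_patients = config.patients_per_cohort
        subgroup_idx = rng.integers(0, len(mask), size=n_patients)
        age_labels = schema.age_labels
        ages = np.empty(n_patients, dtype=int)
        races: list[str] = []
        sexes: list[str] = []
        edges = schema.age_edges
        for p in range(n_patients):
            age_label, race, sex = mask[subgroup_idx[p]]
            bucket = age_labels.index(age_label)
            if bucket == 0:
                low, high = max(edges[0] - 15, 18), edges[0] - 1
            elif bucket == len(age_labels) - 1:
                low, high = edges[-1], edges[-1] + 14
            else:
                low, high = edges[bucket - 1], edges[bucket] - 1
            ages[p] = int(rng.integers(low, high + 1))
            races.append(race)
            sexes.append(sex)
        age_bucket_idx = np.array(
            [age_labels.index(mask[s][0]) for s in subgroup_idx]
        )
        race_idx = np.array(
            [schema.race_categories.index(r) for r in races]
        )
        sex_idx = np.array([schema.sex_categories.index(s) for s in sexes])

        frame = pd.DataFrame(
            {
                "patient_id": [f"{cohort}_P{p + 1:04d}" for p in range(n_patients)],
                "age": ages,
                "race": races,
                "sex": sexes,
            }
        )
        measured = [a for a in var_concept]  # concept + distractor variables
        shift = {
            cid: float(rng.normal(0, config.cohort_shift_sd * means[cid]))
            for cid in sorted({*var_concept.values()})
        }
        values = np.empty((n_patients, len(measured)))
        for v, acc in enumerate(measured):
            cid = var_concept[acc]
            # per-variable offset: same-concept variables measured with
            # different assays/units do not share identical raw values
            var_offset = float(
                rng.normal(0, config.variable_shift_sd * means[cid])
            )
            loc = (
                means[cid]
                + age_slope[cid] * age_bucket_idx
                + race_eff[cid][race_idx]
                + sex_eff[cid][sex_idx]
                + shift[cid]
                + var_offset
            )
            scale = sds[cid] * config.value_noise_scale
            if config.heavy_tail:
                noise = rng.lognormal(0.0, 1.0, n_patients) - np.exp(0.5)
            else:
                noise = rng.standard_normal(n_patients)
            values[:, v] = loc + scale * noise
        if config.missing_rate > 0:
            missing = rng.random(values.shape) < config.missing_rate
            values[missing] = np.nan
        value_frame = pd.DataFrame(values, columns=measured, index=frame.index)
        for acc in zero_accs:
            value_frame[acc] = 0.0
        patients[cohort] = pd.concat([frame, value_frame], axis=1)

    gold = GoldStandard(assignments)
    return SyntheticDataset(
        config=config,
        cohort_ids=cohort_ids,
        dictionaries=dictionaries,
        patients=patients,
        gold=gold,
        hard_concepts=hard_ids,
    )
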