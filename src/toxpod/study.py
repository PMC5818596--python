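"""Study records, inclusion filtering, and effect-level derivation.

The modeling row's left half: each in vivo repeat-dose study contributes one
regression target (the systemic effect level, log10 mg/kg/day) plus eight
study-design covariates. Effect levels come in three types:

* ``LOAEL`` — lowest observed adverse effect level, taken as given when a
  reviewed value is attached to the study;
* ``LEL`` — lowest effect level, computed as the lowest tested dose at which
  any treatment-related systemic effect was observed;
* ``NEL`` — no effect level, assigned to the highest tested dose when no
  systemic effect occurred anywhere in the study (a right-censored
  observation, qualifier ``>=``).

Neurotoxicity-only findings (e.g. cholinesterase inhibition) are excluded
before derivation and never establish an LEL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "EffectLevel",
    "CovariateVector",
    "InputError",
    "SOURCES",
    "STUDY_TYPES",
    "ORAL_ADMIN_METHODS",
    "COVARIATE_NAMES",
    "DEFAULT_PPM_FACTORS",
    "filter_studies",
    "convert_dose",
    "derive_effect_level",
    "covariates_of",
    "effect_table",
    "chemical_mean_effect",
    "read_registry",
    "write_registry",
]

SOURCES = ("TOXREF", "HESS", "COSMOS")
STUDY_TYPES = ("SUB", "CHR", "DEV", "MGR", "SAC")
ORAL_ADMIN_METHODS = ("food", "water", "gavage", "capsule")
POD_TYPES = ("NEL", "LEL", "LOAEL")
QUALIFIERS = ("=", "<=", ">=")

#: the eight study covariates used as model predictors
COVARIATE_NAMES = (
    "study_type",
    "species",
    "strain_group",
    "admin_method",
    "dose_no",
    "dose_spacing",
    "pod_type",
    "pod_qual",
)

#: truncation bounds for log10 effect levels (0.01 to 10,000 mg/kg/day)
TRUNCATION_BOUNDS = (-2.0, 4.0)


class InputError(ValueError):
    """Raised for invalid study inputs (unknown units, missing doses...)."""


# ppm-in-diet -> mg/kg/day conversion factors by (species, duration class).
# Standard food-consumption assumptions: chronic rat feed 0.05, mouse 0.15,
# dog 0.025; subchronic and shorter studies use twice the chronic factor
# (younger, faster-growing animals eat more per unit body weight). Water
# analogues use roughly double the feed factor. Fully configurable; the
# table used for a run is recorded in run metadata.
_CHRONIC_FEED = {"rat": 0.05, "mouse": 0.15, "dog": 0.025, "rabbit": 0.03}
_NONCHRONIC_TYPES = {"SUB", "SAC", "DEV", "MGR"}

DEFAULT_PPM_FACTORS: dict[tuple[str, str], float] = {}
for _sp, _f in _CHRONIC_FEED.items():
    for _st in STUDY_TYPES:
        DEFAULT_PPM_FACTORS[(_sp, _st)] = _f * (2.0 if _st in _NONCHRONIC_TYPES else 1.0)


@dataclass
class StudyRecord:
    """One in vivo repeat-dose study as extracted from a source database."""

    study_id: str
    chemical_id: str
    source: str
    study_type: str
    species: str
    strain_group: str
    admin_method: str
    #: ascending (value, unit) pairs; unit is "mg/kg/day" or "ppm"
    dose_levels: list[tuple[float, str]]
    #: treatment-related systemic effect observed at each dose (1:1 with doses)
    effects: list[bool]
    #: findings at the dose are neurotoxicity-only (excluded from derivation)
    neuro_only: list[bool] = field(default_factory=list)
    #: reviewed (value, unit) LOAEL when expert adjudication exists
    loael: tuple[float, str] | None = None
    guideline_ok: bool = True
    purity: float | None = None
    study_year: int | None = None

    def __post_init__(self) -> None:
        if not self.neuro_only:
            self.neuro_only = [False] * len(self.dose_levels)

    def validate(self) -> None:
        values = [v for v, _ in self.dose_levels]
        if any(v <= 0 for v in values):
            raise InputError(f"{self.study_id}: dose values must be > 0")
        if any(b >= a for b, a in zip(values, values[1:])):
            raise InputError(f"{self.study_id}: dose levels must be strictly increasing")
        if len(self.effects) != len(self.dose_levels):
            raise InputError(f"{self.study_id}: per-dose flags must align with dose levels")
        if len(self.neuro_only) != len(self.dose_levels):
            raise InputError(f"{self.study_id}: neuro flags must align with dose levels")


@dataclass(frozen=True)
class EffectLevel:
    """Derived study response: type, log10 value and censoring qualifier."""

    study_id: str
    pod_type: str
    value_log10: float
    qualifier: str
    truncated: bool = False


@dataclass(frozen=True)
class CovariateVector:
    """The eight study-design covariates entering every model tier."""

    study_type: str
    species: str
    strain_group: str
    admin_method: str
    dose_no: int
    dose_spacing: float
    pod_type: str
    pod_qual: str


def filter_studies(records: Iterable[StudyRecord]) -> list[StudyRecord]:
    """Apply the common study inclusion criteria.

    Retains studies with (1) oral administration (food, water, gavage or
    capsule), (2) more than one dose level, (3) guideline-acceptable quality
    and (4) observation of systemic effects. Neurotoxicity-only findings are
    zeroed out so they cannot establish an effect level downstream.
    """
    kept = []
    for rec in records:
        if rec.admin_method not in ORAL_ADMIN_METHODS:
            continue
        if len(rec.dose_levels) < 2:
            continue
        if not rec.guideline_ok:
            continue
        if rec.effects is None:
            continue
        effects = [e and not n for e, n in zip(rec.effects, rec.neuro_only)]
        if effects != list(rec.effects):
            rec = replace(rec, effects=effects, neuro_only=[False] * len(effects))
        kept.append(rec)
    return kept


def convert_dose(
    value: float,
    unit: str,
    species: str,
    study_type: str,
    ppm_factors: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """Convert a dose to mg/kg/day.

    mg/kg/day passes through; ppm (in diet) is multiplied by a configurable
    species x duration factor built on standard food-consumption assumptions.
    """
    if value <= 0:
        raise InputError(f"dose value must be > 0, got {value}")
    if unit == "mg/kg/day":
        return float(value)
    if unit == "ppm":
        factors = DEFAULT_PPM_FACTORS if ppm_factors is None else ppm_factors
        key = (species, study_type)
        if key not in factors:
            raise InputError(f"no ppm conversion factor for species/study type {key}")
        return float(value) * factors[key]
    raise InputError(f"unknown dose unit {unit!r}")


def _doses_mg_kg_day(
    record: StudyRecord, ppm_factors: Mapping[tuple[float, str], float] | None
) -> list[float]:
    return [
        convert_dose(v, u, record.species, record.study_type, ppm_factors)
        for v, u in record.dose_levels
    ]


def derive_effect_level(
    record: StudyRecord,
    ppm_factors: Mapping[tuple[str, str], float] | None = None,
) -> EffectLevel:
    """Derive the study's effect level, type and qualifier.

    Priority: a reviewed LOAEL when present; otherwise the LEL at the lowest
    dose with a systemic effect; otherwise the NEL at the highest tested dose
    (qualifier ``>=``). Values are log10-transformed and clipped to [-2, 4]
    so extreme doses cannot dominate the regression; the ``truncated`` flag
    records clipping.
    """
    if not record.dose_levels:
        raise InputError(f"{record.study_id}: no dose data")
    record.validate()
    doses = _doses_mg_kg_day(record, ppm_factors)
    order = sorted(range(len(doses)), key=doses.__getitem__)
    doses_sorted = [doses[i] for i in order]
    effects_sorted = [
        record.effects[i] and not record.neuro_only[i] for i in order
    ]

    if record.loael is not None:
        lv, lu = record.loael
        value = convert_dose(lv, lu, record.species, record.study_type, ppm_factors)
        pod_type = "LOAEL"
        qualifier = "<=" if math.isclose(value, doses_sorted[0], rel_tol=1e-9) else "="
    elif any(effects_sorted):
        idx = effects_sorted.index(True)
        value = doses_sorted[idx]
        pod_type = "LEL"
        qualifier = "<=" if idx == 0 else "="
    else:
        value = doses_sorted[-1]
        pod_type = "NEL"
        qualifier = ">="

    log_value = math.log10(value)
    lo, hi = TRUNCATION_BOUNDS
    clipped = min(max(log_value, lo), hi)
    return EffectLevel(
        study_id=record.study_id,
        pod_type=pod_type,
        value_log10=clipped,
        qualifier=qualifier,
        truncated=clipped != log_value,
    )


def covariates_of(
    record: StudyRecord,
    effect_level: EffectLevel,
    ppm_factors: Mapping[tuple[str, str], float] | None = None,
) -> CovariateVector:
    """Assemble the eight-covariate design vector for a study.

    ``dose_spacing`` is the median fold-ratio of consecutive (converted,
    ascending) doses — robust to a single odd gap in the grid.
    """
    doses = sorted(_doses_mg_kg_day(record, ppm_factors))
    ratios = [a / b for b, a in zip(doses, doses[1:])]
    spacing = float(np.median(ratios)) if ratios else float("nan")
    return CovariateVector(
        study_type=record.study_type,
        species=record.species,
        strain_group=record.strain_group,
        admin_method=record.admin_method,
        dose_no=len(doses),
        dose_spacing=spacing,
        pod_type=effect_level.pod_type,
        pod_qual=effect_level.qualifier,
    )


def effect_table(
    records: Sequence[StudyRecord],
    ppm_factors: Mapping[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Derive effect levels + covariates for filtered records as one table.

    One row per study with columns: study_id, chemical_id, source, pod_type,
    value_log10, qualifier, truncated, and the eight covariates.
    """
    rows = []
    for rec in records:
        lvl = derive_effect_level(rec, ppm_factors)
        cov = covariates_of(rec, lvl, ppm_factors)
        rows.append(
            {
                "study_id": rec.study_id,
                "chemical_id": rec.chemical_id,
                "source": rec.source,
                "pod_type": lvl.pod_type,
                "value_log10": lvl.value_log10,
                "qualifier": lvl.qualifier,
                "truncated": lvl.truncated,
                "study_type": cov.study_type,
                "species": cov.species,
                "strain_group": cov.strain_group,
                "admin_method": cov.admin_method,
                "dose_no": cov.dose_no,
                "dose_spacing": cov.dose_spacing,
                "pod_qual": cov.pod_qual,
            }
        )
    return pd.DataFrame(rows)


def chemical_mean_effect(effects: pd.DataFrame) -> pd.Series:
    """Mean effect level per chemical over all of its studies (all types).

    Expects columns ``chemical_id`` and ``value_log10``; returns a Series
    indexed by chemical id. This is both a descriptive statistic and the
    ``podmn`` predictor of the benchmark (upper-bound) model.
    """
    return effects.groupby("chemical_id")["value_log10"].mean()


# ---------------------------------------------------------------------------
# Delimited registry I/O. One study per row; dose levels serialized as
# "value:unit" triplets joined by ';', per-dose flags as '0'/'1' strings.

_REGISTRY_COLUMNS = [
    "study_id",
    "chemical_id",
    "source",
    "study_type",
    "species",
    "strain_group",
    "admin_method",
    "dose_levels",
    "effects",
    "neuro_only",
    "loael_value",
    "loael_unit",
    "guideline_ok",
    "purity",
    "study_year",
]


def write_registry(records: Sequence[StudyRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "chemical_id": r.chemical_id,
                "source": r.source,
                "study_type": r.study_type,
                "species": r.species,
                "strain_group": r.strain_group,
                "admin_method": r.admin_method,
                "dose_levels": ";".join(f"{v:.10g}:{u}" for v, u in r.dose_levels),
                "effects": "".join("1" if e else "0" for e in r.effects),
                "neuro_only": "".join("1" if e else "0" for e in r.neuro_only),
                "loael_value": "" if r.loael is None else f"{r.loael[0]:.10g}",
                "loael_unit": "" if r.loael is None else r.loael[1],
                "guideline_ok": int(r.guideline_ok),
                "purity": "" if r.purity is None else f"{r.purity:.6g}",
                "study_year": "" if r.study_year is None else r.study_year,
            }
        )
    pd.DataFrame(rows, columns=_REGISTRY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_registry(path) -> list[StudyRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        doses = []
        for part in row.dose_levels.split(";"):
            v, u = part.rsplit(":", 1)
            doses.append((float(v), u))
        loael = None
        if row.loael_value:
            loael = (float(row.loael_value), row.loael_unit)
        records.append(
            StudyRecord(
                study_id=row.study_id,
                chemical_id=row.chemical_id,
                source=row.source,
                study_type=row.study_type,
                species=row.species,
                strain_group=row.strain_group,
                admin_method=row.admin_method,
                dose_levels=doses,
                effects=[c == "1" for c in row.effects],
                neuro_only=[c == "1" for c in row.neuro_only],
                loael=loael,
                guideline_ok=row.guideline_ok == "1",
                purity=float(row.purity) if row.purity else None,
                study_year=int(row.study_year) if row.study_year else None,
            )
        )
    return records
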