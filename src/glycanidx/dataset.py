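"""Data model and I/O for compiled culture-condition studies.

A *study* contributes one control condition and one or more manipulated
conditions per experiment group (a study may run independent experiments,
e.g. a temperature series and a pH series, each with its own control).
Each condition carries process metadata and either a full glycoform
distribution, reported index values, or both; the unit of analysis is the
control-vs-manipulated pair.

On-disk format is two CSV files: a conditions metadata table and a
long-format distribution table keyed by ``condition_id`` (see
:mod:`glycanidx.io`).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .indices import GlycanDistribution, IndexSet, Provenance, normalize_distribution
from .io import RawDistributions, read_distributions_csv, write_distributions_csv

__all__ = [
    "Role",
    "ParameterCategory",
    "CultureMode",
    "ConditionRecord",
    "ConditionPair",
    "PairingResult",
    "DatasetError",
    "read_study_table",
    "write_study_table",
    "dataset_to_json",
    "pair_conditions",
    "group_pairs",
    "DEFAULT_GROUPING_KEYS",
]


class DatasetError(ValueError):
    """Raised on dataset validation failures, with a locator where possible."""


class Role(str, Enum):
    CONTROL = "control"
    MANIPULATED = "manipulated"


class ParameterCategory(str, Enum):
    TEMPERATURE = "temperature"
    PH = "pH"
    DISSOLVED_OXYGEN = "dissolved_oxygen"
    PCO2 = "pCO2"
    OSMOLALITY = "osmolality"
    CHEMICAL_ADDITIVE = "chemical_additive"
    OTHER = "other"


class CultureMode(str, Enum):
    BATCH = "batch"
    FED_BATCH = "fed_batch"
    PERFUSION = "perfusion"


@dataclass(frozen=True)
class ConditionRecord:
    """One culture condition: metadata plus distribution and/or indices."""

    study_id: str
    condition_id: str
    role: Role
    parameter_category: ParameterCategory
    manipulation_type: str
    cell_line: str
    product: str
    culture_mode: CultureMode
    distribution: GlycanDistribution | None = None
    reported_indices: IndexSet | None = None
    reference: str = ""
    experiment_group: str | None = None
    replicate_group: str | None = None

    def __post_init__(self) -> None:
        if self.distribution is None and self.reported_indices is None:
            raise DatasetError(
                f"{self.condition_id}: needs a distribution or reported indices"
            )
        is_control = self.role is Role.CONTROL
        if is_control != (self.manipulation_type.strip().lower() == "control"):
            raise DatasetError(
                f"{self.condition_id}: role {self.role.value!r} inconsistent with "
                f"manipulation_type {self.manipulation_type!r}"
            )

    @property
    def suitable_for_indices(self) -> bool:
        """Whether glycan indices can be computed (a distribution is present).

        Derived, never trusted from input; mirrors the published tables'
        suitability tick.
        """
        return self.distribution is not None

    @property
    def group_key(self) -> tuple[str, str]:
        """Control-matching scope: (study, experiment group)."""
        group = self.experiment_group or self.parameter_category.value
        return (self.study_id, group)


@dataclass(frozen=True)
class ConditionPair:
    """A manipulated condition matched to its in-study control."""

    control: ConditionRecord
    manipulated: ConditionRecord

    def __post_init__(self) -> None:
        if self.control.study_id != self.manipulated.study_id:
            raise DatasetError("pair spans two studies")
        if self.control.role is not Role.CONTROL or self.manipulated.role is not Role.MANIPULATED:
            raise DatasetError("pair roles are wrong way round")

    @property
    def study_id(self) -> str:
        return self.control.study_id

    @property
    def parameter_category(self) -> ParameterCategory:
        return self.manipulated.parameter_category

    @property
    def manipulation_type(self) -> str:
        return self.manipulated.manipulation_type

    @property
    def culture_mode(self) -> CultureMode:
        return self.manipulated.culture_mode

    @property
    def cell_line(self) -> str:
        return self.manipulated.cell_line


METADATA_COLUMNS = (
    "study_id", "condition_id", "role", "parameter_category", "manipulation_type",
    "experiment_group", "replicate_group", "cell_line", "product", "culture_mode",
    "reference", "reported_fi", "reported_gi", "reported_si",
)


def _parse_reported(row: Mapping[str, str], locator: str) -> IndexSet | None:
    vals = {}
    for col, attr in (("reported_fi", "fi"), ("reported_gi", "gi"), ("reported_si", "si")):
        text = (row.get(col) or "").strip()
        if text:
            try:
                vals[attr] = float(text)
            except ValueError as exc:
                raise DatasetError(f"{locator}: bad {col} {text!r}") from exc
    if not vals:
        return None
    return IndexSet(provenance=Provenance.REPORTED, **vals)


def read_study_table(
    metadata_path: str | Path,
    distributions_path: str | Path | None = None,
    *,
    tolerance: float = 5.0,
) -> list[ConditionRecord]:
    """Load and validate a study table from metadata + distributions CSVs.

    Every distribution row must reference a metadata ``condition_id``;
    enum violations, duplicates and orphan conditions are reported with
    their row number.
    """
    raw_dists: RawDistributions = {}
    if distributions_path is not None:
        raw_dists = read_distributions_csv(distributions_path)
    records: list[ConditionRecord] = []
    seen_ids: set[str] = set()
    with open(metadata_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = {"study_id", "condition_id", "role", "parameter_category",
                   "manipulation_type", "cell_line", "product", "culture_mode"} \
            - set(reader.fieldnames or ())
        if missing:
            raise DatasetError(f"{metadata_path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            locator = f"{metadata_path} row {i}"
            cid = row["condition_id"].strip()
            if cid in seen_ids:
                raise DatasetError(f"{locator}: duplicate condition_id {cid!r}")
            seen_ids.add(cid)
            try:
                role = Role(row["role"].strip())
                category = ParameterCategory(row["parameter_category"].strip())
                mode = CultureMode(row["culture_mode"].strip())
            except ValueError as exc:
                raise DatasetError(f"{locator}: {exc}") from exc
            dist = None
            if cid in raw_dists:
                try:
                    dist = normalize_distribution(raw_dists[cid], tolerance=tolerance)
                except ValueError as exc:
                    raise DatasetError(f"{locator} ({cid}): {exc}") from exc
            try:
                rec = ConditionRecord(
                    study_id=row["study_id"].strip(),
                    condition_id=cid,
                    role=role,
                    parameter_category=category,
                    manipulation_type=row["manipulation_type"].strip(),
                    cell_line=row["cell_line"].strip(),
                    product=row["product"].strip(),
                    culture_mode=mode,
                    distribution=dist,
                    reported_indices=_parse_reported(row, locator),
                    reference=(row.get("reference") or "").strip(),
                    experiment_group=(row.get("experiment_group") or "").strip() or None,
                    replicate_group=(row.get("replicate_group") or "").strip() or None,
                )
            except DatasetError as exc:
                raise DatasetError(f"{locator}: {exc}") from exc
            records.append(rec)
    orphans = set(raw_dists) - seen_ids
    if orphans:
        raise DatasetError(
            f"{distributions_path}: unknown condition_id(s) {sorted(orphans)}"
        )
    return records


def write_study_table(
    records: Sequence[ConditionRecord],
    metadata_path: str | Path,
    distributions_path: str | Path,
    *,
    raw_distributions: Mapping[str, Mapping[str, float]] | None = None,
) -> None:
    """Write records back to the two-CSV on-disk form.

    Pass ``raw_distributions`` (as read from disk) to preserve the original
    raw abundances bit-exactly; otherwise the normalized values are written.
    """
    with open(metadata_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_COLUMNS)
        for rec in records:
            rep = rec.reported_indices
            writer.writerow([
                rec.study_id, rec.condition_id, rec.role.value,
                rec.parameter_category.value, rec.manipulation_type,
                rec.experiment_group or "", rec.replicate_group or "",
                rec.cell_line, rec.product, rec.culture_mode.value, rec.reference,
                "" if rep is None or rep.fi is None else repr(rep.fi),
                "" if rep is None or rep.gi is None else repr(rep.gi),
                "" if rep is None or rep.si is None else repr(rep.si),
            ])
    dists: dict[str, Mapping[str, float]] = {}
    for rec in records:
        if rec.distribution is None:
            continue
        if raw_distributions and rec.condition_id in raw_distributions:
            dists[rec.condition_id] = raw_distributions[rec.condition_id]
        else:
            dists[rec.condition_id] = dict(rec.distribution.abundances)
    write_distributions_csv(dists, distributions_path)


def dataset_to_json(records: Sequence[ConditionRecord], path: str | Path) -> None:
    """Export the merged dataset (metadata + distributions) as one JSON doc."""
    doc = []
    for rec in records:
        rep = rec.reported_indices
        doc.append({
            "study_id": rec.study_id,
            "condition_id": rec.condition_id,
            "role": rec.role.value,
            "parameter_category": rec.parameter_category.value,
            "manipulation_type": rec.manipulation_type,
            "experiment_group": rec.experiment_group,
            "replicate_group": rec.replicate_group,
            "cell_line": rec.cell_line,
            "product": rec.product,
            "culture_mode": rec.culture_mode.value,
            "reference": rec.reference,
            "suitable_for_indices": rec.suitable_for_indices,
            "distribution": None if rec.distribution is None
            else dict(rec.distribution.abundances),
            "reported_indices": None if rep is None
            else {"fi": rep.fi, "gi": rep.gi, "si": rep.si},
        })
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


@dataclass
class PairingResult:
    pairs: list[ConditionPair]
    unpaired: list[ConditionRecord]


def pair_conditions(records: Iterable[ConditionRecord]) -> PairingResult:
    """Match every manipulated condition with its experiment group's control.

    A multi-level manipulation series (several setpoints against one
    control) yields one pair per level sharing that control.  Groups with
    more than one control are an error; manipulated records in a group with
    no control are returned in ``unpaired``.
    """
    controls: dict[tuple[str, str], ConditionRecord] = {}
    for rec in records:
        if rec.role is Role.CONTROL:
            key = rec.group_key
            if key in controls:
                raise DatasetError(
                    f"study {key[0]!r} group {key[1]!r} has multiple controls "
                    f"({controls[key].condition_id}, {rec.condition_id})"
                )
            controls[key] = rec
    pairs: list[ConditionPair] = []
    unpaired: list[ConditionRecord] = []
    for rec in records:
        if rec.role is not Role.MANIPULATED:
            continue
        control = controls.get(rec.group_key)
        if control is None:
            unpaired.append(rec)
        else:
            pairs.append(ConditionPair(control=control, manipulated=rec))
    return PairingResult(pairs=pairs, unpaired=unpaired)


#: Clustering order used across the compiled tables: operational parameter,
#: then perturbation type, culture mode and CHO cell lineage.
DEFAULT_GROUPING_KEYS = (
    "parameter_category", "manipulation_type", "culture_mode", "cell_line",
)

_GROUPABLE = set(DEFAULT_GROUPING_KEYS)


def _key_value(pair: ConditionPair, key: str) -> str:
    value = getattr(pair, key)
    return value.value if isinstance(value, Enum) else str(value)


def group_pairs(pairs: Sequence[ConditionPair], keys: Sequence[str] = DEFAULT_GROUPING_KEYS):
    """Deterministic nested grouping of pairs by the given metadata keys.

    Returns a nested dict whose leaves are lists of pairs ordered by
    study_id (then condition id for stability); ``keys = []`` yields a
    single leaf list.  Group labels at each level are sorted.
    """
    for key in keys:
        if key not in _GROUPABLE:
            raise DatasetError(f"unknown grouping key {key!r}; choose from {sorted(_GROUPABLE)}")
    ordered = sorted(pairs, key=lambda p: (p.study_id, p.manipulated.condition_id))
    if not keys:
        return ordered
    head, *rest = keys
    buckets: dict[str, list[ConditionPair]] = {}
    for pair in ordered:
        buckets.setdefault(_key_value(pair, head), []).append(pair)
    return {label: group_pairs(buckets[label], rest) for label in sorted(buckets)}
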