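"""End-to-end comparison of control vs. manipulated culture conditions.

For every control–manipulated pair the pipeline computes per-index signed
deltas (manipulated minus control, percentage points), the absolute delta
ΔGIx, and an effect-magnitude bin with left-closed edges at 1.5, 5 and 10
percentage points — the granularity at which process-parameter effects on
IgG glycosylation are typically discussed (negligible / minor / moderate /
major).  Summative-index deltas are computed the same way where both
distributions exist.

Because an occupancy index can stay constant while the underlying glycoform
distribution redistributes (e.g. FA2G1 <-> FA2G2 at constant total
galactose), each comparison also reports the per-species abundance shifts,
so both reporting layers — distribution and indices — stay visible.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .dataset import (
    DEFAULT_GROUPING_KEYS,
    ConditionRecord,
    DatasetError,
    PairingResult,
    group_pairs,
    pair_conditions,
)
from .indices import GlycanDistribution, IndexSet, compute_index_set

__all__ = [
    "EffectBin",
    "Direction",
    "IndexDelta",
    "ComparisonRecord",
    "AggregateReport",
    "PipelineConfig",
    "PipelineResult",
    "classify_effect",
    "delta_indices",
    "species_shifts",
    "average_index_sets",
    "condition_index_set",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = (1.5, 5.0, 10.0)

INDEX_NAMES = ("fi", "gi", "si", "summ_fucose", "summ_galactose", "summ_sialic")
GIX_NAMES = ("fi", "gi", "si")


class EffectBin(str, Enum):
    NEGLIGIBLE = "negligible"
    MINOR = "minor"
    MODERATE = "moderate"
    MAJOR = "major"
    NOT_EVALUABLE = "not_evaluable"


class Direction(str, Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    NONE = "none"


def classify_effect(
    delta_abs: float | None,
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
    *,
    edge_tol: float = 1e-9,
) -> EffectBin:
    """Bin an absolute index change (percentage points) by magnitude.

    Left-closed bins: [0, e1) negligible, [e1, e2) minor, [e2, e3) moderate,
    [e3, inf) major; a missing delta is not evaluable.  A delta within
    ``edge_tol`` of an edge is treated as sitting on it (and so falls in
    the upper bin): index deltas carry float rounding from the weighted
    sums, and a true boundary value must not slip into the lower bin.
    """
    if delta_abs is None:
        return EffectBin.NOT_EVALUABLE
    if delta_abs < 0:
        raise ValueError(f"absolute delta must be >= 0, got {delta_abs}")
    if len(edges) != 3 or list(edges) != sorted(edges):
        raise ValueError(f"need three increasing bin edges, got {edges!r}")
    e1, e2, e3 = edges
    if delta_abs < e1 - edge_tol:
        return EffectBin.NEGLIGIBLE
    if delta_abs < e2 - edge_tol:
        return EffectBin.MINOR
    if delta_abs < e3 - edge_tol:
        return EffectBin.MODERATE
    return EffectBin.MAJOR


@dataclass(frozen=True)
class IndexDelta:
    """Signed and absolute change of one index across a pair."""

    signed: float | None
    absolute: float | None
    bin: EffectBin
    direction: Direction

    @classmethod
    def from_values(
        cls,
        control: float | None,
        manipulated: float | None,
        edges: Sequence[float] = DEFAULT_BIN_EDGES,
    ) -> "IndexDelta":
        if control is None or manipulated is None:
            return cls(None, None, EffectBin.NOT_EVALUABLE, Direction.NONE)
        signed = manipulated - control
        if signed > 0:
            direction = Direction.INCREASE
        elif signed < 0:
            direction = Direction.DECREASE
        else:
            direction = Direction.NONE
        return cls(signed, abs(signed), classify_effect(abs(signed), edges), direction)


def delta_indices(
    control: IndexSet,
    manipulated: IndexSet,
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> dict[str, IndexDelta]:
    """Per-index deltas between two index sets (computed or reported).

    An index missing on either side propagates to a not-evaluable delta.
    """
    return {
        name: IndexDelta.from_values(getattr(control, name), getattr(manipulated, name), edges)
        for name in INDEX_NAMES
    }


def species_shifts(
    control: GlycanDistribution | None, manipulated: GlycanDistribution | None
) -> dict[str, float] | None:
    """Signed per-species abundance changes (manipulated - control, pp).

    None when either distribution is absent.  This is the distribution
    reporting layer: large shifts here can coexist with near-zero index
    deltas when mass redistributes at constant net occupancy.
    """
    if control is None or manipulated is None:
        return None
    names = sorted(set(control.abundances) | set(manipulated.abundances))
    return {
        n: manipulated.abundances.get(n, 0.0) - control.abundances.get(n, 0.0)
        for n in names
    }


@dataclass(frozen=True)
class ComparisonRecord:
    """Full two-layer comparison of one control–manipulated pair."""

    study_id: str
    control_id: str
    manipulated_id: str
    parameter_category: str
    manipulation_type: str
    culture_mode: str
    cell_line: str
    deltas: Mapping[str, IndexDelta]
    species_shifts: Mapping[str, float] | None
    control_indices: IndexSet
    manipulated_indices: IndexSet

    @property
    def max_species_shift(self) -> float | None:
        if self.species_shifts is None:
            return None
        return max((abs(v) for v in self.species_shifts.values()), default=0.0)

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "study_id": self.study_id,
            "control_id": self.control_id,
            "manipulated_id": self.manipulated_id,
            "parameter_category": self.parameter_category,
            "manipulation_type": self.manipulation_type,
            "culture_mode": self.culture_mode,
            "cell_line": self.cell_line,
        }
        for name, d in self.deltas.items():
            row[f"delta_{name}_signed"] = d.signed
            row[f"delta_{name}_abs"] = d.absolute
            row[f"{name}_bin"] = d.bin.value
            row[f"{name}_direction"] = d.direction.value
        row["max_species_shift"] = self.max_species_shift
        return row


@dataclass
class GroupSummary:
    """Aggregate over one node of the grouping tree."""

    path: tuple[str, ...]
    n_pairs: int
    bin_counts: dict[str, dict[str, int]]
    dgix_min: dict[str, float | None]
    dgix_median: dict[str, float | None]
    dgix_max: dict[str, float | None]
    major_pairs: dict[str, list[str]]


@dataclass
class AggregateReport:
    """Machine-readable aggregate: one summary per grouping node.

    Bin counts per index always sum to the node's pair count.
    """

    grouping_keys: tuple[str, ...]
    groups: list[GroupSummary]
    n_pairs: int
    n_not_evaluable: dict[str, int]

    def to_dict(self) -> dict[str, object]:
        return {
            "grouping_keys": list(self.grouping_keys),
            "n_pairs": self.n_pairs,
            "n_not_evaluable": self.n_not_evaluable,
            "groups": [
                {
                    "path": list(g.path),
                    "n_pairs": g.n_pairs,
                    "bin_counts": g.bin_counts,
                    "delta_min": g.dgix_min,
                    "delta_median": g.dgix_median,
                    "delta_max": g.dgix_max,
                    "major_pairs": g.major_pairs,
                }
                for g in self.groups
            ],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


@dataclass(frozen=True)
class PipelineConfig:
    grouping_keys: tuple[str, ...] = DEFAULT_GROUPING_KEYS
    bin_edges: tuple[float, float, float] = DEFAULT_BIN_EDGES
    tolerance: float = 5.0
    strict: bool = False
    high_mannose_fucosylatable: bool = False


@dataclass
class PipelineResult:
    comparisons: list[ComparisonRecord]
    report: AggregateReport
    pairing: PairingResult
    index_sets: dict[str, IndexSet]


def average_index_sets(sets: Sequence[IndexSet]) -> IndexSet:
    """Index-level mean across batch replicates of one condition.

    Each index is averaged over the replicates where it is present; the
    spread (max - min) per index is logged.  Mixing computed and reported
    provenance within one replicate group is rejected.
    """
    if not sets:
        raise ValueError("no index sets to average")
    if len(sets) == 1:
        return sets[0]
    provenances = {s.provenance for s in sets}
    if len(provenances) > 1:
        raise DatasetError("replicate group mixes computed and reported indices")
    values: dict[str, float | None] = {}
    for name in INDEX_NAMES:
        present = [getattr(s, name) for s in sets if getattr(s, name) is not None]
        if not present:
            values[name] = None
            continue
        values[name] = sum(present) / len(present)
        spread = max(present) - min(present)
        if spread:
            logger.info("replicate spread for %s: %.3g pp over %d replicates",
                        name, spread, len(present))
    return IndexSet(provenance=provenances.pop(), **{
        "fi": values["fi"], "gi": values["gi"], "si": values["si"],
        "summ_fucose": values["summ_fucose"],
        "summ_galactose": values["summ_galactose"],
        "summ_sialic": values["summ_sialic"],
    })


def condition_index_set(rec: ConditionRecord, config: PipelineConfig) -> IndexSet:
    """Indices for one condition: computed from its distribution when
    present, otherwise taken as reported (summatives then unavailable)."""
    if rec.distribution is not None:
        return compute_index_set(
            rec.distribution,
            strict=config.strict,
            high_mannose_fucosylatable=config.high_mannose_fucosylatable,
        )
    assert rec.reported_indices is not None
    return rec.reported_indices


def _collapse_replicates(
    records: Sequence[ConditionRecord], config: PipelineConfig
) -> tuple[list[ConditionRecord], dict[str, IndexSet]]:
    """Average replicate conditions at the index level before pairing.

    Records sharing (study, experiment group, role, replicate_group) are
    collapsed onto the first record of the group; its id keys the averaged
    IndexSet.  Distributions of collapsed replicates are not merged — only
    indices are averaged — so a collapsed group loses its species-shift
    layer unless it has a single member.
    """
    index_sets: dict[str, IndexSet] = {}
    kept: list[ConditionRecord] = []
    groups: dict[tuple, list[ConditionRecord]] = {}
    for rec in records:
        if rec.replicate_group is None:
            kept.append(rec)
            index_sets[rec.condition_id] = condition_index_set(rec, config)
        else:
            key = (*rec.group_key, rec.role, rec.replicate_group)
            groups.setdefault(key, []).append(rec)
    for members in groups.values():
        lead = members[0]
        averaged = average_index_sets([condition_index_set(m, config) for m in members])
        kept.append(lead)
        index_sets[lead.condition_id] = averaged
        if len(members) > 1:
            logger.info("averaged %d replicates onto %s", len(members), lead.condition_id)
    return kept, index_sets


def _summarize(path: tuple[str, ...], comps: Sequence[ComparisonRecord],
               names: Sequence[str] = GIX_NAMES) -> GroupSummary:
    bin_counts: dict[str, dict[str, int]] = {}
    mins: dict[str, float | None] = {}
    medians: dict[str, float | None] = {}
    maxs: dict[str, float | None] = {}
    majors: dict[str, list[str]] = {}
    for name in names:
        counts = {b.value: 0 for b in EffectBin}
        present: list[float] = []
        major_ids: list[str] = []
        for c in comps:
            d = c.deltas[name]
            counts[d.bin.value] += 1
            if d.absolute is not None:
                present.append(d.absolute)
            if d.bin is EffectBin.MAJOR:
                major_ids.append(c.manipulated_id)
        bin_counts[name] = counts
        mins[name] = min(present) if present else None
        medians[name] = statistics.median(present) if present else None
        maxs[name] = max(present) if present else None
        majors[name] = major_ids
    return GroupSummary(path, len(comps), bin_counts, mins, medians, maxs, majors)


def _walk(tree, path: tuple[str, ...], comp_of: Mapping[str, ComparisonRecord],
          out: list[GroupSummary]) -> None:
    if isinstance(tree, dict):
        for label in tree:
            _walk(tree[label], path + (label,), comp_of, out)
    else:
        comps = [comp_of[p.manipulated.condition_id] for p in tree
                 if p.manipulated.condition_id in comp_of]
        out.append(_summarize(path, comps))


def run_pipeline(
    records: Iterable[ConditionRecord],
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Compute indices, pair conditions, compare, classify and aggregate.

    Deterministic for a given input; unpaired records and not-evaluable
    deltas are logged, never silently dropped from the report counters.
    """
    records = list(records)
    collapsed, index_sets = _collapse_replicates(records, config)
    pairing = pair_conditions(collapsed)
    for rec in pairing.unpaired:
        logger.warning("no control for %s (study %s); excluded from pairs",
                       rec.condition_id, rec.study_id)
    comparisons: list[ComparisonRecord] = []
    for pair in sorted(pairing.pairs,
                       key=lambda p: (p.study_id, p.manipulated.condition_id)):
        ctrl, man = pair.control, pair.manipulated
        deltas = delta_indices(index_sets[ctrl.condition_id],
                               index_sets[man.condition_id], config.bin_edges)
        comparisons.append(ComparisonRecord(
            study_id=pair.study_id,
            control_id=ctrl.condition_id,
            manipulated_id=man.condition_id,
            parameter_category=pair.parameter_category.value,
            manipulation_type=pair.manipulation_type,
            culture_mode=pair.culture_mode.value,
            cell_line=pair.cell_line,
            deltas=deltas,
            species_shifts=species_shifts(ctrl.distribution, man.distribution),
            control_indices=index_sets[ctrl.condition_id],
            manipulated_indices=index_sets[man.condition_id],
        ))
    comp_of = {c.manipulated_id: c for c in comparisons}
    tree = group_pairs(pairing.pairs, config.grouping_keys)
    summaries: list[GroupSummary] = [_summarize((), comparisons)]
    if isinstance(tree, dict):
        _walk(tree, (), comp_of, summaries)
    n_not_eval = {
        name: sum(1 for c in comparisons
                  if c.deltas[name].bin is EffectBin.NOT_EVALUABLE)
        for name in INDEX_NAMES
    }
    report = AggregateReport(
        grouping_keys=tuple(config.grouping_keys),
        groups=summaries,
        n_pairs=len(comparisons),
        n_not_evaluable=n_not_eval,
    )
    return PipelineResult(comparisons, report, pairing, index_sets)


def comparisons_to_csv(comparisons: Sequence[ComparisonRecord], path: str | Path) -> None:
    """Write comparison records as a flat CSV (one row per pair)."""
    import csv

    rows = [c.to_row() for c in comparisons]
    if not rows:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write("")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        for row in rows:
            writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
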