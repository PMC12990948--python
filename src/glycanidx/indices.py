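"""Glycan index computation from normalized glycoform distributions.

A condition's released-glycan pool is summarized as a distribution of
relative abundances (percent) over glycoform species.  From it we compute:

* the three occupancy **glycan indices** — galactosylation index (GI),
  sialylation index (SI) and fucosylation index (FI) — each the
  abundance-weighted fraction of available sites occupied by the respective
  monosaccharide, expressed in percent;
* the three **summative indices** — the total abundance of species carrying
  at least one galactose, NeuAc or core fucose residue.

Indices with an empty denominator (e.g. SI when no species carries
galactose) are reported as missing with a warning, or raise in strict mode;
published tables routinely contain such conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .nomenclature import parse_species, species_weights

__all__ = [
    "GlycanDistribution",
    "IndexSet",
    "Provenance",
    "MissingDenominatorError",
    "NormalizationError",
    "normalize_distribution",
    "galactosylation_index",
    "sialylation_index",
    "fucosylation_index",
    "summative_indices",
    "compute_index_set",
]

logger = logging.getLogger(__name__)

#: Abundance labels carrying no structural information, dropped before
#: normalization (case-insensitive match).
UNASSIGNED_LABELS = frozenset({"other", "others", "unassigned", "unknown"})

_SUM_TOL = 1e-9


class NormalizationError(ValueError):
    """Raised when a raw distribution cannot be normalized."""


class MissingDenominatorError(ValueError):
    """Raised in strict mode when an index denominator is zero."""


class Provenance(str, Enum):
    """How an :class:`IndexSet` was obtained."""

    COMPUTED = "computed_from_distribution"
    REPORTED = "reported_in_source"


@dataclass(frozen=True)
class GlycanDistribution:
    """Normalized glycoform distribution: canonical species name -> percent.

    Abundances are strictly positive and sum to 100 (within 1e-9);
    ``raw_total`` keeps the pre-normalization sum for audit.
    """

    abundances: Mapping[str, float]
    normalization_applied: bool = False
    raw_total: float = 100.0

    def __post_init__(self) -> None:
        if not self.abundances:
            raise NormalizationError("distribution has no species")
        for name, value in self.abundances.items():
            parse_species(name)
            if not value > 0:
                raise NormalizationError(f"abundance of {name} must be > 0, got {value}")
        total = math.fsum(self.abundances.values())
        if abs(total - 100.0) > _SUM_TOL:
            raise NormalizationError(f"abundances sum to {total!r}, expected 100")

    def species(self) -> tuple[str, ...]:
        return tuple(self.abundances)


def normalize_distribution(
    raw: Mapping[str, float],
    tolerance: float = 5.0,
    *,
    drop_unassigned: bool = True,
) -> GlycanDistribution:
    """Validate and rescale a raw abundance table to sum exactly 100.

    Species named like "Other"/"Unassigned" are dropped (logged) before
    normalization when ``drop_unassigned`` is set, as are zero abundances.
    The remaining total must lie within ``100 ± tolerance`` percentage
    points (published tables carry rounding error and omit trace species);
    otherwise a :class:`NormalizationError` reports the offending total.
    Species names are canonicalized through the parser; the pre-drop,
    pre-rescale total is preserved in ``raw_total``.
    """
    if not raw:
        raise NormalizationError("empty distribution")
    raw_total = math.fsum(raw.values())
    kept: dict[str, float] = {}
    for name, value in raw.items():
        if drop_unassigned and str(name).strip().lower() in UNASSIGNED_LABELS:
            logger.info("dropping unassigned category %r (%.4g%%)", name, value)
            continue
        if value < 0:
            raise NormalizationError(f"negative abundance for {name}: {value}")
        if value == 0:
            continue
        canonical = parse_species(name).name
        if canonical in kept:
            raise NormalizationError(f"duplicate species {canonical!r} in distribution")
        kept[canonical] = float(value)
    if not kept:
        raise NormalizationError("no positive, assigned abundances in distribution")
    total = math.fsum(kept.values())
    lo, hi = 100.0 - tolerance, 100.0 + tolerance
    if not lo <= total <= hi:
        raise NormalizationError(f"total {total:g} outside [{lo:g},{hi:g}]")
    rescaled = total != 100.0
    if rescaled:
        logger.info("rescaling distribution by 100/%.6g", total)
        kept = {k: v * 100.0 / total for k, v in kept.items()}
        resid = math.fsum(kept.values()) - 100.0
        if resid:  # push float residue onto the largest component
            top = max(kept, key=kept.__getitem__)
            kept[top] -= resid
    return GlycanDistribution(kept, normalization_applied=rescaled, raw_total=raw_total)


def _ratio_index(
    dist: GlycanDistribution,
    numer_attr: str,
    denom_attr: str,
    label: str,
    strict: bool,
    **weight_opts,
) -> float | None:
    numer = 0.0
    denom = 0.0
    for name, p in dist.abundances.items():
        w = species_weights(parse_species(name), **weight_opts)
        numer += getattr(w, numer_attr) * p
        denom += getattr(w, denom_attr) * p
    if denom == 0.0:
        msg = f"{label} undefined: no {denom_attr.replace('_', ' ')} in distribution"
        if strict:
            raise MissingDenominatorError(msg)
        logger.warning(msg)
        return None
    return 100.0 * numer / denom


def galactosylation_index(dist: GlycanDistribution, *, strict: bool = False) -> float | None:
    """GI: percent of galactose-capable sites (antennae) carrying galactose.

    Sialyl-capped galactose still occupies its antenna and counts as
    occupied.  Missing (or raising in strict mode) when no species has
    antennae, e.g. a purely high-mannose pool.
    """
    return _ratio_index(dist, "gal_residues", "antenna_sites", "GI", strict)


def sialylation_index(dist: GlycanDistribution, *, strict: bool = False) -> float | None:
    """SI: percent of sialylatable sites (galactose residues) carrying NeuAc."""
    return _ratio_index(dist, "sial_residues", "sialylatable_sites", "SI", strict)


def fucosylation_index(
    dist: GlycanDistribution,
    *,
    strict: bool = False,
    high_mannose_fucosylatable: bool = False,
) -> float | None:
    """FI: percent of fucosylatable (complex-type) species carrying core fucose.

    High-mannose species are excluded from numerator and denominator by
    default; set ``high_mannose_fucosylatable`` to count them as able to
    receive core fucose.
    """
    return _ratio_index(
        dist, "fucosylated", "fucosylatable", "FI", strict,
        high_mannose_fucosylatable=high_mannose_fucosylatable,
    )


def summative_indices(dist: GlycanDistribution) -> tuple[float, float, float]:
    """Total abundance of species carrying >=1 fucose / galactose / NeuAc.

    Returns ``(summ_fucose, summ_galactose, summ_sialic)`` in percent of the
    glycan pool; the afucosylated share is ``100 - summ_fucose``.
    """
    fuc = gal = sia = 0.0
    for name, p in dist.abundances.items():
        sp = parse_species(name)
        if sp.core_fucose:
            fuc += p
        if sp.galactose_count:
            gal += p
        if sp.sialic_count:
            sia += p
    return fuc, gal, sia


@dataclass(frozen=True)
class IndexSet:
    """FI/GI/SI plus summative indices for one condition, in percent.

    Values are ``None`` when not computable (empty denominator) or not
    provided by the source.  When provenance is ``REPORTED`` the underlying
    distribution is unavailable, so summative indices are necessarily
    missing.
    """

    fi: float | None = None
    gi: float | None = None
    si: float | None = None
    summ_fucose: float | None = None
    summ_galactose: float | None = None
    summ_sialic: float | None = None
    provenance: Provenance = Provenance.COMPUTED

    _INDEX_FIELDS = ("fi", "gi", "si", "summ_fucose", "summ_galactose", "summ_sialic")

    def __post_init__(self) -> None:
        for name in self._INDEX_FIELDS:
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0 + _SUM_TOL:
                raise ValueError(f"{name} = {v} outside [0, 100]")
        if self.provenance is Provenance.REPORTED:
            if any(getattr(self, n) is not None
                   for n in ("summ_fucose", "summ_galactose", "summ_sialic")):
                raise ValueError(
                    "summative indices cannot be computed for indices taken as reported"
                )

    def rounded(self, ndigits: int = 1) -> dict[str, float | None]:
        """Reporting view at the conventional one-decimal granularity."""
        return {
            n: (None if getattr(self, n) is None else round(getattr(self, n), ndigits))
            for n in self._INDEX_FIELDS
        }


def compute_index_set(
    dist: GlycanDistribution,
    *,
    strict: bool = False,
    high_mannose_fucosylatable: bool = False,
) -> IndexSet:
    """Bundle all five index computations for one distribution."""
    fuc, gal, sia = summative_indices(dist)
    return IndexSet(
        fi=fucosylation_index(
            dist, strict=strict, high_mannose_fucosylatable=high_mannose_fucosylatable
        ),
        gi=galactosylation_index(dist, strict=strict),
        si=sialylation_index(dist, strict=strict),
        summ_fucose=fuc,
        summ_galactose=gal,
        summ_sialic=sia,
        provenance=Provenance.COMPUTED,
    )
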