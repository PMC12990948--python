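"""Oxford-style glycoform shorthand: parsing, formatting and index weights.

IgG Fc N-glycans are written in the compact Oxford notation, e.g. ``FA2G1S1``:
an optional leading ``F`` for core fucose, ``A<n>`` for the number of GlcNAc
antennae, an optional ``B`` for bisecting GlcNAc, ``G<n>`` for galactose
residues, an optional ``S<n>`` for N-acetylneuraminic acid (NeuAc) residues.
High-mannose species are written ``M<n>`` with n in 5..9; ``M3`` denotes the
bare trimannosyl core (no antennae).

Each species contributes fixed integer weights to the occupancy-index
equations: galactose residues over galactose-capable sites (antennae) for the
galactosylation index, NeuAc residues over sialylatable sites (galactoses) for
the sialylation index, and binary core-fucose membership over the set of
species able to receive core fucose for the fucosylation index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "GlycanSpecies",
    "IndexWeights",
    "GlycanNameError",
    "GlycanStructureError",
    "parse_species",
    "format_species",
    "species_weights",
    "VOCABULARY",
    "vocabulary_table",
]


class GlycanNameError(ValueError):
    """Raised when a shorthand string does not match the grammar."""


class GlycanStructureError(ValueError):
    """Raised when a name parses but describes an impossible structure."""


_COMPLEX_RE = re.compile(r"^(?P<fuc>F)?A(?P<ant>\d)(?P<bis>B)?G(?P<gal>\d)(?:S(?P<sial>\d))?$")
_MANNOSE_RE = re.compile(r"^M(?P<deg>\d)$")

_MAX_ANTENNARITY = 4
_VALID_MANNOSE_DEGREES = frozenset({3, 5, 6, 7, 8, 9})


@dataclass(frozen=True, slots=True)
class GlycanSpecies:
    """Structural record of a single glycoform.

    ``high_mannose_degree`` is 0 for complex-type species and 5..9 for
    high-mannose ones.  The trimannosyl core M3 is encoded with antennarity 0
    and degree 0: it has no GlcNAc antennae, so it is not galactose-capable,
    and it is excluded from the core-fucosylation denominator.
    """

    core_fucose: bool
    antennarity: int
    bisecting: bool
    galactose_count: int
    sialic_count: int
    high_mannose_degree: int

    def __post_init__(self) -> None:
        if self.high_mannose_degree > 0:
            if self.high_mannose_degree not in _VALID_MANNOSE_DEGREES - {3}:
                raise GlycanStructureError(
                    f"high-mannose degree must be 5..9, got M{self.high_mannose_degree}"
                )
            if self.core_fucose or self.antennarity or self.galactose_count \
                    or self.sialic_count or self.bisecting:
                raise GlycanStructureError(
                    "high-mannose species carry no fucose, antennae, galactose or NeuAc"
                )
        else:
            if not 0 <= self.antennarity <= _MAX_ANTENNARITY:
                raise GlycanStructureError(
                    f"antennarity must be 0..{_MAX_ANTENNARITY}, got {self.antennarity}"
                )
            if self.antennarity == 0 and (self.core_fucose or self.bisecting):
                raise GlycanStructureError("M3 (antennarity 0) carries no fucose or bisecting GlcNAc")
            if not 0 <= self.sialic_count <= self.galactose_count <= self.antennarity:
                raise GlycanStructureError(
                    f"need 0 <= S ({self.sialic_count}) <= G ({self.galactose_count})"
                    f" <= A ({self.antennarity})"
                )

    @property
    def is_high_mannose(self) -> bool:
        return self.high_mannose_degree > 0

    @property
    def is_complex(self) -> bool:
        """True for antennary complex-type species (excludes M3 and M5-M9)."""
        return self.high_mannose_degree == 0 and self.antennarity > 0

    @property
    def name(self) -> str:
        return format_species(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass(frozen=True, slots=True)
class IndexWeights:
    """Per-species coefficients entering the three index equations.

    gal_residues / antenna_sites feed the galactosylation index (galactoses
    over galactose-capable antennae, counting sialyl-capped galactose as
    occupied); sial_residues / sialylatable_sites feed the sialylation index
    (NeuAc over total galactose, since NeuAc attaches only to galactose);
    fucosylated / fucosylatable feed the fucosylation index (binary core
    fucose over complex-type species).
    """

    gal_residues: int
    antenna_sites: int
    sial_residues: int
    sialylatable_sites: int
    fucosylated: int
    fucosylatable: int


def parse_species(name: str) -> GlycanSpecies:
    """Parse an Oxford shorthand name into a :class:`GlycanSpecies`.

    The grammar is ``F? A<d> B? G<d> (S<d>)?`` for complex-type species and
    ``M<d>`` (d in {3, 5..9}) for the trimannosyl core and high-mannose
    species; case-sensitive, no whitespace.

    Raises
    ------
    GlycanNameError
        If the text does not match the grammar.
    GlycanStructureError
        If it matches but describes an impossible structure (G > A, S > G,
        M<d> with d outside {3, 5..9}).
    """
    if not isinstance(name, str):
        raise GlycanNameError(f"species name must be text, got {type(name).__name__}")
    m = _MANNOSE_RE.match(name)
    if m:
        degree = int(m.group("deg"))
        if degree not in _VALID_MANNOSE_DEGREES:
            raise GlycanStructureError(
                f"{name!r}: mannose degree must be 3 or 5..9, got M{degree}"
            )
        if degree == 3:
            return GlycanSpecies(False, 0, False, 0, 0, 0)
        return GlycanSpecies(False, 0, False, 0, 0, degree)
    m = _COMPLEX_RE.match(name)
    if m is None:
        raise GlycanNameError(
            f"{name!r} does not match the shorthand grammar F?A<d>B?G<d>(S<d>)? or M<d>"
        )
    ant = int(m.group("ant"))
    gal = int(m.group("gal"))
    sial = int(m.group("sial")) if m.group("sial") is not None else 0
    if ant == 0 or ant > _MAX_ANTENNARITY:
        raise GlycanStructureError(f"{name!r}: antennarity must be 1..{_MAX_ANTENNARITY}")
    if gal > ant:
        raise GlycanStructureError(f"{name!r}: galactose count {gal} exceeds antennae {ant}")
    if sial > gal:
        raise GlycanStructureError(f"{name!r}: NeuAc count {sial} exceeds galactose {gal}")
    return GlycanSpecies(
        core_fucose=m.group("fuc") is not None,
        antennarity=ant,
        bisecting=m.group("bis") is not None,
        galactose_count=gal,
        sialic_count=sial,
        high_mannose_degree=0,
    )


def format_species(sp: GlycanSpecies) -> str:
    """Canonical shorthand for a species; inverse of :func:`parse_species`.

    Canonical order is ``F A<n> B G<n> S<n>`` with ``S0`` omitted; the
    antennarity-0 complex record is written ``M3``.
    """
    if sp.high_mannose_degree > 0:
        return f"M{sp.high_mannose_degree}"
    if sp.antennarity == 0:
        return "M3"
    parts = []
    if sp.core_fucose:
        parts.append("F")
    parts.append(f"A{sp.antennarity}")
    if sp.bisecting:
        parts.append("B")
    parts.append(f"G{sp.galactose_count}")
    if sp.sialic_count:
        parts.append(f"S{sp.sialic_count}")
    return "".join(parts)


def species_weights(sp: GlycanSpecies, *, high_mannose_fucosylatable: bool = False) -> IndexWeights:
    """Index-equation weights for one species.

    High-mannose species (and M3) carry zero weight everywhere: no antennae,
    no galactose, no NeuAc, and — unless ``high_mannose_fucosylatable`` is
    set — they are also excluded from the fucosylation denominator, since
    core fucosylation requires the complex/hybrid processing pathway.
    """
    if sp.is_high_mannose or sp.antennarity == 0:
        fucosylatable = 1 if (high_mannose_fucosylatable and sp.is_high_mannose) else 0
        return IndexWeights(0, 0, 0, 0, 0, fucosylatable)
    return IndexWeights(
        gal_residues=sp.galactose_count,
        antenna_sites=sp.antennarity,
        sial_residues=sp.sialic_count,
        sialylatable_sites=sp.galactose_count,
        fucosylated=1 if sp.core_fucose else 0,
        fucosylatable=1,
    )


#: Species vocabulary observed across the compiled condition tables.
VOCABULARY: tuple[str, ...] = (
    "FA2G0", "FA2G1", "FA2G2",
    "A2G0", "A2G1", "A2G2",
    "FA2G1S1", "FA2G2S1", "FA2G2S2",
    "A1G0", "M3", "M5",
)


def vocabulary_table():
    """Machine-readable table of the vocabulary species and their weights.

    Returns a :class:`pandas.DataFrame` with one row per species, exported
    for documentation and audit.
    """
    import pandas as pd

    rows = []
    for name in VOCABULARY:
        sp = parse_species(name)
        w = species_weights(sp)
        rows.append({
            "species": name,
            "core_fucose": sp.core_fucose,
            "antennarity": sp.antennarity,
            "galactose_count": sp.galactose_count,
            "sialic_count": sp.sialic_count,
            "high_mannose_degree": sp.high_mannose_degree,
            "gal_residues": w.gal_residues,
            "antenna_sites": w.antenna_sites,
            "sial_residues": w.sial_residues,
            "sialylatable_sites": w.sialylatable_sites,
            "fucosylated": w.fucosylated,
            "fucosylatable": w.fucosylatable,
        })
    return pd.DataFrame(rows)
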