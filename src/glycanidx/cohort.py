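"""Synthetic glycoform cohorts from an independent-site occupancy model.

Each complex-type biantennary glycan is modeled with three independent
Bernoulli/binomial layers: core fucosylation with probability ``p_fucose``,
galactosylation of each of the A antennae independently with ``p_gal``, and
sialylation of each attached galactose independently with ``p_sial``; an
optional ``high_mannose_fraction`` of the pool is assigned to M5.  Under
this model the occupancy indices have closed forms

    FI = 100 * p_fucose,   GI = 100 * p_gal,   SI = 100 * p_sial,

unaffected by the high-mannose fraction (which carries no weight in any
index), so every downstream stage can be checked against known truth.
The defaults emulate a typical literature CHO IgG profile (FI above 85%,
GI in the 10-30% band, SI below 10%).

Real glycosylation couples these layers through shared Golgi residence and
substrate pools; that coupling is deliberately not modeled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dataset import ConditionRecord, CultureMode, ParameterCategory, Role
from .indices import GlycanDistribution, normalize_distribution
from .nomenclature import GlycanSpecies, format_species

__all__ = [
    "GeneratorParams",
    "SyntheticStudy",
    "enumerate_distribution",
    "sample_distribution",
    "jitter_params",
    "make_synthetic_study",
    "write_fixture",
    "TYPICAL_CHO",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Independent-site model parameters for one culture condition.

    p_fucose, p_gal, p_sial are per-site occupancy probabilities in [0, 1];
    antennarity is the fixed antenna count (2 for the dominant biantennary
    IgG Fc glycans); high_mannose_fraction is the pool mass diverted to M5;
    n_molecules and seed control the finite-population sampling mode.
    """

    p_fucose: float = 0.95
    p_gal: float = 0.20
    p_sial: float = 0.05
    antennarity: int = 2
    high_mannose_fraction: float = 0.0
    n_molecules: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_fucose", "p_gal", "p_sial", "high_mannose_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 1 <= self.antennarity <= 4:
            raise ValueError(f"antennarity must be 1..4, got {self.antennarity}")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


#: Typical-CHO preset, inside the literature ranges for all three indices.
TYPICAL_CHO = GeneratorParams()


def _species_probabilities(params: GeneratorParams) -> dict[str, float]:
    """Exact species probabilities (fractions summing to 1)."""
    probs: dict[str, float] = {}
    A = params.antennarity
    complex_mass = 1.0 - params.high_mannose_fraction
    for fuc in (False, True):
        p_f = params.p_fucose if fuc else 1.0 - params.p_fucose
        if p_f == 0.0:
            continue
        for k in range(A + 1):
            p_k = math.comb(A, k) * params.p_gal ** k * (1.0 - params.p_gal) ** (A - k)
            if p_k == 0.0:
                continue
            for m in range(k + 1):
                p_m = math.comb(k, m) * params.p_sial ** m * (1.0 - params.p_sial) ** (k - m)
                if p_m == 0.0:
                    continue
                name = format_species(GlycanSpecies(fuc, A, False, k, m, 0))
                probs[name] = complex_mass * p_f * p_k * p_m
    if params.high_mannose_fraction > 0.0:
        probs["M5"] = params.high_mannose_fraction
    return probs


def enumerate_distribution(params: GeneratorParams) -> GlycanDistribution:
    """Exact expected glycoform distribution of the model, in percent.

    Abundances sum to 100 exactly; species with zero probability are
    omitted so the distribution invariants hold.
    """
    probs = _species_probabilities(params)
    abundances = {name: 100.0 * p for name, p in probs.items()}
    total = math.fsum(abundances.values())
    if total != 100.0:  # float residue only; push onto the largest component
        top = max(abundances, key=abundances.__getitem__)
        abundances[top] -= total - 100.0
    return GlycanDistribution(abundances, normalization_applied=False, raw_total=total)


def sample_distribution(params: GeneratorParams) -> GlycanDistribution:
    """Multinomial draw of ``n_molecules`` from the exact model distribution.

    Identical params (including seed) give identical output.
    """
    probs = _species_probabilities(params)
    names = sorted(probs)
    p = np.array([probs[n] for n in names], dtype=float)
    p /= p.sum()
    rng = np.random.default_rng(params.seed)
    counts = rng.multinomial(params.n_molecules, p)
    raw = {name: 100.0 * c / params.n_molecules for name, c in zip(names, counts) if c > 0}
    return normalize_distribution(raw, tolerance=1e-6)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def jitter_params(
    params: GeneratorParams, sd: float, rng: np.random.Generator
) -> GeneratorParams:
    """Batch-noise replicate: Gaussian jitter of each probability on the
    logit scale (sd in logits).  Probabilities at exactly 0 or 1 are fixed
    points and left untouched.
    """
    def jig(p: float) -> float:
        if p <= 0.0 or p >= 1.0:
            return p
        return _expit(_logit(p) + rng.normal(0.0, sd))

    return replace(
        params,
        p_fucose=jig(params.p_fucose),
        p_gal=jig(params.p_gal),
        p_sial=jig(params.p_sial),
    )


@dataclass(frozen=True)
class SyntheticStudy:
    """Generated study fixture with model ground truth attached.

    ``true_deltas`` maps each manipulated condition_id to the closed-form
    absolute index changes {"FI": 100|Δp_f|, "GI": 100|Δp_gal|,
    "SI": 100|Δp_sial|}; ``params`` records θ per condition for the
    manifest.
    """

    records: tuple[ConditionRecord, ...]
    true_deltas: Mapping[str, Mapping[str, float]]
    params: Mapping[str, GeneratorParams]


def make_synthetic_study(
    control: GeneratorParams,
    manipulated: Sequence[GeneratorParams] = (),
    *,
    study_id: str = "synthetic-study",
    parameter_category: ParameterCategory = ParameterCategory.OTHER,
    manipulation_type: str = "synthetic manipulation",
    cell_line: str = "CHO-K1",
    product: str = "IgG1",
    culture_mode: CultureMode = CultureMode.BATCH,
    sampled: bool = False,
) -> SyntheticStudy:
    """Build one control + N manipulated conditions ready for the pipeline.

    ``sampled`` switches from the exact enumerated distribution to a
    finite-population multinomial draw per condition (seeded from each
    params' own seed).
    """
    generate = sample_distribution if sampled else enumerate_distribution

    def record(cid: str, role: Role, mtype: str, params: GeneratorParams) -> ConditionRecord:
        return ConditionRecord(
            study_id=study_id,
            condition_id=cid,
            role=role,
            parameter_category=parameter_category,
            manipulation_type=mtype,
            cell_line=cell_line,
            product=product,
            culture_mode=culture_mode,
            distribution=generate(params),
            reference="synthetic",
            experiment_group=parameter_category.value,
        )

    control_id = f"{study_id}-control"
    records = [record(control_id, Role.CONTROL, "control", control)]
    true_deltas: dict[str, dict[str, float]] = {}
    all_params: dict[str, GeneratorParams] = {control_id: control}
    for i, mparams in enumerate(manipulated, start=1):
        cid = f"{study_id}-manipulated-{i}"
        records.append(record(cid, Role.MANIPULATED, manipulation_type, mparams))
        true_deltas[cid] = {
            "FI": 100.0 * abs(mparams.p_fucose - control.p_fucose),
            "GI": 100.0 * abs(mparams.p_gal - control.p_gal),
            "SI": 100.0 * abs(mparams.p_sial - control.p_sial),
        }
        all_params[cid] = mparams
    return SyntheticStudy(tuple(records), true_deltas, all_params)


def write_fixture(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Write a study fixture as the standard CSV pair plus a θ manifest.

    Returns the paths written (metadata, distributions, manifest).
    """
    from .dataset import write_study_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = directory / "conditions.csv"
    dists = directory / "distributions.csv"
    manifest = directory / "manifest.json"
    write_study_table(study.records, meta, dists)
    doc = {
        cid: {
            "p_fucose": p.p_fucose,
            "p_gal": p.p_gal,
            "p_sial": p.p_sial,
            "antennarity": p.antennarity,
            "high_mannose_fraction": p.high_mannose_fraction,
            "n_molecules": p.n_molecules,
            "seed": p.seed,
        }
        for cid, p in study.params.items()
    }
    doc["_true_deltas"] = {k: dict(v) for k, v in study.true_deltas.items()}
    with open(manifest, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
    return {"metadata": meta, "distributions": dists, "manifest": manifest}
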