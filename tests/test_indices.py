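"""Index equations on distributions: worked examples and invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycanidx import (
    VOCABULARY,
    GlycanDistribution,
    IndexSet,
    MissingDenominatorError,
    NormalizationError,
    Provenance,
    compute_index_set,
    fucosylation_index,
    galactosylation_index,
    normalize_distribution,
    sialylation_index,
    summative_indices,
)


def dist(**kwargs):
    return normalize_distribution({k: float(v) for k, v in kwargs.items()}, tolerance=1e-6)


class TestNormalization:
    def test_rescales_within_tolerance(self):
        d = normalize_distribution({"FA2G0": 49.5, "FA2G1": 30.0, "FA2G2": 19.5})
        assert math.isclose(sum(d.abundances.values()), 100.0, abs_tol=1e-9)
        assert d.normalization_applied
        assert d.raw_total == 99.0
        assert math.isclose(d.abundances["FA2G0"], 49.5 * 100 / 99)

    def test_identity_when_exact(self):
        d = normalize_distribution({"FA2G0": 100.0})
        assert d.abundances == {"FA2G0": 100.0}
        assert not d.normalization_applied

    def test_total_outside_tolerance_rejected(self):
        with pytest.raises(NormalizationError, match=r"total 60 outside \[95,105\]"):
            normalize_distribution({"FA2G0": 60.0}, tolerance=5.0)

    def test_negative_abundance_rejected(self):
        with pytest.raises(NormalizationError, match="negative"):
            normalize_distribution({"FA2G0": 105.0, "FA2G1": -5.0})

    def test_unparseable_species_rejected(self):
        with pytest.raises(ValueError):
            normalize_distribution({"FA2G9": 100.0})

    def test_unassigned_category_dropped_and_audited(self):
        d = normalize_distribution({"FA2G0": 98.0, "Other": 2.0})
        assert set(d.abundances) == {"FA2G0"}
        assert d.raw_total == 100.0  # pre-drop total kept for audit
        assert math.isclose(sum(d.abundances.values()), 100.0, abs_tol=1e-9)

    def test_direct_construction_validates_sum(self):
        with pytest.raises(NormalizationError):
            GlycanDistribution({"FA2G0": 60.0, "FA2G1": 30.0})


class TestGlycanIndices:
    def test_gi_worked_example(self):
        # weighted galactose 0*50 + 1*30 + 2*20 = 70 over antennae 2*100 = 200
        assert math.isclose(galactosylation_index(dist(FA2G0=50, FA2G1=30, FA2G2=20)), 35.0)

    def test_gi_fully_galactosylated(self):
        assert galactosylation_index(dist(FA2G2=100)) == 100.0

    def test_gi_counts_sialyl_capped_galactose(self):
        # A2G0 contributes 0/80, FA2G2S2 contributes 120/120 -> 120/200
        assert math.isclose(galactosylation_index(dist(A2G0=40, FA2G2S2=60)), 60.0)

    def test_gi_missing_for_pure_high_mannose(self):
        assert galactosylation_index(dist(M5=100)) is None
        with pytest.raises(MissingDenominatorError):
            galactosylation_index(dist(M5=100), strict=True)

    def test_si_one_of_two_galactoses_capped(self):
        assert math.isclose(sialylation_index(dist(FA2G2S1=100)), 50.0)

    def test_si_missing_without_galactose(self):
        assert sialylation_index(dist(FA2G0=100)) is None

    def test_si_all_galactoses_capped(self):
        assert math.isclose(sialylation_index(dist(A2G0=40, FA2G2S2=60)), 100.0)

    def test_fi_binary_membership(self):
        assert math.isclose(fucosylation_index(dist(FA2G0=80, A2G0=20)), 80.0)

    def test_fi_excludes_high_mannose_from_denominator(self):
        assert math.isclose(fucosylation_index(dist(M5=20, FA2G0=80)), 100.0)

    def test_fi_high_mannose_in_denominator_when_configured(self):
        d = dist(M5=20, FA2G0=80)
        assert math.isclose(fucosylation_index(d, high_mannose_fucosylatable=True), 80.0)

    def test_fi_afucosylated(self):
        assert fucosylation_index(dist(A2G2=100)) == 0.0


class TestSummativeIndices:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (dict(FA2G0=50, FA2G1=30, FA2G2=20), (100.0, 50.0, 0.0)),
            (dict(A2G0=40, FA2G2S2=60), (60.0, 60.0, 60.0)),
            (dict(M5=100), (0.0, 0.0, 0.0)),
        ],
    )
    def test_membership_sums(self, table, expected):
        fuc, gal, sia = summative_indices(dist(**table))
        assert (fuc, gal, sia) == pytest.approx(expected)

    def test_afucosylated_complement(self, random_distribution):
        fuc, _, _ = summative_indices(random_distribution)
        afuc = sum(
            p for name, p in random_distribution.abundances.items() if not name.startswith("F")
        )
        assert math.isclose(fuc + afuc, 100.0, abs_tol=1e-9)


class TestIndexSet:
    def test_compute_bundles_everything(self):
        # galactose is present (70 sialylatable site-mass), none of it
        # capped, so SI is a defined 0.0 rather than missing
        s = compute_index_set(dist(FA2G0=50, FA2G1=30, FA2G2=20))
        assert s.fi == pytest.approx(100.0)
        assert s.gi == pytest.approx(35.0)
        assert s.si == 0.0
        assert (s.summ_fucose, s.summ_galactose, s.summ_sialic) == pytest.approx((100, 50, 0))
        assert s.provenance is Provenance.COMPUTED

    def test_single_species(self):
        s = compute_index_set(dist(FA2G2=100))
        assert (s.fi, s.gi, s.si) == (100.0, 100.0, 0.0)

    def test_reported_only_cannot_carry_summatives(self):
        s = IndexSet(fi=95.0, gi=20.0, provenance=Provenance.REPORTED)
        assert s.summ_fucose is None
        with pytest.raises(ValueError, match="reported"):
            IndexSet(fi=95.0, summ_fucose=80.0, provenance=Provenance.REPORTED)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            IndexSet(gi=120.0)

    def test_rounded_reporting_view(self):
        s = compute_index_set(dist(FA2G0=50, FA2G1=30, M5=20))
        assert s.rounded()["fi"] == 100.0
        assert s.rounded()["gi"] == pytest.approx(18.8, abs=0.05)
        assert s.rounded()["si"] == 0.0
        assert compute_index_set(dist(M5=100)).rounded()["gi"] is None


abundance_tables = st.dictionaries(
    st.sampled_from(VOCABULARY),
    st.floats(0.01, 100.0, allow_nan=False),
    min_size=2,
    max_size=len(VOCABULARY),
)


@given(abundance_tables, st.floats(0.1, 50.0))
@settings(deadline=None, max_examples=80)
def test_scale_invariance(table, factor):
    """Multiplying raw abundances by a constant leaves every index unchanged."""
    total = sum(table.values())
    base = {k: 100.0 * v / total for k, v in table.items()}
    scaled = {k: v * factor for k, v in base.items()}
    a = compute_index_set(normalize_distribution(base, tolerance=1e-6))
    b = compute_index_set(normalize_distribution(scaled, tolerance=factor * 110 + 110))
    for name in ("fi", "gi", "si"):
        va, vb = getattr(a, name), getattr(b, name)
        assert (va is None) == (vb is None)
        if va is not None:
            assert math.isclose(va, vb, rel_tol=1e-9, abs_tol=1e-9)


@given(abundance_tables)
@settings(deadline=None, max_examples=80)
def test_bounds_and_permutation_invariance(table):
    total = sum(table.values())
    base = {k: 100.0 * v / total for k, v in table.items()}
    permuted = dict(reversed(list(base.items())))
    a = compute_index_set(normalize_distribution(base, tolerance=1e-6))
    b = compute_index_set(normalize_distribution(permuted, tolerance=1e-6))
    for name in ("fi", "gi", "si", "summ_fucose", "summ_galactose", "summ_sialic"):
        va, vb = getattr(a, name), getattr(b, name)
        if va is not None:
            assert -1e-9 <= va <= 100.0 + 1e-9
            assert math.isclose(va, vb, rel_tol=1e-12, abs_tol=1e-9)


def test_monotone_in_galactose_mass():
    """Moving mass FA2G0 -> FA2G2 strictly raises GI, leaves FI at 100."""
    previous = -1.0
    for x in (0.0, 10.0, 30.0, 70.0, 100.0):
        table = {}
        if x < 100:
            table["FA2G0"] = 100 - x
        if x > 0:
            table["FA2G2"] = x
        s = compute_index_set(normalize_distribution(table, tolerance=1e-6))
        assert s.gi > previous
        assert s.fi == 100.0
        previous = s.gi


@given(abundance_tables)
@settings(deadline=None, max_examples=80)
def test_si_gi_consistency(table):
    """Σ(sial·p) = (SI/100)(GI/100)·Σ(antennae·p) whenever both defined."""
    from glycanidx import parse_species, species_weights

    total = sum(table.values())
    base = {k: 100.0 * v / total for k, v in table.items()}
    d = normalize_distribution(base, tolerance=1e-6)
    gi = galactosylation_index(d)
    si = sialylation_index(d)
    if gi is None or si is None:
        return
    sial_mass = sum(species_weights(parse_species(n)).sial_residues * p
                    for n, p in d.abundances.items())
    ant_mass = sum(species_weights(parse_species(n)).antenna_sites * p
                   for n, p in d.abundances.items())
    assert math.isclose(sial_mass, (si / 100) * (gi / 100) * ant_mass,
                        rel_tol=1e-9, abs_tol=1e-9)
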