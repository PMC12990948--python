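# Methods

## Scope and model

`glycanidx` quantifies how cell-culture process conditions move the Fc
N-glycosylation of CHO-produced IgG-type products. The unit of analysis is a
*condition pair*: one control and one manipulated culture condition from the
same study and experiment series, each summarized by a released-glycan
distribution (percent abundance per glycoform) and/or net occupancy indices.

### Nomenclature

Glycoforms are written in Oxford shorthand with the grammar
`F? A<d> B? G<d> (S<d>)?` for complex-type species and `M<d>` for the
trimannosyl core (M3) and high-mannose species (M5–M9). Parsing is
case-sensitive and the canonical order is fixed, so `parse ∘ format` is the
identity over the whole grammar (property-tested by enumeration). Structural
constraints are enforced at parse time and at construction: galactose count
≤ antennarity ≤ 4, NeuAc count ≤ galactose count, mannose degree in
{3, 5..9}. Bisecting GlcNAc (`B`) is accepted by the grammar but carries no
site weight: it is not an antenna and cannot receive galactose.

M3 is encoded as a complex-core record with antennarity 0 and mannose degree
0. It has no GlcNAc antennae, so it contributes zero weight to every index,
including the fucosylation denominator — it appears in published condition
tables and must parse, but it cannot carry any of the scored motifs.

### Index equations

With abundance *p_i* of species *i*:

* GI = 100 · Σ g_i p_i / Σ A_i p_i. The numerator counts **all** galactose
  residues, sialyl-capped or not: a capped galactose still occupies its
  antenna, and the alternative reading would score a fully sialylated
  digalactosylated glycan as ungalactosylated, which is absurd.
* SI = 100 · Σ s_i p_i / Σ g_i p_i. NeuAc attaches only to galactose, so the
  sialylatable sites are exactly the galactose residues (occupied NeuAc
  positions plus uncapped galactose). SI is therefore 0 — defined, not
  missing — for a pool with galactose but no NeuAc, and missing only when
  the pool carries no galactose at all.
* FI = 100 · Σ f_i p_i / Σ p_i over *fucosylatable* species. By default only
  complex-type species count as able to receive core fucose; high-mannose
  species are excluded from numerator and denominator because core
  fucosylation requires the complex/hybrid processing pathway. Whether the
  original coefficient tables of the occupancy methodology included
  high-mannose species in the FI denominator is not documented, so the
  choice is exposed as `high_mannose_fucosylatable` (default False).
* Summative indices are motif-membership sums: the total abundance of
  species carrying ≥ 1 fucose / galactose / NeuAc. The afucosylated share is
  the complement of summative fucose, which closes to 100% on any
  normalized distribution (tested on 1,000 random distributions).

An equivalent site-census reading: realize the distribution as a finite
population of molecules and count occupied over available sites molecule by
molecule. The abundance-weighted equations equal this census exactly (to
float precision); the test suite checks the equivalence against an
independent per-molecule implementation over 1,000 random populations of up
to 10⁴ molecules.

### Degenerate inputs and missing values

An index whose denominator is zero (SI with no galactose anywhere, GI/FI on
a purely high-mannose pool) is reported as missing with a logged warning;
`strict=True` raises instead. Published tables genuinely contain such
conditions, so missing must be representable without aborting a batch run.
Missing values propagate: a pair with an index missing on either side gets a
`not_evaluable` delta, counted separately in every report.

## Normalization

Raw published abundance tables carry rounding error and omit trace species.
`normalize_distribution` drops explicitly unassigned categories
("Other"/"Unassigned", logged) and zero rows, then rescales to exactly 100
when the remaining total is within ±5 percentage points of 100 (tolerance
configurable); totals outside the window are an error naming the total. The
pre-drop raw total is retained on the distribution for audit. The float
residue of the rescale (≤ 1 ulp-scale) is pushed onto the largest component
so the sum is exact, keeping downstream invariants sharp. Indices are
invariant under positive rescaling of the raw table and under species
reordering (property-tested).

## Study dataset

Conditions live in a metadata CSV (study, condition, role, parameter
category, manipulation type, cell line, product, culture mode, reference,
optional reported FI/GI/SI) plus a long-format distribution CSV. Reported
floats are written with `repr` so read → write → read is bit-exact; this is
tested at the scale of the compiled corpus (78 pairs).

Control matching is scoped by `(study_id, experiment_group)`, the experiment
group defaulting to the parameter category — a study that manipulates both
temperature and pH has one control per series. A multi-level series (e.g.
three temperature setpoints) produces one pair per level sharing the
control. A group with several controls is an error unless they are declared
replicates. The "suitable for index calculation" flag is derived from the
presence of a distribution, never trusted from input.

For conditions that published only index values, those values are carried
with provenance `reported_in_source`; ΔGIx is still computable against them,
but summative indices are structurally unavailable (they need the full
distribution) and their deltas are `not_evaluable`.

Batch replicates of one condition (shared `replicate_group`) are averaged at
the *index* level — not the distribution level — before pairing, with the
per-index spread logged. Index-level averaging keeps the order of operations
explicit and auditable; a collapsed replicate group consequently loses its
per-species shift layer.

## Comparison pipeline

Per pair and per index the pipeline reports the signed delta (manipulated −
control, percentage points), the absolute delta, a direction, and a
magnitude bin with left-closed edges at 1.5, 5 and 10 pp (configurable) —
the granularity at which process effects on these indices are conventionally
discussed. Deltas are absolute percentage-point differences, not relative
changes. A delta within `edge_tol` (default 10⁻⁹ pp) of a bin edge is
classified into the upper bin: index values carry float rounding from the
weighted sums, and a mathematically exact boundary case must not fall into
the lower bin by a few ulps. Swapping control and manipulated flips every
signed delta and preserves every absolute delta and bin (tested).

Aggregation groups pairs by parameter category, then manipulation type,
culture mode and cell line (order configurable), and per node reports pair
counts, per-index bin counts (always summing to the pair count), min/median/
max absolute deltas, and the pairs with major effects. No inferential
statistics are computed: the inputs are single published point estimates per
condition, and a meta-analytic error model is out of scope.

Each comparison also carries the per-species abundance shifts and their
maximum, because index deltas can mask redistribution: moving mass FA2G1 →
FA2G0 + FA2G2 in a 2:1:1 ratio leaves total galactose — hence GI — exactly
constant while individual species move by tens of percentage points. Both
layers are always emitted; collapsing to indices alone would hide
distribution changes that matter for effector function.

## Synthetic cohort generator

The generator draws each glycan from an independent-site occupancy model:
core fucose with probability `p_fucose`; each of the A antennae (default
A = 2, the dominant biantennary Fc case) galactosylated independently with
`p_gal`; each attached galactose sialylated independently with `p_sial`; an
optional `high_mannose_fraction` of the pool assigned to M5. The species
probability is the product of a Bernoulli term and two binomial layers, and
the indices have closed forms FI = 100·p_fucose, GI = 100·p_gal,
SI = 100·p_sial, unaffected by high-mannose dilution (zero index weight).
Exact enumeration recovers these to ≤ 10⁻⁹ over a parameter grid; the
multinomial sampling mode (seeded, deterministic) recovers them to < 0.5 pp
at 10⁶ molecules in ≥ 99 of 100 seeds.

The default preset (p_fucose = 0.95, p_gal = 0.20, p_sial = 0.05) lands
inside the ranges typical of literature CHO IgG profiles — FI above 85%, GI
in the 10–30% band, SI below 10%. An optional batch-noise mode jitters each
probability on the logit scale per replicate (seeded, default off) to mimic
batch-to-batch variation under nominally identical conditions.

What the generator deliberately does **not** model: coupling between
fucosylation, galactosylation and sialylation through shared Golgi residence
time and nucleotide-sugar pools; antenna asymmetry; hybrid structures;
bisecting GlcNAc prevalence; analytical noise of specific platforms.
Passing tests on synthetic cohorts therefore demonstrate the correctness of
the index arithmetic, pairing and classification machinery — not that real
process effects follow an independent-site model.

## Numerical choices

* Internal computation keeps full float precision; reporting views round to
  one decimal, matching the granularity of published index values.
* Distribution sums are enforced to 100 within 10⁻⁹ after exact residue
  compensation.
* The normalization tolerance (±5 pp), bin edges, strictness and the FI
  denominator convention are all configurable per run.
* Mannose occupancy is out of scope as an index (its inputs are rarely
  published); high-mannose abundance is still representable and visible in
  the distribution layer and summative complement.

## Known limitations

Curation decisions upstream of this package — which published condition maps
to which control, how oscillatory manipulations pair with steady controls —
are left to the metadata author. Reported-only conditions contribute no
summative or species-shift information. The effect bins are descriptive
conventions, not significance thresholds.
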