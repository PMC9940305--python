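# Methods

`nanomcr` models a miniaturized library-synthesis campaign in which sixteen
isocyanide-based multicomponent reactions (IMCRs) are run side by side on
384-well plates by acoustic droplet ejection (ADE), each scheme sampling a
small random subset — a *sparse matrix* — of its combinatorial
building-block space. This note records the models, conventions and
numerical choices behind each stage, and what the synthetic data generator
does and does not emulate.

## Building-block banks

A bank is a set of classed reagents (amidines, aldehydes, ketones,
isocyanides, carboxylic acids, primary and secondary amines, plus fixed
"special" reagents such as Sc(OTf)3 or TMSN3), each with a SMILES
structure, molecular weight, a stock concentration from the three ADE
tiers (0.5, 0.25, 0.16 M) and a transporter solvent (ethylene glycol by
default, 2-methoxyethanol or dimethoxyethane for stocks that need them).

The synthetic generator builds each class from curated seed cores
decorated combinatorially with halogen / methyl / methoxy / nitro / CF3 /
CN substituents, de-duplicated on canonical SMILES. The cores cover the
motifs that drive class-level structure–reactivity signal in a real
campaign: electron-poor 2-aminopyridines and aminotriazoles among the
amidines, alpha-acidic ester isocyanides, 2-arylethylamines, and
alpha-amino acids with nucleophilic side chains (lysine, ornithine,
extended homoserine) plus short dipeptides inside the primary-amine class.
Generation is a pure function of `(class_sizes, seed)`; every member is
checked against its class-defining substructure (e.g. `[N+]#[C-]` for
isocyanides) at creation and again on file load.

The default campaign bank uses the study-scale class sizes — 36 amidines,
52 aldehydes, 15 ketones, 64 isocyanides, 71 carboxylic acids, 46 primary
and 32 secondary amines (316 variable blocks) — plus 20 fixed reagents,
for 336 occupied source wells. Stock tiers default to 0.5 M with a seeded
minority at 0.25/0.16 M emulating limited-solubility stocks
(70/20/10 weights); per-block overrides pin individual tiers.

What the generator does *not* emulate: real solubility behaviour, vendor
availability, or the exact structures of any real vendor stock list. Tests
passing on these banks demonstrate the pipeline's bookkeeping and
statistics, not the chemistry of any specific reagent.

## Reaction schemes and enumeration

Each scheme is an ordered list of slot classes, fixed reagents with molar
equivalents, a reaction-SMARTS transformation template, a per-well scale
(300/375/500 nmol, assigned by component count and config-exposed), and
condition annotations. The sixteen shipped definitions live in
`data/schemes.yaml`; entries whose slot assignment is a best-guess
reconstruction are marked `provenance: inferred` and can be edited without
touching code.

Enumeration pushes one building block per slot through the template with
RDKit. Two modelling simplifications are deliberate:

* multi-step schemes (the Ugi–Pictet–Spengler sequence, the fused
  tetrazolo-lactams) use one composite template that produces the final
  ring system directly; intermediates are not materialized;
* the intramolecular Ugi of alpha-amino acids is modelled as the
  open-chain 5-center alpha-adduct with the acid retained, because the
  side-chain-length-dependent lactone/lactam closure is not expressible as
  one ring-size-generic SMARTS; stereochemistry is dropped throughout.

A combination the template rejects (wrong functionality, unsanitizable
product) is recorded as *skipped* with a reason, never raised: schemes
like the dipeptide diketopiperazine or the Orru 2-imidazoline legitimately
accept only a subset of their slot class, which mirrors real
building-block incompatibility. Full enumeration satisfies the
conservation law `products + skipped = theoretical space`.

`theoretical_space_size` is pure arithmetic (sum over schemes of the
product of slot-class sizes). Seeded sampling without replacement uses a
mixed-radix index space: a permutation for spaces up to 2M indices,
rejection sampling of distinct integers above that.

## Plate design

The source plate is filled column-major (A1, B1, …), grouped by class in
canonical class order; 336 blocks leave 48 empty wells on one 384-well
plate. Destination wells are assigned scheme-contiguously in scheme-id
order, row-major in 96-well blocks, so four schemes share each 384-well
plate and 16 × 96 wells occupy exactly four plates; other block sizes
spill onto ceiling(total/384) plates.

Transfer volumes follow `V[nL] = scale[nmol] / conc[mol/L]`, rounded *up*
to the nearest droplet multiple (2.5 nL by default — an instrument
characteristic, configurable) so a well never receives less than its
design scale: 500/0.5 → 1000 nL, 375/0.25 → 1500 nL, 300/0.16 → 1875 nL.
Each well receives one transfer per variable slot plus one per fixed
liquid reagent held in the bank (volume scaled by its equivalents); bulk
steps outside the dispenser (10 µL solvent by multichannel pipette,
evaporation, the formic-acid Pictet–Spengler step) are recorded as
`post_additions` annotations, not transfers.

The picklist CSV uses the exact header
`Source Plate Name,Source Well,Destination Plate Name,Destination Well,Transfer Volume`
with volumes printed as integers or one-decimal values, and round-trips
byte-identically through its reader. The whole design is a deterministic
function of (bank, schemes, n, seed).

Four 384-well plates fold onto the virtual 1536-well plate by quadrant
interleave: plate *k* (0-based) maps well (r, c) to (2r + k//2,
2c + k%2), a bijection whose inverse is provided; plate 1's A1 stays at
A1. The interleave choice is cosmetic and documented as such.

## Outcome statistics

Outcome calls are consumed as pre-made three-level categories
(`none`/`medium`/`major`); no MS signal processing happens here, and the
threshold between medium and major is upstream's concern. Ingestion
validates the vocabulary, rejects wells unknown to the campaign and
reports missing wells; aggregations require a complete table.

Per-scheme statistics report full-precision fractions plus
integer-rounded percentages (the convention used when quoting, e.g., a
57% success / 18% major scheme); ranking is by descending success
fraction with scheme-id tie-break. Per-block statistics stack call counts
over every well using the block. The synthetic outcome generator draws
independent per-well calls from per-scheme `(p_major, p_medium)`; its
default profile encodes the campaign-level picture — twelve of sixteen
chemistries succeeding in over half their wells, four clear
under-performers, and the GBB scheme at (0.18, 0.39). Empirical
fractions converge to these probabilities (binomial Monte Carlo is part
of the test suite). Real outcome structure the generator ignores:
block-level reactivity correlations, plate-position effects, and
cross-scheme correlation of shared building blocks.

## Chemoinformatic profile

Descriptors come from RDKit (MW, Crippen cLogP, TPSA, rotatable bonds,
molar refractivity, atom/ring counts). H-bond donors and acceptors use
the original rule-of-five conventions — donors are N/O atoms bearing at
least one hydrogen (a group counts once, so water has one donor),
acceptors are all N and O atoms — because the common toolkit variants
return 0 for small edge cases like water. Two quantities require
external predictors: cLogD and strongest basic pKa are read from an
optional side table and otherwise stubbed (cLogD := cLogP, pKa := 7.0)
with the provenance flagged on every vector.

Filters use inclusive bounds: Lipinski (MW ≤ 500, cLogP ≤ 5, NHD ≤ 5,
NHA ≤ 10; pass = zero violations), Ghose (160 ≤ MW ≤ 480, −0.4 ≤ cLogP ≤
5.6, 40 ≤ MR ≤ 130, 20 ≤ heavy atoms ≤ 70) and Muegge (200 ≤ MW ≤ 600,
−2 ≤ cLogP ≤ 5, TPSA ≤ 150, rings ≤ 7, C > 4, heteroatoms > 1, rot ≤ 15,
NHA ≤ 10, NHD ≤ 5).

CNS MPO sums six piecewise-linear desirabilities, each in [0, 1]:
monotone-decreasing ramps for cLogP over [3, 5], cLogD over [2, 4], MW
over [360, 500], NHD over [0.5, 3.5] and basic pKa over [8, 10], and a
TPSA trapezoid (0 at ≤ 20, 1 on [40, 90], 0 at ≥ 120). The score is
bounded in [0, 6], attribute-monotone, and classed high (> 5) / low (≤ 2)
/ mid. All transform parameters are overridable.

Shape analysis embeds one ETKDGv3 conformer per molecule (fixed seed,
hydrogens included, MMFF-relaxed when parameters exist) and computes the
mass-weighted inertia tensor; eigenvalues I1 ≤ I2 ≤ I3 give NPR1 = I1/I3
and NPR2 = I2/I3. The same tensor code accepts raw coordinates and
masses, which is how the collinear/square/cubic point-mass reference
fixtures pin the rod (0, 1), disc (0.5, 0.5) and sphere (1, 1) corners.
Alternate weightings (heavy-atom only, unit masses) are switchable.
Ensembles are not modelled — one conformer stands in for the molecule,
so flexible structures carry embedding noise that a multi-conformer
average would reduce.

The rod–disc–sphere triangle is partitioned by its edge midpoints
(0.25, 0.75), (0.75, 0.75), (0.5, 1) into three corner regions and a
central *hybrid* region. Boundary points belong to the corner regions,
checked rod → disc → sphere, so each valid point gets exactly one class.
The distribution barycenter is computed per axis from a 1D Gaussian KDE
(Scott bandwidth, configurable): the headline value is the
density-weighted mean, with the KDE argmax reported alongside as an
alternative reading of "the intersection of the density averages";
degenerate (zero-variance) samples fall back to their mean.

Distribution comparisons use the two-sample Kolmogorov–Smirnov test
(asymptotic p-values) over every unordered group pair and descriptor —
17 groups × 7 descriptors gives C(17,2) × 7 = 952 comparisons — with
"highly significant" mapped to p < 0.001. PCA standardizes columns
(constant columns dropped with a warning) before decomposition; variance
fractions sum to 1 and are cross-checked against a direct
eigendecomposition in the tests. The similarity matrix defaults to
Morgan (radius 2, 2048-bit) fingerprints with Tanimoto similarity — a
generic, documented substitute for proprietary pharmacophore
descriptors, so absolute similarity values are not comparable to results
obtained with those.

## Problem sizes and defaults

The test suite and the reproduction script run the campaign at full
design scale (16 × 96 wells, 336-block bank) because the design stage is
cheap; chemoinformatic stages use 24 virtual products per scaffold for
descriptor statistics and 6 per scaffold (plus the 48-drug demo reference
panel) for conformer embedding, keeping the whole reproduction in the
tens of seconds while leaving every code path exercised. Monte-Carlo
parameter recovery uses 500 replicates of a 96-well scheme.

## Known limitations

* Slot assignments for half the schemes are reconstructions; editing
  `schemes.yaml` against an authoritative source changes spaces and
  products without code changes.
* Virtual products carry no stereochemistry and no yield/feasibility
  model; skipped-combination bookkeeping is the only reactivity proxy.
* The shipped reference panel is a small demonstration set, not a curated
  FDA collection; comparative percentages against it are illustrative.
* cLogD/pKa stubs make the CNS MPO cLogD and pKa components degenerate
  (equal to the cLogP component, resp. constant) unless a side table is
  supplied.
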