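# Methods

## The model

`protolattice` simulates an artificial chemistry on a periodic
two-dimensional hexagonal lattice.  Each cell holds a multiset of 15
virtual molecule species (integer counts) plus two kinds of polymer
"boxes".  One time step applies, in order:

1. **Diffusion** of every free species and both polymer kinds;
2. **Reaction stages A–F** inside every cell;
3. **Informant-polymer synthesis** (template copying);
4. **Membrane-polymer synthesis**;
5. **Removal reactions** (stage G), closing every path back to the
   feedstock species (molecule 1);
6. **Membrane-polymer degradation**.

No molecules are created or destroyed: every operation conserves the grand
monomer total (free counts + informant box contents + 100 × membrane
boxes) exactly, as an integer identity.

### Diffusion

Each species has a *residual rate* `r ∈ [0, 1]`, the fraction staying in
its cell per step (the stand-in for an inverse diffusion coefficient).  Of
`b` molecules, `round(b·r)` stay (round half-up; the rounding rule is not
forced by the model definition, and half-up keeps the tabulated rates
unbiased on typical counts), the movers split evenly over the six
neighbors, and the `< 6` remainder goes one-by-one to *distinct* neighbors
chosen uniformly at random.  Updates are synchronous: all sends are
computed from the pre-step state.  Polymer boxes are few, so they move as
whole units: Bernoulli(`r`) stay, otherwise a hop to one uniform neighbor;
the expectation matches the species rule.

### Reaction network

The network compiles a threshold cellular-automaton rule into chemistry.
With `N1` short-range and `N2` long-range activity and a weight `w`, the
CA activates a cell when `N1 > N2·w`.  The chemical realization:

- **A** – morphogen maturation: 2→4 at 5 %, 3→5 at 2 % per step.
  Molecule 2 diffuses slowly (r = 0.75) and molecule 3 fast (r = 0.05),
  so molecules 4 and 5 accumulate at short and long range respectively —
  the two morphogens of the Turing mechanism.
- **B** – comparator production: each unit of 4 converts one feedstock
  unit to 8 and one to 11; each unit of 5 converts one to 9 (all 100 %,
  drawing down the molecule-1 pool in listed order).
- **C** – informant ratio conversion: 8→10 and 9→10, each converting
  `round(n·w)` units where `w` is the local informant ratio; the
  remainder of 8 and 9 resets to molecule 1.  A cell with no informant
  box converts nothing (no informant, no specified rate).
- **D** – pair annihilation 10 + 11 → 1 + 1: molecule 11 survives exactly
  when `n11 > round(n8·w) + round(n9·w)` — the CA inequality.
- **E** – the gate window (below).
- **F** – morphogen regeneration: 11, 13 and 14 each convert feedstock
  into fresh molecules 2 and 3 (one per catalyst unit per step).
- **G** – removals: 4→1 and 5→1 at 5 %, 8→1 and 9→1 at 100 %, 10→1 and
  11→1 at 5 %, 13→1 at 75 %.

Fractional conversions use `floor(n·p)` plus one extra unit with
probability `frac(n·p)`, so expectations are exact and counts stay
integral.  Rules inside a stage run in listed order on the current counts;
the feedstock pool (~10⁶ per cell) essentially never binds.

**Stage-F gating.**  Molecule 14 is present in every cell forever, so a
purely catalyst-gated regeneration stage would seed morphogens everywhere
from step 0 and ignite the entire lattice (measured: 70 % membrane
coverage by step 50), erasing both the localized growth from the seeded
region and the dependence of the outcome on `w`.  The regeneration of
molecules 2/3 accompanies membrane formation, i.e. the presence of
molecule 13; stage F therefore runs only in cells holding molecule 13
(`NetworkDefinition.stage_f_gate = "mol13"`, the default).  The
alternatives remain selectable: `"none"` (catalyst-only gating; global
ignition) and `"mol11_or_13"` (also admits comparator-positive cells; in
our experiments this regime collapses to extinction at every `w`).  With
the default gate the model reproduces the full regime ordering
(mesh → replicating → extinct, see below).

### The gate window (molecules 13/14/15)

Three 100 % reactions applied in one pass per step, in listed order:

1. 14 + 11 → 14 + 1 (up to `c14` units of 11 destroyed);
2. 15 + 11 → 15 + 13 (up to `c15` further units converted);
3. 13 + 11 → 11 + 11 (each remaining 11 flips one 13 back).

Molecule 13 — the membrane trigger — survives only for a contiguous band
of incoming molecule-11 counts, opening just above `c14` and closing near
`c14 + 2·c15`.  For the standard gates (3, 9), exhaustive enumeration
gives the band {4, …, 20}.  The exact endpoints depend on the pairing
schedule of step 3, which the model definition leaves open; the schedule
is a swappable policy (`single_pass` default; an `iterated` variant that
replays step 3 to exhaustion is provided for comparison — it closes the
window entirely and is therefore not usable as the production schedule).

### Polymers

*Informant polymer* (kind 1): a box of `P1_SIZE` monomers of molecules 6
and 7 whose 6-fraction encodes `w`.  `P1_SIZE` defaults to 100, symmetric
with the membrane polymer's stated 100-mer size (the model fixes only the
ratio, not the box capacity); compositions are `(round(w·P1_SIZE),
P1_SIZE − ·)`.  Where molecule 11 and at least one template box coexist
and the free 6/7 pools suffice, one copy per cell per step is made with
the pooled local composition, debited from the free pools.  Informants
never decompose, so with a single founding composition every box ever
made carries the founder ratio exactly — heredity is exact by
construction and asserted after 500 steps in the tests.

*Membrane polymer* (kind 2): exactly 100 molecule-12 monomers per box.
Synthesized (one per cell per step) where molecule 13 is present and 100
free monomers exist; degraded at 5 % per box per step only where
molecule 13 is absent.  The spatial accumulation of these boxes is the
"cell" region.

The box supply is unlimited bookkeeping; synthesis is throttled by the
one-per-cell-per-step cap and monomer availability.

### Lattice geometry

Axial hex coordinates on a rhombic torus: cells form an `H × W` array and
the six neighbor offsets — (0,±1), (±1,0), (1,−1), (−1,1) — are identical
for every cell, with wraparound.  This preserves degree-6 regularity,
neighbor symmetry and isotropy for any `H, W ≥ 3` while making every
lattice-wide operation a fixed set of `np.roll` shifts, which is what
keeps a 100×100 step in the low milliseconds.  (An offset-coordinate
layout with parity-dependent neighbor tables encodes the same topology
with more machinery.)

### Entropy accounting

*Morphological entropy* (natural log, k = 1): the Stirling approximation
of the log-multiplicity of the equidistributed arrangement of `m`
molecules over `X` cells, minus that of the observed arrangement
(`Σ U log U − U` over cells, with 0·log 0 = 0).  Zero for uniform
placement, positive as molecules gather.  Computed over membrane-box
occupancies by default (the quantity of interest is the order of the
cell-like region); any species is selectable.

*Diffusive entropy production*: discretization of `k·D·(∇C)²/C` with
`k = D = 1` as `Σ (Δn)² / mean(pair)` over all unordered adjacent pairs
and selected species; pairs with both counts zero contribute nothing.
The pair mean is our choice of denominator; the discrete form only fixes
"the number of molecules".

*Reactive entropy production*: +1 per molecule converted away from
molecule 1, −1 per molecule returned to it, accumulated over time
(per-molecule, not per-rule-firing, which matches the magnitude of the
continuous growth observed).  Polymerization and degradation move no
molecules into or out of species 1 and tally 0.

## Initial conditions and parameters

Standard per-cell background: 10⁶ of molecule 1, 5·10⁴ each of 6 and 7,
10⁵ of molecule 12, 3 of molecule 14, 9 of molecule 15.  Morphogen seed:
100 each of molecules 2 and 3 in a hex disk of radius 2 (19 cells) at the
grid center — the definition says only "some cells in the center area",
and a compact disk is the simplest such region; the geometry is
configurable and the outcome is insensitive to it (asserted in the
tests).  Ten founding informant boxes with composition ratio `w = 0.650`
are scattered uniformly at random over the central hex disk of radius 3.

Standard residual rates: mol 1 = 0.0, mol 2 = 0.75, mol 3 = 0.05, mols
4/5 track 2/3, mols 6/7 = 0.0, mols 8–11 = 1.0, mol 12 = 0.0, mols
13–15 = 1.0; informant boxes 0.1, membrane boxes 0.75.  Sweepable axes
(`apply_parameter` / `sweep`): `w`, initial mol-14/15 counts, seed
geometry (three central variants), residual rates of mol 2/3 and both
polymers, maturation rates 2→4 and 3→5, and the five removal rates.
Reaction and removal rates are written as percentages in configs, as
printed in the standard-parameter table, and normalized internally.

## Randomness and reproducibility

One `numpy` PCG64 stream per run, seeded from the config; operations
consume draws in a fixed order (species 1–15, then boxes; stages in
order), so a run is bit-for-bit reproducible from (config, seed) — a
test asserts grid equality across repeated runs.

## Problem sizes used in the tests

The full-scale reference field is 100 × 100; a step costs ~10 ms there.
The test suite exercises the complete pipeline at reduced scale — 60 × 60
for 1,500 steps for the regime classification (five seeds of the standard
case plus the `w` sweep endpoints), 40 × 40 × 500 for the conservation
audit — sizes at which every qualitative regime of the full field is
already expressed, chosen so the whole suite runs in about two minutes.

## What the simulations show — and do not show

On the reduced field the `w` sweep reproduces the regime ordering: at
`w = 0.575` the membrane region spreads into a space-filling mesh; at the
standard `w = 0.650` a central domain forms, then repeatedly splits into
multiple domains (self-replication) at low coverage; at `w = 0.725`
domains form transiently and die out.  Along the standard run the
cumulative reactive entropy production grows monotonically while the
morphological entropy of the membrane distribution stays positive after
domain formation — spatial order is maintained at the cost of continuous
entropy production elsewhere.

These are properties of an artificial chemistry: molecule species are
abstract tokens, all reactions are energetically uniform, and nothing
maps onto real biochemical species or rate constants.  Passing tests
show the internal consistency of the model and its claimed regime
structure, not anything about laboratory chemistry.

## Numerical choices, degenerate inputs, limitations

- Products `n·p` are shielded by a 10⁻⁹ epsilon before `floor`/rounding
  so that exact percentages (5 % of 100) stay exact in floating point.
- Cells with no informant box skip ratio conversion entirely (treated as
  0 converted); membrane nucleation therefore requires an informant to
  have diffused in first.
- The CA reference uses hex-distance neighborhoods; its regime thresholds
  sit lower on the `w` axis than the chemical model's (stable spots near
  `w ≈ 0.5`, extinction by `w ≈ 0.65` under 30 % random seeding) because
  neighborhood shape rescales the threshold; the *ordering* of regimes in
  `w` is shared between the two models and is what the cross-model check
  asserts.
- `classify_pattern` thresholds (mesh above 25 % final coverage, etc.)
  are operational definitions of visual categories; all configurable.
- Empty grids, zero rates, and `r = 1` (no diffusion) are exact no-ops.
- Known limitations: no mutation of the informant ratio (heredity without
  evolution), no energy bookkeeping, 2-D only, and the membrane region is
  a density field, not a closed curve — "boundedness" means spatial
  localization of membrane polymer, not topological enclosure.
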