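# Methods

## Constraint-based model

A metabolic model is the pair (S, bounds): a stoichiometric matrix S over
non-boundary metabolites and flux bounds `lb ≤ v ≤ ub` in mmol/gDW/h.
Admissible states are the steady-state flux cone `{v : S v = 0, lb ≤ v ≤ ub}`.
All analyses are linear programs over this cone, solved with HiGHS through
`scipy.optimize.linprog` (deterministic; solver name recorded in reports).
BiGG sign conventions are used throughout: exchange reactions are written
`met ↔ ∅` and negative exchange flux is uptake. Bounds default to
±1000 mmol/gDW/h when a file omits them; irreversible means `lb = 0`.

A growth condition fixes the substrate exchange at `-uptake` (default
6.3 mmol/gDW/h, the reference glucose uptake for *P. putida*), enforces a
lower bound on non-growth ATP maintenance (ATPM, default 0.97 mmol/gDW/h),
and — when the byproduct policy is active — clamps secretion of all
exchanges except the substrate, the product and the known overflow
metabolites (gluconate, 2-ketogluconate, 3-oxoadipate, catechol, lactate,
methanol, CO2, acetate; water and protons always open). The byproduct
policy applies to coupling computations by default but not to plain MTY,
where it can be enabled by flag; MTY likewise exposes an `atpm_active`
flag because published yield tables can be computed either way.

**Maximum theoretical yield.** `MTY = max v_product / uptake` at fixed
uptake. With ATPM at zero the flux cone is homogeneous, so MTY is
invariant to the uptake magnitude (a property test).

**FVA** solves two LPs per reaction under `objective ≥ fraction · optimum`.
**Production envelopes** fix biomass to each point of a uniform grid of
fractions of its optimum (f = 0 covers the non-growing states) and report
min/max product yield; infeasible grid points are recorded as NaN, since
networks that stoichiometrically force growth at fixed uptake genuinely
have no zero-growth state.

**Gene deletions** project gene sets onto reactions through the GPR
boolean rules: a reaction is blocked iff its rule evaluates false with the
deleted genes removed; empty rules never block. In-silico essentiality
uses a threshold of 1e-3 of wild-type growth (no published value exists;
anything between 1e-2 and 1e-6 gives identical calls on the desk-scale
models here).

## Strong coupling and cut-set enumeration

A cut set C strongly couples production when, after forcing `v_r = 0` for
r ∈ C:

* (undesired region blocked) the *minimum* product yield over all
  admissible states — biomass free, including zero — is at least the
  demanded fraction of MTY. Testing the worst case by LP minimisation
  avoids the strict-inequality formulation of "no state below the
  demanded yield"; the tolerance is 1e-6 absolute on yield.
* (desired region kept) a state exists with biomass at least the demanded
  fraction of the wild-type maximum *and* product at the demanded yield.

Demanded-yield grid defaults follow the published sweep (10/50/70/80/85%
of MTY; biomass 10% or 25%, with 10% as the implemented design point).
Exchanges, spontaneous reactions, the biomass reaction, ATPM and
reactions without gene association are never knockable.

Enumeration is an explicit cardinality-ascending search over subsets of
the knockable set with superset pruning: because sizes are visited in
ascending order and supersets of accepted sets are skipped, the search is
exhaustive within `max_cut_size` and every returned set is minimal.
Output order is deterministic (size, then lexicographic reaction ids).
A subset budget caps genome-scale misuse; exhausting it returns a partial
result with an explicit warning and the explored frontier. The dual-MILP
formulation used for genome-scale enumeration in the literature is out of
scope here by design; on desk-scale instances the explicit search is
equivalent (verified against brute-force subset enumeration in the tests)
and needs no MILP solver. Desk default `max_cut_size` is 5; the published
genome-scale default of 50 is accepted but only sensible under the
budgeted mode.

Verification of a chosen cut set follows the FVA criterion: positive
minimum **and** maximum product flux at the demanded biomass confirm
production-obligatory growth.

## Target triage

Reaction cut sets become gene sets via the conservative GPR rule: every
gene in a cut reaction's rule is targeted, for both OR (isozymes) and AND
(complex subunits) structures. Exclusion filters then remove genes called
essential by omics fitness data (omics overrides model-predicted
essentiality on conflict; both are reported) and genes encoding
multi-functional proteins (a user-supplied list — no general annotation
source is bundled, so category subtotals are reported rather than a
single exclusion total). Genes with no essentiality call are treated as
dispensable with a logged warning. Each excluded gene carries exactly one
primary reason code; the two filters commute (set exclusion). A set is
feasible when every gene-associated reaction of the cut retains at least
one targetable gene and no cut reaction lacks a GPR; an `allow_partial`
waiver reproduces the practice of proceeding with an incomplete knockdown
set and recomputing the relaxed envelope. The alternate-carbon check
closes the other candidate substrates, applies the knockouts and runs FBA
for biomass and product per substrate — a design coupled on one substrate
typically loses product capability on a bypass substrate.

## Fermentation analytics

Quantification uses the indigoidine standard curve
`g/L = 0.212·OD612 − 0.0035` (average of two independent calibrations on
purified pigment) and `0.38 g DCW/L per OD600`. The curve's negative
intercept maps very low readings below zero; reported values are clamped
at 0 and the raw affine value is retained, since no convention for
sub-intercept readings is published.

TRY metrics: titer = maximum product; overall rate = net product over
elapsed time to the maximum; window rate = maximal least-squares slope
over a sliding window (default 3 points — the published peak rate's
window is not specified); yield is reported on both a consumed basis
(initial charge + feeds − residual) and a supplied basis (initial charge
+ feeds), because published g/g values do not state the accounting;
%MTY uses the consumed basis. Fold changes are reported rounded to the
nearest integer above 10-fold and one decimal below.

Phase classification computes the smoothed specific growth rate
µ = d ln(OD600)/dt (moving average, window 5), takes µmax from the
steepest 4-point log-linear fit, and defines the growth phase as runs of
at least 3 samples with µ > 0.05·µmax (short runs are noise blips at the
default 5% assay noise, hence the run-length filter). Production is
attributed per interval from the smoothed product trace using *net*
increments, which cancels measurement noise that a positive-increment sum
would accumulate. Class: growth-associated at ≥ 70% of product formed in
the growth phase, stationary at ≤ 30%, mixed in between; constant OD or
zero net production are flagged degenerate.

## Synthetic data

The toy coupled network realises the coupling motif minimally: substrate
oxidation (OXI) yields two growth precursors plus NADH; the product
reaction (PRD) is the only NADH reoxidation route other than `1+k` futile
sinks (RSP_i). Its ground truth — MTY 1.0 mol/mol and the unique minimal
cut set consisting of all sinks — follows from the NADH balance and is
re-verified by LP in the tests rather than assumed. Variants add an
ATP-producing respiration branch with an ATPM drain, and a bypass carbon
source that feeds the precursor without generating NADH (so the coupled
design loses product capability on it). Toy models omit ATP unless the
ATPM variant is requested.

Random networks are branched pathways: a backbone chain guarantees
growth feasibility by construction, and the remaining reaction budget
adds parallel edges that either also secrete the product or are futile;
cut sets then force flux through productive edges, giving the enumerator
non-trivial instances with known-by-oracle answers.

Fermentations follow Luedeking–Piret kinetics,
`dP/dt = α·dX/dt + β·X`, with exponential growth at µmax until the
substrate charge (initial plus feeds) is exhausted and biomass debiting
substrate at 1/Y_XS. Defaults emulate a minimal-medium cultivation on a
10 g/L sugar charge: µmax 0.35 /h, Y_XS 0.40 gDCW/g, X0 0.038 gDCW/L
(OD 0.1), 5% multiplicative observation noise, 36 h sampled hourly.
α-only parameterisations give growth-associated production, β-only give
stationary-phase production. Product carbon is deliberately *not*
debited from measured substrate — stationary-phase production after
carbon depletion (drawing on reserves) is exactly the observed behaviour
being emulated — so the mass-balance closure invariant covers biomass vs
substrate only. Simulated courses do not emulate pH/DO dynamics, lag
phases, product degradation or photobleaching; passing tests therefore
show correct analytics on idealised kinetics, not robustness to every
real bioreactor artefact.

## Problem sizes and verification strategy

Desk-scale batteries are used throughout: the enumeration-vs-oracle
battery runs 50 networks (16 toy variants, 34 random draws) with at most
12 knockable reactions and cut sizes ≤ 5, where exhaustive subset
enumeration is tractable as an independent oracle; phase-recovery uses
100 seeded simulations per regime. FBA itself is cross-checked against
cobrapy (an independent implementation) on the toy fixtures; cobrapy is
never used in the implementation path. Genome-scale reconstructions
(e.g. iJN1462, 2928 reactions) are supported by the same code paths —
readers, census, MTY — but are not packaged; the genome-scale acceptance
test documents where to place the BiGG JSON.

## Known limitations

* Enumeration is exponential in cut size; genome-scale cMCS sweeps need
  the budgeted mode and are not expected to finish exhaustively.
* No thermodynamic (loopless) constraints; mass/charge balance is not
  validated beyond structural checks.
* The spontaneous-reaction list depends on model annotation (SBO term or
  user-supplied ids); published exclusion totals are only reproducible
  with the same annotation sets, so reports give category subtotals.
* Published gene-association counts for iJN1462 disagree internally
  (2030 stated vs 2102 by complement); the census reports both the direct
  count and the complement without forcing agreement.
* Parsimonious FBA, MOMA/ROOM, dynamic FBA and OptKnock-style bi-level
  designs are out of scope.
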