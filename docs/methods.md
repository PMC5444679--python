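# Methods

## Model scope and assumptions

The reconstruction is deliberately small: 56 reactions of central carbon
metabolism in a single compartment, with one pool per cofactor (no
cytosol/mitochondrion split).  It is a tool for reasoning about *cofactor
balances* — ATP/ADP, NAD⁺/NADH, NADP⁺/NADPH — under different carbon
sources and enzyme-activity states, not a genome-scale model.  Protons are
not tracked; water and orthophosphate are tracked but always freely
exchangeable, so only the carbon skeletons and the three cofactor systems
are genuinely balanced.  Charge balancing, thermodynamic (ΔG) feasibility
and enzyme kinetics are out of scope.

Stoichiometries follow the standard MetaCyc definitions of the named
reactions, with these modelling conventions:

* **Electron transport** is one lumped NADH oxidase at P/O = 2.5
  (`nadh + ½O₂ + 2.5 ADP + 2.5 Pi → nad + 2.5 ATP`), the value appropriate
  for a Crabtree-negative yeast.  Succinate-derived electrons enter at
  P/O = 1.5, folded directly into the succinate dehydrogenase reaction so
  the model keeps exactly 56 columns.
* **AMP-forming ligases** (acetate-CoA ligase, acyl-CoA synthetase, PEP
  synthase) hydrolyse two ATP → ADP equivalents, avoiding an AMP pool.
  This preserves the energetic point that the pyruvate dehydrogenase
  bypass costs two ATP equivalents per acetyl-CoA.
* **β-oxidation** is present (synthetase, oxidase, hydratase,
  dehydrogenase, thiolase) with a generic even-chain acyl-CoA modelled at
  C4, the shortest chain for which one round terminates cleanly in two
  acetyl-CoA.  A longer single generic species would either leave a
  dead-end shortened acyl-CoA or, if the thiolase regenerated the same
  species, create carbon from nothing.  The block carries zero flux on
  sugar substrates; its generic fatty acid is exchangeable but closed by
  default.
* **Pyruvate dehydrogenase** is split into its three component reactions
  with explicit lipoamide intermediates, matching the reaction list; the
  internal lipoamide pool forces the three steps to run in lockstep.
* **Biomass** drains eleven carbon-skeleton precursors plus ATP and NADPH
  and produces net NADH, per unit of growth flux (below).

## The linear program

Steady state is `S v − E e = 0` with one equality per metabolite.  *E* has
one unit column per exchangeable metabolite whose scenario mode is not
closed.  Exchange modes are: closed (no column), export-only (e ≥ 0,
"allowed to accumulate"), uptake-only (finite lb ≤ e ≤ 0), fixed
(e pinned) and free.  Two deliberate choices:

* **Carbon uptake is fixed**, not bounded: e(sugar) = −10 exactly.  The
  model's units are relative to this flux.  Fixing rather than bounding
  matters only when metabolism cannot profitably use all carbon — exactly
  the anaerobic malic-enzyme knockout, which is then correctly reported
  infeasible (no steady state) instead of silently idling at zero uptake.
* **"Allowed to accumulate" opens a pair**: the named metabolite gets an
  export-only column and its conjugate partner (ADP for ATP, NADP⁺ for
  NADPH, NAD⁺ for NADH, CoA for acetyl-CoA) a free column, so conserved
  moieties stay exchangeable as a pair.  Making the *reduced* cofactor
  fully free instead would be unsound: free NADH import feeds the
  malic-enzyme triangle as a transhydrogenase and the NADPH-maximisation
  problem becomes unbounded.

Nominally unbounded fluxes are boxed at ±10⁶ inside the solver and
solutions touching the box are flagged.  LPs are solved with HiGHS dual
simplex (deterministic, fixed variable ordering; primal/dual tolerances
10⁻¹⁰), so repeated runs are bit-identical.  Feasibility and mass-balance
residuals are held to 10⁻⁹; objective comparisons use 10⁻⁷.

## Degeneracy, parsimony and substrate cycles

FBA optima are rarely unique.  Reported solutions therefore always pass a
parsimonious refinement: minimise Σ|v| over internal fluxes subject to the
objective staying within 10⁻⁹ of its optimum.  (The pin is this tight on
purpose: with a looser pin the refinement will trade a sliver of objective
for flux parsimony, e.g. a spurious 10⁻⁵ glycerol trickle.)  Remaining
degeneracy is characterised, not hidden, by flux variability analysis —
per-variable min/max at the fixed optimum.

Internal substrate cycles are detected as non-zero flux vectors that
balance every non-cofactor metabolite with all exchanges closed (water is
also exempt).  Each reaction/orientation is probed by LP and reduced to a
minimal support set; the built-in model yields FBP+PFK (net ATP
hydrolysis), pyruvate carboxylase + reverse malate dehydrogenase + malic
enzyme (net ATP hydrolysis plus NADH→NADPH transfer), and the two
PEP/pyruvate interconversion pairs.  Every scenario report audits its
refined solution: a cycle whose flux could be removed without violating
any constraint or changing the objective is flagged, and the suite
requires this audit to be empty.  Cycles that are *pinned* by a closed
cofactor balance (the FBP/PFK cycle acting as the ATP sink) are reported
as active, legitimately flux-carrying cycles.

Parsimony cannot exclude a cycle that improves the objective.  The
malic-enzyme triangle and the PEP/pyruvate pairs would do exactly that in
several aerobic scenarios — laundering NADH into NADPH, or serving as a
free ATP sink — although the organism shows no evidence of either
operating aerobically (the proposed malic-enzyme cycle is an anaerobic
mechanism, and PEP carboxylase is not even annotated in this strain).  The
aerobic scenario registry therefore holds malic enzyme, PEP synthase and
PEP carboxykinase inactive; the anaerobic scenario re-activates malic
enzyme, whose cycle is there the object of study.

## Scenario registry

Eleven configurations (`fig1` … `fig11`): glucose/xylose aerobic reference
growth with ATP accumulating; NADPH maximisation with complete (FBP
active) vs incomplete (FBP inactive, GAP exported, NADPH+GAP weighted 1:1)
PPP cycling; growth with PFK inactive and NADPH open vs closed; growth
with the ATP balance closed, without and with the FBP/PFK pair; the
oxidative-PPP cofactor swap (glucose-6-phosphate dehydrogenase moved from
NADP⁺ to NAD⁺) with FBP vs PFK active; and anaerobic xylose growth.
"All biomass precursors may accumulate" opens an export-only exchange on
every precursor drained by the growth reaction.  The dual NADPH+GAP
objective uses equal weights; the resulting optimum is degenerate between
exporting GAP and oxidising it for one further NADPH via NADP-isocitrate
dehydrogenase, and parsimony selects the export route (the FVA range makes
the alternative visible).  A `limited_malic_config` probe caps malic
enzyme at 50 % of its anaerobic optimum flux: any cap forces xylitol
export, and below ~15 % no anaerobic steady state exists at the forced
uptake, which is why the probe does not sit lower.

## Biomass coefficients

The growth reaction's drain coefficients are a documented stand-in
(provenance `"standin"`), not the externally published set, which is not
bundled.  Values are textbook yeast precursor demands (mmol per gram dry
weight: G6P 2.1, F6P 0.3, R5P 0.9, E4P 0.3, GAP 0.2, 3PG 1.5, PEP 0.7,
pyruvate 2.8, acetyl-CoA 2.4, OAA 1.8, 2-OG 1.1; ATP 35, NADPH 11
consumed, NADH 6 produced), scaled ×10 so one growth-flux unit ≈ 10 g
biomass and simulated growth fluxes land near 0.1 at the reference uptake
of 10 — the comparative-unit regime in which these scenarios are usually
discussed.  Consequences:

* Quantities that are pure stoichiometry (the NADPH balances 90 and 30,
  their three-fold ratio, cycle net conversions, all flux-direction
  facts) are independent of these coefficients, and the acceptance script
  demonstrates this by perturbing every coefficient ±20 % per seed.
* Growth-rate and ATP/O₂-exchange *magnitudes* are coefficient-dependent
  and are asserted only as orderings and signs, verified across 20
  perturbation seeds (`perturb_biomass`, counter-based Philox seeding).

## Synthetic models and the oracle

`random_small_model` plants a unit-yield linear uptake→export chain (so a
non-trivial feasible flux always exists and the no-side-reaction optimum
is known in closed form), then adds random side reactions with
coefficients in {−2, −1, 1, 2}; everything is box-bounded and
deterministic per seed.  `brute_force_optimum` enumerates all basic
feasible solutions of the boxed equality system — vertex enumeration, no
LP library, no code shared with the engine — and agrees with the engine to
10⁻⁷ on 50 seeded instances.  It refuses instances beyond its enumeration
budget rather than approximating.  What the synthetic surface does *not*
emulate: cofactor pairing, conserved moieties and biological reversibility
patterns; those are exercised by the reference-model scenarios instead.

## Known limitations

Single compartment (no mitochondrial NADH shuttle effects); no
maintenance-ATP term (surplus ATP appears as an exchange flux instead, by
design); fixed P/O ratios; glucose repression and all regulation enter
only through manual activity edits; growth and exchange magnitudes are
comparative, not calibrated to measured rates (measured ethanol/acetate
production rates are deliberately not imposed as constraints).  Reaction
reversibility follows standard directionality (glycolytic kinases,
dehydrogenases to CO₂, and ligases irreversible; isomerases, epimerases,
transketolase/transaldolase, aconitase, fumarase, malate and alcohol
dehydrogenase, GAPDH/PGK and succinyl-CoA synthetase reversible); each
reaction's packaged choice is in `reference.py` and the exported model
tables.
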