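# Methods

## The model and what is being optimized

A metabolic model is a set of metabolites and reactions with signed
rational stoichiometry and flux bounds (arbitrary units of
mmol·gDW⁻¹·h⁻¹ type). Exchange reactions are single-sided
(`{met: -1}`): positive flux secretes, a negative lower bound permits
uptake — one exchange per external metabolite, following prevailing
constraint-based convention. Flux balance analysis maximizes the target
exchange flux subject to steady state (**S·v** = 0) and the box bounds.
There is no growth objective anywhere in the package: the design question
is the *theoretical* yield ceiling of the target compound, so the target
flux is the sole objective.

The screening statistic is the **rate of increase**: the augmented
optimum rescaled so the host-only optimum is 100, rounded half-up to an
integer. Rounding is cosmetic — the improved/neutral decision is made on
the raw LP optima with relative tolerance 10⁻⁶, so designs printing 133
and 134 are distinguished before rounding. Whether the original
tabulations rounded or floored is undocumented; half-up is used here and
is consistent with every printed value (e.g. 400/3 → 133).

## Candidate enumeration

The heterologous pool is the universal database minus the host's
reactions, judged by reaction-id match against the host's annotations
(list subtraction). Stoichiometric deduplication is deliberately not the
default: adding a reaction stoichiometrically identical to a host
reaction is harmless (rate stays exactly 100, a tested invariant).

Linking is structural, on carbon-skeleton connectivity:

* a **singleton** candidate is any pool reaction with at least one
  non-currency compound present in the host;
* a **chain** grows outward from such an anchored reaction through *link*
  compounds — novel, non-currency metabolites shared by consecutive
  reactions — each link traversed once;
* with `anchored_both_ends=True` (default) the final reaction of a
  multi-reaction chain must itself touch the host. A dangling far end
  cannot carry steady-state flux and therefore can never change an FBA
  optimum; the permissive mode exists because the outward-growing search
  procedure is also meaningful on its own, and is kept switchable.

A candidate set combines m reaction-disjoint chains totalling n
reactions (n ≤ 5 by the CLI's hard cap). For n = 2 this reproduces the
two canonical addition topologies: two independently anchored singletons
(m = 2) and one two-reaction chain joined through a novel metabolite
(m = 1). The same reaction pair can legitimately appear as both shapes —
they differ in m but define the same LP.

Enumeration order is derived entirely from lexicographic reaction ids;
nothing depends on hash order, and repeated runs are byte-identical.
Exhaustive enumeration carries a hard candidate budget (default 10⁶)
with an explicit truncation flag, since universal databases at full KEGG
scale make the combination space enormous.

### Currency metabolites

The shipped default exclusion list contains H₂O, ATP/ADP/AMP, Pi, PPi,
NAD(P)⁺/NAD(P)H, FAD/FADH₂, CoA, H⁺, O₂, NH₃ and CO₂ (KEGG C-numbers).
It is a reconstruction of the standard currency set, not a copy of any
specific published exclusion table, and is fully user-replaceable
(`--currency`, one id per line). CO₂'s membership only affects linking;
excluded compounds keep their place in every added reaction's
stoichiometry, so carbon balances are unaffected.

## FBA layer

* Primary backend: scipy's HiGHS (`method="highs"`); secondary backend:
  GLPK via optlang. A test asserts agreement within 10⁻⁶ relative; on
  ≤ 8-reaction toy networks both are checked against an exact rational
  vertex-enumeration oracle implemented independently in the test suite.
* Tolerances: steady-state residual ≤ 10⁻⁹ at reported optima
  (measured ~10⁻¹⁴ on the shipped problems), backend agreement 10⁻⁷,
  improvement threshold 10⁻⁶ relative.
* Coefficients are exact rationals in the model layer; the LP layer is
  float64 with the documented tolerances.
* Added heterologous reactions default to bounds (−1000, 1000) when the
  source equation is reversible and (0, 1000) when forward-only,
  mirroring genome-scale convention; the magnitude is configurable
  (`default_bound`).
* Degenerate optima: the objective *value* is the contract. Reported
  flux distributions and the activated-reaction comparison use
  parsimonious FBA (minimize Σ|v| at the target optimum, via variable
  splitting) so the support is stable across solver vertices. "Activated"
  means |v| rises from ≤ 10⁻⁶ to > 10⁻⁶ between the baseline and
  augmented parsimonious solutions, host reactions only.
* Simulation setup for glycogen catabolism in the dark: the glucose-unit
  source exchange capped at the given uptake (default 100), O₂ uptake
  closed, photon fluxes zeroed. CO₂ is efflux-only by default; since
  the membrane is CO₂-permeable a `free` policy is provided as a config
  switch, and on the shipped fixture it provably does not change the
  succinate optimum (tested) because no route makes external CO₂
  carbon-productive there.

## The core fixture

`hymep.fixtures.build_core_model()` is a 20-metabolite, 21-reaction
carbon-skeleton model of *Synechocystis* central metabolism under
glycogen catabolism: lumped glycolysis (glycogen → G6P → 2 PGA → PEP),
PEP carboxylase, pyruvate dehydrogenase, citrate synthase and aconitase,
then the GABA shunt (isocitrate → 2OG → Glu → GABA → SsA → succinate),
a malate/fumarate dead-end arm (no fumarate reductase exists in this
organism), and the initially dormant glyoxylate→glycerate route
(2 Glx → tartronate semialdehyde + CO₂ → D-glycerate → PGA).

Deliberate simplifications, and what they mean for the tests:

* **Cofactors are omitted.** The yields of interest are
  carbon-stoichiometric; with no cofactor constraints stated for the
  glycogen-catabolic condition, tracking ATP/NAD(P)H would add
  unconstrained degrees of freedom without changing the carbon optimum.
  This makes the fixture's optima exactly reproducible (100 and 400/3 by
  rational arithmetic) but means the fixture says nothing about redox or
  energy limitations of real designs.
* **Nitrogen is lumped** (the Glu/GABA aminations are written
  carbon-only), consistent with freely exchanged NH₃.
* **Glycogen is glucose-equivalent units**, so uptake 100 reads as 100
  glucose and yields are mol per mol glucose.
* Every internal reaction is carbon-balanced (audited per-reaction in the
  tests), which yields the model-wide identity
  6·uptake = 4·succinate + CO₂ at any feasible flux, asserted at both
  optima.

The fixture's exact optima: baseline 100 (yield 1.00 mol/mol); with
isocitrate lyase, the 3-phosphoglycerate balance 2·100 + v/2 = 2v gives
v = 400/3 (rate 133), with exactly GCL, TSR and GLYK newly active.

The four-reaction toy database carries the case-study entries
R00479 (isocitrate → succinate + glyoxylate), R00751 (L-threonine →
glycine + acetaldehyde) and R01867 ((S)-dihydroorotate + fumarate →
orotate + succinate). The fourth entry, R10179, has no published
stoichiometry in the source material; the shipped equation is a clearly
marked synthetic stand-in (written as an acetylating acetaldehyde
dehydrogenase, the chemistry consistent with its use alongside threonine
aldolase) and is excluded from every quantitative claim. R00751 and
R01867 are inert on the core fixture by construction — the fixture lacks
the threonine/glycine and pyrimidine subnetworks — so the unique
productive single addition is isocitrate lyase, a tested invariant.

## File formats

* SBML Level-3 + FBC (read/write via COBRApy); KEGG ids are harvested
  from `kegg.compound` / `kegg.reaction` annotations, first well-formed
  match wins (annotation practice across published models is
  inconsistent).
* TSV model dialect: `reaction_id  equation  lb  ub  is_objective`
  (+ optional `universal_id`), `#` comments, equations over model
  metabolite ids with single-sided exchanges allowed.
* Universal database TSV: `reaction_id  equation`, grammar
  `[coef] compound + ... <=>|=> ...`; polymer-style (`n`) entries are
  skipped with a warning since they have no finite stoichiometric column.
* Compound map (host metabolite id → compound id): JSON or two-column
  TSV; many-to-one is allowed, and when several compartmentalized
  metabolites share a compound id the lexicographically first receives
  the heterologous wiring (deterministic, documented tie-break).
* Reports print rates as round-half-up integers and fluxes with six
  significant digits, rows ordered by rate descending then reaction ids.

## Problem sizes and runtime

The shipped analyses are desk-scale by design: the core model (21
reactions), a 4-entry and a 12-entry toy database, random property-test
models of ≤ 8 reactions (small enough for the exact vertex oracle), and
200 randomized addition trials for the monotonicity property. The full
test suite and the acceptance script each run in well under a minute on
one CPU. Screening a genome-scale model against a full KEGG snapshot is
supported by the same code paths but is gated on the user supplying those
inputs; the beam/budget controls exist for that regime.

## Known limitations

* Linking is purely structural; it does not test whether a chain can
  carry flux (the FBA screen settles that), nor thermodynamic
  feasibility, enzyme cost, or atom mapping.
* Exogeneity by id match misses host reactions that exist under a
  different database id.
* The activated-reaction report depends on the parsimonious flux
  convention; other flux-norm choices could report different (equally
  optimal) supports.
* No gene–protein–reaction rules, compartment assignment for added
  reactions (everything lands in the cytosol), growth coupling, or
  variability analysis.
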