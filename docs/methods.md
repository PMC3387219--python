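# Methods

## Model and assumptions

The core computation is steady-state flux balance analysis. A metabolic
network is a set of stoichiometric reactions; at steady state every internal
metabolite's production balances its consumption, so any flux vector **v**
satisfies S v = 0, where S is the stoichiometric matrix (rows: metabolites,
columns: reactions). Reaction irreversibility and transport capacities enter
as bounds a ≤ v ≤ b, and the biosynthetic flux Z is the flux of a *biomass
drain* column that consumes every target molecule in proportion to its
weight. Maximizing Z subject to these constraints is a linear program.

This carries the usual FBA assumptions: constant nutrient supply, no
regulatory or kinetic constraints, and optimality of the flux distribution.
Relaxing them would not lower the minimal reaction counts the pipeline
studies, but it would change flux predictions for real organisms.

The drain construction makes "viable" a single number: because the drain
consumes *all* targets simultaneously in fixed proportions, a positive drain
flux certifies that every required biomass molecule is synthesizable in the
required ratio. Viability is Z ≥ ε with ε = 10⁻⁶ mmol·gDW⁻¹·h⁻¹ — far above
the solver's feasibility tolerance (10⁻⁹, HiGHS defaults) and far below any
genuine growth optimum at the default carbon uptake bound.

The stoichiometric system gives every metabolite a row, external ones
included; exchange reactions (one per external metabolite) are the system
boundary, and the sole-carbon-source condition lives entirely in their
bounds: the designated source's exchange admits uptake up to the carbon
uptake bound, every other carbon-containing exchange is secretion-only, and
carbon-free (inorganic and currency) exchanges are unconstrained in both
directions. This is the conventional boundary formulation; an alternative
that drops external rows and pushes medium constraints onto transports is
equivalent for every quantity reported here but entangles the medium
definition with the transport infrastructure.

## Degenerate optima

FBA optima are rarely unique, and the number of active reactions R_A and the
carbon waste W are properties of a particular optimal vertex. By default the
solver therefore runs lexicographically: maximize Z, then minimize Σ|v| at
fixed Z (the parsimonious-FBA secondary objective, implemented with split
auxiliary variables). This makes (Z, R_A, W) reproducible to 10⁻⁶ across
runs and solvers. A flag disables the second stage to mimic raw solver
behavior. Exact ties among equal-length parallel routes remain possible;
either choice gives the same R_A, which is what the pipeline reports.

## Synthetic universes

Real universal reaction sets are assembled from reaction databases and
curated genome-scale models; they are large, and their pathway structure is
only known a posteriori. The generator instead builds hub-and-spoke
universes whose structure *is* the ground truth:

* a single internal hub metabolite (3 carbon atoms by default — a stand-in
  for central carbon metabolism);
* per carbon source (6 C, external, with transport and exchange), one
  dedicated linear catabolic route of exactly `L_N` internal reactions
  ending in full-yield hub production (6 C source → 2 hub);
* per biomass candidate (3 C, internal), one dedicated linear anabolic route
  of exactly `L_B` internal reactions from the hub;
* `redundancy_factor` equal-length duplicate routes per pathway, with
  distinct intermediates — these make genotype space non-trivial (minimal
  networks differ in composition, reaction swaps have somewhere to go)
  without changing minimal network sizes;
* optional lossy catabolic variants (6 C source → 1 hub + 3 CO2) and
  hub → CO2 waste branches, which make waste and flux vary across networks;
* an optional family of related targets sharing an anabolic prefix plus one
  dedicated step each, emulating biochemically related molecule families
  such as the proteinaceous amino acids;
* carbon-free currency metabolites (cofactor analogs, never counted in B)
  and inorganic medium components, each with transport and exchange.

All coefficients are exact rationals, so the internal-reaction carbon
balance Σ coefficient × carbon = 0 is checked exactly, not to tolerance.
Universes serialize to two TSV tables plus a JSON header carrying a SHA-256
content hash over a canonical (sorted) serialization; genotype files record
the hash of the universe they refer to and are rejected against any other.

Designed consequences used by the tests: a minimal network serving N sources
and B targets contains exactly `L_N·N + L_B·B` reactions (one complete route
per required pathway), so the fitted R~N and R~B slopes have true values
`L_N` and `L_B`; with only full-yield routes, every viable network achieves
the same flux `Z = uptake · (source C / hub C) / Σ weights`, so the S~R
slope is exactly zero. The generated universes emulate the *structure* of
real universal networks (alternative routes, waste-carrying branches, fixed
transport infrastructure), not their scale, connectivity heterogeneity,
cofactor coupling, or cyclic topology — so passing tests certify the
machinery and the qualitative laws, not genome-scale regression constants,
whose values are properties of the real reaction universe.

## Samplers

**Minimal networks.** Starting from a viable network, reactions are visited
in a random order; each is removed if viability on every required
environment survives, and restored otherwise. A single pass suffices:
removing reactions only shrinks the feasible flux cone, so a reaction whose
removal is infeasible now can never become removable after further
deletions (essentiality is monotone under removal). `verify_minimal`
re-audits every output by attempting each single deletion.

**Fixed-size starts.** The same removal loop, stopped when the requested
size R is reached; if the removal order bottoms out on a larger minimal
network first, the failure is explicit (retry with another seed or a larger
R).

**Reaction-swap MCMC.** A move removes one uniformly chosen genotype
reaction and adds one uniformly chosen universe reaction currently absent;
the move is accepted iff the result is viable on all required environments,
otherwise a new pair is proposed within the same step. The number of
(member, non-member) pairs is constant at fixed R, so the proposal is
symmetric and the chain satisfies detailed balance with a uniform stationary
distribution over the reachable viable genotypes of size R. Burn-in and
thinning count *accepted* swaps (a rejected proposal is a retry inside a
step, matching the usual bookkeeping of viability-constrained swap walks); a
chain record stores the attempts-per-swap series so acceptance behavior is
inspectable. Desk-scale defaults are burn-in 5·R and thinning 2·R accepted
swaps; the full-scale preset (2.5×10⁶ burn-in, 5×10³ thinning) is recorded
as constants. Viability results are memoized per genotype, which makes long
chains on small universes cheap.

Environment order inside a viability check is shuffled when a sampler
supplies its generator, so short-circuit failure statistics are not biased
toward the first listed environment; the boolean result is
order-independent.

## Statistics

Trade-off lines are ordinary least squares with t-based 95% confidence
intervals on the slope (e = t₀.₉₇₅,ₙ₋₂ · SE), reported in the display form
y = (a±e)x + b. Multiple regressions report coefficients and R². "Slope
indistinguishable from zero" is operationalized as the 95% CI containing
zero. Pearson correlations carry two-sided t-distribution p-values. Group
comparisons use the two-sided Mann-Whitney U test: exact null for samples of
min size ≤ 8 without ties, normal approximation with continuity and tie
correction otherwise. No multiple-testing correction is applied; the
regression battery is reported in full. A constant response is reported as
slope 0 with R² = 0 and no association test.

The seven-organism comparative table ships as a packaged TSV. Its N~R
Pearson correlation is 0.905 (p = 0.0051). The R_A ~ B regression is plain
OLS on the printed rows — slope 4.1, intercept 65.5 — and the report flags
that this exceeds the 3.4 sometimes quoted for the same table, whose fitting
variant is not reproducible from the printed values.

## Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| carbon uptake bound | 10 | mmol·gDW⁻¹·h⁻¹ | typical genome-scale glucose-uptake order; exposed in config |
| viability threshold ε | 10⁻⁶ | mmol·gDW⁻¹·h⁻¹ | well above LP tolerance, well below any optimum |
| active-flux tolerance | 10⁻⁶ | mmol·gDW⁻¹·h⁻¹ | same scale as ε |
| free bound (inorganics, secretion) | 1000 | mmol·gDW⁻¹·h⁻¹ | effectively unconstrained |
| source / hub carbon | 6 / 3 | atoms | hexose → triose analogy; source must be a multiple of hub |
| L_N, L_B | 2, 3 | reactions | designed slopes of the worked examples |
| burn-in, thinning (desk) | 5·R, 2·R | accepted swaps | exceeds the mixing scale of desk universes |

R_A counts internal plus transport reactions with |flux| above tolerance
(exchanges and the drain are boundary bookkeeping); an `internal_only` flag
restricts to internal reactions, under which every reaction of a minimal
network is active in some required environment.

## Problem sizes

Experiments run at desk scale: universes of 25–62 internal reactions,
grids of N, B ≤ 4, tens of networks per experiment, 10⁴-sample uniformity
chains on a 9-genotype space. These sizes were chosen so that each designed
property (slope recovery, uniformity, minimality) is measured with clear
margins while the whole suite and the acceptance script each complete in
about a minute on one CPU. The flux-versus-size null is evaluated on
universes without lossy route variants, where flux is size-invariant by
construction; with lossy variants present, larger random networks are more
likely to contain a full-yield route, inducing a positive size–flux trend
that is an artifact of the small designed universes rather than a property
of large reaction sets.

## Known limitations

* Hub-and-spoke universes have no cycles, no shared intermediates between
  pathways (outside the designed related-target prefix), and no cofactor
  stoichiometry coupling; quantitative regression constants from them are
  design echoes, not predictions for real universes.
* Uptake bounds are equal-molar across carbon sources; an equal-carbon
  normalization would rescale per-source fluxes (the comparison is exposed
  through the uptake parameter, not automated).
* The LP path reports one parsimonious optimum; flux variability across
  alternate optima is out of scope.
* MCMC uniformity holds over the *reachable* component of fixed-R viable
  genotype space; on designed universes the space is connected, but
  connectivity is not verified for arbitrary user universes.
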