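# Methods

`symbflux` analyzes the metabolism of rhizobial bacteroids — the
differentiated, nitrogen-fixing form of rhizobia inside legume nodule
cells — with constraint-based (stoichiometric) modeling. This note
documents the models and procedures implemented, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic test
network does and does not demonstrate.

## The model and the symbiosis objective

A metabolic model is a set of metabolites (with elemental formulas and
charges), reactions (stoichiometry, flux bounds in mmol gDW⁻¹ h⁻¹, and a
gene-protein-reaction rule), and an objective reaction. Flux balance
analysis (FBA) solves

    max  v_obj    s.t.  S·v = 0,   lb ≤ v ≤ ub

by linear programming. Because bacteroids do not grow, the biomass
objective of ordinary genome-scale models is replaced by a *symbiosis
reaction*: a pseudo-reaction consuming, in fixed stoichiometry, the
components an effective symbiosis demands of the bacteroid — carbon
storage polymers (PHB, glycogen), amino acids, fixed ammonia delivered to
the plant, and cofactors. The composition is specified in mmol of
component per gram of symbiosis product and is rescaled by a single
scalar so that the pseudo-product's molecular weight is exactly
1 g mmol⁻¹; one unit of objective flux is then one gram of symbiotic
output per gDW per hour, and yields are comparable across models after
`rescale_for_cross_model_comparison` equalizes the mass moved per flux
unit.

Yields are reported per mmol of element taken up: carbon yield =
objective flux ÷ Σ|uptake flux|·(C atoms), and likewise for nitrogen;
the C/N column is their ratio. Secreted carbon is deliberately not
subtracted from the denominator (the yield is per mmol *taken up*).

## Model-quality validation

Three checks mirror the consistency battery of community model test
suites:

* **Mass/charge balance** — per internal reaction, Σ coeff·count must be
  zero for every element and for charge (tolerance 10⁻⁶). Generic side
  groups (`R`) are carried as a massless pseudo-element and must cancel.
  Reactions touching a metabolite with unknown formula are "unchecked",
  never silently balanced. Exchange reactions and single-metabolite sinks
  are exempt.
* **Stoichiometric consistency** — existence of a strictly positive mass
  vector `m` with `S_intᵀ m = 0`, solved as the closed feasibility
  problem `m ≥ 1` (scale-invariant). On failure, an auxiliary LP
  maximizes the number of conserved metabolites and reports the minimal
  complement as the unconserved witness set.
* **Energy-generating cycles (EGC)** — all exchanges are closed to
  [0, 0], an ATP dissipation reaction (ATP + H₂O → ADP + Pi) is added
  and its flux maximized; an optimum above 10⁻⁶ exposes an internal loop
  creating energy from nothing, and the nonzero-flux reactions are the
  witness.

## Linear programming

All LPs are solved with HiGHS (through `scipy.optimize.linprog`) at
primal/dual feasibility tolerances of 10⁻⁹, with variables in model file
order so repeated solves return identical vectors. Shadow prices are the
duals of the metabolite balance rows, reported as the marginal objective
change per unit of external supply; they are verified against finite
differences in the test suite. When the optimal basis is degenerate the
duals may be non-unique; a degeneracy flag is surfaced and the prices are
used qualitatively (rate-limiting vs not), which is how the analysis
interprets them. Flux variability analysis (FVA) solves per-reaction
min/max LPs under `v_obj ≥ f·optimum`; the pipeline uses f = 0 for the
E-Flux baseline envelope and f = 1 to ask which reactions are forced at
the optimum.

The two-condition comparison fixes each condition model's objective at
its own optimum (as an equality row — the optimum is attainable by
construction, and an inequality with slack would let the 1-norm
minimization shave the objective by the slack) and minimizes
Σ|v_A| + Σ|v_B| jointly with the standard split `t ≥ |v|`
linearization. This removes futile-cycle flux and makes the two flux
distributions comparable; the optima and hence the yields are unaffected
by whether the 1-norm step runs before or after yield computation.

## Gene deletions

GPR rules are parsed with `and` binding tighter than `or`. A single-gene
deletion disables exactly the reactions whose rule evaluates false with
that gene removed (isozymes survive; complexes fail), sets their bounds
to [0, 0], re-solves, and records the *symbiotic rate ratio*
mutant/wild-type. Classification: **essential** if ratio < 0.05,
**partial** if 0.05 ≤ ratio < 1 − 0.01, **nonessential** otherwise. The
0.01 guard keeps LP round-off from being labeled a partial effect; the
two-threshold rule is the only reading that reconciles a single
"symbiotic gene" cutoff of 0.05 with a separate partial-effect class,
and both thresholds are exposed as parameters. Genes absent from every
GPR are reported with ratio 1 and an out-of-scope flag rather than
omitted.

## E-Flux expression integration

Per-gene normalized expression (one value per gene per condition;
upstream read mapping and normalization are out of scope) is mapped to
reaction activity scores through the GPR tree: `and` → min of child
scores (a complex is limited by its scarcest subunit), `or` → sum
(isozyme capacities add). The sentinel −1 marks missing data: an AND
ignores missing children when another child is scored, an OR sums only
scored children, and a node with no scored child (or an empty rule)
scores −1.

Scores become bounds by shrinking the baseline FVA envelope (fraction 0)
toward zero by a relative activity r. The default normalization is
**per-reaction, cross-condition**: r = score ÷ max of that reaction's
score across the two conditions, so the condition with the higher
expression keeps the full envelope and the other is scaled down by the
between-condition expression ratio. Two alternatives are available for
sensitivity checks: `global` (divide by the maximum finite score over
all reactions and conditions) and `per_condition`. The cross-condition
default is preferred because it compares conditions by their expression
*ratio* — the quantity the transcriptome actually measures — and because
global-max scaling shrinks every bound relative to the single
most-expressed gene, which can push a model with a fixed maintenance
demand into infeasibility even when both conditions are biologically
viable. A zero score closes the reaction ([0, 0]), distinct from −1
(unknown, bounds untouched). Exchange bounds — the nutrient condition —
are never expression-scaled unless the exchange itself carries a GPR.
Whether reversible lower bounds should be scaled symmetrically is not
settled; both bounds are multiplied by the same r ("toward zero"), which
preserves side ordering.

## Evolutionary sensitivity analysis

Starting from the lower-yield condition's bounds, each iteration picks
one reaction uniformly at random from those whose bounds differ between
conditions and interpolates both of its bounds a random fraction
λ ~ U(0, 1) toward the high-yield condition (outright replacement is a
config option). The move is kept only if the optimum improves by more
than 10⁻⁶ (neutral moves are reverted, preventing drift through
degenerate optima). A run ends when the objective reaches the
high-condition optimum or after `stall_limit` consecutive rejections
(default 50 × the number of differing reactions, the expected coverage
of all candidate moves; the published procedure's stopping rule has no
printed tolerance, so these are explicit assumptions). Reactions
accepted in ≥ 90% of runs (threshold configurable) are reported as
determinants, with the mean objective increment credited at acceptance.
One master seed spawns per-run seeds as (seed, run index), so runs are
bit-reproducible and parallel-safe.

A caveat on bracketing: when the low-condition bound set is nested
inside the high-condition one (e.g. a uniform down-shift), every run's
final objective lies between the two condition optima. With noisy
profiles the sets are *not* nested — each condition keeps the full
envelope on the reactions where its own expression is higher — and a
hybrid of adopted and unadopted bounds can legitimately exceed the pure
high-condition optimum. The valid upper bound is then the optimum under
the per-reaction union of the two bound sets, which is what the test
suite asserts in the noisy setting. Note also that a bottleneck spread
over two reactions in series is invisible to single-reaction greedy
moves: neither move alone improves the objective, so neither is ever
accepted. Planted bottlenecks in the synthetic scenarios are therefore
single reactions.

## The synthetic toy bacteroid

`generate_toy_bacteroid_model` emits a 47-reaction, 41-metabolite,
35-gene network with the canonical bacteroid architecture: malate and
succinate uptake (the C₄-dicarboxylate supply from the host plant)
feeding a full TCA cycle; a lumped cytochrome oxidase
(NADH + ½O₂ + 3 ADP + 3 Pi → NAD + 3 ATP + 4 H₂O, a cbb3-type P/O of 3);
the canonical nitrogenase
N₂ + 4 NADH + 16 ATP + 16 H₂O → 2 NH₃ + H₂ + 4 NAD + 16 ADP + 16 Pi
(ATP coefficient configurable); PHB and glycogen synthesis; alanine and
aspartate export; glutamate and myo-inositol as secondary substrates; a
fixed ATP maintenance; and a balanced symbiosis reaction over
{PHB 4, glycogen 1.5, glutamate 0.8, NH₃ 8, Pi 0.3} mmol per g
(pre-scaling) — storage polymers, the amino-acid demand, the fixed
nitrogen delivered to the plant, and phosphate as a cofactor proxy. A
fermentative NADH → NAD + H₂ valve stands in for the electron-overflow
routes real bacteroids possess; without it, every unit of substrate-level
ATP would require oxygen to reoxidize its NADH, and the fixed maintenance
of 4 mmol gDW⁻¹ h⁻¹ would leave expression-scaled condition models with
no feasible margin. All metabolites carry neutral whole-molecule
formulas and charge 0, so elemental balance implies charge balance; every
reaction balances exactly by construction, the network is
stoichiometrically consistent, and it contains no energy-generating
cycle (asserted at generation time by the validation battery).

The standard nitrogen-fixation condition sets malate uptake ≤ 1.44,
succinate ≤ 1.38, O₂ ≤ 1.26 mmol gDW⁻¹ h⁻¹, ATP maintenance fixed at 4,
and −1000 lower bounds on the free cofactor/ion exchanges — the
literature-derived microaerobic bacteroid condition. Glutamate (0.18)
and inositol (0.05) uptakes are placeholders exposed in the condition
YAML; the values used for the published genome-scale model live in its
deposited scripts and must be supplied when reproducing its numbers.
Under these defaults the toy's optimum is 0.0720 g gDW⁻¹ h⁻¹ (carbon
yield 0.0058 g mmol⁻¹ C), reproducible to 10⁻⁸ across solves.

Sign conventions: exchanges are written `metabolite →`, so uptake is a
negative flux and uptake limits are lower bounds.

Synthetic expression profiles draw per-gene values from a lognormal
around per-pathway baseline means (RPKM-like scale, *nif* genes highest
at 900, energy/carbon backbone 600–800, side pathways 200–300), with
σ = 0.2 log-noise drawn independently per gene and condition and 10% of
genes set to the −1 sentinel in both conditions. The default host-shift
scenario multiplies condition B's oxidase genes by 0.5 and inositol
catabolism by 0.4, emulating a poorer host; across seeds this yields
feasible condition models with B's yield below A's, and the sensitivity
analysis recovers CYTOX and INOSD as determinants.

**What the toy does not show.** It is a test fixture, not a biological
claim: pathways are lumped (one oxidase, one gluconeogenesis step),
protons and charge states are absorbed into neutral formulas, the
electron valve is an abstraction, and its ~40 reactions cannot exhibit
the degeneracy, redundancy and annotation noise of a genome-scale
reconstruction. Passing tests demonstrate that the algorithms are
correct on a network whose ground truth is known exactly — not that any
biological conclusion transfers to real data. Conversely, the loaders,
validators and analyses accept genome-scale SBML/JSON models unchanged;
`scripts/reproduce_icc541.py` runs the same pipeline on the published
*S. fredii* bacteroid reconstruction once downloaded.

Two behaviors of the toy differ from naive expectation and are worth
stating: with O₂ uptake 0 the standard condition is *infeasible* (the
fixed maintenance cannot be met), and with the maintenance also released
the optimum is positive but less than half the aerobic value, sustained
by substrate-level phosphorylation through the electron valve.

## Numerical choices

* "Zero" in validators and acceptance decisions: 10⁻⁶ on the solver
  scale; LP feasibility tolerances 10⁻⁹.
* Default bounds ±1000 mmol gDW⁻¹ h⁻¹ where a file omits them.
* TSV outputs round to 4 significant figures (the precision of the
  published tables); JSON sidecars keep full precision.
* Ties in FVA (min > max by round-off on forced fluxes) collapse to the
  midpoint.
* Fractional formula counts (the symbiosis pseudo-product) serialize
  with 12 significant digits so that re-read models still balance below
  tolerance; SBML's FBC `chemicalFormula` forbids decimals, so
  fractional formulas travel in species notes instead.

## Problem sizes used in the test suite

The suite runs entirely on generated fixtures: exact LP oracles
(brute-force vertex enumeration) on networks of ≤ 6 reactions, the
47-reaction toy for pipeline properties, 200 noise-free and 100 noisy
sensitivity runs for determinant recovery — sizes at which every
expected value is computable independently while exercising every code
path of the genome-scale workflow.

## Known limitations

* Shadow prices inherit solver-basis non-uniqueness under degeneracy.
* The E-Flux proportionality assumption (bounds ∝ transcript-derived
  scores) is a proxy for enzyme activity and can misrank reactions under
  post-transcriptional regulation.
* The greedy sensitivity search cannot credit serial multi-reaction
  bottlenecks (see above) and its acceptance frequencies depend on the
  stall limit for marginal-gain reactions.
* Double deletions, MOMA-style quadratic reallocation and loopless FVA
  are out of scope.
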