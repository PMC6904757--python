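# Methods

## Scope and model

The package analyzes stoichiometric metabolic models under the standard
constraint-based assumptions: pseudo-steady state (no net accumulation of
internal metabolites, S·v = 0), flux capacity bounds, and a linear cellular
objective — normally the biomass pseudo-reaction, whose flux is read as the
specific growth rate μ in 1/h. No thermodynamic (loop-law) constraints,
kinetics, or regulation are modeled; a dose–response "toxicity" scan, for
instance, probes only whether the stoichiometry admits co-metabolism of a
forced compound, not inhibition kinetics.

Sign conventions follow the field: exchange reactions carry one metabolite,
negative flux is uptake, positive is secretion; a medium is a map from
exchange ids to non-negative uptake magnitudes, applied by closing uptake of
every other exchange. Exchange detection uses the single-metabolite rule
(an `EX_` id prefix on a multi-metabolite reaction does not qualify); this
also classifies single-metabolite biomass drains on toy networks as
boundaries, which is intended and documented in the fixtures.

## Linear programming

All solves use `scipy.optimize.linprog(method="highs")` at default settings:
HiGHS is deterministic for a fixed problem, which is what makes the TSV
outputs and the acceptance quantities reproducible. Solver feasibility works
at ~1e-9; every equality the package itself asserts (steady-state residuals,
binding objective floors) is checked at 1e-6. Infeasible and unbounded
problems are reported as statuses, never raised, so screens over many
conditions can record them as data points.

- **FBA** maximizes c·v. With alternate optima the returned vertex is
  whatever HiGHS yields; any distribution consumed downstream (flux-sum)
  goes through total-flux minimization instead.
- **Minimum total flux** linearizes Σ|vⱼ| by the split v = p − q with
  p, q ≥ 0 and box bounds chosen so the split reproduces [lb, ub] exactly
  even for reactions forced to run or to reverse; the objective floor
  c·v ≥ f·Z* enters as one inequality row. This suppresses futile cycles
  (they only add |v|) and picks a canonical optimum.
- **FVA** solves two LPs per reaction under the same floor. The fraction
  defaults to 0.9 for "suboptimal" analyses (comparison with measured
  fluxes) and 1.0 elsewhere. An interval endpoint that runs into the
  reaction's own ±1000 default bound is flagged unbounded-by-the-network
  rather than reported as infinite, keeping tabular output finite while
  making futile-cycle spans visible.

## GPR logic and knockouts

GPR expressions are Boolean trees over gene ids (AND = complex subunits,
OR = isozymes; empty = spontaneous/orphan, always active). The grammar gives
AND higher precedence than OR, keywords are case-insensitive, and
associative chains are flattened. Deleting a gene set closes (bounds to
zero) every reaction whose GPR evaluates inactive — reactions are never
removed, so one model object supports repeated what-if queries. A knockout
closes *all* reactions whose rules become inactive, including complexes that
merely contain a deleted gene without isozyme backup; this is the natural
reading of bound-zeroing knockouts when a gene participates in several
associations.

## Flux-sum turnover

φᵢ = ½ Σⱼ |Sᵢⱼ vⱼ| equals both the total production and the total
consumption of metabolite i at steady state (the conservation identity is a
test invariant at 1e-6). Profiles across carbon sources fix an uptake basis
of 1 mmol carbon/gDW/h: each source's exchange bound is basis divided by its
carbon count, read from the metabolite formula when present (element parsing
distinguishes C from Ca/Cl/Co) or from a user table — there is no hard-coded
biochemistry. The distribution entering φ is the minimum-total-flux solution
at fraction 1.0 (configurable), since raw FBA optima are not unique.
Row normalization divides each metabolite by its maximum across sources;
all-zero rows stay zero and the operation is idempotent.

## Batch kinetics

For a time course (tᵢ, xᵢ, Cᵢ), the per-interval estimators are
μᵢ = ln(xᵢ₊₁/xᵢ)/Δtᵢ and vᵢ = μᵢ(Cᵢ₊₁−Cᵢ)/(xᵢ(e^{μᵢΔtᵢ}−1)), signed so
consumption is negative (the medium builder takes magnitudes). The μ → 0
singularity is removable; below |μ| = 1e-9 the limit vᵢ = (Cᵢ₊₁−Cᵢ)/(xᵢΔtᵢ)
is used. The bundled batch simulator is the exact closed-form inverse
(x(t) = x₀e^{μt}, Cᵢ₊₁ = Cᵢ + v·xᵢ(e^{μΔtᵢ}−1)/μ), so recovery is exact to
rounding — that exactness is itself a test.

Through-origin fits report slope Σxy/Σx² with the ordinary Pearson R and its
two-sided p-value (the t transform at n−2 degrees of freedom, via
`scipy.stats.pearsonr`); with fewer than three points or a constant variable
the p-value is NaN rather than a fabricated number.

## Phenotype screens

Each carbon source is simulated independently: base (salts-only) medium, the
source's exchange opened to the uptake bound (default 5 mmol/gDW/h,
configurable — typical for sole-carbon-source simulations), FBA, and a
growth call at threshold 1e-6 1/h so solver noise never counts as growth.
The base medium is user input, not hard-coded, because minimal-medium
compositions are model-specific. Sources lacking a carrier are called
no-growth unless hypothetical transporters are allowed, in which case an
extracellular twin, a reversible gene-less transporter and an exchange are
added *for that run only* and the call is flagged; the exchange finder only
accepts boundaries on extracellular species, so a biomass drain is never
mistaken for a transporter. Concordance is the confusion matrix and
accuracy = 100·(TP+TN)/n over sources with observations.

## Production and dose scans

The two-stage protocol maximizes biomass (μ_max), then maximizes a target
flux under c·v ≥ fraction·μ_max (default 0.9). Production is monotone
non-increasing in the fraction — a test invariant. The carbon-source panel
applies a gene knockout once and repeats the protocol per source with
per-source uptake bounds (e.g. estimated from batch courses).

Dose scans pin the dosed exchange's lower *and* upper bounds to the forced
uptake: with a free lower bound the optimizer would simply refuse a
detrimental compound and every curve would be flat. The two bundled fixtures
restate the diagnostic contrast at desk scale: a network that can only
excrete the compound shows a flat biomass curve, one with an assimilation
route a rising one, and a capacity-limited sink makes high doses infeasible.

## Synthetic data

Generators are pure functions of their arguments (seeded `numpy` RNG, no
global state). `make_toy_core` is a 3-metabolite, 4-reaction network with a
hand-derivable optimum (uptake 10, carbon doubling, Z = 20) and GPRs
covering the complex/isozyme cases; `make_branched_toy` adds a product
branch with hand-derivable two-stage production values (0 / 1 / 5 at
fractions 1.0 / 0.9 / 0.5); `make_futile_cycle_toy` adds a two-reaction
cycle that FVA flags unbounded and total-flux minimization zeroes.
`random_viable_network` plants a backbone circulation (uptake → chain →
objective drain) carrying a seeded flux, guaranteeing feasibility by
construction rather than rejection sampling, then adds random side reactions
with zero planted flux and finite bounds. The planted objective is a lower
bound on the LP optimum. What these fixtures do *not* emulate: genome-scale
degeneracy, compartmentalized cofactor balancing, or biologically realistic
stoichiometry — passing tests certify the algorithms' mathematics, not
biological predictions on any particular organism.

`brute_force_lp_oracle` enumerates polytope vertices (all choices of active
bound constraints completing the steady-state rows), filters feasibility,
and returns the best objective; it is exponential and refuses more than 10
reactions. It provides the solver-independent route for the FBA
equivalence property (50 seeded networks at ≤ 8 reactions, agreement to
1e-6). cobra's own optimizer supplies a second independent cross-check on
SBML files the package writes.

## Serialization

SBML L3+FBC reading/writing is delegated to cobra (libSBML underneath);
the package's own JSON dialect (schema in `megaflux/io.py`) is the lossless
round-trip format and also preserves the hypothetical-reaction flags and
genes unused by any GPR, which SBML-FBC ties to gene products appearing in
rules. Bracketed metabolite ids (`G6P[c]`) are split into id + compartment
on read. TSVs are written with a header, 6 significant digits, and sorted
row order so repeated runs are byte-identical.

## Acceptance quantities and problem sizes

`scripts/acceptance.py` re-derives everything at run time: the toy LP
optimum (4 reactions), the oracle agreement rate (50 networks, 2–5
metabolites, ≤ 8 reactions), suboptimal-FVA containment (10 networks of 7
reactions), the flux-sum conservation error (4 fixtures), batch estimator
recovery (two parameter sets typical of chemostat cultivations, 12
intervals), the growth-prediction correlation across the five printed
chemostat conditions on a dual-source surrogate network (the correlation
coefficient is scale-invariant, so the surrogate's arbitrary carbon yield of
0.01 gDW per mmol C does not affect it), a planted 10-source phenotype
screen with 2 planted discrepancies, two-stage production on the branched
toy, and the dose-response contrast over an 11-point grid. These sizes keep
the whole script in seconds while exercising every pipeline stage; the
genome-scale checks proper require the published SBML file (see
`fixtures/README.txt`).

## Known limitations

- No loopless FVA, MILP-based gap-filling, flux sampling, or MAT-format I/O.
- FVA "unboundedness" is relative to the ±1000 default bounds, as is
  conventional, not a certificate of mathematical unboundedness.
- The GPR parser accepts any non-keyword token as a gene id; exotic SBML
  identifier escaping is handled by libSBML on the SBML path only.
- Through-origin slopes compare observed and predicted rates on the same
  scale; on surrogate networks only the correlation, not the slope, is
  meaningful.
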