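# Methods

This note documents the modeling and numerical choices behind `mcsim`: what
the simulator assumes, which parameters matter, what the bundled example
models do and do not emulate, and where the design was genuinely open.

## Model formalism

A cell model is a deterministic, well-mixed compartmental ODE system. State
variables are species concentrations in arbitrary units (a.u.); time is in
hours. Each reaction contributes flux to its substrates/products through one
of eight rate-law kinds:

| kind | flux | required parameters |
|---|---|---|
| `smm_induced` | `Vmax · Π occ(M_i) · sat(S)` | `vmax` (or `kcat`), `km`, `ka` per activator |
| `smm_summed` | `Σ_i Vmax_i · occ(M_i) · sat(S)` | `vmax[]`, `ka[]`, `km` |
| `smm_inhibited` | `Vmax · sat(S)` | `vmax`, `km`, `ki` per inhibitor |
| `mass_action_irrev` | `kf · Π [r]^stoich` | `kf` |
| `mass_action_rev` | `kf · Π [r]^stoich − kr · Π [p]^stoich` | `kf`, `kr` |
| `synthesis` | `kf · expression_scale(product)` | `kf` |
| `degradation` | `kf · [S]` | `kf` |
| `secretion` | `kf · [S]`, mass moved cell → medium | `kf` |

with `occ(M) = [M]/(Ka+[M])` and `sat(S) = [S]/(Km+[S])`. Inhibitor
modifiers multiply any kind by the noncompetitive factor `1/(1+[I]/Ki)`;
this one-parameter form was chosen because inhibition arms appear in the
modeled pathways without any named inhibition constant, and `Ki` is the
minimal extension consistent with the named parameter set (Ka, Km, kcat,
Vmax). The saturating inducer–substrate product form for `smm_induced` is
likewise the simplest algebra using exactly those named parameters; the
`kcat` variant treats the last activator modifier as the catalytic enzyme
(`Vmax = kcat·[E]`), with any preceding activators keeping occupancy terms.

Two deliberate extensions of the textbook forms:

- **Catalysts in mass action.** An activator modifier on a mass-action
  reaction is a catalyst and multiplies the flux by its concentration (E
  treated as a pseudo-reactant that is not consumed). Without this, a
  catalyst-gated step such as receptor-driven G-protein nucleotide exchange
  would be insensitive to its catalyst's dynamics.
- **Lesion hooks.** Every activator modifier contributes its species'
  `activity_scale` multiplicatively to the flux; inhibitor concentrations are
  weighted by their `activity_scale`. `expression_scale` multiplies initial
  amounts and synthesis fluxes. This realizes "activity-level" vs
  "expression-level" lesions as two orthogonal, composable multipliers.

Modifiers never carry mass flux. Species marked `clamped` have their
derivative forced to zero (constant boundary inputs for staged runs).

## Integration and readout

Systems are integrated with the implicit Radau method (`scipy.solve_ivp`,
`rtol = 1e-6`, `atol = 1e-9`), appropriate for the stiffness produced by fast
binding steps next to slow transcriptional output. Concentrations are
clipped at zero inside the right-hand side, which keeps trajectories
non-negative to within `atol` without event handling. Default endpoint is
`t_end = 64 h` with a 16/32/64 h report grid, matching the culture sampling
scheme the models emulate. `steady_state_reached` records whether
`‖dx/dt‖∞ < tol·max(1, ‖x‖∞)` at the endpoint but is informational only:
readouts are defined at 64 h, not at equilibrium, because the laboratory
quantity being predicted is an endpoint measurement. (Whether published
percent changes were endpoint or steady-state values is not stated anywhere
we could find; endpoint is this package's canonical choice and steady-state
attainment is reported alongside.)

Percent change is `100·(perturbed − control)/control` per output marker.
When the control endpoint lies below a floor `ε = 1e-9 a.u.` (inducible
markers can legitimately rest at zero), the percentage is reported as
undefined (NaN) and the trend falls back to the sign of the absolute
difference with dead band `ε`.

## Trend statistics

Trends use a dead band θ (percent): ▲ iff Δ% > θ, ▼ iff Δ% < −θ, else ▬,
boundary inclusive. θ defaults to 5% — published trend tables draw ▬ arrows
without stating a threshold, so a value had to be fixed; θ is configurable
and surfaced in every report. Matching is strict label equality (▬ matches
only ▬); how a ▬ prediction against a ▲ observation was scored in the
original tallies is unstated, and strict equality is this package's rule.

The exact binomial test uses integer binomial coefficients:
`P(X ≥ k) = Σ_{j=k}^n C(n,j)·p0^j·(1−p0)^(n−j)`, with an exact-rational path
for `p0 = ½`. The two-sided convention is `2·min(upper, lower)` capped at 1,
chosen because it reproduces the published two-sided value for the
nine-of-ten panel (2·11/1024 = 0.02148); the same panel is reported
one-sided as 0.01 elsewhere in the same source — both conventions are
implemented and always labeled, with no attempt to reconcile them. The
Experimental Trend Analysis quantity is the plain arithmetic sum of
single-cell percent-change magnitudes, classified at θ.

## Multi-cell composition

The medium is a single well-mixed compartment with no transport delay
(transwell geometry is not spatially modeled; the emulated models are
compartmental). Secretion moves moles cell → medium scaled by the
cell:medium volume ratio ρ (default 1, since concentrations are in a.u.);
conservation holds as `[cell] + [medium]/ρ = const` when degradation is off.
Default uptake mode is `as_modifier` — the medium species becomes an
additional activator of the target's receptor-activation reaction — because
receptor signaling at cytokine concentrations is approximately non-depleting;
`as_transport` provides consumptive uptake where wanted. Feed-forward runs
stage the computation (sources to endpoint, medium concentrations clamped
into the target) and define the target's control by unperturbed sources;
both staged feed-forward and full bidirectional co-culture are first-class,
since either construction is defensible for the emulated three-cell model.

## Validation machinery

`validate_network` reports unreachable output markers (graph reachability
over the species–reaction bipartite graph, modifiers counted as gating
edges), orphan species, and missing kind-specific parameters; an empty
report guarantees ODE assembly cannot fail. Conserved-moiety candidates are
the exact-rational left null space (sympy) of the stoichiometric matrix
restricted to conversion reactions — all mass-transferring kinds except
synthesis/degradation/secretion, which create, destroy or export mass by
design. Restricting instead to mass-action columns alone would report
vectors that saturating conversions break; the chosen definition makes every
reported moiety exactly invariant whenever turnover reactions are disabled,
which is what the conservation tests assert (drift < 1e-6 relative over
64 h; observed ≈ 1e-15).

SBML Level 3 Version 2 interchange is a minimal hand-written subset
(stdlib `xml.etree`): species, compartments (`cell_<id>` / `medium`),
reactions with modifiers and a kinetic-law element. The authoritative
rate-law kind and parameter bundle travel in a namespaced annotation so that
re-import reconstructs a network whose simulation is identical; the MathML
payload is a flat product expression provided for external tools, not the
source of truth on re-import.

## Example models (fixtures)

The full-genome network library behind the emulated platform is proprietary
and publishes no kinetic parameters, so the bundled models carry invented,
curated, frozen parameters; the tested contracts are directional claims and
exact structural properties, never magnitudes. Consequently, passing tests
demonstrate that the machinery reproduces the *logic* of the approach —
kinetic forms, lesion semantics, coupling, statistics — not that it
reproduces any laboratory measurement.

- **gpcr_camp** (14 species): activation and inhibition arms converge on
  adenylyl cyclase; G-protein pools cycle through pure mass action so seven
  moieties (receptor pairs, Gα pools, Gβγ, cyclase, ATP+cAMP) are conserved.
  A basal cyclase activation keeps the control cAMP endpoint positive so
  percent change is well defined.
- **ifng_stat1** (25 species): receptor assembly by irreversible mass
  action, ligand-gated activation by SMM, a summed-SMM node with two
  activators (exact additivity is asserted), SMM-gated NF-κB translocation,
  and mass-action STAT1 dimerization. Parameters place the dimer endpoint in
  a dose-sensitive regime so dose–response monotonicity is informative.
- **inflammation_trio**: three receptor-complement-distinct cells (TLR4 +
  TLR2/1 on the epithelial- and dendritic-like cells; an IL-1 arm on the
  T-like cell fed by medium uptake) secreting ten markers. Secreted markers
  get first-order decay with an 8 h half-life (kd = ln2/8 h⁻¹) so endpoints
  are bounded — an assumption, since explicit degradation of every species
  is not documented for the emulated models. The synthetic "observed" table
  is a re-simulation with seeded log-uniform parameter jitter (×[1/1.5,
  1.5]) and multiplicative log-normal endpoint noise (σ = 0.2), mimicking
  inter-replicate immunoassay spread; at the default seed 17 it yields a
  frozen 9/10 trend-match regression.
- **mm_dc_pair**: a myeloma-like cell (constitutive RAS → STAT3 drive,
  seven output markers) with two genomic profiles — "weak" (RAS-activating
  mutation by predictor majority) and "strong" (additionally a
  library-called STAT3 activation acting directly on production) — feeding
  a dendritic-like cell whose five maturation markers are noncompetitively
  inhibited by sensed IL-10 and TGF-β1. The strong profile is marker-wise at
  least as immunosuppressive by construction; gene names are illustrative,
  not curated mutation lists of the real cell lines.

Lesion magnitudes (g = 2, l = 0, a = 2) are package defaults: the modeled
claims state directions (gain/loss, over-expression/deletion) but no
magnitudes, so the factors are exposed in `GenomicProfile` and every applied
lesion is itemized in the run report. The predictor-consensus rule (library
hit wins outright; strict majority of non-unknown calls; tie → unknown) is
likewise this package's rule, recorded per lesion, since no weighting of
conflicting predictors is documented.

## Determinism

All randomness flows through a single seed (fixture generation, jitter,
noise). Fixture output is byte-identical per (name, seed); simulations are
bit-identical per environment; every CLI run echoes its fully resolved
configuration, and re-running from that file reproduces outputs
bit-identically.

## Problem sizes

The bundled models span 1–64 state variables and up to ~150 reactions per
composed system; the full test suite and the acceptance script each run in well under
a minute on one CPU. These sizes were chosen so every property (conservation,
decoupling, monotonicity) can be checked against closed forms or exact
arithmetic rather than against other simulations.

## Known limitations

- No stochastic (SSA) simulation, spatial transport, or cell
  proliferation/death dynamics; the medium is a single well-mixed pool.
- Kinetic parameters are curated, not learned; no parameter estimation from
  data is provided.
- Mutation predictors are consumed as calls, never executed; variant calling
  and public mutation-database retrieval are out of scope.
- The SBML subset round-trips only documents this package wrote.
- Magnitude-level agreement with laboratory panels is out of reach by
  construction (no published parameters); only directional and statistical
  machinery is validated.
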