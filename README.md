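# mcsim — multi-cell signaling-network simulator

`mcsim` is a desk-scale simulator for the kind of mechanistic cell-signaling
models used to predict chemokine/cytokine biomarker profiles of inflamed or
cancerous multi-cellular tissues. It targets researchers who want to build
small curated pathway models (receptor → kinase cascade → transcription
factor → secreted marker), perturb them with agonists and genomic lesions,
couple several cell models through a shared medium, and score the predictions
against observed marker trends.

## The model

**Single cells.** A cell is a `PathwayNetwork`: typed species (the ODE state
variables, in declaration order) and reactions carrying one of a small set of
rate laws. Saturating ("simple Michaelis–Menten", SMM) steps with an inducer
*M*, substrate *S* and inhibitors *I<sub>j</sub>*:

    v = Vmax · [M]/(Ka + [M]) · [S]/(Km + [S]) · Π_j 1/(1 + [I_j]/Ki_j)

with a summed variant for nodes driven by several activators (the flux is the
sum of one saturating term per activator), and a kcat form `Vmax = kcat·[E]`
when an enzyme modifier is declared. Mass-action steps:

    v = kf · Π_r [r]^stoich   (minus  kr · Π_p [p]^stoich  if reversible)

plus constant synthesis, first-order degradation and secretion. Systems are
stiff and are integrated with the implicit Radau method (`scipy`), with
trajectories reported at 16/32/64 h and readouts taken at the 64 h culture
endpoint.

**Perturbations.** Agonists (LPS, Pam3CSK4, IFNG, PGE2, …) set their input
ligand's concentration. Genomic lesions map deterministically onto species
scales: deleterious oncogene mutations are gain of function at the *activity*
level (×g, default 2), deleterious tumor-suppressor mutations loss of
function at the activity level (×l, default 0), and copy-number amplification
/ deletion act at the *expression* level (×a, default 2 / ×0). A mutation's
effect call comes from a learnt effect library when present, otherwise from a
strict majority vote over predictor calls (FATHMM, SIFT, … consumed as
input), ties resolving to `unknown` (no action).

**Multi-cell models.** Cells are composed through a well-mixed medium:
secretion reactions export markers (volume-ratio corrected), and uptake makes
a medium species either an extra activator of a receptor-activation reaction
(ligand sensed, not consumed — the default) or a transported mass flux.
Staged feed-forward runs (e.g. myeloma → dendritic cell) simulate source
cells first and clamp their endpoint medium concentrations as constant inputs
of the target.

**Validation statistics.** Biomarker readouts are percent change versus the
control network, classified as ▲/▼/▬ with a ±5% dead band. Against an
observed panel, agreement is summarized as a match rate k/n and an exact
binomial p-value under a null match probability of 0.5:

    p_one = Σ_{j=k}^{n} C(n,j) · 0.5^n        p_two = min(1, 2·min(tails))

computed with exact integer coefficients (and exact rationals for p₀ = ½).

## Worked example

Score a ten-marker predicted-vs-observed trend panel (the LPS-stimulated
three-cell inflammation model, where CCL5 is the one discordant marker):

```
$ mcsim fixture inflammation_trio --seed 17 --out fx/
$ mcsim trendmatch --predicted pred.csv --observed obs.csv
9/10, 90%, p_one=0.01074, p_two=0.02148, (exact 11/1024), theta=5%
```

Nine of ten marker trends agree (90%); under a coin-flip null the one-sided
exact binomial probability of ≥9 matches is 11/1024 ≈ 0.0107 (two-sided
0.0215), so the agreement is unlikely to be chance.

Simulate the GPCR example (PGE2 activates adenylyl cyclase through
PTGER4/Gα<sub>s</sub> and inhibits it through GPR44/Gα<sub>i</sub>):

```
$ mcsim fixture gpcr_camp --out fxg/
$ mcsim simulate --network fxg/gpcr_cell.network.yaml --agonist PGE2 --dose 10.0 --out run1/
$ cat run1/responses.csv
cell_id,marker,control,perturbed,percent_change,trend,t_end_hours
gpcr_cell,cAMP,3.716902127,28.80950169,675.094439,up,64
```

At a 10 µg/ml dose the activation arm dominates: the cAMP endpoint rises from
3.72 to 28.81 a.u., a +675% change, classified ▲. Every run directory also
contains `run_config.yaml`, the fully resolved configuration; re-running with
`--config run1/run_config.yaml` reproduces the outputs bit-identically.

## Layout

- `src/mcsim/network_model.py` — species/reaction data model, YAML schema,
  validation, conserved-moiety detection, SBML Level 3 interchange subset
- `src/mcsim/ode_engine.py` — rate laws, stiff integration, percent-change readout
- `src/mcsim/perturbation.py` — agonist dosing, mutation/CNV semantics
- `src/mcsim/multicell.py` — medium coupling, co-culture composition, feed-forward
- `src/mcsim/trend_stats.py` — trend classification, match tables, exact binomial
- `src/mcsim/fixtures.py` — seeded example models (GPCR/cAMP, IFNG/STAT1,
  three-cell inflammation model, myeloma+DC pair)
- `src/mcsim/cli.py` — `mcsim` command (`simulate`, `compose`, `perturb`,
  `trendmatch`, `fixture`, `validate`)

See `docs/methods.md` for the modeling assumptions and numerical choices.
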