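# gxebreed

Stochastic simulation of two dairy-cattle breeding programs that may
cooperate across environments in the presence of genotype × environment
interaction (G×E).

## The problem

Two breeding programs improve the *same* breeding-goal trait, each in its own
production environment (E1, E2).  G×E makes the trait expressed in E1 and the
trait expressed in E2 genetically distinct: they are modeled as two traits
with additive genetic correlation `r_g < 1`.  Each program can either run
independently — within-environment genetic evaluation and within-environment
sire selection — or cooperate: a joint (bivariate) evaluation across both
environments and truncation selection of sires from the pooled candidates of
both populations.  Dams are always selected within environment, as in dairy
practice.  The question the simulator answers is how much cooperation buys in
genetic gain (ΔG) and rate of inbreeding (ΔF), under genomic (ssGBLUP) versus
pedigree-based (PBLUP) evaluation, and down to which `r_g` cooperation
survives in the long term (the *split-point* genetic correlation).

Scenarios (evaluation × sire-selection scope):

| code  | evaluation        | sire selection |
|-------|-------------------|----------------|
| AG-AS | across, ssGBLUP   | across         |
| WG-WS | within, ssGBLUP   | within         |
| AP-AS | across, PBLUP     | across         |
| WP-WS | within, PBLUP     | within         |
| AG-WS | across, ssGBLUP   | within         |

## The model

* **Genome** — 30 chromosome pairs of 1 Morgan; 40,000 SNPs, 2,000 biallelic
  QTL and 6,000 neutral IBD tracer loci (200 equidistant per chromosome).
  Recombination is Haldane (Poisson crossovers, no interference); there is no
  mutation after the founder phase.
* **Founders** — a neutral forward simulation of 300 males + 300 females
  (effective size 600) mating at random builds drift and map-proportional
  linkage disequilibrium; final-generation chromosomes form sex-specific
  pools from which a base population of 200 males and 4,000 females is
  sampled.
* **Traits** — QTL effects on (trait-in-E1, trait-in-E2) are bivariate normal
  with correlation `r_g`, rescaled so the realized base-population TBV
  covariance is exactly `[[1, r_g], [r_g, 1]]`.  Phenotypes (females only)
  are `p = a + e` with `e ~ N(0, 1/h² − 1)`.
* **Evaluation** — the bivariate animal model
  `y_i = X_i β_i + Z_i a_i + e_i`, `var([a_1; a_2]) = G_0 ⊗ H`, with
  generation-within-environment fixed effects, zero residual covariance, and
  `H` either the pedigree relationship matrix (Henderson/Meuwissen–Luo
  inverse) or the unified single-step matrix combining it with a VanRaden
  method-2 genomic matrix.  Within-environment evaluation sets the model
  `r_g` to 0, which decouples the system into two univariate analyses.
* **Selection** — generation 1: random 50% of the base within environment;
  generations 2–5: within-environment PBLUP truncation for both sexes;
  generations 6–20: the scenario policy.  Only selected sires are genotyped
  before generation 6; afterwards every candidate is genotyped.  Each dam
  produces 3 offspring by a single sire; dams are dealt evenly to sires.
* **Endpoints** — ΔG is the regression of mean newborn TBV on generation
  (t = 10…20) in base genetic SD; ΔF comes from `ln(1 − F_t)` regressed on t
  with `F_t` the realized tracer-locus inbreeding; external-sire proportions,
  split-point `r_g` (lowest `r_g` whose replicate-mean proportion stays ≥ 2%
  through the last generation), and long-term ancestor contributions `r_i`
  (with the diagnostic `ΔF ≈ ¼ Σ r_i²`) complete the report.

## Worked example

Run a small paired comparison at desk scale (structure-preserving, reduced
sizes; see `docs/methods.md`) from Python:

```python
from gxebreed import engine, experiment, metrics
from gxebreed.rng import replicate_seed

fs = experiment.build_founder("desk", master_seed=1, replicate=1)
seed = replicate_seed(1, 1)
ag = engine.run_scenario(engine.desk_config("AG-AS", h2=0.3, rg=0.9), fs, seed)
wg = engine.run_scenario(engine.desk_config("WG-WS", h2=0.3, rg=0.9), fs, seed)
w = (5, 10)
print("dG  AG-AS:", round(metrics.genetic_gain(ag.mean_tbv(1), w), 3),
      " WG-WS:", round(metrics.genetic_gain(wg.mean_tbv(1), w), 3))
print("dF  AG-AS:", round(metrics.rate_of_inbreeding(ag.f_trajectory(1), w), 4),
      " WG-WS:", round(metrics.rate_of_inbreeding(wg.f_trajectory(1), w), 4))
```

prints

```
dG  AG-AS: 0.738  WG-WS: 0.353
dF  AG-AS: 0.0375  WG-WS: 0.0561
```

— in this replicate the cooperative genomic program gains faster
(0.74 vs 0.35 genetic SD per generation) and inbreeds more slowly
(ΔF 0.038 vs 0.056) than the matched independent program, because external
sires enter the top ranks of the joint evaluation.  Single replicates are
noisy; orderings should always be judged over replicate sets.  Desk-scale ΔF values are
far larger than full-scale ones (5 sires per environment instead of 50).

The same comparison from the shell:

```bash
gxebreed run --scenario AG-AS --h2 0.3 --rg 0.9 --replicates 10 --out results/
gxebreed run --scenario WG-WS --h2 0.3 --rg 0.9 --replicates 10 --out results/
gxebreed report --out results/
```

`gxebreed grid --config grid.yaml` runs a factorial (scenario × h² × r_g)
design with resumable, hash-keyed cells; `gxebreed compare` adds
cooperation-benefit percentages and split-point tables.

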