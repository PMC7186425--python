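# Methods

This note documents the model, the numerical choices, and the places where
the design was genuinely open — in enough detail that a reader can judge
what the simulations do and do not show.

## Population model

The simulator advances discrete, non-overlapping generations.  Every
generation event comprises evaluation, truncation selection, even-random
mating and reproduction.  Two environments (E1, E2) each hold one
population; the breeding-goal trait expressed in E1 and in E2 is treated as
a pair of traits with additive genetic correlation `r_g` (G×E as a
two-trait problem).  Every animal carries true breeding values for *both*
traits, but expresses (and, if female, is phenotyped for) only the trait of
its own environment.  Offspring inherit the dam's environment; sires can
serve either environment through semen without relocation, so the same male
may be selected by both programs under across-environment selection.

### Founder phase

The founder population is a neutral forward simulation: 300 males and 300
females (effective size ≈ 600), random mating with replacement, constant
census, starting from independent loci at allele frequency 0.5.  It is run
for a configurable number of historic generations — default 400 at full
scale — to accumulate drift and linkage disequilibrium that decays with map
distance.  This is a generic neutral stand-in for a breed-history
simulation: it preserves the endpoints that matter downstream (Ne = 600,
segregating biallelic loci, LD proportional to map proximity) without
attempting to match any specific breed's LD profile.  No mutation occurs
after the founder phase.

The candidate genome carries ~1.3× the requested numbers of SNPs and QTL;
after the history, the final panels (40,000 SNPs, 2,000 QTL at full scale)
are drawn uniformly at random among candidates whose pooled minor-allele
frequency is ≥ 0.01 (0.05 at desk scale, where the pools hold only 400
copies and rarer alleles could reach the base population monomorphic).
This guarantees that every QTL can contribute variance.

Final-generation chromosomes are gathered by sex into 30 paternal and 30
maternal pools of 600 chromosome copies.  Each base animal draws, per
chromosome pair, two *distinct* copies from its sex's pool (copies are
returned before the next animal draws), so base animals cannot be
autozygous at sampling.

### Genome and recombination

30 chromosomes of 1 Morgan each (a typical cattle-scale map; both numbers
configurable).  SNP and QTL positions are uniform on the genetic map; the
6,000 IBD tracer loci sit at equidistant interior midpoints, 200 per
chromosome.  Crossovers follow the Haldane model: per meiosis and
chromosome a Poisson(length-in-Morgans) number of breakpoints at uniform
positions, no interference, starting strand fair.  All locus classes on a
chromosome share one crossover realization, so tracer alleles co-segregate
with their flanking markers.

### Traits, phenotypes

Raw QTL effects on the two traits are bivariate normal with unit variances
and correlation `r_g`.  The two effect columns are then jointly linearly
transformed so that the *realized* (ddof = 0) covariance matrix of base
TBVs equals `[[1, r_g], [r_g, 1]]` to machine precision — heritability and
`r_g` are exact at generation 0, which tightens every downstream test.  The
transform is `T = L⁻ᵀ Mᵀ` with `L` the Cholesky factor of the realized
covariance and `M` that of the target; at `|r_g| = 1` the degenerate target
is handled by scaling a single effect column.  Base TBV means are absorbed
into an offset so both traits start at 0.  Phenotypes are `p = a + e`,
females only, `e ~ N(0, 1/h² − 1)`, giving base phenotypic SD `1/h`.

### IBD tracer loci

At generation 0 every base animal receives two globally unique allele
labels at each of the 6,000 tracer loci (8,400 labels per locus at full
scale): base animals are non-inbred and mutually unrelated *by
construction*.  Tracer loci are never used in selection.  `F_t` is the
fraction of (animal, locus) pairs in the cohort born at `t` whose two
labels are copies of the same base allele — realized inbreeding relative to
the base, not a pedigree expectation.  Per-generation transmission strands
are recorded so that realized genomic contributions of any ancestor
generation can be traced to any later cohort.

## Genetic evaluation

The bivariate animal model is

    y_i = X_i β_i + Z_i a_i + e_i ,   i = 1, 2

with `β_i` one fixed generation mean per generation with records in
environment `i` (levels grow by one per generation), genetic covariance
`G₀ ⊗ H` with `G₀ = [[σ²a1, r_g σa1 σa2], [·, σ²a2]]`, and diagonal
residuals (an animal expresses only one trait, so the residual covariance
is structurally zero).  Variance components are fixed at the
simulation-true values; no REML step.  Within-environment evaluation sets
the model `r_g` to 0, decoupling the system into two univariate analyses.

Evaluations are cumulative: all phenotypes and pedigree from generation 0
to the candidate generation enter each evaluation, including the candidate
cohort's own female phenotypes (one generation unit contains phenotyping
before selection).

* **PBLUP** — `H⁻¹ = A⁻¹` assembled by Henderson's rules with
  Meuwissen–Luo inbreeding coefficients.
* **ssGBLUP** — `G` is VanRaden's second method (per-locus standardization
  `z_j z_jᵀ / (2 p_j q_j)`, averaged over loci); centering frequencies are
  computed from the earliest genotyped cohort of the run and then frozen,
  so relationships stay on a fixed scale across generations; loci outside
  `p ∈ [0.01, 0.99]` in that reference are excluded.  `G` is rescaled
  (`a·G + b`) so its mean diagonal and overall mean match `A₂₂`, then
  blended, `G_w = 0.95·G_adj + 0.05·A₂₂`, for invertibility and
  pedigree compatibility.  `H⁻¹ = A⁻¹ + [0 0; 0 G_w⁻¹ − A₂₂⁻¹]`.
  `A₂₂` is obtained by solving `A⁻¹ X = E` on the genotyped unit columns
  rather than forming dense `A`.

The mixed-model equations are assembled as one COO triplet set (the
genomic correction block is dense) and solved by sparse LU; the relative
residual of the normal equations is checked against 10⁻⁸ on every solve.
A direct factorization is used at every problem size the package targets —
the dense genotyped block dominates the factorization anyway, and a direct
solve makes the dense-oracle equivalence tests exact.  Generation-mean
fixed effects use plain dummy coding without an intercept; the fixed-effect
block is already full column rank, so no explicit constraint is needed and
EBV contrasts are unaffected.  The model `r_g` is clipped to
`±(1 − 10⁻⁸)` so `G₀` stays invertible in the degenerate `|r_g| = 1` case.

## Breeding policies

* **Event 1** — random selection of 50% of base males and females within
  environment (base animals are appointed to environments at random, in
  proportion to the dam numbers).
* **Events 2–5** — within-environment PBLUP truncation selection for both
  sexes; only the selected sires are genotyped.
* **Events 6–20** — scenario policy: evaluation mode (PBLUP / ssGBLUP) ×
  evaluation scope × sire-selection scope; all candidates are genotyped
  before selection; dams always within environment.  Unequal-size runs
  select 20/80 sires (E1/E2) in phase 1 and 50/50 in phase 2, matching the
  study design in which both environments select the same sire numbers
  during the scenario phase.

Selection is top-`n` on the target environment's trait EBV; ties break to
the smaller id for determinism.  Candidate pools smaller than the draw
raise a typed error rather than silently resampling.  Sex is pure
Bernoulli(1/2) per offspring (the literal reading of the reproduction
rule), so a sex can in principle run short in tiny test populations —
which also raises the typed error.

## Endpoints

* ΔG: OLS slope of mean newborn own-trait TBV on generation over the late
  window ([10, 20] at full scale; the second half of the run generally), in
  base genetic SD.
* ΔF: `1 − exp(b)` with `b` the OLS slope of `ln(1 − F_t)` on `t` over the
  same window, from the identity `F_t = 1 − (1 − ΔF)ᵗ`.
* External-sire proportion per selecting environment and generation;
  long-term cooperation at a grid `r_g` means the replicate-mean proportion
  stays ≥ 0.02 in every scenario-phase generation (the 2% baseline
  corresponds to at least one external sire among 50); the split-point is
  the lowest sustaining grid value, reported as an open interval when the
  indicator flips between adjacent grid points.  Both the threshold and the
  aggregation are configurable.
* Ancestor contributions are *realized* genomic contributions — the
  fraction of a late cohort's tracer alleles descending from each ancestor
  — rather than expected pedigree contributions; they sum to one per
  ancestor generation.  The diagnostic identity `ΔF ≈ ¼ (1 − α) Σ r_i²`
  is used with `α = 0` (Hardy–Weinberg).
* Cooperation benefit: `100 (coop − indep)/indep` per metric, computed
  from unrounded replicate means (ratio of means, not mean of ratios).

## Randomness and pairing

One master seed per replicate; every component (founder history, base
sampling, QTL effects, the breeding loop) draws from its own named
substream.  Within an experiment grid, replicate seeds and founder genomes
are shared across cells, so a cooperative scenario and its independent
baseline evolve identically through the pre-scenario phase and diverge
exactly when their policies first differ — a paired design that removes
founder noise from scenario contrasts.  Derived seeds stay below 2³¹.

## Desk scale

The desk preset preserves the structure of the full design — phase
schedule, 50% base selection, genotyping rule, 3 offspring per dam, even
mating — at reduced sizes chosen so that one replicate runs in seconds:

| quantity | full | desk |
|---|---|---|
| chromosomes | 30 | 5 |
| SNPs / QTL / tracers | 40,000 / 2,000 / 6,000 | 2,000 / 200 / 500 |
| base males / females | 200 / 4,000 | 20 / 200 |
| dams per environment | 1,000 (400:1,600) | 50 (20:80) |
| sires per environment | 50 (20/80 phase 1) | 5 (2/8 phase 1) |
| generations | 20 | 10 |
| founder history | 400 generations, 300+300 | 100 generations, 100+100 |

Desk runs demonstrate orderings and mechanisms (cooperative ≥ independent
gain at high `r_g`, larger candidate-EBV variance under single-step, zero
external sires under within-scope policies) but *not* full-scale
magnitudes: with 5 sires per environment, drift and inbreeding rates are an
order of magnitude larger than at full scale, and single replicates are
noisy enough that orderings must be judged over replicate sets.

## What the synthetic data does not emulate

The founder genome has no mutation–drift equilibrium allele-frequency
spectrum (all loci start at 0.5), no breed-specific LD structure, no
selection history, and uniform marker informativeness.  The breeding model
has no overlapping generations, progeny testing, reproductive technologies,
dominance/epistasis, or environmental trends beyond the generation mean.
Passing tests therefore establish internal correctness of the estimators
and machinery and the direction of the cooperation mechanisms, not
quantitative predictions for any real cattle population.

## Numerical details

* Meiosis, Meuwissen–Luo inbreeding: numba kernels; gamete strands are
  computed per chromosome by counting breakpoints below each locus.
* `G` is maintained incrementally (new standardized rows extend `W` and
  `W Wᵀ`), which keeps per-generation cost linear in the new cohort.
* Exact-scaling of QTL effects is idempotent to < 10⁻¹²; re-deriving the
  transform from scaled effects yields the identity.
* Degenerate inputs (empty genotyped set, single sire, monomorphic QTL,
  cyclic pedigrees, pools smaller than draws) raise typed errors or reduce
  to the pedigree-only path, as tested.
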