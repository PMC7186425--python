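"""Founder population, chromosome pools, base sampling and QTL effects.

The founder phase is a neutral forward-in-time simulation: a closed
population of constant size (default 300 males + 300 females, effective size
600) mates at random with replacement for a configurable number of historic
generations, starting from independent loci at allele frequency 0.5.  Drift
and Haldane recombination accumulate linkage disequilibrium proportional to
map distance.  The final generation's chromosomes are gathered by sex into
paternal and maternal pools (600 chromosome copies each at full scale), from
which base-population genotypes are sampled without replacement per animal.

The SNP and QTL panels are selected *after* the history, uniformly at random
among loci still segregating above a minor-allele-frequency floor, so every
QTL contributes variance in the base population.

QTL effects on the two environment-traits are drawn from a bivariate normal
with correlation ``rg`` and then linearly transformed so that the *realized*
base-population TBV covariance matrix equals ``[[1, rg], [rg, 1]]`` exactly;
heritability and the genetic correlation therefore hold exactly at
generation 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeMap, _build_map
from .inheritance import breed_batch, breeding_values

__all__ = [
    "ChromosomePools", "TraitArchitecture", "FounderSet",
    "build_founder_pools", "select_final_panels", "simulate_founders",
    "sample_base_population", "assign_ibd_tracer_alleles",
    "assign_qtl_effects", "founder_regime_f_trajectory",
    "MonomorphicLocusError",
]


class MonomorphicLocusError(ValueError):
    """A locus required to segregate is fixed."""


@dataclass
class ChromosomePools:
    """Phased chromosome copies of the final historic generation, by sex.

    ``paternal``/``maternal`` have shape ``(2 * n_parents, L)``; row
    ``2*i + c`` is copy ``c`` of parent ``i``.  Because base animals sample
    each chromosome pair independently, the per-chromosome pools are the
    column slices given by the map's chromosome offsets.
    """

    gmap: GenomeMap
    paternal: np.ndarray
    maternal: np.ndarray

    @property
    def n_copies(self) -> int:
        return self.paternal.shape[0]

    def pooled_frequencies(self) -> np.ndarray:
        """Allele-1 frequency per geno locus over both pools combined."""
        tot = self.paternal.sum(axis=0, dtype=np.int64) \
            + self.maternal.sum(axis=0, dtype=np.int64)
        return tot / (self.paternal.shape[0] + self.maternal.shape[0])


@dataclass
class TraitArchitecture:
    """Additive bivariate trait architecture over the QTL panel.

    ``effects[j]`` is the allele-substitution effect of QTL ``j`` on
    (Trait 1, Trait 2); ``offset`` is the base-population TBV mean that is
    subtracted so base means are zero.  ``sigma2_e = 1/h2 - 1`` puts the base
    phenotypic variance at ``1/h2`` for a genetic variance of 1.
    """

    effects: np.ndarray            # (n_qtl, 2)
    qtl_index: np.ndarray          # columns of the geno axis that are QTL
    rg: float
    h2: float
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    sigma2_a: float = 1.0

    @property
    def sigma2_e(self) -> float:
        return 1.0 / self.h2 - 1.0

    def tbv(self, geno: np.ndarray) -> np.ndarray:
        """True breeding values ``(n, 2)`` for a phased genotype cohort."""
        return breeding_values(geno, self.qtl_index, self.effects, self.offset)


@dataclass
class FounderSet:
    """Final genome map plus chromosome pools, ready for base sampling."""

    gmap: GenomeMap
    pools: ChromosomePools


def build_founder_pools(gmap: GenomeMap, n_hist_generations: int,
                        rng: np.random.Generator, *, n_males: int = 300,
                        n_females: int = 300) -> ChromosomePools:
    """Run the neutral founder history and gather final-generation pools.

    Every locus starts at frequency 0.5 with independent alleles; the
    population then drifts for ``n_hist_generations`` of random mating with
    replacement at constant census (sexes fixed at ``n_males``/``n_females``).
    """
    if n_hist_generations < 1:
        raise ValueError("need at least one historic generation")
    N = n_males + n_females
    geno = rng.integers(0, 2, size=(N, 2, gmap.n_geno_loci), dtype=np.int8)
    for _ in range(n_hist_generations):
        sires = rng.integers(0, n_males, size=N)
        dams = n_males + rng.integers(0, n_females, size=N)
        geno, _, _ = breed_batch(geno, None, sires, dams, gmap, rng)
    L = gmap.n_geno_loci
    return ChromosomePools(
        gmap=gmap,
        paternal=geno[:n_males].reshape(2 * n_males, L).copy(),
        maternal=geno[n_males:].reshape(2 * n_females, L).copy(),
    )


def select_final_panels(pools: ChromosomePools, n_snp: int, n_qtl: int,
                        rng: np.random.Generator, *, maf_min: float = 0.01,
                        ) -> FounderSet:
    """Pick the final SNP and QTL panels among segregating candidate loci.

    Candidates whose pooled minor-allele frequency falls below ``maf_min``
    are discarded; the requested panel sizes are then drawn uniformly at
    random from the survivors of each class.
    """
    gmap = pools.gmap
    p = pools.pooled_frequencies()
    eligible = (p >= maf_min) & (p <= 1.0 - maf_min)
    chosen = []
    for index, n_want, label in ((gmap.snp_index, n_snp, "SNP"),
                                 (gmap.qtl_index, n_qtl, "QTL")):
        ok = index[eligible[index]]
        if len(ok) < n_want:
            raise MonomorphicLocusError(
                f"only {len(ok)} segregating {label} candidates for "
                f"{n_want} requested; increase oversampling or shorten "
                "the history")
        chosen.append(rng.choice(ok, size=n_want, replace=False))
    keep = np.sort(np.concatenate(chosen))
    new_map = pools.gmap.subset_geno(keep)
    return FounderSet(
        gmap=new_map,
        pools=ChromosomePools(gmap=new_map, paternal=pools.paternal[:, keep],
                              maternal=pools.maternal[:, keep]),
    )


def simulate_founders(rng: np.random.Generator, *, n_chromosomes: int = 30,
                      chrom_length: float = 1.0, n_snp: int = 40_000,
                      n_qtl: int = 2_000, n_tracer_per_chrom: int = 200,
                      n_hist_generations: int = 400, n_males: int = 300,
                      n_females: int = 300, oversample: float = 1.3,
                      maf_min: float = 0.01) -> FounderSet:
    """Full founder pipeline: candidate map -> history -> panel selection."""
    cand = _build_map(n_chromosomes, chrom_length,
                      int(np.ceil(n_snp * oversample)),
                      int(np.ceil(n_qtl * oversample)),
                      n_tracer_per_chrom, rng)
    pools = build_founder_pools(cand, n_hist_generations, rng,
                                n_males=n_males, n_females=n_females)
    return select_final_panels(pools, n_snp, n_qtl, rng, maf_min=maf_min)


def sample_base_population(pools: ChromosomePools, n_males: int,
                           n_females: int, rng: np.random.Generator,
                           ) -> np.ndarray:
    """Sample base-animal genotypes from the sex-matched chromosome pools.

    For each animal and chromosome pair, two *distinct* pool copies are drawn
    (without replacement within the animal) and returned to the pool before
    the next animal, so pool cardinality is conserved and within-animal
    identity at sampling is impossible.  Returns phased genotypes
    ``(n_males + n_females, 2, L)`` with males first.
    """
    if n_males <= 0 or n_females <= 0:
        raise ValueError("need positive numbers of base males and females")
    gmap = pools.gmap
    out = np.empty((n_males + n_females, 2, gmap.n_geno_loci), dtype=np.int8)
    for pool, sl_animals in ((pools.paternal, slice(0, n_males)),
                             (pools.maternal, slice(n_males, None))):
        n_copies = pool.shape[0]
        if n_copies < 2:
            raise ValueError("pool must hold at least two chromosome copies")
        n = sl_animals.stop - sl_animals.start if sl_animals.stop else n_females
        for c in range(gmap.n_chromosomes):
            lo, hi = gmap.geno_offsets[c], gmap.geno_offsets[c + 1]
            first = rng.integers(0, n_copies, size=n)
            second = rng.integers(0, n_copies - 1, size=n)
            second += second >= first          # distinct from first
            out[sl_animals, 0, lo:hi] = pool[first, lo:hi]
            out[sl_animals, 1, lo:hi] = pool[second, lo:hi]
    return out


def assign_ibd_tracer_alleles(n_animals: int, n_tracer: int) -> np.ndarray:
    """Unique tracer allele labels for every base chromosome copy.

    Label ``2*i + c`` marks copy ``c`` of base animal ``i`` at every tracer
    locus, giving ``2 * n_animals`` distinct labels per locus; base animals
    are therefore non-inbred and mutually unrelated at the tracer loci by
    construction.
    """
    if 2 * n_animals > np.iinfo(np.int16).max:
        raise ValueError("too many base animals for int16 tracer labels")
    labels = (2 * np.arange(n_animals, dtype=np.int16)[:, None]
              + np.arange(2, dtype=np.int16)[None, :])
    return np.broadcast_to(labels[:, :, None],
                           (n_animals, 2, n_tracer)).copy()


def _target_cholesky(rg: float) -> np.ndarray:
    if not -1.0 <= rg <= 1.0:
        raise ValueError("rg must lie in [-1, 1]")
    return np.array([[1.0, 0.0], [rg, np.sqrt(max(0.0, 1.0 - rg * rg))]])


def assign_qtl_effects(gmap: GenomeMap, base_geno: np.ndarray, rg: float,
                       h2: float, rng: np.random.Generator,
                       ) -> TraitArchitecture:
    """Draw bivariate QTL effects and scale them to the exact base covariance.

    Raw effects come from N(0, [[1, rg], [rg, 1]]); the two effect columns
    are then jointly transformed so the realized (population, ddof=0) TBV
    covariance of the base animals equals [[1, rg], [rg, 1]] to machine
    precision, and the base TBV means are absorbed into ``offset``.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    q = gmap.n_qtl
    dosage = (base_geno[:, 0, gmap.qtl_index].astype(np.float64)
              + base_geno[:, 1, gmap.qtl_index])
    if np.any(dosage.min(axis=0) == dosage.max(axis=0)):
        raise MonomorphicLocusError("monomorphic QTL in base population "
                                    "cannot contribute genetic variance")
    target_l = _target_cholesky(rg)
    raw = rng.standard_normal((q, 2)) @ target_l.T
    if abs(rg) == 1.0:
        # degenerate target: trait 2 is (+/-) trait 1; scale one column
        e1 = raw[:, 0]
        e1 = e1 / np.sqrt(np.var(dosage @ e1))
        effects = np.column_stack([e1, rg * e1])
    else:
        tbv = dosage @ raw
        realized = np.cov(tbv, rowvar=False, ddof=0)
        chol = np.linalg.cholesky(realized)
        transform = np.linalg.solve(chol.T, target_l.T)
        effects = raw @ transform
    offset = (dosage @ effects).mean(axis=0)
    return TraitArchitecture(effects=effects, qtl_index=gmap.qtl_index,
                             rg=float(rg), h2=float(h2), offset=offset)


def founder_regime_f_trajectory(n_generations: int, rng: np.random.Generator,
                                *, n_males: int = 300, n_females: int = 300,
                                n_chromosomes: int = 30,
                                chrom_length: float = 1.0,
                                n_tracer_per_chrom: int = 200,
                                return_final_labels: bool = False):
    """Gene-drop the founder mating regime and record mean tracer inbreeding.

    Starts a population of unique-labelled, non-inbred animals and applies
    the founder regime (constant census, random mating with replacement) for
    ``n_generations``; returns ``F_t`` for ``t = 0 .. n_generations``.  The
    realized rate of inbreeding estimates the regime's effective population
    size via ``Ne = 1 / (2 * dF)``.
    """
    gmap = _build_map(n_chromosomes, chrom_length, 0, 0,
                      n_tracer_per_chrom, rng)
    N = n_males + n_females
    geno = np.zeros((N, 2, 0), dtype=np.int8)
    tracer = assign_ibd_tracer_alleles(N, gmap.n_tracer)
    f = np.empty(n_generations + 1)
    f[0] = 0.0
    for t in range(1, n_generations + 1):
        sires = rng.integers(0, n_males, size=N)
        dams = n_males + rng.integers(0, n_females, size=N)
        geno, tracer, _ = breed_batch(geno, tracer, sires, dams, gmap, rng)
        f[t] = np.mean(tracer[:, 0, :] == tracer[:, 1, :])
    if return_final_labels:
        return f, tracer
    return f
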