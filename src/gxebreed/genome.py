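"""Genome layout: marker, QTL and IBD-tracer loci on a genetic map.

The simulated genome is a set of autosome pairs carrying three disjoint
classes of biallelic loci positioned on a genetic (Morgan) map:

* **SNP markers** — the observable loci used to build genomic relationship
  matrices; never causal.
* **QTL** — the causal loci whose additive effects define the true breeding
  values of the two environment-traits.
* **IBD tracer loci** — neutral loci that are equidistant within each
  chromosome and carry globally unique founder alleles, used only to measure
  realized identity-by-descent inbreeding and genomic contributions.

Positions are expressed in Morgans from the start of each chromosome, and the
map is what the recombination model consumes: crossovers occur as a Poisson
process along each chromosome (no interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeMap", "default_map", "desk_map"]


@dataclass(frozen=True)
class GenomeMap:
    """Immutable layout of SNP, QTL and IBD-tracer loci on a genetic map.

    Genotype-bearing loci (SNP + QTL) are stored on a single concatenated
    axis in (chromosome, position) order; ``snp_index`` / ``qtl_index``
    address the two classes on that axis.  Tracer loci live on their own
    axis because they carry integer allele labels rather than 0/1 alleles.
    """

    chrom_lengths: np.ndarray          # (C,) genetic length in Morgans
    geno_pos: np.ndarray               # (L,) positions of SNP+QTL loci
    geno_chrom: np.ndarray             # (L,) chromosome of each geno locus
    snp_index: np.ndarray              # indices into geno axis that are SNPs
    qtl_index: np.ndarray              # indices into geno axis that are QTL
    tracer_pos: np.ndarray             # (T,) positions of IBD tracer loci
    tracer_chrom: np.ndarray           # (T,) chromosome of each tracer locus
    geno_offsets: np.ndarray = field(init=False)    # (C+1,) chrom slices
    tracer_offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "geno_offsets",
                           _chrom_offsets(self.geno_chrom, self.n_chromosomes))
        object.__setattr__(self, "tracer_offsets",
                           _chrom_offsets(self.tracer_chrom, self.n_chromosomes))
        self.validate()

    # -- basic properties ---------------------------------------------------
    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths)

    @property
    def n_geno_loci(self) -> int:
        return len(self.geno_pos)

    @property
    def n_snp(self) -> int:
        return len(self.snp_index)

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_index)

    @property
    def n_tracer(self) -> int:
        return len(self.tracer_pos)

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        C = self.n_chromosomes
        if C < 1:
            raise ValueError("need at least one chromosome")
        if np.any(self.chrom_lengths <= 0):
            raise ValueError("chromosome lengths must be positive")
        for chrom, pos, offs in (
            (self.geno_chrom, self.geno_pos, self.geno_offsets),
            (self.tracer_chrom, self.tracer_pos, self.tracer_offsets),
        ):
            if np.any(np.diff(chrom) < 0):
                raise ValueError("loci must be sorted by chromosome")
            for c in range(C):
                p = pos[offs[c]:offs[c + 1]]
                if p.size and (np.any(np.diff(p) <= 0)
                               or p[0] < 0 or p[-1] > self.chrom_lengths[c]):
                    raise ValueError(
                        f"positions on chromosome {c} must be strictly "
                        "increasing within [0, chrom_length]")
        both = np.concatenate([self.snp_index, self.qtl_index])
        if len(np.unique(both)) != self.n_geno_loci:
            raise ValueError("snp_index and qtl_index must partition the "
                             "geno axis")
        # SNP/QTL/tracer positions must be disjoint per chromosome
        for c in range(C):
            g = self.geno_pos[self.geno_offsets[c]:self.geno_offsets[c + 1]]
            t = self.tracer_pos[self.tracer_offsets[c]:self.tracer_offsets[c + 1]]
            if np.intersect1d(g, t).size:
                raise ValueError("SNP/QTL and tracer positions overlap")

    def subset_geno(self, keep: np.ndarray) -> "GenomeMap":
        """Return a map restricted to the geno loci ``keep`` (sorted indices).

        Used to select the final SNP and QTL panels out of an oversampled
        candidate set after the founder history.  Tracer loci are unchanged.
        """
        keep = np.asarray(keep)
        lookup = -np.ones(self.n_geno_loci, dtype=np.int64)
        lookup[keep] = np.arange(len(keep))
        new_snp = lookup[self.snp_index]
        new_qtl = lookup[self.qtl_index]
        return GenomeMap(
            chrom_lengths=self.chrom_lengths,
            geno_pos=self.geno_pos[keep],
            geno_chrom=self.geno_chrom[keep],
            snp_index=np.sort(new_snp[new_snp >= 0]),
            qtl_index=np.sort(new_qtl[new_qtl >= 0]),
            tracer_pos=self.tracer_pos,
            tracer_chrom=self.tracer_chrom,
        )


def _chrom_offsets(chrom: np.ndarray, n_chrom: int) -> np.ndarray:
    return np.searchsorted(chrom, np.arange(n_chrom + 1))


def _spread_counts(total: int, n_bins: int) -> np.ndarray:
    """Split ``total`` loci over ``n_bins`` chromosomes as evenly as possible."""
    base = total // n_bins
    counts = np.full(n_bins, base, dtype=np.int64)
    counts[: total - base * n_bins] += 1
    return counts


def _build_map(n_chromosomes: int, chrom_length: float, n_snp: int,
               n_qtl: int, n_tracer_per_chrom: int, rng: np.random.Generator,
               ) -> GenomeMap:
    lengths = np.full(n_chromosomes, float(chrom_length))
    snp_counts = _spread_counts(n_snp, n_chromosomes)
    qtl_counts = _spread_counts(n_qtl, n_chromosomes)
    geno_pos, geno_chrom, kinds = [], [], []
    tracer_pos, tracer_chrom = [], []
    for c in range(n_chromosomes):
        L = lengths[c]
        # tracers at equidistant interior midpoints: spacing L/n, offset L/2n
        t = (np.arange(n_tracer_per_chrom) + 0.5) * L / n_tracer_per_chrom
        n_g = snp_counts[c] + qtl_counts[c]
        while True:
            g = np.sort(rng.uniform(0.0, L, size=n_g))
            # resample on (vanishingly unlikely) ties or collisions
            if (np.all(np.diff(g) > 0)
                    and not np.intersect1d(g, t).size):
                break
        kind = np.zeros(n_g, dtype=np.int8)          # 0 = SNP, 1 = QTL
        kind[rng.choice(n_g, size=qtl_counts[c], replace=False)] = 1
        geno_pos.append(g)
        geno_chrom.append(np.full(n_g, c, dtype=np.int32))
        kinds.append(kind)
        tracer_pos.append(t)
        tracer_chrom.append(np.full(n_tracer_per_chrom, c, dtype=np.int32))
    kind_all = np.concatenate(kinds)
    return GenomeMap(
        chrom_lengths=lengths,
        geno_pos=np.concatenate(geno_pos),
        geno_chrom=np.concatenate(geno_chrom),
        snp_index=np.flatnonzero(kind_all == 0),
        qtl_index=np.flatnonzero(kind_all == 1),
        tracer_pos=np.concatenate(tracer_pos),
        tracer_chrom=np.concatenate(tracer_chrom),
    )


def default_map(rng: np.random.Generator, *, n_chromosomes: int = 30,
                chrom_length: float = 1.0, n_snp: int = 40_000,
                n_qtl: int = 2_000, n_tracer_per_chrom: int = 200,
                ) -> GenomeMap:
    """Full-scale cattle-like genome: 30 x 1 Morgan chromosomes, 40k SNPs,
    2k QTL, 200 tracer loci per chromosome (6,000 total)."""
    return _build_map(n_chromosomes, chrom_length, n_snp, n_qtl,
                      n_tracer_per_chrom, rng)


def desk_map(rng: np.random.Generator, *, n_chromosomes: int = 5,
             chrom_length: float = 1.0, n_snp: int = 2_000, n_qtl: int = 200,
             n_tracer_per_chrom: int = 100) -> GenomeMap:
    """Scaled-down genome for fast desk-scale experiments and tests."""
    return _build_map(n_chromosomes, chrom_length, n_snp, n_qtl,
                      n_tracer_per_chrom, rng)
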