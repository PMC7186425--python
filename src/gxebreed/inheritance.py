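"""Meiosis, reproduction, true breeding values and phenotypes.

Recombination follows the Haldane model: per chromosome the crossover count
is Poisson with mean equal to the genetic length in Morgans, breakpoints are
uniform and there is no interference.  The starting parental strand is chosen
with probability 1/2 per chromosome.  SNP, QTL and tracer loci on the same
chromosome are co-transmitted through the *same* crossover realization, so
tracer alleles travel with their flanking markers.

Genomes are phased: a cohort of ``n`` animals carries

* ``geno``   — ``(n, 2, L)`` int8 array of 0/1 alleles at SNP+QTL loci;
* ``tracer`` — ``(n, 2, T)`` int16 array of founder-allele labels at the
  IBD tracer loci.

True breeding values are purely additive: the dosage at the QTL columns times
the allele-substitution effect matrix, minus the base-population mean.
"""

from __future__ import annotations

import numba as nb
import numpy as np

from .genome import GenomeMap

__all__ = [
    "meiosis_batch", "make_gamete", "breed_batch", "breeding_values",
    "sample_phenotypes", "SexError",
]


class SexError(ValueError):
    """Raised when an operation receives an animal of the wrong sex."""


@nb.njit(cache=True)
def _strand_kernel(pos, chrom_offsets, counts, breaks_flat, break_start,
                   start_strand, out):  # pragma: no cover - compiled
    n_gam, C = counts.shape
    for g in range(n_gam):
        for c in range(C):
            b0 = break_start[g, c]
            b = np.sort(breaks_flat[b0:b0 + counts[g, c]])
            s = start_strand[g, c]
            bi = 0
            for l in range(chrom_offsets[c], chrom_offsets[c + 1]):
                x = pos[l]
                while bi < b.size and b[bi] < x:
                    s = 1 - s
                    bi += 1
                out[g, l] = s


@nb.njit(cache=True)
def _gather_kernel(haps, parent_idx, strands, out):  # pragma: no cover
    n, L = strands.shape
    for g in range(n):
        p = parent_idx[g]
        for l in range(L):
            out[g, l] = haps[p, strands[g, l], l]


def _draw_crossovers(n: int, gmap: GenomeMap, rng: np.random.Generator):
    C = gmap.n_chromosomes
    counts = rng.poisson(gmap.chrom_lengths, size=(n, C)).astype(np.int64)
    flat_counts = counts.ravel()
    lens = np.broadcast_to(gmap.chrom_lengths, (n, C)).ravel()
    breaks_flat = rng.random(int(flat_counts.sum())) * np.repeat(lens, flat_counts)
    offs = np.concatenate(([0], np.cumsum(flat_counts)[:-1]))
    break_start = offs.reshape(n, C)
    start_strand = rng.integers(0, 2, size=(n, C)).astype(np.uint8)
    return counts, breaks_flat, break_start, start_strand


def meiosis_batch(geno_haps: np.ndarray, tracer_haps: np.ndarray | None,
                  parent_idx: np.ndarray, gmap: GenomeMap,
                  rng: np.random.Generator):
    """Produce one gamete per entry of ``parent_idx``.

    Returns ``(geno_gametes, tracer_gametes, tracer_strands)``; the tracer
    outputs are ``None`` when ``tracer_haps`` is ``None``.  ``tracer_strands``
    records, per gamete and tracer locus, which parental strand (0/1) was
    transmitted — the raw material for realized-contribution tracing.
    """
    parent_idx = np.ascontiguousarray(parent_idx, dtype=np.int64)
    n = len(parent_idx)
    counts, breaks_flat, break_start, start_strand = _draw_crossovers(n, gmap, rng)

    g_str = np.empty((n, gmap.n_geno_loci), dtype=np.uint8)
    _strand_kernel(gmap.geno_pos, gmap.geno_offsets, counts, breaks_flat,
                   break_start, start_strand, g_str)
    geno_gam = np.empty((n, gmap.n_geno_loci), dtype=geno_haps.dtype)
    _gather_kernel(geno_haps, parent_idx, g_str, geno_gam)

    tracer_gam = tracer_str = None
    if tracer_haps is not None:
        tracer_str = np.empty((n, gmap.n_tracer), dtype=np.uint8)
        _strand_kernel(gmap.tracer_pos, gmap.tracer_offsets, counts,
                       breaks_flat, break_start, start_strand, tracer_str)
        tracer_gam = np.empty((n, gmap.n_tracer), dtype=tracer_haps.dtype)
        _gather_kernel(tracer_haps, parent_idx, tracer_str, tracer_gam)
    return geno_gam, tracer_gam, tracer_str


def make_gamete(geno_haps: np.ndarray, tracer_haps: np.ndarray | None,
                gmap: GenomeMap, rng: np.random.Generator):
    """Single-parent convenience wrapper around :func:`meiosis_batch`.

    ``geno_haps`` is the ``(2, L)`` phased genotype of one parent.
    """
    g, t, s = meiosis_batch(geno_haps[None], None if tracer_haps is None
                            else tracer_haps[None], np.zeros(1, np.int64),
                            gmap, rng)
    return g[0], (None if t is None else t[0]), (None if s is None else s[0])


def breed_batch(parent_geno: np.ndarray, parent_tracer: np.ndarray | None,
                sire_idx: np.ndarray, dam_idx: np.ndarray, gmap: GenomeMap,
                rng: np.random.Generator):
    """Union of one sire gamete (copy 0) and one dam gamete (copy 1) per
    offspring.  Returns ``(geno, tracer, tracer_strands)`` with leading
    shape ``(n_offspring, 2, ...)``."""
    gs, ts, ss = meiosis_batch(parent_geno, parent_tracer, sire_idx, gmap, rng)
    gd, td, sd = meiosis_batch(parent_geno, parent_tracer, dam_idx, gmap, rng)
    geno = np.stack([gs, gd], axis=1)
    tracer = None if ts is None else np.stack([ts, td], axis=1)
    strands = None if ss is None else np.stack([ss, sd], axis=1)
    return geno, tracer, strands


def breeding_values(geno: np.ndarray, qtl_index: np.ndarray,
                    effects: np.ndarray, offset: np.ndarray | float = 0.0,
                    ) -> np.ndarray:
    """True breeding values: QTL dosage times effect matrix, minus the base
    mean so that the base population is centred at zero."""
    dosage = geno[:, 0, qtl_index].astype(np.float64) + geno[:, 1, qtl_index]
    return dosage @ effects - offset


def sample_phenotypes(own_tbv: np.ndarray, sigma2_e: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Phenotype = own-environment TBV + N(0, sigma2_e) residual.

    With base genetic variance 1 and sigma2_e = 1/h^2 - 1 the base phenotypic
    standard deviation is 1/h.
    """
    if sigma2_e < 0:
        raise ValueError("residual variance must be non-negative")
    return own_tbv + rng.normal(0.0, np.sqrt(sigma2_e), size=len(own_tbv))
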