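"""Pedigree (A), genomic (G) and single-step (H) relationship structures.

* ``A`` is Wright's numerator relationship matrix; its sparse inverse is
  assembled directly from Henderson's rules with inbreeding coefficients
  computed by the Meuwissen-Luo algorithm.
* ``G`` follows VanRaden's second method: each frequency-centred marker
  column is standardized by its own expected variance ``2 p q`` before
  averaging, so every usable locus contributes equally.
* ``H^-1`` is the standard single-step form: the pedigree inverse plus a
  correction ``Gw^-1 - A22^-1`` on the genotyped block, where ``Gw`` blends
  the (rescaled) genomic matrix with the pedigree relationships among
  genotyped animals to guarantee invertibility and compatibility.

Pedigrees are encoded positionally: animals are ``0..n-1`` with parents
preceding offspring and ``-1`` for unknown parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba as nb
import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "PedigreeError", "RelationshipStructure", "pedigree_inbreeding",
    "pedigree_a_inverse", "a22_matrix", "genomic_g", "h_inverse",
]


class PedigreeError(ValueError):
    """Invalid pedigree: a parent does not precede its offspring."""


@dataclass
class RelationshipStructure:
    """Relationship inverses ready for the mixed-model equations."""

    n_animals: int
    a_inverse: sp.csr_matrix
    inbreeding: np.ndarray
    h_inverse: sp.csr_matrix          # equals a_inverse when nobody genotyped
    genotyped_index: np.ndarray
    g_matrix: np.ndarray | None = None


@nb.njit(cache=True)
def _ml_inbreeding(sire, dam):  # pragma: no cover - compiled
    n = sire.size
    F = np.zeros(n)
    D = np.empty(n)
    L = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        Fs = F[s] if s >= 0 else -1.0
        Fd = F[d] if d >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (Fs + Fd)
        if s < 0 or d < 0:
            continue
        # accumulate A_ii = sum_j r_j^2 D_j over ancestors j of i
        aii = 0.0
        L[i] = 1.0
        for j in range(i, -1, -1):
            r = L[j]
            if r == 0.0:
                continue
            sj, dj = sire[j], dam[j]
            if sj >= 0:
                L[sj] += 0.5 * r
            if dj >= 0:
                L[dj] += 0.5 * r
            aii += r * r * D[j]
            L[j] = 0.0
        F[i] = aii - 1.0
        D[i] = 0.5 - 0.25 * (Fs + Fd)
    return F, D


def _check_pedigree(sire: np.ndarray, dam: np.ndarray) -> None:
    n = sire.size
    for par in (sire, dam):
        bad = (par >= np.arange(n)) & (par >= 0)
        if np.any(bad) or np.any(par < -1) or np.any(par >= n):
            raise PedigreeError("parents must precede offspring and be "
                                "valid ids (-1 for unknown)")


def pedigree_inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficient per animal (Meuwissen-Luo)."""
    sire = np.ascontiguousarray(sire, dtype=np.int64)
    dam = np.ascontiguousarray(dam, dtype=np.int64)
    _check_pedigree(sire, dam)
    return _ml_inbreeding(sire, dam)[0]


def pedigree_a_inverse(sire: np.ndarray, dam: np.ndarray):
    """Sparse ``A^-1`` with inbreeding, plus the inbreeding coefficients.

    Henderson's rules: each animal contributes ``alpha = 1/D_i`` (the inverse
    Mendelian-sampling variance, inbreeding-adjusted) to the (animal, sire,
    dam) block.
    """
    sire = np.ascontiguousarray(sire, dtype=np.int64)
    dam = np.ascontiguousarray(dam, dtype=np.int64)
    _check_pedigree(sire, dam)
    F, D = _ml_inbreeding(sire, dam)
    n = sire.size
    alpha = 1.0 / D
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    idx = np.arange(n)
    add(idx, idx, alpha)
    for par in (sire, dam):
        known = par >= 0
        add(idx[known], par[known], -0.5 * alpha[known])
        add(par[known], idx[known], -0.5 * alpha[known])
        add(par[known], par[known], 0.25 * alpha[known])
    both = (sire >= 0) & (dam >= 0)
    add(sire[both], dam[both], 0.25 * alpha[both])
    add(dam[both], sire[both], 0.25 * alpha[both])
    a_inv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsr()
    return a_inv, F


def a22_matrix(a_inverse: sp.spmatrix, genotyped_index: np.ndarray,
               ) -> np.ndarray:
    """Dense pedigree relationships among the genotyped subset.

    Obtained by solving ``A^-1 X = E`` for the genotyped unit columns, which
    avoids ever forming the full dense ``A``.
    """
    genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
    n = a_inverse.shape[0]
    lu = splu(a_inverse.tocsc())
    rhs = np.zeros((n, len(genotyped_index)))
    rhs[genotyped_index, np.arange(len(genotyped_index))] = 1.0
    cols = lu.solve(rhs)
    a22 = cols[genotyped_index]
    return 0.5 * (a22 + a22.T)        # symmetrize away solver noise


def genomic_g(dosage: np.ndarray, freqs: np.ndarray, *,
              maf_bounds: tuple[float, float] = (0.01, 0.99)) -> np.ndarray:
    """VanRaden method-2 genomic relationship matrix.

    ``G = (1/m) * sum_j z_j z_j' / (2 p_j (1 - p_j))`` over the usable loci,
    with ``z_j`` the ``freqs``-centred dosage column.  Loci whose reference
    frequency falls outside ``maf_bounds`` are excluded.
    """
    dosage = np.asarray(dosage, dtype=np.float64)
    freqs = np.asarray(freqs, dtype=np.float64)
    use = (freqs >= maf_bounds[0]) & (freqs <= maf_bounds[1])
    m = int(use.sum())
    if m == 0:
        raise ValueError("no usable loci after frequency filtering")
    p = freqs[use]
    w = (dosage[:, use] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p) * m)
    return w @ w.T


def h_inverse(a_inverse: sp.spmatrix, g: np.ndarray,
              genotyped_index: np.ndarray, *, omega: float = 0.95,
              rescale: bool = True, a22: np.ndarray | None = None,
              ) -> sp.csr_matrix:
    """Single-step ``H^-1 = A^-1 + [0, 0; 0, Gw^-1 - A22^-1]``.

    ``Gw = omega * G_adj + (1 - omega) * A22`` where ``G_adj`` (when
    ``rescale``) is ``a*G + b`` with ``a, b`` chosen so that the mean
    diagonal and overall mean of ``G_adj`` match those of ``A22``.
    """
    genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
    if len(genotyped_index) == 0:
        return a_inverse.tocsr().copy()
    if g.shape != (len(genotyped_index),) * 2:
        raise ValueError("G must be square over the genotyped subset")
    if a22 is None:
        a22 = a22_matrix(a_inverse, genotyped_index)
    g_adj = np.asarray(g, dtype=np.float64)
    if rescale:
        denom = np.mean(np.diag(g_adj)) - np.mean(g_adj)
        if abs(denom) < 1e-12:
            raise ValueError("degenerate G: cannot rescale to A22")
        a = (np.mean(np.diag(a22)) - np.mean(a22)) / denom
        b = np.mean(a22) - a * np.mean(g_adj)
        g_adj = a * g_adj + b
    gw = omega * g_adj + (1.0 - omega) * a22
    correction = np.linalg.inv(gw) - np.linalg.inv(a22)
    corr = sp.coo_matrix(
        (correction.ravel(),
         (np.repeat(genotyped_index, len(genotyped_index)),
          np.tile(genotyped_index, len(genotyped_index)))),
        shape=a_inverse.shape)
    return (a_inverse + corr).tocsr()


def build_relationships(sire: np.ndarray, dam: np.ndarray,
                        genotyped_index: np.ndarray | None = None,
                        dosage: np.ndarray | None = None,
                        freqs: np.ndarray | None = None, *,
                        single_step: bool = False, omega: float = 0.95,
                        ) -> RelationshipStructure:
    """Convenience assembly of everything the evaluation needs."""
    a_inv, F = pedigree_a_inverse(sire, dam)
    if not single_step or genotyped_index is None or len(genotyped_index) == 0:
        return RelationshipStructure(
            n_animals=len(sire), a_inverse=a_inv, inbreeding=F,
            h_inverse=a_inv,
            genotyped_index=np.zeros(0, dtype=np.int64))
    g = genomic_g(dosage, freqs)
    h_inv = h_inverse(a_inv, g, genotyped_index, omega=omega)
    return RelationshipStructure(
        n_animals=len(sire), a_inverse=a_inv, inbreeding=F, h_inverse=h_inv,
        genotyped_index=np.asarray(genotyped_index, dtype=np.int64),
        g_matrix=g)
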