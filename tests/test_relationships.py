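"""Pedigree/genomic/single-step relationship structures vs dense oracles."""

import numpy as np
import pytest

from gxebreed.relationships import (PedigreeError, a22_matrix, genomic_g,
                                    h_inverse, pedigree_a_inverse,
                                    pedigree_inbreeding)


def dense_a(sire, dam):
    """Independent tabular-recursion oracle for the numerator matrix A."""
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def random_pedigree(rng, n_founders=10, n_per_gen=15, n_gens=4):
    sire = [-1] * n_founders
    dam = [-1] * n_founders
    prev = list(range(n_founders))
    for _ in range(n_gens):
        cur = []
        for _ in range(n_per_gen):
            s, d = rng.choice(prev, 2, replace=False)
            cur.append(len(sire))
            sire.append(int(s))
            dam.append(int(d))
        prev = cur
    return np.array(sire), np.array(dam)


class TestPedigree:
    def test_trio_base_case(self):
        sire = np.array([-1, -1, 0])
        dam = np.array([-1, -1, 1])
        A = dense_a(sire, dam)
        assert A[2, 0] == 0.5 and A[2, 2] == 1.0
        a_inv, F = pedigree_a_inverse(sire, dam)
        assert np.allclose(a_inv.toarray(), np.linalg.inv(A), atol=1e-10)
        assert np.allclose(F, 0.0)

    def test_fullsib_mating_inbreeding(self):
        # parents -> two full sibs -> their offspring has F = 0.25
        sire = np.array([-1, -1, 0, 0, 2])
        dam = np.array([-1, -1, 1, 1, 3])
        F = pedigree_inbreeding(sire, dam)
        assert F[4] == pytest.approx(0.25)
        A = dense_a(sire, dam)
        assert A[4, 4] == pytest.approx(1.25)

    def test_sparse_inverse_matches_dense_oracle(self, rng):
        sire, dam = random_pedigree(rng)
        A = dense_a(sire, dam)
        a_inv, F = pedigree_a_inverse(sire, dam)
        assert np.max(np.abs(a_inv.toarray() - np.linalg.inv(A))) < 1e-8
        assert np.allclose(F, np.diag(A) - 1, atol=1e-10)

    def test_cycle_rejected(self):
        with pytest.raises(PedigreeError):
            pedigree_a_inverse(np.array([1]), np.array([-1]))

    def test_a22_matches_dense_submatrix(self, rng):
        sire, dam = random_pedigree(rng)
        A = dense_a(sire, dam)
        a_inv, _ = pedigree_a_inverse(sire, dam)
        idx = rng.choice(len(sire), 12, replace=False)
        idx.sort()
        assert np.allclose(a22_matrix(a_inv, idx), A[np.ix_(idx, idx)],
                           atol=1e-8)


class TestGenomicG:
    def test_hand_computed_single_locus(self):
        g = genomic_g(np.array([[0.0], [2.0]]), np.array([0.5]))
        assert np.allclose(g, [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicate_animal_gives_identical_rows(self, rng):
        dos = rng.integers(0, 3, (5, 60)).astype(float)
        dos[4] = dos[0]
        g = genomic_g(dos, dos.mean(axis=0) / 2)
        assert np.allclose(g[0], g[4])
        assert abs(np.linalg.det(g)) < 1e-8

    def test_frequency_filter(self, rng):
        dos = rng.integers(0, 3, (10, 50)).astype(float)
        freqs = np.full(50, 0.5)
        freqs[:25] = 0.0                       # excluded
        g_half = genomic_g(dos, freqs)
        g_manual = genomic_g(dos[:, 25:], np.full(25, 0.5))
        assert np.allclose(g_half, g_manual)
        with pytest.raises(ValueError):
            genomic_g(dos, np.zeros(50))

    def test_mean_diagonal_near_one_on_base_animals(self, desk_founders,
                                                    rng):
        from gxebreed import founders
        geno = founders.sample_base_population(desk_founders.pools, 50, 50,
                                               rng)
        snp = desk_founders.gmap.snp_index
        dos = (geno[:, 0, snp] + geno[:, 1, snp]).astype(float)
        g = genomic_g(dos, dos.mean(axis=0) / 2)
        # base animals are non-inbred and unrelated: mean diagonal ~ 1
        assert abs(np.mean(np.diag(g)) - 1.0) < 0.05


class TestSingleStep:
    def _setup(self, rng, n_geno=15):
        sire, dam = random_pedigree(rng)
        n = len(sire)
        a_inv, _ = pedigree_a_inverse(sire, dam)
        idx = np.sort(rng.choice(np.arange(n // 2, n), n_geno,
                                 replace=False))
        dos = rng.integers(0, 3, (n_geno, 120)).astype(float)
        freqs = np.clip(dos.mean(axis=0) / 2, 0.05, 0.95)
        g = genomic_g(dos, freqs)
        return sire, dam, a_inv, idx, g

    def test_empty_genotyped_set_returns_a_inverse(self, rng):
        sire, dam = random_pedigree(rng)
        a_inv, _ = pedigree_a_inverse(sire, dam)
        h_inv = h_inverse(a_inv, np.zeros((0, 0)), np.array([], dtype=int))
        assert np.allclose(h_inv.toarray(), a_inv.toarray())

    def test_g_equal_a22_gives_identity_correction(self, rng):
        sire, dam, a_inv, idx, _ = self._setup(rng)
        a22 = a22_matrix(a_inv, idx)
        h_inv = h_inverse(a_inv, a22.copy(), idx, omega=0.95, rescale=False)
        assert np.max(np.abs((h_inv - a_inv).toarray())) < 1e-8

    def test_h_inverse_matches_dense_h_oracle(self, rng):
        # build dense H explicitly from its textbook block form, invert it,
        # and compare against the sparse-plus-dense assembly
        sire, dam, a_inv, idx, g = self._setup(rng)
        n = len(sire)
        omega = 0.95
        A = dense_a(sire, dam)
        a22 = A[np.ix_(idx, idx)]
        denom = np.mean(np.diag(g)) - np.mean(g)
        a = (np.mean(np.diag(a22)) - np.mean(a22)) / denom
        b = np.mean(a22) - a * np.mean(g)
        gw = omega * (a * g + b) + (1 - omega) * a22
        rest = np.setdiff1d(np.arange(n), idx)
        a22i = np.linalg.inv(a22)
        A12 = A[np.ix_(rest, idx)]
        H = np.zeros((n, n))
        H[np.ix_(rest, rest)] = (A[np.ix_(rest, rest)]
                                 + A12 @ a22i @ (gw - a22) @ a22i @ A12.T)
        H[np.ix_(rest, idx)] = A12 @ a22i @ gw
        H[np.ix_(idx, rest)] = H[np.ix_(rest, idx)].T
        H[np.ix_(idx, idx)] = gw
        h_inv = h_inverse(a_inv, g, idx, omega=omega)
        assert np.max(np.abs(h_inv.toarray() - np.linalg.inv(H))) < 1e-6

    def test_blending_weight_zero_recovers_pedigree(self, rng):
        sire, dam, a_inv, idx, g = self._setup(rng)
        h_small = h_inverse(a_inv, g, idx, omega=1e-10)
        assert np.max(np.abs((h_small - a_inv).toarray())) < 1e-6
        h_big = h_inverse(a_inv, g, idx, omega=0.95)
        assert np.max(np.abs((h_big - a_inv).toarray())) > 1e-3
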