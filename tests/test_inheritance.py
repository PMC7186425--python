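"""Meiosis, reproduction, TBV additivity and phenotype model."""

import numpy as np
import pytest

from gxebreed import founders, inheritance
from gxebreed.genome import desk_map


@pytest.fixture(scope="module")
def tiny_map():
    return desk_map(np.random.default_rng(2), n_chromosomes=2, n_snp=100,
                    n_qtl=20, n_tracer_per_chrom=10)


class TestMeiosis:
    def test_no_crossover_copies_parent_verbatim(self, rng):
        # vanishing genetic length -> Poisson(0) crossovers; the gamete is
        # one parental strand unchanged
        gmap = desk_map(rng, n_chromosomes=1, chrom_length=1e-9, n_snp=50,
                        n_qtl=10, n_tracer_per_chrom=5)
        haps = rng.integers(0, 2, (1, 2, gmap.n_geno_loci)).astype(np.int8)
        g, _, _ = inheritance.make_gamete(haps[0], None, gmap, rng)
        assert (np.array_equal(g, haps[0, 0])
                or np.array_equal(g, haps[0, 1]))

    def test_mendelian_transmission_is_fair(self, tiny_map, rng):
        # heterozygous parent transmits each allele with probability 1/2
        haps = np.zeros((1, 2, tiny_map.n_geno_loci), dtype=np.int8)
        haps[0, 0] = 1
        gam, _, _ = inheritance.meiosis_batch(
            haps, None, np.zeros(2000, np.int64), tiny_map, rng)
        frac = gam.mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / gam.size) + 0.02

    def test_haldane_recombination_fraction(self, rng):
        # two loci 0.1 M apart: r = (1 - exp(-0.2)) / 2 ~= 0.0906
        gmap = desk_map(rng, n_chromosomes=1, chrom_length=1.0, n_snp=2,
                        n_qtl=0, n_tracer_per_chrom=2)
        d = gmap.geno_pos[1] - gmap.geno_pos[0]
        haps = np.zeros((1, 2, 2), dtype=np.int8)
        haps[0, 0] = 1          # strand 0 carries 1-1, strand 1 carries 0-0
        n = 100_000
        gam, _, _ = inheritance.meiosis_batch(
            haps, None, np.zeros(n, np.int64), gmap, rng)
        observed = np.mean(gam[:, 0] != gam[:, 1])
        expected = 0.5 * (1 - np.exp(-2 * d))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se

    def test_tracer_cotransmitted_with_flanking_markers(self, tiny_map, rng):
        # parent strands are globally distinguishable: tracer strand choice
        # must match the geno strand at a locus at (almost) zero distance
        haps_g = np.zeros((1, 2, tiny_map.n_geno_loci), dtype=np.int8)
        haps_g[0, 0] = 1
        haps_t = np.zeros((1, 2, tiny_map.n_tracer), dtype=np.int16)
        haps_t[0, 0] = 1
        g, t, s = inheritance.meiosis_batch(
            haps_g, haps_t, np.zeros(500, np.int64), tiny_map, rng)
        assert np.array_equal(t, 1 - s)  # strand 0 carries label 1 here
        # nearest geno neighbour of each tracer locus mostly shares strand
        for c in range(tiny_map.n_chromosomes):
            tl, th = tiny_map.tracer_offsets[c], tiny_map.tracer_offsets[c + 1]
            gl, gh = tiny_map.geno_offsets[c], tiny_map.geno_offsets[c + 1]
            for k in range(tl, th):
                j = gl + np.argmin(np.abs(tiny_map.geno_pos[gl:gh]
                                          - tiny_map.tracer_pos[k]))
                agree = np.mean(g[:, j] == t[:, k])
                assert agree > 0.9


class TestBreeding:
    def test_tbv_additive_and_equal_for_identical_homozygous_parents(
            self, tiny_map, rng):
        q = tiny_map.n_qtl
        effects = rng.normal(size=(q, 2))
        geno = np.ones((2, 2, tiny_map.n_geno_loci), dtype=np.int8)
        off, _, _ = inheritance.breed_batch(
            geno, None, np.array([0]), np.array([1]), tiny_map, rng)
        tbv_par = inheritance.breeding_values(geno, tiny_map.qtl_index,
                                              effects)
        tbv_off = inheritance.breeding_values(off, tiny_map.qtl_index,
                                              effects)
        assert np.allclose(tbv_off[0], tbv_par[0], atol=1e-10)

    def test_fullsib_mean_tbv_is_midparent(self, desk_founders, rng):
        pools = desk_founders.pools
        gmap = desk_founders.gmap
        geno = founders.sample_base_population(pools, 1, 1, rng)
        arch = founders.assign_qtl_effects(
            gmap, founders.sample_base_population(pools, 20, 200, rng),
            0.9, 0.3, rng)
        n = 20_000
        off, _, _ = inheritance.breed_batch(
            geno, None, np.zeros(n, np.int64), np.ones(n, np.int64), gmap,
            rng)
        tbv_par = arch.tbv(geno)
        tbv_off = arch.tbv(off)
        mid = tbv_par.mean(axis=0)
        se = tbv_off.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(tbv_off.mean(axis=0) - mid) < 4 * se + 1e-3)

    def test_no_new_alleles_after_base(self, desk_founders, rng):
        # the segregating allele set never grows: offspring alleles are a
        # subset of parental alleles at every locus
        geno = founders.sample_base_population(desk_founders.pools, 5, 5,
                                               rng)
        off, _, _ = inheritance.breed_batch(
            geno, None, rng.integers(0, 5, 30),
            5 + rng.integers(0, 5, 30), desk_founders.gmap, rng)
        par_has_one = geno.max(axis=(0, 1))
        par_has_zero = 1 - geno.min(axis=(0, 1))
        assert np.all(off.max(axis=(0, 1)) <= par_has_one)
        assert np.all(1 - off.min(axis=(0, 1)) <= par_has_zero)


class TestPhenotypes:
    def test_residual_variance_from_heritability(self, rng):
        tbv = np.zeros(50_000)
        phen = inheritance.sample_phenotypes(tbv, 1 / 0.1 - 1, rng)
        assert phen.var() == pytest.approx(9.0, rel=0.05)

    def test_h2_one_gives_exact_tbv(self, rng):
        tbv = rng.normal(size=100)
        phen = inheritance.sample_phenotypes(tbv, 0.0, rng)
        assert np.array_equal(phen, tbv)

    def test_base_phenotypic_variance_matches_one_over_h2(
            self, desk_founders, rng):
        geno = founders.sample_base_population(desk_founders.pools, 20, 200,
                                               rng)
        arch = founders.assign_qtl_effects(desk_founders.gmap, geno, 0.9,
                                           0.3, rng)
        tbv = arch.tbv(geno)
        reps = [inheritance.sample_phenotypes(tbv[:, 0], arch.sigma2_e,
                                              rng).var()
                for _ in range(30)]
        target = 1 / 0.3
        se = np.std(reps) / np.sqrt(len(reps))
        assert abs(np.mean(reps) - target) < 4 * se + 0.05

    def test_heritability_recovered_by_regression(self, desk_founders, rng):
        geno = founders.sample_base_population(desk_founders.pools, 100,
                                               4000, rng)
        arch = founders.assign_qtl_effects(desk_founders.gmap, geno, 0.9,
                                           0.3, rng)
        tbv = arch.tbv(geno)[:, 0]
        phen = inheritance.sample_phenotypes(tbv, arch.sigma2_e, rng)
        slope = np.polyfit(phen, tbv, 1)[0]
        se = np.sqrt((1 - 0.3) * 0.3 / len(phen)) * 3  # rough slope SE
        assert abs(slope - 0.3) < 3 * max(se, 0.01)
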