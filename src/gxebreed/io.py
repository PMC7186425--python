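"""Delimited-text exports and binary persistence for run artifacts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .engine import RunResult
from .founders import ChromosomePools, FounderSet
from .genome import GenomeMap

__all__ = ["export_pedigree", "export_snapshot", "export_genotypes_tped",
           "export_ebv", "save_founders", "load_founders"]


def export_pedigree(animals: pd.DataFrame, path: str | Path) -> None:
    """Three-column pedigree (id, sire, dam), 0 meaning unknown; ids are
    1-based positions so 0 stays free for the unknown code."""
    out = pd.DataFrame({
        "id": animals.index.to_numpy() + 1,
        "sire": animals["sire"].to_numpy() + 1,
        "dam": animals["dam"].to_numpy() + 1,
    })
    out.to_csv(path, sep="\t", index=False)


def export_snapshot(animals: pd.DataFrame, path: str | Path) -> None:
    """Per-animal snapshot: id, sire, dam, sex, environment, generation,
    genotyped flag and phenotype (empty when unobserved)."""
    out = pd.DataFrame({
        "id": animals.index.to_numpy() + 1,
        "sire": animals["sire"].to_numpy() + 1,
        "dam": animals["dam"].to_numpy() + 1,
        "sex": np.where(animals["sex"].to_numpy() == 0, "M", "F"),
        "env": animals["env"].to_numpy(),
        "generation": animals["generation"].to_numpy(),
        "genotyped": animals["genotyped"].astype(int).to_numpy(),
        "phenotype": animals["phenotype"].to_numpy(),
    })
    out.to_csv(path, sep="\t", index=False, na_rep="")


def export_genotypes_tped(gmap: GenomeMap, dosage: np.ndarray,
                          ids: np.ndarray, path: str | Path) -> None:
    """PLINK-style transposed genotype text: one row per SNP locus with
    chromosome, locus id, genetic position and the per-animal dosages."""
    snp = gmap.snp_index
    with open(path, "w") as fh:
        fh.write("chrom\tsnp\tpos_morgan\t"
                 + "\t".join(str(i + 1) for i in ids) + "\n")
        for k, j in enumerate(snp):
            row = "\t".join(str(int(d)) for d in dosage[:, k])
            fh.write(f"{gmap.geno_chrom[j] + 1}\tsnp{k + 1}\t"
                     f"{gmap.geno_pos[j]:.6f}\t{row}\n")


def export_ebv(ebv: np.ndarray, animals: pd.DataFrame, path: str | Path,
               ) -> None:
    """EBV table: id, generation, environment, both trait EBVs."""
    out = pd.DataFrame({
        "id": animals.index.to_numpy() + 1,
        "generation": animals["generation"].to_numpy(),
        "env": animals["env"].to_numpy(),
        "trait1_ebv": ebv[:, 0],
        "trait2_ebv": ebv[:, 1],
    })
    out.to_csv(path, sep="\t", index=False)


def read_ebv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_founders(founder: FounderSet, path: str | Path) -> None:
    """Persist a founder set (map + pools) to a compressed npz archive."""
    g = founder.gmap
    np.savez_compressed(
        path, chrom_lengths=g.chrom_lengths, geno_pos=g.geno_pos,
        geno_chrom=g.geno_chrom, snp_index=g.snp_index,
        qtl_index=g.qtl_index, tracer_pos=g.tracer_pos,
        tracer_chrom=g.tracer_chrom, paternal=founder.pools.paternal,
        maternal=founder.pools.maternal)


def load_founders(path: str | Path) -> FounderSet:
    with np.load(path) as z:
        gmap = GenomeMap(
            chrom_lengths=z["chrom_lengths"], geno_pos=z["geno_pos"],
            geno_chrom=z["geno_chrom"], snp_index=z["snp_index"],
            qtl_index=z["qtl_index"], tracer_pos=z["tracer_pos"],
            tracer_chrom=z["tracer_chrom"])
        pools = ChromosomePools(gmap=gmap, paternal=z["paternal"],
                                maternal=z["maternal"])
    return FounderSet(gmap=gmap, pools=pools)


def export_run(run: RunResult, outdir: str | Path) -> None:
    """Write the delimited artifacts of one run into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    export_pedigree(run.animals, outdir / "pedigree.tsv")
    export_snapshot(run.animals, outdir / "animals.tsv")
    run.records.to_csv(outdir / "generation_records.csv", index=False)
    run.sires.to_csv(outdir / "selected_sires.csv", index=False)
    run.dams.to_csv(outdir / "selected_dams.csv", index=False)
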