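"""File formats: VCF genotypes, tidy TSV tables, YAML configs.

Coordinates are 1-based inclusive (VCF convention).  Written VCFs are
minimal GT-only files with synthetic REF/ALT alleles (A/G) — the
pipeline's genotypes are allele counts, not sequences.  Reading uses
cyvcf2 and maps GT to counts: 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. ->
missing.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
import yaml

from .cohort import GenotypeMatrix, VariantCatalog

__all__ = ["write_vcf", "read_genotypes", "write_phenotypes",
           "read_phenotypes", "load_yaml", "dump_yaml", "sha256_of"]


def write_vcf(gm: GenotypeMatrix, catalog: VariantCatalog | None, path,
              seed=None) -> None:
    """Write counts as a minimal GT-only VCF (synthetic A/G alleles)."""
    if catalog is not None:
        cat = catalog.frame.set_index("variant_id")
        chrom = cat["chrom"].astype(str).to_dict()
        pos = cat["pos"].astype(int).to_dict()
    else:
        chrom, pos = {}, {}
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pathstep (synthetic alleles A/G)\n")
        if seed is not None:
            fh.write(f"##pathstep_seed={seed}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        for c in sorted({chrom.get(v, "1") for v in gm.variant_ids},
                        key=lambda x: (len(x), x)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, gm.ids)) + "\n")
        for j, vid in enumerate(gm.variant_ids):
            col = gm.counts[:, j]
            gts = "\t".join(gt_map.get(c if not np.isnan(c) else None, "./.")
                            for c in col)
            fh.write(f"{chrom.get(vid, '1')}\t{pos.get(vid, j + 1)}\t{vid}"
                     f"\tA\tG\t.\t.\t.\tGT\t{gts}\n")


def read_genotypes(path, fmt: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from VCF or a counts TSV into a GenotypeMatrix."""
    if fmt == "tsv":
        return GenotypeMatrix.read_tsv(path)
    if fmt != "vcf":
        raise ValueError(f"unknown genotype format {fmt!r}")
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in VCF")
    variant_ids, cols = [], []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    mapping = np.array([0.0, 1.0, np.nan, 2.0])
    for i, rec in enumerate(vcf):
        if len(rec.ALT) > 1:
            raise ValueError(f"multi-allelic record at line index {i} "
                             f"({rec.CHROM}:{rec.POS}); split upstream")
        variant_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        cols.append(mapping[rec.gt_types])
    counts = (np.column_stack(cols) if cols
              else np.zeros((len(samples), 0)))
    return GenotypeMatrix(samples, variant_ids, counts)


def write_phenotypes(df: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# generating_seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
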