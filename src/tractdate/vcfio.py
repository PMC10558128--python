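"""Minimal VCF reading/writing for genotype matrices.

Reading goes through cyvcf2; writing emits a minimal plain-text VCF 4.2
(one ALT allele, diploid phased GTs) sufficient for the statistics here and
round-trippable through standard tools.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = ["GenotypeTable", "read_vcf_genotypes", "write_vcf"]


class GenotypeTable(NamedTuple):
    chrom: np.ndarray
    pos: np.ndarray  # 0-based
    genotypes: np.ndarray  # (sites, samples) dosage 0/1/2, -1 missing
    samples: list[str]


def read_vcf_genotypes(path: str | Path) -> GenotypeTable:
    """Load biallelic SNP genotypes from a VCF as a dosage matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, pos, rows = [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        gts = np.array(variant.genotypes)[:, :2]
        dosage = np.where((gts < 0).any(axis=1), -1, gts.clip(min=0).sum(axis=1))
        chroms.append(variant.CHROM)
        pos.append(variant.POS - 1)
        rows.append(dosage)
    if not rows:
        raise ValueError(f"no biallelic sites in {path}")
    return GenotypeTable(
        chrom=np.array(chroms),
        pos=np.array(pos, dtype=np.int64),
        genotypes=np.array(rows, dtype=np.int8),
        samples=samples,
    )


def write_vcf(
    path: str | Path,
    chrom: np.ndarray,
    pos: np.ndarray,
    genotypes: np.ndarray,
    samples: list[str],
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a dosage matrix as a minimal phased diploid VCF.

    Dosage 1 is written as ``0|1`` (phase is arbitrary for these statistics),
    -1 as ``.|.``; REF/ALT are placeholder A/T.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.shape != (len(pos), len(samples)):
        raise ValueError("genotype matrix shape must be (sites, samples)")
    gt_str = {0: "0|0", 1: "0|1", 2: "1|1", -1: ".|."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tractdate\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(map(str, chrom)):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for c, p, row in zip(chrom, pos, genotypes):
            fields = [str(c), str(int(p) + 1), ".", "A", "T", ".", "PASS", ".", "GT"]
            fields += [gt_str[int(d)] for d in row]
            fh.write("\t".join(fields) + "\n")
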