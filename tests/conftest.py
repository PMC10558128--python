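import numpy as np
import pandas as pd
import pytest

import tractdate as td


@pytest.fixture(scope="session")
def small_genome() -> td.GenomeMap:
    """Four 50-Mb chromosomes at 1.63 cM/Mb — fast but structurally realistic."""
    return td.uniform_genome(n_chromosomes=4)


@pytest.fixture(scope="session")
def one_chrom_genome() -> td.GenomeMap:
    """A single 100-Mb chromosome at 1 cM/Mb (1 morgan)."""
    return td.GenomeMap([td.Chromosome("chr1", 100_000_000, 1.0)])


@pytest.fixture(scope="session")
def sim_tracts(small_genome) -> td.TractSet:
    """Single-pulse mosaic at T=18.1, f=0.3 on the small genome."""
    cfg = td.SimConfig(seed=7, genome=small_genome, n_sites=100)
    return td.simulate_admixed_tracts(cfg)


def constant_tract_set(
    genome: td.GenomeMap,
    minor_len_bp: int,
    n_minor: int,
    spacer_bp: int,
    labels=("naumanni", "arctica"),
) -> td.TractSet:
    """TractSet with n_minor interior minor tracts of exactly minor_len_bp
    per haplotype, separated (and flanked) by major spacers."""
    minor, major = labels
    rows = []
    for chrom in genome:
        for hap in (0, 1):
            pos = 0
            for _ in range(n_minor):
                rows.append((chrom.name, pos, pos + spacer_bp, "ind0", hap, major))
                pos += spacer_bp
                rows.append((chrom.name, pos, pos + minor_len_bp, "ind0", hap, minor))
                pos += minor_len_bp
            assert pos < chrom.length_bp, "fixture does not fit the chromosome"
            rows.append((chrom.name, pos, chrom.length_bp, "ind0", hap, major))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "individual", "haplotype", "ancestry"]
    )
    return td.TractSet(genome, df, labels=labels)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
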