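"""Genome map: chromosome lengths and recombination rates.

The map carries, per chromosome, its physical length in base pairs and a
constant recombination rate in cM/Mb, which is all the downstream tract
arithmetic needs: genetic length in morgans is ``length_bp * rate * 1e-8``
(1 cM/Mb = 1e-8 morgan/bp). Fine-scale recombination maps are deliberately
not modelled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "MORGAN_PER_BP",
    "Chromosome",
    "GenomeMap",
    "read_genome_map",
    "uniform_genome",
]

#: morgans per bp at 1 cM/Mb
MORGAN_PER_BP = 1e-8


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the genome map."""

    name: str
    length_bp: int
    rate_cm_per_mb: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name!r}: length_bp must be > 0")
        if self.rate_cm_per_mb <= 0:
            raise ValueError(f"chromosome {self.name!r}: rate must be > 0")

    @property
    def rate_morgan_per_bp(self) -> float:
        return self.rate_cm_per_mb * MORGAN_PER_BP

    @property
    def length_morgans(self) -> float:
        return self.length_bp * self.rate_morgan_per_bp


class GenomeMap:
    """Ordered collection of chromosomes with unique names."""

    def __init__(self, chromosomes: Iterable[Chromosome]):
        self._chroms = list(chromosomes)
        if not self._chroms:
            raise ValueError("genome map is empty")
        names = [c.name for c in self._chroms]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome name(s): {dup}")
        self._by_name = {c.name: c for c in self._chroms}

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self._chroms)

    def __len__(self) -> int:
        return len(self._chroms)

    def __getitem__(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeMap):
            return NotImplemented
        return self._chroms == other._chroms

    @property
    def names(self) -> list[str]:
        return [c.name for c in self._chroms]

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self._chroms)

    @property
    def total_morgans(self) -> float:
        return sum(c.length_morgans for c in self._chroms)

    def morgans(self, name: str) -> float:
        return self[name].length_morgans

    def bp_to_morgans(self, name: str, bp: float) -> float:
        return bp * self[name].rate_morgan_per_bp

    def morgans_to_bp(self, name: str, morgans: float) -> float:
        return morgans / self[name].rate_morgan_per_bp

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tlength_bp\trate_cM_per_Mb\n")
            for c in self._chroms:
                fh.write(f"{c.name}\t{c.length_bp}\t{c.rate_cm_per_mb:g}\n")

    def __repr__(self) -> str:
        return (
            f"GenomeMap({len(self)} chromosomes, {self.total_bp / 1e6:.1f} Mb, "
            f"{self.total_morgans:.2f} M)"
        )


def read_genome_map(source: str | Path | io.TextIOBase) -> GenomeMap:
    """Read a genome map TSV with header ``chrom  length_bp  rate_cM_per_Mb``.

    Malformed rows are rejected with their line number.
    """
    own = isinstance(source, (str, Path))
    fh = open(source) if own else source
    try:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["chrom", "length_bp", "rate_cM_per_Mb"]
        if header != expected:
            raise ValueError(f"genome map header must be {expected}, got {header}")
        chroms: list[Chromosome] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"genome map line {lineno}: expected 3 columns")
            name, length_s, rate_s = parts
            try:
                chrom = Chromosome(name, int(length_s), float(rate_s))
            except ValueError as exc:
                raise ValueError(f"genome map line {lineno}: {exc}") from None
            chroms.append(chrom)
        try:
            return GenomeMap(chroms)
        except ValueError as exc:
            raise ValueError(f"genome map: {exc}") from None
    finally:
        if own:
            fh.close()


def uniform_genome(
    n_chromosomes: int = 24,
    chrom_length_bp: int = 50_000_000,
    rate_cm_per_mb: float = 1.63,
) -> GenomeMap:
    """Equal-sized genome map used as the default simulation layout.

    Defaults mimic the study system: 24 autosomes totalling ~1.2 Gb at the
    genome-wide mean recombination rate of 1.63 cM/Mb.
    """
    return GenomeMap(
        Chromosome(f"chr{i + 1}", chrom_length_bp, rate_cm_per_mb)
        for i in range(n_chromosomes)
    )
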