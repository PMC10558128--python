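"""Admixture-validation statistics: f3, ABBA-BABA D, f4-ratio.

All three are frequency-based moment statistics on an
:class:`AlleleCountMatrix`; standard errors come from a delete-one block
jackknife over contiguous genomic blocks (default 5 Mb), and Z = value / SE.
A significantly negative f3(target; p1, p2) indicates the target is admixed
between relatives of p1 and p2; a nonzero D indicates gene flow violating
the strict ``(((p1, p2), p3), outgroup)`` tree; the f4-ratio
``f4(a, o; x, c) / f4(a, o; b, c)`` estimates the ancestry proportion of the
b-related source in x.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AlleleCountMatrix",
    "FStatResult",
    "block_jackknife",
    "f3",
    "d_statistic",
    "f4_ratio",
]

DEFAULT_BLOCK_BP = 5_000_000


@dataclass
class AlleleCountMatrix:
    """Per-site, per-population alternate-allele counts.

    ``pops`` maps a population name to ``(alt_count, total_count)`` arrays.
    Any population may serve as the outgroup in :func:`d_statistic`; sites
    where that population is polymorphic are excluded there.
    """

    chrom: np.ndarray
    pos: np.ndarray
    pops: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        n = len(self.pos)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom)
        for name, (alt, tot) in self.pops.items():
            alt = np.asarray(alt, dtype=np.int64)
            tot = np.asarray(tot, dtype=np.int64)
            if len(alt) != n or len(tot) != n:
                raise ValueError(f"population {name!r}: count arrays misaligned")
            if ((alt < 0) | (alt > tot)).any():
                raise ValueError(f"population {name!r}: counts outside [0, total]")
            self.pops[name] = (alt, tot)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def frequency(self, pop: str) -> np.ndarray:
        alt, tot = self._get(pop)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def _get(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self.pops[pop]
        except KeyError:
            raise KeyError(f"unknown population {pop!r} (have {sorted(self.pops)})") from None

    def _complete_mask(self, pops: list[str]) -> np.ndarray:
        """Sites with no missing data in any involved population (listwise)."""
        mask = np.ones(self.n_sites, dtype=bool)
        for p in pops:
            _alt, tot = self._get(p)
            mask &= tot == tot.max()
        return mask

    # ------------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        data = {"chrom": self.chrom, "pos": self.pos}
        for name, (alt, tot) in self.pops.items():
            data[f"alt_{name}"] = alt
            data[f"tot_{name}"] = tot
        pd.DataFrame(data).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleCountMatrix":
        df = pd.read_csv(path, sep="\t")
        pops = {}
        for col in df.columns:
            if col.startswith("alt_"):
                name = col[4:]
                pops[name] = (df[col].to_numpy(), df[f"tot_{name}"].to_numpy())
        return cls(chrom=df["chrom"].to_numpy(), pos=df["pos"].to_numpy(), pops=pops)

    @classmethod
    def from_vcf(cls, path: str | Path, populations: dict[str, list[str]]) -> "AlleleCountMatrix":
        """Build counts from a diploid-GT VCF and a sample→population map."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        idx = {
            name: np.array([samples.index(s) for s in members])
            for name, members in populations.items()
        }
        chroms, pos = [], []
        counts: dict[str, list[tuple[int, int]]] = {name: [] for name in populations}
        for variant in vcf:
            if len(variant.ALT) != 1:
                continue
            gts = np.array(variant.genotypes)[:, :2]  # (n_samples, 2) alleles, -1 missing
            chroms.append(variant.CHROM)
            pos.append(variant.POS - 1)  # 0-based
            for name, ix in idx.items():
                sub = gts[ix].ravel()
                called = sub >= 0
                counts[name].append((int(sub[called].sum()), int(called.sum())))
        pops = {
            name: (
                np.array([c[0] for c in vals]),
                np.array([c[1] for c in vals]),
            )
            for name, vals in counts.items()
        }
        return cls(chrom=np.array(chroms), pos=np.array(pos), pops=pops)


@dataclass
class FStatResult:
    statistic: str
    value: float
    jackknife_se: float
    z: float
    n_blocks: int
    n_sites_used: int

    def __str__(self) -> str:
        return (
            f"{self.statistic} = {self.value:.6g} ± {self.jackknife_se:.3g} "
            f"(Z = {self.z:.2f}, {self.n_blocks} blocks, {self.n_sites_used} sites)"
        )


# ----------------------------------------------------------------------
def block_jackknife(
    numerators: np.ndarray, denominators: np.ndarray, blocks: np.ndarray
) -> tuple[float, float]:
    """Delete-one-block jackknife for a ratio-of-sums estimator.

    Returns the full-data estimate and the equal-weight jackknife SE
    ``sqrt(((m - 1) / m) * sum((theta_-i - mean)^2))`` over the ``m``
    non-empty blocks.
    """
    numerators = np.asarray(numerators, dtype=float)
    denominators = np.asarray(denominators, dtype=float)
    codes, _uniques = pd.factorize(blocks)
    m = codes.max() + 1 if len(codes) else 0
    if m < 2:
        raise ValueError(f"block jackknife needs >= 2 non-empty blocks, got {m}")
    num_b = np.bincount(codes, weights=numerators, minlength=m)
    den_b = np.bincount(codes, weights=denominators, minlength=m)
    num_tot, den_tot = num_b.sum(), den_b.sum()
    if den_tot == 0:
        raise ValueError("zero denominator in jackknife estimate")
    loo_den = den_tot - den_b
    if (loo_den == 0).any():
        raise ValueError("a delete-one block leaves a zero denominator")
    theta = num_tot / den_tot
    loo = (num_tot - num_b) / loo_den
    se = float(np.sqrt((m - 1) / m * ((loo - loo.mean()) ** 2).sum()))
    return float(theta), se


def _blocks(acm: AlleleCountMatrix, mask: np.ndarray, block_size_bp: float) -> np.ndarray:
    if block_size_bp <= 0:
        raise ValueError("block size must be > 0")
    return pd.Series(
        [f"{c}:{p // int(block_size_bp)}" for c, p in zip(acm.chrom[mask], acm.pos[mask])]
    ).to_numpy()


def _result(stat: str, value: float, se: float, m: int, n: int) -> FStatResult:
    z = value / se if se > 0 else float("nan")
    return FStatResult(stat, value, se, z, m, n)


def f3(
    acm: AlleleCountMatrix,
    target: str,
    p1: str,
    p2: str,
    block_size_bp: float = DEFAULT_BLOCK_BP,
    correction: bool = False,
) -> FStatResult:
    """f3(target; p1, p2) = mean[(c − a)(c − b)] with block-jackknife SE.

    ``correction=True`` subtracts the sampling-variance term
    ``c(1 − c) / (n_c − 1)`` for the target, relevant when its frequencies
    come from few haplotypes; off by default.
    """
    mask = acm._complete_mask([target, p1, p2])
    a = acm.frequency(p1)[mask]
    b = acm.frequency(p2)[mask]
    c = acm.frequency(target)[mask]
    poly = (
        ((a > 0) & (a < 1)) | ((b > 0) & (b < 1)) | ((c > 0) & (c < 1)) | (a != b) | (a != c)
    )
    if not poly.any():
        raise ValueError("f3: no polymorphic/informative sites")
    num = (c - a) * (c - b)
    if correction:
        _alt, tot = acm._get(target)
        n_c = tot[mask]
        if (n_c < 2).any():
            raise ValueError("f3 correction needs >= 2 target alleles per site")
        num = num - c * (1 - c) / (n_c - 1)
    blocks = _blocks(acm, mask, block_size_bp)
    value, se = block_jackknife(num, np.ones_like(num), blocks)
    return _result("f3", value, se, len(np.unique(blocks)), int(mask.sum()))


def _polarized(acm: AlleleCountMatrix, pops: list[str], outgroup: str):
    """Derived-allele frequencies polarized by a fixed outgroup allele."""
    mask = acm._complete_mask(pops + [outgroup])
    out_f = acm.frequency(outgroup)
    fixed = (out_f == 0) | (out_f == 1)
    mask &= fixed
    if not mask.any():
        raise ValueError("no sites with a fixed outgroup allele")
    anc = out_f[mask]  # 0 or 1: the ancestral allele as alt-dosage
    freqs = []
    for p in pops:
        f = acm.frequency(p)[mask]
        freqs.append(np.where(anc == 1, 1.0 - f, f))
    return mask, freqs


def d_statistic(
    acm: AlleleCountMatrix,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    block_size_bp: float = DEFAULT_BLOCK_BP,
) -> FStatResult:
    """ABBA-BABA D for (((p1, p2), p3), outgroup), frequency form.

    D = sum[(1 − q1) q2 q3 − q1 (1 − q2) q3] / sum[(1 − q1) q2 q3 + q1 (1 − q2) q3]
    with derived frequencies q polarized by the outgroup allele. Positive D
    means an excess of ABBA sites, i.e. sharing between p2 and p3.
    """
    mask, (q1, q2, q3) = _polarized(acm, [p1, p2, p3], outgroup)
    abba = (1 - q1) * q2 * q3
    baba = q1 * (1 - q2) * q3
    den = abba + baba
    if den.sum() == 0:
        raise ValueError("D statistic: zero denominator (no ABBA or BABA signal)")
    blocks = _blocks(acm, mask, block_size_bp)
    value, se = block_jackknife(abba - baba, den, blocks)
    return _result("D", value, se, len(np.unique(blocks)), int(mask.sum()))


def f4_ratio(
    acm: AlleleCountMatrix,
    a: str,
    o: str,
    x: str,
    b: str,
    c: str,
    block_size_bp: float = DEFAULT_BLOCK_BP,
) -> FStatResult:
    """f4-ratio alpha = f4(a, o; x, c) / f4(a, o; b, c).

    Estimates the ancestry proportion of the b-related source in the admixed
    population x. Raises when the denominator f4 is within one jackknife SE
    of zero (non-estimable topology).
    """
    mask = acm._complete_mask([a, o, x, b, c])
    if not mask.any():
        raise ValueError("f4_ratio: no complete sites")
    fa = acm.frequency(a)[mask]
    fo = acm.frequency(o)[mask]
    fx = acm.frequency(x)[mask]
    fb = acm.frequency(b)[mask]
    fc = acm.frequency(c)[mask]
    num = (fa - fo) * (fx - fc)
    den = (fa - fo) * (fb - fc)
    blocks = _blocks(acm, mask, block_size_bp)
    den_val, den_se = block_jackknife(den, np.ones_like(den), blocks)
    if abs(den_val) <= den_se:
        raise ValueError(
            f"f4_ratio non-estimable: denominator f4 = {den_val:.3g} ± {den_se:.3g}"
        )
    value, se = block_jackknife(num, den, blocks)
    return _result("f4_ratio", value, se, len(np.unique(blocks)), int(mask.sum()))
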