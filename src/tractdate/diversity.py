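"""Folded-SFS diversity statistics, windowed F_ST and temporal contrasts.

All statistics operate on called diploid genotypes (0/1/2 alt-allele dosage,
-1 missing): the folded site-frequency spectrum, nucleotide diversity (pi),
Tajima's D, per-individual heterozygosity, Hudson's F_ST in sliding windows
(ratio of averages), the expected heterozygosity of a hybrid given its
parental populations, and a Wilcoxon rank-sum contrast for temporal
(historical vs modern) comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "FoldedSFS",
    "folded_sfs",
    "nucleotide_diversity",
    "tajimas_d",
    "individual_heterozygosity",
    "hudson_fst",
    "windowed_stats",
    "expected_hybrid_heterozygosity",
    "temporal_comparison",
]


@dataclass
class FoldedSFS:
    """Folded 1D site-frequency spectrum.

    ``counts[i]`` is the number of sites whose minor-allele count is ``i``
    for ``i = 0 .. n // 2``; monomorphic sites sit in bin 0, so
    ``counts.sum()`` equals the total number of sites, variant or not.
    """

    n_haplotypes: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.n_haplotypes < 2 or self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be an even count >= 2")
        if len(self.counts) != self.n_haplotypes // 2 + 1:
            raise ValueError(
                f"folded SFS for n={self.n_haplotypes} needs "
                f"{self.n_haplotypes // 2 + 1} bins, got {len(self.counts)}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative SFS count")

    @property
    def total_sites(self) -> int:
        return int(self.counts.sum())

    @property
    def segregating_sites(self) -> int:
        return int(self.counts[1:].sum())


def folded_sfs(genotypes: np.ndarray) -> FoldedSFS:
    """Fold per-site diploid genotypes (sites x individuals) into an SFS.

    Genotypes are alt-allele dosages 0/1/2; sites containing any missing
    call (< 0) are dropped before folding (documented policy).
    """
    gt = np.asarray(genotypes)
    if gt.ndim != 2 or gt.shape[1] < 1:
        raise ValueError("genotypes must be a (sites, individuals) matrix")
    n = 2 * gt.shape[1]
    keep = (gt >= 0).all(axis=1)
    gt = gt[keep]
    if gt.shape[0] == 0:
        raise ValueError("no fully-called sites")
    alt = gt.sum(axis=1)
    minor = np.minimum(alt, n - alt)
    counts = np.bincount(minor, minlength=n // 2 + 1)
    return FoldedSFS(n_haplotypes=n, counts=counts)


def _pi_total(sfs: FoldedSFS) -> float:
    """Sum over sites of the pairwise-difference probability."""
    n = sfs.n_haplotypes
    i = np.arange(len(sfs.counts))
    per_site = 2.0 * i * (n - i) / (n * (n - 1))
    return float((sfs.counts * per_site).sum())


def nucleotide_diversity(sfs: FoldedSFS) -> float:
    """pi per site: mean pairwise difference averaged over all SFS sites."""
    if sfs.total_sites == 0:
        raise ValueError("empty SFS")
    return _pi_total(sfs) / sfs.total_sites


def tajimas_d(sfs: FoldedSFS) -> float:
    """Tajima's D with the standard a1..e2 constants.

    Requires at least one segregating site and n >= 4 haplotypes; undefined
    (error) at S = 0.
    """
    n = sfs.n_haplotypes
    if n < 4:
        raise ValueError("Tajima's D needs >= 4 haplotypes")
    s = sfs.segregating_sites
    if s == 0:
        raise ValueError("Tajima's D undefined with no segregating sites")
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return float((_pi_total(sfs) - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1)))


def individual_heterozygosity(sfs: FoldedSFS) -> float:
    """Polymorphic fraction of a single diploid's SFS (n = 2): counts[1] / total."""
    if sfs.n_haplotypes != 2:
        raise ValueError("individual heterozygosity needs an n = 2 SFS")
    if sfs.total_sites == 0:
        raise ValueError("empty SFS")
    return float(sfs.counts[1] / sfs.total_sites)


# ----------------------------------------------------------------------
def hudson_fst(gt1: np.ndarray, gt2: np.ndarray) -> float:
    """Hudson's F_ST, ratio of averages over sites.

    ``1 - mean(within-population heterozygosity) / mean(between-population
    heterozygosity)`` with the unbiased within-population estimator
    ``2 p (1 - p) n / (n - 1)``.
    """
    gt1 = np.asarray(gt1)
    gt2 = np.asarray(gt2)
    if gt1.shape[0] != gt2.shape[0]:
        raise ValueError("populations must share the site set")
    keep = (gt1 >= 0).all(axis=1) & (gt2 >= 0).all(axis=1)
    gt1, gt2 = gt1[keep], gt2[keep]
    n1, n2 = 2 * gt1.shape[1], 2 * gt2.shape[1]
    if min(n1, n2) < 4:
        raise ValueError("Hudson F_ST needs >= 2 diploids per population")
    p1 = gt1.sum(axis=1) / n1
    p2 = gt2.sum(axis=1) / n2
    hw = (2 * p1 * (1 - p1) * n1 / (n1 - 1) + 2 * p2 * (1 - p2) * n2 / (n2 - 1)) / 2
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    if hb.sum() == 0:
        raise ValueError("no between-population heterozygosity (monomorphic input)")
    return float(1.0 - hw.sum() / hb.sum())


class WindowedStats(NamedTuple):
    windows: pd.DataFrame
    genome_means: dict


def windowed_stats(
    positions: np.ndarray,
    genotypes: dict[str, np.ndarray],
    seq_length: int,
    window_bp: int = 50_000,
    min_sites: int = 1,
) -> WindowedStats:
    """Per-window pi, Tajima's D (and F_ST for two populations) plus means.

    ``positions`` are 0-based sorted site coordinates on one sequence of
    ``seq_length`` bp. pi uses the window's physical size as denominator
    (unsampled sites are assumed callable and monomorphic). Windows with
    fewer than ``min_sites`` variant sites are masked (NaN), not zero, and
    excluded from the genome-level means (mean over windows).
    """
    positions = np.asarray(positions)
    if len(positions) and (np.diff(positions) < 0).any():
        raise ValueError("positions must be sorted")
    if len(genotypes) not in (1, 2):
        raise ValueError("one or two populations supported")
    pop_names = list(genotypes)
    n_win = int(np.ceil(seq_length / window_bp))
    rows = []
    for w in range(n_win):
        lo, hi = w * window_bp, min((w + 1) * window_bp, seq_length)
        sel = (positions >= lo) & (positions < hi)
        row: dict = {"start": lo, "end": hi, "n_sites": int(sel.sum())}
        masked = row["n_sites"] < min_sites
        for name in pop_names:
            gt = genotypes[name][sel]
            if masked:
                row[f"pi_{name}"] = np.nan
                row[f"tajimas_d_{name}"] = np.nan
                continue
            sfs = folded_sfs(gt) if len(gt) else None
            pi_tot = _pi_total(sfs) if sfs else 0.0
            row[f"pi_{name}"] = pi_tot / (hi - lo)
            try:
                row[f"tajimas_d_{name}"] = tajimas_d(sfs) if sfs else np.nan
            except ValueError:
                row[f"tajimas_d_{name}"] = np.nan
        if len(pop_names) == 2:
            if masked:
                row["fst"] = np.nan
            else:
                try:
                    row["fst"] = hudson_fst(
                        genotypes[pop_names[0]][sel], genotypes[pop_names[1]][sel]
                    )
                except ValueError:
                    row["fst"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    means = {
        col: float(df[col].mean(skipna=True))
        for col in df.columns
        if col not in ("start", "end", "n_sites")
    }
    return WindowedStats(windows=df, genome_means=means)


# ----------------------------------------------------------------------
def expected_hybrid_heterozygosity(
    h1: float, h2: float, fst: float, alpha: float
) -> float:
    """Expected hybrid heterozygosity from parental het, F_ST and ancestry.

    ``H = alpha^2 h1 + (1 - alpha)^2 h2 + 2 alpha (1 - alpha) H_b`` with the
    between-parent heterozygosity recovered by inverting Hudson's estimator:
    ``H_b = ((h1 + h2) / 2) / (1 - fst)``.
    """
    for name, v in (("h1", h1), ("h2", h2), ("alpha", alpha), ("fst", fst)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} = {v} outside [0, 1]")
    if fst == 1:
        raise ValueError("fst = 1: between-population heterozygosity undefined")
    h_b = ((h1 + h2) / 2.0) / (1.0 - fst)
    return alpha**2 * h1 + (1 - alpha) ** 2 * h2 + 2 * alpha * (1 - alpha) * h_b


class RankSumResult(NamedTuple):
    w: float
    p_value: float


def temporal_comparison(values_a, values_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) contrast of two cohorts.

    W counts the pairs where a value from the first group exceeds one from
    the second (ties half-weighted), so W = 0 when the first group lies
    entirely below the second and W = n_a * n_b in the mirror case. The
    p-value is exact for small tie-free samples (combined n <= 20), else a
    tie-corrected normal approximation. All-tied input yields p = 1 with a
    warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied; rank-sum test uninformative", stacklevel=2)
        w = float(len(a) * len(b) / 2.0)
        return RankSumResult(w, 1.0)
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 20 and not ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue))
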