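"""Synthetic inputs with the statistical structure the estimators assume.

Four generators, all driven by one :class:`SimConfig`:

* admixed tract mosaics — Markovian single- or two-pulse model: recombination
  breakpoints fall as a Poisson process at rate ``T − 1`` per morgan and each
  inter-breakpoint segment draws minor ancestry independently with
  probability ``f``; adjacent same-ancestry segments are merged, so observed
  minor-tract lengths are exponential with mean ``1 / ((1 − f)(T − 1))``
  morgans. A second, more recent pulse is painted over the older mosaic.
* per-window heterozygosity tracks with embedded low-heterozygosity segments
  (fixture for the RoH caller);
* allele counts for four populations on a ``(((P1,P2),P3),O)`` drift tree
  plus an optional admixed population ``X`` mixing two lineage frequencies
  (fixture for f3 / D / f4-ratio; the drift model is a truncated-Gaussian
  perturbation of frequencies — a fixture choice, not a population-genetic
  claim);
* a divergent pseudo-haploid sequence pair at a stated per-site divergence
  (fixture for the mutation-rate stage).

All randomness derives from ``SimConfig.seed`` through fixed, documented
sub-streams, so a given config is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fstats import AlleleCountMatrix
from .genome import GenomeMap, uniform_genome
from .roh import HetTrack
from .tracts import TractSet

__all__ = [
    "SimConfig",
    "GenotypePanel",
    "simulate_admixed_tracts",
    "simulate_het_track",
    "simulate_genotype_panel",
    "simulate_allele_counts",
    "simulate_divergent_pair",
]

# fixed sub-stream ids: one independent generator per output kind
_STREAMS = {"tracts": 0, "het": 1, "counts": 2, "pair": 3}

#: default per-branch drift magnitudes (SD of the truncated-Gaussian
#: frequency perturbation) for the ((P1,P2),P3),O tree
DEFAULT_TREE = {
    "internal": 0.12,
    "p1": 0.08,
    "p2": 0.08,
    "p3": 0.15,
    "outgroup": 0.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all synthetic inputs.

    Defaults mirror the analysed system: 6 diploid hybrids on a 24 × 50 Mb
    genome at 1.63 cM/Mb, a single admixture pulse 18.1 generations back with
    minor-ancestry fraction 0.3, and an admixture proportion of 0.297 for the
    allele-count fixture.
    """

    seed: int = 0
    n_individuals: int = 6
    pulse_times: tuple[float, ...] = (18.1,)
    minor_fractions: tuple[float, ...] = (0.3,)
    genome: GenomeMap = field(default_factory=uniform_genome)
    labels: tuple[str, str] = ("naumanni", "arctica")  # (minor, major)
    # heterozygosity track
    het_baseline: float = 1.2e-3
    het_noise_sd: float = 0.0
    window_bp: int = 100_000
    low_het_segments: tuple[tuple[str, int, int, float], ...] = ()
    # allele-count fixture
    tree_params: dict = field(default_factory=lambda: dict(DEFAULT_TREE))
    n_sites: int = 100_000
    n_haplotypes: int = 50
    admix_alpha: float | None = 0.297
    admix_sources: tuple[str, str] = ("P3", "P2")
    # divergent pair
    divergence_d: float = 0.082

    def __post_init__(self) -> None:
        if len(self.pulse_times) not in (1, 2):
            raise ValueError("pulse_times must have 1 or 2 entries")
        if len(self.pulse_times) != len(self.minor_fractions):
            raise ValueError("pulse_times and minor_fractions must align")
        for t in self.pulse_times:
            if t < 1:
                raise ValueError(f"pulse time {t} < 1 generation")
        for f in self.minor_fractions:
            # f == 0 is a documented degenerate case: an all-major mosaic
            if not 0 <= f < 1:
                raise ValueError(f"minor fraction {f} outside [0, 1)")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be > 0")
        if self.n_haplotypes < 2 or self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be an even count >= 2")
        if not 0 <= self.divergence_d < 1:
            raise ValueError("divergence_d must lie in [0, 1)")
        if self.admix_alpha is not None and not 0 <= self.admix_alpha <= 1:
            raise ValueError("admix_alpha outside [0, 1]")
        for branch, sd in self.tree_params.items():
            if not 0 <= sd <= 0.5:
                raise ValueError(f"tree drift {branch}={sd} outside [0, 0.5]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


# ----------------------------------------------------------------------
# tract mosaics
# ----------------------------------------------------------------------
def _overlay_pulse(
    rng: np.random.Generator,
    edges: np.ndarray,
    labels: np.ndarray,
    g_len: float,
    t_gen: float,
    frac: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint one pulse over an existing mosaic (positions in morgans)."""
    n_bp = rng.poisson((t_gen - 1.0) * g_len)
    new_edges = np.concatenate(([0.0], np.sort(rng.uniform(0.0, g_len, n_bp)), [g_len]))
    painted = rng.random(len(new_edges) - 1) < frac
    all_edges = np.unique(np.concatenate([edges, new_edges]))
    mid = 0.5 * (all_edges[:-1] + all_edges[1:])
    new_idx = np.searchsorted(new_edges, mid, side="right") - 1
    old_idx = np.searchsorted(edges, mid, side="right") - 1
    lab = np.where(painted[new_idx], True, labels[old_idx])
    return all_edges, lab


def _merge_edges(edges: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = np.ones(len(labels), dtype=bool)
    keep[1:] = labels[1:] != labels[:-1]
    return np.concatenate([edges[:-1][keep], edges[-1:]]), labels[keep]


def simulate_admixed_tracts(config: SimConfig) -> TractSet:
    """Simulate a phased admixed tract mosaic for every individual.

    Single pulse: breakpoints at rate ``T − 1`` per morgan, i.i.d. minor
    labels with probability ``f``. Two pulses: the older layer is generated
    first and the recent pulse painted over it. Output tracts tile every
    chromosome exactly; adjacent same-ancestry tracts are merged.
    """
    rng = config.rng("tracts")
    minor, major = config.labels
    pulses = sorted(
        zip(config.pulse_times, config.minor_fractions), key=lambda p: -p[0]
    )  # oldest first
    rows: list[pd.DataFrame] = []
    for i in range(config.n_individuals):
        ind = f"ind{i}"
        for hap in (0, 1):
            for chrom in config.genome:
                g_len = chrom.length_morgans
                edges = np.array([0.0, g_len])
                labels = np.array([False])
                for t_gen, frac in pulses:
                    edges, labels = _overlay_pulse(rng, edges, labels, g_len, t_gen, frac)
                    edges, labels = _merge_edges(edges, labels)
                # morgans -> bp, guarding against collapsed segments
                bp = np.rint(edges / chrom.rate_morgan_per_bp).astype(np.int64)
                bp[0], bp[-1] = 0, chrom.length_bp
                keep = bp[1:] > bp[:-1]
                bp_edges = np.concatenate([bp[:-1][keep], bp[-1:]])
                bp_labels = labels[keep]
                bp_edges, bp_labels = _merge_edges(bp_edges, bp_labels)
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom.name,
                            "start": bp_edges[:-1],
                            "end": bp_edges[1:],
                            "individual": ind,
                            "haplotype": hap,
                            "ancestry": np.where(bp_labels, minor, major),
                        }
                    )
                )
    df = pd.concat(rows, ignore_index=True)
    return TractSet(config.genome, df, labels=config.labels)


# ----------------------------------------------------------------------
# heterozygosity tracks
# ----------------------------------------------------------------------
def simulate_het_track(config: SimConfig) -> list[HetTrack]:
    """Per-window heterozygosity tracks, one per chromosome.

    Windows are ``window_bp`` wide with a final partial window covering any
    remainder. A window takes a segment's value when it lies fully inside
    that segment; otherwise it takes the baseline (plus optional Gaussian
    noise, truncated at zero). Overlapping segments are rejected.
    """
    rng = config.rng("het")
    segs_by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for chrom_name, start, end, value in config.low_het_segments:
        if chrom_name not in config.genome:
            raise ValueError(f"low_het segment on unknown chromosome {chrom_name!r}")
        segs_by_chrom.setdefault(chrom_name, []).append((int(start), int(end), value))
    for chrom_name, segs in segs_by_chrom.items():
        segs.sort()
        for (s1, e1, _), (s2, _e2, _) in zip(segs[:-1], segs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping low_het_segments on {chrom_name}")
    tracks = []
    for chrom in config.genome:
        n_win = int(np.ceil(chrom.length_bp / config.window_bp))
        het = np.full(n_win, config.het_baseline, dtype=float)
        if config.het_noise_sd > 0:
            het = np.maximum(het + rng.normal(0.0, config.het_noise_sd, n_win), 0.0)
        for s, e, value in segs_by_chrom.get(chrom.name, []):
            w_start = np.arange(n_win) * config.window_bp
            w_end = np.minimum(w_start + config.window_bp, chrom.length_bp)
            inside = (w_start >= s) & (w_end <= e)
            het[inside] = value
        tracks.append(
            HetTrack(
                chrom=chrom.name,
                window_bp=config.window_bp,
                het=het,
                chrom_length_bp=chrom.length_bp,
            )
        )
    return tracks


# ----------------------------------------------------------------------
# allele counts on the drift tree
# ----------------------------------------------------------------------
@dataclass
class GenotypePanel:
    """Per-haplotype genotype draws for the drift-tree populations.

    ``haplotypes[pop]`` is an (n_sites, n_haplotypes) 0/1 matrix; the
    outgroup is a single pseudo-haploid state vector.
    """

    chrom: np.ndarray
    pos: np.ndarray
    haplotypes: dict[str, np.ndarray]
    outgroup_state: np.ndarray
    frequencies: dict[str, np.ndarray]

    def genotypes(self, pop: str) -> np.ndarray:
        """Diploid 0/1/2 genotype matrix (n_sites, n_haplotypes // 2)."""
        hap = self.haplotypes[pop]
        return hap[:, 0::2] + hap[:, 1::2]

    def allele_counts(self) -> AlleleCountMatrix:
        pops = {
            name: (hap.sum(axis=1), np.full(len(self.pos), hap.shape[1]))
            for name, hap in self.haplotypes.items()
        }
        pops["O"] = (self.outgroup_state.astype(np.int64), np.ones(len(self.pos), dtype=np.int64))
        return AlleleCountMatrix(chrom=self.chrom, pos=self.pos, pops=pops)


def _site_positions(genome: GenomeMap, n_sites: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic, evenly spaced site placement proportional to length."""
    total = genome.total_bp
    quota = [int(round(n_sites * c.length_bp / total)) for c in genome]
    # adjust rounding drift on the last chromosome
    quota[-1] += n_sites - sum(quota)
    chroms, pos = [], []
    for c, k in zip(genome, quota):
        if k <= 0:
            continue
        step = c.length_bp / (k + 1)
        chroms.append(np.repeat(c.name, k))
        pos.append((step * np.arange(1, k + 1)).astype(np.int64))
    return np.concatenate(chroms), np.concatenate(pos)


def simulate_genotype_panel(config: SimConfig) -> GenotypePanel:
    """Draw haplotypes for P1, P2, P3 (plus X when configured) and the outgroup.

    Site frequencies: ancestral frequency uniform on (0, 1); each branch adds
    a zero-mean Gaussian perturbation of the configured SD, truncated to
    [0, 1]. ``X`` mixes two lineage frequencies:
    ``x = alpha * p[src1] + (1 - alpha) * p[src2]``.
    """
    rng = config.rng("counts")
    n = config.n_sites
    tp = config.tree_params

    def drift(freq: np.ndarray, sd: float) -> np.ndarray:
        if sd == 0:
            return freq.copy()
        return np.clip(freq + rng.normal(0.0, sd, len(freq)), 0.0, 1.0)

    p_root = rng.uniform(0.0, 1.0, n)
    p_internal = drift(p_root, tp["internal"])
    freqs = {
        "P1": drift(p_internal, tp["p1"]),
        "P2": drift(p_internal, tp["p2"]),
        "P3": drift(p_root, tp["p3"]),
    }
    p_out = drift(p_root, tp["outgroup"])
    if config.admix_alpha is not None:
        a = config.admix_alpha
        s1, s2 = config.admix_sources
        for s in (s1, s2):
            if s not in freqs:
                raise ValueError(f"admix source {s!r} not among {sorted(freqs)}")
        freqs["X"] = a * freqs[s1] + (1.0 - a) * freqs[s2]
    chrom, pos = _site_positions(config.genome, n)
    haplotypes = {
        name: (rng.random((n, config.n_haplotypes)) < freq[:, None]).astype(np.int8)
        for name, freq in freqs.items()
    }
    outgroup_state = (rng.random(n) < p_out).astype(np.int8)
    return GenotypePanel(
        chrom=chrom,
        pos=pos,
        haplotypes=haplotypes,
        outgroup_state=outgroup_state,
        frequencies=freqs,
    )


def simulate_allele_counts(config: SimConfig) -> AlleleCountMatrix:
    """Allele-count matrix for the drift-tree populations plus outgroup ``O``."""
    return simulate_genotype_panel(config).allele_counts()


# ----------------------------------------------------------------------
# divergent sequence pair
# ----------------------------------------------------------------------
def simulate_divergent_pair(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Two pseudo-haploid 0/1 site vectors differing at rate ``divergence_d``."""
    rng = config.rng("pair")
    a = (rng.random(config.n_sites) < 0.5).astype(np.int8)
    flip = rng.random(config.n_sites) < config.divergence_d
    b = np.where(flip, 1 - a, a).astype(np.int8)
    return a, b


# ----------------------------------------------------------------------
# text-format writers used by the CLI / pipeline
# ----------------------------------------------------------------------
def write_het_tracks(tracks: list[HetTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\thet\n")
        for tr in tracks:
            for (s, e), h in zip(tr.windows(), tr.het):
                fh.write(f"{tr.chrom}\t{s}\t{e}\t{h:.6e}\n")


def read_het_tracks(path: str | Path) -> list[HetTrack]:
    df = pd.read_csv(path, sep="\t")
    tracks = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        widths = (grp["end"] - grp["start"]).to_numpy()
        window_bp = int(widths[0]) if len(widths) else 0
        tracks.append(
            HetTrack(
                chrom=str(chrom),
                window_bp=window_bp,
                het=grp["het"].to_numpy(dtype=float),
                chrom_length_bp=int(grp["end"].max()),
            )
        )
    return tracks
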