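"""Runs of homozygosity from windowed heterozygosity tracks.

An RoH is a maximal run of consecutive windows whose heterozygosity falls
below a cutoff, kept when it spans at least ``min_consecutive`` windows and
at least ``min_length_bp`` of sequence. The genomic inbreeding proxy
``F_RoH`` is the fraction of the assayed genome inside such runs. Defaults
follow the field's convention for this system: 100-kb windows, cutoff
0.482e-3, two consecutive windows, 150-kbp minimum length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["HetTrack", "RoHSet", "call_rohs"]

DEFAULT_CUTOFF = 0.482e-3


@dataclass
class HetTrack:
    """Per-window heterozygosity along one chromosome.

    Windows are contiguous, ``window_bp`` wide, starting at 0; the final
    window may be partial (it ends at ``chrom_length_bp``).
    """

    chrom: str
    window_bp: int
    het: np.ndarray
    chrom_length_bp: int
    n_callable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.het = np.asarray(self.het, dtype=float)
        if (self.het < 0).any():
            raise ValueError("negative heterozygosity value")
        n_win = int(np.ceil(self.chrom_length_bp / self.window_bp)) if self.window_bp else 0
        if self.window_bp and len(self.het) != n_win:
            raise ValueError(
                f"{self.chrom}: {len(self.het)} windows but chromosome length "
                f"{self.chrom_length_bp} implies {n_win}"
            )

    def windows(self) -> np.ndarray:
        starts = np.arange(len(self.het), dtype=np.int64) * self.window_bp
        ends = np.minimum(starts + self.window_bp, self.chrom_length_bp)
        return np.stack([starts, ends], axis=1)


@dataclass
class RoHSet:
    """Called runs of homozygosity and the derived F_RoH."""

    rohs: pd.DataFrame  # chrom, start, end
    assayed_bp: int
    f_roh: float = field(init=False)

    def __post_init__(self) -> None:
        roh_bp = int((self.rohs["end"] - self.rohs["start"]).sum()) if len(self.rohs) else 0
        self.f_roh = roh_bp / self.assayed_bp if self.assayed_bp else float("nan")

    def write_bed(self, path: str | Path) -> None:
        self.rohs.to_csv(path, sep="\t", header=False, index=False)


def call_rohs(
    tracks: HetTrack | list[HetTrack],
    cutoff: float = DEFAULT_CUTOFF,
    min_consecutive: int = 2,
    min_length_bp: int = 150_000,
) -> RoHSet:
    """Call RoHs on one or several heterozygosity tracks.

    A run is every maximal stretch of consecutive windows with
    ``het < cutoff``; it becomes an RoH when it contains at least
    ``min_consecutive`` windows *and* spans at least ``min_length_bp``
    (window boundary to window boundary). With full ``min_consecutive``
    100-kb windows the length floor only binds for partial terminal windows.
    """
    if isinstance(tracks, HetTrack):
        tracks = [tracks]
    if not tracks or all(len(t.het) == 0 for t in tracks):
        raise ValueError("empty heterozygosity track")
    rows = []
    assayed = 0
    for tr in tracks:
        assayed += tr.chrom_length_bp
        low = tr.het < cutoff
        if not low.any():
            continue
        bounds = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
        win = tr.windows()
        for i0, i1 in zip(bounds[0::2], bounds[1::2]):  # [i0, i1) windows
            n_win = i1 - i0
            start, end = int(win[i0, 0]), int(win[i1 - 1, 1])
            if n_win >= min_consecutive and end - start >= min_length_bp:
                rows.append((tr.chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return RoHSet(rohs=df, assayed_bp=assayed)
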