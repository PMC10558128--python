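"""Phased local-ancestry tracts: data model, validation and I/O.

A :class:`TractSet` holds, for every haplotype of every individual, the
maximal same-ancestry segments that tile each chromosome. Coordinates are
0-based half-open (BED convention) everywhere; RFMix ``.msp.tsv`` physical
positions are converted on read. Exactly two ancestry source labels are
supported.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeMap

__all__ = [
    "TRACT_COLUMNS",
    "TractSet",
    "TractLengthSummary",
    "read_tracts",
    "global_ancestry_fraction",
    "tract_length_distribution",
]

TRACT_COLUMNS = ["chrom", "start", "end", "individual", "haplotype", "ancestry"]


def _merge_group(df: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent same-ancestry rows of one (individual, haplotype, chrom)."""
    df = df.sort_values("start", kind="stable")
    anc = df["ancestry"].to_numpy()
    new_run = np.ones(len(df), dtype=bool)
    new_run[1:] = anc[1:] != anc[:-1]
    run_id = np.cumsum(new_run)
    out = df.groupby(run_id, sort=True).agg(
        chrom=("chrom", "first"),
        start=("start", "min"),
        end=("end", "max"),
        individual=("individual", "first"),
        haplotype=("haplotype", "first"),
        ancestry=("ancestry", "first"),
    )
    return out.reset_index(drop=True)


class TractSet:
    """Ancestry tracts for a set of phased diploid individuals.

    Parameters
    ----------
    genome :
        Genome map the tracts live on.
    tracts :
        DataFrame with columns ``chrom, start, end, individual, haplotype,
        ancestry``. Adjacent same-ancestry tracts are merged on construction;
        the tiling invariant (sorted, non-overlapping, covering
        ``[0, chrom length)`` per haplotype) is enforced.
    labels :
        The two allowed ancestry source labels. Inferred from the data when
        omitted (at most two distinct labels).
    """

    def __init__(
        self,
        genome: GenomeMap,
        tracts: pd.DataFrame,
        labels: tuple[str, str] | None = None,
        validate: bool = True,
    ):
        missing = [c for c in TRACT_COLUMNS if c not in tracts.columns]
        if missing:
            raise ValueError(f"tract table missing columns: {missing}")
        df = tracts[TRACT_COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["haplotype"] = df["haplotype"].astype(np.int64)
        df["ancestry"] = df["ancestry"].astype(str)

        observed = sorted(df["ancestry"].unique())
        if labels is None:
            if len(observed) > 2:
                raise ValueError(f"more than two ancestry labels: {observed}")
            labels = tuple(observed) if len(observed) == 2 else (observed[0], observed[0])  # type: ignore[assignment]
            if len(observed) == 1:
                # degenerate single-label set keeps a one-element label pair
                labels = (observed[0],)  # type: ignore[assignment]
        else:
            unknown = set(observed) - set(labels)
            if unknown:
                raise ValueError(f"unknown ancestry label(s): {sorted(unknown)}")

        df = (
            df.groupby(["individual", "haplotype", "chrom"], sort=True, group_keys=False)[
                TRACT_COLUMNS
            ]
            .apply(_merge_group)
            .reset_index(drop=True)
        )
        self.genome = genome
        self.labels: tuple[str, ...] = tuple(labels)
        self.tracts = df
        if validate:
            self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        df = self.tracts
        if (df["start"] < 0).any():
            raise ValueError("negative tract start")
        if (df["start"] >= df["end"]).any():
            raise ValueError("empty or inverted tract (start >= end)")
        bad_hap = ~df["haplotype"].isin([0, 1])
        if bad_hap.any():
            raise ValueError("haplotype must be 0 or 1")
        for chrom in df["chrom"].unique():
            if chrom not in self.genome:
                raise ValueError(f"tract on chromosome {chrom!r} absent from genome map")
        for (ind, hap, chrom), grp in df.groupby(["individual", "haplotype", "chrom"]):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            length = self.genome[chrom].length_bp
            if starts[0] != 0 or ends[-1] != length:
                raise ValueError(
                    f"{ind}/hap{hap}/{chrom}: tracts do not span [0, {length})"
                )
            if (starts[1:] != ends[:-1]).any():
                raise ValueError(f"{ind}/hap{hap}/{chrom}: gap or overlap between tracts")

    # ------------------------------------------------------------------
    @property
    def individuals(self) -> list:
        return sorted(self.tracts["individual"].unique())

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.individuals)

    def haplotypes(self):
        """Iterate ``(individual, haplotype, chrom, edges_bp, is_label)`` lazily.

        ``edges_bp`` is the sorted array of segment boundaries (length k+1),
        ``ancestries`` the per-segment label array (length k).
        """
        for (ind, hap, chrom), grp in self.tracts.groupby(
            ["individual", "haplotype", "chrom"], sort=True
        ):
            starts = grp["start"].to_numpy()
            edges = np.append(starts, grp["end"].to_numpy()[-1])
            yield ind, hap, chrom, edges, grp["ancestry"].to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TractSet):
            return NotImplemented
        a = self.tracts.sort_values(TRACT_COLUMNS).reset_index(drop=True)
        b = other.tracts.sort_values(TRACT_COLUMNS).reset_index(drop=True)
        return self.genome == other.genome and a.equals(b)

    def __repr__(self) -> str:
        return (
            f"TractSet({len(self.individuals)} individuals, "
            f"{len(self.tracts)} tracts, labels={self.labels})"
        )

    # ------------------------------------------------------------------
    def write_bed(self, path: str | Path) -> None:
        """Write as BED-like TSV (chrom, start, end, individual, haplotype, ancestry)."""
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(TRACT_COLUMNS) + "\n")
            self.tracts.to_csv(fh, sep="\t", header=False, index=False)

    def write_msp(self, path: str | Path) -> None:
        """Write in the RFMix2 ``.msp.tsv`` dialect.

        One row per maximal span on which no haplotype changes ancestry;
        columns are per-haplotype integer codes into the subpopulation order.
        """
        code = {lab: i for i, lab in enumerate(self.labels)}
        hap_cols = [
            f"{ind}.{hap}" for ind in self.individuals for hap in (0, 1)
        ]
        with open(path, "w") as fh:
            fh.write(
                "#Subpopulation order/codes: "
                + "\t".join(f"{lab}={i}" for lab, i in code.items())
                + "\n"
            )
            fh.write(
                "#chm\tspos\tepos\tsgpos\tegpos\tn snps\t" + "\t".join(hap_cols) + "\n"
            )
            for chrom_name in self.genome.names:
                sub = self.tracts[self.tracts["chrom"] == chrom_name]
                if sub.empty:
                    continue
                cuts = np.unique(
                    np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()])
                )
                rate = self.genome[chrom_name].rate_cm_per_mb
                # per-haplotype arrays of (edges, codes) for fast lookup
                lookup = {}
                for (ind, hap), grp in sub.groupby(["individual", "haplotype"]):
                    grp = grp.sort_values("start")
                    lookup[(ind, hap)] = (
                        grp["start"].to_numpy(),
                        np.array([code[a] for a in grp["ancestry"]]),
                    )
                for s, e in zip(cuts[:-1], cuts[1:]):
                    row = [chrom_name, str(s), str(e)]
                    # genetic positions in cM
                    row.append(f"{s * rate / 1e6:.6f}")
                    row.append(f"{e * rate / 1e6:.6f}")
                    row.append("0")
                    for ind in self.individuals:
                        for hap in (0, 1):
                            starts, codes = lookup[(ind, hap)]
                            idx = np.searchsorted(starts, s, side="right") - 1
                            row.append(str(codes[idx]))
                    fh.write("\t".join(row) + "\n")


def read_tracts(
    path: str | Path,
    genome: GenomeMap,
    dialect: str = "bed_tsv",
    labels: tuple[str, str] | None = None,
) -> TractSet:
    """Read a tract file in either the BED-like TSV or RFMix ``.msp.tsv`` dialect.

    Adjacent same-ancestry spans are merged into maximal tracts; the tiling
    invariant is enforced (a gap or overlap is an error — there is no
    gap-filling policy).
    """
    if dialect == "bed_tsv":
        df = pd.read_csv(
            path,
            sep="\t",
            comment=None,
            names=TRACT_COLUMNS,
            skiprows=1,
            dtype={"chrom": str, "individual": str},
        )
        return TractSet(genome, df, labels=labels)
    if dialect == "rfmix_msp":
        return _read_msp(path, genome, labels)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_msp(
    path: str | Path, genome: GenomeMap, labels: tuple[str, str] | None
) -> TractSet:
    with open(path) as fh:
        subpop_line = fh.readline().rstrip("\n")
        prefix = "#Subpopulation order/codes: "
        if not subpop_line.startswith(prefix):
            raise ValueError("msp file must start with a '#Subpopulation order/codes:' line")
        code_to_label: dict[int, str] = {}
        for item in subpop_line[len(prefix):].split("\t"):
            lab, _, num = item.partition("=")
            code_to_label[int(num)] = lab
        if len(code_to_label) > 2:
            raise ValueError(
                f"only two ancestries supported, file declares {len(code_to_label)}"
            )
        header = fh.readline().rstrip("\n").split("\t")
        if header[:6] != ["#chm", "spos", "epos", "sgpos", "egpos", "n snps"]:
            raise ValueError("malformed msp column header")
        hap_cols = header[6:]
        body = pd.read_csv(fh, sep="\t", names=header)
    rows = []
    for col in hap_cols:
        ind, _, hap = col.rpartition(".")
        if hap not in ("0", "1"):
            raise ValueError(f"haplotype column {col!r} must end in .0 or .1")
        codes = body[col].to_numpy()
        unknown = set(np.unique(codes)) - set(code_to_label)
        if unknown:
            raise ValueError(f"unknown ancestry code(s) {sorted(unknown)} in column {col}")
        rows.append(
            pd.DataFrame(
                {
                    "chrom": body["#chm"].astype(str),
                    "start": body["spos"].astype(np.int64),
                    "end": body["epos"].astype(np.int64),
                    "individual": ind,
                    "haplotype": int(hap),
                    "ancestry": [code_to_label[c] for c in codes],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    if labels is None and len(code_to_label) == 2:
        labels = tuple(code_to_label[c] for c in sorted(code_to_label))  # type: ignore[assignment]
    return TractSet(genome, df, labels=labels)


# ----------------------------------------------------------------------
def global_ancestry_fraction(ts: TractSet, label: str) -> pd.Series:
    """Per-individual diploid genome fraction carrying ``label`` ancestry."""
    if label not in ts.labels:
        raise ValueError(f"unknown ancestry label {label!r} (labels: {ts.labels})")
    df = ts.tracts
    lengths = (df["end"] - df["start"]).to_numpy()
    total = 2 * ts.genome.total_bp
    hit = df.assign(length=np.where(df["ancestry"] == label, lengths, 0))
    frac = hit.groupby("individual")["length"].sum() / total
    frac.name = f"f_{label}"
    return frac


class TractLengthSummary:
    """Lengths of the tracts of one ancestry, in bp and morgans, with summaries."""

    def __init__(self, ts: TractSet, label: str):
        if label not in ts.labels:
            raise ValueError(f"unknown ancestry label {label!r}")
        sub = ts.tracts[ts.tracts["ancestry"] == label]
        self.label = label
        self.lengths_bp = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        rates = np.array(
            [ts.genome[c].rate_morgan_per_bp for c in sub["chrom"]], dtype=float
        )
        self.lengths_morgans = self.lengths_bp * rates
        self.chrom = sub["chrom"].to_numpy()
        self.count = len(sub)
        self.mean_bp = float(self.lengths_bp.mean()) if self.count else float("nan")
        self.mean_morgans = (
            float(self.lengths_morgans.mean()) if self.count else float("nan")
        )

    def per_chromosome(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "length_bp": self.lengths_bp})
        return (
            df.groupby("chrom")["length_bp"]
            .agg(mean="mean", count="count")
            .reset_index()
        )

    def histogram(self, bins: int | Sequence[float] = 30) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.lengths_bp, bins=bins)


def tract_length_distribution(
    ts: TractSet, label: str, per_chromosome: bool = False
):
    """Tract lengths for ``label`` with pooled and optional per-chromosome means.

    An empty label yields a summary with ``count == 0`` and NaN means rather
    than an error.
    """
    summary = TractLengthSummary(ts, label)
    if per_chromosome:
        return summary, summary.per_chromosome()
    return summary
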