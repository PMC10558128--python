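"""Pipeline orchestration: staged runs, manifests, and reporting.

A run executes a validated subset of stages in dependency order, writes
text outputs (JSON estimates, TSV tables, BED tracts/RoHs) plus a
``manifest.json`` recording the config snapshot, master seed, package
version, per-stage timings and the SHA-256 digest of every output file.
All stage randomness derives from the master seed via fixed sub-streams,
so stochastic-stage outputs are byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dating import (
    AncestryDecayDating,
    TractLengthDating,
    combine_ci,
    generations_to_years,
)
from .diversity import folded_sfs, nucleotide_diversity, tajimas_d, windowed_stats
from .fstats import d_statistic, f3, f4_ratio
from .genome import GenomeMap, read_genome_map, uniform_genome
from .mutation import estimate_mutation_rate, pairwise_divergence
from .roh import call_rohs
from .simulate import (
    SimConfig,
    read_het_tracks,
    simulate_admixed_tracts,
    simulate_divergent_pair,
    simulate_genotype_panel,
    simulate_het_track,
    write_het_tracks,
)
from .tracts import read_tracts

__all__ = ["run_pipeline", "report", "KNOWN_STAGES"]

log = logging.getLogger("tractdate")

KNOWN_STAGES = (
    "simulate",
    "date_tracts",
    "date_decay",
    "roh",
    "diversity",
    "fstats",
    "mutation_rate",
)

_STAGE_SEEDS = {name: i for i, name in enumerate(KNOWN_STAGES)}


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(100 + _STAGE_SEEDS[stage],))
    return int(ss.generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _validate_config(config: dict) -> dict:
    if "stages" not in config or not isinstance(config["stages"], list):
        raise ValueError("config must declare a 'stages' list")
    unknown = [s for s in config["stages"] if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stage name(s): {unknown} (known: {list(KNOWN_STAGES)})")
    if "seed" not in config:
        raise ValueError("config must declare a master 'seed'")
    needs_tracts = {"date_tracts", "date_decay"} & set(config["stages"])
    if needs_tracts and "simulate" not in config["stages"]:
        inputs = config.get("inputs", {})
        for key in ("tracts", "genome_map"):
            if key not in inputs:
                raise ValueError(
                    f"dating stages need inputs.{key} when 'simulate' is not run"
                )
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(f"missing input file: {inputs[key]}")
    return config


def _sim_config(config: dict, master_seed: int) -> SimConfig:
    sim = dict(config.get("simulate") or {})
    genome = uniform_genome(
        n_chromosomes=int(sim.pop("n_chromosomes", 24)),
        chrom_length_bp=int(sim.pop("chrom_length_bp", 50_000_000)),
        rate_cm_per_mb=float(sim.pop("rate_cm_per_mb", 1.63)),
    )
    for key in ("pulse_times", "minor_fractions", "low_het_segments"):
        if key in sim:
            sim[key] = tuple(tuple(x) if isinstance(x, list) else x for x in sim[key]) \
                if key == "low_het_segments" else tuple(sim[key])
    return SimConfig(seed=_stage_seed(master_seed, "simulate"), genome=genome, **sim)


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the configured stages; return the manifest (also written to disk)."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = _validate_config(config)
    seed = int(config["seed"])
    outdir = Path(outdir or config.get("outdir", "tractdate_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    gen_time = float(config.get("generation_time", 14.2))
    minor = config.get("minor_ancestry", "naumanni")

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
        "outputs": {},
    }
    outputs = manifest["outputs"]
    state: dict = {}

    def _finish(stage: str, t0: float, paths: list[Path]) -> None:
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        for p in paths:
            outputs[str(p.relative_to(outdir))] = _sha256(p)
        log.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)

    # --- inputs when not simulating ------------------------------------
    if "simulate" not in stages and {"date_tracts", "date_decay"} & set(stages):
        inputs = config["inputs"]
        genome = read_genome_map(inputs["genome_map"])
        state["tracts"] = read_tracts(
            inputs["tracts"], genome, dialect=inputs.get("dialect", "bed_tsv")
        )
        if "het" in inputs:
            state["het"] = read_het_tracks(inputs["het"])

    for stage in stages:
        t0 = time.perf_counter()
        if stage == "simulate":
            sim = _sim_config(config, seed)
            state["sim"] = sim
            state["tracts"] = simulate_admixed_tracts(sim)
            state["het"] = simulate_het_track(sim)
            state["panel"] = simulate_genotype_panel(sim)
            state["pair"] = simulate_divergent_pair(sim)
            paths = []
            p = outdir / "genome_map.tsv"; sim.genome.to_tsv(p); paths.append(p)
            p = outdir / "tracts.bed.tsv"; state["tracts"].write_bed(p); paths.append(p)
            p = outdir / "tracts.msp.tsv"; state["tracts"].write_msp(p); paths.append(p)
            p = outdir / "het_track.tsv"; write_het_tracks(state["het"], p); paths.append(p)
            p = outdir / "allele_counts.tsv"
            state["panel"].allele_counts().to_tsv(p); paths.append(p)
            _finish(stage, t0, paths)
        elif stage == "date_tracts":
            opts = config.get("date_tracts") or {}
            est = TractLengthDating(
                state["tracts"], opts.get("minor", minor),
                unit=opts.get("unit", "chromosome"),
            ).fit(
                n_boot=int(opts.get("n_boot", 10_000)),
                seed=_stage_seed(seed, stage),
            )
            state["est_tracts"] = est
            p = outdir / "date_tracts.json"
            p.write_text(json.dumps(est.to_dict(), indent=2, sort_keys=True))
            _finish(stage, t0, [p])
        elif stage == "date_decay":
            opts = config.get("date_decay") or {}
            est = AncestryDecayDating(
                state["tracts"], opts.get("minor", minor),
                max_dist=float(opts.get("max_dist", 0.3)),
                n_bins=int(opts.get("n_bins", 25)),
                n_pairs=int(opts.get("n_pairs", 150)),
            ).fit(
                model=opts.get("model", "auto"),
                n_boot=int(opts.get("n_boot", 100)),
                seed=_stage_seed(seed, stage),
            )
            state["est_decay"] = est
            p = outdir / "date_decay.json"
            p.write_text(json.dumps(est.to_dict(), indent=2, sort_keys=True))
            _finish(stage, t0, [p])
        elif stage == "roh":
            opts = config.get("roh") or {}
            rohs = call_rohs(
                state["het"],
                cutoff=float(opts.get("cutoff", 0.482e-3)),
                min_consecutive=int(opts.get("min_consecutive", 2)),
                min_length_bp=int(opts.get("min_length_bp", 150_000)),
            )
            p1 = outdir / "rohs.bed"
            rohs.write_bed(p1)
            p2 = outdir / "f_roh.tsv"
            p2.write_text(f"f_roh\tassayed_bp\n{rohs.f_roh:.6g}\t{rohs.assayed_bp}\n")
            state["rohs"] = rohs
            _finish(stage, t0, [p1, p2])
        elif stage == "diversity":
            panel = state["panel"]
            opts = config.get("diversity") or {}
            rows = []
            for pop in sorted(panel.haplotypes):
                sfs = folded_sfs(panel.genotypes(pop))
                row = {"pop": pop, "pi": nucleotide_diversity(sfs)}
                try:
                    row["tajimas_d"] = tajimas_d(sfs)
                except ValueError:
                    row["tajimas_d"] = float("nan")
                rows.append(row)
            import pandas as pd

            p = outdir / "diversity.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            state["diversity"] = rows
            _finish(stage, t0, [p])
        elif stage == "fstats":
            panel = state["panel"]
            acm = panel.allele_counts()
            opts = config.get("fstats") or {}
            block = float(opts.get("block_size_bp", 5e6))
            res = {}
            if "X" in acm.pops:
                res["f3"] = vars(
                    f3(acm, "X", "P2", "P3", block_size_bp=block, correction=True)
                )
                res["d"] = vars(d_statistic(acm, "P1", "X", "P3", "O", block_size_bp=block))
                res["f4_ratio"] = vars(
                    f4_ratio(acm, "P1", "O", "X", "P3", "P2", block_size_bp=block)
                )
            res["d_null"] = vars(d_statistic(acm, "P1", "P2", "P3", "O", block_size_bp=block))
            p = outdir / "fstats.json"
            p.write_text(json.dumps(res, indent=2, sort_keys=True))
            state["fstats"] = res
            _finish(stage, t0, [p])
        elif stage == "mutation_rate":
            opts = config.get("mutation_rate") or {}
            a, b = state["pair"]
            d_ibs = pairwise_divergence(a, b)
            est = estimate_mutation_rate(
                {"polymorphic_fraction": d_ibs, "ibs_distance": d_ibs},
                t_div_years=float(opts.get("t_div_years", 34e6)),
                generation_time=float(opts.get("generation_time", gen_time)),
            )
            p = outdir / "mutation_rate.json"
            p.write_text(json.dumps(vars(est), indent=2, sort_keys=True))
            state["mutation_rate"] = est
            _finish(stage, t0, [p])

    if "est_tracts" in state and "est_decay" in state:
        lo, hi = combine_ci(state["est_tracts"], state["est_decay"], gen_time)
        p = outdir / "combined_span.json"
        p.write_text(json.dumps({"years_low": lo, "years_high": hi}, sort_keys=True))
        outputs[str(p.relative_to(outdir))] = _sha256(p)

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def report(manifest_path: str | Path, generation_time: float = 14.2) -> str:
    """Human-readable summary of a pipeline run from its manifest."""
    mpath = Path(manifest_path)
    try:
        manifest = json.loads(mpath.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read manifest {manifest_path}: {exc}") from exc
    if not manifest.get("outputs"):
        raise ValueError("manifest lists no outputs")
    outdir = mpath.parent
    lines = [f"tractdate run (version {manifest['version']}, seed {manifest['seed']})", ""]
    for name in ("date_tracts.json", "date_decay.json"):
        path = outdir / name
        if str(name) in manifest["outputs"] and path.exists():
            est = json.loads(path.read_text())
            yrs = generations_to_years(est["t_generations"], generation_time).years
            lines.append(
                f"{est['method']}: onset {est['t_generations']:.1f} generations "
                f"({yrs} years), CI{int(est['ci_level'] * 100)}% "
                f"[{est['ci_low']:.1f}, {est['ci_high']:.1f}] generations"
            )
    combined = outdir / "combined_span.json"
    if combined.exists():
        span = json.loads(combined.read_text())
        lines.append(
            f"combined CI span: {span['years_low']} to {span['years_high']} years ago"
        )
    froh = outdir / "f_roh.tsv"
    if froh.exists():
        lines.append("")
        lines.append(froh.read_text().strip())
    div = outdir / "diversity.tsv"
    if div.exists():
        lines.append("")
        lines.append(div.read_text().strip())
    fst = outdir / "fstats.json"
    if fst.exists():
        stats = json.loads(fst.read_text())
        lines.append("")
        for key, res in sorted(stats.items()):
            lines.append(
                f"{key}: {res['value']:.4g} (Z = {res['z']:.2f}, "
                f"{res['n_sites_used']} sites)"
            )
    mut = outdir / "mutation_rate.json"
    if mut.exists():
        est = json.loads(mut.read_text())
        lines.append("")
        lines.append(f"mutation rate (combined mean): {est['combined_mean']:.4g} /generation")
    return "\n".join(lines)
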