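"""One-config orchestration of the full analysis.

Stage order: collapse -> diversity -> differentiation -> structure ->
samova -> network -> demography -> barcode. Each stage writes
self-describing JSON/TSV artifacts into the output directory and can be
re-run in isolation. All randomness is funneled through one master seed,
expanded deterministically per stage.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import barcode as bc
from . import demography as dem
from . import haplotypes as hap
from . import structure as struct
from .distances import distance_matrix
from .errors import InputError
from .io import (
    read_fasta_alignment,
    read_population_map,
    site_summary,
    write_json,
)
from .network import median_joining

log = logging.getLogger("phylopop.pipeline")

ALL_STAGES = (
    "collapse",
    "diversity",
    "differentiation",
    "structure",
    "samova",
    "network",
    "demography",
    "barcode",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([master_seed, ALL_STAGES.index(stage)])
    return int(ss.generate_state(1)[0])


@dataclass
class PipelineConfig:
    alignment: str
    population_map: str
    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    n_perm: int = 1000
    n_sim: int = 1000
    n_boot: int = 200
    n_reps: int = 500
    samova_k: int = 2
    samova_restarts: int = 20
    mu: float = 1.15e-8
    k_sites: int | None = None
    generation_time: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise InputError("pipeline config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def run_full_analysis(config: PipelineConfig | str | Path) -> Path:
    """Run the configured stages; returns the output directory."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln = read_fasta_alignment(config.alignment)
    pm = read_population_map(config.population_map)
    pm.validate_against(aln)
    run_log = {
        "seed": config.seed,
        "stages": list(config.stages),
        "alignment": str(config.alignment),
        "population_map": str(config.population_map),
        "n_sequences": aln.n,
        "alignment_length": aln.length,
    }

    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise InputError(f"unknown stage: {stage!r}")

    cat = None
    if set(config.stages) & {
        "collapse", "diversity", "differentiation", "network"
    }:
        cat = hap.collapse_haplotypes(aln, pm)

    for stage in config.stages:
        seed = stage_seed(config.seed, stage)
        log.info("stage %s (seed %d)", stage, seed)
        try:
            if stage == "collapse":
                write_json(cat, outdir / "haplotypes.json")
                cat.write_tsv(outdir / "haplotype_counts.tsv")
                cat.write_fasta(outdir / "haplotypes.fasta")
                write_json(site_summary(aln), outdir / "site_summary.json")
            elif stage == "diversity":
                table = hap.diversity_table(cat, aln, pm)
                write_json(table, outdir / "diversity.json")
            elif stage == "differentiation":
                diff = hap.gst_nst(
                    cat, n_perm=config.n_perm, seed=seed
                )
                write_json(diff, outdir / "differentiation.json")
            elif stage == "structure":
                dm_raw = distance_matrix(aln, metric="raw")
                res = struct.amova(
                    dm_raw, pm, n_perm=config.n_perm, seed=seed
                )
                write_json(res, outdir / "amova.json")
                res.write_tsv(outdir / "amova.tsv")
                pf = struct.pairwise_fst(
                    dm_raw, pm, n_perm=min(config.n_perm, 199), seed=seed
                )
                write_json(pf, outdir / "pairwise_fst.json")
            elif stage == "samova":
                dm_raw = distance_matrix(aln, metric="raw")
                res = struct.samova(
                    dm_raw,
                    pm,
                    k=config.samova_k,
                    n_restarts=config.samova_restarts,
                    seed=seed,
                )
                write_json(res, outdir / "samova.json")
            elif stage == "network":
                net = median_joining(cat)
                write_json(net, outdir / "network.json")
                net.write_edges_tsv(outdir / "network_edges.tsv")
            elif stage == "demography":
                stats = dem.neutrality_tests(
                    aln, n_sim=config.n_sim, seed=seed
                )
                hist = dem.mismatch_observed(aln)
                fit = dem.fit_sudden_expansion(
                    hist, n_boot=config.n_boot, seed=seed, n_sequences=aln.n
                )
                k_sites = config.k_sites or aln.length
                times = dem.expansion_time(
                    fit.tau, config.mu, k_sites, config.generation_time
                )
                write_json(
                    {
                        "neutrality": stats.to_dict(),
                        "mismatch_fit": fit.to_dict(),
                        "expansion_time": times.to_dict(),
                    },
                    outdir / "demography.json",
                )
            elif stage == "barcode":
                dm = distance_matrix(aln, metric="k2p")
                gap = bc.barcoding_gap(dm, pm)
                write_json(gap, outdir / "barcoding_gap.json")
                report = bc.loo_success(
                    aln,
                    pm,
                    method="md",
                    n_reps=config.n_reps,
                    seed=seed,
                )
                write_json(report, outdir / "identification_md.json")
                report_bcm = bc.loo_success(
                    aln,
                    pm,
                    method="bcm",
                    n_reps=config.n_reps,
                    seed=seed,
                )
                write_json(report_bcm, outdir / "identification_bcm.json")
        except Exception as exc:
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n"
    )
    return outdir
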