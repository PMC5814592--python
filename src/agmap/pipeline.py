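"""End-to-end pipeline: simulate -> QC -> map -> homoeology -> introgression.

Every stage writes its artifacts to the output directory; a JSON
manifest records the tool version, the parameter hash, the seed and the
SHA-256 of every artifact, so a rerun with identical inputs and
configuration is byte-identical and verifiably so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .homoeology import HomoeologyAssigner
from .introgression import IntrogressionCaller
from .io import params_hash, read_genotype_matrix, write_genotype_matrix, write_table
from .mapping import LinkageMapper
from .qc import MarkerQC
from .simulate import (
    SimCrossConfig,
    default_map_truth,
    default_wheat_marker_map,
    reference_panel_specs,
    simulate_cp_cross,
    simulate_hit_table,
    simulate_introgression_lines,
)

log = logging.getLogger("agmap")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters with their validated defaults."""

    seed: int = 0
    # synthetic data
    n_progeny: int = 119
    markers_per_chromosome: int = 100
    genotyping_error_rate: float = 0.01
    missing_rate: float = 0.15
    distorted_fraction: float = 0.0
    distortion_strength: float = 0.2
    hit_noise_rate: float = 0.02
    # qc
    call_rate_threshold: float = 0.8
    data_tolerance: float = 0.001
    missing_limit: float = 0.2
    # mapping
    lod_limit: float = 11.0
    min_group_size: int = 15
    n_iterations: int = 40
    map_error_rate: float = 0.01
    min_informative: int = 20
    # homoeology
    e_cutoff: float = 1e-5
    ambiguity_ratio: float = 0.5
    min_block: int = 5
    max_rank_gap: int = 3
    target_bp: float = 500e6
    # introgression
    window_mb: float = 50.0
    step_mb: float = 1.0
    het_z_min: float = 5.0
    missing_z_min: float = 5.0

    def __post_init__(self):
        checks = {
            "n_progeny": self.n_progeny >= 2,
            "markers_per_chromosome": self.markers_per_chromosome >= 2,
            "genotyping_error_rate": 0 <= self.genotyping_error_rate < 1,
            "missing_rate": 0 <= self.missing_rate < 1,
            "distorted_fraction": 0 <= self.distorted_fraction < 1,
            "hit_noise_rate": 0 <= self.hit_noise_rate < 1,
            "call_rate_threshold": 0 < self.call_rate_threshold <= 1,
            "data_tolerance": 0 <= self.data_tolerance < 1,
            "missing_limit": 0 <= self.missing_limit <= 1,
            "lod_limit": self.lod_limit > 0,
            "min_group_size": self.min_group_size >= 1,
            "n_iterations": self.n_iterations >= 1,
            "map_error_rate": 0 <= self.map_error_rate < 0.5,
            "e_cutoff": self.e_cutoff > 0,
            "ambiguity_ratio": 0 < self.ambiguity_ratio <= 1,
            "window_mb": self.window_mb > self.step_mb > 0,
            "het_z_min": self.het_z_min > 0,
            "missing_z_min": self.missing_z_min > 0,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid pipeline configuration: {bad}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir, stages=("simulate", "qc", "map", "homoeology", "introgress")) -> dict:
    """Run the requested stages in order; returns the manifest dict.

    ``simulate`` writes the synthetic inputs; later stages read their
    inputs from ``outdir``, so the pipeline can also run on externally
    provided files in the same layout.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phash = params_hash(config.as_dict())
    artifacts: list[Path] = []
    rng_seed = np.random.SeedSequence(config.seed)
    child = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in zip(
        ("truth", "cross", "hits", "lines"), rng_seed.spawn(4)
    )}

    if "simulate" in stages:
        log.info("stage simulate: seed=%d", config.seed)
        truth = default_map_truth(
            n_markers_per_chromosome=config.markers_per_chromosome,
            distorted_fraction=config.distorted_fraction,
            seed=child["truth"],
        )
        gm, sim_truth = simulate_cp_cross(
            truth,
            SimCrossConfig(
                n_progeny=config.n_progeny,
                genotyping_error_rate=config.genotyping_error_rate,
                missing_rate=config.missing_rate,
                distorted_fraction=config.distorted_fraction,
                distortion_strength=config.distortion_strength,
                seed=child["cross"],
            ),
        )
        hits, hit_truth = simulate_hit_table(
            truth, noise_rate=config.hit_noise_rate, seed=child["hits"]
        )
        marker_map = default_wheat_marker_map(seed=child["lines"])
        specs = reference_panel_specs()
        lines, line_truth = simulate_introgression_lines(
            specs, marker_map, seed=child["lines"]
        )
        write_genotype_matrix(gm, outdir / "cp_genotypes.tsv", phash)
        write_table(hits, outdir / "hits.tsv", phash)
        write_table(hit_truth, outdir / "hit_truth.tsv", phash)
        write_genotype_matrix(lines, outdir / "line_genotypes.tsv", phash)
        write_table(marker_map, outdir / "wheat_marker_map.tsv", phash)
        write_table(line_truth, outdir / "line_truth.tsv", phash)
        truth_json = {
            "chromosomes": [{"name": c.name, "length_cM": c.length_cM} for c in truth.chromosomes],
            "markers": [
                {
                    "id": m.id, "chromosome": m.chromosome, "true_cM": m.true_cM,
                    "pattern": m.pattern, "distorted": m.distorted,
                }
                for m in truth.markers
            ],
        }
        (outdir / "map_truth.json").write_text(json.dumps(truth_json, indent=1))
        artifacts += [
            outdir / p
            for p in (
                "cp_genotypes.tsv", "hits.tsv", "hit_truth.tsv",
                "line_genotypes.tsv", "wheat_marker_map.tsv", "line_truth.tsv",
                "map_truth.json",
            )
        ]

    qc = mapper = assigner = None
    if "qc" in stages:
        gm = read_genotype_matrix(outdir / "cp_genotypes.tsv")
        qc = MarkerQC(
            call_rate_threshold=config.call_rate_threshold,
            data_tolerance=config.data_tolerance,
            missing_limit=config.missing_limit,
        ).fit(gm)
        log.info("stage qc: %s", dict(qc.attrition_))
        write_table(qc.table_.reset_index(), outdir / "marker_qc.tsv", phash)
        write_table(
            qc.attrition_.rename_axis("reason").reset_index(name="count"),
            outdir / "qc_attrition.tsv",
            phash,
        )
        artifacts += [outdir / "marker_qc.tsv", outdir / "qc_attrition.tsv"]

    if "map" in stages:
        gm = read_genotype_matrix(outdir / "cp_genotypes.tsv")
        if qc is None:
            qc = MarkerQC(
                call_rate_threshold=config.call_rate_threshold,
                data_tolerance=config.data_tolerance,
                missing_limit=config.missing_limit,
            ).fit(gm)
        mapper = LinkageMapper(
            lod_limit=config.lod_limit,
            min_group_size=config.min_group_size,
            n_iterations=config.n_iterations,
            error_rate=config.map_error_rate,
            min_informative=config.min_informative,
        ).fit(gm, qc_table=qc.table_)
        log.info("stage map: %d linkage groups", len(mapper.groups_))
        for origin, gmap in mapper.maps_.items():
            write_table(gmap.table, outdir / f"map_{origin}.tsv", phash)
            artifacts.append(outdir / f"map_{origin}.tsv")
        write_table(mapper.summary_, outdir / "map_summary.tsv", phash)
        artifacts.append(outdir / "map_summary.tsv")

    if "homoeology" in stages:
        if mapper is None:
            raise RuntimeError("homoeology stage needs the map stage in the same run")
        hits_path = outdir / "hits.tsv"
        if not hits_path.exists():
            raise FileNotFoundError(f"homoeology stage requires a hit table at {hits_path}")
        hits = pd.read_csv(hits_path, sep="\t", comment="#")
        assigner = HomoeologyAssigner(
            e_cutoff=config.e_cutoff,
            ambiguity_ratio=config.ambiguity_ratio,
            min_block=config.min_block,
            max_rank_gap=config.max_rank_gap,
            target_bp=config.target_bp,
        ).fit(mapper.maps_["integrated"], hits)
        log.info(
            "stage homoeology: %s",
            dict(zip(assigner.assignments_["lg"], assigner.assignments_["assigned_P"])),
        )
        write_table(assigner.assignments_, outdir / "homoeology_assignments.tsv", phash)
        write_table(assigner.blocks_, outdir / "synteny_blocks.tsv", phash)
        write_table(assigner.rearrangements_, outdir / "rearrangements.tsv", phash)
        write_table(assigner.small_fragments_, outdir / "small_fragments.tsv", phash)
        write_table(assigner.scaled_map_, outdir / "map_scaled_bp.tsv", phash)
        artifacts += [
            outdir / p
            for p in (
                "homoeology_assignments.tsv", "synteny_blocks.tsv",
                "rearrangements.tsv", "small_fragments.tsv", "map_scaled_bp.tsv",
            )
        ]

    if "introgress" in stages:
        lines = read_genotype_matrix(outdir / "line_genotypes.tsv")
        marker_map = pd.read_csv(outdir / "wheat_marker_map.tsv", sep="\t", comment="#")
        group_to_p = assigner.group_to_p() if assigner is not None else None
        expected = None
        truth_path = outdir / "line_truth.tsv"
        if truth_path.exists():
            lt = pd.read_csv(truth_path, sep="\t", comment="#")
            expected = dict(zip(lt["line_id"], lt["expected_alien_count"]))
        caller = IntrogressionCaller(
            window_mb=config.window_mb,
            step_mb=config.step_mb,
            het_z_min=config.het_z_min,
            missing_z_min=config.missing_z_min,
        ).fit(group_to_p)
        report = caller.predict(lines, marker_map, expected)
        log.info("stage introgress: %d lines called", len(report))
        write_table(report, outdir / "introgression_report.tsv", phash)
        tracks = pd.concat(
            [t.windows.assign(line_id=lid) for lid, t in caller.tracks_.items()],
            ignore_index=True,
        )
        write_table(tracks, outdir / "window_tracks.tsv", phash)
        chrom_tracks = pd.concat(
            [t.chromosomes.assign(line_id=lid) for lid, t in caller.tracks_.items()],
            ignore_index=True,
        )
        write_table(chrom_tracks, outdir / "chromosome_tracks.tsv", phash)
        artifacts += [
            outdir / "introgression_report.tsv",
            outdir / "window_tracks.tsv",
            outdir / "chromosome_tracks.tsv",
        ]

    manifest = {
        "tool": "agmap",
        "version": __version__,
        "seed": config.seed,
        "params_hash": phash,
        "parameters": config.as_dict(),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
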