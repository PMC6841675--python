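"""End-to-end pipeline orchestration.

A :class:`PipelineConfig` (JSON on disk) names the stages to run, their
parameters and one seed per stochastic stage.  :func:`run_pipeline`
executes the stages in dependency order, writes every output under the
configured directory and returns a manifest mapping each output file to
its SHA-256 hash; re-running the same config reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import intervals as iv
from . import io as sio
from . import radial as rq
from .errors import SamQuantError, ValidationError
from .geometry import estimate_center
from .synthetic import IntervalWorldSpec, SamSpec, generate_interval_world, generate_sam

logger = logging.getLogger("samquant")

_STAGES = ("simulate_sam", "fit_center", "radial", "simulate_intervals", "interval_postprocess")


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips losslessly through JSON."""

    out_dir: str
    stages: tuple = _STAGES
    sam: dict = field(default_factory=dict)  # SamSpec overrides
    interval_world: dict = field(default_factory=dict)  # IntervalWorldSpec overrides
    profile: dict = field(default_factory=dict)  # ProfileConfig overrides
    annotation: dict = field(default_factory=dict)  # AnnotationConfig overrides
    seeds: dict = field(default_factory=lambda: {"sam": 0, "intervals": 0, "bootstrap": 0})
    cells_path: str | None = None  # external inputs when not simulating
    grid_path: str | None = None
    seeds_path: str | None = None  # 3-row TSV of primordium seed points
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["stages"] = tuple(d.get("stages", _STAGES))
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(sio.read_json(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


class _Stage:
    """Collects the files a stage writes so failures can be cleaned up."""

    def __init__(self, name: str, out_dir: Path):
        self.name = name
        self.out_dir = out_dir
        self.files: list[Path] = []

    def path(self, filename: str) -> Path:
        p = self.out_dir / filename
        self.files.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.files:
            p.unlink(missing_ok=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns (and writes) the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="[samquant %(levelname)s] %(message)s")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seeds": dict(config.seeds),
        "stages": {},
    }
    state: dict = {}
    for stage_name in config.stages:
        if stage_name not in _STAGES:
            raise ValidationError(f"unknown stage {stage_name!r}; valid: {_STAGES}")
        stage = _Stage(stage_name, out_dir)
        logger.info("stage %s", stage_name)
        try:
            _run_stage(stage, config, state)
        except Exception as exc:
            stage.cleanup()
            raise SamQuantError(f"stage {stage_name}: {exc}") from exc
        manifest["stages"][stage_name] = {
            p.name: _sha256(p) for p in stage.files if p.exists()
        }
    manifest_path = out_dir / "manifest.json"
    sio.write_json(manifest, manifest_path)
    return manifest


def _run_stage(stage: _Stage, config: PipelineConfig, state: dict) -> None:
    if stage.name == "simulate_sam":
        spec = SamSpec(**{**config.sam, "seed": config.seeds.get("sam", 0)})
        table, grid, truth = generate_sam(spec)
        sio.write_nucleus_table(table, stage.path("cells.tsv"))
        sio.write_grid(grid, stage.path("grid.tsv"))
        sio.write_json(truth.to_dict(), stage.path("sam_ground_truth.json"))
        state.update(cells=table, grid=grid, sam_truth=truth)

    elif stage.name == "fit_center":
        cells = state.get("cells")
        if cells is None:
            if config.cells_path is None:
                raise ValidationError("no cells available: simulate_sam not run and no cells_path")
            cells = sio.read_nucleus_table(config.cells_path)
        if "sam_truth" in state:
            seeds = np.array(state["sam_truth"].primordium_seeds)
        elif config.seeds_path is not None:
            seeds = np.loadtxt(config.seeds_path, ndmin=2)
        else:
            raise ValidationError("no primordium seeds: provide seeds_path or run simulate_sam")
        fit, center = estimate_center(cells, seeds)
        report = {
            "center": list(map(float, fit.center)),
            "rad_sphere": fit.radius,
            "rms_residual": fit.rms_residual,
            "n_points_used": fit.n_points,
            "p_center": list(map(float, center.p_center)),
            "axis_direction": list(map(float, center.axis_direction)),
            "candidate_discarded": list(map(float, center.candidate_discarded)),
        }
        sio.write_json(report, stage.path("center_report.json"))
        state.update(fit=fit, center=center, cells=cells)

    elif stage.name == "radial":
        for key in ("fit", "center"):
            if key not in state:
                raise ValidationError("fit_center must run before the radial stage")
        grid = state.get("grid")
        if grid is None:
            if config.grid_path is None:
                raise ValidationError("no grid available: simulate_sam not run and no grid_path")
            grid = sio.read_grid(config.grid_path)
        cfg = rq.ProfileConfig(**config.profile)
        center2d = state["center"].p_center[:2]
        profile = rq.cross_section_profiles(grid, center2d, cfg)
        prof_df = _profile_frame(profile)
        prof_df.to_csv(stage.path("radial_profile.tsv"), sep="\t", index=False)
        thr = rq.threshold_distance(profile, cfg)
        gated = rq.gate_stem_cells(state["cells"], state["fit"], state["center"].axis, cfg)
        gated.to_csv(stage.path("cell_records.tsv"), sep="\t", index=False)
        sio.write_json(
            {
                "threshold_distance_um": thr.distance,
                "censored": thr.censored,
                "central_mean": rq.central_mean(profile, cfg),
                "n_stem_cells": int(gated["is_stem_cell"].sum()),
            },
            stage.path("radial_stats.json"),
        )

    elif stage.name == "simulate_intervals":
        spec = IntervalWorldSpec(
            **{**config.interval_world, "seed": config.seeds.get("intervals", 0)}
        )
        genes, binding, up, down, open_chrom, truth = generate_interval_world(spec)
        sio.write_gff3(genes, stage.path("genes.gff3"))
        sio.write_bed(binding, stage.path("binding.bed"))
        sio.write_bed(up, stage.path("acet_up.bed"))
        sio.write_bed(down, stage.path("acet_down.bed"))
        sio.write_bed(open_chrom, stage.path("open_chromatin.bed"))
        sio.write_json(truth.to_dict(), stage.path("interval_ground_truth.json"))
        state.update(genes=genes, binding=binding, acet_up=up, acet_down=down,
                     open_chrom=open_chrom, interval_truth=truth)

    elif stage.name == "interval_postprocess":
        for key in ("genes", "binding", "acet_up", "acet_down"):
            if key not in state:
                raise ValidationError("simulate_intervals must run before interval_postprocess")
        cfg = iv.AnnotationConfig(**config.annotation)
        binding = iv.reduce_intervals(iv.filter_posterior(state["binding"]))
        up = iv.reduce_intervals(iv.filter_posterior(state["acet_up"]))
        down = iv.reduce_intervals(iv.filter_posterior(state["acet_down"]))
        up_kept, down_kept, removed = iv.conflict_filter(up, down)
        sio.write_bed(binding, stage.path("binding.reduced.bed"))
        sio.write_bed(up_kept, stage.path("acet_up.filtered.bed"))
        sio.write_bed(down_kept, stage.path("acet_down.filtered.bed"))
        sio.write_bed(removed, stage.path("conflicts.removed.bed"))
        ann = iv.annotate(binding, state["genes"], cfg)
        ann.to_csv(stage.path("binding.annotated.tsv"), sep="\t", index=False)
        venn = iv.overlap_sets(binding, up_kept, down_kept,
                               names=("binding", "acet_up", "acet_down"))
        meta = iv.tss_metaprofile(
            binding, state["genes"], seed=config.seeds.get("bootstrap", 0)
        )
        meta_df = _metaprofile_frame(meta)
        meta_df.to_csv(stage.path("tss_metaprofile.tsv"), sep="\t", index=False)
        sio.write_json({"venn": venn}, stage.path("interval_stats.json"))


def _profile_frame(profile: rq.RadialProfile):
    import pandas as pd

    n = np.sum(~np.isnan(profile.per_section), axis=0)
    return pd.DataFrame(
        {
            "distance_um": profile.distances,
            "mean_intensity": profile.mean_intensity,
            "n_sections": n,
        }
    )


def _metaprofile_frame(meta: iv.MetaprofileResult):
    import pandas as pd

    return pd.DataFrame(
        {
            "tss_distance_bp": meta.bin_centers,
            "density": meta.density,
            "lower95": meta.lower,
            "upper95": meta.upper,
        }
    )
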