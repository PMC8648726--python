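"""Reproducible multi-stage runs with manifests.

A :class:`RunConfig` (typically loaded from a YAML file; unknown keys are
rejected) names the stages to execute — simulate, cn, phenotype,
cytoskeleton, cellcycle — with one master seed from which every stage
derives its own child seeds.  Each run writes its artifacts plus a
manifest recording the stage, parameters, seed and SHA-256 digests of all
inputs and outputs, so a rerun with an identical config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import cn as cn_mod
from .cellcycle import DeanJettFox
from .cytoskeleton import (feature_statistics, normalize_localization,
                           segment_focal_adhesions, segment_stress_fibers)
from .mixtures import PHASE_MIXTURES, PHASES
from .phenotype import partition_periods
from .simulate import (MovieGenConfig, child_seeds, generate_cell_movie,
                       generate_cytoskeleton_image, generate_dna_population)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


class SimulateParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_movies: int = 25
    duration_min: float = 60.0
    interval_min: float = 1.0


class CNParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cutoff_deg: float = 75.0
    k: int | None = None


class PhenotypeParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_frames: int = 120
    boundaries: tuple[int, int] = (40, 80)
    noise_sd: float = 0.1


class CytoskeletonParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_fibers: int = 8
    n_adhesions: int = 25
    polarity_bias: float = 0.5
    noise_sd: float = 5.0


class CellCycleParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    truth_fractions: tuple[float, float, float] = (60.0, 20.0, 20.0)
    n_cells: int = 5000
    cv: float = 0.05
    constrain_ratio: bool = False


class RunConfig(BaseModel):
    """Declarative description of one reproducible run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    phase: str = "earlyG1"
    out_dir: str = "cncorr_run"
    stages: list[str] = Field(default_factory=lambda: ["simulate", "cn"])
    simulate: SimulateParams = Field(default_factory=SimulateParams)
    cn: CNParams = Field(default_factory=CNParams)
    phenotype: PhenotypeParams = Field(default_factory=PhenotypeParams)
    cytoskeleton: CytoskeletonParams = Field(default_factory=CytoskeletonParams)
    cellcycle: CellCycleParams = Field(default_factory=CellCycleParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_KNOWN_STAGES = ("simulate", "cn", "phenotype", "cytoskeleton", "cellcycle")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order; returns the run report."""
    if config.phase not in PHASES:
        raise ValueError(f"unknown phase {config.phase!r}; expected {PHASES}")
    for stage in config.stages:
        if stage not in _KNOWN_STAGES:
            raise ValueError(f"unknown stage {stage!r}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(_KNOWN_STAGES, child_seeds(config.seed, len(_KNOWN_STAGES))))
    manifest: list[dict] = []
    report: dict = {"seed": config.seed, "phase": config.phase, "stages": {}}
    movies = None

    for stage in config.stages:
        try:
            if stage == "simulate":
                movies = _stage_simulate(config, seeds[stage], out, manifest)
                report["stages"][stage] = {"n_movies": len(movies)}
            elif stage == "cn":
                report["stages"][stage] = _stage_cn(config, seeds[stage], out,
                                                    manifest, movies)
            elif stage == "phenotype":
                report["stages"][stage] = _stage_phenotype(config, seeds[stage],
                                                           out, manifest)
            elif stage == "cytoskeleton":
                report["stages"][stage] = _stage_cytoskeleton(
                    config, seeds[stage], out, manifest)
            elif stage == "cellcycle":
                report["stages"][stage] = _stage_cellcycle(
                    config, seeds[stage], out, manifest)
        except Exception:
            _write_manifest(out, config, manifest, failed_stage=stage)
            logger.exception("stage %r failed; partial outputs retained in %s",
                             stage, out)
            raise RuntimeError(f"pipeline stage {stage!r} failed") from None

    _write_manifest(out, config, manifest)
    report["manifest"] = str(out / "manifest.json")
    return report


def _record(manifest, stage, params, seed, outputs):
    manifest.append({
        "stage": stage,
        "parameters": params,
        "seed": seed,
        "outputs": {str(p): _digest(Path(p)) for p in outputs},
    })


def _write_manifest(out: Path, config: RunConfig, manifest, failed_stage=None):
    payload = {
        "config": config.model_dump(),
        "entries": manifest,
    }
    if failed_stage is not None:
        payload["failed_stage"] = failed_stage
    (out / "manifest.json").write_text(json.dumps(payload, indent=1,
                                                  sort_keys=True))


def _stage_simulate(config, seed, out, manifest):
    p = config.simulate
    mixture = PHASE_MIXTURES[config.phase]
    movies = []
    paths = []
    for i, s in enumerate(child_seeds(seed, p.n_movies)):
        movie = generate_cell_movie(mixture, MovieGenConfig(
            duration=p.duration_min, interval=p.interval_min, seed=s))
        csv = out / f"movie_{config.phase}_{i:03d}.csv"
        movie.to_csv(csv)
        truth = out / f"movie_{config.phase}_{i:03d}_truth.json"
        movie.truth_to_json(truth)
        paths += [csv, truth]
        movies.append(movie)
    _record(manifest, "simulate", p.model_dump(), seed, paths)
    return movies


def _stage_cn(config, seed, out, manifest, movies):
    p = config.cn
    if movies is None:
        sim = config.simulate
        mixture = PHASE_MIXTURES[config.phase]
        movies = [generate_cell_movie(mixture, MovieGenConfig(
            duration=sim.duration_min, interval=sim.interval_min, seed=s))
            for s in child_seeds(seed + 1, sim.n_movies)]
    profiles = [cn_mod.compute_cn_data(m, cell_id=i)
                for i, m in enumerate(movies)]
    profile = cn_mod.CNProfile.concatenate(profiles)
    csv = out / f"cn_profile_{config.phase}.csv"
    profile.to_dataframe().to_csv(csv, index=False)
    decomp = cn_mod.UNMDecomposer(k=p.k, random_state=seed).fit(profile.angle)
    djson = out / f"unm_{config.phase}.json"
    djson.write_text(json.dumps(decomp.to_dict(), indent=1, sort_keys=True))
    result = cn_mod.cmpi(profile, cutoff=p.cutoff_deg)
    _record(manifest, "cn", p.model_dump(), seed, [csv, djson])
    return {"n_data": len(profile), "cmpi_um": result.cmpi,
            "occurrence": result.occurrence, "k": decomp.k_}


def _stage_phenotype(config, seed, out, manifest):
    from .simulate import generate_phenotype_series

    p = config.phenotype
    X = generate_phenotype_series(p.n_frames, p.boundaries,
                                  levels=[1.0, 2.0, 3.0],
                                  noise_sd=p.noise_sd, seed=seed)
    part = partition_periods(X)
    pj = out / "partition.json"
    pj.write_text(json.dumps({
        "boundaries": list(part.boundaries), "score": part.score,
        "group_means": part.group_means.tolist(),
    }, indent=1))
    _record(manifest, "phenotype", p.model_dump(), seed, [pj])
    return {"boundaries": list(part.boundaries), "score": part.score}


def _stage_cytoskeleton(config, seed, out, manifest):
    import pandas as pd

    p = config.cytoskeleton
    # channels are assumed pre-separated: one actin-like (fibers) and one
    # vinculin-like (adhesions) image, from per-channel child seeds
    seed_f, seed_a = child_seeds(seed, 2)
    img = generate_cytoskeleton_image(p.n_fibers, 0,
                                      polarity_bias=p.polarity_bias,
                                      noise_sd=p.noise_sd, seed=seed_f)
    img_a = generate_cytoskeleton_image(0, p.n_adhesions,
                                        polarity_bias=p.polarity_bias,
                                        noise_sd=p.noise_sd, seed=seed_a)
    fibers = segment_stress_fibers(img.intensity, img.cell_mask,
                                   pixel_size=img.pixel_size)
    adhesions = segment_focal_adhesions(img_a.intensity, img_a.cell_mask,
                                        pixel_size=img_a.pixel_size)
    stats_ = feature_statistics(fibers, adhesions, img.cell_mask,
                                img.pixel_size)
    fib_csv = out / "fibers.csv"
    pd.DataFrame([{
        "id": i, "length_um": f.length, "orientation_deg": f.orientation,
        "width_um": f.width, "mean_intensity": f.mean_intensity,
    } for i, f in enumerate(fibers)]).to_csv(fib_csv, index=False)
    adh_csv = out / "adhesions.csv"
    pd.DataFrame([{
        "id": i, "area_um2": a.area, "cx_um": a.centroid[0],
        "cy_um": a.centroid[1], "mean_intensity": a.mean_intensity,
    } for i, a in enumerate(adhesions)]).to_csv(adh_csv, index=False)
    outputs = [fib_csv, adh_csv]
    if adhesions:
        loc = normalize_localization(
            [a.centroid / img_a.pixel_size for a in adhesions],
            img_a.cell_mask)
        stats_["adhesion_localization_ar"] = loc.ar
    sj = out / "cytoskeleton_summary.json"
    sj.write_text(json.dumps(stats_, indent=1, sort_keys=True))
    outputs.append(sj)
    _record(manifest, "cytoskeleton", p.model_dump(), seed, outputs)
    return stats_


def _stage_cellcycle(config, seed, out, manifest):
    p = config.cellcycle
    pop = generate_dna_population(p.truth_fractions, p.n_cells, p.cv,
                                  seed=seed)
    est = DeanJettFox(constrain_ratio=p.constrain_ratio).fit(pop.intensities)
    cj = out / "cellcycle_fit.json"
    cj.write_text(json.dumps(est.to_dict(), indent=1, sort_keys=True))
    _record(manifest, "cellcycle", p.model_dump(), seed, [cj])
    return est.to_dict()["fractions"]
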