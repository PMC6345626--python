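"""Pipeline orchestration: one reproducible run from designs to statistics.

A run proceeds design -> cohort truth -> phantoms -> quantification ->
scoring -> statistics.  All randomness derives from a single seed through a
``numpy.random.SeedSequence`` hierarchy, so each stage is independently
reproducible and a re-run with the same config is bit-identical.

:func:`cohort_run` executes the chain in memory (one phantom at a time) and
returns the tables; :func:`run_pipeline` wraps it with file outputs (TIFF
phantoms, CSV tables, JSON report) and a content-hashed manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTruth, default_cohort, simulate_raters
from .designs import APPARENT_MODULUS_MPA, DESIGNS
from .phantom import build_phantom, render_fluor_section
from .quantify import quantify_phantom
from .scoring import (consensus_scores, mineral_apposition_rate,
                      true_scores_for_phantom)
from .stats import cohort_report

__all__ = ["RunConfig", "CohortRun", "cohort_run", "run_pipeline",
           "verify_manifest", "StageError", "ChecksumError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class ChecksumError(RuntimeError):
    """A run artifact does not match its manifest hash; names the file."""


@dataclass
class RunConfig:
    """Reproducible run configuration (YAML round-trippable)."""

    seed: int = 0
    voxel_size_um: float = 100.0
    jitter_sd_pp: float = 0.0
    n_raters: int = 3
    rater_p_up: float = 0.1
    rater_p_down: float = 0.1
    outdir: str = "run"
    write_volumes: bool = True
    stages: tuple[str, ...] = ("designs", "cohort", "quantify", "score",
                               "stats")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if isinstance(data.get("stages"), list):
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True,
                       default=list).encode()).hexdigest()[:16]


@dataclass
class CohortRun:
    """In-memory results of one full synthetic-cohort run."""

    truth: CohortTruth
    table: pd.DataFrame          # 24 rows: quantified ingrowth + covariate
    true_scores: pd.DataFrame    # 120 rows: rubric scores of truth masks
    rater_scores: pd.DataFrame   # 360 rows: 3 simulated raters
    consensus: pd.DataFrame      # 120 rows: resolved consensus scores
    rescore_log: pd.DataFrame
    mar_um_day: pd.DataFrame     # 24 rows: per-sample MAR measurements
    report: dict
    seed: int


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def cohort_run(seed: int = 0, voxel_size_um: float = 100.0,
               jitter_sd_pp: float = 0.0, n_raters: int = 3,
               rater_p_up: float = 0.1, rater_p_down: float = 0.1,
               phantom_hook=None) -> CohortRun:
    """Run the full synthetic study for one cohort seed.

    ``phantom_hook(sample_id, phantom, bone_mask)`` is called per sample
    (used by :func:`run_pipeline` to write volumes) before the phantom is
    discarded.
    """
    s_cohort, s_raters, s_consensus, s_fluor, s_base = _child_seeds(seed, 5)
    truth = default_cohort(seed=s_cohort, jitter_sd_pp=jitter_sd_pp)
    fluor_rng = np.random.default_rng(s_fluor)

    rows, score_frames, mar_rows = [], [], []
    for i, sample in truth.samples.iterrows():
        design = DESIGNS[sample["design"]]
        sample_id = f"A{sample['animal_id']:02d}{sample['leg']}"
        ph = build_phantom(design, sample["latent_total_pp"],
                           sample["peripheral_pp"],
                           voxel_size_um=voxel_size_um,
                           seed=(s_base + 7 * i) % (2**31))
        res, bone = quantify_phantom(ph)
        if phantom_hook is not None:
            phantom_hook(sample_id, ph, bone)
        rows.append({
            "animal_id": int(sample["animal_id"]),
            "leg": sample["leg"],
            "design": sample["design"],
            "modulus_mpa": APPARENT_MODULUS_MPA[sample["design"]],
            "bone_voxels": res.bone_voxels,
            "defect_voxels": res.defect_voxels,
            "porosity": res.porosity_used,
            "fraction_pct": res.fraction_pct,
            "latent_total_pp": float(sample["latent_total_pp"]),
        })
        score_frames.append(true_scores_for_phantom(ph, sample_id))
        # fluorescence: one mid-depth peripheral section per sample
        offset = float(fluor_rng.uniform(28.0, 42.0))
        central_level = min(1.0, float(sample["central_pp"]) / 20.0)
        section = render_fluor_section(
            depth_mm=7.5, band_offset_um=offset,
            seed=int(fluor_rng.integers(2**31)),
            central_level=central_level)
        mar_rows.append({"sample_id": sample_id,
                         "band_offset_truth_um": offset,
                         "mar_um_day": mineral_apposition_rate(section)})

    table = pd.DataFrame(rows)
    true_scores = pd.concat(score_frames, ignore_index=True)
    rater_scores = simulate_raters(true_scores, n_raters=n_raters,
                                   p_up=rater_p_up, p_down=rater_p_down,
                                   seed=s_raters)
    consensus, rescore_log = consensus_scores(
        rater_scores, seed=s_consensus, p_up=rater_p_up,
        p_down=rater_p_down)
    report = cohort_report(table)
    return CohortRun(truth, table, true_scores, rater_scores, consensus,
                     rescore_log, pd.DataFrame(mar_rows), report, seed)


def verify_manifest(outdir) -> None:
    """Re-hash every file listed in a run manifest.

    Raises :class:`ChecksumError` naming the first corrupted or missing
    file.
    """
    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    for rel, digest in manifest["files"].items():
        p = out / rel
        if not p.exists():
            raise ChecksumError(f"missing run artifact: {rel}")
        if _sha256(p) != digest:
            raise ChecksumError(f"corrupted run artifact: {rel}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a content-hashed manifest.

    Outputs under ``config.outdir``: ``designs/`` (STL + JSON sidecars),
    ``phantoms/`` (gray volume + label volume TIFFs), ``sections/``
    (virtual-section TIFFs), ``results.csv``, ``scores.csv``,
    ``consensus.csv``, ``mar.csv``, ``report.json``, ``manifest.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path):
        written.append(path)

    try:
        if "designs" in config.stages:
            from .lattice import build_design, export_mesh
            ddir = out / "designs"
            ddir.mkdir(exist_ok=True)
            for acro, design in DESIGNS.items():
                lat = build_design(design, seed=0)
                p = export_mesh(lat, ddir / f"{acro}.stl")
                emit(p)
                emit(p.with_suffix(p.suffix + ".json"))
    except Exception as exc:
        raise StageError(f"stage 'designs' failed: {exc}") from exc

    run = None
    if {"cohort", "quantify", "score", "stats"} & set(config.stages):
        import tifffile

        pdir = out / "phantoms"
        sdir = out / "sections"

        def hook(sample_id, ph, bone):
            if not config.write_volumes:
                return
            pdir.mkdir(exist_ok=True)
            sdir.mkdir(exist_ok=True)
            gray = np.clip(ph.volume / 2.0, 0, 1)
            p = pdir / f"{sample_id}.tif"
            tifffile.imwrite(p, (gray * 255).astype(np.uint8).T,
                             compression="zlib")
            emit(p)
            labels = np.zeros(ph.volume.shape, dtype=np.uint8)
            labels[ph.scaffold_mask] = 1
            labels[ph.bone_mask] = 2
            p = pdir / f"{sample_id}_labels.tif"
            tifffile.imwrite(p, labels.T, compression="zlib")
            emit(p)
            from .quantify import virtual_sections
            secs = virtual_sections(ph.volume, ph.origin_mm,
                                    ph.voxel_size_um, ph.periosteal_z_mm)
            for depth, sl in secs.items():
                p = sdir / f"{sample_id}_d{depth:04.1f}mm.tif"
                tifffile.imwrite(
                    p, (np.clip(sl / 2.0, 0, 1) * 255).astype(np.uint8),
                    compression="zlib")
                emit(p)

        try:
            run = cohort_run(seed=config.seed,
                             voxel_size_um=config.voxel_size_um,
                             jitter_sd_pp=config.jitter_sd_pp,
                             n_raters=config.n_raters,
                             rater_p_up=config.rater_p_up,
                             rater_p_down=config.rater_p_down,
                             phantom_hook=hook)
        except Exception as exc:
            raise StageError(f"stage 'cohort' failed: {exc}") from exc

        try:
            run.truth.samples.to_csv(out / "cohort_truth.csv", index=False)
            emit(out / "cohort_truth.csv")
            run.table.to_csv(out / "results.csv", index=False)
            emit(out / "results.csv")
            run.rater_scores.to_csv(out / "scores.csv", index=False)
            emit(out / "scores.csv")
            run.consensus.to_csv(out / "consensus.csv", index=False)
            emit(out / "consensus.csv")
            run.mar_um_day.to_csv(out / "mar.csv", index=False)
            emit(out / "mar.csv")
            (out / "report.json").write_text(
                json.dumps(run.report, indent=2, default=float))
            emit(out / "report.json")
        except Exception as exc:
            raise StageError(f"stage 'stats' failed: {exc}") from exc

    config.to_yaml(out / "config.yaml")
    emit(out / "config.yaml")
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "files": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
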