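"""End-to-end pipeline: unmix -> segment -> features, driven by one config."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, features, io_envi, segmentation, unmixing

log = logging.getLogger("seedspectra")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Serializable parameters for a full run."""

    header_path: str = ""
    raw_path: str = ""
    out_dir: str = "run"
    trim_fraction: float = 0.05
    n_trim_start: int | None = None
    n_trim_end: int | None = None
    pfa: float = 1e-3
    n_endmembers: int | None = None  # override the NWHFC estimate
    n_skewers: int = 10_000
    mse_cutoff: float = 5e-5
    constraint: str = "full"
    fg_labels: list[str] | str = "auto"
    se_side: int = 3
    median_band: tuple[float, float] = (0.5, 1.5)
    mm_per_px: float = 0.17
    include_logR: bool = False
    include_dR: bool = False
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.median_band, list):
            cfg.median_band = tuple(cfg.median_band)
        return cfg


def _stage(name: str):
    log.info("stage: %s", name)
    return name


def run_pipeline(config: PipelineConfig) -> Path:
    """Run unmixing, segmentation and feature extraction; write artifacts.

    Produces endmembers.csv, abundance ENVI cube, regions.csv, features.csv
    and run.log under ``config.out_dir``. Identical config + seed gives
    byte-identical CSV outputs. Raises with the failing stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "init"
    try:
        log.info("seedspectra %s; config: %s", __version__,
                 json.dumps(asdict(config), default=str))
        stage = _stage("io_envi")
        cube = io_envi.read_envi(config.header_path, config.raw_path)
        cube = io_envi.trim_bands(cube, config.trim_fraction,
                                  n_trim_start=config.n_trim_start,
                                  n_trim_end=config.n_trim_end)

        stage = _stage("unmixing")
        p = config.n_endmembers
        if p is None:
            p = max(unmixing.estimate_num_endmembers(cube, pfa=config.pfa), 2)
        log.info("endmembers requested: %d", p)
        candidates = unmixing.ppi_extract(cube, p=p, n_skewers=config.n_skewers,
                                          seed=config.seed)
        ems = unmixing.consolidate_endmembers([candidates],
                                              mse_cutoff=config.mse_cutoff)
        ab = unmixing.estimate_abundances(cube, ems, constraint=config.constraint)
        recon = unmixing.reconstruct(ems, ab)
        score = unmixing.rrmse(recon, cube)
        log.info("reconstruction rRMSE: %.4f%%", score)

        em_frame = pd.DataFrame(ems.spectra.T, columns=ems.labels)
        em_frame.insert(0, "wavelength_nm", ems.wavelengths)
        em_frame.to_csv(out / "endmembers.csv", index=False)
        ab_cube = io_envi.Hypercube(data=ab.maps,
                                    wavelengths=np.arange(1.0, len(ems) + 1.0))
        io_envi.write_envi(ab_cube, out / "abundance.hdr", out / "abundance.raw")

        stage = _stage("segmentation")
        ems = segmentation.assign_roles(ems, ab, config.fg_labels)
        ab = unmixing.AbundanceStack(maps=ab.maps, endmembers=ems)
        regions, _ = segmentation.segment_scene(
            cube, ab, se_side=config.se_side, median_band=config.median_band)
        log.info("segmented %d seeds", len(regions))
        rows = []
        for r in regions:
            rows.append({"id": r.id, "area_px": r.area_px,
                         "major_px": r.major_axis_px, "minor_px": r.minor_axis_px,
                         "centroid_r": r.centroid[0], "centroid_c": r.centroid[1],
                         "dominant_em": r.dominant_em})
        pd.DataFrame(rows).to_csv(out / "regions.csv", index=False)

        stage = _stage("features")
        rgb = io_envi.render_rgb(cube)
        seed_records = []
        for r in regions:
            area, height, width = features.morphometrics(r, config.mm_per_px)
            triplet, gray = features.mean_rgb(rgb, r.coat_mask)
            spec = features.mean_reflectance(cube, r.mask)
            try:
                ndvi, ari2, tcari = features.vegetation_indices(spec)
            except ValueError:
                ndvi = ari2 = tcari = None
            seed_records.append(features.SeedFeatures(
                accession=cube.meta.get("accession", "unknown"), seed_id=r.id,
                area_mm2=area, height_mm=height, width_mm=width,
                rgb=triplet, gray=gray, mean_reflectance=spec,
                ndvi=ndvi, ari2=ari2, tcari=tcari))
        table = features.build_feature_table(seed_records,
                                             include_logR=config.include_logR,
                                             include_dR=config.include_dR)
        table.frame.to_csv(out / "features.csv", index=False)
        with open(out / "features_manifest.json", "w") as fh:
            json.dump(table.manifest, fh, indent=2)
        with open(out / "metrics.json", "w") as fh:
            json.dump({"rrmse_pct": score, "n_endmembers": len(ems),
                       "n_seeds_segmented": len(regions),
                       "n_predictors": table.n_predictors, "seed": config.seed},
                      fh, indent=2)
        config.to_yaml(out / "config.yaml")
        log.info("run complete: %s", out)
        return out
    except Exception as exc:
        log.error("stage '%s' failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
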