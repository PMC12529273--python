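"""End-to-end orchestration: simulate -> factors -> AHP -> overlay ->
cluster scan -> exposure tables -> kriged odds-ratio surface.

One root seed expands into per-stage seeds; every stage's parameters and
outputs are recorded in a JSON run manifest so each reported number is
recomputable from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io
from .ahp import PairwiseMatrix, ahp_weights, default_factor_matrix
from .errors import StageError
from .exposure import build_contingency, format_report, frequency_report, pearson_chi2
from .factors import KDEConfig, compute_factor_scores
from .geo_core import case_indicator, residence_xy
from .kriging import empirical_variogram, fit_variogram, odds_ratio_surface, ordinary_krige
from .moran import DEFAULT_BAND, distance_band_weights, local_morans_i
from .overlay import WLCConfig, susceptibility_map
from .synth_region import CohortConfig, RegionConfig, generate_region, generate_residences

log = logging.getLogger("smcair")

EXPOSURE_VARIABLES = {
    "susceptibility": "susceptibility",   # from the overlay classes
    "prtr_distance": "prtr_distance",
    "prtr_density": "prtr_density",       # continuous factor classified for tabulation
    "roads": "roads",
    "landuse": "landuse",
    "fog": "fog",
}


@dataclass
class MoranConfig:
    band: float = DEFAULT_BAND
    n_perm: int = 999
    alpha: float = 0.05


@dataclass
class KrigingConfig:
    model: str = "exponential"
    max_neighbors: int = 16
    prediction_cell_size: Optional[float] = None  # default: region cell size


@dataclass
class PipelineConfig:
    region: RegionConfig = field(default_factory=RegionConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    ahp_matrix: Optional[PairwiseMatrix] = None   # None -> bundled default
    use_recomputed_weights: bool = False
    wlc: WLCConfig = field(default_factory=WLCConfig)
    kde: KDEConfig = field(default_factory=KDEConfig)
    moran: MoranConfig = field(default_factory=MoranConfig)
    kriging: KrigingConfig = field(default_factory=KrigingConfig)
    seed: int = 0
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        # one root seed expands into per-stage seeds
        self.region.seed = int(self.seed)
        self.cohort.seed = int(self.seed)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig(
        region=RegionConfig(**{**doc.get("region", {}),
                               "bounds": tuple(doc.get("region", {}).get(
                                   "bounds", RegionConfig().bounds))}),
        cohort=CohortConfig(**doc.get("cohort", {})),
        wlc=WLCConfig(**doc.get("wlc", {})) if "wlc" in doc else WLCConfig(),
        kde=KDEConfig(**doc.get("kde", {})) if "kde" in doc else KDEConfig(),
        moran=MoranConfig(**doc.get("moran", {})),
        kriging=KrigingConfig(**doc.get("kriging", {})),
        seed=int(doc.get("seed", 0)),
        use_recomputed_weights=bool(doc.get("use_recomputed_weights", False)),
    )
    return cfg


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # abort with the stage name and cause
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return run
    return wrap


def run_all(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict.  With
    ``cfg.out_dir`` set, writes all rasters/tables/results there."""
    manifest: dict = {
        "seed": cfg.seed,
        "stages": {},
        "config": {
            "region": {**asdict(cfg.region), "bounds": list(cfg.region.bounds)},
            "cohort": asdict(cfg.cohort),
            "moran": asdict(cfg.moran),
            "kriging": asdict(cfg.kriging),
            "wlc": {"weights": dict(cfg.wlc.weights),
                    "class_method": cfg.wlc.class_method},
            "kde": asdict(cfg.kde),
        },
    }

    region = _stage("simulate")(generate_region)(cfg.region)
    residences = _stage("simulate")(generate_residences)(region, cfg.cohort)
    n_cases = sum(r.group == "case" for r in residences)
    n_controls = len(residences) - n_cases
    manifest["stages"]["simulate"] = {"n_cases": n_cases, "n_controls": n_controls,
                                      "n_facilities": len(region.facilities)}

    matrix = cfg.ahp_matrix or default_factor_matrix()
    ahp_res = _stage("ahp")(ahp_weights)(matrix)
    manifest["stages"]["ahp"] = {
        "weights": {k: round(float(v), 4) for k, v in ahp_res.weight_map().items()},
        "lambda_max": round(ahp_res.lambda_max, 4),
        "CI": round(ahp_res.CI, 4), "CR": round(ahp_res.CR, 4),
        "warnings": ahp_res.warnings,
    }
    wlc_cfg = cfg.wlc
    if cfg.use_recomputed_weights:
        wlc_cfg = WLCConfig(weights=ahp_res.weight_map(),
                            class_method=cfg.wlc.class_method)

    factors = _stage("factors")(compute_factor_scores)(region, cfg.kde)
    smap = _stage("overlay")(susceptibility_map)(factors, wlc_cfg)
    manifest["stages"]["overlay"] = {
        "weights": wlc_cfg.weights, "class_method": wlc_cfg.class_method,
        "S_range": [float(smap.S.valid_values().min()),
                    float(smap.S.valid_values().max())],
        "class_shares": {int(c): int((smap.classes.values == c).sum())
                         for c in (1, 2, 3)},
    }

    # cluster scan on the binary case indicator
    xy = residence_xy(residences)
    marks = case_indicator(residences)
    w = distance_band_weights(xy, band=cfg.moran.band)
    moran_res = _stage("moran")(local_morans_i)(
        marks, w, n_perm=cfg.moran.n_perm, seed=cfg.seed, alpha=cfg.moran.alpha)
    from collections import Counter
    manifest["stages"]["moran"] = {
        "band": cfg.moran.band, "n_perm": cfg.moran.n_perm,
        "alpha": cfg.moran.alpha, "labels": dict(Counter(moran_res.label)),
    }

    # exposure tabulation: overlay classes + the four classified factors
    from .factors import classify_by_breaks  # noqa: F401 (factors already classed)
    from .overlay import classify_susceptibility
    tabulate = {"susceptibility": smap.classes}
    for name in ("prtr_distance", "landuse", "roads", "fog"):
        tabulate[name] = factors[name]
    # density factor is continuous [1,3]; reuse the index classifier
    tabulate["prtr_density"] = classify_susceptibility(factors["prtr_density"], wlc_cfg)

    tables = {}
    chi2_results = {}
    for name, raster in tabulate.items():
        t = _stage("chisq")(build_contingency)(residences, raster)
        tables[name] = t
        try:
            chi2_results[name] = pearson_chi2(t)
        except Exception:
            chi2_results[name] = None
    report = frequency_report(tables)
    manifest["stages"]["exposure"] = {
        name: {"counts": t.counts.values.tolist(),
               "p": (None if chi2_results[name] is None
                     else round(chi2_results[name].p, 3)),
               "exclusions": t.exclusions}
        for name, t in tables.items()
    }

    # kriged odds-ratio surface (coarser prediction grid allowed)
    kcell = cfg.kriging.prediction_cell_size or cfg.region.cell_size
    from .geo_core import make_grid
    kgrid = make_grid(cfg.region.bounds, kcell)
    emp = _stage("krige")(empirical_variogram)(xy, marks)
    vg = fit_variogram(emp, model=cfg.kriging.model)
    p_hat = ordinary_krige(xy, marks, vg, kgrid,
                           max_neighbors=cfg.kriging.max_neighbors)
    ors = odds_ratio_surface(p_hat, n_cases, n_controls)
    manifest["stages"]["krige"] = {
        "variogram": {"model": vg.model, "nugget": round(vg.nugget, 5),
                      "partial_sill": round(vg.partial_sill, 5),
                      "range_m": round(vg.range_, 1)},
        "baseline_odds": round(ors.baseline_odds, 4),
        "OR_range": [float(ors.OR.values.min()), float(ors.OR.values.max())],
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_residences(out / "residences.csv", residences)
        io.write_featureset(out / "facilities.geojson", region.facilities)
        io.write_featureset(out / "roads.geojson", region.roads)
        io.write_featureset(out / "fog.geojson", region.fog)
        io.write_featureset(out / "postal_centroids.geojson", region.postal_centroids)
        io.write_raster(out / "landuse.asc", region.landuse)
        for name, r in factors.items():
            io.write_raster(out / f"factor_{name}.asc", r)
        io.write_raster(out / "susceptibility_S.asc", smap.S)
        io.write_raster(out / "susceptibility_class.asc", smap.classes)
        io.write_raster(out / "p_hat.asc", ors.p_hat)
        io.write_raster(out / "odds_ratio.asc", ors.OR)
        report.to_csv(out / "frequency_report.csv", index=False)
        (out / "frequency_report.txt").write_text(format_report(report))
        import pandas as pd
        pd.DataFrame({
            "id": [r.id for r in residences],
            "I": moran_res.I, "z": moran_res.z_score,
            "p": moran_res.p_value, "label": moran_res.label,
        }).to_csv(out / "local_moran.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    manifest["_objects"] = {
        "region": region, "residences": residences, "factors": factors,
        "susceptibility": smap, "moran": moran_res, "tables": tables,
        "chi2": chi2_results, "report": report, "or_surface": ors,
        "ahp": ahp_res,
    }
    return manifest
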