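"""End-to-end pipeline driver.

Runs the full workflow — simulate (optional) -> rasterize -> sample ->
train -> predict -> classify -> abundance -> validate — writing every
intermediate artifact plus a machine-readable run manifest (parameters
with their source, seeds, package version, SHA-256 checksum of every
artifact). Reruns with the same configuration produce bit-identical
artifacts; the manifest makes that checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import yaml

from . import __version__
from .abundance import abundance_summary, validate_points
from .boost import (BoostConfig, fit_boosted_trees, partial_dependence,
                    roc_auc, variable_importance)
from .cloud import merge_vegetation
from .features import FEATURE_CLASSES
from .grids import GridSpec
from . import io as mio
from .rasters import (build_dem, canopy_density, canopy_height,
                      euclidean_distance, slope_aspect, stack_predictors)
from .sampling import (build_sample_table, random_absences,
                       sampling_density_per_ha)
from .surface import (classify_occupancy, idw_interpolate, make_lattice,
                      occupancy_threshold, score_lattice)
from .synthetic import (LandscapeConfig, calibrate_intercept,
                        default_response_truth, generate_canopy,
                        generate_features, generate_point_cloud,
                        generate_terrain, simulate_middens,
                        study_area_polygon, thin_middens)

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "simulate_landscape"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, input_checksum: str = ""):
        self.stage = stage
        super().__init__(
            f"stage '{stage}' failed"
            + (f" (input checksum {input_checksum[:12]})" if input_checksum else "")
            + f": {message}"
        )


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    # inputs; when cloud_path is None the synthetic landscape is generated
    cloud_path: str | None = None
    features_dir: str | None = None
    presences_path: str | None = None
    validation_path: str | None = None
    area_path: str | None = None
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    boost: BoostConfig = field(default_factory=BoostConfig)
    n_absences: int = 600
    min_dist: float = 0.0
    lattice_spacing: float | None = None  # None -> predictor cell size
    idw_power: float = 2.0
    idw_k: int = 12
    coverage: float = 0.95
    max_secondary: int = 3
    target_presences: float = 198.0   # expected synthetic midden count
    target_validation: float = 28.0   # expected independent survey count
    thin_radius: float = 10.0
    _user_keys: set = field(default_factory=set, repr=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        landscape = LandscapeConfig(**d.pop("landscape", {}))
        boost = BoostConfig(**d.pop("boost", {}))
        user_keys = set(d)
        cfg = cls(landscape=landscape, boost=boost, **d)
        cfg._user_keys = user_keys
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def params_with_source(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            if f.name.startswith("_"):
                continue
            value = getattr(self, f.name)
            if dataclasses.is_dataclass(value):
                value = dataclasses.asdict(value)
            out[f.name] = {
                "value": value,
                "source": "user" if f.name in self._user_keys else "default",
            }
        return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_landscape(config: LandscapeConfig, out_dir: str,
                       target_presences: float = 198.0,
                       target_validation: float = 28.0,
                       thin_radius: float = 10.0) -> dict:
    """Generate and write the full synthetic study area.

    Produces terrain/canopy rasters, the feature classes, the classified
    point cloud, the study-area polygon, midden presences (thinned by the
    <10 m diffuse-midden rule) and an independent validation point set,
    plus the generative truth record.
    """
    os.makedirs(out_dir, exist_ok=True)
    elevation = generate_terrain(config)
    height, density = generate_canopy(config, elevation)
    features = generate_features(config)
    cloud = generate_point_cloud(config, elevation, height, density)
    area = study_area_polygon(config)
    spec = elevation.spec

    # response stack for the generative model (true rasters + distances)
    dist = {name: euclidean_distance(features, name, spec)
            for name in FEATURE_CLASSES}
    truth_stack = stack_predictors(height, density, dist["trails"], dist["lake"])
    truth = default_response_truth()
    truth.intercept = calibrate_intercept(truth_stack, truth,
                                          target_presences, area)
    presences, truth_rec = simulate_middens(truth_stack, truth,
                                            config.seed, area)
    presences = thin_middens(presences, thin_radius)

    val_truth = default_response_truth()
    val_truth.intercept = calibrate_intercept(truth_stack, val_truth,
                                              target_validation, area)
    validation, _ = simulate_middens(truth_stack, val_truth,
                                     config.seed + 1, area)
    validation = thin_middens(validation, thin_radius)

    mio.write_ascii_grid(elevation, os.path.join(out_dir, "true_elevation.asc"))
    mio.write_ascii_grid(height, os.path.join(out_dir, "true_canopy_height.asc"))
    mio.write_ascii_grid(density, os.path.join(out_dir, "true_canopy_density.asc"))
    mio.write_features(features, os.path.join(out_dir, "features"))
    mio.write_cloud_csv(cloud, os.path.join(out_dir, "cloud.csv"))
    mio.write_polygon_geojson(area, os.path.join(out_dir, "area.geojson"))
    pres_df = pd.DataFrame({"id": np.arange(len(presences)),
                            "x": presences[:, 0], "y": presences[:, 1],
                            "label": 1})
    mio.write_points_csv(pres_df, os.path.join(out_dir, "presences.csv"))
    val_df = pd.DataFrame({"id": np.arange(len(validation)),
                           "x": validation[:, 0], "y": validation[:, 1],
                           "label": 1})
    mio.write_points_csv(val_df, os.path.join(out_dir, "validation.csv"))
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth_rec.to_dict(), fh, indent=2)
    return {
        "cloud": os.path.join(out_dir, "cloud.csv"),
        "features": os.path.join(out_dir, "features"),
        "presences": os.path.join(out_dir, "presences.csv"),
        "validation": os.path.join(out_dir, "validation.csv"),
        "area": os.path.join(out_dir, "area.geojson"),
        "n_presences": len(presences),
        "n_validation": len(validation),
    }


def run_pipeline(config: RunConfig) -> str:
    """Execute the whole workflow; returns the run directory."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    artifacts: dict[str, str] = {}
    log: list[dict] = []

    def record(path: str) -> str:
        artifacts[os.path.relpath(path, out)] = _sha256(path)
        return path

    def stage(name: str, **info):
        log.append({"stage": name, **info})

    # ---- stage 0: inputs (simulate if no cloud given) ---------------------
    try:
        if config.cloud_path is None:
            sim_dir = os.path.join(out, "synthetic")
            land = dataclasses.replace(config.landscape, seed=config.seed)
            sim = simulate_landscape(land, sim_dir,
                                     config.target_presences,
                                     config.target_validation,
                                     config.thin_radius)
            cloud_path = sim["cloud"]
            features_dir = sim["features"]
            presences_path = sim["presences"]
            validation_path = sim["validation"]
            area_path = sim["area"]
            stage("simulate", n_presences=sim["n_presences"],
                  n_validation=sim["n_validation"])
        else:
            cloud_path = config.cloud_path
            features_dir = config.features_dir
            presences_path = config.presences_path
            validation_path = config.validation_path
            area_path = config.area_path
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # ---- stage 1: rasterize ----------------------------------------------
    try:
        for label, path in (("cloud", cloud_path), ("features", features_dir),
                            ("presences", presences_path), ("area", area_path)):
            if path is None or not os.path.exists(path):
                raise FileNotFoundError(f"{label} input missing: {path}")
        cloud = merge_vegetation(mio.read_cloud_csv(cloud_path))
        features = mio.read_features(features_dir)
        area = mio.read_polygon_geojson(area_path)
        # grid snapped to whole cells covering the cloud footprint
        cell = config.landscape.cell_size
        origin_x = float(np.floor(cloud.x.min() / cell) * cell)
        origin_y = float(np.ceil(cloud.y.max() / cell) * cell)
        bottom = float(np.floor(cloud.y.min() / cell) * cell)
        n_cols = int(np.ceil((cloud.x.max() - origin_x) / cell))
        n_rows = int(np.round((origin_y - bottom) / cell))
        spec = GridSpec(origin_x=origin_x, origin_y=origin_y, cell_size=cell,
                        n_rows=n_rows, n_cols=n_cols)
        dem = build_dem(cloud, spec)
        dens = canopy_density(cloud, spec)
        chm = canopy_height(cloud, dem)
        slope, aspect = slope_aspect(dem)
        dist = {name: euclidean_distance(features, name, spec)
                for name in FEATURE_CLASSES}
        stack = stack_predictors(
            chm, dens, slope, aspect, dem,
            dist["lake"], dist["trails"], dist["dogtrail"],
            dist["highway"], dist["buildings"],
        )
        record(mio.write_stack(stack, os.path.join(out, "stack")))
        for layer in stack.names:
            record(os.path.join(out, "stack", f"{layer}.asc"))
        stage("rasterize", n_returns=len(cloud), grid=[n_rows, n_cols])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("rasterize", str(exc)) from exc

    # ---- stage 2: sample --------------------------------------------------
    try:
        pres_df = mio.read_points_csv(presences_path)
        presences = pres_df[["x", "y"]].to_numpy(dtype=float)
        absences = random_absences(area, config.n_absences, config.seed,
                                   presences=presences,
                                   min_dist=config.min_dist)
        table = build_sample_table(presences, absences, stack)
        mio.write_sample_table(table, os.path.join(out, "sample_table.csv"))
        record(os.path.join(out, "sample_table.csv"))
        density_log = sampling_density_per_ha(len(table), area.area)
        stage("sample", n_presence=len(presences), n_absence=len(absences),
              sampling_points_per_ha=round(density_log, 2))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("sample", str(exc)) from exc

    # ---- stage 3: train ---------------------------------------------------
    try:
        boost_cfg = dataclasses.replace(config.boost, seed=config.seed)
        model = fit_boosted_trees(table, boost_cfg)
        model.to_json(os.path.join(out, "model.json"))
        record(os.path.join(out, "model.json"))
        imp = variable_importance(model)
        imp.to_csv(os.path.join(out, "importance.csv"), index=False,
                   float_format="%.2f")
        record(os.path.join(out, "importance.csv"))
        train_auc = roc_auc(table["label"].to_numpy(), model.predict(table),
                            table["weight"].to_numpy())
        pd_rows = []
        for feat in ("canopy_height", "dist_trails", "canopy_density",
                     "dist_lake"):
            if feat not in stack.names:
                continue
            vals = table[feat].to_numpy()
            grid = np.linspace(vals.min(), vals.max(), 41)
            curve = partial_dependence(model, table, feat, grid)
            curve.insert(0, "feature", feat)
            pd_rows.append(curve)
        if pd_rows:
            pd.concat(pd_rows, ignore_index=True).to_csv(
                os.path.join(out, "partial_dependence.csv"), index=False,
                float_format="%.17g")
            record(os.path.join(out, "partial_dependence.csv"))
        stage("train", training_auc=round(train_auc, 4),
              hyperparameters=dataclasses.asdict(boost_cfg))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("train", str(exc)) from exc

    # ---- stage 4: predict -------------------------------------------------
    try:
        spacing = config.lattice_spacing or spec.cell_size
        lattice = make_lattice(area, spacing, spec)
        scored = score_lattice(model, lattice, stack)
        mio.write_points_csv(scored, os.path.join(out, "lattice_scores.csv"))
        record(os.path.join(out, "lattice_scores.csv"))
        surface = idw_interpolate(scored, spec, power=config.idw_power,
                                  k=config.idw_k, area_polygon=area)
        mio.write_ascii_grid(surface, os.path.join(out, "rio.asc"))
        record(os.path.join(out, "rio.asc"))
        stage("predict", n_lattice=len(lattice), spacing=spacing)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("predict", str(exc)) from exc

    # ---- stage 5: classify ------------------------------------------------
    try:
        rio_at_pres = surface.sample(presences[:, 0], presences[:, 1])
        t_occ = occupancy_threshold(rio_at_pres, config.coverage)
        occ = classify_occupancy(surface, t_occ, config.coverage)
        mio.write_ascii_grid(occ.raster, os.path.join(out, "occupancy.asc"))
        record(os.path.join(out, "occupancy.asc"))
        n_in = occ.presences_in_occupied(presences)
        stage("classify", t_occupied=round(t_occ, 4),
              occupied_area_ha=round(occ.area_ha, 2),
              presences_in_occupied=n_in,
              presence_fraction=round(n_in / len(presences), 4))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    # ---- stage 6: abundance ----------------------------------------------
    try:
        area_ha = area.area / 1e4
        est_full = abundance_summary(len(presences), area_ha,
                                     config.max_secondary)
        est_occ = abundance_summary(n_in, occ.area_ha, config.max_secondary)
        abundance_out = {
            "study_area": est_full.rounded(),
            "occupied_area": est_occ.rounded(density_dp=1),
        }
        with open(os.path.join(out, "abundance.json"), "w") as fh:
            json.dump(abundance_out, fh, indent=2)
        record(os.path.join(out, "abundance.json"))
        stage("abundance", **abundance_out["study_area"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("abundance", str(exc)) from exc

    # ---- stage 7: validate ------------------------------------------------
    try:
        report = None
        if validation_path and os.path.exists(validation_path):
            val_df = mio.read_points_csv(validation_path)
            val_pts = val_df[["x", "y"]].to_numpy(dtype=float)
            report = validate_points(surface, val_pts,
                                     scored["PROB_1"].to_numpy())
            with open(os.path.join(out, "validation_report.json"), "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            record(os.path.join(out, "validation_report.json"))
            stage("validate", **{k: (round(v, 4) if isinstance(v, float) else v)
                                 for k, v in report.to_dict().items()})
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("validate", str(exc)) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.params_with_source(),
        "stages": log,
        "artifacts": artifacts,
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
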