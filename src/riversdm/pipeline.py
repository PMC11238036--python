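"""End-to-end pipeline driver: synth -> network -> downscale -> bioclim ->
fit/select -> map/change, with artifact writing and a machine-readable run
report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioclim as _bioclim
from . import downscale as _downscale
from . import evaluation as _eval
from . import habitat as _habitat
from . import maxent as _maxent
from . import streams as _streams
from . import synthetic as _synth
from .climate import write_climate_csv
from .grids import write_ascii_grid

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("riversdm")


@dataclass
class PipelineConfig:
    """All pipeline parameters with spec-matching defaults.

    Loadable from a YAML mapping mirroring the field names; unknown keys are
    rejected.
    """

    seed: int = 0
    world: dict = field(default_factory=lambda: {
        "relief_amplitude": 450.0, "regional_slope": 0.06,
    })
    # cold/wet-optimum species: suitability peaks at cool (higher-elevation)
    # temperatures and high catchment precipitation
    niche: dict = field(default_factory=lambda: {
        "baseline": 2.0,
        "responses": [
            {"predictor": "bio1", "optimum_quantile": 0.35, "breadth_factor": 1.0,
             "weight": 1.0},
            {"predictor": "bio12h", "optimum_quantile": 0.7, "breadth_factor": 1.5,
             "weight": 1.0},
        ],
    })
    n_presences: int = 120
    scenarios: list = field(default_factory=lambda: [
        {"label": "SSP245-like", "delta_t": 2.0, "precip_scale": 0.85},
        {"label": "SSP585-like", "delta_t": 4.0, "precip_scale": 0.70},
    ])
    network: dict = field(default_factory=lambda: {
        "min_area_km2": 0.1, "target_length_m": 100.0,
        "valley_search_radius_m": 300.0, "valley_relief_threshold_m": 10.0,
    })
    downscale: dict = field(default_factory=lambda: {
        "enabled": True, "bandwidth_m": None, "use_stations": True,
        "bandwidth_candidates_cells": [1.5, 3.0, 6.0],
    })
    model: dict = field(default_factory=lambda: {
        "betas": [0.5, 1.0, 2.0],
        "feature_class_sets": ["l", "lq", "lqp"],
        "knots_per_hinge": 5,
        "predictors": None,   # default: the niche's predictors
        "transform": "cloglog",
    })
    evaluation: dict = field(default_factory=lambda: {
        "train_fraction": 0.7, "replicates": 10, "omission_e": 5.0,
        "proc_iterations": 500, "proc_sample_fraction": 0.5,
    })
    density: dict = field(default_factory=lambda: {
        "suitability_bandwidth": 0.05, "elevation_bandwidth_m": 50.0,
    })

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls(**{k: v for k, v in data.items() if k in known})
        return base

    def to_yaml_text(self) -> str:
        return yaml.safe_dump(vars(self), sort_keys=True)

    def sha256(self) -> str:
        return hashlib.sha256(self.to_yaml_text().encode()).hexdigest()


def _resolve_niche(cfg: PipelineConfig, predictors: pd.DataFrame) -> _synth.TrueNiche:
    """Turn quantile-specified optima/breadths into absolute values."""
    responses = []
    for r in cfg.niche["responses"]:
        x = predictors[r["predictor"]].to_numpy(dtype=float)
        if "optimum" in r:
            opt = float(r["optimum"])
        else:
            opt = float(np.quantile(x, r.get("optimum_quantile", 0.5)))
        if "breadth" in r:
            br = float(r["breadth"])
        else:
            spread = float(x.std()) or 1.0
            br = spread * float(r.get("breadth_factor", 0.5))
        responses.append(_synth.NicheResponse(
            predictor=r["predictor"], optimum=opt, breadth=br,
            weight=float(r.get("weight", 1.0)),
        ))
    return _synth.TrueNiche(responses=responses,
                            baseline=float(cfg.niche.get("baseline", 0.0)))


def _stage(name: str):
    log.info("stage %s ...", name)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage on a synthetic world and write all artifacts.

    Returns the run report (also written to ``outdir/report.json``);
    idempotent given the seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_sha256": config.sha256(),
            "seed": config.seed,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
    }
    (out / "config.yaml").write_text(config.to_yaml_text())

    # --- synth ---------------------------------------------------------
    t0 = _stage("synth")
    world = _synth.SyntheticWorldConfig(seed=config.seed, **config.world)
    dem = _synth.make_dem(world)
    fine_true, coarse, stations = _synth.make_monthly_climate(dem, world)
    write_ascii_grid(dem, out / "dem.asc")
    stations.to_csv(out / "stations.csv", index=False)
    _done("synth", t0)

    # --- network -------------------------------------------------------
    t0 = _stage("network")
    ncfg = config.network
    filled = _streams.fill_sinks(dem)
    flow = _streams.flow_direction(filled)
    flow = _streams.flow_accumulation(flow)
    mask = _streams.extract_streams(flow, ncfg["min_area_km2"])
    net = _streams.segment_reaches(mask, flow, ncfg["target_length_m"])
    _streams.characterize_network(
        net, filled, flow,
        search_radius=ncfg["valley_search_radius_m"],
        relief_threshold=ncfg["valley_relief_threshold_m"],
    )
    net.write_geojson(out / "network.geojson")
    net.to_dataframe().to_csv(out / "reaches.csv", index=False)
    report["network"] = {
        "n_reaches": len(net),
        "n_outlets": len(net.outlets()),
        "stream_cells": int(mask.sum()),
    }
    _done("network", t0)

    # --- downscale -----------------------------------------------------
    t0 = _stage("downscale")
    dcfg = config.downscale
    if dcfg.get("enabled", True):
        elev_coarse = _streams.RasterGrid(
            _synth._block_mean(dem.values, world.coarse_factor),
            coarse.cell_size, dem.origin,
        )
        bw = dcfg.get("bandwidth_m")
        if bw is None:
            cands = [c * coarse.cell_size
                     for c in dcfg["bandwidth_candidates_cells"]]
            rg = _streams.RasterGrid(coarse.tmin[0], coarse.cell_size, dem.origin)
            bw = _downscale.select_bandwidth(rg, elev_coarse, cands)
        st = stations if dcfg.get("use_stations", True) else None
        fine = _downscale.downscale_climate(coarse, elev_coarse, dem, bw,
                                            stations=st)
        report["downscale"] = {"bandwidth_m": float(bw)}
    else:
        fine = fine_true
        report["downscale"] = {"bandwidth_m": None, "skipped": True}
    write_climate_csv(fine, out / "climate_fine.csv")
    _done("downscale", t0)

    # --- bioclim / predictors -----------------------------------------
    t0 = _stage("bioclim")
    tables = {"present": _bioclim.reach_predictor_table(net, fine, flow)}
    for sc in config.scenarios:
        delta = _synth.ScenarioDelta(
            delta_t=sc["delta_t"], precip_scale=sc["precip_scale"],
            label=sc["label"],
        )
        # uniform deltas commute with the linear downscaling machinery, so
        # they are applied to the downscaled fine climate directly
        clim = _synth.apply_scenario(fine, delta)
        tables[sc["label"]] = _bioclim.reach_predictor_table(net, clim, flow)
    for label, tbl in tables.items():
        tbl.to_csv(out / f"predictors_{label}.csv")
    _done("bioclim", t0)

    # --- truth + presences --------------------------------------------
    t0 = _stage("presences")
    present = tables["present"]
    niche = _resolve_niche(config, present)
    truth = _synth.true_suitability(present, niche)
    midpoints = present[["x", "y"]]
    occurrences = _synth.sample_presences(
        truth, config.n_presences, config.seed, midpoints
    )
    occurrences.to_csv(out / "occurrences.csv", index=False)
    _done("presences", t0)

    # --- fit / select --------------------------------------------------
    t0 = _stage("fit")
    mcfg = config.model
    pred_cols = mcfg.get("predictors") or [
        r.predictor for r in niche.responses
    ]
    background = present[pred_cols]
    pres_rows = present.loc[occurrences["reach_id"], pred_cols]
    ecfg = _eval.EvaluationConfig(seed=config.seed, **{
        k: v for k, v in config.evaluation.items()
    })
    grid = _eval.candidate_grid(mcfg["betas"], mcfg["feature_class_sets"])
    cand = _eval.evaluate_candidates(grid, pres_rows, background, ecfg,
                                     mcfg["knots_per_hinge"])
    best = _eval.select_best(cand, ecfg.omission_e)
    cand.loc[best.name, "selected"] = True
    cand.to_csv(out / "candidates.csv", index=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        feats = _maxent.build_features(background, best["classes"],
                                       mcfg["knots_per_hinge"])
        model = _maxent.fit_maxent(feats, pres_rows, background,
                                   float(best["beta"]))
        validation = _eval.replicate_validation(
            float(best["beta"]), best["classes"], pres_rows, background, ecfg,
            mcfg["knots_per_hinge"],
        )
    validation.to_csv(out / "replicates.csv", index=False)
    (out / "model_lambdas.txt").write_text(model.to_lambdas_text())
    (out / "model_header.json").write_text(model.header_json())
    report["model"] = {
        "beta": float(best["beta"]),
        "classes": best["classes"],
        "aicc": float(best["aicc"]),
        "auc_ratio": float(best["auc_ratio"]),
        "p_value": float(best["p_value"]),
        "omission": float(best["omission"]),
        "auc": float(best["auc"]),
        "validation_mean_auc": float(validation["auc"].mean()),
        "validation_mean_omission": float(validation["omission_mtp"].mean()),
    }
    _done("fit", t0)

    # --- map / change --------------------------------------------------
    t0 = _stage("map")
    transform = mcfg.get("transform", "cloglog")
    suits = {}
    for label, tbl in tables.items():
        p = _maxent.predict(model, tbl[pred_cols], transform)
        suits[label] = pd.Series(p, index=tbl.index, name="P")
    train_pred = suits["present"].loc[occurrences["reach_id"]].to_numpy()
    mtp = _habitat.mtp_threshold(train_pred)
    mtp_used = float(np.clip(mtp, 1e-6, 0.499))
    if mtp_used != mtp:
        warnings.warn(f"MTP {mtp:.3g} clamped to {mtp_used:.3g} for classification")
    report["mtp"] = {"value": float(mtp), "used": mtp_used}

    lengths = net.to_dataframe().set_index("reach_id")["length_m"]
    elevs = net.to_dataframe().set_index("reach_id")["elevation_m"]
    class_maps = {}
    suit_df = pd.DataFrame(suits)
    suit_df.index.name = "reach_id"
    suit_df.to_csv(out / "suitability.csv")
    report["habitat_km"] = {}
    for label, p in suits.items():
        cm = _habitat.classify_suitability(p, mtp_used, scenario=label)
        class_maps[label] = cm
        km = _habitat.suitable_length_km(cm, lengths)
        report["habitat_km"][label] = km
        dens = _habitat.suitability_density(
            p, _habitat.DensityConfig(config.density["suitability_bandwidth"])
        )
        dens.to_csv(out / f"density_suitability_{label}.csv", index=False)
        egrid = np.linspace(float(elevs.min()), float(elevs.max()), 256)
        edens = _habitat.elevation_density(
            p, elevs, mtp_used,
            _habitat.DensityConfig(config.density["elevation_bandwidth_m"], egrid),
        )
        edens.to_csv(out / f"density_elevation_{label}.csv", index=False)
    classes_df = pd.DataFrame(
        {label: cm.classes for label, cm in class_maps.items()}
    )
    classes_df.index.name = "reach_id"
    classes_df.to_csv(out / "habitat_classes.csv")

    report["change"] = {}
    for sc in config.scenarios:
        label = sc["label"]
        summary = _habitat.change_analysis(
            class_maps["present"], class_maps[label], lengths
        )
        report["change"][label] = summary.as_dict()
    _done("map", t0)

    report["mean_suitable_elevation_m"] = {
        label: float(elevs[p > mtp_used].mean()) if (p > mtp_used).any() else None
        for label, p in suits.items()
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
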