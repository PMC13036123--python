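"""End-to-end pipeline stages.

Each stage reads its inputs from the run directory, writes its artifacts
there, and drops a JSON manifest (config hash, seed, input/output digests)
so any artifact can be traced to the exact configuration that produced
it.  Stages never mutate their inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import dilution as dil
from . import indi as indi_mod
from . import inversion as inv
from . import io as io_mod
from . import synthetic as syn
from .io import PipelineConfig, RunManifest
from .spectral import BAND_NAMES

log = logging.getLogger("indicot")

__all__ = ["STAGE_ORDER", "run_stage", "run_all"]


def _outdir(cfg: PipelineConfig) -> Path:
    p = Path(cfg.output_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the {produced_by!r} stage first"
        )
    return path


def _manifest(stage, cfg, out, inputs, outputs):
    m = RunManifest.create(stage, cfg, inputs=inputs, outputs=outputs)
    m.write(out / f"manifest_{stage}.json")


def simulate(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    gen = syn.GeneratorConfig(
        replicates=cfg.replicates,
        reflectance_noise=cfg.reflectance_noise,
        seed=cfg.seed,
    )
    obs = syn.generate_experiment(gen)
    table = out / "plot_table.csv"
    io_mod.write_plot_table(obs, table)
    log.info("simulate: %d plot records -> %s", len(obs), table)
    _manifest("simulate", cfg, out, [], [table])
    return table


def indices(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    table = _require(out / "plot_table.csv", "simulate")
    obs = io_mod.read_plot_table(table)
    enriched = inv.add_vegetation_indices(obs)
    dest = out / "indices_table.csv"
    enriched.to_csv(dest, index=False)
    log.info("indices: 14 vegetation indices appended -> %s", dest)
    _manifest("indices", cfg, out, [table], [dest])
    return dest


def build_indi(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    src = _require(out / "indices_table.csv", "indices")
    obs = pd.read_csv(src)
    results = {
        scheme: indi_mod.build_indi(obs, indicators=cfg.indicators, scheme=scheme)
        for scheme in indi_mod.SCHEMES
    }
    weights = pd.DataFrame(
        {scheme: res.weights.as_series() for scheme, res in results.items()}
    ).T
    weights.index.name = "scheme"
    weights.to_csv(out / "weights_report.csv")
    agreement = indi_mod.scheme_agreement(
        {s: r.indi for s, r in results.items()}, obs["stage"]
    )
    agreement.to_csv(out / "scheme_agreement.csv", index=False)
    obs = obs.copy()
    obs["indi"] = results[cfg.weighting_scheme].indi
    dest = out / "indi_table.csv"
    obs.to_csv(dest, index=False)
    log.info(
        "indi: scheme=%s weights=%s -> %s",
        cfg.weighting_scheme,
        dict(results[cfg.weighting_scheme].weights.as_series().round(4)),
        dest,
    )
    _manifest("indi", cfg, out, [src], [dest, out / "weights_report.csv", out / "scheme_agreement.csv"])
    return dest


def dilution_curves(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    table = _require(out / "plot_table.csv", "simulate")
    obs = io_mod.read_plot_table(table)
    curves = dil.fit_dilution_by_irrigation(obs, theta=cfg.theta)
    dest = out / "dilution_curves.csv"
    curves.to_csv(dest, index=False)
    a_resp, b_resp = _responses_from_frame(curves)
    payload = {
        "a": {"coefficients": list(a_resp.coefficients), "r_squared": a_resp.r_squared},
        "b": {"coefficients": list(b_resp.coefficients), "r_squared": b_resp.r_squared},
        "i_range_mm": list(a_resp.i_range),
    }
    (out / "irrigation_responses.json").write_text(json.dumps(payload, indent=2))
    for _, row in curves.iterrows():
        log.info(
            "dilution: I=%.2f mm a=%.4f b=%.4f R2=%.3f",
            row["irrigation_mm"], row["a"], row["b"], row["r_squared"],
        )
    _manifest("dilution", cfg, out, [table], [dest, out / "irrigation_responses.json"])
    return dest


def _responses_from_frame(curves: pd.DataFrame):
    a_resp = dil.fit_quadratic_response(curves["irrigation_mm"], curves["a"], name="a")
    b_resp = dil.fit_quadratic_response(curves["irrigation_mm"], curves["b"], name="b")
    return a_resp, b_resp


def nni(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    src = _require(out / "indi_table.csv", "indi")
    _require(out / "dilution_curves.csv", "dilution")
    obs = pd.read_csv(src)
    curves = pd.read_csv(out / "dilution_curves.csv")
    a_resp, b_resp = _responses_from_frame(curves)
    nc = dil.nc_model(obs["irrigation_mm"].to_numpy(), obs["dm"].to_numpy(), a_resp, b_resp)
    obs["nc"] = nc
    obs["nni"] = obs["lnc_upper"] / obs["nc"]
    obs["nni_class"] = dil.classify_nni(obs["nni"].to_numpy(), delta=cfg.class_delta)
    dest = out / "nni_table.csv"
    obs.to_csv(dest, index=False)
    links = inv.indi_nni_link(obs["indi"], obs["nni"], obs["stage"])
    (out / "indi_nni_link.json").write_text(json.dumps(links, indent=2, sort_keys=True))
    log.info("nni: per-stage INDI->NNI R2 = %s",
             {s: round(v["r2"], 3) for s, v in links.items()})
    _manifest("nni", cfg, out, [src], [dest, out / "indi_nni_link.json"])
    return dest


def train(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    src = _require(out / "indi_table.csv", "indi")
    obs = pd.read_csv(src)
    target = "indi"
    if cfg.use_default_features:
        features = list(inv.DEFAULT_FEATURES[target])
    else:
        from .spectral import VI_NAMES

        candidates = [n for n in VI_NAMES if n in obs.columns]
        screen = inv.pearson_screen(
            obs[candidates], obs[target], threshold=cfg.screen_threshold
        )
        for name, reason in screen.removed.items():
            log.info("screen: dropped %s (%s)", name, reason)
        filt = inv.collinearity_filter(
            obs[screen.selected], obs[target], r_max=cfg.r_max, vif_max=cfg.vif_max
        )
        for name, reason in filt.removed.items():
            log.info("collinearity: dropped %s (%s)", name, reason)
        features = filt.selected
    spec = inv.ModelSpec(family=cfg.model_family, seed=cfg.seed)
    model, result, details = inv.train_inversion_model(
        obs[features], obs[target], spec, stage_labels=obs["stage"]
    )
    dest = out / "model.joblib"
    joblib.dump({"model": model, "features": features, "target": target}, dest)
    metrics = {
        "target": target,
        "family": cfg.model_family,
        "features": features,
        "r2": result.r2,
        "rmse": result.rmse,
        "re_pct": result.re_pct,
        "n_validation": result.n,
        "best_params": details["best_params"],
    }
    (out / "metrics_report.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    log.info("train: %s held-out R2=%.3f RMSE=%.3f params=%s",
             cfg.model_family, result.r2, result.rmse, details["best_params"])
    _manifest("train", cfg, out, [src], [dest, out / "metrics_report.json"])
    return dest


def invert(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    table = _require(out / "plot_table.csv", "simulate")
    model_path = _require(out / "model.joblib", "train")
    obs = io_mod.read_plot_table(table)
    bundle = joblib.load(model_path)
    raster, layout, _ = syn.rasterize_stage(
        obs, cfg.map_stage, pixel_size=cfg.pixel_size,
        noise_scale=cfg.reflectance_noise, seed=cfg.seed,
    )
    io_mod.write_layout_geojson(layout, out / "plot_layout.geojson")
    inverted = inv.invert_raster(bundle["model"], raster, bundle["features"])
    dest = out / f"indi_{cfg.map_stage}.tif"
    io_mod.write_raster(inverted, dest)
    log.info("invert: stage=%s grid=%s -> %s", cfg.map_stage, inverted.shape, dest)
    _manifest("invert", cfg, out, [table, model_path], [dest])
    return dest


def classify(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    tif = _require(out / f"indi_{cfg.map_stage}.tif", "invert")
    links_path = _require(out / "indi_nni_link.json", "nni")
    links = json.loads(links_path.read_text())
    raster = io_mod.read_raster(tif)
    raster.classes = inv.classify_map(
        raster.indi, cfg.map_stage, links, delta=cfg.class_delta, mask=np.isfinite(raster.indi)
    )
    dest = out / f"classes_{cfg.map_stage}.tif"
    io_mod.write_raster(raster, dest)
    counts = {int(k): int(v) for k, v in
              zip(*np.unique(raster.classes, return_counts=True))}
    log.info("map: class pixel counts %s -> %s", counts, dest)
    _manifest("map", cfg, out, [tif, links_path], [dest])
    return dest


def report(cfg: PipelineConfig) -> Path:
    out = _outdir(cfg)
    summary = {}
    for name in ("weights_report.csv", "dilution_curves.csv", "metrics_report.json",
                 "indi_nni_link.json", "scheme_agreement.csv"):
        p = out / name
        summary[name] = "present" if p.exists() else "missing"
    if (out / "metrics_report.json").exists():
        summary["metrics"] = json.loads((out / "metrics_report.json").read_text())
    dest = out / "report.json"
    dest.write_text(json.dumps(summary, indent=2, sort_keys=True))
    _manifest("report", cfg, out, [], [dest])
    return dest


STAGE_ORDER = {
    "simulate": simulate,
    "indices": indices,
    "indi": build_indi,
    "dilution": dilution_curves,
    "nni": nni,
    "train": train,
    "invert": invert,
    "map": classify,
    "report": report,
}


def run_stage(name: str, cfg: PipelineConfig) -> Path:
    if name not in STAGE_ORDER and name != "all":
        raise ValueError(f"unknown stage {name!r}; valid: {list(STAGE_ORDER) + ['all']}")
    if name == "all":
        return run_all(cfg)
    return STAGE_ORDER[name](cfg)


def run_all(cfg: PipelineConfig) -> Path:
    for name, fn in STAGE_ORDER.items():
        fn(cfg)
    return Path(cfg.output_dir) / "report.json"
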