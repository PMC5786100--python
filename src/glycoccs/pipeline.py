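"""Configured end-to-end runs: calibration → comparison → ensemble → H-bonds.

A run is described by a single YAML key-value file with one block per
stage; unknown keys (top-level or inside a block) are errors, not
warnings — silent misconfiguration is worse than failure.  Paths may use
the ``builtin:`` prefix to reference tables packaged with glycoccs.
The report is a plain dict, serialized as JSON with sorted keys and no
timestamps, so identical config + seed reproduces a byte-identical
file.  All rounding happens at render time; the JSON carries full
precision alongside explicitly ``*_rounded`` display fields.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import (cluster_ensemble, major_conformers, rmsf, shape_descriptor,
                       weighted_ccs_distribution)
from .calibration import (apply_calibration, calibration_report, fit_calibration,
                          read_analyte_table, read_calibrant_table)
from .ccs import TrajectoryParams, ccs_for_conformers
from .compare import (isomer_separation, load_isomer_pairs, load_published_table,
                      protonation_delta, state_statistics)
from .ensemble import ConformerEnsemble
from .errors import ConfigError, GlycoCCSError
from .gas import load_gas
from .hbonds import HBondCriteria, categorize_hbonds, detect_hbonds, hbond_occupancy_map
from .synthetic import make_glycan_mimic, make_two_state_ensemble, plant_hbond

logger = logging.getLogger(__name__)

_STAGE_KEYS = {
    "calibration": {"calibrants", "analytes"},
    "comparison": {"table", "pairs"},
    "synthetic_ensemble": {"n_frames", "weight_a", "rmsd_separation", "noise_sigma",
                           "n_atoms"},
    "clustering": {"threshold"},
    "ccs": {"method", "gas", "temperature", "n_orientations", "n_darts", "n_points",
            "max_cycles"},
    "hbonds": {"mimic", "n_frames", "planted", "r_max", "theta_max"},
}
_TOP_KEYS = set(_STAGE_KEYS) | {"seed"}
_MIMIC_KEYS = {"core_length", "arm13_length", "arm16_length", "fucose"}
_PLANT_KEYS = {"donor_residue", "acceptor_residue", "r_xy", "theta", "fraction"}


def _resolve(path: str) -> Path:
    if path.startswith("builtin:"):
        return Path(str(resources.files("glycoccs").joinpath("data/" + path[8:])))
    return Path(path)


def _check_keys(name: str, block: dict, allowed: set[str]) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"stage {name!r}: unknown keys {sorted(unknown)}; "
                          f"allowed: {sorted(allowed)}")


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        data = yaml.safe_load(Path(config).read_text())
    else:
        data = dict(config)
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level config keys {sorted(unknown)}; "
                          f"allowed: {sorted(_TOP_KEYS)}")
    for name, allowed in _STAGE_KEYS.items():
        if name in data:
            if not isinstance(data[name], dict):
                raise ConfigError(f"stage {name!r} must be a mapping")
            _check_keys(name, data[name], allowed)
    return data


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_calibration(block: dict) -> dict:
    series = read_calibrant_table(_resolve(block["calibrants"]))
    model = fit_calibration(series)
    report = calibration_report(model, series)
    out = {
        "slope_A2_per_ms": model.slope,
        "intercept_A2": model.intercept,
        "r_squared": model.r_squared,
        "n_points": model.n_points,
        "max_abs_residual_A2": float(report["residual_A2"].abs().max()),
        "printed_style": {
            "slope": round(model.slope, 1),
            "intercept": round(model.intercept),
            "r_squared": round(model.r_squared, 3),
        },
    }
    if "analytes" in block:
        analytes = read_analyte_table(_resolve(block["analytes"]))
        ccs = apply_calibration(model, analytes["drift_ms"].to_numpy())
        out["analytes"] = [
            {"species": str(s), "drift_ms": float(t), "ccs_A2": float(c),
             "ccs_A2_rounded": int(round(c))}
            for s, t, c in zip(analytes["species"], analytes["drift_ms"], ccs)
        ]
    return out


def _stage_comparison(block: dict) -> dict:
    records = load_published_table(
        _resolve(block["table"]) if "table" in block else None)
    stats = state_statistics(records)
    delta = protonation_delta(records)
    pairs = load_isomer_pairs(_resolve(block["pairs"]) if "pairs" in block else None)
    out = {
        "records": [
            {"glycan": r.glycan, "exp_ccs_A2": r.exp_ccs,
             "calc_n2_A2": dict(sorted(r.calc_n2.items())),
             "pct_diff": {s: r.percent_diff(s) for s in sorted(r.calc_n2)},
             "pct_diff_printed_style": {s: round(abs(r.percent_diff(s)), 1)
                                        for s in sorted(r.calc_n2)}}
            for r in records
        ],
        "pearson_r": stats["pearson_r"],
        "avg_abs_pct_diff": stats["avg_abs_pct_diff"],
        "avg_abs_pct_diff_printed": stats["avg_abs_pct_diff_printed"],
        "protonation_delta": {
            "per_glycan": dict(sorted(delta.per_glycan.items())),
            "mean": delta.mean, "mean_rounded": round(delta.mean),
            "argmax": list(delta.argmax), "argmin": list(delta.argmin),
        },
        "isomer_separation": isomer_separation(records, pairs),
    }
    return out


def _stage_ensemble(cfg: dict, seed: int) -> dict:
    syn = cfg.get("synthetic_ensemble", {})
    ensemble, truth = make_two_state_ensemble(
        n_frames=int(syn.get("n_frames", 60)),
        weight_a=float(syn.get("weight_a", 0.6)),
        rmsd_separation=float(syn.get("rmsd_separation", 10.0)),
        noise_sigma=float(syn.get("noise_sigma", 0.1)),
        n_atoms=int(syn.get("n_atoms", 20)),
        seed=seed,
    )
    clu = cfg.get("clustering", {})
    clusterset = cluster_ensemble(ensemble, threshold=float(clu.get("threshold", 2.5)))
    ccs_cfg = cfg.get("ccs", {})
    gas = load_gas(str(ccs_cfg.get("gas", "He")),
                   temperature=float(ccs_cfg.get("temperature", 300.0)))
    method = str(ccs_cfg.get("method", "projection"))
    params = TrajectoryParams(seed=seed,
                              n_points=int(ccs_cfg.get("n_points", 25)),
                              max_cycles=int(ccs_cfg.get("max_cycles", 40)))
    results = ccs_for_conformers(
        ensemble, clusterset.medoids, method, gas, params=params,
        n_orientations=int(ccs_cfg.get("n_orientations", 100)),
        n_darts=int(ccs_cfg.get("n_darts", 2000)))
    dist = weighted_ccs_distribution(clusterset, dict(enumerate(results)))
    fluct = rmsf(ensemble)
    shapes = [shape_descriptor(ensemble.conformer(m)) for m in clusterset.medoids]
    return {
        "n_frames": ensemble.n_conformers,
        "true_state_fractions": {str(k): v / ensemble.n_conformers
                                 for k, v in truth.state_counts.items()},
        "n_clusters": len(clusterset.clusters),
        "clusters": [
            {"medoid": c.medoid, "weight": c.weight, "size": len(c.members)}
            for c in clusterset.clusters
        ],
        "major_conformers": [{"medoid": m, "weight": w}
                             for m, w in major_conformers(clusterset)],
        "medoid_ccs_A2": [{"omega": r.omega, "standard_error": r.standard_error,
                           "method": r.method, "gas": r.gas} for r in results],
        "weighted_mean_ccs_A2": dist.weighted_mean,
        "distribution_support": [list(p) for p in dist.support],
        "medoid_shapes": [{"kappa_squared": s.kappa_squared, "label": s.label,
                           "gyration_radius_A": s.gyration_radius} for s in shapes],
        "mean_rmsf_A": float(fluct.values.mean()),
    }


def _stage_hbonds(block: dict, seed: int) -> dict:
    mimic_cfg = dict(block.get("mimic", {}))
    _check_keys("hbonds.mimic", mimic_cfg, _MIMIC_KEYS)
    single, annotation = make_glycan_mimic(
        core_length=int(mimic_cfg.get("core_length", 2)),
        arm13_length=int(mimic_cfg.get("arm13_length", 3)),
        arm16_length=int(mimic_cfg.get("arm16_length", 2)),
        fucose=bool(mimic_cfg.get("fucose", False)),
        seed=seed,
    )
    n_frames = int(block.get("n_frames", 20))
    ensemble = ConformerEnsemble(single.atoms,
                                 np.repeat(single.coords, n_frames, axis=0))
    planted_info = []
    for plant in block.get("planted", []):
        _check_keys("hbonds.planted[]", dict(plant), _PLANT_KEYS)
        fraction = float(plant.get("fraction", 1.0))
        frames = list(range(int(round(fraction * n_frames))))
        ensemble, rec = plant_hbond(ensemble, int(plant["donor_residue"]),
                                    int(plant["acceptor_residue"]),
                                    float(plant["r_xy"]), float(plant["theta"]),
                                    frames=frames)
        planted_info.append({"donor_residue": int(plant["donor_residue"]),
                             "acceptor_residue": int(plant["acceptor_residue"]),
                             "r_xy": rec.distance, "theta": rec.angle,
                             "fraction": len(rec.frames) / n_frames})
    criteria = HBondCriteria(r_max=float(block.get("r_max", 3.5)),
                             theta_max=float(block.get("theta_max", 30.0)))
    hmap = hbond_occupancy_map(ensemble, criteria, annotation)
    bonds = [detect_hbonds(ensemble, f, criteria) for f in range(n_frames)]
    summary = categorize_hbonds(bonds, annotation, ensemble.residue_indices)
    return {
        "planted": planted_info,
        "criteria": {"r_max_A": criteria.r_max, "theta_max_deg": criteria.theta_max},
        "occupancy": {f"{i}-{j}": occ for (i, j), occ in sorted(hmap.occupancy.items())},
        "avg_bonds_per_conformer": summary.avg_count,
        "category_percentages": summary.percentages,
        "n_categorized": summary.n_categorized,
        "n_other": summary.n_other,
    }


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_pipeline(config: str | Path | dict, seed: int | None = None) -> dict:
    """Execute the configured stages in order and return the report dict.

    ``seed`` overrides the config's seed.  Stage failures abort the run
    with the stage name in the error; stages absent from the config are
    marked skipped in the report.
    """
    cfg = load_config(config)
    run_seed = int(seed if seed is not None else cfg.get("seed", 0))
    canonical = json.dumps(cfg | {"seed": run_seed}, sort_keys=True)
    report: dict = {
        "meta": {
            "package": "glycoccs",
            "version": __version__,
            "seed": run_seed,
            "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        },
    }
    stages = (
        ("calibration", lambda: _stage_calibration(cfg["calibration"])),
        ("comparison", lambda: _stage_comparison(cfg["comparison"])),
        ("ensemble", lambda: _stage_ensemble(cfg, run_seed)),
        ("hbonds", lambda: _stage_hbonds(cfg["hbonds"], run_seed)),
    )
    for name, runner in stages:
        key = {"ensemble": "synthetic_ensemble"}.get(name, name)
        if key not in cfg:
            report[name] = {"skipped": True}
            continue
        try:
            logger.info("running stage %s", name)
            report[name] = runner()
        except GlycoCCSError as exc:
            raise ConfigError(f"stage {name!r} failed: {exc}") from exc
    return report


def render_report(report: dict) -> str:
    """Human-readable plain-text rendering of a report dict."""
    lines = [f"glycoccs {report['meta']['version']} report (seed {report['meta']['seed']})"]
    cal = report.get("calibration", {})
    if cal and not cal.get("skipped"):
        ps = cal["printed_style"]
        lines.append(
            f"calibration: CCS = {ps['slope']} x t + {ps['intercept']} "
            f"(R^2 = {ps['r_squared']}, n = {cal['n_points']})")
        for a in cal.get("analytes", []):
            lines.append(f"  {a['species']:<12s} t = {a['drift_ms']:.2f} ms  "
                         f"CCS = {a['ccs_A2_rounded']} A^2")
    cmp_block = report.get("comparison", {})
    if cmp_block and not cmp_block.get("skipped"):
        pr = cmp_block["pearson_r"]
        av = cmp_block["avg_abs_pct_diff_printed"]
        lines.append(f"comparison: r(P3) = {pr['p3']:.2f}, r(P6) = {pr['p6']:.2f}; "
                     f"avg |%diff| P3 = {av['p3']:.1f}, P6 = {av['p6']:.1f}")
        pd_block = cmp_block["protonation_delta"]
        lines.append(f"  mean |dCCS(P3, P6)| = {pd_block['mean_rounded']} A^2 "
                     f"(max {', '.join(pd_block['argmax'])}; min {', '.join(pd_block['argmin'])})")
        for row in cmp_block["isomer_separation"]:
            lines.append(f"  pair {row['pair']}: calc {row['calc_delta']:+.0f} A^2, "
                         f"exp {row['exp_delta']:+.0f} A^2")
    ens = report.get("ensemble", {})
    if ens and not ens.get("skipped"):
        lines.append(f"ensemble: {ens['n_clusters']} clusters from {ens['n_frames']} frames; "
                     f"weighted mean CCS = {ens['weighted_mean_ccs_A2']:.1f} A^2")
    hb = report.get("hbonds", {})
    if hb and not hb.get("skipped"):
        cats = ", ".join(f"{k} {v:.0f}%" for k, v in hb["category_percentages"].items())
        lines.append(f"h-bonds: {hb['avg_bonds_per_conformer']:.2f} per conformer; {cats}")
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write report.json (sorted keys, byte-stable) and report.txt; returns JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    json_path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    (out / "report.txt").write_text(render_report(report))
    return json_path
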