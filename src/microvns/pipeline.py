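"""Configuration-driven orchestration of the two study arms.

``run_em_study`` reproduces the electromagnetic comparison (planar
spiral vs solenoid on a nerve block; planar spiral on cylindrical and
flattened nerves; cuff-electrode eVNS), emitting activation summaries,
depth profiles, VTK field maps and a comparison table.
``run_morphometry_study`` runs synthetic-image generation →
segmentation → measurement → classification → clustering → regression,
in single-seed or multi-seed batch mode.  Every output directory gets a
manifest (config hash, seeds, package version).
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activation_metrics as am
from . import coil_geometry as cg
from . import em_fields as em
from . import evns_conduction as ev
from . import fiber_clustering as fc
from . import fiber_morphometry as fm
from . import pulse_waveforms as pw
from . import synthetic_tem as st
from .io import write_manifest, write_vtk_polyline, write_vtk_structured

log = logging.getLogger("microvns")

__all__ = [
    "default_em_config",
    "default_morphometry_config",
    "run_em_study",
    "run_morphometry_study",
    "load_config",
    "apply_overrides",
]


def default_em_config() -> dict:
    return {
        "grid_spacing_m": 5e-6,
        "standoff_m": 5e-6,
        "max_seg_m": 15e-6,
        "drive": {
            "convention": "harmonic",  # or "pulse_support_rms"
            "I_peak_A": 10.0,
            "pulse_width_s": 10e-6,
            "n_pulses": 5,
            "rate_hz": 20.0,
        },
        "spiral": {"n_turns": 8.5, "trace_width_m": 7e-6, "nominal_L_H": 33e-9},
        "solenoid": {"n_turns": 21.0, "wire_width_m": 7e-6, "nominal_L_H": 100e-9},
        "nerves": ["block", "cylinder", "ellipse"],
        "evns": {"enabled": True, "amplitude_A": 0.5e-3, "separation_m": 1.5e-3},
        "af_threshold": 1e5,
        "e_level": 6.0,
        "write_vtk": True,
        "refine_af": True,
    }


def default_morphometry_config() -> dict:
    return {
        "seeds": [1],
        "nerve_semi_axes_um": [160.0, 160.0],
        "fiber_count": 2000,
        "median_diameter_um": 2.98,
        "radial_slope": -0.009,
        "pixel_size_um": 0.2,
        "noise_sd": 6.0,
        "hotspots": [],
        "size_threshold": "median",
        "cluster_threshold_um": 2.97,
        "k": 11,
        "replicates": 5,
        "use_ground_truth": False,
        "write_overlay": True,
    }


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def apply_overrides(config: dict, overrides) -> dict:
    """Apply ``a.b.c=value`` dotted-key overrides (YAML-parsed values)."""
    for item in overrides or ():
        key, _, raw = item.partition("=")
        val = yaml.safe_load(raw)
        if isinstance(val, str):
            # YAML 1.1 misses bare scientific notation like 2e-5
            try:
                val = float(val)
            except ValueError:
                pass
        node = config
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = val
    return config


def _drive_factor(cfg: dict) -> float:
    d = cfg["drive"]
    train = pw.PulseTrain(
        I_peak=d["I_peak_A"],
        pulse_width=d["pulse_width_s"],
        n_pulses_per_train=d["n_pulses"],
        intra_train_rate=d["rate_hz"],
    )
    if d.get("convention", "harmonic") == "harmonic":
        return pw.harmonic_drive_factor(train)
    return pw.exponential_pulse_rms_didt(train.I_peak, train.pulse_width)


def build_coils(cfg: dict):
    """Calibrated spiral + solenoid placed at the configured standoff."""
    standoff = cfg["standoff_m"]
    sp = cg.default_spiral_spec(
        n_turns=cfg["spiral"]["n_turns"],
        conductor_width=cfg["spiral"]["trace_width_m"],
        nominal_inductance=cfg["spiral"]["nominal_L_H"],
    )
    sp = cg.calibrate_spiral_pitch(sp)
    sp = replace(sp, center=(0.0, 0.0, standoff))
    sol = cg.default_solenoid_spec(
        n_turns=cfg["solenoid"]["n_turns"],
        conductor_width=cfg["solenoid"]["wire_width_m"],
        nominal_inductance=cfg["solenoid"]["nominal_L_H"],
    )
    sol = cg.calibrate_solenoid_radius(sol)
    r = sol.outer_extent[1] / 2.0
    sol = replace(sol, center=(0.0, 0.0, standoff + r), axis=(1, 0, 0), in_plane=(0, 1, 0))
    return sp, sol


def _solve_coil(path, tissue, drive, refine_af=True, af_threshold=1e5, e_level=6.0):
    A = em.vector_potential(path, tissue.grid)
    Ep = em.primary_e_field(A, drive)
    Et = em.conduction_correction(tissue, Ep)
    mask = tissue.mask
    mag = np.where(mask, Et.magnitude, 0.0)
    af = am.activating_function(Et, tissue.fiber_axis, mask)
    voa = am.volume_of_activation(af, af_threshold)
    af_max = float(np.abs(af.af_values[mask]).max())
    if refine_af:
        af_max = am.af_max_refined(path, tissue, Ep, Et, drive)
    layer_max = mag.max(axis=(0, 1))[::-1]  # surface -> deep
    z_step = tissue.grid.spacing[2]
    offsets = (np.arange(layer_max.size) + 0.5) * z_step - 0.5 * z_step
    profile = pd.DataFrame(
        {"offset_m": offsets, "e_rms": layer_max,
         "grad_e": np.abs(np.gradient(layer_max, z_step))}
    )
    depth6 = am.first_crossing(offsets, layer_max, e_level)
    kpk = int(np.argmax(profile["grad_e"]))
    summary = am.ActivationSummary(
        e_max_rms=float(mag.max()),
        af_max_abs=af_max,
        voa=voa,
        voc=tissue.nerve_volume,
        selectivity=voa / tissue.nerve_volume,
        depth_at_6Vpm=depth6,
        peak_grad_value=float(profile["grad_e"].iloc[kpk]),
        peak_grad_offset=float(profile["offset_m"].iloc[kpk]),
    )
    return {"summary": summary, "profile": profile, "field": Et, "af": af}


def run_em_study(config: dict | None = None, outdir=None, dry_run: bool = False) -> dict:
    """Solve the configured µM-VNS / eVNS comparison; return a report dict."""
    cfg = default_em_config()
    if config:
        cfg = {**cfg, **config}
    h = cfg["grid_spacing_m"]
    if dry_run:
        sizes = {
            "block": em.nerve_block(spacing=h).grid.shape,
            "cylinder": em.nerve_cylinder(spacing=h).grid.shape,
        }
        return {"config": cfg, "grid_sizes": sizes, "dry_run": True}

    drive = _drive_factor(cfg)
    spiral_spec, solenoid_spec = build_coils(cfg)
    spiral = cg.build_planar_spiral(spiral_spec, cfg["max_seg_m"])
    solenoid = cg.build_solenoid(solenoid_spec, cfg["max_seg_m"])
    report: dict = {"config": cfg, "drive_didt_rms": drive}
    results = {}

    if "block" in cfg["nerves"]:
        block = em.nerve_block(spacing=h)
        log.info("solving planar spiral on nerve block %s", block.grid.shape)
        results["block_spiral"] = _solve_coil(
            spiral, block, drive, cfg["refine_af"], cfg["af_threshold"], cfg["e_level"]
        )
        log.info("solving solenoid on nerve block")
        results["block_solenoid"] = _solve_coil(
            solenoid, block, drive, cfg["refine_af"], cfg["af_threshold"], cfg["e_level"]
        )
        comp = am.compare_coils(
            results["block_spiral"]["profile"], results["block_solenoid"]["profile"]
        )
        if comp["crossover_depth_m"] is None:
            # spiral superior over the whole solved depth
            comp["superiority_depth_m"] = float(
                results["block_spiral"]["profile"]["offset_m"].iloc[-1]
            )
        else:
            comp["superiority_depth_m"] = comp["crossover_depth_m"]
        report["coil_comparison"] = comp

    if "cylinder" in cfg["nerves"]:
        cyl = em.nerve_cylinder(spacing=h)
        log.info("solving planar spiral on cylindrical nerve")
        results["cylinder_spiral"] = _solve_coil(
            spiral, cyl, drive, cfg["refine_af"], cfg["af_threshold"], cfg["e_level"]
        )
        if cfg["evns"]["enabled"]:
            cyl_e = em.nerve_cylinder(spacing=max(h, 10e-6), length=3e-3)
            pair = ev.ElectrodePair(
                separation=cfg["evns"]["separation_m"],
                amplitude=cfg["evns"]["amplitude_A"],
            )
            log.info("solving eVNS cuff pair on cylindrical nerve")
            sol_e = ev.solve_evns(cyl_e, pair)
            report["evns_cylinder"] = {
                k: v for k, v in ev.evns_activation(sol_e, cyl_e).items()
            }

    if "ellipse" in cfg["nerves"]:
        ell = em.nerve_ellipse_cylinder(spacing=h)
        log.info("solving planar spiral on flattened nerve")
        results["ellipse_spiral"] = _solve_coil(
            spiral, ell, drive, cfg["refine_af"], cfg["af_threshold"], cfg["e_level"]
        )

    report["summaries"] = {
        k: v["summary"].__dict__ for k, v in results.items()
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for k, v in results.items():
            v["profile"].to_csv(outdir / f"profile_{k}.csv", index=False)
            if cfg["write_vtk"]:
                write_vtk_structured(outdir / f"field_{k}.vtk", v["field"])
        write_vtk_polyline(outdir / "coil_spiral.vtk", spiral)
        write_vtk_polyline(outdir / "coil_solenoid.vtk", solenoid)
        with open(outdir / "em_report.json", "w") as fh:
            json.dump(
                {kk: vv for kk, vv in report.items() if kk != "config"},
                fh, indent=2, default=_jsonable,
            )
        write_manifest(outdir, cfg, seeds=None)
    return {"report": report, "results": results}


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, am.ActivationSummary):
        return o.__dict__
    return str(o)


def _morph_spec(cfg: dict, seed: int) -> st.SyntheticNerveSpec:
    return st.SyntheticNerveSpec(
        nerve_semi_axes=tuple(cfg["nerve_semi_axes_um"]),
        target_fiber_count=cfg["fiber_count"],
        diameter_mixture=st.calibrated_mixture(cfg["median_diameter_um"]),
        radial_slope=cfg["radial_slope"],
        pixel_size=cfg["pixel_size_um"],
        noise_sd=cfg["noise_sd"],
        clustering_hotspots=tuple(tuple(hs) for hs in cfg["hotspots"]),
        seed=seed,
    )


def run_morphometry_seed(cfg: dict, seed: int) -> dict:
    """One generate → segment → measure → classify → cluster → regress run."""
    spec = _morph_spec(cfg, seed)
    truth = st.sample_population(spec)
    img, boundary, origin = st.render_image(truth, spec)
    if cfg["use_ground_truth"]:
        records = truth.copy()
    else:
        labels = fm.segment_fibers(img)
        records = fm.measure_fibers(labels, spec.pixel_size, boundary, origin)
    records = fm.classify_size(records, cfg["size_threshold"])
    summary = fm.summarize(records, boundary, spec.pixel_size)
    regression = fm.diameter_distance_regression(records)
    large = records[records["diameter_um"] > cfg["cluster_threshold_um"]]
    cluster = None
    if len(large) >= cfg["k"]:
        weights = fc.assign_weights(large)
        cluster = fc.weighted_kmeans(
            large[["x_um", "y_um"]].to_numpy(), weights,
            k=cfg["k"], replicates=cfg["replicates"], seed=seed,
        )
        cluster = fc.classify_cluster_location(cluster, boundary)
    return {
        "spec": spec,
        "truth": truth,
        "records": records,
        "summary": summary,
        "regression": regression,
        "cluster": cluster,
        "image": img,
        "boundary": boundary,
        "origin": origin,
    }


def run_morphometry_study(config: dict | None = None, outdir=None) -> dict:
    """Run the morphometry arm over the configured seeds."""
    cfg = default_morphometry_config()
    if config:
        cfg = {**cfg, **config}
    per_seed = []
    slopes, medians = [], []
    for seed in cfg["seeds"]:
        log.info("morphometry run, seed %d", seed)
        r = run_morphometry_seed(cfg, seed)
        per_seed.append(r)
        slopes.append(r["regression"]["slope"])
        medians.append(r["summary"].median_diameter_um)
    agg = {
        "n_seeds": len(cfg["seeds"]),
        "mean_slope": float(np.mean(slopes)),
        "sd_slope": float(np.std(slopes, ddof=1)) if len(slopes) > 1 else 0.0,
        "mean_median_diameter_um": float(np.mean(medians)),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for r, seed in zip(per_seed, cfg["seeds"]):
            tag = f"seed{seed:03d}"
            r["records"].to_csv(outdir / f"fibers_{tag}.csv", index=False)
            r["summary"].to_json(outdir / f"summary_{tag}.json")
            with open(outdir / f"regression_{tag}.json", "w") as fh:
                json.dump(r["regression"], fh, indent=2)
            if r["cluster"] is not None:
                np.savetxt(outdir / f"centroids_{tag}.csv", r["cluster"].centroids,
                           delimiter=",", header="x_um,y_um", comments="")
            if cfg["write_overlay"]:
                _write_overlay(outdir / f"overlay_{tag}.png", r)
        with open(outdir / "aggregate.json", "w") as fh:
            json.dump(agg, fh, indent=2)
        write_manifest(outdir, cfg, seeds=list(cfg["seeds"]))
    return {"per_seed": per_seed, "aggregate": agg, "config": cfg}


def _write_overlay(path, result) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = result["image"]
    origin = result["origin"]
    px = result["spec"].pixel_size
    fig, ax = plt.subplots(figsize=(6, 6))
    extent = [origin[1], origin[1] + img.shape[1] * px,
              origin[0] + img.shape[0] * px, origin[0]]
    ax.imshow(img, cmap="gray", extent=extent)
    rec = result["records"]
    large = rec[rec["size_class"] == "large"]
    ax.scatter(large["y_um"], large["x_um"], s=2, c="tab:red", alpha=0.5, lw=0)
    if result["cluster"] is not None:
        c = result["cluster"].centroids
        ax.scatter(c[:, 1], c[:, 0], marker="x", s=80, c="tab:blue")
    ax.set_xlabel("y (µm)")
    ax.set_ylabel("x (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
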