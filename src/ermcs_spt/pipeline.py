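"""End-to-end orchestration: simulate -> track -> map -> landscape -> states -> dwell,
and volume -> contacts -> mesh -> curvature.

Every stage is also callable on its own; ``run_pipeline`` wires them in
dependency order, writes each artifact plus a resolved-config snapshot to
the run directory, and aggregates a machine-readable JSON report.  All
randomness derives from the single config seed through named
``SeedSequence`` spawns, so a rerun with the same config is byte-identical.
A failure while analysing one site flags that site and moves on.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import io as pio
from . import difflandscape, sitemap, statedyn, trackasm
from .simkit import SimulationConfig, image_and_localize, make_er_geometry, simulate_molecules

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},            # SimulationConfig field overrides
    "geometry": {},            # make_er_geometry overrides
    "filter": {"band": [20.0, 30.0]},
    "link": {"max_disp_nm": 400.0, "max_gap": 1},
    "curate": {"ratio_max": 2.0},
    "map": {"bin_size_nm": 30.0},
    "detect": {"theta": 5.0, "min_area_bins": 4},
    "associate": {"max_gap_nm": 250.0},
    "landscape": {"min_steps": 20},
    "classify": {"phi": 0.5, "window": 15},
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


def resolve_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in (config or {}).items():
        if key not in _KNOWN_KEYS:
            raise ValueError(f"unknown config key {key!r}; known: {sorted(_KNOWN_KEYS)}")
        if isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _spawn_seed(seed: int, label: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(label)]).generate_state(1)[0] % (2**31))


def run_pipeline(config: dict | None = None, out_dir: str | Path = "run",
                 locs=None, geometry=None) -> dict:
    """Run the tracking-side pipeline end to end and write artifacts.

    With no ``locs`` given, inputs are simulated from the config's geometry
    and simulation blocks.  Returns the report dict (also written to
    ``report.json``).
    """
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_resolved.json").write_text(json.dumps(cfg, sort_keys=True, indent=1))
    seed = int(cfg["seed"])

    report: dict = {"stages": [], "seed": seed}

    if geometry is None:
        geometry = make_er_geometry(**cfg["geometry"])
    sidecar = None
    if locs is None:
        sim_cfg = SimulationConfig(**{**cfg["simulate"], "seed": _spawn_seed(seed, 1)})
        tracks = simulate_molecules(geometry, sim_cfg)
        locs, sidecar = image_and_localize(tracks, sim_cfg)
        pio.write_localizations(out / "localizations.csv", locs)
        if sidecar is not None:
            pio.write_table(out / "ground_truth_sidecar.csv", sidecar)
        report["stages"].append("simulate")
        report["n_localizations_raw"] = int(len(locs))

    flt = trackasm.filter_localizations(locs, band=tuple(cfg["filter"]["band"]))
    report["stages"].append("filter")
    report["n_localizations_filtered"] = int(len(flt))

    trajs = trackasm.link_trajectories(flt, **cfg["link"])
    trajs = trackasm.curate_by_structure(trajs, geometry.er_mask, geometry.pixel_size_nm,
                                         ratio_max=cfg["curate"]["ratio_max"])
    pio.write_table(out / "trajectories.csv", trajs)
    steps = trackasm.make_steps(trajs)
    pio.write_table(out / "steps.csv", steps)
    report["stages"] += ["link", "curate", "steps"]
    report["n_trajectories"] = int(trajs["track_id"].nunique()) if len(trajs) else 0
    report["n_steps"] = int(len(steps))

    pmap = sitemap.probability_map(flt, bin_size_nm=cfg["map"]["bin_size_nm"])
    pio.write_probability_map(out / "probability_map.tif", pmap)
    sites = sitemap.detect_hotspots(pmap, **cfg["detect"])
    sites, enrichment = sitemap.associate_mitochondria(
        sites, geometry.mito_mask, geometry.pixel_size_nm, pmap,
        max_gap_nm=cfg["associate"]["max_gap_nm"], locs=flt, er_mask=geometry.er_mask)
    pio.write_sites(out / "sites.json", sites, out / "sites.csv")
    report["stages"] += ["map", "detect", "associate"]
    report["n_sites"] = len(sites)
    report["mito_enrichment"] = enrichment
    report["sites"] = pio.sites_to_records(sites)
    for r in report["sites"]:
        r.pop("footprint_bins", None)

    landscapes = []
    for site in sites:
        try:
            vmap = difflandscape.tessellate(site, flt, steps, seed=_spawn_seed(seed, 100 + site.site_id))
            vmap = difflandscape.map_landscape(vmap, steps, min_steps=cfg["landscape"]["min_steps"])
            d = vmap.d_values()
            landscapes.append({
                "site_id": site.site_id,
                "n_cells": len(vmap.cells),
                "n_steps": vmap.n_steps,
                "D_mode_nm2_s": [None if not np.isfinite(v) else float(v) for v in d],
            })
        except Exception as exc:  # keep other sites alive
            log.warning("landscape failed for site %d: %s", site.site_id, exc)
            landscapes.append({"site_id": site.site_id, "failed": str(exc)})
    report["stages"].append("landscape")
    report["landscapes"] = landscapes

    dwell_summary = None
    if sites and len(steps):
        try:
            labels = statedyn.classify_contact_steps(
                steps, sites, phi=cfg["classify"]["phi"], window=cfg["classify"]["window"])
            records, summ = statedyn.dwell_times(steps, labels)
            pio.write_table(out / "dwell_records.csv", records)
            per_site, mean_tf, sem_tf = statedyn.trapped_fraction(records)
            dwell_summary = {
                "n_interactions": summ.n_interactions,
                "n_censored": summ.n_censored,
                "median_dwell_s": None if np.isnan(summ.median_s) else float(summ.median_s),
                "leaving_frequency_per_s": None if np.isnan(summ.leaving_frequency_per_s)
                else float(summ.leaving_frequency_per_s),
                "total_bound_time_s": float(summ.total_bound_time_s),
                "trapped_fraction_mean": None if np.isnan(mean_tf) else float(mean_tf),
                "trapped_fraction_sem": None if np.isnan(sem_tf) else float(sem_tf),
            }
        except Exception as exc:
            log.warning("dwell analysis failed: %s", exc)
            dwell_summary = {"failed": str(exc)}
    report["stages"].append("dwell")
    report["dwell"] = dwell_summary

    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report


def run_volume_pipeline(vol, out_dir: str | Path = "run_vol", distance_nm: float = 24.0,
                        smoothing_sigma_vox: float = 1.5, layers: int = 20,
                        curvature_on_contact_only: bool = True) -> dict:
    """Volume-side pipeline: contacts -> mesh -> curvature -> report."""
    from . import surfmorph

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labeled, counts = surfmorph.identify_contacts_3d(vol, distance_nm=distance_nm)
    pio.write_volume(out / "labeled_volume.tif", labeled.labels, labeled.voxel_size_nm)
    report: dict = {"contacts": counts}
    mesh = surfmorph.mesh_from_voxels(labeled, smoothing_sigma_vox=smoothing_sigma_vox)
    mask = None
    if curvature_on_contact_only and "contact" in mesh.vertex_attributes:
        mask = mesh.vertex_attributes["contact"]
        if not mask.any():
            mask = None
    H = surfmorph.mean_curvature(mesh, layers=layers, vertex_mask=mask)
    pio.write_mesh(out / "er_surface.ply", mesh)
    ok = np.isfinite(H)
    report["curvature"] = {
        "n_vertices": int(len(H)),
        "n_evaluated": int(ok.sum()),
        "median_H_per_nm": float(np.median(H[ok])) if ok.any() else None,
        "smoothing_sigma_vox": smoothing_sigma_vox,
        "layers": layers,
    }
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report
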