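"""End-to-end validation experiments with known ground truth.

Each function builds a synthetic study at the package's standard conditions,
runs the relevant slice of the pipeline exactly as a user would, and returns
the measured quantities together with the truth they should recover.  They
back the regression suite and the reproduction script; problem sizes are
chosen so every experiment completes in seconds to a few minutes on one
core.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from . import difflandscape as dl
from . import io as pio
from . import sitemap, statedyn, trackasm
from .pipeline import run_pipeline
from .simkit import (
    SimulationConfig,
    image_and_localize,
    make_er_geometry,
    make_test_mesh,
    make_voxel_phantom,
    simulate_molecules,
    simulate_switching_diffusion,
)
from .surfmorph import identify_contacts_3d, mean_curvature, simulate_localization_projection

DT = 1.0 / 95.0


def _seed(seed: int, label: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(label)]).generate_state(1)[0] % (2**31))


def _site_from_planted_footprint(geometry, bin_size_nm=30.0, dilate=1):
    """ContactSite wrapping the simulator's planted footprint."""
    ny, nx = geometry.er_mask.shape
    gy = int(np.ceil(ny * geometry.pixel_size_nm / bin_size_nm))
    gx = int(np.ceil(nx * geometry.pixel_size_nm / bin_size_nm))
    fp = np.zeros((gy, gx), dtype=bool)
    iy, ix = np.nonzero(geometry.contact_footprint)
    fp[((iy + 0.5) * geometry.pixel_size_nm / bin_size_nm).astype(int),
       ((ix + 0.5) * geometry.pixel_size_nm / bin_size_nm).astype(int)] = True
    if dilate:
        fp = ndimage.binary_dilation(fp, np.ones((3, 3), dtype=bool), iterations=dilate)
    site = sitemap.ContactSite(site_id=0, footprint=fp, bin_size_nm=bin_size_nm,
                               origin_nm=(0.0, 0.0))
    if geometry.contact_list_nm:
        site.centre_nm = tuple(geometry.contact_list_nm[0][:2])
    return site


def diffusion_recovery(seed: int = 0, D_true: float = 5.0e5, sigma: float = 25.0,
                       n_cells: int = 9, steps_per_cell: int = 1200) -> dict:
    """Per-cell Voronoi Bayesian recovery of a uniform free-diffusion field.

    Free 2D diffusion at D_true with static localization error sigma; the
    field is tessellated and each cell's posterior mode is compared with the
    truth; the sigma-ignorant estimator's bias is measured alongside
    (expected ~ sigma^2/dt).
    """
    rng = np.random.default_rng(_seed(seed, 1))
    n = n_cells * steps_per_cell
    std = np.sqrt(2 * D_true * DT + 2 * sigma**2)
    starts = rng.uniform(0, 1200.0, size=(n, 2))
    steps = pd.DataFrame({
        "track_id": np.zeros(n, dtype=int),
        "t_start": np.arange(n) * DT,
        "x_start": starts[:, 0], "y_start": starts[:, 1],
        "dx_nm": rng.normal(0, std, n), "dy_nm": rng.normal(0, std, n),
        "dt_s": np.full(n, DT),
        "sigma_start": np.full(n, sigma), "sigma_end": np.full(n, sigma),
        "gap_closed": np.zeros(n, dtype=bool),
    })
    locs = pd.DataFrame({"frame": np.arange(n), "t_s": steps["t_start"],
                         "x_nm": steps["x_start"], "y_nm": steps["y_start"],
                         "sigma_nm": steps["sigma_start"]})
    vmap = dl.tessellate(None, locs, steps, n_cells=n_cells, dt_s=DT, seed=_seed(seed, 2))
    vmap = dl.map_landscape(vmap, steps)
    modes = vmap.d_values()
    rel_err = np.abs(modes / D_true - 1)
    naive = dl.naive_diffusion_estimate(steps["dx_nm"].to_numpy(),
                                        steps["dy_nm"].to_numpy(), DT)
    corrected = np.mean(modes)
    return {
        "max_cell_rel_err_pct": float(rel_err.max() * 100),
        "naive_bias_um2_s": float((naive - corrected) / 1e6),
        "expected_bias_um2_s": float(sigma**2 / DT / 1e6),
        "n_steps": int(n),
    }


def posterior_mle_equivalence(seed: int = 0, n_sets: int = 100) -> dict:
    """Max deviation (in log-D) between the grid posterior mode under a flat
    prior and the closed-form noise-corrected MLE, over random step sets."""
    rng = np.random.default_rng(_seed(seed, 3))
    grid_step = np.log(1e8 / 1e2) / 399
    worst = 0.0
    for _ in range(n_sets):
        D = 10 ** rng.uniform(4, 7)
        sig = rng.uniform(20, 30)
        n = int(rng.integers(100, 1000))
        std = np.sqrt(2 * D * DT + 2 * sig**2)
        dx = rng.normal(0, std, n)
        dy = rng.normal(0, std, n)
        post = dl.infer_cell_diffusion(dx, dy, DT, sig)
        rx, ry = dx - dx.mean(), dy - dy.mean()
        mle = max(0.0, float(np.sum(rx**2 + ry**2) / (4 * n * DT) - sig**2 / DT))
        if mle > 1e3:
            worst = max(worst, abs(np.log(post.mode_nm2_s / mle)))
    return {"max_log_dev": float(worst), "grid_step_log": float(grid_step), "n_sets": n_sets}


def dwell_recovery(seed: int = 0, k_off: float = 1.25, n_frames: int = 340_000) -> dict:
    """Dwell-time kinetics through the full ground-truth-free pipeline.

    Sparse photoactivation (~1 concurrent molecule, so tracking stays
    reliable even at the site), negligible bleaching, a 200 nm contact with
    moderate binding rate; the observed median dwell should approach
    ln2/k_off and the truncation-corrected leaving frequency k_off.
    """
    g = make_er_geometry(tubule_length_nm=5000.0, contact_radius_nm=100.0)
    # bleaching must be negligible next to k_off, or the observed-duration
    # distribution itself (censored included at observed length) follows
    # rate k_off + bleach and the median target no longer applies
    cfg = SimulationConfig(n_frames=n_frames, seed=_seed(seed, 4), k_off=k_off,
                           k_on=10.0, bleach_rate=0.02, activation_rate=0.00025)
    tracks = simulate_molecules(g, cfg)
    locs, _ = image_and_localize(tracks, cfg)
    flt = trackasm.filter_localizations(locs)
    trajs = trackasm.link_trajectories(flt, max_disp_nm=400.0, max_gap=1)
    trajs = trackasm.curate_by_structure(trajs, g.er_mask, g.pixel_size_nm)
    steps = trackasm.make_steps(trajs)
    site = _site_from_planted_footprint(g)
    labels = statedyn.classify_contact_steps(steps, [site])
    window = 15
    floor = max(window // 3, 1) * DT  # classifier's minimum reportable run
    records, summ = statedyn.dwell_times(steps, labels, detection_floor_s=floor)
    return {
        "median_dwell_s": float(summ.median_s),
        "expected_median_s": float(np.log(2) / k_off),
        "leaving_frequency_per_s": float(summ.leaving_frequency_per_s),
        "expected_leaving_per_s": float(k_off),
        "n_interactions": int(summ.n_interactions),
        "n_uncensored": int(summ.n_interactions - summ.n_censored),
    }


def slds_two_state_benchmark(seed: int = 0, n_replicates: int = 10,
                             n_steps: int = 5000) -> dict:
    """Per-step label accuracy of the SLDS on the two-state benchmark
    (D ratio 5, mean state dwell 100 steps) plus a single-state control."""
    accs = []
    for r in range(n_replicates):
        traj = simulate_switching_diffusion(n_steps, D_states=(5e5, 1e5),
                                            mean_dwell_steps=100,
                                            seed=_seed(seed, 10 + r))
        cfg = statedyn.SLDSConfig(seed=_seed(seed, 110 + r))
        seg = statedyn.segment_trajectory_slds(traj, cfg)
        truth = traj["state"].to_numpy()[:-1]
        _, acc = statedyn.match_labels(seg.labels, truth)
        accs.append(acc)
    control = simulate_switching_diffusion(2000, D_states=(5e5,),
                                           mean_dwell_steps=1e12, seed=_seed(seed, 5))
    seg = statedyn.segment_trajectory_slds(control, statedyn.SLDSConfig(seed=_seed(seed, 6)))
    _, counts = np.unique(seg.labels, return_counts=True)
    D = seg.states[seg.dominant_state()].diffusion_eigenvalues_nm2_s
    return {
        "mean_accuracy_pct": float(np.mean(accs) * 100),
        "min_accuracy_pct": float(np.min(accs) * 100),
        "control_dominant_pct": float(counts.max() / counts.sum() * 100),
        "control_D_rel_err_pct": float(np.abs(D / 5e5 - 1).max() * 100),
        "n_replicates": n_replicates,
    }


def site_detection_and_sizing(seed: int = 0) -> dict:
    """Plant three gaussian_center discs (radii 120/200/300 nm) on one
    tubule; detect, locate and size them from a 60 s recording.

    Size truth is the moment diameter of the simulator's true bound
    positions (the localization-density footprint of a gaussian_center site
    is narrower than its geometric disc).
    """
    contacts = [(2500.0, 550.0, 120.0), (5000.0, 550.0, 200.0), (7500.0, 550.0, 300.0)]
    g = make_er_geometry(tubule_length_nm=9000.0, contacts_nm=contacts)
    cfg = SimulationConfig(n_frames=5700, seed=_seed(seed, 7))
    tracks = simulate_molecules(g, cfg)
    locs, _ = image_and_localize(tracks, cfg)
    flt = trackasm.filter_localizations(locs)
    pmap = sitemap.probability_map(flt)
    sites = sitemap.detect_hotspots(pmap)

    t = tracks.table
    centre_errs, diam_errs = [], []
    for s in sites:
        d = [np.hypot(s.centre_nm[0] - c[0], s.centre_nm[1] - c[1]) for c in contacts]
        k = int(np.argmin(d))
        centre_errs.append(d[k])
        cx, cy, r = contacts[k]
        sel = (t["state"] == 1) & (np.hypot(t["x_nm"] - cx, t["y_nm"] - cy) < r + 60)
        var = 0.5 * (t.loc[sel, "x_nm"].var() + t.loc[sel, "y_nm"].var())
        true_diam = 4.0 * np.sqrt(var)
        diam_errs.append(abs(s.equivalent_diameter_nm - true_diam))
    return {
        "n_planted": len(contacts),
        "n_detected": len(sites),
        "max_centre_err_nm": float(np.max(centre_errs)) if centre_errs else np.nan,
        "max_diameter_err_nm": float(np.max(diam_errs)) if diam_errs else np.nan,
    }


def curvature_analytics(seed: int = 0) -> dict:
    """Mean curvature on analytic surfaces: flat plane, 200 nm sphere,
    50 nm cylinder, and the sign flip under normal inversion."""
    plane = make_test_mesh("plane")
    Hp = mean_curvature(plane)
    interior = plane.vertex_attributes["interior"]
    sphere = make_test_mesh("sphere", radius_nm=200.0)
    Hs = mean_curvature(sphere)
    cyl = make_test_mesh("cylinder", radius_nm=50.0)
    Hc = mean_curvature(cyl)
    cyl_int = cyl.vertex_attributes["interior"]
    inv = sphere.copy()
    inv.invert()
    Hi = mean_curvature(inv)
    return {
        "plane_max_abs_H_per_nm": float(np.nanmax(np.abs(Hp[interior]))),
        "sphere_median_H_per_nm": float(np.nanmedian(Hs)),
        "cylinder_median_H_per_nm": float(np.nanmedian(Hc[cyl_int])),
        "flip_sum_per_nm": float(np.nanmedian(Hs) + np.nanmedian(Hi)),
    }


def contacts_3d_phantoms(seed: int = 0) -> dict:
    """Contact identification on phantoms at gaps 0/16/40 nm vs a
    brute-force pairwise voxel-distance oracle."""
    out = {}
    agree = True
    for gap in (0.0, 16.0, 40.0):
        vol = make_voxel_phantom(gap)
        _, counts = identify_contacts_3d(vol, distance_nm=24.0)
        er = vol.voxel_centres(1)
        omm = vol.voxel_centres(2)
        mind = np.full(len(er), np.inf)
        for i in range(0, len(er), 4000):
            mind[i:i + 4000] = cdist(er[i:i + 4000], omm).min(axis=1)
        oracle = int((np.maximum(mind - vol.voxel_size_nm, 0) <= 24.0).sum())
        agree &= counts["n_contact_voxels"] == oracle
        out[f"contact_voxels_gap{int(gap)}"] = counts["n_contact_voxels"]
    out["oracle_agreement"] = bool(agree)
    return out


def curation_fixture(seed: int = 0) -> dict:
    """Parallel-tubule fixture: cross-gap links must be cut, along-tubule
    links kept, and geodesics must match a Dijkstra oracle."""
    import heapq

    ny, nx = 60, 300
    mask = np.zeros((ny, nx), dtype=bool)
    mask[10:20, 10:290] = True
    mask[40:50, 10:290] = True
    mask[10:50, 280:290] = True
    px = 10.0

    frames = np.arange(12)
    along = pd.DataFrame({"frame": frames, "t_s": frames * DT,
                          "x_nm": 200.0 + 80.0 * frames,
                          "y_nm": np.full(12, 150.0),
                          "sigma_nm": np.full(12, 25.0),
                          "track_id": 0, "gap_closed": False, "fixture": "along"})
    cross = pd.DataFrame({"frame": [0, 1], "t_s": [0.0, DT],
                          "x_nm": [200.0, 200.0], "y_nm": [150.0, 450.0],
                          "sigma_nm": [25.0, 25.0], "track_id": 1,
                          "gap_closed": False, "fixture": "cross"})
    trajs = pd.concat([along, cross], ignore_index=True)
    out = trackasm.curate_by_structure(trajs, mask, px)
    n_along_tracks = out.loc[out["fixture"] == "along", "track_id"].nunique()
    n_cross_tracks = out.loc[out["fixture"] == "cross", "track_id"].nunique()

    def dijkstra(start_nm, end_nm):
        s = (int(start_nm[1] // px), int(start_nm[0] // px))
        e = (int(end_nm[1] // px), int(end_nm[0] // px))
        dist = {s: 0.0}
        heap = [(0.0, s)]
        while heap:
            d, (iy, ix) = heapq.heappop(heap)
            if (iy, ix) == e:
                return d * px
            if d > dist.get((iy, ix), np.inf):
                continue
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == dx == 0:
                        continue
                    jy, jx = iy + dy, ix + dx
                    if 0 <= jy < ny and 0 <= jx < nx and mask[jy, jx]:
                        nd = d + np.hypot(dy, dx)
                        if nd < dist.get((jy, jx), np.inf):
                            dist[(jy, jx)] = nd
                            heapq.heappush(heap, (nd, (jy, jx)))
        return np.inf

    geo = trackasm.geodesic_distance(mask, px, (200.0, 150.0), (200.0, 450.0))
    oracle = dijkstra((200.0, 150.0), (200.0, 450.0))
    return {
        "cross_link_cut": bool(n_cross_tracks == 2),  # the gap link is severed
        "along_links_kept": bool(n_along_tracks == 1),
        "geodesic_nm": float(geo),
        "oracle_geodesic_nm": float(oracle),
        "geodesic_rel_err": float(abs(geo - oracle) / oracle),
    }


def projection_metric_consistency(seed: int = 0) -> dict:
    """EM-style projection of a planar contact patch, measured with the same
    moment metric as light-microscopy sites, against the patch's analytic
    projected moments."""
    mesh = make_test_mesh("plane", extent_nm=600.0)
    mesh.vertex_attributes["contact"] = np.ones(len(mesh.vertices), dtype=bool)
    _, site, _ = simulate_localization_projection(mesh, n_points=40000, sigma_nm=0.0,
                                                  bin_nm=30.0, seed=_seed(seed, 8),
                                                  projection_axes=(0, 1))
    true_axis = 4.0 * np.sqrt(600.0**2 / 12.0)
    return {
        "major_axis_err_nm": float(abs(site.major_axis_nm - true_axis)),
        "minor_axis_err_nm": float(abs(site.minor_axis_nm - true_axis)),
        "bin_nm": 30.0,
    }


def pipeline_determinism(seed: int = 0) -> dict:
    """Fixed-seed end-to-end rerun must be byte-identical and satisfy the
    localization/step/dwell conservation identities."""
    cfg = {"seed": _seed(seed, 9), "simulate": {"n_frames": 1500}}
    with tempfile.TemporaryDirectory() as tmp:
        r1 = run_pipeline(cfg, Path(tmp) / "a")
        run_pipeline(cfg, Path(tmp) / "b")
        identical = ((Path(tmp) / "a" / "report.json").read_bytes()
                     == (Path(tmp) / "b" / "report.json").read_bytes())
        locs = pio.read_localizations(Path(tmp) / "a" / "localizations.csv")
        trajs = pio.read_table(Path(tmp) / "a" / "trajectories.csv")
        steps = pio.read_table(Path(tmp) / "a" / "steps.csv")
        conserve = (r1["n_localizations_raw"] == len(locs)
                    and r1["n_localizations_filtered"] == len(trajs)
                    and len(steps) == sum(len(g) - 1 for _, g in trajs.groupby("track_id")))
        dwell_ok = True
        if r1["dwell"] and "total_bound_time_s" in r1["dwell"]:
            recs = pio.read_table(Path(tmp) / "a" / "dwell_records.csv")
            tot = recs["duration_s"].sum() if len(recs) else 0.0
            dwell_ok = abs(r1["dwell"]["total_bound_time_s"] - tot) < 1e-9
    return {
        "rerun_byte_identical": bool(identical),
        "conservation_ok": bool(conserve and dwell_ok),
        "n_localizations": int(len(locs)),
    }
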