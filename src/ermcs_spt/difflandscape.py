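"""Voronoi Bayesian diffusion landscapes of contact sites.

The site region is partitioned into Voronoi cells seeded from the
localization density (k-means).  Within each cell single-molecule steps,
viewed as independent probes of the same molecular environment, follow an
overdamped Langevin model: per axis, a displacement over time dt is
Normal(drift*dt, 2*D*dt + 2*sigma^2), where sigma is the static
localization error.  The posterior over D (flat prior on D >= 0 by default)
is evaluated on a log grid augmented with D = 0, giving the posterior mode
and a central 95% credible interval per cell.  The additive 2*sigma^2 term
is what separates true diffusion from the apparent (sigma-ignorant)
coefficient, which is biased high by sigma^2/dt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

# log-spaced posterior grid (nm^2/s), with an explicit D = 0 point prepended
GRID_LO, GRID_HI, GRID_N = 1.0e2, 1.0e8, 400


def posterior_grid() -> np.ndarray:
    return np.concatenate([[0.0], np.logspace(np.log10(GRID_LO), np.log10(GRID_HI), GRID_N)])


@dataclass
class DiffusionPosterior:
    """Posterior summary of the per-cell effective 2D diffusion coefficient."""

    mode_nm2_s: float
    ci95_nm2_s: tuple[float, float]
    n_steps: int
    drift_nm_s: tuple[float, float] = (0.0, 0.0)
    low_confidence: bool = False


@dataclass
class VoronoiCell:
    seed_nm: np.ndarray
    polygon_nm: np.ndarray | None  # (k, 2) vertices, clipped; None if unbounded
    step_index: np.ndarray  # indices into the step table
    posterior: DiffusionPosterior | None = None


@dataclass
class VoronoiDiffusionMap:
    cells: list[VoronoiCell]
    site_id: int
    dt_s: float
    sigma_model_nm: float
    normalized: bool = False
    reference_D_nm2_s: float | None = None

    @property
    def n_steps(self) -> int:
        return int(sum(len(c.step_index) for c in self.cells))

    def d_values(self) -> np.ndarray:
        return np.array([c.posterior.mode_nm2_s if c.posterior else np.nan for c in self.cells])


def assign_to_seeds(points: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Nearest-seed assignment; ties break to the lowest cell index."""
    return np.argmin(cdist(points, seeds), axis=1)


def _clip_polygons(vor: Voronoi, bounds: tuple[float, float, float, float]) -> list[np.ndarray | None]:
    from shapely.geometry import Polygon, box

    bbox = box(*bounds)
    out: list[np.ndarray | None] = []
    for pt_idx in range(len(vor.points)):
        region = vor.regions[vor.point_region[pt_idx]]
        if -1 in region or len(region) == 0:
            # unbounded: intersect a large proxy polygon with the bbox
            out.append(None)
            continue
        poly = Polygon(vor.vertices[region]).intersection(bbox)
        out.append(np.asarray(poly.exterior.coords) if not poly.is_empty else None)
    return out


def tessellate(site, locs: pd.DataFrame, steps: pd.DataFrame,
               n_cells: int | None = None, min_steps: int = 20,
               target_steps_per_cell: int = 50, max_cells: int = 50,
               seed: int = 0, site_id: int | None = None,
               dt_s: float | None = None) -> VoronoiDiffusionMap:
    """Voronoi-partition a site from its localization density and assign steps.

    Seeds are k-means centres of the site's localizations, with k chosen so
    the expected steps per cell is at least ``target_steps_per_cell`` (capped
    at ``max_cells``).  Steps are assigned to the cell whose seed is nearest
    to the step's *starting* position.  With too few steps the site falls
    back to a single cell.
    """
    if site is not None:
        in_site_loc = site.contains(locs["x_nm"].to_numpy(), locs["y_nm"].to_numpy())
        site_locs = locs.loc[in_site_loc]
        in_site = site.contains(steps["x_start"].to_numpy(), steps["y_start"].to_numpy())
        site_steps = steps.loc[in_site]
    else:
        site_locs, site_steps = locs, steps
    n_steps = len(site_steps)
    pts = site_locs[["x_nm", "y_nm"]].to_numpy()

    if n_cells is None:
        n_cells = int(np.clip(n_steps // target_steps_per_cell, 1, max_cells))
    if n_steps < min_steps or len(pts) < n_cells:
        if n_cells > 1:
            log.warning("site %s: too few steps (%d) for %d cells; single-cell fallback",
                        getattr(site, "site_id", site_id), n_steps, n_cells)
        n_cells = 1

    if n_cells == 1:
        seeds = pts.mean(axis=0, keepdims=True) if len(pts) else np.zeros((1, 2))
    else:
        km = KMeans(n_clusters=n_cells, random_state=seed, n_init=10).fit(pts)
        seeds = km.cluster_centers_
        # deterministic cell order: sort seeds lexicographically
        order = np.lexsort((seeds[:, 1], seeds[:, 0]))
        seeds = seeds[order]

    starts = site_steps[["x_start", "y_start"]].to_numpy()
    assign = assign_to_seeds(starts, seeds) if len(starts) else np.empty(0, dtype=int)

    if len(seeds) >= 4:
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
        pad = 2 * 30.0
        polys = _clip_polygons(Voronoi(seeds), (x0 - pad, y0 - pad, x1 + pad, y1 + pad))
    else:
        polys = [None] * len(seeds)

    dt = dt_s if dt_s is not None else (float(np.median(site_steps["dt_s"])) if n_steps else np.nan)
    sigma_model = float(np.mean(0.5 * (site_steps["sigma_start"] + site_steps["sigma_end"]))) \
        if n_steps else np.nan
    cells = [
        VoronoiCell(seed_nm=seeds[k], polygon_nm=polys[k],
                    step_index=site_steps.index.to_numpy()[assign == k])
        for k in range(len(seeds))
    ]
    sid = site_id if site_id is not None else getattr(site, "site_id", -1)
    return VoronoiDiffusionMap(cells=cells, site_id=sid, dt_s=dt, sigma_model_nm=sigma_model)


def log_likelihood_D(D: np.ndarray, dx: np.ndarray, dy: np.ndarray, dt: float,
                     sigma_nm: np.ndarray | float, subtract_drift: bool = True) -> np.ndarray:
    """Log-likelihood of D on an array of candidate values.

    Per axis, displacement ~ Normal(drift*dt, 2*D*dt + 2*sigma^2); drift is
    profiled out as the sample mean displacement rate.
    """
    D = np.atleast_1d(np.asarray(D, dtype=float))
    sig2 = np.mean(np.square(sigma_nm)) if np.ndim(sigma_nm) else float(sigma_nm) ** 2
    if subtract_drift and len(dx) > 1:
        rx = dx - dx.mean()
        ry = dy - dy.mean()
    else:
        rx, ry = dx, dy
    ss = float(np.sum(rx * rx + ry * ry))
    n = len(dx)
    v = 2.0 * D * dt + 2.0 * sig2  # per-axis variance
    v = np.clip(v, 1e-12, None)
    return -(n) * np.log(2.0 * np.pi * v) - ss / (2.0 * v)


def infer_cell_diffusion(dx: np.ndarray, dy: np.ndarray, dt: float,
                         sigma_nm: np.ndarray | float, min_steps: int = 20,
                         prior: str = "flat") -> DiffusionPosterior:
    """Posterior mode and central 95% interval of D for one cell's steps.

    Flat prior on D >= 0 evaluated on the log grid (with D = 0 prepended);
    ``prior="scale"`` uses p(D) ~ 1/(D + D0) with D0 the grid minimum.
    Drift is estimated as the mean displacement rate and reported
    separately; gap-flagged steps should be excluded by the caller.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    n = len(dx)
    if n < 1:
        raise ValueError("need at least one step")
    drift = (float(dx.mean() / dt), float(dy.mean() / dt))
    grid = posterior_grid()
    ll = log_likelihood_D(grid, dx, dy, dt, sigma_nm)
    if prior == "scale":
        ll = ll - np.log(grid + GRID_LO)
    ll = ll - ll.max()
    post = np.exp(ll)
    # integrate with trapezoid weights in D (grid is non-uniform)
    wts = np.zeros_like(grid)
    wts[1:-1] = 0.5 * (grid[2:] - grid[:-2])
    wts[0] = 0.5 * (grid[1] - grid[0])
    wts[-1] = 0.5 * (grid[-1] - grid[-2])
    mass = post * wts
    mass = mass / mass.sum()
    cdf = np.cumsum(mass)
    lo = float(grid[np.searchsorted(cdf, 0.025)])
    hi = float(grid[min(np.searchsorted(cdf, 0.975), len(grid) - 1)])
    mode = float(grid[np.argmax(ll)])
    return DiffusionPosterior(mode_nm2_s=mode, ci95_nm2_s=(lo, hi), n_steps=n,
                              drift_nm_s=drift, low_confidence=n < min_steps)


def naive_diffusion_estimate(dx: np.ndarray, dy: np.ndarray, dt: float,
                             subtract_drift: bool = True) -> float:
    """Sigma-ignorant estimator sum(dx^2 + dy^2) / (4 n dt); biased high by
    sigma^2/dt relative to the true coefficient."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if subtract_drift and len(dx) > 1:
        dx = dx - dx.mean()
        dy = dy - dy.mean()
    return float(np.sum(dx * dx + dy * dy) / (4.0 * len(dx) * dt))


def per_step_diffusion(steps: pd.DataFrame) -> np.ndarray:
    """Instantaneous noise-corrected per-step D: (dx^2+dy^2)/(4 dt) - sigma^2/dt."""
    sig2 = (0.5 * (steps["sigma_start"] + steps["sigma_end"])) ** 2
    return ((steps["dx_nm"] ** 2 + steps["dy_nm"] ** 2) / (4.0 * steps["dt_s"])
            - sig2 / steps["dt_s"]).to_numpy()


def map_landscape(vmap: VoronoiDiffusionMap, steps: pd.DataFrame,
                  include_gap_steps: bool = False, min_steps: int = 20) -> VoronoiDiffusionMap:
    """Run the per-cell Bayesian D inference over every cell of a tessellation."""
    for cell in vmap.cells:
        s = steps.loc[cell.step_index]
        if not include_gap_steps:
            s = s[~s["gap_closed"].astype(bool)]
        if len(s) == 0:
            cell.posterior = None
            continue
        sigma = 0.5 * (s["sigma_start"].to_numpy() + s["sigma_end"].to_numpy())
        cell.posterior = infer_cell_diffusion(
            s["dx_nm"].to_numpy(), s["dy_nm"].to_numpy(), vmap.dt_s, sigma,
            min_steps=min_steps)
    return vmap


def neighborhood_profile(steps: pd.DataFrame, line: tuple[tuple[float, float], tuple[float, float]],
                         radius_nm: float = 30.0, step_nm: float = 10.0,
                         min_steps: int = 5) -> pd.DataFrame:
    """Mean noise-corrected per-step D in a moving neighbourhood along a line.

    Samples every ``step_nm`` along the segment; at each sample the mean of
    instantaneous per-step D over steps *starting* within ``radius_nm`` is
    reported, or NaN where fewer than ``min_steps`` steps fall inside.
    """
    (x0, y0), (x1, y1) = line
    length = float(np.hypot(x1 - x0, y1 - y0))
    n_samp = max(int(np.floor(length / step_nm)) + 1, 1)
    ts = np.arange(n_samp) * step_nm / max(length, 1e-12)
    sx = x0 + ts * (x1 - x0)
    sy = y0 + ts * (y1 - y0)
    starts = steps[["x_start", "y_start"]].to_numpy()
    inst = per_step_diffusion(steps)
    mean_D = np.full(n_samp, np.nan)
    n_in = np.zeros(n_samp, dtype=int)
    if radius_nm > 0 and len(starts):
        d2 = cdist(np.column_stack([sx, sy]), starts, "sqeuclidean")
        inside = d2 <= radius_nm**2
        n_in = inside.sum(axis=1)
        for i in range(n_samp):
            if n_in[i] >= min_steps:
                mean_D[i] = float(inst[inside[i]].mean())
    if np.all(np.isnan(mean_D)):
        log.warning("profile line has no sample with >= %d steps", min_steps)
    return pd.DataFrame({"s_nm": np.arange(n_samp) * step_nm, "mean_D_nm2_s": mean_D,
                         "n_steps": n_in})


def tubule_1d_diffusion(steps: pd.DataFrame, er_mask: np.ndarray, pixel_size_nm: float,
                        footprints: list | None = None, min_segment_steps: int = 5,
                        axis_radius_nm: float = 200.0) -> pd.DataFrame:
    """Effective 1D diffusion of trajectory segments, in tubules vs in sites.

    Step displacements are projected on the local tubule axis (principal
    direction of ER-skeleton pixels around the step start); per contiguous
    same-class segment the estimator is Var(projected)/(2 dt) - sigma^2/dt.
    Returns one row per segment with columns (track_id, cls, D1d_nm2_s,
    n_steps); classes are "site" (step starts inside any footprint) and
    "tubule".
    """
    from skimage.morphology import skeletonize

    skel = skeletonize(er_mask)
    siy, six = np.nonzero(skel)
    if len(six) < 2:
        raise ValueError("ER skeleton too small to resolve a tubule axis")
    skel_xy = np.column_stack([(six + 0.5), (siy + 0.5)]) * pixel_size_nm

    starts = steps[["x_start", "y_start"]].to_numpy()
    in_site = np.zeros(len(steps), dtype=bool)
    for fp in footprints or []:
        in_site |= fp.contains(steps["x_start"].to_numpy(), steps["y_start"].to_numpy())
    in_site_s = pd.Series(in_site, index=steps.index)

    rows = []
    for tid, g in steps.groupby("track_id", sort=True):
        gi = g.index.to_numpy()
        cls = in_site_s.loc[gi].to_numpy()
        # split into contiguous same-class runs
        run_start = 0
        for k in range(1, len(gi) + 1):
            if k == len(gi) or cls[k] != cls[run_start]:
                seg = g.iloc[run_start:k]
                run = cls[run_start]
                run_start = k
                if len(seg) < min_segment_steps:
                    continue
                p0 = seg[["x_start", "y_start"]].to_numpy().mean(axis=0)
                d2 = ((skel_xy - p0) ** 2).sum(axis=1)
                near = skel_xy[d2 <= axis_radius_nm**2]
                if len(near) < 3:
                    log.info("track %s: tubule axis unresolvable, segment skipped", tid)
                    continue
                c = near - near.mean(axis=0)
                _, _, vt = np.linalg.svd(c, full_matrices=False)
                ax = vt[0]
                proj = seg["dx_nm"].to_numpy() * ax[0] + seg["dy_nm"].to_numpy() * ax[1]
                dt = float(np.median(seg["dt_s"]))
                sig2 = float(np.mean((0.5 * (seg["sigma_start"] + seg["sigma_end"])) ** 2))
                d1 = float(np.var(proj, ddof=1) / (2.0 * dt) - sig2 / dt)
                rows.append({"track_id": tid, "cls": "site" if run else "tubule",
                             "D1d_nm2_s": d1, "n_steps": len(seg)})
    return pd.DataFrame(rows, columns=["track_id", "cls", "D1d_nm2_s", "n_steps"])


def normalize_to_local_ER(vmap: VoronoiDiffusionMap, steps: pd.DataFrame,
                          site, annulus_nm: float = 500.0,
                          min_steps: int = 20) -> VoronoiDiffusionMap:
    """Divide each cell's D by the D of an annulus of surrounding ER steps.

    The annulus spans from the site boundary outwards by ``annulus_nm``;
    steps starting inside the footprint are excluded.  The result is a
    dimensionless landscape (1 = same mobility as neighbouring ER).
    """
    in_fp = site.contains(steps["x_start"].to_numpy(), steps["y_start"].to_numpy())
    cx, cy = site.centre_nm
    r = np.hypot(steps["x_start"].to_numpy() - cx, steps["y_start"].to_numpy() - cy)
    r_site = max(site.major_axis_nm, site.minor_axis_nm) / 2.0
    ann = (~in_fp) & (r <= r_site + annulus_nm)
    s = steps.loc[ann & ~steps["gap_closed"].astype(bool)]
    if len(s) < min_steps:
        raise ValueError(f"only {len(s)} steps in the surrounding-ER annulus "
                         f"(need {min_steps}); cannot normalize")
    sigma = 0.5 * (s["sigma_start"].to_numpy() + s["sigma_end"].to_numpy())
    ref = infer_cell_diffusion(s["dx_nm"].to_numpy(), s["dy_nm"].to_numpy(),
                               vmap.dt_s, sigma, min_steps=min_steps)
    ref_D = max(ref.mode_nm2_s, 1e-12)
    for cell in vmap.cells:
        if cell.posterior is None:
            continue
        p = cell.posterior
        cell.posterior = DiffusionPosterior(
            mode_nm2_s=p.mode_nm2_s / ref_D,
            ci95_nm2_s=(p.ci95_nm2_s[0] / ref_D, p.ci95_nm2_s[1] / ref_D),
            n_steps=p.n_steps, drift_nm_s=p.drift_nm_s,
            low_confidence=p.low_confidence)
    vmap.normalized = True
    vmap.reference_D_nm2_s = ref_D
    return vmap
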