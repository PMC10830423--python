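"""Spatial probability maps and contact-site detection / morphometry.

A probability map bins localizations into square pixels (30 nm by default)
and normalizes counts to the total, giving a spatially defined probability
mass function that is insensitive to photoactivation efficiency or
expression level.  Contact sites appear as hotspots: 8-connected clusters
of bins far above the median occupied-bin mass.  Site size is measured from
the second central moments of the mass distribution (full width at +/-2
sigma per principal axis) - the same metric applied to EM-projection
simulations, so light- and electron-microscopy sizes are comparable by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

log = logging.getLogger(__name__)


@dataclass
class ProbabilityMap:
    """Unit-sum spatial probability mass function on a square-bin grid."""

    values: np.ndarray  # (ny, nx), non-negative, sums to 1 when n_localizations > 0
    bin_size_nm: float = 30.0
    origin_nm: tuple[float, float] = (0.0, 0.0)  # (x0, y0) of grid corner
    window_s: tuple[float, float] | None = None
    n_localizations: int = 0

    def bin_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinate arrays, each shaped like ``values``."""
        ny, nx = self.values.shape
        x = self.origin_nm[0] + (np.arange(nx) + 0.5) * self.bin_size_nm
        y = self.origin_nm[1] + (np.arange(ny) + 0.5) * self.bin_size_nm
        return np.meshgrid(x, y)


@dataclass
class ContactSite:
    """A detected hotspot footprint and its morphometrics."""

    site_id: int
    footprint: np.ndarray  # boolean grid, same shape as the source map
    bin_size_nm: float = 30.0
    origin_nm: tuple[float, float] = (0.0, 0.0)
    centre_nm: tuple[float, float] = (np.nan, np.nan)
    major_axis_nm: float = np.nan
    minor_axis_nm: float = np.nan
    area_nm2: float = np.nan
    mito_associated: bool | None = None
    tubule_axis: np.ndarray | None = None  # unit vector, or None
    degenerate: bool = False
    unstable: bool | None = None
    diffusion_map: object = field(default=None, repr=False)

    @property
    def equivalent_diameter_nm(self) -> float:
        """Geometric-mean diameter of the +/-2 sigma mass ellipse."""
        return float(np.sqrt(self.major_axis_nm * self.minor_axis_nm))

    def contains(self, x_nm: np.ndarray, y_nm: np.ndarray,
                 bin_size_nm: float | None = None,
                 origin_nm: tuple[float, float] | None = None) -> np.ndarray:
        """Boolean membership of points in the footprint bins."""
        bin_size_nm = self.bin_size_nm if bin_size_nm is None else bin_size_nm
        origin_nm = self.origin_nm if origin_nm is None else origin_nm
        ix = np.floor((np.asarray(x_nm) - origin_nm[0]) / bin_size_nm).astype(int)
        iy = np.floor((np.asarray(y_nm) - origin_nm[1]) / bin_size_nm).astype(int)
        ny, nx = self.footprint.shape
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        out = np.zeros(np.shape(x_nm), dtype=bool)
        out[ok] = self.footprint[iy[ok], ix[ok]]
        return out


def probability_map(locs: pd.DataFrame, bin_size_nm: float = 30.0,
                    window_s: tuple[float, float] | None = None,
                    roi_nm: tuple[float, float, float, float] | None = None) -> ProbabilityMap:
    """Bin localizations into square pixels and normalize to total count.

    ``roi_nm`` is (x0, x1, y0, y1); by default the data bounding box, with
    the origin snapped down to a bin boundary.  Empty input gives an
    all-zero single-bin map with ``n_localizations = 0``.
    """
    if bin_size_nm <= 0:
        raise ValueError("bin_size_nm must be positive")
    d = locs
    if window_s is not None:
        d = d[(d["t_s"] >= window_s[0]) & (d["t_s"] < window_s[1])]
    x = d["x_nm"].to_numpy(dtype=float)
    y = d["y_nm"].to_numpy(dtype=float)
    bad = ~(np.isfinite(x) & np.isfinite(y))
    if bad.any():
        rows = np.flatnonzero(bad)[:20]
        raise ValueError(f"non-finite coordinates in rows {rows.tolist()}")
    if roi_nm is None:
        if len(d) == 0:
            return ProbabilityMap(values=np.zeros((1, 1)), bin_size_nm=bin_size_nm,
                                  origin_nm=(0.0, 0.0), window_s=window_s, n_localizations=0)
        x0 = np.floor(x.min() / bin_size_nm) * bin_size_nm
        y0 = np.floor(y.min() / bin_size_nm) * bin_size_nm
        x1, y1 = x.max(), y.max()
    else:
        x0, x1, y0, y1 = roi_nm
        keep = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        x, y = x[keep], y[keep]
    nx = max(int(np.ceil((x1 - x0) / bin_size_nm)), 1)
    ny = max(int(np.ceil((y1 - y0) / bin_size_nm)), 1)
    ix = np.clip(np.floor((x - x0) / bin_size_nm).astype(int), 0, nx - 1)
    iy = np.clip(np.floor((y - y0) / bin_size_nm).astype(int), 0, ny - 1)
    counts = np.zeros((ny, nx))
    np.add.at(counts, (iy, ix), 1.0)
    n = int(counts.sum())
    values = counts / n if n > 0 else counts
    return ProbabilityMap(values=values, bin_size_nm=bin_size_nm, origin_nm=(x0, y0),
                          window_s=window_s, n_localizations=n)


def detect_hotspots(pmap: ProbabilityMap, theta: float = 5.0,
                    min_area_bins: int = 4, merge_gap_bins: float = 2.0) -> list[ContactSite]:
    """Detect contact-site hotspots as connected clusters of high-mass bins.

    Background is the median of strictly positive bin masses; bins at or
    above ``theta`` times background form candidate pixels, 8-connected
    components with at least ``min_area_bins`` bins become sites, and
    components whose mass centroids are within ``merge_gap_bins`` bins merge.
    """
    v = pmap.values
    pos = v[v > 0]
    if pos.size == 0:
        return []
    b = float(np.median(pos))
    mask = v >= theta * b
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    comps = [lab == k for k in range(1, n + 1) if (lab == k).sum() >= min_area_bins]
    if not comps:
        return []

    def centroid(fp):
        w = v * fp
        cy, cx = ndimage.center_of_mass(w)
        return np.array([cx, cy])

    cents = [centroid(fp) for fp in comps]
    # merge components with centroid gap <= merge_gap_bins (union-find)
    parent = list(range(len(comps)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            if np.linalg.norm(cents[i] - cents[j]) <= merge_gap_bins:
                parent[find(i)] = find(j)
    groups: dict[int, np.ndarray] = {}
    for i, fp in enumerate(comps):
        r = find(i)
        groups[r] = groups.get(r, np.zeros_like(fp)) | fp

    sites = []
    for k, fp in enumerate(sorted(groups.values(), key=lambda f: tuple(np.argwhere(f)[0]))):
        site = ContactSite(site_id=k, footprint=fp, bin_size_nm=pmap.bin_size_nm,
                           origin_nm=pmap.origin_nm)
        sites.append(measure_site(site, pmap))
    return sites


def measure_site(site: ContactSite, pmap: ProbabilityMap,
                 aperture_dilation_bins: int = 3,
                 subtract_background: bool = True) -> ContactSite:
    """Mass-weighted centroid and +/-2 sigma principal-axis widths of a site.

    Axis lengths are ``4 * sqrt(eigenvalue)`` of the second-central-moment
    matrix of the site's mass.  So the measured size does not depend on the
    detection threshold, moments are taken over an aperture (the footprint
    dilated by ``aperture_dilation_bins``) after subtracting the map's
    background (median positive bin mass): the threshold defines where a
    site is, the background-corrected mass defines how big it is.  A
    single-bin footprint is flagged degenerate with both axes equal to the
    bin size.
    """
    fp = site.footprint
    if not fp.any():
        raise ValueError("cannot measure an empty footprint")
    if aperture_dilation_bins > 0:
        aperture = ndimage.binary_dilation(fp, np.ones((3, 3), dtype=bool),
                                           iterations=aperture_dilation_bins)
    else:
        aperture = fp
    if subtract_background:
        pos = pmap.values[pmap.values > 0]
        bg = float(np.median(pos)) if pos.size else 0.0
    else:
        bg = 0.0  # e.g. projection simulations, where there is no backdrop
    w = np.clip(pmap.values - bg, 0.0, None) * aperture
    tot = w.sum()
    if tot == 0:  # no mass above background: fall back to raw footprint mass
        w = pmap.values * fp
        tot = w.sum()
    if tot == 0:  # still nothing: uniform occupancy of the footprint
        w = fp.astype(float)
        tot = w.sum()
    xc, yc = pmap.bin_centres()
    mx = float((w * xc).sum() / tot)
    my = float((w * yc).sum() / tot)
    site.centre_nm = (mx, my)
    site.area_nm2 = float(fp.sum() * pmap.bin_size_nm**2)
    if fp.sum() == 1:
        site.major_axis_nm = site.minor_axis_nm = pmap.bin_size_nm
        site.degenerate = True
        return site
    dx = xc - mx
    dy = yc - my
    cov = np.array([
        [(w * dx * dx).sum(), (w * dx * dy).sum()],
        [(w * dx * dy).sum(), (w * dy * dy).sum()],
    ]) / tot
    ev = np.linalg.eigvalsh(cov)
    ev = np.clip(ev, 0.0, None)
    site.minor_axis_nm = float(4.0 * np.sqrt(ev[0]))
    site.major_axis_nm = float(4.0 * np.sqrt(ev[1]))
    site.degenerate = False
    return site


def associate_mitochondria(sites: list[ContactSite], mito_mask: np.ndarray | None,
                           mask_pixel_nm: float, pmap: ProbabilityMap,
                           max_gap_nm: float = 250.0,
                           locs: pd.DataFrame | None = None,
                           er_mask: np.ndarray | None = None) -> tuple[list[ContactSite], float | None]:
    """Flag sites near mitochondria and compute a localization enrichment.

    A site is mito-associated iff its footprint, dilated by ``max_gap_nm``,
    overlaps the mitochondria mask (default gap: the ~250 nm confocal
    resolution scale).  When localizations and an ER mask are supplied, the
    mitochondrial enrichment coefficient is also returned: the fraction of
    localizations in the mito-proximal ER region divided by the fraction of
    ER area that is mito-proximal (1.0 = no enrichment).
    """
    if mito_mask is None or not np.any(mito_mask):
        log.warning("no mitochondria mask; association skipped")
        return sites, None
    # distance (nm) from every mask pixel to the nearest mito pixel
    dist_nm = ndimage.distance_transform_edt(~mito_mask) * mask_pixel_nm
    ny, nx = mito_mask.shape
    for site in sites:
        iy, ix = np.nonzero(site.footprint)
        bx = pmap.origin_nm[0] + (ix + 0.5) * pmap.bin_size_nm
        by = pmap.origin_nm[1] + (iy + 0.5) * pmap.bin_size_nm
        jx = np.clip(np.floor(bx / mask_pixel_nm).astype(int), 0, nx - 1)
        jy = np.clip(np.floor(by / mask_pixel_nm).astype(int), 0, ny - 1)
        site.mito_associated = bool((dist_nm[jy, jx] <= max_gap_nm).any())

    enrichment = None
    if locs is not None and er_mask is not None and er_mask.any():
        proximal = er_mask & (dist_nm <= max_gap_nm)
        area_frac = proximal.sum() / er_mask.sum()
        if area_frac > 0 and len(locs):
            ix = np.clip(np.floor(locs["x_nm"].to_numpy() / mask_pixel_nm).astype(int), 0, nx - 1)
            iy = np.clip(np.floor(locs["y_nm"].to_numpy() / mask_pixel_nm).astype(int), 0, ny - 1)
            on_er = er_mask[iy, ix]
            if on_er.sum() > 0:
                loc_frac = proximal[iy[on_er], ix[on_er]].sum() / on_er.sum()
                enrichment = float(loc_frac / area_frac)
    return sites, enrichment


def estimate_tubule_axis(site: ContactSite, er_mask: np.ndarray, mask_pixel_nm: float,
                         radius_nm: float = 500.0) -> np.ndarray | None:
    """Local tubule direction: principal direction of ER-skeleton pixels
    within ``radius_nm`` of the site centre.  Returns a unit vector or None."""
    from skimage.morphology import skeletonize

    skel = skeletonize(er_mask)
    iy, ix = np.nonzero(skel)
    px = (ix + 0.5) * mask_pixel_nm
    py = (iy + 0.5) * mask_pixel_nm
    cx, cy = site.centre_nm
    near = (px - cx) ** 2 + (py - cy) ** 2 <= radius_nm**2
    if near.sum() < 3:
        return None
    pts = np.column_stack([px[near], py[near]])
    pts = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    axis = vt[0]
    site.tubule_axis = axis / np.linalg.norm(axis)
    return site.tubule_axis


def rotate_and_bin(locs: pd.DataFrame, centre_nm: tuple[float, float], axis: np.ndarray,
                   half_extent_nm: float, bin_size_nm: float) -> np.ndarray:
    """Rotate localizations so ``axis`` maps to +x about ``centre_nm`` and
    bin into a square patch of +/- half_extent.  Returns raw counts."""
    theta = -np.arctan2(axis[1], axis[0])
    c, s = np.cos(theta), np.sin(theta)
    x = locs["x_nm"].to_numpy() - centre_nm[0]
    y = locs["y_nm"].to_numpy() - centre_nm[1]
    xr = c * x - s * y
    yr = s * x + c * y
    nb = int(np.ceil(2 * half_extent_nm / bin_size_nm))
    keep = (np.abs(xr) < half_extent_nm) & (np.abs(yr) < half_extent_nm)
    ix = np.floor((xr[keep] + half_extent_nm) / bin_size_nm).astype(int)
    iy = np.floor((yr[keep] + half_extent_nm) / bin_size_nm).astype(int)
    ix = np.clip(ix, 0, nb - 1)
    iy = np.clip(iy, 0, nb - 1)
    counts = np.zeros((nb, nb))
    np.add.at(counts, (iy, ix), 1.0)
    return counts


def align_and_average(sites: list[ContactSite], locs: pd.DataFrame,
                      half_extent_nm: float = 600.0, bin_size_nm: float = 30.0,
                      profile_band_nm: float = 90.0) -> tuple[ProbabilityMap, pd.DataFrame]:
    """Centre-align sites, rotate each so its tubule axis is +x, and average.

    Returns the renormalized average map (origin at the common centre) and a
    1D profile: mass summed over ``|y| <= profile_band_nm`` per x bin.
    """
    usable = [s for s in sites if s.tubule_axis is not None]
    if not usable:
        raise ValueError("no site has a resolvable tubule axis")
    total = None
    for s in usable:
        counts = rotate_and_bin(locs, s.centre_nm, s.tubule_axis, half_extent_nm, bin_size_nm)
        total = counts if total is None else total + counts
    n = total.sum()
    values = total / n if n > 0 else total
    avg = ProbabilityMap(values=values, bin_size_nm=bin_size_nm,
                         origin_nm=(-half_extent_nm, -half_extent_nm),
                         n_localizations=int(n))
    nb = values.shape[0]
    ycent = -half_extent_nm + (np.arange(nb) + 0.5) * bin_size_nm
    band = np.abs(ycent) <= profile_band_nm
    prof_mass = values[band, :].sum(axis=0)
    xcent = -half_extent_nm + (np.arange(values.shape[1]) + 0.5) * bin_size_nm
    profile = pd.DataFrame({"s_nm": xcent, "mass": prof_mass})
    return avg, profile


def site_stability(locs: pd.DataFrame, site: ContactSite, pmap: ProbabilityMap,
                   window_s: float = 15.0, theta: float = 5.0,
                   min_area_bins: int = 4) -> bool:
    """Re-detect the site on consecutive sub-windows; flag unstable when it
    is absent (no overlapping hotspot) in at least one sub-window."""
    t = locs["t_s"]
    t0, t1 = float(t.min()), float(t.max())
    n_win = max(int((t1 - t0) // window_s), 1)
    stable = True
    for k in range(n_win):
        sub = probability_map(locs, pmap.bin_size_nm,
                              window_s=(t0 + k * window_s, t0 + (k + 1) * window_s),
                              roi_nm=(pmap.origin_nm[0],
                                      pmap.origin_nm[0] + pmap.values.shape[1] * pmap.bin_size_nm,
                                      pmap.origin_nm[1],
                                      pmap.origin_nm[1] + pmap.values.shape[0] * pmap.bin_size_nm))
        subsites = detect_hotspots(sub, theta=theta, min_area_bins=min_area_bins)
        if not any((s.footprint & site.footprint).any() for s in subsites):
            stable = False
            break
    site.unstable = not stable
    return stable
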