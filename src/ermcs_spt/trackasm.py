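"""Trajectory assembly: precision filtering, LAP linking with gap closing,
and structure-constrained curation against the ER mask.

Trajectories are represented as a single tidy DataFrame with columns
``track_id, frame, t_s, x_nm, y_nm, sigma_nm, gap_closed`` (``gap_closed``
flags a localization whose link *to the previous row* bridged one or more
missing frames).  Steps are one row per consecutive localization pair.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

TRAJ_COLUMNS = ["track_id", "frame", "t_s", "x_nm", "y_nm", "sigma_nm", "gap_closed"]
STEP_COLUMNS = ["track_id", "t_start", "x_start", "y_start", "dx_nm", "dy_nm",
                "dt_s", "sigma_start", "sigma_end", "gap_closed"]


def filter_localizations(locs: pd.DataFrame,
                         band: tuple[float, float] = (20.0, 30.0)) -> pd.DataFrame:
    """Keep localizations whose precision lies inside ``band`` (inclusive).

    The default band matches the 20-30 nm quality filter a CRLB-reporting
    localizer supports; set the lower bound to 0 to keep better-than-20 nm
    localizations.
    """
    lo, hi = band
    if lo > hi:
        raise ValueError(f"band minimum {lo} exceeds maximum {hi}")
    keep = (locs["sigma_nm"] >= lo) & (locs["sigma_nm"] <= hi)
    removed = int((~keep).sum())
    if removed:
        log.info("precision filter removed %d of %d localizations", removed, len(locs))
    out = locs.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        log.warning("precision filter left no localizations")
    return out


def _match_frames(prev_xy: np.ndarray, cur_xy: np.ndarray, max_disp: float,
                  greedy_threshold: int = 500) -> list[tuple[int, int]]:
    """Minimum-cost bipartite matching between two point sets, gated at
    ``max_disp``; greedy nearest-neighbour fallback on very dense frames."""
    if len(prev_xy) == 0 or len(cur_xy) == 0:
        return []
    d = cdist(prev_xy, cur_xy)
    if max(len(prev_xy), len(cur_xy)) > greedy_threshold:
        pairs = []
        d = d.copy()
        while True:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            if d[i, j] > max_disp:
                break
            pairs.append((int(i), int(j)))
            d[i, :] = np.inf
            d[:, j] = np.inf
        return pairs
    big = max_disp * 1e6 + 1.0
    cost = np.where(d <= max_disp, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if d[i, j] <= max_disp]


def link_trajectories(locs: pd.DataFrame, max_disp_nm: float = 400.0,
                      max_gap: int = 1) -> pd.DataFrame:
    """Assemble trajectories by per-frame LAP matching plus gap closing.

    Between consecutive frames a global minimum-cost assignment is solved on
    pairwise distances, discarding candidate links longer than
    ``max_disp_nm``.  Track ends may then reconnect to later track starts
    across up to ``max_gap`` missing frames, with the distance gate inflated
    to ``max_disp_nm * sqrt(gap + 1)`` (Brownian search-radius scaling).
    """
    if max_disp_nm <= 0:
        raise ValueError("max_disp_nm must be positive")
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    if len(locs) == 0:
        return pd.DataFrame(columns=TRAJ_COLUMNS)

    locs = locs.sort_values(["frame"], kind="stable").reset_index(drop=True)
    frames = locs["frame"].to_numpy()
    xy = locs[["x_nm", "y_nm"]].to_numpy()
    track_of = np.full(len(locs), -1, dtype=np.int64)
    next_track = 0

    frame_values = np.unique(frames)
    idx_by_frame = {f: np.flatnonzero(frames == f) for f in frame_values}

    prev_idx: np.ndarray | None = None
    for fi, f in enumerate(frame_values):
        cur_idx = idx_by_frame[f]
        if prev_idx is not None and frame_values[fi - 1] == f - 1:
            pairs = _match_frames(xy[prev_idx], xy[cur_idx], max_disp_nm)
        else:
            pairs = []
        matched_cur = set()
        for i, j in pairs:
            track_of[cur_idx[j]] = track_of[prev_idx[i]]
            matched_cur.add(j)
        for j in range(len(cur_idx)):
            if j not in matched_cur:
                track_of[cur_idx[j]] = next_track
                next_track += 1
        prev_idx = cur_idx

    gap_closed = np.zeros(len(locs), dtype=bool)

    if max_gap > 0 and next_track > 1:
        # Segment ends / starts for gap closing.
        seg_first, seg_last = {}, {}
        for i in range(len(locs)):
            t = track_of[i]
            if t not in seg_first:
                seg_first[t] = i
            seg_last[t] = i
        ends = np.array(sorted(seg_last.values()))
        starts = np.array(sorted(seg_first.values()))
        cand = []
        # group by frame so only compatible (end, start) pairs are scanned
        starts_by_frame: dict[int, np.ndarray] = {}
        for f in np.unique(frames[starts]):
            starts_by_frame[int(f)] = starts[frames[starts] == f]
        for g in range(1, max_gap + 1):
            gate = max_disp_nm * np.sqrt(g + 1)
            for f in np.unique(frames[ends]):
                ss = starts_by_frame.get(int(f) + g + 1)
                if ss is None:
                    continue
                ee = ends[frames[ends] == f]
                d = cdist(xy[ee], xy[ss])
                for ii, jj in zip(*np.nonzero(d <= gate)):
                    ei, si = int(ee[ii]), int(ss[jj])
                    if track_of[si] != track_of[ei]:
                        cand.append((ei, si, float(d[ii, jj])))
        # Global LAP over candidate (end, start) pairs.
        if cand:
            es = sorted({c[0] for c in cand})
            ss = sorted({c[1] for c in cand})
            e_pos = {e: k for k, e in enumerate(es)}
            s_pos = {s: k for k, s in enumerate(ss)}
            big = max_disp_nm * 1e6
            cost = np.full((len(es), len(ss)), big)
            for e, s, dist in cand:
                cost[e_pos[e], s_pos[s]] = dist
            rows, cols = linear_sum_assignment(cost)
            # merge, relabeling in ascending end order for determinism
            merges = [(es[i], ss[j]) for i, j in zip(rows, cols) if cost[i, j] < big]
            for e, s in sorted(merges):
                old = track_of[s]
                new = track_of[e]
                if old == new:
                    continue
                track_of[track_of == old] = new
                gap_closed[s] = True

    out = locs.copy()
    out["track_id"] = track_of
    out["gap_closed"] = gap_closed
    # renumber tracks in order of first appearance
    order = out.sort_values(["frame"], kind="stable")["track_id"]
    remap = {t: k for k, t in enumerate(pd.unique(order))}
    out["track_id"] = out["track_id"].map(remap)
    out = out.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    extras = [c for c in out.columns if c not in TRAJ_COLUMNS]
    return out[TRAJ_COLUMNS + extras]  # extra columns (e.g. test sidecars) ride along


def geodesic_distance(er_mask: np.ndarray, pixel_size_nm: float,
                      start_nm: tuple[float, float], end_nm: tuple[float, float]) -> float:
    """Shortest-path distance through the ER foreground (8-connected,
    pixel-centre metric), in nm.  Returns inf when no path exists or an
    endpoint falls off the mask."""
    from skimage.graph import MCP_Geometric

    ny, nx = er_mask.shape

    def to_pix(p):
        ix, iy = int(np.floor(p[0] / pixel_size_nm)), int(np.floor(p[1] / pixel_size_nm))
        return iy, ix

    s = to_pix(start_nm)
    e = to_pix(end_nm)
    for (iy, ix) in (s, e):
        if not (0 <= iy < ny and 0 <= ix < nx) or not er_mask[iy, ix]:
            return np.inf
    if s == e:
        return 0.0
    costs = np.where(er_mask, 1.0, np.inf)
    mcp = MCP_Geometric(costs, fully_connected=True)
    cum, _ = mcp.find_costs(starts=[s], ends=[e], find_all_ends=False)
    d = cum[e]
    return float(d * pixel_size_nm) if np.isfinite(d) else np.inf


def curate_by_structure(trajs: pd.DataFrame, er_mask: np.ndarray,
                        pixel_size_nm: float, ratio_max: float = 2.0,
                        snap_tolerance_nm: float = 75.0) -> pd.DataFrame:
    """Cut trajectory links that are close in 2D but far through the ER.

    For every link the geodesic distance between its endpoints through the
    ER foreground is compared with the Euclidean distance; links whose ratio
    exceeds ``ratio_max`` (or with no connecting path at all) are cut and
    the trajectory split.  Deterministic replacement for the manual curation
    step a human would perform against the ER reference channel.

    Localization error pushes genuine endpoints slightly off a thin tubule
    mask, so endpoints are snapped to the nearest ER pixel within
    ``snap_tolerance_nm`` (≈ 3σ at 25 nm precision) before the geodesic is
    computed; endpoints farther off the structure than that cut the link.
    """
    if er_mask is None or not np.any(er_mask):
        raise ValueError("structure-constrained curation requires a non-empty ER mask")
    if len(trajs) == 0:
        return trajs.copy()

    trajs = trajs.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    xy = trajs[["x_nm", "y_nm"]].to_numpy()
    tids = trajs["track_id"].to_numpy()
    cut_before = np.zeros(len(trajs), dtype=bool)
    n_cut = 0
    ny, nx = er_mask.shape

    from scipy import ndimage
    dist_pix, nearest = ndimage.distance_transform_edt(~er_mask, return_indices=True)

    is_link = np.zeros(len(trajs), dtype=bool)
    is_link[1:] = tids[1:] == tids[:-1]
    link_idx = np.flatnonzero(is_link)
    a_all = xy[link_idx - 1]
    b_all = xy[link_idx]

    def snap_all(p):
        """Snapped coordinates (nm) and validity for an (n, 2) array."""
        ix = np.floor(p[:, 0] / pixel_size_nm).astype(int)
        iy = np.floor(p[:, 1] / pixel_size_nm).astype(int)
        on_grid = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        ixc = np.clip(ix, 0, nx - 1)
        iyc = np.clip(iy, 0, ny - 1)
        near_ok = dist_pix[iyc, ixc] * pixel_size_nm <= snap_tolerance_nm
        valid = on_grid & near_ok
        sy = nearest[0][iyc, ixc]
        sx = nearest[1][iyc, ixc]
        out = np.column_stack([(sx + 0.5), (sy + 0.5)]) * pixel_size_nm
        on_mask = on_grid & er_mask[iyc, ixc]
        out[on_mask] = p[on_mask]  # already on the structure: keep exact position
        return out, valid

    def segments_on_mask(a, b):
        """Vectorized: is the straight a->b segment fully on the foreground?

        Links are bucketed by length so the sample count adapts per bucket
        (samples every half pixel) without blowing up memory on rare long
        gap-closed steps.
        """
        n_links = len(a)
        out = np.zeros(n_links, dtype=bool)
        if n_links == 0:
            return out
        lengths = np.hypot(*(b - a).T)
        k_need = np.maximum(np.ceil(lengths / (0.5 * pixel_size_nm)).astype(int) + 1, 2)
        k_round = 2 ** np.ceil(np.log2(k_need)).astype(int)  # bucket by power of two
        for k in np.unique(k_round):
            sel = np.flatnonzero(k_round == k)
            ts = np.linspace(0.0, 1.0, int(k))
            pts = a[sel, None, :] + ts[None, :, None] * (b[sel] - a[sel])[:, None, :]
            ix = np.floor(pts[..., 0] / pixel_size_nm).astype(int)
            iy = np.floor(pts[..., 1] / pixel_size_nm).astype(int)
            on_grid = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            ok = on_grid & er_mask[np.clip(iy, 0, ny - 1), np.clip(ix, 0, nx - 1)]
            out[sel] = ok.all(axis=1)
        return out

    eu_all = np.hypot(*(b_all - a_all).T)
    direct = segments_on_mask(a_all, b_all)
    a_snap, a_ok = snap_all(a_all)
    b_snap, b_ok = snap_all(b_all)
    snap_ok = a_ok & b_ok
    snap_direct = np.zeros(len(link_idx), dtype=bool)
    todo = ~direct & snap_ok
    snap_direct[todo] = segments_on_mask(a_snap[todo], b_snap[todo])
    geo_all = np.full(len(link_idx), np.inf)
    geo_all[snap_direct] = np.hypot(*(b_snap[snap_direct] - a_snap[snap_direct]).T)

    allowance = 2 * np.sqrt(2) * pixel_size_nm  # pixel-centre discretization slack
    for j in np.flatnonzero(~direct):
        if not snap_ok[j]:
            cut_before[link_idx[j]] = True
            n_cut += 1
            continue
        geo = geo_all[j] if snap_direct[j] else geodesic_distance(
            er_mask, pixel_size_nm, tuple(a_snap[j]), tuple(b_snap[j]))
        if not np.isfinite(geo) or geo > ratio_max * eu_all[j] + allowance:
            cut_before[link_idx[j]] = True
            n_cut += 1
    if n_cut:
        log.info("structure curation cut %d links", n_cut)

    new_tid = np.zeros(len(trajs), dtype=np.int64)
    tid = -1
    for i in range(len(trajs)):
        if i == 0 or tids[i] != tids[i - 1] or cut_before[i]:
            tid += 1
        new_tid[i] = tid
    out = trajs.copy()
    out["track_id"] = new_tid
    out.loc[cut_before, "gap_closed"] = False
    return out


def make_steps(trajs: pd.DataFrame) -> pd.DataFrame:
    """One row per consecutive localization pair within a track.

    ``dt_s`` comes from the timestamps, not frame counts, so a step spanning
    a closed gap carries its true (longer) time interval and keeps the
    ``gap_closed`` flag.
    """
    if len(trajs) == 0:
        return pd.DataFrame(columns=STEP_COLUMNS)
    t = trajs.sort_values(["track_id", "frame"], kind="stable")
    g = t.groupby("track_id", sort=True)
    first = g.cumcount() == 0
    prev = t.shift(1)
    ok = ~first.to_numpy()
    steps = pd.DataFrame({
        "track_id": t["track_id"].to_numpy()[ok],
        "t_start": prev["t_s"].to_numpy()[ok],
        "x_start": prev["x_nm"].to_numpy()[ok],
        "y_start": prev["y_nm"].to_numpy()[ok],
        "dx_nm": (t["x_nm"] - prev["x_nm"]).to_numpy()[ok],
        "dy_nm": (t["y_nm"] - prev["y_nm"]).to_numpy()[ok],
        "dt_s": (t["t_s"] - prev["t_s"]).to_numpy()[ok],
        "sigma_start": prev["sigma_nm"].to_numpy()[ok],
        "sigma_end": t["sigma_nm"].to_numpy()[ok],
        "gap_closed": t["gap_closed"].to_numpy()[ok],
    }).reset_index(drop=True)
    return steps
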