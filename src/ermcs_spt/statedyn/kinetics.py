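"""Contact-bound step classification and dwell-time statistics.

A step is "bound" when it starts inside a detected contact-site footprint
and its motion is slow relative to the free-ER reference: for long tracks
the SLDS state's largest diffusion eigenvalue is compared against
``phi * D_ref``; short tracks (the majority in sptPALM, where bleaching
limits track length) use a centred rolling window of noise-corrected
per-step diffusion estimates instead.  A binding interaction is a maximal
run of consecutive bound steps at one site; interactions still bound when
the track ends (bleaches) are censored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..difflandscape import per_step_diffusion

log = logging.getLogger(__name__)

DWELL_COLUMNS = ["site_id", "track_id", "t_enter", "t_exit", "duration_s", "censored"]


def free_reference_diffusion(steps: pd.DataFrame, sites: list) -> float:
    """Pooled noise-corrected D over steps starting outside every footprint."""
    outside = np.ones(len(steps), dtype=bool)
    for site in sites:
        outside &= ~site.contains(steps["x_start"].to_numpy(), steps["y_start"].to_numpy())
    if outside.sum() < 10:
        raise ValueError("no free-state reference estimable: too few steps outside sites")
    return float(np.mean(per_step_diffusion(steps.loc[outside])))


def _clean_runs(b: np.ndarray, sid: np.ndarray, min_bound_run: int,
                max_free_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Suppress state flickers below the window estimator's resolution:
    drop bound runs shorter than ``min_bound_run`` steps, then bridge free
    gaps shorter than ``max_free_gap`` steps flanked by bound runs at the
    same site."""
    b = b.copy()
    sid = sid.copy()
    n = len(b)
    # opening: remove too-short bound runs
    i = 0
    while i < n:
        if b[i]:
            j = i
            while j + 1 < n and b[j + 1] and sid[j + 1] == sid[i]:
                j += 1
            if j - i + 1 < min_bound_run:
                b[i:j + 1] = False
                sid[i:j + 1] = -1
            i = j + 1
        else:
            i += 1
    # closing: fill short free gaps between bound runs at the same site
    i = 0
    while i < n:
        if not b[i]:
            j = i
            while j + 1 < n and not b[j + 1]:
                j += 1
            gap = j - i + 1
            if (0 < i and j < n - 1 and gap < max_free_gap
                    and b[i - 1] and b[j + 1] and sid[i - 1] == sid[j + 1]):
                b[i:j + 1] = True
                sid[i:j + 1] = sid[i - 1]
            i = j + 1
        else:
            i += 1
    return b, sid


def classify_contact_steps(steps: pd.DataFrame, sites: list,
                           segmentations: dict[int, object] | None = None,
                           phi: float = 0.5, window: int = 15,
                           reference_D_nm2_s: float | None = None,
                           min_bound_run: int | None = None,
                           max_free_gap: int | None = None) -> pd.DataFrame:
    """Label every step bound/free and attribute bound steps to a site.

    Returns a DataFrame aligned with ``steps`` (same index) with columns
    ``bound`` and ``site_id`` (-1 for free steps).  ``phi`` is the slow-state
    threshold as a fraction of the free-ER reference diffusion coefficient.
    Because the rolling-window estimate cannot resolve states shorter than
    its own window, label runs below that resolution are treated as noise:
    bound runs shorter than ``min_bound_run`` (default window // 3) are
    dropped and free gaps shorter than ``max_free_gap`` (default
    2 * window // 3) between same-site bound runs are bridged.
    """
    if reference_D_nm2_s is None:
        reference_D_nm2_s = free_reference_diffusion(steps, sites)
    thr = phi * reference_D_nm2_s
    if min_bound_run is None:
        min_bound_run = max(window // 3, 1)
    if max_free_gap is None:
        max_free_gap = max(2 * window // 3, 1)

    n = len(steps)
    site_of_start = np.full(n, -1, dtype=np.int64)
    xs = steps["x_start"].to_numpy()
    ys = steps["y_start"].to_numpy()
    for site in sites:
        inside = site.contains(xs, ys)
        site_of_start[inside & (site_of_start == -1)] = site.site_id

    bound = np.zeros(n, dtype=bool)
    site_id = np.full(n, -1, dtype=np.int64)
    inst = per_step_diffusion(steps)

    for tid, g in steps.groupby("track_id", sort=True):
        pos = steps.index.get_indexer(g.index)
        seg = (segmentations or {}).get(tid)
        if seg is not None and len(seg.labels) == len(pos):
            state_D = np.array([
                seg.states[k].diffusion_eigenvalues_nm2_s.max() if k in seg.states else np.inf
                for k in seg.labels
            ])
            slow = state_D < thr
            b = slow & (site_of_start[pos] >= 0)
            bound[pos] = b
            site_id[pos[b]] = site_of_start[pos[b]]
        else:
            # Centred rolling estimate of D and of start position.  The
            # window statistic is a median rescaled for consistency (for
            # Gaussian steps the squared displacement is exponential, whose
            # median is ln2 of the mean), so one large step cannot poison a
            # whole window the way a mean would.
            sig2 = ((0.5 * (steps["sigma_start"].to_numpy()[pos]
                            + steps["sigma_end"].to_numpy()[pos])) ** 2
                    / steps["dt_s"].to_numpy()[pos])
            raw = pd.Series(inst[pos] + sig2)  # uncorrected apparent D
            roll_med = raw.rolling(window, center=True, min_periods=1).median().to_numpy()
            roll_D = roll_med / np.log(2.0) - sig2
            rx = pd.Series(xs[pos]).rolling(window, center=True, min_periods=1).mean().to_numpy()
            ry = pd.Series(ys[pos]).rolling(window, center=True, min_periods=1).mean().to_numpy()
            cent_site = np.full(len(pos), -1, dtype=np.int64)
            for site in sites:
                inside = site.contains(rx, ry)
                cent_site[inside & (cent_site == -1)] = site.site_id
            b = (roll_D < thr) & (cent_site >= 0)
            sid_local = np.where(b, cent_site, -1)
            b, sid_local = _clean_runs(b, sid_local, min_bound_run, max_free_gap)
            bound[pos] = b
            site_id[pos] = sid_local

    return pd.DataFrame({"bound": bound, "site_id": site_id}, index=steps.index)


@dataclass
class DwellSummary:
    median_s: float
    leaving_frequency_per_s: float
    n_interactions: int
    n_censored: int
    total_bound_time_s: float
    ecdf_durations_s: np.ndarray
    ecdf_probs: np.ndarray


def dwell_times(steps: pd.DataFrame, labels: pd.DataFrame,
                dt_s: float | None = None,
                detection_floor_s: float = 0.0) -> tuple[pd.DataFrame, DwellSummary]:
    """Extract binding interactions and their dwell-time statistics.

    An interaction is a maximal run of consecutive bound steps at one site;
    duration = run length x dt.  Runs that reach the end of a track are
    censored (the fluorophore bleached while bound): they contribute their
    observed duration to the median and the denominator of the leaving
    frequency, but not to its numerator.

    ``detection_floor_s`` is the shortest dwell the upstream classifier can
    report (its minimum-run length x dt).  Observed durations are then
    left-truncated, and the leaving frequency uses the truncation-corrected
    exponential estimator n_uncensored / (total_time - n * floor); with
    floor 0 it reduces to the plain events-per-bound-time rate.
    """
    rows = []
    for tid, g in steps.groupby("track_id", sort=True):
        lb = labels.loc[g.index]
        b = lb["bound"].to_numpy()
        sid = lb["site_id"].to_numpy()
        t0 = g["t_start"].to_numpy()
        dts = g["dt_s"].to_numpy()
        dt = dt_s if dt_s is not None else float(np.median(dts))
        i = 0
        n = len(g)
        while i < n:
            if not b[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and b[j + 1] and sid[j + 1] == sid[i]:
                j += 1
            run_len = j - i + 1
            rows.append({
                "site_id": int(sid[i]),
                "track_id": tid,
                "t_enter": float(t0[i]),
                "t_exit": float(t0[i] + run_len * dt),
                "duration_s": float(run_len * dt),
                "censored": bool(j == n - 1),
            })
            i = j + 1
    records = pd.DataFrame(rows, columns=DWELL_COLUMNS)
    if len(records):
        dur = records["duration_s"].to_numpy()
        cens = records["censored"].to_numpy()
        total = float(dur.sum())
        order = np.sort(dur)
        eff_total = total - len(dur) * detection_floor_s
        summary = DwellSummary(
            median_s=float(np.median(dur)),
            leaving_frequency_per_s=float((~cens).sum() / eff_total) if eff_total > 0 else np.nan,
            n_interactions=len(records),
            n_censored=int(cens.sum()),
            total_bound_time_s=total,
            ecdf_durations_s=order,
            ecdf_probs=np.arange(1, len(order) + 1) / len(order),
        )
    else:
        summary = DwellSummary(np.nan, np.nan, 0, 0, 0.0, np.array([]), np.array([]))
    return records, summary


def trapped_fraction(records: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Per-site fraction of visiting molecules bound for the rest of their
    fluorophore lifetime.

    A molecule is trapped at a site when its only interaction there is
    censored — every observed step from first binding to the end of the
    track stayed bound.  Returns (per-site table, mean, s.e.m.) across
    sites with at least one visitor.
    """
    rows = []
    for sid, g in records.groupby("site_id", sort=True):
        per_track = g.groupby("track_id")
        n_visit = per_track.ngroups
        if n_visit == 0:
            continue
        n_trapped = 0
        for _, r in per_track:
            if len(r) == 1 and bool(r["censored"].iloc[0]):
                n_trapped += 1
        rows.append({"site_id": sid, "n_visitors": n_visit, "n_trapped": n_trapped,
                     "trapped_fraction": n_trapped / n_visit})
    table = pd.DataFrame(rows, columns=["site_id", "n_visitors", "n_trapped", "trapped_fraction"])
    if len(table) == 0:
        return table, np.nan, np.nan
    vals = table["trapped_fraction"].to_numpy()
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return table, mean, sem
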