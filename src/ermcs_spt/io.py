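"""Readers and writers for the pipeline's on-disk formats.

Formats: localization/trajectory/step tables as CSV; masks as single-plane
grayscale TIFF (0/255) with a JSON metadata sidecar; probability maps as
32-bit float TIFF + JSON; label volumes as multi-page TIFF; meshes as PLY
(binary little-endian) with the curvature scalar in the ``quality`` channel;
sites as JSON records plus a flat CSV; configs as TOML.  Every writer has a
matching reader and the pair round-trips (coordinates to 1e-3 nm for PLY,
bit-identical for CSV/TIFF).
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh

from .sitemap import ContactSite, ProbabilityMap

LOC_COLUMNS = ["frame", "t_s", "x_nm", "y_nm", "sigma_nm"]


def write_localizations(path: str | Path, locs: pd.DataFrame) -> None:
    # %.17g guarantees doubles survive the text round trip exactly
    locs.to_csv(path, index=False, float_format="%.17g",
                columns=[c for c in LOC_COLUMNS if c in locs.columns])


def read_localizations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LOC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing localization columns {missing}")
    bad = df[["x_nm", "y_nm"]].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: malformed rows at lines "
                         f"{(np.flatnonzero(bad) + 2)[:10].tolist()}")  # +2: header, 1-based
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_mask(path: str | Path, mask: np.ndarray, pixel_size_nm: float,
               origin_nm: tuple[float, float] = (0.0, 0.0)) -> None:
    tifffile.imwrite(str(path), (mask.astype(np.uint8) * 255))
    meta = {"pixel_size_nm": pixel_size_nm, "origin_nm": list(origin_nm)}
    Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True))


def read_mask(path: str | Path) -> tuple[np.ndarray, dict]:
    arr = tifffile.imread(str(path))
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {"pixel_size_nm": 1.0}
    return arr > 0, meta


def write_probability_map(path: str | Path, pmap: ProbabilityMap) -> None:
    tifffile.imwrite(str(path), pmap.values.astype(np.float32))
    meta = {
        "bin_size_nm": pmap.bin_size_nm,
        "origin_nm": list(pmap.origin_nm),
        "window_s": list(pmap.window_s) if pmap.window_s else None,
        "n_localizations": pmap.n_localizations,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True))


def read_probability_map(path: str | Path) -> ProbabilityMap:
    values = tifffile.imread(str(path)).astype(np.float64)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return ProbabilityMap(
        values=values,
        bin_size_nm=meta["bin_size_nm"],
        origin_nm=tuple(meta["origin_nm"]),
        window_s=tuple(meta["window_s"]) if meta.get("window_s") else None,
        n_localizations=meta.get("n_localizations", 0),
    )


def write_volume(path: str | Path, labels: np.ndarray, voxel_size_nm: float) -> None:
    tifffile.imwrite(str(path), labels.astype(np.uint8))
    Path(str(path) + ".json").write_text(json.dumps({"voxel_size_nm": voxel_size_nm}))


def read_volume(path: str | Path):
    from .simkit.phantoms import VoxelVolume

    labels = tifffile.imread(str(path))
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {"voxel_size_nm": 8.0}
    return VoxelVolume(labels=labels, voxel_size_nm=meta["voxel_size_nm"])


def write_mesh(path: str | Path, mesh: trimesh.Trimesh) -> None:
    """Binary little-endian PLY; per-vertex mean curvature rides in the
    standard ``quality`` channel when present."""
    out = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    h = mesh.vertex_attributes.get("mean_curvature")
    if h is not None:
        out.vertex_attributes["quality"] = np.nan_to_num(h).astype(np.float32)
    export = trimesh.exchange.ply.export_ply(out, encoding="binary_little_endian",
                                             include_attributes=True)
    Path(path).write_bytes(export)


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), process=False)
    # PLY 'quality' comes back via vertex attributes when present
    q = None
    if hasattr(mesh, "metadata"):
        q = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data", {})
    try:
        if q is not None and "quality" in q.dtype.names:
            mesh.vertex_attributes["mean_curvature"] = np.asarray(q["quality"], dtype=float)
    except Exception:
        pass
    return mesh


def sites_to_records(sites: list[ContactSite]) -> list[dict]:
    recs = []
    for s in sites:
        recs.append({
            "site_id": s.site_id,
            "centre_nm": [float(s.centre_nm[0]), float(s.centre_nm[1])],
            "major_axis_nm": float(s.major_axis_nm),
            "minor_axis_nm": float(s.minor_axis_nm),
            "equivalent_diameter_nm": float(s.equivalent_diameter_nm),
            "area_nm2": float(s.area_nm2),
            "mito_associated": s.mito_associated,
            "degenerate": bool(s.degenerate),
            "unstable": s.unstable,
            "bin_size_nm": float(s.bin_size_nm),
            "origin_nm": [float(s.origin_nm[0]), float(s.origin_nm[1])],
            "footprint_bins": np.argwhere(s.footprint).tolist(),
            "footprint_shape": list(s.footprint.shape),
            "tubule_axis": s.tubule_axis.tolist() if s.tubule_axis is not None else None,
        })
    return recs


def write_sites(path_json: str | Path, sites: list[ContactSite],
                path_csv: str | Path | None = None) -> None:
    recs = sites_to_records(sites)
    Path(path_json).write_text(json.dumps(recs, sort_keys=True, indent=1))
    if path_csv is not None:
        flat = pd.DataFrame([{k: r[k] for k in
                              ("site_id", "major_axis_nm", "minor_axis_nm",
                               "equivalent_diameter_nm", "area_nm2", "mito_associated")}
                             | {"centre_x_nm": r["centre_nm"][0], "centre_y_nm": r["centre_nm"][1]}
                             for r in recs])
        flat.to_csv(path_csv, index=False)


def read_sites(path_json: str | Path) -> list[ContactSite]:
    recs = json.loads(Path(path_json).read_text())
    sites = []
    for r in recs:
        fp = np.zeros(tuple(r["footprint_shape"]), dtype=bool)
        idx = np.asarray(r["footprint_bins"], dtype=int)
        if len(idx):
            fp[idx[:, 0], idx[:, 1]] = True
        s = ContactSite(
            site_id=r["site_id"], footprint=fp,
            bin_size_nm=r["bin_size_nm"], origin_nm=tuple(r["origin_nm"]),
            centre_nm=tuple(r["centre_nm"]),
            major_axis_nm=r["major_axis_nm"], minor_axis_nm=r["minor_axis_nm"],
            area_nm2=r["area_nm2"], mito_associated=r["mito_associated"],
            degenerate=r["degenerate"], unstable=r["unstable"],
            tubule_axis=np.asarray(r["tubule_axis"]) if r["tubule_axis"] else None,
        )
        sites.append(s)
    return sites


def read_config_toml(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)
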