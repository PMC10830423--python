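"""Analytic triangulated test surfaces with known mean curvature.

Fixtures for the curvature operator: plane (H = 0), sphere (H = 1/R),
cylinder lateral surface (H = 1/(2R)) and a saddle.  The analytic reference
curvature is stored per vertex in ``mesh.vertex_attributes
['reference_mean_curvature']`` and a boolean ``interior`` attribute marks
vertices away from open boundaries where the reference applies cleanly.
All normals are oriented outward (plane/saddle: +z).
"""

from __future__ import annotations

import numpy as np
import trimesh


def _grid_faces(ni: int, nj: int) -> np.ndarray:
    """Triangulate an (ni x nj) vertex grid (two triangles per quad, CCW)."""
    idx = np.arange(ni * nj).reshape(ni, nj)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    return np.concatenate([np.column_stack([a, b, c]), np.column_stack([a, c, d])])


def make_test_mesh(shape: str, radius_nm: float = 200.0, extent_nm: float = 1000.0,
                   height_nm: float | None = None, edge_nm: float = 20.0,
                   saddle_scale_nm: float = 200.0) -> trimesh.Trimesh:
    """Build an analytic test surface.

    shape: "plane", "sphere", "cylinder" (open-ended lateral surface along z)
    or "saddle" (z = (x^2 - y^2) / (2*saddle_scale_nm)).
    """
    if edge_nm <= 0:
        raise ValueError("target edge length must be positive")
    if shape in ("sphere", "cylinder") and radius_nm <= 0:
        raise ValueError(f"degenerate radius {radius_nm} for {shape}")
    if shape in ("plane", "saddle") and extent_nm <= 0:
        raise ValueError("extent must be positive")

    if shape == "plane":
        n = max(int(round(extent_nm / edge_nm)) + 1, 2)
        xs = np.linspace(-extent_nm / 2, extent_nm / 2, n)
        xx, yy = np.meshgrid(xs, xs, indexing="ij")
        verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        mesh = trimesh.Trimesh(vertices=verts, faces=_grid_faces(n, n), process=False)
        ref = np.zeros(len(verts))
        margin = extent_nm / 2 - 2 * edge_nm
        interior = (np.abs(verts[:, 0]) < margin) & (np.abs(verts[:, 1]) < margin)

    elif shape == "sphere":
        subdiv = max(0, int(np.ceil(np.log2(max(radius_nm / edge_nm, 1.0)))))
        mesh = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius_nm)
        ref = np.full(len(mesh.vertices), 1.0 / radius_nm)
        interior = np.ones(len(mesh.vertices), dtype=bool)

    elif shape == "cylinder":
        h = height_nm if height_nm is not None else 4 * radius_nm
        n_sec = max(int(round(2 * np.pi * radius_nm / edge_nm)), 8)
        n_z = max(int(round(h / edge_nm)) + 1, 2)
        theta = np.arange(n_sec) * 2 * np.pi / n_sec
        zs = np.linspace(-h / 2, h / 2, n_z)
        tt, zz = np.meshgrid(theta, zs, indexing="ij")
        verts = np.column_stack([
            radius_nm * np.cos(tt).ravel(),
            radius_nm * np.sin(tt).ravel(),
            zz.ravel(),
        ])
        # faces on the (theta, z) grid with wraparound in theta
        idx = np.arange(n_sec * n_z).reshape(n_sec, n_z)
        idx_wrap = np.vstack([idx, idx[:1]])
        faces = _grid_faces(n_sec + 1, n_z)
        faces = idx_wrap.ravel()[faces]
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
        ref = np.full(len(mesh.vertices), 1.0 / (2 * radius_nm))
        interior = np.abs(mesh.vertices[:, 2]) < h / 2 - 2 * edge_nm

    elif shape == "saddle":
        n = max(int(round(extent_nm / edge_nm)) + 1, 2)
        xs = np.linspace(-extent_nm / 2, extent_nm / 2, n)
        xx, yy = np.meshgrid(xs, xs, indexing="ij")
        zz = (xx**2 - yy**2) / (2 * saddle_scale_nm)
        verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        mesh = trimesh.Trimesh(vertices=verts, faces=_grid_faces(n, n), process=False)
        # H of z = (x^2 - y^2)/(2c) w.r.t. upward normal
        c = saddle_scale_nm
        zx = verts[:, 0] / c
        zy = -verts[:, 1] / c
        zxx, zyy = 1.0 / c, -1.0 / c
        denom = (1 + zx**2 + zy**2) ** 1.5
        ref = ((1 + zy**2) * zxx + (1 + zx**2) * zyy) / (2 * denom)
        margin = extent_nm / 2 - 2 * edge_nm
        interior = (np.abs(verts[:, 0]) < margin) & (np.abs(verts[:, 1]) < margin)

    else:
        raise ValueError(f"unknown test-mesh shape {shape!r}")

    # Orient normals outward / upward.
    if shape == "sphere":
        if mesh.volume < 0:
            mesh.invert()
    elif shape == "cylinder":
        radial = mesh.vertices[:, :2]
        radial = radial / np.linalg.norm(radial, axis=1, keepdims=True)
        if np.mean(np.einsum("ij,ij->i", mesh.vertex_normals[:, :2], radial)) < 0:
            mesh.invert()
    else:
        if mesh.vertex_normals[:, 2].mean() < 0:
            mesh.invert()

    mesh.vertex_attributes["reference_mean_curvature"] = ref
    mesh.vertex_attributes["interior"] = interior
    return mesh
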