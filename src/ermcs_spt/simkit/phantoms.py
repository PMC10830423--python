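"""3D voxel phantoms: membrane shells at a known separation.

A capsule-shaped "mitochondrion" (label 2, OMM shell) and a cylindrical
"ER tubule" (label 1, shell) run parallel; their closest approach equals
the requested gap, measured with the same surface metric the contact
identifier uses (voxel-centre distance minus one voxel, floored at zero).
Default voxels are isotropic 8 nm, as in FIB-SEM reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

LABEL_BG, LABEL_ER, LABEL_OMM, LABEL_CONTACT = 0, 1, 2, 3


@dataclass
class VoxelVolume:
    """Integer label volume with isotropic voxels (nm).

    Labels: 0 background, 1 ER membrane, 2 outer mitochondrial membrane,
    3 ER-contact (assigned by contact identification; subset of ER).
    """

    labels: np.ndarray
    voxel_size_nm: float = 8.0

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel_size_nm must be positive")

    def voxel_centres(self, label: int) -> np.ndarray:
        """(n, 3) nm coordinates of voxel centres carrying *label* (z, y, x order)."""
        idx = np.argwhere(self.labels == label)
        return (idx + 0.5) * self.voxel_size_nm


def _shell(solid: np.ndarray) -> np.ndarray:
    """One-voxel-thick surface shell of a solid mask (6-connected erosion)."""
    interior = ndimage.binary_erosion(solid, structure=ndimage.generate_binary_structure(3, 1))
    return solid & ~interior


def make_voxel_phantom(
    gap_nm: float,
    voxel_size_nm: float = 8.0,
    mito_radius_nm: float = 200.0,
    mito_length_nm: float = 800.0,
    er_radius_nm: float = 48.0,
    margin_nm: float = 80.0,
) -> VoxelVolume:
    """Capsule mitochondrion shell + parallel ER tube shell at a known gap.

    The gap is the surface separation at closest approach: the nearest
    ER-shell and OMM-shell voxel centres are vertically aligned and
    ``gap_nm + voxel_size_nm`` apart (centre to centre).  Geometry is snapped
    to the voxel grid so this holds exactly.  ``gap_nm`` must be a multiple
    of the voxel size for exactness; other values are rounded.
    """
    if gap_nm < 0:
        raise ValueError("gap must be non-negative (overlapping shapes are not supported)")
    vx = voxel_size_nm
    gap_vox = int(round(gap_nm / vx))
    rm = int(round(mito_radius_nm / vx))
    re = int(round(er_radius_nm / vx))
    lm = int(round(mito_length_nm / vx))
    mrg = int(round(margin_nm / vx))
    if rm < 2 or re < 2:
        raise ValueError("radii must span at least two voxels")

    # Mito capsule axis along x at voxel-centre height y_m; ER tube axis above.
    y_m = mrg + rm
    y_e = y_m + rm + gap_vox + 1 + re  # +1 voxel: centre-to-centre = gap + 1 voxel
    nz = 2 * (mrg + max(rm, re)) + 1
    ny = y_e + re + mrg + 1
    nx = lm + 2 * (mrg + rm)
    z_c = nz // 2

    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    x0, x1 = mrg + rm, mrg + rm + lm  # capsule cylindrical section
    ax = np.clip(xx, x0, x1)
    d2_mito = (zz - z_c) ** 2 + (yy - y_m) ** 2 + (xx - ax) ** 2
    mito_solid = d2_mito <= rm**2

    d2_er = (zz - z_c) ** 2 + (yy - y_e) ** 2
    er_solid = d2_er <= re**2

    if (mito_solid & er_solid).any():
        raise ValueError("mitochondrion and ER shapes overlap; increase the gap")

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    labels[_shell(er_solid)] = LABEL_ER
    labels[_shell(mito_solid)] = LABEL_OMM
    return VoxelVolume(labels=labels, voxel_size_nm=vx)
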