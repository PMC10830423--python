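"""Synthetic 2D organelle geometry: ER tubule masks, mitochondria, contact footprints.

Coordinates are nanometres; the raster convention is ``mask[iy, ix]`` with x
right / y down, pixel ``i`` covering the half-open interval
``[i*px, (i+1)*px)`` and its centre at ``(i + 0.5)*px``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GeometryMasks:
    """Binary rasters for ER, mitochondria, and the contact-site footprint.

    The contact footprint is always a subset of the ER mask; all rasters
    share a shape and pixel size.  ``contact_list_nm`` records the planted
    (cx, cy, radius) of each disc so simulators and tests know the truth.
    """

    er_mask: np.ndarray
    mito_mask: np.ndarray
    contact_footprint: np.ndarray
    pixel_size_nm: float
    contact_list_nm: list[tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if not (self.er_mask.shape == self.mito_mask.shape == self.contact_footprint.shape):
            raise ValueError("all masks must share one raster shape")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if np.any(self.contact_footprint & ~self.er_mask):
            raise ValueError("contact footprint must lie inside the ER mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.er_mask.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        """(width, height) of the raster in nm."""
        return (self.shape[1] * self.pixel_size_nm, self.shape[0] * self.pixel_size_nm)

    def pixel_centres(self, mask: np.ndarray) -> np.ndarray:
        """(n, 2) array of (x, y) centres of foreground pixels of *mask*."""
        iy, ix = np.nonzero(mask)
        return np.column_stack([(ix + 0.5), (iy + 0.5)]) * self.pixel_size_nm


def _disc_mask(shape: tuple[int, int], centre_nm: tuple[float, float], radius_nm: float,
               pixel_size_nm: float) -> np.ndarray:
    """Pixels whose centres lie within radius of centre. Radius 0 -> empty."""
    out = np.zeros(shape, dtype=bool)
    if radius_nm <= 0:
        return out
    iy, ix = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx = (ix + 0.5) * pixel_size_nm
    cy = (iy + 0.5) * pixel_size_nm
    out = (cx - centre_nm[0]) ** 2 + (cy - centre_nm[1]) ** 2 <= radius_nm**2
    return out


def make_er_geometry(
    tubule_width_nm: float = 100.0,
    tubule_length_nm: float = 5000.0,
    contact_radius_nm: float = 150.0,
    pixel_size_nm: float = 10.0,
    contact_centre_nm: tuple[float, float] | None = None,
    margin_nm: float = 500.0,
    mito_radius_nm: float = 400.0,
    mito_gap_nm: float = 30.0,
    shape: str = "strip",
    contacts_nm: list[tuple[float, float, float]] | None = None,
) -> GeometryMasks:
    """Build a tubule-strip ER mask, an adjacent mitochondrion, and disc footprints.

    ``shape`` may be ``"strip"`` (a single straight tubule) or ``"cross"``
    (two perpendicular tubules crossing at the contact centre).  By default
    one contact disc sits at the tubule midpoint; ``contacts_nm`` plants an
    explicit list of (cx, cy, radius) discs instead.  Disc centres must sit
    on the tubule (the ER mask locally widens into each footprint).
    """
    if tubule_width_nm <= 0 or tubule_length_nm <= 0 or pixel_size_nm <= 0:
        raise ValueError("tubule width, length and pixel size must be positive")
    if contact_radius_nm < 0:
        raise ValueError("contact radius must be non-negative")

    px = pixel_size_nm
    # Align the tubule to pixel boundaries so the rasterized strip is exact.
    x0 = round(margin_nm / px) * px
    y0 = round(margin_nm / px) * px
    nx = int(round((tubule_length_nm + 2 * margin_nm) / px))
    ny = int(round((tubule_width_nm + 2 * margin_nm) / px))
    grid_shape = (ny, nx)

    iy, ix = np.mgrid[0:ny, 0:nx]
    cx = (ix + 0.5) * px
    cy = (iy + 0.5) * px

    er = (cx >= x0) & (cx < x0 + tubule_length_nm) & (cy >= y0) & (cy < y0 + tubule_width_nm)
    midline_y = y0 + tubule_width_nm / 2.0
    if contact_centre_nm is None:
        contact_centre_nm = (x0 + tubule_length_nm / 2.0, midline_y)
    if contacts_nm is None:
        contacts_nm = [(contact_centre_nm[0], contact_centre_nm[1], contact_radius_nm)]

    if shape == "cross":
        cx0 = contacts_nm[0][0]
        er |= (cx >= cx0 - tubule_width_nm / 2) & (cx < cx0 + tubule_width_nm / 2)

    # The ER membrane is present throughout each contact patch: the mask
    # locally widens into the footprint (a contact disc can be wider than
    # the tubule).  Centres must sit on the tubule, otherwise a site would
    # be disconnected from the ER network.
    footprint = np.zeros(grid_shape, dtype=bool)
    for ccx, ccy, r in contacts_nm:
        on_tubule = (x0 <= ccx < x0 + tubule_length_nm) and (y0 <= ccy < y0 + tubule_width_nm)
        if shape == "cross":
            on_tubule = on_tubule or (
                contacts_nm[0][0] - tubule_width_nm / 2 <= ccx < contacts_nm[0][0] + tubule_width_nm / 2
            )
        if r > 0 and not on_tubule:
            raise ValueError(
                f"contact centre ({ccx}, {ccy}) nm lies off the tubule "
                f"(x in [{x0}, {x0 + tubule_length_nm}), y in [{y0}, {y0 + tubule_width_nm}))"
            )
        footprint |= _disc_mask(grid_shape, (ccx, ccy), r, px)
    er |= footprint

    # Mitochondrion: a disc sitting below the tubule, facing the first contact.
    mito_centre = (
        contacts_nm[0][0],
        y0 + tubule_width_nm + mito_gap_nm + mito_radius_nm,
    )
    mito = _disc_mask(grid_shape, mito_centre, mito_radius_nm, px)

    return GeometryMasks(er_mask=er, mito_mask=mito, contact_footprint=footprint,
                         pixel_size_nm=px, contact_list_nm=list(contacts_nm))
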