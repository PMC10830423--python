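import numpy as np
import pytest

from ermcs_spt.simkit import (
    SimulationConfig,
    image_and_localize,
    make_er_geometry,
    simulate_molecules,
)


@pytest.fixture(scope="session")
def default_geometry():
    return make_er_geometry()


@pytest.fixture(scope="session")
def short_sim(default_geometry):
    """A small simulated scene reused across tests: geometry, tracks,
    localizations, ground-truth sidecar."""
    cfg = SimulationConfig(n_frames=1200, seed=42)
    tracks = simulate_molecules(default_geometry, cfg)
    locs, sidecar = image_and_localize(tracks, cfg)
    return default_geometry, cfg, tracks, locs, sidecar


def truth_site_from_geometry(geometry, bin_size_nm=30.0, dilate=1):
    """ContactSite built from the planted footprint (test oracle helper)."""
    from scipy import ndimage

    from ermcs_spt.sitemap import ContactSite

    ny, nx = geometry.er_mask.shape
    gy = int(np.ceil(ny * geometry.pixel_size_nm / bin_size_nm))
    gx = int(np.ceil(nx * geometry.pixel_size_nm / bin_size_nm))
    fp = np.zeros((gy, gx), dtype=bool)
    iy, ix = np.nonzero(geometry.contact_footprint)
    fp[((iy + 0.5) * geometry.pixel_size_nm / bin_size_nm).astype(int),
       ((ix + 0.5) * geometry.pixel_size_nm / bin_size_nm).astype(int)] = True
    if dilate:
        fp = ndimage.binary_dilation(fp, np.ones((3, 3), dtype=bool), iterations=dilate)
    site = ContactSite(site_id=0, footprint=fp, bin_size_nm=bin_size_nm, origin_nm=(0.0, 0.0))
    if geometry.contact_list_nm:
        site.centre_nm = tuple(geometry.contact_list_nm[0][:2])
    return site
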