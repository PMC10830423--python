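"""Simulate a contact site and map it from localization density.

Builds a 5 um ER tubule with one 300 nm contact disc facing a
mitochondrion, runs a 60 s sptPALM-style recording, bins the localizations
into a 30 nm probability map and detects/measures the hotspot.
"""

import numpy as np

from ermcs_spt import sitemap, trackasm
from ermcs_spt.simkit import SimulationConfig, image_and_localize, make_er_geometry, simulate_molecules

geometry = make_er_geometry()  # tubule + 150 nm-radius contact + mitochondrion
cfg = SimulationConfig(n_frames=5700, seed=1)  # ~60 s at 95 Hz
tracks = simulate_molecules(geometry, cfg)
locs, _ = image_and_localize(tracks, cfg)
locs = trackasm.filter_localizations(locs)  # 20-30 nm precision band

pmap = sitemap.probability_map(locs)  # unit-sum 30 nm-binned density
sites = sitemap.detect_hotspots(pmap)
sites, enrichment = sitemap.associate_mitochondria(
    sites, geometry.mito_mask, geometry.pixel_size_nm, pmap,
    locs=locs, er_mask=geometry.er_mask)

cx, cy, r = geometry.contact_list_nm[0]
print(f"localizations: {len(locs)}; detected sites: {len(sites)}")
for s in sites:
    err = np.hypot(s.centre_nm[0] - cx, s.centre_nm[1] - cy)
    print(f"site {s.site_id}: centre ({s.centre_nm[0]:.0f}, {s.centre_nm[1]:.0f}) nm "
          f"[{err:.0f} nm from truth], equivalent diameter "
          f"{s.equivalent_diameter_nm:.0f} nm, mito-associated: {s.mito_associated}")
print(f"mitochondrial enrichment coefficient: {enrichment:.2f} "
      "(1.0 = localizations spread evenly over the ER)")
# The detected centre lands within a bin or two of the planted centre, and
# the moment diameter tracks the bound-molecule distribution (~2x the
# Gaussian binding width), not the raw pixel footprint.
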