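# ermcs_spt

Quantitative mapping of ER–mitochondria contact sites (ERMCSs) from
high-speed single-molecule trajectories and from segmented
electron-microscopy volumes.

Membrane contact sites are sub-diffraction structures (~100–600 nm) where
the ER membrane comes within molecular-tether distance (~24 nm) of the
outer mitochondrial membrane. Tether proteins such as VAPB diffuse freely
in the ER membrane (~0.5 µm²/s) and transiently bind at contact sites,
where their motion slows dramatically and their dwell times are set by the
unbinding kinetics. This package turns those raw observations —
localization tables from sptPALM at ~95 Hz with 20–30 nm precision, and
labeled 8 nm-voxel FIB-SEM volumes — into contact-site maps, diffusion
landscapes, kinetic parameters and membrane morphometrics, with a
synthetic-data module so every stage is verifiable against ground truth.

## What it computes

- **simkit** — synthetic ER geometry, Markov-switching diffusion tracks
  (free ⇄ contact-bound), noisy localization tables, analytic test meshes
  and 3D voxel phantoms, all with ground-truth sidecars.
- **trackasm** — precision filtering, LAP trajectory linking with gap
  closing, and structure-constrained curation: links that are close in 2D
  but far through the ER (geodesic/Euclidean > 2) are cut.
- **sitemap** — 30 nm-binned unit-sum spatial probability maps, hotspot
  detection (≥ 5× median occupied-bin mass), moment-based site sizing
  (±2σ axis widths), mitochondria association and enrichment,
  centre-aligned averaging along the tubule axis.
- **difflandscape** — Voronoi tessellation of each site seeded from its
  density, per-cell Bayesian inference of the effective 2D diffusion
  coefficient with static localization error separated out (per axis,
  Δx ~ N(drift·Δt, 2DΔt + 2σ²)), line profiles, tubule 1D coefficients,
  normalization to the surrounding ER.
- **statedyn** — sticky HDP-SLDS segmentation of long trajectories into
  latent diffusive states (blocked Gibbs; noise and thermal motion
  identified separately), bound-step classification, dwell-time records
  with censoring, leaving frequency, trapped fraction.
- **surfmorph** — ER voxels within 24 nm of the OMM labeled as contact
  (EDT surface metric), Gaussian-smoothed marching-cubes membrane meshes,
  per-vertex mean curvature by multi-ring quadratic-jet fitting, and
  simulated localization projections sized with the same moment metric as
  the light-microscopy sites.
- **pipeline / CLI** — `ermcs-spt run|demo|simulate|track|map-density|
  detect-contacts|infer-landscape|segment-states|dwell|curvature`, thin
  wrappers over the library; fixed-seed runs are byte-reproducible.

## Worked example

```python
from ermcs_spt import sitemap, trackasm
from ermcs_spt.simkit import (SimulationConfig, image_and_localize,
                              make_er_geometry, simulate_molecules)

geometry = make_er_geometry()                     # tubule + 300 nm contact disc
cfg = SimulationConfig(n_frames=5700, seed=1)     # ~60 s at 95 Hz
tracks = simulate_molecules(geometry, cfg)
locs, _ = image_and_localize(tracks, cfg)
locs = trackasm.filter_localizations(locs)        # 20-30 nm precision band

pmap = sitemap.probability_map(locs)              # 30 nm unit-sum density
sites = sitemap.detect_hotspots(pmap)
print(len(locs), len(sites), sites[0].centre_nm, sites[0].equivalent_diameter_nm)
```

prints

```
277839 1 (2999.656174863388, 550.3342076502732) 286.29212508532606
```

— 277,839 localizations yield exactly one detected site, its centre within
a nanometre of the planted (3000, 550) nm, and a moment-based equivalent
diameter of ~286 nm for the bound-molecule distribution of the 300 nm
disc with its Gaussian binding sub-domain. `examples/` contains one short
script per capability (density mapping, diffusion landscapes, state
segmentation, dwell kinetics, 3D curvature, full pipeline), each printing
the numbers it computes and what they mean.

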