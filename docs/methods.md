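# Methods

`ermcs_spt` maps ER–mitochondria contact sites (ERMCSs) two ways — from
high-speed single-particle tracking of a tether protein, and from labeled
electron-microscopy volumes — and keeps the two measurements comparable by
using one size metric for both. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data
does and does not emulate.

## Coordinate and unit conventions

All lengths are nanometres, times seconds, diffusion coefficients nm²/s
(reports also print µm²/s; 1 µm²/s = 10⁶ nm²/s). Rasters are indexed
`[iy, ix]` with x right / y down; pixel `i` covers the half-open interval
`[i·px, (i+1)·px)` with its centre at `(i+0.5)·px`. All randomness flows
from a single integer seed through named `numpy.random.SeedSequence`
spawns, so any fixed-seed run is byte-reproducible.

## Forward model (simkit)

The generator emulates a sptPALM experiment on a peripheral ER tubule:

- **Geometry.** A straight tubule strip (default 100 nm × 5 µm at 10 nm
  pixels) with one or more disc-shaped contact footprints on its midline;
  the ER mask locally widens into each footprint, since the membrane is
  present throughout a contact. A disc mitochondrion faces the first
  contact.
- **Motion.** Frame-synchronous Euler–Maruyama steps with per-axis std
  √(2·D·Δt), Δt = 1/95 s. Free molecules reflect at the ER mask
  (rejection-and-resample, ≤100 attempts, then clamp); **bound molecules
  are confined to the contact footprint** — a tethered molecule stays at
  its site. This confinement is a deliberate forward-model choice: without
  it, an exponentially-dwelling bound population with any appreciable
  mobility would drift far outside the footprint, contradicting the
  bound-state construct every downstream analysis measures.
- **Kinetics.** Free→bound with probability 1−exp(−k_on·Δt), only inside
  the footprint, optionally scaled by a Gaussian affinity
  exp(−r²/2w²) from the site centre (default w = radius/2, the
  `gaussian_center` profile emulating a central binding sub-domain);
  bound→free with probability 1−exp(−k_off·Δt). Defaults: k_on = 100 s⁻¹,
  k_off = 1.25 s⁻¹ (ln 2 / 556 ms — a median dwell on the ~half-second
  scale measured for VAPB at ERMCSs), D_free = 5·10⁵ nm²/s,
  D_bound = 2.5·10⁴ nm²/s.
- **Photophysics.** Poisson activation (default 1 molecule/frame),
  exponential bleaching (default 2 s⁻¹; mean track ≈ 0.5 s ≈ 47 frames).
  No blinking, no motion blur (5 ms exposure against a 10.5 ms frame makes
  blur second-order), no camera noise or PSF rendering.
- **Localization.** One observation per live molecule per frame: true
  position plus per-axis Gaussian error with σ drawn per localization from
  U[20, 30] nm, matching the 20–30 nm CRLB band a PALM localizer reports;
  the drawn σ rides in the table. Ground-truth identity/state go to a
  separate sidecar file so observed tables look like real data.

What passing tests on this generator do **not** show about real data: the
ER here is a straight tubule, not a network (no junction ambiguity); the
affinity profile inside a site is a modelling construct, not biology; and
there is no drift, no blinking-induced re-detection, and no segmentation
error in the reference channels.

**Molecule density matters.** Diagnostics during development showed that at
high activation (tens of concurrent molecules on one tubule) the
frame-to-frame assignment, like any tracker, preferentially links nearest
neighbours; identity swaps then inflate apparent dwell times and deflate
step variances. Experiments whose conclusions rest on per-molecule
statistics (dwell kinetics, landscape wells) therefore use sparse
activation (~1–4 concurrent molecules) and longer recordings, which is also
how sptPALM is actually run.

## Trajectory assembly (trackasm)

Precision filter (default band [20, 30] nm, lower bound settable to 0),
then per-frame minimum-cost bipartite matching (Jonker–Volgenant via
`scipy.optimize.linear_sum_assignment`) gated at `max_disp_nm` (default
400 nm), greedy fallback above 500 localizations/frame; gap closing
reconnects track ends across ≤ `max_gap` missing frames with the gate
inflated by √(gap+1) (Brownian search-radius scaling).

The manual curation a microscopist would perform against the ER reference
channel is replaced by a deterministic rule: for each link, the geodesic distance through the
ER foreground (8-connected grid, pixel-centre metric, `skimage` MCP with a
Dijkstra oracle in the tests) is compared with the Euclidean distance; a
link is cut when geodesic > 2.0 × Euclidean + 2√2·px (the additive term
absorbs pixel discretization on short steps) or when no path exists.
Because 25 nm localization error routinely pushes genuine endpoints off a
100 nm-wide mask, endpoints are first snapped to the nearest ER pixel
within 75 nm (≈3σ); endpoints farther off the structure cut the link.
Curation is idempotent.

## Density maps and sites (sitemap)

Localizations are binned into 30 nm square pixels and normalized to the
total count — a spatial probability mass function insensitive to
activation efficiency or expression level. Hotspots: background b = median
of strictly positive bin masses; bins ≥ θ·b (θ = 5) form 8-connected
components, components ≥ 4 bins become sites, components with centroids
≤ 2 bins apart merge.

**Site size.** Second central moments of the site's mass; axis lengths are
4·√eigenvalue (full width at ±2σ), and the scalar size is
`equivalent_diameter = √(major·minor)`. Two deliberate choices:

1. Moments are taken over an *aperture* (footprint dilated by 3 bins)
   after subtracting the map background, not over the raw
   threshold-surviving bins. The threshold decides where a site is; the
   background-corrected mass decides how big it is. The literal
   footprint-only rule truncates the mass tails with a bias that grows
   with site size.
2. For a `gaussian_center` site the stationary bound-molecule distribution
   is genuinely narrower than the geometric disc (truncated-Gaussian
   binding, partial diffusional fill), so size recovery is validated
   against the moment diameter of the *true bound positions*, not against
   2·radius.

The same moment metric sizes the EM-projection simulation (below), which
is what makes light- and electron-microscopy sizes comparable.

Mito association: a site is mito-associated iff its footprint dilated by
250 nm (the confocal-resolution scale, configurable) overlaps the
mitochondria mask. The mitochondrial enrichment coefficient — our
reconstruction, printed in output metadata — is (fraction of localizations
in the mito-proximal ER region) / (fraction of ER area that is
mito-proximal). Site stability is probed by re-detection on 15 s
sub-windows. Aligned averaging rotates each site's localizations so the
local tubule axis (principal direction of ER-skeleton pixels within
500 nm) maps to +x, then sums and renormalizes.

## Diffusion landscapes (difflandscape)

Within a site, k-means centres of the site's localizations seed a Voronoi
tessellation (k chosen for ≥ 50 expected steps/cell, capped at 50; fixed
seed; nearest-seed ties break to the lowest cell index). Steps are
assigned by their starting position. Per cell, the overdamped-Langevin
likelihood per axis is

    Δx ~ Normal(drift·Δt, 2·D·Δt + 2·σ²),

with σ the per-step mean of the two endpoint precisions and drift profiled
out as the sample mean displacement rate (reported separately as a
displacement-rate field, not a force — converting to force would need the
friction coefficient, which is not available). The posterior over D (flat
prior on D ≥ 0; optional 1/(D+D₀) scale prior) is evaluated on a 400-point
log grid spanning [10², 10⁸] nm²/s with D = 0 prepended, giving the mode
and the central 95% interval; with the flat prior the mode equals the
closed-form noise-corrected MLE max(0, Σ(dx²+dy²)/(4nΔt) − σ²/Δt) to
within one grid step (~3.5%), which the tests assert against an
independent implementation. The σ-ignorant estimator is biased high by
σ²/Δt ≈ 0.059 µm²/s at σ = 25 nm — the reason noise separation is not
optional at 95 Hz. Gap-closed steps are excluded by default (their Δt
differs).

Line profiles report the mean noise-corrected per-step D over steps
starting within 30 nm of each 10 nm sample point (< 5 steps → missing).
Tubule 1D coefficients project displacements onto the local skeleton
direction, estimator Var(proj)/(2Δt) − σ²/Δt per contiguous same-class
segment. Landscape normalization divides each cell's D by the estimate
from an annulus of surrounding ER steps (site boundary to +500 nm).

## Latent states and dwell kinetics (statedyn)

**SLDS.** Trajectories ≥ 500 steps (≈5.5 s) are segmented with a switching
linear dynamical system: latent 2D position z_t = A_s·z_{t−1} + b_s + w_t,
w_t ~ N(0, Q_s); observation y_t = z_t + v_t, v_t ~ N(0, σ_t²·I) with
observation noise *fixed* from the per-localization precision — thermal
motion and measurement error are identified separately. The state sequence
follows a sticky weak-limit-truncated HDP Markov prior (truncation L = 8,
ample for the ~3 mechanistic states seen in practice; stickiness κ = 50
with α = 1, i.e. expected self-transition ≈ 0.98 at 10.5 ms frames; γ = 1).
Inference is blocked Gibbs — Kalman forward-filter backward-sampling of z,
HMM FFBS of s, matrix-normal inverse-Wishart conjugate updates of
(A, b, Q) per state (prior centred at A = I, b = 0, E[Q] set from the
trajectory's noise-corrected displacement variance), and CRT-based table
counts with the sticky override correction for the HDP weights — 500
sweeps, 250 burn-in, labels by per-step majority vote over retained
sweeps, parameters by posterior mean over sweeps where the state is
occupied. The 2×2 Kalman/HMM inner loops are numba-compiled with all
randomness pre-drawn from the session's generator, so fixed seeds give
identical output. Langevin interpretation: relaxation tensor
B = (I−A)/Δt (1/s), diffusion tensor D = Q/(2Δt); both eigen-decomposed
for 1D summaries.

**Bound-step classification.** A step is bound iff it starts inside a
detected footprint *and* its motion is slow: for segmented tracks, the
state's largest diffusion eigenvalue < φ·D_ref (φ = 0.5, D_ref = pooled
noise-corrected D of steps outside all sites); short tracks use a centred
15-step rolling window. The window statistic is a *median* of apparent
per-step D rescaled by ln 2 (squared Gaussian steps are exponential, whose
median is ln 2 of the mean) — consistent for the same quantity but immune
to the single large steps that poison a mean over 15 consecutive windows.
Because a 15-step window cannot resolve shorter state flickers, label runs
below that resolution are treated as noise: bound runs < window/3 are
dropped, free gaps < 2·window/3 between same-site bound runs are bridged.

**Dwell statistics.** A binding interaction is a maximal run of
consecutive bound steps at one site; duration = run length × Δt; runs
reaching the end of a track are censored (bleached while bound) and enter
the median at their observed length but not the leaving-frequency
numerator. Because the classifier cannot report dwells shorter than its
minimum run, observed durations are left-truncated; the leaving frequency
uses the truncation-corrected exponential estimator
n_uncensored / (T_total − n·d₀) with d₀ the classifier's detection floor
(window/3 × Δt). The trapped fraction is, per site, the fraction of
visiting molecules whose only interaction there is censored — bound for
the entire remaining fluorophore lifetime — reported as mean ± s.e.m.
across sites.

## 3D morphometrics (surfmorph)

**Contacts.** One Euclidean distance transform from the OMM label,
converted to a surface distance d = max(0, EDT − voxel); ER voxels with
d ≤ 24 nm (three 8 nm voxels) are relabeled contact. The surface metric
makes `distance = 0` label exactly the face-adjacent voxels and matches
the morphological-dilation description of the threshold.

**Meshing.** The label's binary indicator (contact counts as ER) has its
enclosed lumen filled (membrane labels are one-voxel shells that would
otherwise fade under smoothing), is Gaussian-smoothed (default σ = 1.5
voxels; σ = 0 keeps the raw staircase), iso-surfaced at half the smoothed
peak by marching cubes, scaled to the voxel-centre nm frame, and oriented
outward. Contact flags transfer to vertices within one voxel of a contact
voxel centre.

**Mean curvature.** Per vertex, the 20-edge-ring topological
neighbourhood is expressed in the local frame (outward vertex normal = z);
neighbours whose normals deviate > 60° are dropped so the patch never
wraps past the horizon on thin or strongly curved structures (a 20-ring
patch at fine mesh pitch wraps a 50 nm tube several times over). A quartic
Monge jet is least-squares fitted (quadratic below 20 points; < 6 usable
neighbours → NaN), and H comes from the second-order coefficients with the
first-order metric correction, sign positive-convex / negative-concave
relative to the outward normal. The fit is refined once with the patch
shrunk to 0.6 of the estimated principal curvature radius, cancelling the
higher-order bias a wide patch induces (skipped when < 16 points would
remain). On analytic fixtures this lands within ~2% of 1/R (sphere) and
1/2R (cylinder), with < 1% change under 2× mesh refinement.

**Projection.** Localizations are sampled uniformly by area over
contact-flagged triangles, projected to the imaging plane, jittered with
per-axis Gaussian σ (default 25 nm), binned at 30 nm and measured with
`sitemap.measure_site` — the identical moment metric as light-microscopy
sites (no background subtraction: a projection has no backdrop). The
uniform-by-area sampling rule is a documented choice; the tether-density
weighting of a real experiment is unknown.

## Pipeline and reproducibility

`run_pipeline` wires simulate → filter → link → curate → steps → map →
detect → associate → landscape → classify → dwell, writes every artifact
plus a resolved-config snapshot, aggregates a JSON report (no timestamps,
sorted keys), and flags per-site failures without aborting the run.
Tables are written with `%.17g` floats and read with round-trip parsing,
so CSV round trips are value-exact; PLY meshes round-trip coordinates to
float32 (≤ 10⁻³ nm here) with curvature in the `quality` channel.

`scripts/acceptance.py --seed S --out results.json` re-runs the validation
experiments in `ermcs_spt.benchmarks` from scratch. Problem sizes are
chosen so the whole script completes in a few minutes on one core:
9 × 1200 steps for diffusion recovery, 100 random step sets for the
estimator equivalence, a 340k-frame sparse recording (~1 concurrent
molecule, ~1000 interactions) for dwell kinetics — bleaching kept
negligible next to k_off, since the observed-duration distribution follows
rate k_off + bleach — 10 × 5000-step replicates for the SLDS benchmark,
three planted discs over 60 s for detection/sizing, and ~0.4-megavoxel
phantoms for the 3D stages.

## Known limitations

- The tracker's assignment degrades gracefully but measurably with
  molecule density; no statistical track-linking (e.g. multiple-hypothesis
  tracking) is implemented.
- The rolling-window classifier cannot see dwells below ~window/3 frames;
  the truncation-corrected leaving frequency accounts for this on an
  exponential assumption, the median does not.
- Voronoi cell polygons are geometric output only; inference weights every
  step equally regardless of cell area.
- Curvature near open mesh boundaries is extrapolated from one-sided
  neighbourhoods and should be read with the `interior` flag.
- Real EM volumes must arrive pre-labeled; segmentation is out of scope.
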