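"""Probability maps, hotspot detection, site morphometry, alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ermcs_spt import sitemap, trackasm
from ermcs_spt.sitemap import ContactSite, ProbabilityMap
from ermcs_spt.simkit import SimulationConfig, image_and_localize, make_er_geometry, simulate_molecules


def make_locs(x, y, t=None):
    x = np.asarray(x, dtype=float)
    t = np.zeros(len(x)) if t is None else np.asarray(t, dtype=float)
    return pd.DataFrame({"frame": np.arange(len(x)), "t_s": t, "x_nm": x,
                         "y_nm": np.asarray(y, dtype=float),
                         "sigma_nm": np.full(len(x), 25.0)})


class TestProbabilityMap:
    def test_single_localization_holds_all_mass(self):
        pmap = sitemap.probability_map(make_locs([100.0], [50.0]))
        assert pmap.values.max() == 1.0
        assert pmap.n_localizations == 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=500), st.integers(0, 2**31 - 1))
    def test_normalization_property(self, n, seed):
        rng = np.random.default_rng(seed)
        pmap = sitemap.probability_map(make_locs(rng.uniform(0, 3000, n),
                                                 rng.uniform(0, 1000, n)))
        assert pmap.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert (pmap.values >= 0).all()

    def test_uniform_points_max_bin_is_multinomial(self):
        rng = np.random.default_rng(1)
        n = 100_000
        pmap = sitemap.probability_map(
            make_locs(rng.uniform(0, 300, n), rng.uniform(0, 300, n)),
            roi_nm=(0, 300, 0, 300))
        assert pmap.values.shape == (10, 10)
        p = 0.01
        sd = np.sqrt(p * (1 - p) / n)
        assert pmap.values.max() < p + 5 * sd

    def test_non_finite_coordinates_raise(self):
        locs = make_locs([0.0, np.nan], [0.0, 1.0])
        with pytest.raises(ValueError, match="non-finite"):
            sitemap.probability_map(locs)

    def test_empty_input_gives_zero_map(self):
        pmap = sitemap.probability_map(make_locs([], []))
        assert pmap.n_localizations == 0
        assert pmap.values.sum() == 0


class TestHotspots:
    def test_uniform_map_has_no_hotspots(self):
        rng = np.random.default_rng(2)
        pmap = sitemap.probability_map(
            make_locs(rng.uniform(0, 3000, 50_000), rng.uniform(0, 3000, 50_000)))
        assert sitemap.detect_hotspots(pmap) == []

    def test_all_zero_map_gives_empty_list(self):
        pmap = ProbabilityMap(values=np.zeros((5, 5)))
        assert sitemap.detect_hotspots(pmap) == []

    def test_single_simulated_site_detected_once(self, sim60s):
        g, locs, _ = sim60s
        pmap = sitemap.probability_map(locs)
        sites = sitemap.detect_hotspots(pmap)
        assert len(sites) == 1
        cx, cy, r = g.contact_list_nm[0]
        assert sites[0].contains(np.array([cx]), np.array([cy]))[0]

    def test_two_distant_sites_detected_with_accurate_centres(self):
        contacts = [(2000.0, 550.0, 150.0), (4000.0, 550.0, 150.0)]
        g = make_er_geometry(tubule_length_nm=5000.0, contacts_nm=contacts)
        cfg = SimulationConfig(n_frames=5700, seed=21)
        locs, _ = image_and_localize(simulate_molecules(g, cfg), cfg)
        pmap = sitemap.probability_map(trackasm.filter_localizations(locs))
        sites = sitemap.detect_hotspots(pmap)
        assert len(sites) == 2
        centres = sorted(s.centre_nm for s in sites)
        for (mx, my), (tx, ty, _) in zip(centres, contacts):
            assert np.hypot(mx - tx, my - ty) < 60.0

    def test_threshold_monotonicity(self, sim60s):
        _, locs, _ = sim60s
        pmap = sitemap.probability_map(locs)
        lo = sitemap.detect_hotspots(pmap, theta=4.0)
        hi = sitemap.detect_hotspots(pmap, theta=8.0)
        union_lo = np.any([s.footprint for s in lo], axis=0)
        for s in hi:
            assert (s.footprint & ~union_lo).sum() == 0


@pytest.fixture(scope="module")
def sim60s():
    g = make_er_geometry()
    cfg = SimulationConfig(n_frames=5700, seed=17)
    tracks = simulate_molecules(g, cfg)
    locs, sidecar = image_and_localize(tracks, cfg)
    return g, trackasm.filter_localizations(locs), sidecar


class TestMeasure:
    def _site_from_mask(self, mask, values, bin_nm=30.0):
        pmap = ProbabilityMap(values=values / values.sum(), bin_size_nm=bin_nm,
                              n_localizations=int(values.sum()))
        site = ContactSite(site_id=0, footprint=mask, bin_size_nm=bin_nm)
        return sitemap.measure_site(site, pmap, aperture_dilation_bins=0), pmap

    def test_elongated_mask_axis_ratio(self):
        # 9 x 3 uniform block: axis ratio must match the block's own moments
        values = np.zeros((21, 21))
        values[9:12, 6:15] = 1.0
        mask = values > 0
        site, _ = self._site_from_mask(mask, values)
        xs = np.arange(6, 15)  # bin indices along the long axis
        var_long = ((xs - xs.mean()) ** 2).mean() * 30.0**2
        ys = np.arange(9, 12)
        var_short = ((ys - ys.mean()) ** 2).mean() * 30.0**2
        assert site.major_axis_nm == pytest.approx(4 * np.sqrt(var_long), rel=1e-6)
        assert site.minor_axis_nm == pytest.approx(4 * np.sqrt(var_short), rel=1e-6)

    def test_symmetric_disc_axis_ratio_near_one(self, sim60s):
        _, locs, _ = sim60s
        pmap = sitemap.probability_map(locs)
        site = sitemap.detect_hotspots(pmap)[0]
        assert site.major_axis_nm / site.minor_axis_nm < 1.10

    def test_rotation_leaves_axes_invariant(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(scale=(120.0, 40.0), size=(20000, 2))
        theta = np.deg2rad(37.0)
        rot = pts @ np.array([[np.cos(theta), -np.sin(theta)],
                              [np.sin(theta), np.cos(theta)]])
        axes = []
        for xy in (pts, rot):
            pmap = sitemap.probability_map(make_locs(xy[:, 0] + 2000, xy[:, 1] + 2000))
            site = ContactSite(site_id=0, footprint=pmap.values > 0,
                               bin_size_nm=pmap.bin_size_nm, origin_nm=pmap.origin_nm)
            site = sitemap.measure_site(site, pmap, aperture_dilation_bins=0)
            axes.append((site.major_axis_nm, site.minor_axis_nm))
        assert axes[0][0] == pytest.approx(axes[1][0], rel=0.01)
        assert axes[0][1] == pytest.approx(axes[1][1], rel=0.01)

    def test_single_bin_footprint_is_degenerate(self):
        values = np.zeros((5, 5))
        values[2, 2] = 1.0
        site, _ = self._site_from_mask(values > 0, values)
        assert site.degenerate
        assert site.major_axis_nm == 30.0


class TestMitoAssociation:
    def test_site_on_mito_is_associated_and_distant_site_is_not(self, sim60s):
        g, locs, _ = sim60s
        pmap = sitemap.probability_map(locs)
        sites = sitemap.detect_hotspots(pmap)
        sites, _ = sitemap.associate_mitochondria(sites, g.mito_mask, g.pixel_size_nm, pmap)
        assert sites[0].mito_associated  # planted next to the mitochondrion

        far = ContactSite(site_id=9, footprint=np.zeros_like(sites[0].footprint),
                          bin_size_nm=pmap.bin_size_nm, origin_nm=pmap.origin_nm)
        far.footprint[0, 0] = True  # top-left corner, ~1 um from the mito
        out, _ = sitemap.associate_mitochondria([far], g.mito_mask, g.pixel_size_nm, pmap)
        assert not out[0].mito_associated

    def test_uniform_er_coverage_gives_unit_enrichment(self):
        g = make_er_geometry(contact_radius_nm=0.0)
        rng = np.random.default_rng(5)
        centres = g.pixel_centres(g.er_mask)
        pick = centres[rng.integers(0, len(centres), 200_000)]
        pick = pick + (rng.random((200_000, 2)) - 0.5) * g.pixel_size_nm
        locs = make_locs(pick[:, 0], pick[:, 1])
        pmap = sitemap.probability_map(locs)
        _, enrichment = sitemap.associate_mitochondria(
            [], g.mito_mask, g.pixel_size_nm, pmap, locs=locs, er_mask=g.er_mask)
        assert enrichment == pytest.approx(1.0, rel=0.05)

    def test_missing_mask_skips_with_none(self, sim60s):
        g, locs, _ = sim60s
        pmap = sitemap.probability_map(locs)
        sites, enrichment = sitemap.associate_mitochondria([], None, g.pixel_size_nm, pmap)
        assert enrichment is None


class TestAlignAndAverage:
    def test_single_site_output_equals_its_rotated_patch(self, sim60s):
        g, locs, _ = sim60s
        pmap = sitemap.probability_map(locs)
        site = sitemap.detect_hotspots(pmap)[0]
        sitemap.estimate_tubule_axis(site, g.er_mask, g.pixel_size_nm)
        avg, _ = sitemap.align_and_average([site], locs)
        patch = sitemap.rotate_and_bin(locs, site.centre_nm, site.tubule_axis, 600.0, 30.0)
        assert np.allclose(avg.values, patch / patch.sum())

    def test_alignment_undoes_coordinate_rotation(self, sim60s):
        g, locs, _ = sim60s
        pmap = sitemap.probability_map(locs)
        site = sitemap.detect_hotspots(pmap)[0]
        sitemap.estimate_tubule_axis(site, g.er_mask, g.pixel_size_nm)
        base, _ = sitemap.align_and_average([site], locs)

        theta = np.pi / 2
        c, s = np.cos(theta), np.sin(theta)
        cx, cy = site.centre_nm
        x = locs["x_nm"].to_numpy() - cx
        y = locs["y_nm"].to_numpy() - cy
        rot = locs.copy()
        rot["x_nm"] = c * x - s * y + cx
        rot["y_nm"] = s * x + c * y + cy
        site_rot = ContactSite(site_id=0, footprint=site.footprint,
                               bin_size_nm=site.bin_size_nm, origin_nm=site.origin_nm,
                               centre_nm=site.centre_nm,
                               tubule_axis=np.array([c * site.tubule_axis[0] - s * site.tubule_axis[1],
                                                     s * site.tubule_axis[0] + c * site.tubule_axis[1]]))
        rot_avg, _ = sitemap.align_and_average([site_rot], rot)
        assert np.abs(rot_avg.values - base.values).max() < 1e-6

    def test_average_matches_per_site_loop_oracle(self):
        contacts = [(2000.0, 550.0, 150.0), (4000.0, 550.0, 150.0)]
        g = make_er_geometry(tubule_length_nm=5000.0, contacts_nm=contacts)
        cfg = SimulationConfig(n_frames=4000, seed=23)
        locs, _ = image_and_localize(simulate_molecules(g, cfg), cfg)
        pmap = sitemap.probability_map(locs)
        sites = sitemap.detect_hotspots(pmap)
        for s in sites:
            sitemap.estimate_tubule_axis(s, g.er_mask, g.pixel_size_nm)
        avg, profile = sitemap.align_and_average(sites, locs)
        # oracle: naive per-site loop
        total = None
        for s in sites:
            patch = sitemap.rotate_and_bin(locs, s.centre_nm, s.tubule_axis, 600.0, 30.0)
            total = patch if total is None else total + patch
        assert np.allclose(avg.values, total / total.sum())
        # profile peaks at the aligned centre
        peak_x = profile.loc[profile["mass"].idxmax(), "s_nm"]
        assert abs(peak_x) <= 60.0

    def test_no_resolvable_axis_raises(self, sim60s):
        _, locs, _ = sim60s
        site = ContactSite(site_id=0, footprint=np.ones((3, 3), dtype=bool))
        with pytest.raises(ValueError, match="axis"):
            sitemap.align_and_average([site], locs)
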