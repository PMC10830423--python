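"""Latent-state segmentation, bound-step classification, dwell statistics."""

import numpy as np
import pandas as pd
import pytest

from ermcs_spt import sitemap, trackasm
from ermcs_spt.simkit import simulate_switching_diffusion
from ermcs_spt.statedyn import (
    SLDSConfig,
    classify_contact_steps,
    dwell_times,
    match_labels,
    segment_trajectory_slds,
    trapped_fraction,
)

DT = 1.0 / 95.0
FAST_CFG = SLDSConfig(n_sweeps=300, burn_in=150, seed=0)


class TestSLDS:
    def test_single_state_recovery(self):
        traj = simulate_switching_diffusion(2000, D_states=(5e5,),
                                            mean_dwell_steps=1e12, seed=1)
        seg = segment_trajectory_slds(traj, FAST_CFG)
        _, counts = np.unique(seg.labels, return_counts=True)
        assert counts.max() / counts.sum() >= 0.95
        D = seg.states[seg.dominant_state()].diffusion_eigenvalues_nm2_s
        assert np.all(np.abs(D / 5e5 - 1) < 0.15)

    def test_two_state_label_accuracy(self):
        traj = simulate_switching_diffusion(5000, D_states=(5e5, 1e5),
                                            mean_dwell_steps=100, seed=2)
        seg = segment_trajectory_slds(traj, FAST_CFG)
        truth = traj["state"].to_numpy()[:-1]
        _, acc = match_labels(seg.labels, truth)
        assert acc >= 0.85

    def test_stationary_emitter_noise_separation(self):
        # D = 0 with 25 nm noise: recovered diffusion must stay far below the
        # apparent sigma^2/dt level a noise-blind estimator would report
        traj = simulate_switching_diffusion(2000, D_states=(0.0,),
                                            mean_dwell_steps=1e12, seed=3)
        seg = segment_trajectory_slds(traj, FAST_CFG)
        D = seg.states[seg.dominant_state()].diffusion_eigenvalues_nm2_s
        apparent = 25.0**2 / DT
        assert D.max() <= 0.05 * apparent

    def test_fixed_seed_is_deterministic(self):
        traj = simulate_switching_diffusion(800, D_states=(5e5, 1e5),
                                            mean_dwell_steps=100, seed=4)
        cfg = SLDSConfig(n_sweeps=120, burn_in=60, min_len=500, seed=11)
        a = segment_trajectory_slds(traj, cfg)
        b = segment_trajectory_slds(traj, cfg)
        assert np.array_equal(a.labels, b.labels)

    def test_seed_agreement_on_two_state_benchmark(self):
        traj = simulate_switching_diffusion(3000, D_states=(5e5, 1e5),
                                            mean_dwell_steps=100, seed=5)
        truth = traj["state"].to_numpy()[:-1]
        labels = []
        for seed in range(3):
            cfg = SLDSConfig(n_sweeps=200, burn_in=100, seed=seed)
            seg = segment_trajectory_slds(traj, cfg)
            remapped, _ = match_labels(seg.labels, truth)
            labels.append(remapped)
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.mean(labels[i] == labels[j]) >= 0.90

    def test_sigma_invariance_of_recovered_D(self):
        for i, sig in enumerate((20.0, 25.0, 30.0)):
            traj = simulate_switching_diffusion(2000, D_states=(2e5,),
                                                mean_dwell_steps=1e12,
                                                sigma_loc_nm=sig, seed=6 + i)
            seg = segment_trajectory_slds(traj, FAST_CFG)
            D = seg.states[seg.dominant_state()].diffusion_eigenvalues_nm2_s
            assert np.all(np.abs(D / 2e5 - 1) < 0.15)

    def test_short_trajectory_rejected(self):
        traj = simulate_switching_diffusion(100, seed=7)
        with pytest.raises(ValueError, match="min_len"):
            segment_trajectory_slds(traj, SLDSConfig())


def steps_from_positions(x, y, sigma=25.0, track_id=0):
    n = len(x) - 1
    return pd.DataFrame({
        "track_id": np.full(n, track_id),
        "t_start": np.arange(n) * DT,
        "x_start": np.asarray(x[:-1], dtype=float),
        "y_start": np.asarray(y[:-1], dtype=float),
        "dx_nm": np.diff(np.asarray(x, dtype=float)),
        "dy_nm": np.diff(np.asarray(y, dtype=float)),
        "dt_s": np.full(n, DT),
        "sigma_start": np.full(n, sigma),
        "sigma_end": np.full(n, sigma),
        "gap_closed": np.zeros(n, dtype=bool),
    })


def central_site(half_bins=5, bin_nm=30.0, extent_bins=40):
    fp = np.zeros((extent_bins, extent_bins), dtype=bool)
    c = extent_bins // 2
    fp[c - half_bins:c + half_bins, c - half_bins:c + half_bins] = True
    return sitemap.ContactSite(site_id=0, footprint=fp, bin_size_nm=bin_nm,
                               origin_nm=(-extent_bins / 2 * bin_nm,
                                          -extent_bins / 2 * bin_nm),
                               centre_nm=(0.0, 0.0))


def two_phase_track(rng, n_free=120, n_bound=60, D_free=5e5, D_bound=2.5e4,
                    sigma=25.0, end_free=True, track_id=0):
    """Free walk into the origin, a bound episode at the centre, then
    (optionally) free again.  Returns (steps, truth_bound)."""
    stds = []
    stds += [np.sqrt(2 * D_free * DT)] * n_free
    stds += [np.sqrt(2 * D_bound * DT)] * n_bound
    if end_free:
        stds += [np.sqrt(2 * D_free * DT)] * n_free
    steps = rng.normal(size=(len(stds), 2)) * np.asarray(stds)[:, None]
    pos = np.cumsum(steps, axis=0)
    # recentre so the bound stretch sits at the origin (inside the site)
    mid = slice(n_free, n_free + n_bound)
    pos = pos - pos[mid].mean(axis=0)
    # keep the free stretches away from the site: push entry/exit outward
    pos[:n_free] += np.array([-1200.0, 0.0]) * np.linspace(1, 0, n_free)[:, None]
    if end_free:
        pos[n_free + n_bound:] += np.array([1200.0, 0.0]) * np.linspace(0, 1, n_free)[:, None]
    obs = pos + rng.normal(size=pos.shape) * sigma
    truth = np.zeros(len(pos) - 1, dtype=bool)
    truth[mid] = True
    return steps_from_positions(obs[:, 0], obs[:, 1], sigma, track_id), truth[:len(pos) - 1]


class TestClassification:
    def test_track_never_entering_site_is_all_free(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(0, 100, 300)) + 5000.0
        y = np.cumsum(rng.normal(0, 100, 300)) + 5000.0
        steps = steps_from_positions(x, y)
        lab = classify_contact_steps(steps, [central_site()], reference_D_nm2_s=5e5)
        assert not lab["bound"].any()

    def test_phi_zero_binds_nothing(self):
        rng = np.random.default_rng(1)
        steps, _ = two_phase_track(rng)
        lab = classify_contact_steps(steps, [central_site()], phi=0.0,
                                     reference_D_nm2_s=5e5)
        assert not lab["bound"].any()

    def test_bound_episode_boundaries_recovered(self):
        # 60-step bound episode inside the footprint, 20x D contrast:
        # recovered boundaries within a few steps of truth
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            steps, truth = two_phase_track(rng)
            lab = classify_contact_steps(steps, [central_site()],
                                         reference_D_nm2_s=5e5)
            b = lab["bound"].to_numpy()
            if not b.any():
                hits.append(np.inf)
                continue
            t_idx = np.flatnonzero(truth)
            b_idx = np.flatnonzero(b)
            hits.append(max(abs(b_idx[0] - t_idx[0]), abs(b_idx[-1] - t_idx[-1])))
        assert np.median(hits) <= 8  # within ~half a window

    def test_missing_free_reference_raises(self):
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.normal(0, 10, 50))
        y = np.cumsum(rng.normal(0, 10, 50))
        steps = steps_from_positions(x, y)
        big = sitemap.ContactSite(site_id=0, footprint=np.ones((200, 200), dtype=bool),
                                  bin_size_nm=30.0, origin_nm=(-3000.0, -3000.0))
        with pytest.raises(ValueError, match="reference"):
            classify_contact_steps(steps, [big])


class TestDwell:
    def _labels(self, steps, bound, site_id=0):
        sid = np.where(bound, site_id, -1)
        return pd.DataFrame({"bound": bound, "site_id": sid}, index=steps.index)

    def test_single_run_arithmetic(self):
        dt = 0.010
        steps = steps_from_positions(np.zeros(16), np.zeros(16))
        steps["dt_s"] = dt
        bound = np.zeros(15, dtype=bool)
        bound[2:12] = True  # 10 bound steps
        recs, summ = dwell_times(steps, self._labels(steps, bound))
        assert len(recs) == 1
        assert recs["duration_s"].iloc[0] == pytest.approx(0.100)
        assert not recs["censored"].iloc[0]

    def test_track_ending_bound_is_censored(self):
        steps = steps_from_positions(np.zeros(11), np.zeros(11))
        bound = np.zeros(10, dtype=bool)
        bound[6:] = True
        recs, summ = dwell_times(steps, self._labels(steps, bound))
        assert bool(recs["censored"].iloc[0])
        assert summ.leaving_frequency_per_s != summ.leaving_frequency_per_s or \
            summ.n_interactions - summ.n_censored == 0

    def test_label_record_consistency(self):
        rng = np.random.default_rng(3)
        steps = steps_from_positions(rng.normal(0, 10, 501), rng.normal(0, 10, 501))
        bound = rng.random(500) < 0.3
        recs, summ = dwell_times(steps, self._labels(steps, bound))
        assert summ.total_bound_time_s == pytest.approx(bound.sum() * DT)
        assert sum(r / DT for r in recs["duration_s"]) == pytest.approx(bound.sum())

    def test_exponential_dwell_median_recovered_from_labels(self):
        # geometric run lengths at k_off = 1.25/s: the extractor's median
        # matches ln2/k_off (pure label bookkeeping, no classification)
        rng = np.random.default_rng(4)
        k_off = 1.25
        p = -np.expm1(-k_off * DT)
        frames, bounds, tids = [], [], []
        for tid in range(400):
            runs = []
            n_bound = rng.geometric(p)
            runs += [False] * 10 + [True] * n_bound + [False] * 10
            bounds.append(np.array(runs))
            tids.append(np.full(len(runs), tid))
        bound = np.concatenate(bounds)
        tid = np.concatenate(tids)
        n = len(bound)
        steps = steps_from_positions(np.zeros(n + 1), np.zeros(n + 1))
        steps["track_id"] = tid
        recs, summ = dwell_times(steps, self._labels(steps, bound))
        assert summ.n_interactions == 400
        assert abs(summ.median_s / (np.log(2) / k_off) - 1) < 0.15
        assert abs(summ.leaving_frequency_per_s / k_off - 1) < 0.15


class TestTrappedFraction:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "track_id", "t_enter",
                                           "t_exit", "duration_s", "censored"])

    def test_all_uncensored_gives_zero(self):
        recs = self._records([(0, t, 0.0, 1.0, 1.0, False) for t in range(10)])
        _, mean, _ = trapped_fraction(recs)
        assert mean == 0.0

    def test_all_censored_single_visits_give_one(self):
        recs = self._records([(0, t, 0.0, 1.0, 1.0, True) for t in range(10)])
        _, mean, _ = trapped_fraction(recs)
        assert mean == 1.0

    def test_half_mixture_is_binomial_half(self):
        rng = np.random.default_rng(5)
        rows = []
        n = 400
        for t in range(n):
            trapped = rng.random() < 0.5
            rows.append((0, t, 0.0, 1.0, 1.0, trapped))
        _, mean, _ = trapped_fraction(self._records(rows))
        assert abs(mean - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_repeat_visitor_is_not_trapped(self):
        recs = self._records([
            (0, 1, 0.0, 1.0, 1.0, False),
            (0, 1, 2.0, 3.0, 1.0, True),  # second interaction censored
            (0, 2, 0.0, 1.0, 1.0, True),
        ])
        table, mean, _ = trapped_fraction(recs)
        assert table["n_trapped"].iloc[0] == 1
        assert mean == pytest.approx(0.5)
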