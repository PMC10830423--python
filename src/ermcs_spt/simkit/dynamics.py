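"""Ground-truth Markov-switching 2D diffusion inside synthetic ER geometry.

The forward model: molecules appear by sparse photoactivation (Poisson per
frame), diffuse by Euler-Maruyama steps with a state-dependent coefficient
(free vs contact-bound), switch free->bound only inside the contact
footprint at rate ``k_on`` (optionally modulated by a Gaussian affinity
profile) and bound->free at rate ``k_off``, and disappear by exponential
photobleaching.  Positions are sampled instantaneously at frame times; no
motion blur is rendered.  Free motion reflects at the ER mask boundary;
bound motion is confined to the contact footprint (a tethered molecule
stays at its site).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GeometryMasks

FREE, BOUND = 0, 1


@dataclass
class SimulationConfig:
    """Parameters of the switching-diffusion / imaging forward model.

    Rates are per second; diffusion coefficients in nm^2/s.  The defaults
    are the study conditions the rest of the package is validated under:
    ~95 Hz frames, free diffusion of ~0.5 um^2/s, a 20x slower bound state,
    an unbinding rate matching a ~556 ms median dwell, and localization
    precision drawn uniformly from the 20-30 nm band.
    """

    pixel_size_nm: float = 10.0
    frame_interval_s: float = 1.0 / 95.0
    n_frames: int = 2000
    D_free: float = 5.0e5
    D_bound: float = 2.5e4
    k_on: float = 100.0
    k_off: float = 1.25
    affinity_profile: str = "gaussian_center"  # or "uniform"
    affinity_width_nm: float | None = None  # default: footprint radius / 2
    sigma_loc_nm: float = 25.0
    sigma_band_nm: tuple[float, float] | None = (20.0, 30.0)
    activation_rate: float = 1.0  # new molecules per frame
    bleach_rate: float = 2.0  # 1/s
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("D_free", "D_bound", "k_on", "k_off", "sigma_loc_nm",
                     "activation_rate", "bleach_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be a positive integer")
        if self.affinity_profile not in ("uniform", "gaussian_center"):
            raise ValueError(f"unknown affinity_profile {self.affinity_profile!r}")


@dataclass
class GroundTruthTracks:
    """Per-frame true molecule records: (molecule_id, frame, t_s, x_nm, y_nm, state).

    ``state`` is 0 (free) or 1 (contact-bound) and names the state in effect
    for the step *leaving* that frame.  Birth/death frames per molecule are
    derivable from the record; kept explicit for convenience.
    """

    table: pd.DataFrame
    birth_frame: np.ndarray = field(repr=False, default=None)
    death_frame: np.ndarray = field(repr=False, default=None)

    @property
    def n_molecules(self) -> int:
        return 0 if len(self.table) == 0 else int(self.table["molecule_id"].nunique())

    def bound_episodes(self) -> pd.DataFrame:
        """Maximal runs of bound frames per molecule: columns
        (molecule_id, n_frames, duration_s, completed)."""
        rows = []
        for mid, g in self.table.groupby("molecule_id", sort=True):
            s = g["state"].to_numpy()
            t = g["t_s"].to_numpy()
            dt = np.median(np.diff(t)) if len(t) > 1 else 0.0
            bound = s == BOUND
            if not bound.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate([[0], bound.view(np.int8), [0]])))
            for a, b in zip(edges[::2], edges[1::2]):
                rows.append({
                    "molecule_id": mid,
                    "n_frames": int(b - a),
                    "duration_s": float((b - a) * dt),
                    "completed": bool(b < len(s)),  # ended by unbinding, not bleach
                })
        return pd.DataFrame(rows, columns=["molecule_id", "n_frames", "duration_s", "completed"])


def _reflect_into(pos: np.ndarray, prev: np.ndarray, inside, step_std: np.ndarray,
                  rng: np.random.Generator, max_attempts: int = 100) -> np.ndarray:
    """Rejection-and-resample reflection: offenders redraw their Gaussian step
    from the previous position; after ``max_attempts`` failures the molecule
    stays put (clamp)."""
    bad = ~inside(pos)
    attempts = 0
    while bad.any() and attempts < max_attempts:
        n_bad = int(bad.sum())
        pos[bad] = prev[bad] + rng.normal(size=(n_bad, 2)) * step_std[bad, None]
        bad = ~inside(pos)
        attempts += 1
    pos[bad] = prev[bad]
    return pos


def simulate_molecules(geometry: GeometryMasks, cfg: SimulationConfig) -> GroundTruthTracks:
    """Simulate switching-diffusion ground-truth tracks inside the geometry.

    Frame-synchronous and vectorized across live molecules; all randomness
    flows from ``cfg.seed``, so identical configs give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.frame_interval_s
    px = geometry.pixel_size_nm
    er = geometry.er_mask
    fp = geometry.contact_footprint
    ny, nx = er.shape

    step_free = np.sqrt(2.0 * cfg.D_free * dt)
    extent = min(nx * px, ny * px)
    if step_free > extent / 4.0:
        raise ValueError(
            f"rms step {step_free:.0f} nm exceeds a quarter of the raster extent "
            f"({extent:.0f} nm); use a finer frame_interval_s or larger geometry"
        )

    def inside_mask(mask):
        def f(pos):
            ix = np.floor(pos[:, 0] / px).astype(np.int64)
            iy = np.floor(pos[:, 1] / px).astype(np.int64)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            out = np.zeros(len(pos), dtype=bool)
            out[ok] = mask[iy[ok], ix[ok]]
            return out
        return f

    inside_er = inside_mask(er)
    inside_fp = inside_mask(fp)

    er_centres = geometry.pixel_centres(er)
    if len(er_centres) == 0:
        raise ValueError("ER mask is empty")

    # Affinity profile at a position, in [0, 1]; with several planted discs
    # each has its own Gaussian sub-domain (default width = radius / 2).
    if cfg.affinity_profile == "gaussian_center" and fp.any():
        if geometry.contact_list_nm:
            sites = [(np.array([sx, sy]),
                      cfg.affinity_width_nm if cfg.affinity_width_nm is not None else r / 2.0)
                     for sx, sy, r in geometry.contact_list_nm if r > 0]
        else:
            fp_centre = geometry.pixel_centres(fp).mean(axis=0)
            fp_radius = np.sqrt(fp.sum() * px * px / np.pi)
            w = cfg.affinity_width_nm if cfg.affinity_width_nm is not None else fp_radius / 2.0
            sites = [(fp_centre, w)]

        def affinity(pos):
            out = np.zeros(len(pos))
            for centre, w in sites:
                r2 = ((pos - centre) ** 2).sum(axis=1)
                out = np.maximum(out, np.exp(-r2 / (2.0 * w * w)))
            return out
    else:
        def affinity(pos):
            return np.ones(len(pos))

    p_bind = -np.expm1(-cfg.k_on * dt)
    p_unbind = -np.expm1(-cfg.k_off * dt)
    p_survive = np.exp(-cfg.bleach_rate * dt)

    # Per-frame births, each with a pre-drawn geometric lifetime (frames).
    births_per_frame = rng.poisson(cfg.activation_rate, size=cfg.n_frames)

    pos_list, state_list, id_list, frame_list = [], [], [], []
    live_pos = np.empty((0, 2))
    live_state = np.empty(0, dtype=np.int8)
    live_id = np.empty(0, dtype=np.int64)
    live_death = np.empty(0, dtype=np.int64)
    next_id = 0
    birth_frames: list[int] = []
    death_frames: list[int] = []

    for f in range(cfg.n_frames):
        # Move survivors.
        alive = live_death > f
        live_pos, live_state, live_id, live_death = (
            live_pos[alive], live_state[alive], live_id[alive], live_death[alive])
        if len(live_pos):
            stds = np.where(live_state == BOUND,
                            np.sqrt(2.0 * cfg.D_bound * dt), step_free)
            prev = live_pos.copy()
            prop = prev + rng.normal(size=prev.shape) * stds[:, None]
            new_pos = prop.copy()
            is_free = live_state == FREE
            if is_free.any():
                new_pos[is_free] = _reflect_into(prop[is_free], prev[is_free],
                                                 inside_er, stds[is_free], rng)
            is_bound = ~is_free
            if is_bound.any():
                new_pos[is_bound] = _reflect_into(prop[is_bound], prev[is_bound],
                                                   inside_fp, stds[is_bound], rng)
            live_pos = new_pos

        # Births: uniform over the ER foreground.
        nb = births_per_frame[f]
        if nb:
            pix = rng.integers(0, len(er_centres), size=nb)
            jitter = (rng.random(size=(nb, 2)) - 0.5) * px
            bpos = er_centres[pix] + jitter
            # geometric lifetime in frames, min 1 (visible this frame)
            lifetimes = (rng.geometric(1.0 - p_survive, size=nb)
                         if p_survive < 1.0 else np.full(nb, cfg.n_frames + 1))
            live_pos = np.vstack([live_pos, bpos])
            live_state = np.concatenate([live_state, np.zeros(nb, dtype=np.int8)])
            ids = np.arange(next_id, next_id + nb)
            live_id = np.concatenate([live_id, ids])
            live_death = np.concatenate([live_death, f + lifetimes])
            birth_frames.extend([f] * nb)
            death_frames.extend((f + lifetimes).tolist())
            next_id += nb

        if len(live_pos) == 0:
            continue

        # State transitions, evaluated at the current position.
        u = rng.random(len(live_pos))
        in_fp = inside_fp(live_pos)
        binds = (live_state == FREE) & in_fp & (u < p_bind * affinity(live_pos))
        unbinds = (live_state == BOUND) & (u < p_unbind)
        live_state = live_state.copy()
        live_state[binds] = BOUND
        live_state[unbinds] = FREE

        pos_list.append(live_pos.copy())
        state_list.append(live_state.copy())
        id_list.append(live_id.copy())
        frame_list.append(np.full(len(live_pos), f, dtype=np.int64))

    if pos_list:
        pos = np.concatenate(pos_list)
        table = pd.DataFrame({
            "molecule_id": np.concatenate(id_list),
            "frame": np.concatenate(frame_list),
            "t_s": np.concatenate(frame_list) * dt,
            "x_nm": pos[:, 0],
            "y_nm": pos[:, 1],
            "state": np.concatenate(state_list),
        }).sort_values(["molecule_id", "frame"], kind="stable").reset_index(drop=True)
    else:
        table = pd.DataFrame(columns=["molecule_id", "frame", "t_s", "x_nm", "y_nm", "state"])

    return GroundTruthTracks(
        table=table,
        birth_frame=np.asarray(birth_frames, dtype=np.int64),
        death_frame=np.asarray(death_frames, dtype=np.int64),
    )


def simulate_switching_diffusion(
    n_steps: int,
    D_states: tuple[float, ...] = (5.0e5, 1.0e5),
    mean_dwell_steps: float = 100.0,
    dt_s: float = 1.0 / 95.0,
    sigma_loc_nm: float = 25.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Unconfined 2D diffusion with Markov switching between diffusive states.

    The benchmark generator for latent-state segmentation: returns a frame
    table with true positions, noisy observed positions and the true state
    per step.  Columns: frame, t_s, x_nm, y_nm, x_true_nm, y_true_nm, state,
    sigma_nm.  ``state[i]`` governs the step from frame i to i+1.
    """
    rng = np.random.default_rng(seed)
    k = len(D_states)
    p_switch = 1.0 / mean_dwell_steps
    states = np.empty(n_steps + 1, dtype=np.int8)
    states[0] = rng.integers(k)
    for i in range(1, n_steps + 1):
        if rng.random() < p_switch:
            states[i] = (states[i - 1] + rng.integers(1, k)) % k
        else:
            states[i] = states[i - 1]
    stds = np.sqrt(2.0 * np.asarray(D_states) * dt_s)
    steps = rng.normal(size=(n_steps, 2)) * stds[states[:-1], None]
    true = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    obs = true + rng.normal(size=true.shape) * sigma_loc_nm
    frames = np.arange(n_steps + 1)
    return pd.DataFrame({
        "frame": frames,
        "t_s": frames * dt_s,
        "x_nm": obs[:, 0],
        "y_nm": obs[:, 1],
        "x_true_nm": true[:, 0],
        "y_true_nm": true[:, 1],
        "state": states,
        "sigma_nm": np.full(n_steps + 1, float(sigma_loc_nm)),
    })
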