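"""Synthetic entorhinal/hippocampal population and replay sessions.

Emulates recordings from an alternating home-away well arena so the replay
analysis pipeline can be validated without external data. Three entorhinal
classes — 10 grid cells (triangular lattice, 120 cm spacing, 6 deg rotation,
random translation), 20 object-vector cells per day (uniform direction,
uniform 0-200 cm distance from the home well) and 40 sensory cells (uniform
random centers) — are each rescaled so the class-wise population maximum is
20 Hz. Their pairwise rate-map products give 10 x 20 = 200 hippocampal
landmark cells and 10 x 40 = 400 place cells (600 conjunctive cells total).

Field widths: the Gaussian bumps use variances of 0.02 m^2 (grid, sensory;
sigma ~= 14.1 cm) and 0.012 m^2 (object-vector; sigma ~= 11.0 cm). With the
x25 replay rate scaling these widths put the session at around 30 Poisson
spikes per replay trajectory.

A simulated session holds 100 replay trajectories (1 home : 3 elsewhere,
spread evenly over 10-3000 s; 100-300 cm over 20 steps of 5 ms), Poisson
replay spikes at 25x behavioral rates, and per-spike ground-truth rate-map
changes: a landmark cell that first spiked in a home replay at t0 changes by
(t0 / t1) of its full field in a replay at t1, plus 0.5 Hz white noise
smoothed with a 4 cm kernel; place-cell changes are that noise alone. A
landmark cell never spikes in an elsewhere replay before its first home
replay spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter


@dataclass(frozen=True)
class PopulationConfig:
    arena_cm: float = 200.0
    bin_cm: float = 2.0
    n_grid: int = 10
    n_ovc: int = 20
    n_sensory: int = 40
    grid_spacing_cm: float = 120.0
    grid_rotation_deg: float = 6.0
    grid_var_cm2: float = 200.0  # 0.02 m^2
    ovc_var_cm2: float = 120.0  # 0.012 m^2
    sensory_var_cm2: float = 200.0
    max_rate_hz: float = 20.0
    ovc_max_dist_cm: float = 200.0

    @property
    def n_bins(self) -> int:
        return int(round(self.arena_cm / self.bin_cm))

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_cm


@dataclass
class EntorhinalPopulations:
    """Rate maps (cells x bins x bins, Hz) for the three entorhinal classes."""

    config: PopulationConfig
    grid: np.ndarray
    ovc_day1: np.ndarray
    ovc_day2: np.ndarray
    sensory: np.ndarray
    home_day1: np.ndarray
    home_day2: np.ndarray
    ovc_vectors: np.ndarray  # (n_ovc, 2) preferred vector from home, cm


def _gauss_map(config: PopulationConfig, centers, var_cm2: float) -> np.ndarray:
    xs = config.bin_centers()
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    m = np.zeros((config.n_bins, config.n_bins))
    for cx, cy in np.atleast_2d(centers):
        m += np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * var_cm2))
    return m


def build_entorhinal_populations(
    config: PopulationConfig,
    home_day1,
    home_day2,
    rng: np.random.Generator,
) -> EntorhinalPopulations:
    """Generate and 20 Hz-normalize the grid / object-vector / sensory maps.

    Day-2 object-vector maps are the day-1 maps translated by the home-well
    displacement (the preferred vectors are shared across days).
    """
    ang = np.deg2rad(config.grid_rotation_deg)
    v1 = config.grid_spacing_cm * np.array([np.cos(ang), np.sin(ang)])
    v2 = config.grid_spacing_cm * np.array(
        [np.cos(ang + np.pi / 3), np.sin(ang + np.pi / 3)]
    )
    span = int(np.ceil(2 * config.arena_cm / config.grid_spacing_cm)) + 2
    grid = []
    for _ in range(config.n_grid):
        offset = rng.uniform(0, config.grid_spacing_cm, 2)
        centers = [
            offset + i * v1 + j * v2
            for i in range(-span, span + 1)
            for j in range(-span, span + 1)
        ]
        centers = [
            c
            for c in centers
            if -3 * np.sqrt(config.grid_var_cm2) - config.arena_cm
            < min(c)  # keep peaks near enough to matter
            and max(c) < 2 * config.arena_cm
        ]
        grid.append(_gauss_map(config, centers, config.grid_var_cm2))
    grid = np.asarray(grid)
    grid *= config.max_rate_hz / grid.max()

    directions = rng.uniform(0, 2 * np.pi, config.n_ovc)
    distances = rng.uniform(0, config.ovc_max_dist_cm, config.n_ovc)
    vectors = np.column_stack(
        [distances * np.cos(directions), distances * np.sin(directions)]
    )
    home1 = np.asarray(home_day1, dtype=float)
    home2 = np.asarray(home_day2, dtype=float)
    ovc1 = np.asarray(
        [_gauss_map(config, home1 + v, config.ovc_var_cm2) for v in vectors]
    )
    ovc2 = np.asarray(
        [_gauss_map(config, home2 + v, config.ovc_var_cm2) for v in vectors]
    )
    scale = config.max_rate_hz / max(ovc1.max(), 1e-12)
    ovc1 *= scale
    # day-2 maps share the day-1 normalization so a translated field keeps
    # its amplitude
    ovc2 *= scale

    sens_centers = rng.uniform(0, config.arena_cm, (config.n_sensory, 2))
    sensory = np.asarray(
        [_gauss_map(config, c, config.sensory_var_cm2) for c in sens_centers]
    )
    sensory *= config.max_rate_hz / sensory.max()

    return EntorhinalPopulations(
        config=config,
        grid=grid,
        ovc_day1=ovc1,
        ovc_day2=ovc2,
        sensory=sensory,
        home_day1=home1,
        home_day2=home2,
        ovc_vectors=vectors,
    )


@dataclass
class ConjunctivePopulation:
    """600 conjunctive hippocampal cells: 200 landmark + 400 place.

    ``landmark_day1/2[i * n_ovc + j]`` is grid cell i x object-vector cell j;
    ``place[i * n_sensory + k]`` is grid cell i x sensory cell k. ``labels``
    is "landmark" for the first 200 cells and "place" for the rest, in the
    cell-id order used by sessions (landmark cells first).
    """

    config: PopulationConfig
    landmark_day1: np.ndarray
    landmark_day2: np.ndarray
    place: np.ndarray
    parents: list
    home_day1: np.ndarray
    home_day2: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.landmark_day1.shape[0] + self.place.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return np.array(
            ["landmark"] * self.landmark_day1.shape[0]
            + ["place"] * self.place.shape[0]
        )

    def ratemaps(self, day: int = 1) -> np.ndarray:
        land = self.landmark_day1 if day == 1 else self.landmark_day2
        return np.concatenate([land, self.place])


def build_conjunctive_population(ent: EntorhinalPopulations) -> ConjunctivePopulation:
    """Elementwise products of parent maps, class-rescaled to 20 Hz max.

    One factor per conjunctive class (landmark, place); the landmark factor
    is shared across both days so day-to-day changes stay construction-true.
    """
    cfg = ent.config
    land1 = (ent.grid[:, None] * ent.ovc_day1[None]).reshape(
        -1, cfg.n_bins, cfg.n_bins
    )
    land2 = (ent.grid[:, None] * ent.ovc_day2[None]).reshape(
        -1, cfg.n_bins, cfg.n_bins
    )
    place = (ent.grid[:, None] * ent.sensory[None]).reshape(
        -1, cfg.n_bins, cfg.n_bins
    )
    land_scale = cfg.max_rate_hz / max(land1.max(), land2.max(), 1e-12)
    land1 = land1 * land_scale
    land2 = land2 * land_scale
    place = place * (cfg.max_rate_hz / max(place.max(), 1e-12))
    parents = [("grid", i, "ovc", j) for i in range(cfg.n_grid) for j in range(cfg.n_ovc)]
    parents += [
        ("grid", i, "sensory", k)
        for i in range(cfg.n_grid)
        for k in range(cfg.n_sensory)
    ]
    return ConjunctivePopulation(
        config=cfg,
        landmark_day1=land1,
        landmark_day2=land2,
        place=place,
        parents=parents,
        home_day1=ent.home_day1,
        home_day2=ent.home_day2,
    )


# ---------------------------------------------------------------------------
# replay sessions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionConfig:
    n_replays: int = 100
    t_start_s: float = 10.0
    t_end_s: float = 3000.0
    min_length_cm: float = 100.0
    max_length_cm: float = 300.0
    n_steps: int = 20
    step_dt_s: float = 0.005
    rate_scale: float = 25.0
    home_exclusion_cm: float = 30.0
    change_noise_hz: float = 0.5
    change_noise_smooth_cm: float = 4.0


@dataclass
class SyntheticSession:
    """One simulated day-1 recording session of replay events."""

    config: SessionConfig
    pop: ConjunctivePopulation
    events: pd.DataFrame  # replay_id, time_s, kind, animal_x/y_cm, n_steps
    trajectories: pd.DataFrame  # replay_id, step, x_cm, y_cm, t_s
    spikes: pd.DataFrame  # cell, time_s, replay_id, first_home_spike
    first_home_spike_time: dict  # landmark cell id -> t0 (s)
    _noise_seeds: dict = field(default_factory=dict)  # (cell, replay_id) -> seed

    def smoothed_noise(self, cell: int, replay_id: int) -> np.ndarray:
        cfg, pcfg = self.config, self.pop.config
        seed = self._noise_seeds[(cell, replay_id)]
        rng = np.random.default_rng(seed)
        nb = pcfg.n_bins
        noise = rng.standard_normal((nb, nb)) * cfg.change_noise_hz
        return gaussian_filter(
            noise, cfg.change_noise_smooth_cm / pcfg.bin_cm, mode="constant"
        )

    def change_map(self, cell: int, replay_id: int) -> np.ndarray:
        """Ground-truth (after - before) rate-map change for one cell around
        one replay event: the t0/t1-scaled landmark field plus smoothed
        noise, or noise alone for place cells."""
        noise = self.smoothed_noise(cell, replay_id)
        labels = self.pop.labels
        if labels[cell] == "place":
            return noise
        t0 = self.first_home_spike_time.get(cell)
        t1 = float(
            self.events.loc[self.events.replay_id == replay_id, "time_s"].iloc[0]
        )
        if t0 is None or t1 < t0:
            return noise
        return (t0 / t1) * self.pop.landmark_day1[cell] + noise


def _sample_trajectory(
    cfg: SessionConfig, pcfg: PopulationConfig, kind: str, home, rng
) -> np.ndarray:
    """Straight replay path; cut short at the arena edge or (elsewhere) at
    the 30 cm home exclusion zone. Returns (n_steps_kept, 2) in cm."""
    home = np.asarray(home, dtype=float)
    while True:
        if kind == "home":
            start = home.copy()
        else:
            start = rng.uniform(0, pcfg.arena_cm, 2)
            if np.linalg.norm(start - home) < cfg.home_exclusion_cm:
                continue
        length = rng.uniform(cfg.min_length_cm, cfg.max_length_cm)
        theta = rng.uniform(0, 2 * np.pi)
        steps = np.linspace(0, length, cfg.n_steps)
        pts = start[None, :] + steps[:, None] * np.array(
            [np.cos(theta), np.sin(theta)]
        )
        ok = (
            (pts[:, 0] >= 0)
            & (pts[:, 0] < pcfg.arena_cm)
            & (pts[:, 1] >= 0)
            & (pts[:, 1] < pcfg.arena_cm)
        )
        if kind == "elsewhere":
            ok &= np.linalg.norm(pts - home, axis=1) >= cfg.home_exclusion_cm
        n_keep = int(np.argmin(ok)) if not ok.all() else cfg.n_steps
        if n_keep >= 2:
            return pts[:n_keep]


def simulate_replay_session(
    pop: ConjunctivePopulation,
    rng: np.random.Generator,
    config: SessionConfig = SessionConfig(),
) -> SyntheticSession:
    """Sample trajectories and Poisson replay spikes for the day-1 session.

    Events repeat home, elsewhere, elsewhere, elsewhere and are spaced evenly
    over the session. Rates are the day-1 rate maps scaled by 25; a landmark
    cell's spikes in elsewhere replays are suppressed until the cell has
    spiked in a home replay.
    """
    cfg, pcfg = config, pop.config
    times = np.linspace(cfg.t_start_s, cfg.t_end_s, cfg.n_replays)
    kinds = [
        "home" if i % 4 == 0 else "elsewhere" for i in range(cfg.n_replays)
    ]
    maps = pop.ratemaps(day=1)
    labels = pop.labels
    n_landmark = int((labels == "landmark").sum())
    first_home = {}
    ev_rows, traj_rows, spike_rows = [], [], []
    noise_seeds = {}
    for rid, (t_event, kind) in enumerate(zip(times, kinds)):
        pts = _sample_trajectory(cfg, pcfg, kind, pop.home_day1, rng)
        n_steps = pts.shape[0]
        if kind == "home":
            animal = np.asarray(pop.home_day1, dtype=float)
        else:
            animal = pts[0]
        ev_rows.append(
            dict(
                replay_id=rid,
                time_s=t_event,
                kind=kind,
                animal_x_cm=animal[0],
                animal_y_cm=animal[1],
                n_steps=n_steps,
            )
        )
        step_times = t_event + np.arange(n_steps) * cfg.step_dt_s
        for s, (p, ts) in enumerate(zip(pts, step_times)):
            traj_rows.append(
                dict(replay_id=rid, step=s, x_cm=p[0], y_cm=p[1], t_s=ts)
            )
        bi = np.clip((pts / pcfg.bin_cm).astype(int), 0, pcfg.n_bins - 1)
        rates = maps[:, bi[:, 1], bi[:, 0]]  # cells x steps, Hz
        lam = rates * cfg.rate_scale * cfg.step_dt_s
        counts = rng.poisson(lam)
        if kind == "elsewhere":
            # a landmark cell cannot spike here before its first home spike
            for c in range(n_landmark):
                if c not in first_home:
                    counts[c, :] = 0
        for c, s in zip(*np.nonzero(counts)):
            k = int(counts[c, s])
            t_spk = step_times[s] + rng.uniform(0, cfg.step_dt_s, k)
            is_first = False
            if labels[c] == "landmark" and kind == "home" and c not in first_home:
                first_home[int(c)] = float(t_event)
                is_first = True
            for t in np.sort(t_spk):
                spike_rows.append(
                    dict(
                        cell=int(c),
                        time_s=float(t),
                        replay_id=rid,
                        first_home_spike=is_first,
                    )
                )
                is_first = False
        for c in np.unique(np.nonzero(counts)[0]):
            noise_seeds[(int(c), rid)] = int(rng.integers(2**31 - 1))
    return SyntheticSession(
        config=cfg,
        pop=pop,
        events=pd.DataFrame(ev_rows),
        trajectories=pd.DataFrame(traj_rows),
        spikes=pd.DataFrame(
            spike_rows,
            columns=["cell", "time_s", "replay_id", "first_home_spike"],
        ),
        first_home_spike_time={k: v for k, v in first_home.items()},
        _noise_seeds=noise_seeds,
    )


def day2_change_maps(
    pop: ConjunctivePopulation,
    rng: np.random.Generator,
    noise_hz: float = 0.5,
    smooth_cm: float = 4.0,
) -> np.ndarray:
    """Cumulative day-2 change per cell: (day-2 map - day-1 map) + noise.

    Landmark changes show a positive field at the vector from the new home
    and a matching negative field at the old home; place changes are noise.
    """
    pcfg = pop.config
    maps1 = pop.ratemaps(day=1)
    maps2 = pop.ratemaps(day=2)
    noise = rng.standard_normal(maps1.shape) * noise_hz
    noise = gaussian_filter(
        noise, (0, smooth_cm / pcfg.bin_cm, smooth_cm / pcfg.bin_cm), mode="constant"
    )
    return maps2 - maps1 + noise


# ---------------------------------------------------------------------------
# behavioral foraging track (synthetic stand-in; no counterpart is described
# for the source recordings)
# ---------------------------------------------------------------------------


def simulate_foraging_track(
    pcfg: PopulationConfig,
    rng: np.random.Generator,
    duration_s: float = 300.0,
    dt_s: float = 0.02,
    speed_cm_s: float = 20.0,
    turn_sd: float = 0.5,
) -> pd.DataFrame:
    """Smooth random-walk behavior track: (time_s, x_cm, y_cm).

    Heading follows a random walk; the track reflects off arena boundaries.
    Speed is constant, above the 5 cm/s rate-map filter.
    """
    n = int(duration_s / dt_s)
    pos = np.empty((n, 2))
    p = rng.uniform(0.25 * pcfg.arena_cm, 0.75 * pcfg.arena_cm, 2)
    theta = rng.uniform(0, 2 * np.pi)
    for i in range(n):
        theta += rng.normal(0, turn_sd * np.sqrt(dt_s))
        step = speed_cm_s * dt_s * np.array([np.cos(theta), np.sin(theta)])
        q = p + step
        for d in range(2):
            if q[d] < 0:
                q[d] = -q[d]
                theta = np.pi - theta if d == 0 else -theta
            elif q[d] > pcfg.arena_cm:
                q[d] = 2 * pcfg.arena_cm - q[d]
                theta = np.pi - theta if d == 0 else -theta
        p = q
        pos[i] = p
    return pd.DataFrame(
        {"time_s": np.arange(n) * dt_s, "x_cm": pos[:, 0], "y_cm": pos[:, 1]}
    )


def poisson_spikes_on_track(
    ratemaps: np.ndarray,
    track: pd.DataFrame,
    pcfg: PopulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson spikes (cell, time_s) for each cell along a behavior track."""
    dt = float(np.median(np.diff(track.time_s.values)))
    bi = np.clip(
        (track[["x_cm", "y_cm"]].values / pcfg.bin_cm).astype(int),
        0,
        pcfg.n_bins - 1,
    )
    rows = []
    for c in range(ratemaps.shape[0]):
        lam = ratemaps[c, bi[:, 1], bi[:, 0]] * dt
        counts = rng.poisson(lam)
        idx = np.nonzero(counts)[0]
        for i in idx:
            for t in track.time_s.values[i] + rng.uniform(0, dt, counts[i]):
                rows.append({"cell": c, "time_s": float(t)})
    df = pd.DataFrame(rows, columns=["cell", "time_s"])
    return df.sort_values("time_s").reset_index(drop=True)
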