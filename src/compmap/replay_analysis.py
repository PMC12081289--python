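"""Replay-decoding analysis pipeline.

Implements the empirical analysis chain for arena recordings (real or
synthetic): occupancy-normalized rate maps, replay-event segmentation around
ripple times, memoryless Bayesian position decoding with leave-one-neuron-out
spike-location interpolation, replay-spike-aligned rate-map change maps,
home/elsewhere event classification with time-matched controls, change
summaries (origin ROI and radial spokes), home-shift generalization
correlations, replay/change overlap statistics, and nonlocal-door-spike
detection.

All positions are in cm; rate maps use 2 cm bins smoothed with a 4 cm-s.d.
Gaussian kernel (kernel renormalized over in-arena bins); decoding uses
20 ms windows slid by 5 ms. The decoder posterior over position bins is

    p(pos | spikes) = F / sum(F),
    F = (prod_i f_i(pos)^{n_i}) * exp(-tau * sum_i f_i(pos)),

with n_i the window spike count of neuron i, f_i its rate map and tau the
window width; everything is computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.ndimage import gaussian_filter

EPS_RATE = 1e-10


def _smooth_masked(values: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Gaussian smoothing with the kernel renormalized over valid bins."""
    v = gaussian_filter(values, sigma_bins, mode="constant")
    w = gaussian_filter(np.ones_like(values), sigma_bins, mode="constant")
    return v / np.maximum(w, 1e-12)


def track_speed(track: pd.DataFrame) -> np.ndarray:
    """Instantaneous speed (cm/s) from a (time_s, x_cm, y_cm) track."""
    t = track.time_s.values
    vx = np.gradient(track.x_cm.values, t)
    vy = np.gradient(track.y_cm.values, t)
    return np.hypot(vx, vy)


# ---------------------------------------------------------------------------
# rate maps
# ---------------------------------------------------------------------------


@dataclass
class RateMap:
    """Smoothed spikes-over-occupancy firing-rate map.

    ``rate`` is NaN-masked where smoothed occupancy falls below
    ``occupancy_floor_s``.
    """

    rate: np.ndarray
    occupancy_s: np.ndarray
    spike_counts: np.ndarray
    bin_cm: float
    mask: np.ndarray  # True where the map is valid


def compute_ratemap(
    spikes: pd.DataFrame,
    track: pd.DataFrame,
    interval=None,
    arena_cm: float = 200.0,
    bin_cm: float = 2.0,
    smooth_cm: float = 4.0,
    speed_min_cm_s: float = 5.0,
    occupancy_floor_s: float = 0.2,
) -> RateMap:
    """Rate map from spike times and a behavior track.

    Only samples where the animal moves faster than 5 cm/s contribute; both
    the occupancy and spike-count maps are smoothed with the same 4 cm
    kernel before division.
    """
    t = track.time_s.values
    dt = float(np.median(np.diff(t)))
    speed = track_speed(track)
    keep = speed > speed_min_cm_s
    if interval is not None:
        keep &= (t >= interval[0]) & (t < interval[1])
    if not keep.any():
        raise ValueError("no track samples pass the speed/interval filter")
    nb = int(round(arena_cm / bin_cm))
    edges = np.arange(nb + 1) * bin_cm
    occ, _, _ = np.histogram2d(
        track.y_cm.values[keep], track.x_cm.values[keep], bins=(edges, edges)
    )
    occ *= dt
    # spikes inherit the speed filter of their nearest track sample
    st = spikes.time_s.values
    idx = np.clip(np.searchsorted(t, st), 0, len(t) - 1)
    s_keep = keep[idx]
    if interval is not None:
        s_keep &= (st >= interval[0]) & (st < interval[1])
    sx = np.interp(st[s_keep], t, track.x_cm.values)
    sy = np.interp(st[s_keep], t, track.y_cm.values)
    cnt, _, _ = np.histogram2d(sy, sx, bins=(edges, edges))
    sigma = smooth_cm / bin_cm
    occ_s = _smooth_masked(occ, sigma)
    cnt_s = _smooth_masked(cnt, sigma)
    mask = occ_s >= occupancy_floor_s
    rate = np.full_like(occ_s, np.nan)
    rate[mask] = cnt_s[mask] / occ_s[mask]
    return RateMap(rate, occ_s, cnt_s, bin_cm, mask)


# ---------------------------------------------------------------------------
# population rate and event segmentation
# ---------------------------------------------------------------------------


@dataclass
class PopulationRate:
    t0: float
    dt: float  # 1 ms
    rate: np.ndarray  # smoothed spike counts per bin

    def at(self, t: float) -> float:
        i = int(np.clip((t - self.t0) / self.dt, 0, len(self.rate) - 1))
        return float(self.rate[i])


def population_rate(
    spike_times: np.ndarray,
    t_range,
    track: pd.DataFrame = None,
    speed_max_cm_s: float = 5.0,
    bin_ms: float = 1.0,
    smooth_ms: float = 10.0,
) -> PopulationRate:
    """Smoothed 1 ms-binned histogram of all spikes during immobility.

    If a track is given, only spikes while the animal moves slower than
    5 cm/s are counted; the histogram is smoothed with a 10 ms-s.d. kernel
    (mass preserving in the interior).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if track is not None and len(track):
        speed = track_speed(track)
        idx = np.clip(
            np.searchsorted(track.time_s.values, spike_times),
            0,
            len(track) - 1,
        )
        spike_times = spike_times[speed[idx] < speed_max_cm_s]
    dt = bin_ms / 1000.0
    t0, t1 = float(t_range[0]), float(t_range[1])
    n = max(int(np.ceil((t1 - t0) / dt)), 1)
    counts, _ = np.histogram(spike_times, bins=n, range=(t0, t0 + n * dt))
    rate = gaussian_filter(counts.astype(float), smooth_ms / bin_ms, mode="constant")
    return PopulationRate(t0, dt, rate)


@dataclass
class EventWindow:
    start_s: float
    end_s: float
    ripple_s: float


def detect_replay_events(
    pop_rate: PopulationRate,
    ripple_times,
    pre_window_s: float = 0.5,
) -> list:
    """Bracket each ripple by threshold crossings of the population rate.

    The event starts at the last time before the ripple that the rate was at
    or below its pre-ripple mean (mean over nonzero 1 ms bins in a 500 ms
    window) and ends when the rate drops below the analogous post-ripple
    mean. Ripples in silent regions (zero rate at the ripple) are rejected.
    """
    events = []
    r = pop_rate.rate
    for t_rip in np.atleast_1d(ripple_times):
        i_rip = int(round((t_rip - pop_rate.t0) / pop_rate.dt))
        if i_rip < 0 or i_rip >= len(r) or r[i_rip] <= 0:
            continue
        npre = int(round(pre_window_s / pop_rate.dt))
        pre = r[max(i_rip - npre, 0) : i_rip]
        pre_nz = pre[pre > 0]
        post = r[i_rip : i_rip + npre]
        post_nz = post[post > 0]
        if pre_nz.size == 0 or post_nz.size == 0:
            continue
        thr_pre, thr_post = pre_nz.mean(), post_nz.mean()
        i = i_rip
        while i > 0 and r[i - 1] > thr_pre:
            i -= 1
        j = i_rip
        while j < len(r) - 1 and r[j + 1] >= thr_post:
            j += 1
        start = pop_rate.t0 + i * pop_rate.dt
        end = pop_rate.t0 + (j + 1) * pop_rate.dt
        if start < t_rip < end:
            events.append(EventWindow(start, end, float(t_rip)))
    return events


# ---------------------------------------------------------------------------
# Bayesian decoding
# ---------------------------------------------------------------------------


def bayesian_decode(
    spike_counts: np.ndarray, ratemaps: np.ndarray, tau: float
) -> np.ndarray:
    """Memoryless posterior over position bins for one window.

    ``spike_counts`` has one entry per neuron, ``ratemaps`` is
    (neurons, ny, nx) in Hz. Returns the normalized posterior (ny, nx).
    """
    counts = np.asarray(spike_counts, dtype=float)
    f = np.maximum(ratemaps, EPS_RATE)
    logf = np.log(f)
    log_post = np.tensordot(counts, logf, axes=1) - tau * f.sum(axis=0)
    log_post -= log_post.max()
    post = np.exp(log_post)
    z = post.sum()
    if not np.isfinite(z) or z <= 0:
        raise ValueError("all-zero likelihood in decoding window")
    return post / z


def _map_position(post: np.ndarray, bin_cm: float) -> tuple[float, float]:
    """Posterior-maximum position; near-ties resolved by their centroid."""
    m = post.max()
    ties = np.argwhere(post >= m * (1 - 1e-12))
    y, x = ties.mean(axis=0)
    return (float((x + 0.5) * bin_cm), float((y + 0.5) * bin_cm))


@dataclass
class DecodedTrajectory:
    centers_s: np.ndarray
    positions_cm: np.ndarray  # (n_windows, 2)
    excluded_cell: object = None


class Decoder:
    """Sliding-window event decoder with precomputed log rate maps.

    Precomputing ``log f_i`` and ``sum_i f_i`` makes each leave-one-out
    decode a cheap per-window adjustment (subtract the excluded neuron's
    rate and log-rate) instead of a full recomputation.
    """

    def __init__(self, ratemaps: np.ndarray, bin_cm: float = 2.0,
                 tau: float = 0.02, step_s: float = 0.005):
        self.f = np.maximum(ratemaps, EPS_RATE)
        self.logf = np.log(self.f)
        self.sum_f = self.f.sum(axis=0)
        self.bin_cm = bin_cm
        self.tau = tau
        self.step_s = step_s

    def decode_event(
        self, spikes: pd.DataFrame, t_start: float, t_end: float, exclude=None
    ) -> DecodedTrajectory:
        tau = self.tau
        if t_end - t_start < tau:
            raise ValueError("event shorter than one decoding window")
        centers = np.arange(t_start + tau / 2, t_end - tau / 2 + 1e-9, self.step_s)
        sum_f = self.sum_f
        if exclude is not None:
            sum_f = sum_f - self.f[int(exclude)]
        cells = spikes.cell.values
        times = spikes.time_s.values
        positions = np.empty((len(centers), 2))
        for w, c in enumerate(centers):
            in_win = (times >= c - tau / 2) & (times < c + tau / 2)
            log_post = -tau * sum_f
            for cell in cells[in_win]:
                if exclude is not None and int(cell) == int(exclude):
                    continue
                log_post = log_post + self.logf[int(cell)]
            log_post = log_post - log_post.max()
            post = np.exp(log_post)
            post /= post.sum()
            positions[w] = _map_position(post, self.bin_cm)
        return DecodedTrajectory(centers, positions, exclude)


def decode_event_trajectory(
    spikes: pd.DataFrame,
    ratemaps: np.ndarray,
    t_start: float,
    t_end: float,
    bin_cm: float = 2.0,
    tau: float = 0.02,
    step_s: float = 0.005,
    exclude=None,
) -> DecodedTrajectory:
    """Sliding-window decode of one replay event.

    Windows of width ``tau`` slide by 5 ms through [t_start, t_end]; the
    excluded neuron (leave-one-out) contributes neither spike counts nor its
    rate map. Raises if the event is shorter than one window.
    """
    dec = Decoder(ratemaps, bin_cm, tau, step_s)
    return dec.decode_event(spikes, t_start, t_end, exclude=exclude)


def interpolate_spike_location(
    spike_time: float, traj: DecodedTrajectory
) -> tuple[np.ndarray, bool]:
    """Linear interpolation of a spike's position along the decoded trajectory.

    Returns (position, clamped): spikes outside the decoded span take the
    nearest endpoint and are flagged.
    """
    c = traj.centers_s
    clamped = spike_time < c[0] or spike_time > c[-1]
    x = np.interp(spike_time, c, traj.positions_cm[:, 0])
    y = np.interp(spike_time, c, traj.positions_cm[:, 1])
    return np.array([x, y]), bool(clamped)


# ---------------------------------------------------------------------------
# spike-aligned change maps
# ---------------------------------------------------------------------------


def align_on_spike(
    change_map: np.ndarray, spike_xy, bin_cm: float
) -> np.ndarray:
    """Translate a change map so the spike location sits at the canvas origin.

    Returns a (2n-1, 2n-1) canvas, NaN outside the translated map; the
    canvas center holds the change value at the spike's bin.
    """
    nb = change_map.shape[0]
    bx = int(np.clip(spike_xy[0] // bin_cm, 0, nb - 1))
    by = int(np.clip(spike_xy[1] // bin_cm, 0, nb - 1))
    canvas = np.full((2 * nb - 1, 2 * nb - 1), np.nan)
    cy, cx = nb - 1 - by, nb - 1 - bx
    canvas[cy : cy + nb, cx : cx + nb] = change_map
    return canvas


def spike_aligned_change(
    change_map: np.ndarray, spike_locations, bin_cm: float
) -> np.ndarray:
    """Per-(cell, event) aligned change canvas.

    A cell's multiple spikes within one event are averaged into a single
    canvas before any cross-cell averaging.
    """
    canvases = [
        align_on_spike(change_map, xy, bin_cm) for xy in np.atleast_2d(spike_locations)
    ]
    return nanmean_stack(canvases)


def nanmean_stack(canvases) -> np.ndarray:
    """Mean of aligned canvases ignoring NaN padding."""
    acc = np.zeros_like(canvases[0])
    cnt = np.zeros_like(canvases[0])
    for c in canvases:
        v = np.isfinite(c)
        acc[v] += c[v]
        cnt[v] += 1
    out = np.full_like(acc, np.nan)
    out[cnt > 0] = acc[cnt > 0] / cnt[cnt > 0]
    return out


# ---------------------------------------------------------------------------
# event classification and controls
# ---------------------------------------------------------------------------


def classify_replay_event(
    decoded_positions: np.ndarray,
    home_cm,
    animal_cm,
    home_radius: float = 10.0,
    pass_radius: float = 30.0,
    remote_dist: float = 40.0,
) -> str:
    """Label an event home / elsewhere / excluded.

    Home: animal within 10 cm of the home well, decoded trajectory within
    30 cm of home at least once, mean decoded position at least 40 cm from
    the animal. Elsewhere: animal more than 10 cm from home, trajectory
    always at least 30 cm from home, mean decoded position at least 40 cm
    from the animal. Everything else is excluded.
    """
    pos = np.atleast_2d(decoded_positions)
    home = np.asarray(home_cm, dtype=float)
    animal = np.asarray(animal_cm, dtype=float)
    d_home = np.linalg.norm(pos - home, axis=1)
    animal_at_home = np.linalg.norm(animal - home) <= home_radius
    mean_remote = np.linalg.norm(pos.mean(axis=0) - animal) >= remote_dist
    if animal_at_home and d_home.min() <= pass_radius and mean_remote:
        return "home"
    if (not animal_at_home) and d_home.min() >= pass_radius and mean_remote:
        return "elsewhere"
    return "excluded"


def match_controls(
    home_times: np.ndarray,
    elsewhere_times: np.ndarray,
    rng: np.random.Generator,
    n_samples: int = 10_000,
    n_bins: int = 5,
) -> np.ndarray:
    """Indices into ``elsewhere_times`` of the time-matched control sample.

    Draws 10,000 subsamples of size len(home_times) and keeps the one whose
    5-bin event-time histogram correlates best with the home histogram.
    """
    home_times = np.asarray(home_times, dtype=float)
    elsewhere_times = np.asarray(elsewhere_times, dtype=float)
    if len(elsewhere_times) < len(home_times):
        raise ValueError("fewer elsewhere than home events")
    lo = min(home_times.min(), elsewhere_times.min())
    hi = max(home_times.max(), elsewhere_times.max())
    edges = np.linspace(lo, hi + 1e-9, n_bins + 1)
    h_home, _ = np.histogram(home_times, bins=edges)
    best, best_r = None, -np.inf
    k = len(home_times)
    for _ in range(n_samples):
        idx = rng.choice(len(elsewhere_times), size=k, replace=False)
        h, _ = np.histogram(elsewhere_times[idx], bins=edges)
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(h_home, h)[0, 1]
        if np.isnan(r):
            r = 1.0 if np.array_equal(h, h_home) else -1.0
        if r > best_r:
            best, best_r = idx, r
    return best


# ---------------------------------------------------------------------------
# change summaries
# ---------------------------------------------------------------------------


@dataclass
class ChangeSummary:
    roi_values: np.ndarray  # per-item mean change within the origin ROI
    profiles: np.ndarray  # per-item 50-point radial profile
    radii_cm: np.ndarray

    @property
    def roi_mean(self) -> float:
        return float(np.nanmean(self.roi_values))

    @property
    def roi_sem(self) -> float:
        v = self.roi_values[np.isfinite(self.roi_values)]
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan


def summarize_changes(
    canvases,
    bin_cm: float = 2.0,
    roi_cm: float = 8.0,
    n_angles: int = 20,
    n_steps: int = 50,
    step_cm: float = 2.0,
) -> ChangeSummary:
    """Origin-ROI mean and radial-spoke profile per aligned canvas.

    The ROI is the set of bins within 8 cm of the origin; the profile samples
    the nearest bin at 50 radii spaced 2 cm along 20 uniform angles and
    averages over angles.
    """
    canvases = list(canvases)
    n = canvases[0].shape[0]
    center = (n - 1) // 2
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot((xx - center) * bin_cm, (yy - center) * bin_cm)
    roi_mask = rr <= roi_cm
    radii = (np.arange(n_steps) + 1) * step_cm
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    sx = np.rint(
        center + np.outer(radii, np.cos(angles)) / bin_cm
    ).astype(int)
    sy = np.rint(
        center + np.outer(radii, np.sin(angles)) / bin_cm
    ).astype(int)
    sx = np.clip(sx, 0, n - 1)
    sy = np.clip(sy, 0, n - 1)
    roi_vals, profiles = [], []
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for c in canvases:
            roi_vals.append(np.nanmean(c[roi_mask]))
            profiles.append(np.nanmean(c[sy, sx], axis=1))
    return ChangeSummary(np.asarray(roi_vals), np.asarray(profiles), radii)


# ---------------------------------------------------------------------------
# generalization statistics
# ---------------------------------------------------------------------------


def _align_on_point(m: np.ndarray, point_xy, bin_cm: float) -> np.ndarray:
    return align_on_spike(m, point_xy, bin_cm)


def home_shift_correlation(
    total_change_map: np.ndarray,
    current_home,
    previous_home,
    bin_cm: float = 2.0,
) -> float:
    """Correlation between the change map aligned on the current home and the
    same map aligned on the previous home; negative values signal a response
    that moved with the home well."""
    a = _align_on_point(total_change_map, current_home, bin_cm)
    b = _align_on_point(total_change_map, previous_home, bin_cm)
    valid = np.isfinite(a) & np.isfinite(b)
    if valid.sum() < 3:
        raise ValueError("insufficient overlap between aligned change maps")
    x, y = a[valid], b[valid]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def replay_change_overlap(
    total_change_map: np.ndarray,
    spike_locations_cm,
    bin_cm: float = 2.0,
    smooth_cm: float = 4.0,
) -> tuple[float, int, float]:
    """(overlap, n_replay_spikes, location_correlation) for one cell.

    Overlap: mean of |change| times the smoothed map of interpolated replay
    spike locations. Location correlation: Pearson correlation of |change|
    with that spike map, separating alignment from spike count.
    """
    nb = total_change_map.shape[0]
    spike_map = np.zeros((nb, nb))
    locs = np.atleast_2d(spike_locations_cm) if len(spike_locations_cm) else []
    for xy in locs:
        bx = int(np.clip(xy[0] // bin_cm, 0, nb - 1))
        by = int(np.clip(xy[1] // bin_cm, 0, nb - 1))
        spike_map[by, bx] += 1.0
    n_spikes = int(len(locs))
    if n_spikes == 0:
        return 0.0, 0, np.nan
    spike_map = gaussian_filter(spike_map, smooth_cm / bin_cm, mode="constant")
    abs_change = np.abs(total_change_map)
    overlap = float(np.mean(abs_change * spike_map))
    if abs_change.std() == 0 or spike_map.std() == 0:
        corr = np.nan
    else:
        corr = float(np.corrcoef(abs_change.ravel(), spike_map.ravel())[0, 1])
    return overlap, n_spikes, corr


# ---------------------------------------------------------------------------
# nonlocal door spikes
# ---------------------------------------------------------------------------


def nonlocal_door_spikes(
    spikes: pd.DataFrame,
    track: pd.DataFrame,
    closed_doors,
    place_field_masks: dict,
    bin_cm: float = 2.0,
    door_radius_cm: float = 10.0,
    speed_max_cm_s: float = 5.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag spikes that serve as a replay proxy at closed doors.

    A spike is flagged iff the animal is within 10 cm of a closed door,
    moving slower than 5 cm/s, and the spiking cell has no place field at
    the animal's current location (``place_field_masks[cell]`` is a boolean
    bin mask of its fields). Returns the flagged spike table and a per-cell
    binary replay indicator.
    """
    doors = np.atleast_2d(np.asarray(closed_doors, dtype=float))
    if doors.size == 0:
        raise ValueError("no closed doors given")
    t = track.time_s.values
    speed = track_speed(track)
    st = spikes.time_s.values
    idx = np.clip(np.searchsorted(t, st), 0, len(t) - 1)
    ax = np.interp(st, t, track.x_cm.values)
    ay = np.interp(st, t, track.y_cm.values)
    d_door = np.min(
        np.hypot(ax[:, None] - doors[None, :, 0], ay[:, None] - doors[None, :, 1]),
        axis=1,
    )
    slow = speed[idx] < speed_max_cm_s
    flagged = []
    for i, (c, near, sl) in enumerate(zip(spikes.cell.values, d_door, slow)):
        if near > door_radius_cm or not sl:
            flagged.append(False)
            continue
        mask = place_field_masks.get(int(c))
        if mask is not None:
            nb = mask.shape[0]
            bx = int(np.clip(ax[i] // bin_cm, 0, nb - 1))
            by = int(np.clip(ay[i] // bin_cm, 0, nb - 1))
            if mask[by, bx]:
                flagged.append(False)
                continue
        flagged.append(True)
    out = spikes.copy()
    out["nonlocal_door_spike"] = flagged
    indicator = out.groupby("cell")["nonlocal_door_spike"].any()
    return out, indicator


def replay_newfield_regression(
    new_field: np.ndarray, replayed: np.ndarray, mean_rate: np.ndarray
):
    """Regress new-field emergence on the replay indicator (one-tailed).

    Ordinary least squares of the binary new-field indicator on the binary
    replay indicator plus the cell's mean firing rate; returns
    (coefficient, t statistic, one-tailed p for coefficient > 0).
    """
    X = sm.add_constant(
        np.column_stack([np.asarray(replayed, float), np.asarray(mean_rate, float)])
    )
    fit = sm.OLS(np.asarray(new_field, float), X).fit()
    coef, tval = fit.params[1], fit.tvalues[1]
    from scipy import stats

    p_one = float(stats.t.sf(tval, fit.df_resid))
    return float(coef), float(tval), p_one


# ---------------------------------------------------------------------------
# synthetic-session pipeline (Figs-4/5-style validation)
# ---------------------------------------------------------------------------


@dataclass
class SessionAnalysis:
    events: pd.DataFrame  # per event: label, n_spikes
    canvases: dict  # label -> list of per-(cell, event) aligned canvases
    mean_maps: dict  # label -> mean aligned canvas
    summaries: dict  # label -> ChangeSummary
    bin_cm: float


def analyze_synthetic_session(
    session, rng: np.random.Generator, tau: float = 0.02, step_s: float = 0.005
) -> SessionAnalysis:
    """Run the decoding/alignment pipeline on one synthetic session.

    Decodes every replay event with leave-one-neuron-out, interpolates each
    spiking cell's spike locations, classifies events by the home/elsewhere
    criteria, builds time-matched elsewhere controls, and aggregates
    spike-aligned change canvases per group.
    """
    pop = session.pop
    pcfg = pop.config
    decoder = Decoder(pop.ratemaps(day=1), pcfg.bin_cm, tau, step_s)
    labels, times = [], []
    per_event_cell_canvases = []  # (event_label_idx, canvases by cell)
    ev_rows = []
    for _, ev in session.events.iterrows():
        rid = int(ev.replay_id)
        sp = session.spikes[session.spikes.replay_id == rid]
        t0 = float(ev.time_s)
        t1 = t0 + float(ev.n_steps) * session.config.step_dt_s
        if len(sp) == 0 or t1 - t0 < tau:
            continue
        base = decoder.decode_event(sp, t0, t1)
        label = classify_replay_event(
            base.positions_cm,
            np.asarray(pop.home_day1),
            (float(ev.animal_x_cm), float(ev.animal_y_cm)),
        )
        cell_canvases = {}
        for cell in np.unique(sp.cell.values):
            loo = decoder.decode_event(sp, t0, t1, exclude=int(cell))
            spike_locs = [
                interpolate_spike_location(t, loo)[0]
                for t in sp[sp.cell == cell].time_s.values
            ]
            change = session.change_map(int(cell), rid)
            cell_canvases[int(cell)] = spike_aligned_change(
                change, np.asarray(spike_locs), pcfg.bin_cm
            )
        ev_rows.append(
            dict(replay_id=rid, time_s=t0, label=label, n_cells=len(cell_canvases))
        )
        labels.append(label)
        times.append(t0)
        per_event_cell_canvases.append(cell_canvases)
    ev_df = pd.DataFrame(ev_rows)
    groups = {"home": [], "elsewhere": []}
    for lab, canv in zip(labels, per_event_cell_canvases):
        if lab in groups:
            groups[lab].extend(canv.values())
    # time-matched elsewhere controls at the event level
    home_t = ev_df.loc[ev_df.label == "home", "time_s"].values
    elsewhere_idx = ev_df.index[ev_df.label == "elsewhere"].values
    matched = []
    if len(home_t) > 0 and len(elsewhere_idx) >= len(home_t):
        sel = match_controls(
            home_t, ev_df.loc[elsewhere_idx, "time_s"].values, rng
        )
        for k in elsewhere_idx[sel]:
            matched.extend(per_event_cell_canvases[int(k)].values())
    groups["matched"] = matched
    mean_maps, summaries = {}, {}
    for lab, canv in groups.items():
        if canv:
            mean_maps[lab] = nanmean_stack(canv)
            summaries[lab] = summarize_changes(canv, pcfg.bin_cm)
    return SessionAnalysis(ev_df, groups, mean_maps, summaries, pcfg.bin_cm)
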