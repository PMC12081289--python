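"""Offline replay as imagined path integration, contrasted with Q backups.

Constructive replay starts at an anchor (the reward or home), imagines a
trajectory outward, path integrates the anchor's vector code along it, and
encodes a (location key, vector value) memory at every step — with no memory
retrieval during the replay, and with path-integration noise corrupting both
the key and the value. The contrast model replays the same trajectories but
performs backward temporal-difference (Q) backups instead of encoding
memories. Two benchmark experiments quantify the difference: policy success
per replay visit, and homing error under path-integration noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent_memory import (
    NO_MEMORY,
    KeyValueMemory,
    PathIntegrationNoise,
    fuse_discrete,
    path_integrate_discrete,
    retrieve_memory_discrete,
    sample_discrete,
)
from .environments import (
    ACTIONS,
    ACTION_VECTORS,
    GridWorld,
    optimal_policy,
    sample_gridworld,
    transition,
)

_OPPOSITE = {"north": "south", "south": "north", "east": "west", "west": "east"}


@dataclass
class ReplayTrajectory:
    """Imagined path from a start state; one action per step taken."""

    locations: list  # length n_steps + 1, starts at the anchor
    actions: list  # length n_steps
    mode: str  # "random" | "reverse_optimal"


def sample_replay_trajectory(
    world: GridWorld,
    start,
    mode: str,
    rng: np.random.Generator,
    length: int = None,
    table=None,
) -> ReplayTrajectory:
    """Replay trajectory from ``start`` along a random or reverse-optimal policy.

    Reverse-optimal trajectories ascend the distance-to-reward field (each
    step moves to a neighbor one step farther from reward) and stop when no
    such neighbor exists. Default length cap: twice the grid diameter.
    """
    if length is None:
        length = 2 * (world.width + world.height)
    locs, acts = [tuple(start)], []
    if mode == "reverse_optimal" and table is None:
        table = optimal_policy(world)
    for _ in range(length):
        loc = locs[-1]
        if mode == "random":
            # random policy over *moving* actions: imagined steps always
            # advance, so the path-integrated key tracks the trajectory
            options = [
                (a, transition(world, loc, a))
                for a in ACTIONS
                if transition(world, loc, a) != loc
            ]
            if not options:
                break
            a, nxt = options[int(rng.integers(len(options)))]
        elif mode == "reverse_optimal":
            d = table.distance[loc]
            ups = []
            for a in ACTIONS:
                nxt = transition(world, loc, a)
                if nxt != loc and table.distance.get(nxt) == d + 1:
                    ups.append((a, nxt))
            if not ups:
                break
            a, nxt = ups[int(rng.integers(len(ups)))]
        else:
            raise ValueError(f"unknown replay mode {mode!r}")
        locs.append(nxt)
        acts.append(a)
    return ReplayTrajectory(locs, acts, mode)


def constructive_replay(
    memory: KeyValueMemory,
    trajectory: ReplayTrajectory,
    noise: PathIntegrationNoise,
    rng: np.random.Generator,
    anchor_offset=(0, 0),
    time: float = 0.0,
) -> KeyValueMemory:
    """Encode one memory per replay step by pure path integration.

    Both the location key and the vector value are path integrated (the
    transitioned location cannot be observed during replay), so with noise
    either may drift; with zero noise every entry is exact. Memory is never
    read during the replay.
    """
    reads_before = memory.read_count
    offset = tuple(anchor_offset)
    key = trajectory.locations[0]
    for a in trajectory.actions:
        offset = sample_discrete(path_integrate_discrete(offset, a, noise), rng)
        # key path-integrates in the opposite sense: the imagined location
        # moves with the action
        dc, dr = ACTION_VECTORS[a]
        correct_key = (key[0] + dc, key[1] + dr)
        if noise.e_pi > 0 and rng.random() < noise.e_pi:
            sc, sr = [(0, 1), (1, 0), (0, -1), (-1, 0)][int(rng.integers(4))]
            key = (correct_key[0] + sc, correct_key[1] + sr)
        else:
            key = correct_key
        memory.encode(key, offset, time, origin="replay")
    assert memory.read_count == reads_before, "replay must not retrieve"
    return memory


# ---------------------------------------------------------------------------
# Q backups
# ---------------------------------------------------------------------------


@dataclass
class QTable:
    """Tabular action values, gamma = 0.7, alpha = 0.8, initialized at zero."""

    gamma: float = 0.7
    alpha: float = 0.8
    values: dict = field(default_factory=dict)

    def q(self, state, action) -> float:
        return self.values.get((tuple(state), action), 0.0)

    def max_q(self, state) -> float:
        return max(self.q(state, a) for a in ACTIONS)

    def greedy(self, state) -> str:
        qs = [self.q(state, a) for a in ACTIONS]
        return ACTIONS[int(np.argmax(qs))]


def q_backup_replay(
    q: QTable, trajectory: ReplayTrajectory, reward_state, reward: float = 1.0
) -> QTable:
    """Backward Q updates along a replay trajectory.

    After a replay transition a -> b, the backup runs from b to a: the
    reverse action from b is credited with the reward at a plus the
    discounted value of a. Replays extending out from the reward therefore
    propagate value outward in a single pass.
    """
    for loc, a, nxt in zip(
        trajectory.locations[:-1], trajectory.actions, trajectory.locations[1:]
    ):
        rev = _OPPOSITE[a]
        r = reward if tuple(loc) == tuple(reward_state) else 0.0
        target = r + q.gamma * q.max_q(loc)
        key = (tuple(nxt), rev)
        q.values[key] = q.q(nxt, rev) + q.alpha * (target - q.q(nxt, rev))
    return q


# ---------------------------------------------------------------------------
# policy-success-per-visit benchmark
# ---------------------------------------------------------------------------


def _memory_policy_success(memory: KeyValueMemory, world, loc, table) -> bool:
    """Does the vector memory at ``loc`` give an *optimal* path to reward?

    The agent retrieves the believed reward vector once at the queried
    location, then walks greedily while path integrating it (noiseless), as
    it would in behavior; intermediate locations need no memories of their
    own.
    """
    p_m = retrieve_memory_discrete(memory, loc)
    if p_m is NO_MEMORY:
        return False
    offset = max(p_m.items(), key=lambda kv: kv[1])[0]
    budget = table.distance.get(loc, 0)
    cur = loc
    for _ in range(int(budget)):
        best, best_d = None, abs(offset[0]) + abs(offset[1])
        for a in ACTIONS:
            dc, dr = ACTION_VECTORS[a]
            d = abs(offset[0] - dc) + abs(offset[1] - dr)
            if d < best_d:
                best, best_d = a, d
        if best is None:
            return False
        nxt = transition(world, cur, best)
        if nxt != cur:
            dc, dr = ACTION_VECTORS[best]
            offset = (offset[0] - dc, offset[1] - dr)
        cur = nxt
    return cur == world.reward


def _q_policy_success(q: QTable, world, loc, table) -> bool:
    budget = table.distance.get(loc, 0)
    cur = loc
    for _ in range(int(budget)):
        if q.max_q(cur) <= 0.0:
            return False
        cur = transition(world, cur, q.greedy(cur))
    return cur == world.reward


def replay_visit_curve(
    config: dict = None,
    rng: np.random.Generator = None,
    n_worlds: int = 25,
    n_visits: int = 15,
    n_replays: int = 120,
) -> pd.DataFrame:
    """Policy success vs per-state replay-visit count for the four conditions
    {memory, q} x {random, reverse_optimal}, noiseless, averaged over worlds.

    At every replay step the currently learned policy (memory read-out or
    greedy Q) is scored on whether it yields an optimal path to reward from
    that location; successes are aggregated by that location's visit number.
    """
    config = dict(config or {"width": 6, "height": 6, "n_walls": 0})
    rng = rng if rng is not None else np.random.default_rng(0)
    noise = PathIntegrationNoise(e_pi=0.0)
    rows = []
    for wid in range(n_worlds):
        world = sample_gridworld(config, rng)
        table = optimal_policy(world)
        for agent in ("memory", "q"):
            for mode in ("random", "reverse_optimal"):
                memory = KeyValueMemory()
                q = QTable()
                visits = {}
                succ = np.zeros(n_visits)
                cnt = np.zeros(n_visits)
                for _ in range(n_replays):
                    traj = sample_replay_trajectory(
                        world, world.reward, mode, rng, table=table
                    )
                    offset = (0, 0)  # believed reward vector at current step
                    for i, a in enumerate(traj.actions):
                        step_traj = ReplayTrajectory(
                            traj.locations[i : i + 2], [a], mode
                        )
                        if agent == "memory":
                            constructive_replay(
                                memory, step_traj, noise, rng,
                                anchor_offset=offset,
                            )
                            offset = memory.entries[-1].value
                        else:
                            q_backup_replay(q, step_traj, world.reward)
                        loc = traj.locations[i + 1]
                        k = visits.get(loc, 0)
                        visits[loc] = k + 1
                        if k < n_visits:
                            if agent == "memory":
                                ok = _memory_policy_success(memory, world, loc, table)
                            else:
                                ok = _q_policy_success(q, world, loc, table)
                            succ[k] += ok
                            cnt[k] += 1
                for k in range(n_visits):
                    if cnt[k] > 0:
                        rows.append(
                            {
                                "world": wid,
                                "agent": agent,
                                "mode": mode,
                                "visit": k + 1,
                                "success": succ[k] / cnt[k],
                            }
                        )
    return pd.DataFrame(rows)


def _true_offset(world: GridWorld, loc) -> tuple:
    return (world.reward[0] - loc[0], world.reward[1] - loc[1])


# ---------------------------------------------------------------------------
# homing benchmark
# ---------------------------------------------------------------------------


def _greedy_home_action(offset) -> str:
    """Action that most decreases the believed home offset (L1)."""
    best, best_d = None, abs(offset[0]) + abs(offset[1])
    for a in ACTIONS:
        dc, dr = ACTION_VECTORS[a]
        d = abs(offset[0] - dc) + abs(offset[1] - dr)
        if d < best_d:
            best, best_d = a, d
    return best


def _run_homing_trial(
    world: GridWorld,
    home,
    agent: str,
    e_pi: float,
    n_explore: int,
    n_replays: int,
    rng: np.random.Generator,
    w: float = 0.5,
    replay_every: int = 4,
    replay_len: int = 10,
) -> float:
    """One exploration + escape episode; returns final distance from home."""
    noise = PathIntegrationNoise(e_pi=e_pi)
    table = optimal_policy(GridWorld(world.width, world.height, (), home))
    memory = KeyValueMemory()
    q = QTable()
    loc = home
    offset = (0, 0)  # believed home vector (home - agent)
    memory.encode(loc, offset, 0.0)
    for step in range(n_explore):
        a = ACTIONS[int(rng.integers(4))]
        nxt = transition(world, loc, a)
        if nxt != loc:
            p_pi = path_integrate_discrete(offset, a, noise)
            if agent == "memory":
                p_m = retrieve_memory_discrete(memory, nxt)
                offset = fuse_discrete(p_pi, p_m, w, rng, memory, nxt)
            else:
                offset = sample_discrete(p_pi, rng)
        loc = nxt
        if agent in ("memory", "q") and (step + 1) % replay_every == 0:
            for _ in range(n_replays):
                traj = sample_replay_trajectory(
                    world, home, "random", rng, length=replay_len
                )
                if agent == "memory":
                    constructive_replay(memory, traj, noise, rng)
                else:
                    # replayed locations are path integrated: corrupt the
                    # trajectory's keys before the backups
                    noisy_locs = [traj.locations[0]]
                    for l_correct, act in zip(traj.locations[1:], traj.actions):
                        prev = noisy_locs[-1]
                        dc, dr = ACTION_VECTORS[act]
                        k = (prev[0] + dc, prev[1] + dr)
                        if rng.random() < e_pi:
                            sc, sr = [(0, 1), (1, 0), (0, -1), (-1, 0)][
                                int(rng.integers(4))
                            ]
                            k = (k[0] + sc, k[1] + sr)
                        noisy_locs.append(k)
                    q_backup_replay(
                        q,
                        ReplayTrajectory(noisy_locs, traj.actions, "random"),
                        home,
                    )
    # escape
    budget = 4 * (world.width + world.height)
    for _ in range(budget):
        if agent == "q":
            if q.max_q(loc) <= 0:
                break
            a = q.greedy(loc)
            loc = transition(world, loc, a)
            if loc == home:
                break
        else:
            if offset == (0, 0):
                break
            a = _greedy_home_action(offset)
            if a is None:
                break
            nxt = transition(world, loc, a)
            if nxt != loc:
                p_pi = path_integrate_discrete(offset, a, noise)
                if agent == "memory":
                    p_m = retrieve_memory_discrete(memory, nxt)
                    offset = fuse_discrete(p_pi, p_m, w, rng, memory, nxt)
                else:
                    offset = sample_discrete(p_pi, rng)
            loc = nxt
    return float(abs(loc[0] - home[0]) + abs(loc[1] - home[1]))


def _run_homing_trial_continuous(
    agent: str,
    noise: PathIntegrationNoise,
    n_explore: int,
    n_replays: int,
    rng: np.random.Generator,
    side: float = 1.0,
    step: float = 0.05,
    w: float = 0.5,
    replay_every: int = 4,
    replay_len: int = 20,
    n_dirs: int = 8,
    q_cell: float = 0.1,
) -> float:
    """Continuous arena homing episode; returns final distance from home (m).

    The memory agent fuses continuous path integration with softmax memory
    retrieval (5 cm cutoff) and replays from home with noise on both the
    imagined location (key) and the home vector (value). The Q agent
    discretizes position (10 cm cells) and heading (8 directions); its
    replayed updates path integrate the imagined location, so credit can go
    to the wrong cell, but its escape read-out observes the true location.
    """
    from .agent_memory import (
        fuse_continuous,
        path_integrate_continuous,
        retrieve_memory_continuous,
    )

    home = np.array([side / 2, side / 2])
    dirs = 2 * np.pi * np.arange(n_dirs) / n_dirs
    n_cells = int(round(side / q_cell))

    def cell_of(p):
        return (
            int(np.clip(p[0] // q_cell, 0, n_cells - 1)),
            int(np.clip(p[1] // q_cell, 0, n_cells - 1)),
        )

    def clip_step(p, v):
        q = np.clip(p + v, 0.0, side)
        return q

    memory = KeyValueMemory(cutoff=0.05)
    qvals = {}

    def q_get(c, k):
        return qvals.get((c, k), 0.0)

    def q_max(c):
        return max(q_get(c, k) for k in range(n_dirs))

    pos = home.copy()
    offset = np.zeros(2)  # believed home vector (home - agent)
    memory.encode(tuple(pos), tuple(offset), 0.0)
    for t in range(n_explore):
        theta = rng.uniform(0, 2 * np.pi)
        v = step * np.array([np.cos(theta), np.sin(theta)])
        new = clip_step(pos, v)
        actual = new - pos
        if np.linalg.norm(actual) > 1e-9:
            s_pi = path_integrate_continuous(offset, actual, noise, rng)
            if agent == "memory":
                s_m = retrieve_memory_continuous(memory, new)
                offset = fuse_continuous(s_pi, s_m, w, memory, tuple(new))
            else:
                offset = s_pi
        pos = new
        if agent in ("memory", "q") and (t + 1) % replay_every == 0:
            for _ in range(n_replays):
                loc = home.copy()  # imagined location (noisy key)
                val = np.zeros(2)  # imagined home vector (noisy value)
                for _ in range(replay_len):
                    th = rng.uniform(0, 2 * np.pi)
                    sv = step * np.array([np.cos(th), np.sin(th)])
                    val = path_integrate_continuous(val, sv, noise, rng)
                    key_step = -path_integrate_continuous(
                        np.zeros(2), sv, noise, rng
                    )
                    loc = clip_step(loc, key_step)
                    if agent == "memory":
                        memory.encode(tuple(loc), tuple(val), float(t))
                    else:
                        # backward update: credit the direction from the
                        # imagined new location back toward the previous one
                        k = int(np.argmin(np.abs(
                            (np.arctan2(-sv[1], -sv[0]) - dirs + np.pi)
                            % (2 * np.pi) - np.pi
                        )))
                        c = cell_of(loc)
                        prev = cell_of(loc - key_step)
                        r = 1.0 if np.linalg.norm(
                            (np.array(prev) + 0.5) * q_cell - home
                        ) < q_cell else 0.0
                        tgt = r + 0.7 * q_max(prev)
                        qvals[(c, k)] = q_get(c, k) + 0.8 * (tgt - q_get(c, k))
    budget = int(8 * side / step)
    for _ in range(budget):
        if agent == "q":
            c = cell_of(pos)
            if q_max(c) <= 0:
                break
            k = int(np.argmax([q_get(c, kk) for kk in range(n_dirs)]))
            pos = clip_step(pos, step * np.array([np.cos(dirs[k]), np.sin(dirs[k])]))
            if np.linalg.norm(pos - home) < step:
                break
        else:
            if np.linalg.norm(offset) < step / 2:
                break
            v = step * offset / np.linalg.norm(offset)
            new = clip_step(pos, v)
            actual = new - pos
            if np.linalg.norm(actual) > 1e-9:
                s_pi = path_integrate_continuous(offset, actual, noise, rng)
                if agent == "memory":
                    s_m = retrieve_memory_continuous(memory, new)
                    offset = fuse_continuous(s_pi, s_m, w, memory, tuple(new))
                else:
                    offset = s_pi
            pos = new
    return float(np.linalg.norm(pos - home))


def homing_experiment_continuous(
    rng: np.random.Generator = None,
    noise_levels=(0.1, 0.2, 0.4),
    explore_lengths=(16, 32, 64),
    replay_counts=(1, 2, 5),
    n_seeds: int = 8,
) -> pd.DataFrame:
    """Continuous-arena analogue of :func:`homing_experiment`.

    Noise levels set the direction s.d. (radians) of each path-integration
    update; step-size noise is fixed at 20% of the step. Same tidy output
    schema as the discrete experiment, with errors in meters.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for e in noise_levels:
        noise = PathIntegrationNoise(direction_sd=e, step_sd=0.01)
        for n_explore in explore_lengths:
            for agent in ("pi", "memory"):
                for seed in range(n_seeds):
                    err = _run_homing_trial_continuous(
                        agent, noise, n_explore, 5, rng
                    )
                    rows.append(
                        dict(
                            experiment="explore", agent=agent, e_pi=e,
                            n_explore=n_explore, n_replays=5, seed=seed,
                            error=err,
                        )
                    )
        for n_rep in replay_counts:
            for agent in ("memory", "q"):
                for seed in range(n_seeds):
                    err = _run_homing_trial_continuous(
                        agent, noise, explore_lengths[-1], n_rep, rng
                    )
                    rows.append(
                        dict(
                            experiment="replays", agent=agent, e_pi=e,
                            n_explore=explore_lengths[-1], n_replays=n_rep,
                            seed=seed, error=err,
                        )
                    )
    return pd.DataFrame(rows)


def homing_experiment(
    config: dict = None, rng: np.random.Generator = None,
    noise_levels=(0.1, 0.2, 0.4),
    explore_lengths=(16, 32, 64),
    replay_counts=(1, 2, 5, 10),
    n_seeds: int = 10,
    width: int = 9,
    height: int = 9,
) -> pd.DataFrame:
    """Homing error grids for agents {pi, memory, q}.

    Grid 1 (experiment "explore"): noise x exploration length, replay count
    fixed at 5 per bout, agents pi vs memory. Grid 2 (experiment "replays"):
    noise x replay count, exploration length fixed, agents memory vs q.
    Tidy long-format output: (experiment, agent, e_pi, n_explore, n_replays,
    seed, error).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    config = dict(config or {})
    width = int(config.get("width", width))
    height = int(config.get("height", height))
    home = (width // 2, height // 2)
    world = GridWorld(width, height, (), home)
    rows = []
    for e in noise_levels:
        for n_explore in explore_lengths:
            for agent in ("pi", "memory"):
                for seed in range(n_seeds):
                    err = _run_homing_trial(
                        world, home, agent, e, n_explore, 5, rng
                    )
                    rows.append(
                        dict(
                            experiment="explore", agent=agent, e_pi=e,
                            n_explore=n_explore, n_replays=5, seed=seed,
                            error=err,
                        )
                    )
        for n_rep in replay_counts:
            for agent in ("memory", "q"):
                for seed in range(n_seeds):
                    err = _run_homing_trial(
                        world, home, agent, e, explore_lengths[-1], n_rep, rng
                    )
                    rows.append(
                        dict(
                            experiment="replays", agent=agent, e_pi=e,
                            n_explore=explore_lengths[-1], n_replays=n_rep,
                            seed=seed, error=err,
                        )
                    )
    return pd.DataFrame(rows)
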