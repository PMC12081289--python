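"""Supervised policies f(s) = a on traditional vs compositional state codes.

A *traditional* state representation is an absolute location code (one-hot
cell index on grids; a Gaussian place population in arenas) and carries no
information about walls or rewards. A *compositional* representation
concatenates object-vector codes — the reward code first, then two codes per
wall (one per wall end) in environment-generation order — and therefore
transfers across environments. Policies are feedforward networks trained by
supervised learning on ground-truth optimal actions and evaluated by rolling
them out and scoring the fraction of start locations from which they reach
the reward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.neural_network import MLPClassifier, MLPRegressor

from . import environments as env
from .environments import ACTIONS, GridWorld, ContinuousArena, transition
from .representations import (
    VectorPopulation,
    continuous_object_vector,
    discrete_object_vector,
)


@dataclass(frozen=True)
class RepresentationLayout:
    """Fixed concatenation layout shared by all environments of one config.

    Discrete: ``max_dist`` is the one-hot range D-1 (D = max grid side);
    ``n_walls`` slots are always present, each contributing two wall-end
    codes; absent walls are all-zero blocks. ``grid_shape`` sizes the
    traditional one-hot. Continuous uses ``pop`` for every object code and a
    place population for the traditional code.
    """

    mode: str  # "traditional" | "compositional"
    discrete: bool = True
    max_dist: int = 5
    n_walls: int = 0
    grid_shape: tuple = (6, 6)
    pop: VectorPopulation = VectorPopulation()

    @property
    def dim(self) -> int:
        if self.mode == "traditional":
            if self.discrete:
                return self.grid_shape[0] * self.grid_shape[1]
            return len(self.pop)
        block = 4 * (self.max_dist + 2) if self.discrete else len(self.pop)
        return block * (1 + 2 * self.n_walls)


def build_state_representation(world, location, layout: RepresentationLayout):
    """State vector for ``location`` under the layout's mode.

    Compositional codes include only the objects present in ``world``;
    missing wall slots stay all-zero. Raises when the world has more walls
    than the layout provides slots for.
    """
    if layout.mode == "traditional":
        if layout.discrete:
            v = np.zeros(layout.dim)
            if (world.width, world.height) != tuple(layout.grid_shape):
                raise ValueError("world size does not match layout grid_shape")
            v[world.cell_index(location)] = 1.0
            return v
        return continuous_object_vector(
            np.asarray(location) - 0.5 * world.side, (0.0, 0.0), layout.pop
        ).activities
    if layout.discrete:
        blocks = [discrete_object_vector(location, world.reward, world).activities]
        obj_cells = [(w.end_a, w.end_b) for w in world.walls]
    else:
        blocks = [
            continuous_object_vector(location, world.reward, layout.pop).activities
        ]
        obj_cells = [(w[0], w[1]) for w in world.walls]
    if len(obj_cells) > layout.n_walls:
        raise ValueError("more walls than layout slots")
    block_size = blocks[0].size
    for i in range(layout.n_walls):
        if i < len(obj_cells):
            a, b = obj_cells[i]
            if layout.discrete:
                blocks.append(discrete_object_vector(location, a, world).activities)
                blocks.append(discrete_object_vector(location, b, world).activities)
            else:
                blocks.append(
                    continuous_object_vector(location, a, layout.pop).activities
                )
                blocks.append(
                    continuous_object_vector(location, b, layout.pop).activities
                )
        else:
            blocks.append(np.zeros(block_size))
            blocks.append(np.zeros(block_size))
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# training sets
# ---------------------------------------------------------------------------


@dataclass
class TrainingSet:
    X: np.ndarray
    y: np.ndarray  # action index (discrete) or (sin, cos) heading (continuous)
    env_ids: np.ndarray


def sample_training_set(
    worlds, tables, n_per_world: int, layout: RepresentationLayout,
    rng: np.random.Generator,
) -> TrainingSet:
    """(state representation, optimal action) pairs sampled uniformly over
    locations with a defined optimal action."""
    X, y, ids = [], [], []
    for wid, (world, table) in enumerate(zip(worlds, tables)):
        locs = list(table.actions.keys())
        idx = rng.integers(0, len(locs), n_per_world)
        for i in idx:
            loc = locs[i]
            X.append(build_state_representation(world, loc, layout))
            if layout.discrete:
                y.append(ACTIONS.index(table.actions[loc]))
            else:
                hx, hy = table.actions[loc]
                th = np.arctan2(hy, hx)
                y.append([np.sin(th), np.cos(th)])
            ids.append(wid)
    return TrainingSet(np.asarray(X), np.asarray(y), np.asarray(ids))


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolicyNetworkSpec:
    """Feedforward policy: ReLU hidden layers trained with Adam.

    Default hidden dims are 1000/750/500 for discrete and 3000/2000/1000 for
    continuous environments; experiments may scale these down.
    """

    hidden: tuple = (1000, 750, 500)
    discrete: bool = True
    max_iter: int = 200
    tol: float = 1e-5

    @staticmethod
    def continuous_default() -> "PolicyNetworkSpec":
        return PolicyNetworkSpec(hidden=(3000, 2000, 1000), discrete=False)


def train_policy_network(
    ts: TrainingSet, spec: PolicyNetworkSpec, rng: np.random.Generator
):
    """Fit the policy network; seeded, hence reproducible run-to-run."""
    if ts.X.size == 0:
        raise ValueError("empty training set")
    seed = int(rng.integers(2**31 - 1))
    if spec.discrete:
        net = MLPClassifier(
            hidden_layer_sizes=spec.hidden,
            activation="relu",
            solver="adam",
            max_iter=spec.max_iter,
            tol=spec.tol,
            random_state=seed,
        )
    else:
        net = MLPRegressor(
            hidden_layer_sizes=spec.hidden,
            activation="relu",
            solver="adam",
            max_iter=spec.max_iter,
            tol=spec.tol,
            random_state=seed,
        )
    net.fit(ts.X, ts.y)
    if not np.all(np.isfinite(net.loss_curve_)):
        raise RuntimeError("policy training diverged (non-finite loss)")
    return net


def policy_action(net, world, location, layout: RepresentationLayout):
    """Greedy action of the trained network at one location."""
    s = build_state_representation(world, location, layout)[None, :]
    if layout.discrete:
        probs = net.predict_proba(s)[0]
        return ACTIONS[int(np.argmax(probs))]
    sin_cos = net.predict(s)[0]
    return float(np.arctan2(sin_cos[0], sin_cos[1]))


def rollout_budget(optimal_steps: float, factor: int = 4, minimum: int = 30) -> int:
    return max(minimum, int(np.ceil(factor * optimal_steps)))


def evaluate_policy(net, world, starts, layout: RepresentationLayout,
                    table=None) -> float:
    """Fraction of start locations from which the greedy policy reaches the
    reward (within 5 cm in arenas) inside the rollout budget."""
    if table is None:
        table = (
            env.optimal_policy(world)
            if layout.discrete
            else env.optimal_policy_continuous(world)
        )
    successes = 0
    for start in starts:
        if layout.discrete:
            budget = rollout_budget(table.distance.get(tuple(start), 10))
            loc = tuple(start)
            for _ in range(budget):
                if loc == world.reward:
                    break
                loc = transition(world, loc, policy_action(net, world, loc, layout))
            successes += loc == world.reward
        else:
            node = env.nearest_policy_node(table, start)
            budget = rollout_budget(table.distance[node] / world.step_size)
            p = np.asarray(start, dtype=float)
            ok = False
            for _ in range(budget):
                if np.linalg.norm(p - np.asarray(world.reward)) <= 0.05:
                    ok = True
                    break
                heading = policy_action(net, world, p, layout)
                p = np.asarray(env.transition_continuous(world, p, heading))
            ok = ok or np.linalg.norm(p - np.asarray(world.reward)) <= 0.05
            successes += ok
    return successes / max(len(starts), 1)


def random_policy_success(world, starts, rng: np.random.Generator) -> float:
    """Monte-Carlo baseline: uniform-random action rollouts, same budget."""
    table = env.optimal_policy(world)
    successes = 0
    for start in starts:
        budget = rollout_budget(table.distance.get(tuple(start), 10))
        loc = tuple(start)
        for _ in range(budget):
            if loc == world.reward:
                break
            loc = transition(world, loc, ACTIONS[int(rng.integers(4))])
        successes += loc == world.reward
    return successes / max(len(starts), 1)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def single_environment_protocol(
    world_config: dict,
    layout: RepresentationLayout,
    spec: PolicyNetworkSpec,
    rng: np.random.Generator,
    n_samples: int = 1000,
    n_test_locations: int = 25,
):
    """Train and test on the same environment (1000 discrete samples)."""
    world = env.sample_gridworld(world_config, rng)
    table = env.optimal_policy(world)
    ts = sample_training_set([world], [table], n_samples, layout, rng)
    net = train_policy_network(ts, spec, rng)
    locs = list(table.actions.keys())
    starts = [locs[i] for i in rng.integers(0, len(locs), n_test_locations)]
    return evaluate_policy(net, world, starts, layout, table)


def multi_environment_protocol(
    world_config: dict,
    layout: RepresentationLayout,
    spec: PolicyNetworkSpec,
    rng: np.random.Generator,
    n_envs: int = 25,
    n_per_env: int = 200,
    n_rounds: int = 100,
    n_test_envs: int = 25,
    n_test_locations: int = 20,
):
    """Train across many environments, test on held-out ones.

    Each round samples ``n_envs`` fresh environments and ``n_per_env``
    (state, action) pairs from each; all rounds are pooled into one
    supervised fit. Returns (success on unseen envs, random baseline).
    """
    chunks = []
    for _ in range(n_rounds):
        worlds = [env.sample_gridworld(world_config, rng) for _ in range(n_envs)]
        tables = [env.optimal_policy(w) for w in worlds]
        chunks.append(sample_training_set(worlds, tables, n_per_env, layout, rng))
    ts = TrainingSet(
        np.concatenate([c.X for c in chunks]),
        np.concatenate([c.y for c in chunks]),
        np.concatenate([c.env_ids for c in chunks]),
    )
    net = train_policy_network(ts, spec, rng)
    succ, base = [], []
    for _ in range(n_test_envs):
        world = env.sample_gridworld(world_config, rng)
        table = env.optimal_policy(world)
        locs = list(table.actions.keys())
        starts = [locs[i] for i in rng.integers(0, len(locs), n_test_locations)]
        succ.append(evaluate_policy(net, world, starts, layout, table))
        base.append(random_policy_success(world, starts, rng))
    return float(np.mean(succ)), float(np.mean(base)), succ, base


# ---------------------------------------------------------------------------
# latent learning
# ---------------------------------------------------------------------------


def _behind_wall_states(world: GridWorld) -> list:
    """States whose optimal distance or action changes when walls are removed."""
    bare = GridWorld(world.width, world.height, (), world.reward)
    with_table = env.optimal_policy(world)
    bare_table = env.optimal_policy(bare)
    out = []
    for cell in world.cells():
        if cell == world.reward or cell not in with_table.distance:
            continue
        if with_table.distance[cell] != bare_table.distance[cell]:
            out.append(cell)
    return out


def _plan_success(world: GridWorld, start, known_walls) -> bool:
    """Can a planner that only knows ``known_walls`` reach the reward?

    Actions come from the optimal policy of the *believed* world; rollouts
    run in the true world, so planning through an unknown wall stalls.
    """
    believed = GridWorld(world.width, world.height, tuple(known_walls), world.reward)
    table = env.optimal_policy(believed)
    if start not in table.actions and start != world.reward:
        return False
    true_table = env.optimal_policy(world)
    budget = rollout_budget(true_table.distance.get(start, 10))
    loc = start
    for _ in range(budget):
        if loc == world.reward:
            return True
        a = table.actions.get(loc)
        if a is None:
            return False
        loc = transition(world, loc, a)
    return loc == world.reward


def latent_learning_experiment(
    config: dict = None, rng: np.random.Generator = None,
    n_worlds: int = 25, n_encounters: int = 15, n_steps: int = 2000,
):
    """Success at behind-wall states by encounter count, latent vs non-latent.

    Both agents have just found the reward (and track its vector perfectly).
    The latent agent already carries the wall representation from unrewarded
    exploration; the non-latent agent must rediscover the wall (stand on a
    cell adjacent to it) before the wall enters its state representation.
    Returns two (n_encounters,) curves averaged over worlds.
    """
    config = dict(config or {"width": 6, "height": 6, "n_walls": 1})
    rng = rng if rng is not None else np.random.default_rng(0)
    latent_curve = np.zeros(n_encounters)
    nonlatent_curve = np.zeros(n_encounters)
    counts = np.zeros(n_encounters)
    for _ in range(n_worlds):
        world = env.sample_gridworld(config, rng)
        targets = _behind_wall_states(world)
        if not targets:
            continue
        wall_cells = {c for w in world.walls for e in w.edges for c in e}
        loc = (int(rng.integers(world.width)), int(rng.integers(world.height)))
        wall_known = False
        encounter = {t: 0 for t in targets}
        lat = np.zeros(n_encounters)
        non = np.zeros(n_encounters)
        cnt = np.zeros(n_encounters)
        for _ in range(n_steps):
            loc = transition(world, loc, ACTIONS[int(rng.integers(4))])
            if loc in wall_cells:
                wall_known = True
            if loc in encounter and encounter[loc] < n_encounters:
                k = encounter[loc]
                encounter[loc] += 1
                lat[k] += _plan_success(world, loc, world.walls)
                non[k] += _plan_success(
                    world, loc, world.walls if wall_known else ()
                )
                cnt[k] += 1
        mask = cnt > 0
        latent_curve[mask] += lat[mask] / cnt[mask]
        nonlatent_curve[mask] += non[mask] / cnt[mask]
        counts[mask] += 1
    counts = np.maximum(counts, 1)
    return latent_curve / counts, nonlatent_curve / counts
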