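"""Deterministic MDP worlds: discrete square grids and continuous square arenas.

Worlds carry randomly placed walls and a single reward. Discrete walls are
blocked *edges* between adjacent cells (never filled cells); each wall keeps
its two end cells so that downstream vector-cell populations can anchor one
population on each wall end. Continuous walls are line segments inside a
1 m x 1 m arena.

Coordinates: discrete cells are 0-based ``(col, row)`` with the origin at the
southwest corner; continuous coordinates are meters with the same origin.
Actions are ordered ``north, east, south, west``; in continuous worlds an
action is a heading angle and every step advances ``step_size`` meters.
Blocked moves (into a wall or out of the arena) are no-ops.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

ACTIONS = ("north", "east", "south", "west")
#: displacement of each action on the grid, (dcol, drow)
ACTION_VECTORS = {
    "north": (0, 1),
    "east": (1, 0),
    "south": (0, -1),
    "west": (-1, 0),
}

Cell = tuple[int, int]
Edge = frozenset  # frozenset of two adjacent cells


class WorldSamplingError(RuntimeError):
    """Raised when no solvable world is found within the attempt budget."""


# ---------------------------------------------------------------------------
# discrete worlds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Wall:
    """A straight barrier of blocked edges with its two end cells.

    ``end_a`` / ``end_b`` are the cells adjacent to either end of the
    barrier (on the side of the first cell of each blocked edge); they feed
    the two wall-end vector populations.
    """

    edges: tuple[Edge, ...]
    end_a: Cell
    end_b: Cell


@dataclass(frozen=True)
class GridWorld:
    width: int
    height: int
    walls: tuple[Wall, ...]
    reward: Cell

    @property
    def blocked_edges(self) -> frozenset:
        return frozenset(e for w in self.walls for e in w.edges)

    def cells(self) -> list[Cell]:
        return [(c, r) for r in range(self.height) for c in range(self.width)]

    def in_bounds(self, cell: Cell) -> bool:
        c, r = cell
        return 0 <= c < self.width and 0 <= r < self.height

    def cell_index(self, cell: Cell) -> int:
        return cell[1] * self.width + cell[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "width": self.width,
                "height": self.height,
                "reward": list(self.reward),
                "walls": [
                    {
                        "edges": [sorted(map(list, e)) for e in w.edges],
                        "end_a": list(w.end_a),
                        "end_b": list(w.end_b),
                    }
                    for w in self.walls
                ],
            }
        )

    @staticmethod
    def from_json(doc: str) -> "GridWorld":
        d = json.loads(doc)
        walls = tuple(
            Wall(
                edges=tuple(
                    frozenset((tuple(a), tuple(b))) for a, b in w["edges"]
                ),
                end_a=tuple(w["end_a"]),
                end_b=tuple(w["end_b"]),
            )
            for w in d["walls"]
        )
        return GridWorld(d["width"], d["height"], walls, tuple(d["reward"]))


def transition(world: GridWorld, location: Cell, action: str) -> Cell:
    """Deterministic grid transition; blocked or out-of-bounds moves are no-ops."""
    if action not in ACTION_VECTORS:
        raise ValueError(f"invalid action {action!r}")
    if not world.in_bounds(location):
        raise ValueError(f"location {location} outside world")
    dc, dr = ACTION_VECTORS[action]
    nxt = (location[0] + dc, location[1] + dr)
    if not world.in_bounds(nxt):
        return location
    if frozenset((location, nxt)) in world.blocked_edges:
        return location
    return nxt


def _grid_adjacency(world: GridWorld):
    n = world.width * world.height
    rows, cols = [], []
    blocked = world.blocked_edges
    for cell in world.cells():
        for a in ACTIONS:
            dc, dr = ACTION_VECTORS[a]
            nxt = (cell[0] + dc, cell[1] + dr)
            if world.in_bounds(nxt) and frozenset((cell, nxt)) not in blocked:
                rows.append(world.cell_index(cell))
                cols.append(world.cell_index(nxt))
    data = np.ones(len(rows))
    return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def reward_connected(world: GridWorld) -> bool:
    """True iff every cell can reach the reward (breadth-first over open edges)."""
    adj = _grid_adjacency(world)
    dist = dijkstra(adj, indices=world.cell_index(world.reward), unweighted=True)
    return bool(np.all(np.isfinite(dist)))


@dataclass(frozen=True)
class PolicyTable:
    """Ground-truth optimal policy: per-location best action and distance to reward.

    Discrete tables map cells to action names; continuous tables hold a unit
    heading per node of a fine discretization. Unreachable locations are
    excluded and reported in ``unreachable``.
    """

    actions: dict
    distance: dict
    unreachable: tuple = ()


def optimal_policy(world: GridWorld) -> PolicyTable:
    """Shortest-path policy (fewest steps to reward), ties broken by action order."""
    adj = _grid_adjacency(world)
    dist = dijkstra(adj, indices=world.cell_index(world.reward), unweighted=True)
    actions, distance, unreachable = {}, {}, []
    for cell in world.cells():
        d = dist[world.cell_index(cell)]
        if not np.isfinite(d):
            unreachable.append(cell)
            continue
        distance[cell] = int(d)
        if cell == world.reward:
            continue
        for a in ACTIONS:
            nxt = transition(world, cell, a)
            if nxt != cell and dist[world.cell_index(nxt)] == d - 1:
                actions[cell] = a
                break
    return PolicyTable(actions, distance, tuple(unreachable))


def _sample_wall(width: int, height: int, rng: np.random.Generator) -> Wall:
    """A straight run of blocked edges between two grid rows or columns."""
    horizontal = bool(rng.integers(2))  # barrier along east-west line
    if horizontal:
        r = int(rng.integers(0, height - 1))  # blocks (c,r)-(c,r+1)
        length = int(rng.integers(1, max(2, width // 2) + 1))
        c0 = int(rng.integers(0, width - length + 1))
        edges = tuple(
            frozenset(((c, r), (c, r + 1))) for c in range(c0, c0 + length)
        )
        end_a, end_b = (c0, r), (c0 + length - 1, r)
    else:
        c = int(rng.integers(0, width - 1))
        length = int(rng.integers(1, max(2, height // 2) + 1))
        r0 = int(rng.integers(0, height - length + 1))
        edges = tuple(
            frozenset(((c, r), (c + 1, r))) for r in range(r0, r0 + length)
        )
        end_a, end_b = (c, r0), (c, r0 + length - 1)
    return Wall(edges, end_a, end_b)


def sample_gridworld(
    config: dict, rng: np.random.Generator, max_attempts: int = 200
) -> GridWorld:
    """Sample a grid world with random walls and reward, kept fully connected.

    ``config`` keys: ``width``, ``height`` (>= 2), ``n_walls`` (default 0),
    ``reward`` (optional fixed cell; otherwise sampled uniformly).
    """
    width, height = int(config["width"]), int(config["height"])
    if width < 2 or height < 2:
        raise ValueError("grid must be at least 2x2")
    n_walls = int(config.get("n_walls", 0))
    for _ in range(max_attempts):
        if "reward" in config and config["reward"] is not None:
            reward = tuple(config["reward"])
        else:
            reward = (int(rng.integers(width)), int(rng.integers(height)))
        walls = tuple(_sample_wall(width, height, rng) for _ in range(n_walls))
        world = GridWorld(width, height, walls, reward)
        if reward_connected(world):
            return world
    raise WorldSamplingError(
        f"no connected world in {max_attempts} attempts (over-constrained config?)"
    )


# ---------------------------------------------------------------------------
# continuous arenas
# ---------------------------------------------------------------------------


def _segments_intersect(p1, p2, q1, q2) -> bool:
    """Proper/improper intersection of segments p1-p2 and q1-q2."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(v) < 1e-12:
            return 0
        return 1 if v > 0 else -1

    def on_seg(a, b, c):
        return (
            min(a[0], b[0]) - 1e-12 <= c[0] <= max(a[0], b[0]) + 1e-12
            and min(a[1], b[1]) - 1e-12 <= c[1] <= max(a[1], b[1]) + 1e-12
        )

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    if o1 != o2 and o3 != o4:
        return True
    if o1 == 0 and on_seg(p1, p2, q1):
        return True
    if o2 == 0 and on_seg(p1, p2, q2):
        return True
    if o3 == 0 and on_seg(q1, q2, p1):
        return True
    if o4 == 0 and on_seg(q1, q2, p2):
        return True
    return False


@dataclass(frozen=True)
class ContinuousArena:
    """Square arena of ``side`` meters with line-segment walls and a point reward."""

    side: float = 1.0
    walls: tuple = ()  # tuples ((x1,y1),(x2,y2))
    reward: tuple = (0.5, 0.5)
    contact_radius: float = 0.05
    step_size: float = 0.05

    def in_bounds(self, p) -> bool:
        return 0.0 <= p[0] <= self.side and 0.0 <= p[1] <= self.side

    def move_blocked(self, p, q) -> bool:
        if not self.in_bounds(q):
            return True
        return any(_segments_intersect(p, q, w[0], w[1]) for w in self.walls)

    def to_json(self) -> str:
        return json.dumps(
            {
                "side": self.side,
                "reward": list(self.reward),
                "walls": [[list(a), list(b)] for a, b in self.walls],
                "contact_radius": self.contact_radius,
                "step_size": self.step_size,
            }
        )

    @staticmethod
    def from_json(doc: str) -> "ContinuousArena":
        d = json.loads(doc)
        return ContinuousArena(
            side=d["side"],
            walls=tuple((tuple(a), tuple(b)) for a, b in d["walls"]),
            reward=tuple(d["reward"]),
            contact_radius=d["contact_radius"],
            step_size=d["step_size"],
        )


def transition_continuous(
    arena: ContinuousArena, location, heading: float
):
    """Advance one step of ``step_size`` along ``heading`` (radians); blocked
    moves (wall crossing or leaving the arena) are no-ops."""
    p = np.asarray(location, dtype=float)
    q = p + arena.step_size * np.array([np.cos(heading), np.sin(heading)])
    if arena.move_blocked(tuple(p), tuple(q)):
        return tuple(p)
    return tuple(q)


def sample_arena(
    config: dict, rng: np.random.Generator, max_attempts: int = 200
) -> ContinuousArena:
    """Sample a 1 m x 1 m arena with random wall segments and reward.

    ``config`` keys: ``n_walls`` (default 0), ``wall_length`` (default 0.4 m),
    ``reward`` (optional fixed coordinate).
    """
    n_walls = int(config.get("n_walls", 0))
    wall_length = float(config.get("wall_length", 0.4))
    side = float(config.get("side", 1.0))
    for _ in range(max_attempts):
        walls = []
        for _ in range(n_walls):
            for _ in range(100):
                c = rng.uniform(0.15, side - 0.15, 2)
                th = rng.uniform(0, np.pi)
                h = 0.5 * wall_length * np.array([np.cos(th), np.sin(th)])
                a, b = c - h, c + h
                if (0 <= a).all() and (a <= side).all() and (0 <= b).all() and (b <= side).all():
                    walls.append((tuple(a), tuple(b)))
                    break
        if "reward" in config and config["reward"] is not None:
            reward = tuple(config["reward"])
        else:
            reward = tuple(rng.uniform(0.1, side - 0.1, 2))
        arena = ContinuousArena(side=side, walls=tuple(walls), reward=reward)
        # reachability on the fine discretization used for the optimal policy
        table = optimal_policy_continuous(arena)
        if len(table.unreachable) == 0:
            return arena
    raise WorldSamplingError(
        f"no solvable arena in {max_attempts} attempts (over-constrained config?)"
    )


def optimal_policy_continuous(
    arena: ContinuousArena, resolution: float = 0.025
) -> PolicyTable:
    """Shortest obstacle-avoiding paths on a fine 8-connected discretization.

    Returns per-node unit headings toward reward and metric distances. The
    grid spacing (default 2.5 cm) is finer than the agent step (5 cm).
    """
    n = int(round(arena.side / resolution))
    centers = (np.arange(n) + 0.5) * resolution
    nodes = [(x, y) for y in centers for x in centers]

    def idx(i, j):
        return j * n + i

    rows, cols, data = [], [], []
    moves = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for j in range(n):
        for i in range(n):
            p = (centers[i], centers[j])
            for di, dj in moves:
                ii, jj = i + di, j + dj
                if not (0 <= ii < n and 0 <= jj < n):
                    continue
                q = (centers[ii], centers[jj])
                if any(
                    _segments_intersect(p, q, w[0], w[1]) for w in arena.walls
                ):
                    continue
                rows.append(idx(i, j))
                cols.append(idx(ii, jj))
                data.append(np.hypot(q[0] - p[0], q[1] - p[1]))
    adj = coo_matrix((data, (rows, cols)), shape=(n * n, n * n)).tocsr()
    ri = int(np.clip(arena.reward[0] / resolution, 0, n - 1))
    rj = int(np.clip(arena.reward[1] / resolution, 0, n - 1))
    dist, pred = dijkstra(
        adj, indices=idx(ri, rj), return_predecessors=True
    )
    actions, distance, unreachable = {}, {}, []
    for j in range(n):
        for i in range(n):
            k = idx(i, j)
            node = (centers[i], centers[j])
            if not np.isfinite(dist[k]):
                unreachable.append(node)
                continue
            distance[node] = float(dist[k])
            if k == idx(ri, rj) or pred[k] < 0:
                # at reward: head straight in
                v = np.array(arena.reward) - np.array(node)
                nv = np.linalg.norm(v)
                actions[node] = tuple(v / nv) if nv > 1e-9 else (1.0, 0.0)
                continue
            p = pred[k]
            tgt = np.array([centers[p % n], centers[p // n]])
            v = tgt - np.array(node)
            actions[node] = tuple(v / np.linalg.norm(v))
    return PolicyTable(actions, distance, tuple(unreachable))


def nearest_policy_node(table: PolicyTable, p):
    """Closest discretization node of a continuous policy table to point p."""
    nodes = np.array(list(table.distance.keys()))
    d = np.linalg.norm(nodes - np.asarray(p), axis=1)
    return tuple(nodes[int(np.argmin(d))])
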