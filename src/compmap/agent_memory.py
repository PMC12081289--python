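"""Online tracking of object-vector representations.

The agent discovers objects by contact, then keeps each object's vector
relation up to date by combining two sources on every transition:

* noisy path integration of the previous relation given the action taken, and
* retrieval of relations previously stored in a key-value memory, indexed by
  the observed location.

Discrete relations are integer offsets (dx, dy) to the object; continuous
relations are 2D vectors in meters. The fused estimate is re-encoded into
memory at the new location, so memory both stabilizes tracking and
accumulates a latent map of the environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environments import ACTION_VECTORS

NO_MEMORY = None  # explicit "no memory retrieved" marker


@dataclass
class MemoryEntry:
    key: object  # cell id (discrete) or 2D coordinate (continuous)
    value: object  # offset tuple / 2D vector
    time: float
    origin: str = "behavior"  # "behavior" | "replay"


@dataclass
class KeyValueMemory:
    """Append-only location-indexed store of vector relations.

    Continuous retrieval only considers entries within ``cutoff`` (5 cm) of
    the query location; discrete retrieval requires an exact key match.
    """

    cutoff: float = 0.05
    entries: list = field(default_factory=list)
    read_count: int = 0

    def encode(self, key, value, time: float = 0.0, origin: str = "behavior"):
        self.entries.append(MemoryEntry(key, value, time, origin))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "key": [e.key for e in self.entries],
                "value": [e.value for e in self.entries],
                "time": [e.time for e in self.entries],
                "origin": [e.origin for e in self.entries],
            }
        )


@dataclass(frozen=True)
class PathIntegrationNoise:
    """Discrete: wrong-neighbor probability e_pi. Continuous: s.d. of Gaussian
    noise on the direction (radians) and step size (meters) of each update."""

    e_pi: float = 0.0
    direction_sd: float = 0.0
    step_sd: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.e_pi <= 1.0:
            raise ValueError("e_pi must be in [0, 1]")
        if self.direction_sd < 0 or self.step_sd < 0:
            raise ValueError("noise s.d. must be nonnegative")


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------


def discover_object_discrete(agent_cell, object_cell):
    """Initialize a relation on discovery of an adjacent object.

    The initialized relation is the true (object - agent) offset: the zero
    offset when the agent stands on the object (the all-zero-distance code),
    a unit offset when adjacent. Discovery requires Chebyshev distance <= 1;
    anything farther is out of range and raises.
    """
    dx = object_cell[0] - agent_cell[0]
    dy = object_cell[1] - agent_cell[1]
    if max(abs(dx), abs(dy)) > 1:
        raise ValueError("discrete discovery requires an adjacent location")
    return (dx, dy)


def discover_object_continuous(agent_pos, object_pos, radius: float = 0.05):
    """Initialize the vector relation when the object comes in range (5 cm)."""
    offset = np.asarray(object_pos, float) - np.asarray(agent_pos, float)
    if np.linalg.norm(offset) > radius:
        raise ValueError("continuous discovery requires range <= 5 cm")
    return offset


# ---------------------------------------------------------------------------
# path integration
# ---------------------------------------------------------------------------

_NEIGHBOR_STEPS = [(0, 1), (1, 0), (0, -1), (-1, 0)]


def path_integrate_discrete(offset, action: str, noise: PathIntegrationNoise):
    """Distribution p_PI over the updated relation.

    The correct update (offset minus the action step) carries probability
    1 - e_pi; each of its four action-adjacent neighbors carries e_pi / 4.
    Returns a dict offset -> probability (normalized).
    """
    dc, dr = ACTION_VECTORS[action]
    correct = (offset[0] - dc, offset[1] - dr)
    p = {correct: 1.0 - noise.e_pi}
    if noise.e_pi > 0:
        for sc, sr in _NEIGHBOR_STEPS:
            nb = (correct[0] + sc, correct[1] + sr)
            p[nb] = p.get(nb, 0.0) + noise.e_pi / 4.0
    total = sum(p.values())
    return {k: v / total for k, v in p.items()}


def path_integrate_continuous(
    offset, step, noise: PathIntegrationNoise, rng: np.random.Generator
):
    """Noisy continuous update s_PI = offset - noisy(step).

    Gaussian noise perturbs the direction and magnitude of the step
    independently; with zero noise the update is exact, and across draws the
    update is unbiased in direction.
    """
    step = np.asarray(step, dtype=float)
    mag = np.linalg.norm(step)
    if mag == 0.0:
        return np.asarray(offset, dtype=float).copy()
    theta = np.arctan2(step[1], step[0]) + rng.normal(0.0, noise.direction_sd)
    mag = mag + rng.normal(0.0, noise.step_sd)
    noisy = mag * np.array([np.cos(theta), np.sin(theta)])
    return np.asarray(offset, dtype=float) - noisy


# ---------------------------------------------------------------------------
# retrieval and fusion
# ---------------------------------------------------------------------------


def retrieve_memory_discrete(memory: KeyValueMemory, location):
    """p_M over stored relations at this key, proportional to retrieval counts.

    Returns NO_MEMORY when nothing is stored at the key.
    """
    memory.read_count += 1
    values = [e.value for e in memory.entries if e.key == location]
    if not values:
        return NO_MEMORY
    p = {}
    for v in values:
        p[v] = p.get(v, 0.0) + 1.0
    total = sum(p.values())
    return {k: v / total for k, v in p.items()}


def retrieve_memory_continuous(
    memory: KeyValueMemory, location, temperature: float = 1.0
):
    """Softmax-weighted combination of relations stored within the cutoff.

    Weights are a softmax over cosine similarities between each memory's
    location and the query location. Returns NO_MEMORY when no entry lies
    within the cutoff.
    """
    memory.read_count += 1
    loc = np.asarray(location, dtype=float)
    keys, vals = [], []
    for e in memory.entries:
        k = np.asarray(e.key, dtype=float)
        if np.linalg.norm(k - loc) <= memory.cutoff:
            keys.append(k)
            vals.append(np.asarray(e.value, dtype=float))
    if not vals:
        return NO_MEMORY
    sims = []
    nl = np.linalg.norm(loc)
    for k in keys:
        nk = np.linalg.norm(k)
        if nl < 1e-12 or nk < 1e-12:
            sims.append(1.0)
        else:
            sims.append(float(np.dot(k, loc) / (nk * nl)))
    sims = np.asarray(sims) / temperature
    w = np.exp(sims - sims.max())
    w /= w.sum()
    return np.sum(w[:, None] * np.asarray(vals), axis=0)


def fuse_discrete(
    p_pi: dict,
    p_m,
    w: float,
    rng: np.random.Generator,
    memory: KeyValueMemory = None,
    new_location=None,
    time: float = 0.0,
):
    """Sample s ~ w * p_PI + (1 - w) * p_M and encode it at the new location.

    With no retrieved memory the mixture degenerates to path integration.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("fusion weight w must be in [0, 1]")
    if p_pi is None and p_m is NO_MEMORY:
        raise ValueError("both fusion sources empty")
    if p_m is NO_MEMORY:
        mix = dict(p_pi)
    elif p_pi is None:
        mix = dict(p_m)
    else:
        mix = {k: w * v for k, v in p_pi.items()}
        for k, v in p_m.items():
            mix[k] = mix.get(k, 0.0) + (1.0 - w) * v
    keys = list(mix.keys())
    probs = np.array([mix[k] for k in keys])
    probs /= probs.sum()
    s = keys[int(rng.choice(len(keys), p=probs))]
    if memory is not None and new_location is not None:
        memory.encode(new_location, s, time)
    return s


def fuse_continuous(
    s_pi,
    s_m,
    w: float,
    memory: KeyValueMemory = None,
    new_location=None,
    time: float = 0.0,
):
    """s = w * s_PI + (1 - w) * s_M, encoded at the new location."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("fusion weight w must be in [0, 1]")
    if s_pi is None and s_m is NO_MEMORY:
        raise ValueError("both fusion sources empty")
    if s_m is NO_MEMORY:
        s = np.asarray(s_pi, dtype=float)
    elif s_pi is None:
        s = np.asarray(s_m, dtype=float)
    else:
        s = w * np.asarray(s_pi, float) + (1.0 - w) * np.asarray(s_m, float)
    if memory is not None and new_location is not None:
        memory.encode(tuple(np.asarray(new_location, float)), tuple(s), time)
    return s


def sample_discrete(p: dict, rng: np.random.Generator):
    """Draw one relation from a discrete distribution over offsets."""
    keys = list(p.keys())
    probs = np.array([p[k] for k in keys])
    probs /= probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]
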