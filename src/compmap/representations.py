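"""Building-block population codes and their conjunctions.

Discrete object-vector codes concatenate, in the fixed action order
(north, east, south, west), one-hot encodings of the signed distance from the
agent's location to the object along each action; any action pointing away
from the object is encoded as distance -1 regardless of magnitude. Continuous
object-vector codes are populations of 2D Gaussian fields whose preferred
vectors tile a square grid centered on the object. Conjunctions are outer
products: every pair of parent cells contributes one product cell, which is
how hippocampal landmark/place responses are modeled downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environments import ACTIONS

# ---------------------------------------------------------------------------
# discrete codes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscreteVectorCode:
    """Four one-hot blocks of signed distance, one per action.

    Each block has ``max_dist + 2`` entries covering distances -1 .. max_dist.
    Exactly one entry per block is active.
    """

    activities: np.ndarray
    max_dist: int

    @property
    def block_size(self) -> int:
        return self.max_dist + 2

    def __len__(self) -> int:
        return self.activities.size


def _onehot(dist: int, max_dist: int) -> np.ndarray:
    if dist < -1 or dist > max_dist:
        raise ValueError(f"distance {dist} outside one-hot range -1..{max_dist}")
    v = np.zeros(max_dist + 2)
    v[dist + 1] = 1.0
    return v


def encode_offset(dx: int, dy: int, max_dist: int) -> DiscreteVectorCode:
    """Encode the offset (object - location) = (dx, dy) as a vector code."""
    per_action = {
        "north": dy if dy > 0 else (0 if dy == 0 else -1),
        "east": dx if dx > 0 else (0 if dx == 0 else -1),
        "south": -dy if dy < 0 else (0 if dy == 0 else -1),
        "west": -dx if dx < 0 else (0 if dx == 0 else -1),
    }
    blocks = [_onehot(per_action[a], max_dist) for a in ACTIONS]
    return DiscreteVectorCode(np.concatenate(blocks), max_dist)


def decode_offset(code: DiscreteVectorCode) -> tuple[int, int]:
    """Recover (dx, dy) from a discrete vector code (inverse of encode_offset)."""
    b = code.block_size
    dists = []
    for i in range(4):
        block = code.activities[i * b : (i + 1) * b]
        (idx,) = np.nonzero(block)
        dists.append(int(idx[0]) - 1)
    north, east, south, west = dists
    dy = north if north >= 0 and south == -1 else (0 if north == 0 else -south)
    dx = east if east >= 0 and west == -1 else (0 if east == 0 else -west)
    # dy/dx zero case: both opposing blocks show 0
    if north == 0 and south == 0:
        dy = 0
    if east == 0 and west == 0:
        dx = 0
    return dx, dy


def discrete_object_vector(x, o, world) -> DiscreteVectorCode:
    """Vector code for object cell ``o`` seen from location cell ``x``."""
    max_dist = max(world.width, world.height) - 1
    return encode_offset(o[0] - x[0], o[1] - x[1], max_dist)


# ---------------------------------------------------------------------------
# continuous codes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VectorPopulation:
    """Preferred vectors on a square grid centered on the object.

    Defaults: grid spans +-1 m at 10 cm spacing, isotropic Gaussian fields of
    5 cm width.
    """

    extent: float = 1.0
    spacing: float = 0.1
    width: float = 0.05

    @property
    def preferred(self) -> np.ndarray:
        g = np.arange(-self.extent, self.extent + self.spacing / 2, self.spacing)
        xx, yy = np.meshgrid(g, g, indexing="xy")
        return np.column_stack([xx.ravel(), yy.ravel()])

    def __len__(self) -> int:
        n = int(round(2 * self.extent / self.spacing)) + 1
        return n * n


@dataclass(frozen=True)
class ContinuousVectorCode:
    activities: np.ndarray
    pop: VectorPopulation

    def __len__(self) -> int:
        return self.activities.size

    @property
    def all_near_zero(self) -> bool:
        """True when the offset falls outside the population's coverage."""
        return bool(self.activities.max(initial=0.0) < 1e-6)


def evaluate_population(pop: VectorPopulation, offset) -> np.ndarray:
    d2 = np.sum((pop.preferred - np.asarray(offset)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * pop.width**2))


def continuous_object_vector(x, o, pop: VectorPopulation) -> ContinuousVectorCode:
    """Population activity for location ``x`` relative to object ``o``:
    the Gaussian population centered on ``o`` evaluated at ``x``."""
    offset = np.asarray(o, dtype=float) - np.asarray(x, dtype=float)
    return ContinuousVectorCode(evaluate_population(pop, offset), pop)


def decode_continuous_offset(code: ContinuousVectorCode) -> np.ndarray:
    """Preferred vector of the maximally active cell."""
    return code.pop.preferred[int(np.argmax(code.activities))]


# ---------------------------------------------------------------------------
# conjunctions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConjunctiveCode:
    """All pairwise products of two parent codes (outer product, flattened).

    Cell (i, j) of the conjunction equals a_i * b_j; ``parents[k]`` recovers
    (i, j) for flattened cell k.
    """

    activities: np.ndarray
    shape: tuple[int, int]

    def parents(self, k: int) -> tuple[int, int]:
        return divmod(k, self.shape[1])

    def __len__(self) -> int:
        return self.activities.size


def conjunction(a: np.ndarray, b: np.ndarray) -> ConjunctiveCode:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("conjunction of an empty parent code")
    return ConjunctiveCode(np.outer(a, b).ravel(), (a.size, b.size))


# ---------------------------------------------------------------------------
# rate-map conjunctions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinnedMap:
    """Dense 2D rate map with bin metadata (bin size, origin).

    ``values[j, i]`` is the rate in the bin whose center is
    ``origin + bin_size * (i + 0.5, j + 0.5)``.
    """

    values: np.ndarray
    bin_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def same_binning(self, other: "BinnedMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.bin_size, other.bin_size)
            and np.allclose(self.origin, other.origin)
        )


def ratemap_conjunction(map_a: BinnedMap, map_b: BinnedMap) -> BinnedMap:
    """Elementwise product of two rate maps on identical binning.

    The product vanishes wherever either parent is silent, which is what
    turns an object-vector map (a field at every object) times a grid map
    into a landmark map responding at only some objects.
    """
    if not map_a.same_binning(map_b):
        raise ValueError("rate maps have mismatched binning")
    return BinnedMap(map_a.values * map_b.values, map_a.bin_size, map_a.origin)
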