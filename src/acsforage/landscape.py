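"""Clustered resource landscapes on a torus.

The landscape is a square of side ``L`` with periodic (toroidal) boundaries,
holding ``k`` circular resource clusters of radius ``g``.  Cluster centers
("parent points") are placed uniformly at random subject to a minimum pairwise
separation of ``3 g`` (toroidal distance), which guarantees the cluster disks
are disjoint.  Resource items ("daughter points") are scattered uniformly on
the disk around their parent, so the realized pattern is a Matérn-style
cluster process with a fixed number of parents and an expected
``R̄ = π g² u`` items per cluster at density ``u``.

The live set of items is held in a :class:`ResourcePool`, backed by a
periodic uniform-grid cell list (linked arrays) supporting exact fixed-radius
queries, single-item removal (harvest) and insertion (replenishment) in
amortized O(1).  Query results are exact: they always equal a brute-force
scan over all live items.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "ConfigurationError",
    "LandscapeSpec",
    "Landscape",
    "ResourcePool",
    "torus_wrap",
    "torus_distance",
    "place_parents",
    "sample_daughter",
    "init_resources",
    "save_landscape",
    "load_landscape",
]


class ConfigurationError(ValueError):
    """An infeasible or inconsistent landscape/scenario configuration."""


# ---------------------------------------------------------------------------
# torus geometry
# ---------------------------------------------------------------------------

def torus_wrap(point, L: float):
    """Wrap coordinates into ``[0, L)`` under periodic boundaries.

    Works elementwise on scalars or arrays of any shape.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    return np.mod(np.asarray(point, dtype=float), L)


def torus_distance(a, b, L: float):
    """Euclidean distance under the minimum-image convention.

    ``a`` and ``b`` are points or arrays of points whose last axis has
    length 2; standard numpy broadcasting applies.  The result is bounded by
    ``L·√2/2``, the half-diagonal of the fundamental square.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = np.abs(a - b)
    d = np.minimum(d, L - d)
    return np.sqrt(np.sum(d * d, axis=-1))


# ---------------------------------------------------------------------------
# specification and landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandscapeSpec:
    """Geometry of a clustered-resource landscape.

    Parameters
    ----------
    L : float
        Side length of the square landscape (spatial units).
    k : int
        Number of resource clusters (parent points), ``k >= 1``.
    g : float
        Cluster radius (spatial units).
    u : float
        Resource density inside clusters (items per unit area).
    min_sep : float
        Minimum toroidal separation between parent points; fixed at ``3 g``.
    """

    L: float = 2000.0
    k: int = 16
    g: float = 80.0
    u: float = 0.01
    min_sep: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.L <= 0:
            raise ConfigurationError("L must be positive")
        if self.k < 1 or int(self.k) != self.k:
            raise ConfigurationError("k must be an integer >= 1")
        if self.g <= 0:
            raise ConfigurationError("g must be positive")
        if self.u <= 0:
            raise ConfigurationError("u must be positive")
        if self.min_sep is None:
            object.__setattr__(self, "min_sep", 3.0 * self.g)
        elif not math.isclose(self.min_sep, 3.0 * self.g):
            raise ConfigurationError("min_sep must equal 3*g")
        if self.k * math.pi * self.g ** 2 >= self.L ** 2:
            raise ConfigurationError("clusters do not fit in the landscape")

    @property
    def expected_per_cluster(self) -> float:
        """Expected item count per cluster, ``R̄ = π g² u``."""
        return math.pi * self.g ** 2 * self.u

    @property
    def coverage_fraction(self) -> float:
        """Fraction of the landscape area covered by cluster disks."""
        return self.k * math.pi * self.g ** 2 / self.L ** 2


def place_parents(
    spec: LandscapeSpec, rng: np.random.Generator, max_attempts: int = 10 ** 6
) -> np.ndarray:
    """Rejection-sample ``k`` parent points with pairwise separation >= 3g.

    Returns a ``(k, 2)`` array of coordinates in ``[0, L)``.  Raises
    :class:`ConfigurationError` if the packing cannot be realized within
    ``max_attempts`` candidate draws.
    """
    parents = np.empty((spec.k, 2))
    n_placed = 0
    for _ in range(max_attempts):
        cand = rng.uniform(0.0, spec.L, size=2)
        if n_placed == 0 or np.all(
            torus_distance(cand, parents[:n_placed], spec.L) >= spec.min_sep
        ):
            parents[n_placed] = cand
            n_placed += 1
            if n_placed == spec.k:
                return parents
    raise ConfigurationError(
        f"could not place {spec.k} parents with separation {spec.min_sep} "
        f"within {max_attempts} attempts (packing too dense)"
    )


def sample_daughter(
    parent, g: float, L: float, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Sample point(s) uniformly on the disk of radius ``g`` around ``parent``.

    Points are torus-wrapped into ``[0, L)``; the toroidal distance to the
    parent is always <= g.  With ``size=None`` a single ``(2,)`` point is
    returned, otherwise a ``(size, 2)`` array.
    """
    n = 1 if size is None else int(size)
    r = g * np.sqrt(rng.random(n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    pts = np.asarray(parent, dtype=float) + np.column_stack(
        (r * np.cos(theta), r * np.sin(theta))
    )
    pts = torus_wrap(pts, L)
    return pts[0] if size is None else pts


@dataclass(frozen=True)
class Landscape:
    """A realized landscape: a spec plus concrete parent coordinates."""

    spec: LandscapeSpec
    parents: np.ndarray  # (k, 2)

    def __post_init__(self):
        parents = np.atleast_2d(np.asarray(self.parents, dtype=float))
        object.__setattr__(self, "parents", parents)
        if parents.shape != (self.spec.k, 2):
            raise ConfigurationError(
                f"expected {self.spec.k} parent points, got shape {parents.shape}"
            )
        if np.any(parents < 0) or np.any(parents >= self.spec.L):
            raise ConfigurationError("parent coordinates must lie in [0, L)")

    @classmethod
    def generate(cls, spec: LandscapeSpec, rng: np.random.Generator) -> "Landscape":
        return cls(spec=spec, parents=place_parents(spec, rng))

    @property
    def expected_per_cluster(self) -> float:
        return self.spec.expected_per_cluster

    def membership(self, points) -> np.ndarray:
        """Cluster index for each point, or -1 outside every cluster.

        Disks are closed (distance <= g counts as inside); the 3g parent
        separation makes the assignment unique.  Accepts a single point or an
        array of points (last axis length 2); returns an int array of the
        leading shape.
        """
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        member = np.full(pts.shape[0], -1, dtype=np.int64)
        for j in range(self.spec.k):
            inside = torus_distance(pts, self.parents[j], self.spec.L) <= self.spec.g
            member[inside] = j
        return member[0] if single else member


# ---------------------------------------------------------------------------
# cell-list kernels (periodic uniform grid, linked arrays)
# ---------------------------------------------------------------------------
# head[cell] -> first item slot in cell or -1; nxt[slot] -> next slot in the
# same cell or -1; cell_of[slot] -> current cell (-1 when not indexed).

@njit(cache=True)
def _grid_insert(head, nxt, cell_of, slot, cell):
    nxt[slot] = head[cell]
    head[cell] = slot
    cell_of[slot] = cell


@njit(cache=True)
def _grid_remove(head, nxt, cell_of, slot):
    cell = cell_of[slot]
    j = head[cell]
    if j == slot:
        head[cell] = nxt[slot]
    else:
        while nxt[j] != slot:
            j = nxt[j]
        nxt[j] = nxt[slot]
    cell_of[slot] = -1


@njit(cache=True)
def _insert_many(head, nxt, cell_of, slots, xs, ys, s, G):
    for i in range(slots.shape[0]):
        ix = int(xs[i] / s) % G
        iy = int(ys[i] / s) % G
        _grid_insert(head, nxt, cell_of, slots[i], ix * G + iy)


@njit(cache=True)
def _axis_window(i0, reach, G, buf):
    # unique wrapped column/row indices covering [i0-reach, i0+reach]
    n = 2 * reach + 1
    if n >= G:
        for j in range(G):
            buf[j] = j
        return G
    for t in range(n):
        buf[t] = (i0 - reach + t) % G
    return n


@njit(cache=True)
def _query_ids(head, nxt, item_x, item_y, cx, cy, r, L, G, out):
    """Collect live item slots within toroidal distance r of (cx, cy)."""
    s = L / G
    reach = int(r / s) + 1
    winx = np.empty(G, np.int64)
    winy = np.empty(G, np.int64)
    nx = _axis_window(int(cx / s) % G, reach, G, winx)
    ny = _axis_window(int(cy / s) % G, reach, G, winy)
    r2 = r * r
    m = 0
    for a in range(nx):
        for b in range(ny):
            item = head[winx[a] * G + winy[b]]
            while item != -1:
                dx = abs(item_x[item] - cx)
                if dx > L - dx:
                    dx = L - dx
                dy = abs(item_y[item] - cy)
                if dy > L - dy:
                    dy = L - dy
                if dx * dx + dy * dy <= r2:
                    out[m] = item
                    m += 1
                item = nxt[item]
    return m


@njit(cache=True)
def _step_harvest(head, nxt, cell_of, item_x, item_y, px, py, perm, c, L, G, removed):
    """Sequential harvest for one simulation step.

    Individuals are processed in permutation order; each removes every live
    item within radius c of its (post-move) position, so later movers see the
    depletion left by earlier ones.  Returns per-individual counts and the
    number of removed slots written into ``removed``.
    """
    n_ind = px.shape[0]
    counts = np.zeros(n_ind, np.int64)
    s = L / G
    reach = int(c / s) + 1
    winx = np.empty(G, np.int64)
    winy = np.empty(G, np.int64)
    c2 = c * c
    m = 0
    for q in range(n_ind):
        i = perm[q]
        cx = px[i]
        cy = py[i]
        nx = _axis_window(int(cx / s) % G, reach, G, winx)
        ny = _axis_window(int(cy / s) % G, reach, G, winy)
        for a in range(nx):
            for b in range(ny):
                item = head[winx[a] * G + winy[b]]
                while item != -1:
                    nxt_item = nxt[item]
                    dx = abs(item_x[item] - cx)
                    if dx > L - dx:
                        dx = L - dx
                    dy = abs(item_y[item] - cy)
                    if dy > L - dy:
                        dy = L - dy
                    if dx * dx + dy * dy <= c2:
                        _grid_remove(head, nxt, cell_of, item)
                        removed[m] = item
                        m += 1
                        counts[i] += 1
                    item = nxt_item
    return counts, m


# ---------------------------------------------------------------------------
# resource pool
# ---------------------------------------------------------------------------

class ResourcePool:
    """Live resource items with an exact fixed-radius toroidal spatial index.

    Items occupy integer slots; harvested slots are recycled by subsequent
    replenishment.  ``cell_radius`` sizes the grid cells (cells are never
    smaller than the typical query radius, so a query scans a bounded
    neighborhood of cells).
    """

    _GRID_CAP = 4096  # max cells per side; bounds memory for tiny radii

    def __init__(self, L: float, cell_radius: float = 1.0, capacity: int = 16):
        if L <= 0 or cell_radius <= 0:
            raise ConfigurationError("L and cell_radius must be positive")
        self.L = float(L)
        self.G = max(1, min(int(L / cell_radius), self._GRID_CAP))
        self._head = np.full(self.G * self.G, -1, dtype=np.int64)
        cap = max(16, int(capacity))
        self.item_x = np.empty(cap)
        self.item_y = np.empty(cap)
        self.parent_of = np.full(cap, -1, dtype=np.int64)
        self.alive = np.zeros(cap, dtype=bool)
        self._nxt = np.full(cap, -1, dtype=np.int64)
        self._cell_of = np.full(cap, -1, dtype=np.int64)
        self._free: list[int] = list(range(cap - 1, -1, -1))
        self._n_alive = 0
        self._scratch = np.empty(cap, dtype=np.int64)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_items(
        cls, L: float, positions, parent_of, cell_radius: float = 1.0
    ) -> "ResourcePool":
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        if positions.size == 0:
            positions = positions.reshape(0, 2)
        parent_of = np.asarray(parent_of, dtype=np.int64)
        pool = cls(L, cell_radius, capacity=positions.shape[0])
        pool.insert(positions, parent_of)
        return pool

    # -- basic properties ---------------------------------------------------

    def __len__(self) -> int:
        return self._n_alive

    @property
    def n_items(self) -> int:
        return self._n_alive

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) coordinates of live items (slot order)."""
        idx = np.flatnonzero(self.alive)
        return np.column_stack((self.item_x[idx], self.item_y[idx]))

    @property
    def live_slots(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    # -- mutation -----------------------------------------------------------

    def _grow(self, needed: int):
        cap = len(self.item_x)
        new_cap = cap
        while new_cap - (cap - len(self._free)) < needed:
            new_cap *= 2
        if new_cap == cap:
            return
        for name in ("item_x", "item_y"):
            arr = np.empty(new_cap)
            arr[:cap] = getattr(self, name)
            setattr(self, name, arr)
        for name, fillval in (("parent_of", -1), ("_nxt", -1), ("_cell_of", -1)):
            arr = np.full(new_cap, fillval, dtype=np.int64)
            arr[:cap] = getattr(self, name)
            setattr(self, name, arr)
        alive = np.zeros(new_cap, dtype=bool)
        alive[:cap] = self.alive
        self.alive = alive
        self._free.extend(range(new_cap - 1, cap - 1, -1))
        self._scratch = np.empty(new_cap, dtype=np.int64)

    def insert(self, positions: np.ndarray, parent_of: np.ndarray) -> np.ndarray:
        """Insert items at ``positions`` (already wrapped); returns their slots."""
        n = positions.shape[0]
        if n == 0:
            return np.empty(0, dtype=np.int64)
        if len(self._free) < n:
            self._grow(n)
        slots = np.array([self._free.pop() for _ in range(n)], dtype=np.int64)
        self.item_x[slots] = positions[:, 0]
        self.item_y[slots] = positions[:, 1]
        self.parent_of[slots] = parent_of
        self.alive[slots] = True
        _insert_many(
            self._head, self._nxt, self._cell_of, slots,
            positions[:, 0], positions[:, 1], self.L / self.G, self.G,
        )
        self._n_alive += n
        return slots

    def query_radius(self, center, radius: float) -> np.ndarray:
        """Slots of all live items within toroidal distance ``radius`` (closed).

        Exact: identical to a brute-force scan of every live item.  Results
        are returned sorted for determinism.
        """
        if radius <= 0:
            raise ValueError("radius must be positive")
        center = np.asarray(center, dtype=float)
        out = self._scratch
        m = _query_ids(
            self._head, self._nxt, self.item_x, self.item_y,
            float(center[0]), float(center[1]), float(radius),
            self.L, self.G, out,
        )
        found = out[:m].copy()
        found.sort()
        return found

    def harvest(self, slots) -> int:
        """Remove the given live items; returns the count removed.

        Removing a slot that is not live is a contract violation and raises.
        """
        slots = np.atleast_1d(np.asarray(slots, dtype=np.int64))
        if slots.size and not np.all(self.alive[slots]):
            raise ValueError("harvest of a non-live item slot")
        for slot in slots:
            _grid_remove(self._head, self._nxt, self._cell_of, slot)
        self.release_slots(slots)
        return int(slots.size)

    def release_slots(self, slots: np.ndarray):
        """Mark already-unlinked slots dead (engine fast path after a step)."""
        self.alive[slots] = False
        self._free.extend(int(s) for s in slots)
        self._n_alive -= int(slots.size)

    def replenish(self, landscape: Landscape, n: int, rng: np.random.Generator):
        """Add ``n`` fresh items as daughters of uniformly chosen parents."""
        if n < 0:
            raise ValueError("n must be >= 0")
        if n == 0:
            return
        parent_idx = rng.integers(0, landscape.spec.k, size=n)
        pts = sample_daughter(
            np.zeros(2), landscape.spec.g, landscape.spec.L, rng, size=n
        )
        # sample_daughter around the origin, then translate to each parent
        pts = torus_wrap(landscape.parents[parent_idx] + pts, landscape.spec.L)
        self.insert(pts, parent_idx.astype(np.int64))

    # -- engine fast path ---------------------------------------------------

    def step_harvest(self, px, py, perm, c: float):
        """Sequential harvest of one step (see :func:`_step_harvest`)."""
        counts, m = _step_harvest(
            self._head, self._nxt, self._cell_of, self.item_x, self.item_y,
            px, py, perm, float(c), self.L, self.G, self._scratch,
        )
        removed = self._scratch[:m].copy()
        self.release_slots(removed)
        return counts, removed


def init_resources(
    landscape: Landscape, rng: np.random.Generator, cell_radius: float = 1.0
) -> ResourcePool:
    """Populate a fresh pool: per cluster, a Poisson(R̄) number of daughters."""
    spec = landscape.spec
    counts = rng.poisson(spec.expected_per_cluster, size=spec.k)
    pool = ResourcePool(spec.L, cell_radius=cell_radius, capacity=int(counts.sum()))
    for j in range(spec.k):
        if counts[j] == 0:
            continue
        pts = sample_daughter(landscape.parents[j], spec.g, spec.L, rng, size=counts[j])
        pool.insert(pts, np.full(counts[j], j, dtype=np.int64))
    return pool


# ---------------------------------------------------------------------------
# snapshot I/O
# ---------------------------------------------------------------------------

def save_landscape(path, landscape: Landscape, pool: ResourcePool | None = None):
    """Write a JSON snapshot of the landscape (and optionally its items)."""
    data = {
        "spec": {
            "L": landscape.spec.L,
            "k": landscape.spec.k,
            "g": landscape.spec.g,
            "u": landscape.spec.u,
        },
        "parents": landscape.parents.tolist(),
    }
    if pool is not None:
        idx = pool.live_slots
        data["items"] = {
            "x": pool.item_x[idx].tolist(),
            "y": pool.item_y[idx].tolist(),
            "parent": pool.parent_of[idx].tolist(),
        }
    Path(path).write_text(json.dumps(data))


def load_landscape(path, cell_radius: float = 1.0):
    """Read a snapshot; returns ``(landscape, pool_or_None)``."""
    data = json.loads(Path(path).read_text())
    spec = LandscapeSpec(**data["spec"])
    landscape = Landscape(spec=spec, parents=np.asarray(data["parents"]))
    pool = None
    if "items" in data:
        items = data["items"]
        positions = np.column_stack((items["x"], items["y"]))
        pool = ResourcePool.from_items(
            spec.L, positions, np.asarray(items["parent"], dtype=np.int64),
            cell_radius=cell_radius,
        )
    return landscape, pool
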