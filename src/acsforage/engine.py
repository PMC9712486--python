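"""Simulation engine: initialization, stepping, logging.

One simulation releases ``N`` individuals into a realized landscape and
iterates ``T`` synchronous time steps.  Within a step, individuals are
processed in a fresh random permutation; each moves one step under the ACS
kernel, then immediately harvests every resource item within its perception
radius at its new position (so later movers in the same step see the
depletion left by earlier ones).  After all individuals have moved, every
item removed during the step is replaced by a new daughter point of a
uniformly chosen parent (global replacement), keeping the landscape-wide
item count constant.  Searching times are then updated: reset to 0 on a
successful step, incremented otherwise.

Randomness is organized as three independent substreams spawned from the
master seed — landscape realization, population initialization, and
stepping — so replicates with different seeds get independently created
landscapes, and a fixed seed reproduces a run bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import (
    ConfigurationError,
    Landscape,
    LandscapeSpec,
    ResourcePool,
    init_resources,
    sample_daughter,
)
from .movement import TWO_PI, IndividualState, MovementParams, turning_sd, wrap_angle

__all__ = [
    "SimulationConfig",
    "Population",
    "TrajectoryLog",
    "init_population",
    "simulate_step",
    "run",
]

PLACEMENTS = ("within_clusters", "uniform_random")


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level parameters.

    Defaults follow the standard study conditions: 80 individuals moving for
    10,000 steps with the last 2,000 analyzed, released inside clusters with
    an initial searching time of 500 (near-straight movement at the start).
    """

    n_individuals: int = 80
    total_steps: int = 10_000
    analysis_window: int = 2_000
    init_delta_s: int = 500
    init_placement: str = "within_clusters"
    seed: int | None = None
    log_full_trajectory: bool = False

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if not (0 < self.analysis_window <= self.total_steps):
            raise ConfigurationError("require 0 < analysis_window <= total_steps")
        if self.init_delta_s < 0:
            raise ConfigurationError("init_delta_s must be >= 0")
        if self.init_placement not in PLACEMENTS:
            raise ConfigurationError(f"init_placement must be one of {PLACEMENTS}")


class Population:
    """Structure-of-arrays container for the individuals' state."""

    def __init__(self, x, y, heading, delta_s):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.heading = np.asarray(heading, dtype=float)
        self.delta_s = np.asarray(delta_s, dtype=np.int64)

    def __len__(self) -> int:
        return self.x.shape[0]

    def as_states(self) -> list[IndividualState]:
        return [
            IndividualState(
                position=np.array([self.x[i], self.y[i]]),
                heading=self.heading[i],
                delta_s=int(self.delta_s[i]),
            )
            for i in range(len(self))
        ]


def init_population(
    config: SimulationConfig, landscape: Landscape, rng: np.random.Generator
) -> Population:
    """Release individuals with uniform headings and ΔS = init_delta_s.

    ``within_clusters`` picks a cluster uniformly per individual, then a
    uniform point on its disk (clusters are congruent, so this equals
    uniform-by-area over the habitat); ``uniform_random`` scatters uniformly
    over the whole landscape.
    """
    n = config.n_individuals
    spec = landscape.spec
    if config.init_placement == "within_clusters":
        cluster = rng.integers(0, spec.k, size=n)
        offsets = sample_daughter(np.zeros(2), spec.g, spec.L, rng, size=n)
        pts = np.mod(landscape.parents[cluster] + offsets, spec.L)
    else:
        pts = rng.uniform(0.0, spec.L, size=(n, 2))
    heading = rng.uniform(0.0, TWO_PI, size=n)
    return Population(
        x=pts[:, 0], y=pts[:, 1], heading=heading,
        delta_s=np.full(n, config.init_delta_s, dtype=np.int64),
    )


def simulate_step(
    pop: Population,
    pool: ResourcePool,
    landscape: Landscape,
    params: MovementParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance the whole population one time step in place.

    Returns the per-individual harvest counts.  Movement depends only on
    each individual's own state, so all moves are drawn at once; harvesting
    is then applied sequentially in a fresh random permutation (equivalent
    to fully interleaved move-and-harvest, since moves never read the pool).
    Replenishment restores the pool to its pre-step size.
    """
    n = len(pop)
    L = landscape.spec.L
    sds = turning_sd(pop.delta_s, params)
    turns = wrap_angle(rng.normal(0.0, 1.0, size=n) * sds)
    pop.heading = np.mod(pop.heading + turns, TWO_PI)
    pop.x = np.mod(pop.x + params.p * np.cos(pop.heading), L)
    pop.y = np.mod(pop.y + params.p * np.sin(pop.heading), L)

    perm = rng.permutation(n)
    counts, removed = pool.step_harvest(pop.x, pop.y, perm, params.c)
    pool.replenish(landscape, removed.size, rng)

    pop.delta_s = np.where(counts > 0, 0, pop.delta_s + 1)
    return counts


@dataclass
class TrajectoryLog:
    """Per-step, per-individual record over the logged window.

    Arrays are shaped ``(S, N)`` where ``S`` is the number of logged steps
    (the analysis window by default, the full run when
    ``log_full_trajectory`` is set) and ``N`` the number of individuals.
    ``membership`` holds the cluster index of the post-move position, −1 in
    the matrix.
    """

    steps: np.ndarray  # (S,) global step indices (0-based)
    x: np.ndarray  # (S, N)
    y: np.ndarray  # (S, N)
    harvested: np.ndarray  # (S, N) item counts
    membership: np.ndarray  # (S, N) cluster index or -1
    landscape: Landscape
    config: SimulationConfig
    params: MovementParams
    n_items: int  # realized landscape-wide item count

    @property
    def n_individuals(self) -> int:
        return self.x.shape[1]

    @property
    def window(self) -> int:
        return self.x.shape[0]

    def window_slice(self, window: int | None = None) -> "TrajectoryLog":
        """Restrict to the last ``window`` logged steps (default: config's)."""
        w = self.config.analysis_window if window is None else window
        if w > self.window:
            raise ValueError("requested window exceeds logged steps")
        sl = slice(self.window - w, self.window)
        return TrajectoryLog(
            steps=self.steps[sl], x=self.x[sl], y=self.y[sl],
            harvested=self.harvested[sl], membership=self.membership[sl],
            landscape=self.landscape, config=self.config, params=self.params,
            n_items=self.n_items,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: individual, step, x, y, cluster, harvested."""
        S, N = self.x.shape
        return pd.DataFrame(
            {
                "individual": np.tile(np.arange(N), S),
                "step": np.repeat(self.steps, N),
                "x": self.x.ravel(),
                "y": self.y.ravel(),
                "cluster": self.membership.ravel(),
                "harvested": self.harvested.ravel(),
            }
        )

    def write(self, path):
        """Write the trajectory table (CSV) plus a metadata sidecar (JSON)."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = {
            "config": asdict(self.config),
            "movement": asdict(self.params),
            "landscape_spec": {
                "L": self.landscape.spec.L,
                "k": self.landscape.spec.k,
                "g": self.landscape.spec.g,
                "u": self.landscape.spec.u,
            },
            "parents": self.landscape.parents.tolist(),
            "n_items": int(self.n_items),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1)
        )


def run(
    spec: LandscapeSpec,
    params: MovementParams,
    config: SimulationConfig,
    landscape: Landscape | None = None,
) -> TrajectoryLog:
    """Execute one full simulation replicate.

    The landscape is realized from the seed's landscape substream unless an
    explicit (e.g. fixture) landscape is supplied.  Logging covers the final
    ``analysis_window`` steps, or every step with ``log_full_trajectory``.
    An identical configuration and seed reproduce the log bit for bit.
    """
    ss = np.random.SeedSequence(config.seed)
    land_ss, init_ss, step_ss = ss.spawn(3)
    rng_land = np.random.default_rng(land_ss)
    rng_init = np.random.default_rng(init_ss)
    rng_step = np.random.default_rng(step_ss)

    if landscape is None:
        landscape = Landscape.generate(spec, rng_land)
    elif landscape.spec != spec:
        raise ConfigurationError("provided landscape does not match spec")
    pool = init_resources(landscape, rng_land, cell_radius=params.c)
    n_items = pool.n_items
    pop = init_population(config, landscape, rng_init)

    T = config.total_steps
    log_start = 0 if config.log_full_trajectory else T - config.analysis_window
    S = T - log_start
    N = config.n_individuals
    xs = np.empty((S, N))
    ys = np.empty((S, N))
    harvested = np.zeros((S, N), dtype=np.int32)

    for t in range(T):
        counts = simulate_step(pop, pool, landscape, params, rng_step)
        if t >= log_start:
            s = t - log_start
            xs[s] = pop.x
            ys[s] = pop.y
            harvested[s] = counts

    membership = _membership_grid(xs, ys, landscape)
    return TrajectoryLog(
        steps=np.arange(log_start, T), x=xs, y=ys, harvested=harvested,
        membership=membership, landscape=landscape, config=config,
        params=params, n_items=n_items,
    )


def read_log(path) -> TrajectoryLog:
    """Reload a trajectory log written by :meth:`TrajectoryLog.write`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    df = pd.read_csv(path)
    steps = np.sort(df["step"].unique())
    S = steps.size
    N = int(df["individual"].max()) + 1
    df = df.sort_values(["step", "individual"])
    shape = (S, N)
    spec = LandscapeSpec(**meta["landscape_spec"])
    landscape = Landscape(spec=spec, parents=np.asarray(meta["parents"]))
    return TrajectoryLog(
        steps=steps,
        x=df["x"].to_numpy().reshape(shape),
        y=df["y"].to_numpy().reshape(shape),
        harvested=df["harvested"].to_numpy().reshape(shape),
        membership=df["cluster"].to_numpy().reshape(shape),
        landscape=landscape,
        config=SimulationConfig(**meta["config"]),
        params=MovementParams(**meta["movement"]),
        n_items=meta["n_items"],
    )


def _membership_grid(xs: np.ndarray, ys: np.ndarray, landscape: Landscape) -> np.ndarray:
    """Vectorized cluster membership for (S, N) position arrays."""
    spec = landscape.spec
    member = np.full(xs.shape, -1, dtype=np.int32)
    for j in range(spec.k):
        px, py = landscape.parents[j]
        dx = np.abs(xs - px)
        np.minimum(dx, spec.L - dx, out=dx)
        dy = np.abs(ys - py)
        np.minimum(dy, spec.L - dy, out=dy)
        member[dx * dx + dy * dy <= spec.g * spec.g] = j
    return member
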