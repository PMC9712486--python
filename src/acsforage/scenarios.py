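"""Scenario grid, replicate execution, and deterministic test fixtures.

The study design crosses five cluster geometries of equal total habitat
area — (k, g) ∈ {(16, 80), (8, 80√2), (4, 160), (2, 160√2), (1, 320)}, each
covering k·π·g² = π·320² ≈ 8% of the 2000×2000 landscape — with eight
resource densities u ∈ {0.01, …, 1.27}, at 10 replicates per combination on
independently realized landscapes.  Control movement modes (SLM, CRW) and
the random-start ACS variant are run for the four-cluster geometry.

Replicate seeds derive from (master seed, scenario index, replicate index)
through a SeedSequence spawn key, so the grid is reproducible and can be
extended without disturbing existing runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import SimulationConfig, TrajectoryLog, run
from .landscape import ConfigurationError, Landscape, LandscapeSpec, ResourcePool
from .metrics import ScenarioSummary, summarize
from .movement import IndividualState, MovementParams

__all__ = [
    "KG_PAIRS",
    "U_LADDER",
    "MODES",
    "ScenarioConfig",
    "make_scenario",
    "build_grid",
    "run_replicate",
    "run_grid",
    "aggregate",
    "make_fixture",
    "FixtureSpec",
]

#: Equal-area cluster geometries: k clusters of radius g.
KG_PAIRS: tuple[tuple[int, float], ...] = (
    (16, 80.0),
    (8, 80.0 * math.sqrt(2.0)),
    (4, 160.0),
    (2, 160.0 * math.sqrt(2.0)),
    (1, 320.0),
)

#: Resource-density ladder (items per unit area inside clusters).
U_LADDER: tuple[float, ...] = (0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64, 1.27)

#: Movement/initialization modes.  ACS starts within clusters; the control
#: modes and the ACS-Random variant start at uniform random positions.
MODES = ("ACS", "ACS_random", "CRW", "SLM")

DEFAULT_REPLICATES = 10
#: Geometry used for the control-mode comparisons.
CONTROL_KG = (4, 160.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the scenario grid, expanded to a runnable configuration."""

    label: str
    mode: str
    landscape: LandscapeSpec
    movement: MovementParams
    sim: SimulationConfig
    u: float | None = None  # grid ladder value (supply parameter); the
    # realized within-cluster density is landscape.u

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, sim=replace(self.sim, seed=int(seed)))


def make_scenario(
    k: int,
    g: float,
    u: float,
    mode: str = "ACS",
    movement: MovementParams | None = None,
    sim: SimulationConfig | None = None,
    label: str | None = None,
) -> ScenarioConfig:
    """Assemble a scenario from its grid coordinates and mode.

    ``mode`` sets the half-saturation constant (h = 200 for ACS variants,
    0 for SLM, 10,000 for CRW) and the release rule (within clusters for
    plain ACS, uniform random otherwise); explicit ``movement``/``sim``
    objects override these defaults.

    Resource supply follows the grid convention: the ladder value ``u`` is
    the within-cluster item density of the single-cluster geometry, and a
    k-cluster landscape divides that same single-cluster-equivalent supply
    among its clusters — the realized within-cluster density is ``u/k``
    (expected per-cluster count π·g²·u/k).  Only under this convention does
    the system show its documented regime structure: a random-distribution
    regime at many small sparse clusters and a strong foraging-success
    contrast between the one- and 16-cluster geometries.  To hold per-area
    density at ``u`` for every k instead, construct a
    :class:`~acsforage.landscape.LandscapeSpec` directly and call
    :func:`~acsforage.engine.run`.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; expected one of {MODES}")
    if movement is None:
        h = {"ACS": 200.0, "ACS_random": 200.0, "CRW": 10_000.0, "SLM": 0.0}[mode]
        movement = MovementParams(h=h)
    if sim is None:
        sim = SimulationConfig()
    placement = "within_clusters" if mode == "ACS" else "uniform_random"
    sim = replace(sim, init_placement=placement)
    if label is None:
        label = f"{mode}_k{k}_u{u:g}"
    return ScenarioConfig(
        label=label,
        mode=mode,
        landscape=LandscapeSpec(k=k, g=g, u=u / k),
        movement=movement,
        sim=sim,
        u=u,
    )


def replicate_seed(master_seed: int, scenario_index: int, rep: int) -> int:
    """Stable 31-bit replicate seed derived from (master, scenario, rep)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(scenario_index, rep))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def build_grid(
    modes=("ACS",),
    replicates: int = DEFAULT_REPLICATES,
    master_seed: int = 0,
    kg_pairs=KG_PAIRS,
    u_values=U_LADDER,
    sim: SimulationConfig | None = None,
) -> list[ScenarioConfig]:
    """Expand the scenario grid into seeded replicate configurations.

    ACS runs on every (k, g) × u combination; the control modes (CRW, SLM)
    and ACS-Random are paired with the four-cluster geometry only.  Each
    replicate carries its own derived seed, hence an independently realized
    landscape.
    """
    jobs = []
    scenario_index = 0
    for mode in modes:
        pairs = kg_pairs if mode == "ACS" else (CONTROL_KG,)
        for k, g in pairs:
            for u in u_values:
                base = make_scenario(k, g, u, mode=mode, sim=sim)
                for r in range(replicates):
                    seed = replicate_seed(master_seed, scenario_index, r)
                    jobs.append(base.with_seed(seed))
                scenario_index += 1
    return jobs


def run_replicate(job: ScenarioConfig) -> tuple[ScenarioSummary, TrajectoryLog]:
    """Execute one replicate and summarize its analysis window."""
    log = run(job.landscape, job.movement, job.sim)
    return summarize(log), log


def run_grid(jobs: list[ScenarioConfig], progress: bool = False) -> pd.DataFrame:
    """Run all replicates; one row per replicate.

    Rows are independent, so the table is identical regardless of execution
    order.  A failing replicate is recorded in the ``error`` column and does
    not abort the rest of the grid.
    """
    rows = []
    for i, job in enumerate(jobs):
        row = {
            "label": job.label,
            "mode": job.mode,
            "k": job.landscape.k,
            "g": job.landscape.g,
            "u": job.u if job.u is not None else job.landscape.u,
            "seed": job.sim.seed,
            "error": "",
        }
        try:
            summary, _ = run_replicate(job)
            row.update(summary.as_dict())
        except Exception as exc:  # noqa: BLE001 - per-run isolation
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
        if progress:
            print(f"[{i + 1}/{len(jobs)}] {job.label} seed={job.sim.seed}", flush=True)
    return pd.DataFrame(rows)


METRIC_COLUMNS = [
    "foraging_success",
    "clusters_harvested",
    "visit_time",
    "search_time",
    "pct_permanent_emigration",
    "occupancy",
    "pct_in_clusters",
    "patch_changes",
    "dist_to_center",
]


def aggregate(replicate_table: pd.DataFrame) -> pd.DataFrame:
    """Grand means over replicates per scenario.

    Each replicate value is already an across-individual average, so the
    scenario value is the mean of per-replicate means, not a pooled-
    individual mean.
    """
    ok = replicate_table[replicate_table["error"] == ""]
    return (
        ok.groupby(["label", "mode", "k", "g", "u"], as_index=False)[METRIC_COLUMNS]
        .mean()
    )


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """A fully hand-specified micro-landscape for unit tests (no RNG)."""

    name: str
    landscape: Landscape
    item_positions: np.ndarray  # (n, 2)
    item_parents: np.ndarray  # (n,)
    individuals: tuple[IndividualState, ...]

    def build_pool(self, cell_radius: float = 1.0) -> ResourcePool:
        return ResourcePool.from_items(
            self.landscape.spec.L,
            self.item_positions,
            self.item_parents,
            cell_radius=cell_radius,
        )


def _fixture_one_cluster_3_items() -> FixtureSpec:
    spec = LandscapeSpec(L=100.0, k=1, g=10.0, u=0.01)
    landscape = Landscape(spec=spec, parents=np.array([[50.0, 50.0]]))
    items = np.array([[52.0, 50.0], [50.0, 55.0], [44.0, 47.0]])
    individuals = (
        # 0.5 units left of the first item, heading toward it
        IndividualState(position=np.array([51.5, 50.0]), heading=0.0, delta_s=500),
    )
    return FixtureSpec(
        name="one-cluster-3-items",
        landscape=landscape,
        item_positions=items,
        item_parents=np.zeros(3, dtype=np.int64),
        individuals=individuals,
    )


def _fixture_no_items() -> FixtureSpec:
    spec = LandscapeSpec(L=100.0, k=1, g=10.0, u=0.01)
    landscape = Landscape(spec=spec, parents=np.array([[50.0, 50.0]]))
    return FixtureSpec(
        name="no-items",
        landscape=landscape,
        item_positions=np.empty((0, 2)),
        item_parents=np.empty(0, dtype=np.int64),
        individuals=(
            IndividualState(position=np.array([50.0, 50.0]), heading=1.0, delta_s=0),
        ),
    )


def _fixture_seam_cluster() -> FixtureSpec:
    """A cluster straddling the torus seam at the origin."""
    spec = LandscapeSpec(L=100.0, k=1, g=10.0, u=0.01)
    landscape = Landscape(spec=spec, parents=np.array([[0.0, 0.0]]))
    items = np.array([[98.0, 0.0], [2.0, 99.0], [0.0, 5.0]])
    individuals = (
        IndividualState(position=np.array([99.0, 0.0]), heading=0.0, delta_s=500),
    )
    return FixtureSpec(
        name="seam-cluster",
        landscape=landscape,
        item_positions=items,
        item_parents=np.zeros(3, dtype=np.int64),
        individuals=individuals,
    )


_FIXTURES = {
    "one-cluster-3-items": _fixture_one_cluster_3_items,
    "no-items": _fixture_no_items,
    "seam-cluster": _fixture_seam_cluster,
}


def make_fixture(name: str) -> FixtureSpec:
    """Build a named deterministic fixture; raises KeyError on unknown names."""
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return factory()
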