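"""Spatial-structure statistics computed from trajectory logs.

The analysis window of a run is summarized by eight statistics: (1) foraging
success, (2) number of distinct clusters harvested, (3) patch visitation
time, (4) patch searching time, (5) percentage of permanent emigrations
(outside excursions of at least 200 steps, the rest being "foray loops"),
(6) patch occupancy, (7) percentage of individuals located in clusters, and
(8) successful patch changes per individual — plus, for single-cluster
landscapes, the mean distance of in-cluster individuals to the patch center
at the final step.

Per-individual membership series are segmented into alternating inside /
outside episodes; each inside→outside transition is an emigration event
whose outside duration classifies it as a foray loop (< 200 steps) or a
permanent emigration (>= 200).  Episodes touching the window boundary are
censored: they contribute their truncated durations to the visitation and
searching means, but an emigration whose outside episode is right-censored
below the cutoff cannot be classified and is excluded from the permanent
percentage.  Individuals that never set foot in a patch during the window
are excluded from the visitation, searching, emigration-classification and
patch-change statistics (but not from foraging success, clusters harvested,
occupancy, or percentage in clusters).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .landscape import Landscape, torus_distance
from .movement import wrap_angle

__all__ = [
    "FORAY_CUTOFF",
    "Episode",
    "EmigrationEvent",
    "ScenarioSummary",
    "membership_series",
    "segment_episodes",
    "detect_events",
    "apply_exclusions",
    "foraging_success",
    "clusters_harvested",
    "visit_and_search_times",
    "pct_permanent_emigration",
    "occupancy",
    "pct_in_clusters",
    "patch_changes",
    "dist_to_center",
    "mean_abs_turn_inside_outside",
    "summarize",
]

#: Outside excursions shorter than this many steps are foray loops;
#: longer (or equal) ones count as permanent emigration.
FORAY_CUTOFF = 200


@dataclass(frozen=True)
class Episode:
    """A maximal run of constant inside/outside status for one individual."""

    individual: int
    kind: str  # "inside" | "outside"
    cluster: int | None  # cluster index for inside episodes
    start: int  # first window step of the run (inclusive, 0-based)
    end: int  # last window step of the run (inclusive)
    left_censored: bool
    right_censored: bool

    @property
    def duration(self) -> int:
        return self.end - self.start + 1

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored


@dataclass(frozen=True)
class EmigrationEvent:
    """One inside→outside transition and the excursion that follows it."""

    individual: int
    source: int
    exit_step: int  # first step outside
    reentry_step: int | None  # first step back inside, None if unobserved
    destination: int | None
    duration_outside: int  # observed (possibly censored) outside steps
    classification: str  # "foray_loop" | "permanent" | "censored"


@dataclass
class ScenarioSummary:
    """Replicate-level summary: the eight statistics plus extras.

    Percentages are on the 0–100 scale; ``foraging_success`` is a proportion
    in [0, 1].  ``dist_to_center`` is NaN except in single-cluster runs.
    """

    foraging_success: float
    clusters_harvested: float
    visit_time: float
    search_time: float
    pct_permanent_emigration: float
    occupancy: float
    pct_in_clusters: float
    patch_changes: float
    dist_to_center: float
    n_excluded: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# series and segmentation
# ---------------------------------------------------------------------------

def membership_series(log, landscape: Landscape | None = None) -> np.ndarray:
    """(S, N) cluster-membership series recomputed from logged positions.

    The engine logs membership alongside positions; this recomputes it from
    scratch through :meth:`Landscape.membership` so consistency can be
    checked independently.
    """
    landscape = log.landscape if landscape is None else landscape
    S, N = log.x.shape
    pts = np.stack((log.x.ravel(), log.y.ravel()), axis=-1)
    return landscape.membership(pts).reshape(S, N)


def segment_episodes(series: np.ndarray, individual: int = 0) -> list[Episode]:
    """Split one individual's membership series into alternating episodes.

    ``series`` is a 1-D int array over the window (−1 = outside).  Episodes
    partition the window; the first and last are flagged censored at the
    window boundary they touch.
    """
    series = np.asarray(series)
    if series.ndim != 1:
        raise ValueError("series must be 1-D; pass one individual's series")
    S = series.shape[0]
    inside = series >= 0
    # run boundaries: a new run starts where inside-status or cluster changes
    change = np.flatnonzero(
        (inside[1:] != inside[:-1]) | (inside[1:] & (series[1:] != series[:-1]))
    )
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [S - 1]))
    episodes = []
    for s, e in zip(starts, ends):
        episodes.append(
            Episode(
                individual=individual,
                kind="inside" if inside[s] else "outside",
                cluster=int(series[s]) if inside[s] else None,
                start=int(s),
                end=int(e),
                left_censored=s == 0,
                right_censored=e == S - 1,
            )
        )
    return episodes


def detect_events(
    episodes: Sequence[Episode], cutoff: int = FORAY_CUTOFF
) -> list[EmigrationEvent]:
    """Emigration events from one individual's ordered episode list.

    Every inside→outside transition yields one event.  A completed outside
    episode classifies by its duration against ``cutoff``; a right-censored
    one is classified "permanent" if its observed duration already reaches
    the cutoff and "censored" otherwise.
    """
    events = []
    for idx in range(len(episodes) - 1):
        a, b = episodes[idx], episodes[idx + 1]
        if a.kind != "inside" or b.kind != "outside":
            continue
        # the episode after b, if any, is the re-entry
        nxt = episodes[idx + 2] if idx + 2 < len(episodes) else None
        dur = b.duration
        if not b.right_censored:
            classification = "foray_loop" if dur < cutoff else "permanent"
        else:
            classification = "permanent" if dur >= cutoff else "censored"
        events.append(
            EmigrationEvent(
                individual=a.individual,
                source=a.cluster,
                exit_step=b.start,
                reentry_step=nxt.start if nxt is not None else None,
                destination=nxt.cluster if nxt is not None else None,
                duration_outside=dur,
                classification=classification,
            )
        )
    return events


def apply_exclusions(membership: np.ndarray) -> np.ndarray:
    """Boolean mask of individuals with at least one inside step.

    Individuals that never entered a patch within the window are excluded
    from the visitation/searching/emigration/patch-change statistics.  An
    individual already inside at the window start counts as having entered.
    """
    return (membership >= 0).any(axis=0)


# ---------------------------------------------------------------------------
# the eight statistics
# ---------------------------------------------------------------------------

def foraging_success(log) -> float:
    """Mean over individuals of the fraction of steps with >= 1 item found."""
    return float((log.harvested > 0).mean(axis=0).mean())


def clusters_harvested(log) -> float:
    """Mean number of distinct clusters an individual harvested from.

    A harvest is attributed to the cluster the individual occupies at that
    step; individuals that never harvested contribute zero (they stay in the
    mean).
    """
    S, N = log.harvested.shape
    values = np.empty(N)
    for i in range(N):
        hit = (log.harvested[:, i] > 0) & (log.membership[:, i] >= 0)
        values[i] = np.unique(log.membership[hit, i]).size
    return float(values.mean())


def _episodes_by_individual(membership: np.ndarray) -> list[list[Episode]]:
    return [
        segment_episodes(membership[:, i], individual=i)
        for i in range(membership.shape[1])
    ]


def visit_and_search_times(
    episodes_per_ind: list[list[Episode]], included: np.ndarray
) -> tuple[float, float]:
    """Mean patch visitation and patch searching times (steps).

    Per included individual, the mean duration of its inside (visitation)
    and outside (searching) episodes — censored episodes contribute their
    truncated durations — then averaged across individuals.  Individuals
    with no episode of a kind do not enter that mean.
    """
    visit_means, search_means = [], []
    for i in np.flatnonzero(included):
        eps = episodes_per_ind[i]
        v = [e.duration for e in eps if e.kind == "inside"]
        s = [e.duration for e in eps if e.kind == "outside"]
        if v:
            visit_means.append(np.mean(v))
        if s:
            search_means.append(np.mean(s))
    visit = float(np.mean(visit_means)) if visit_means else float("nan")
    search = float(np.mean(search_means)) if search_means else float("nan")
    return visit, search


def pct_permanent_emigration(events: Iterable[EmigrationEvent]) -> float:
    """Percentage of classifiable emigration events that are permanent."""
    classified = [e for e in events if e.classification != "censored"]
    if not classified:
        return float("nan")
    n_perm = sum(e.classification == "permanent" for e in classified)
    return 100.0 * n_perm / len(classified)


def occupancy(membership: np.ndarray, k: int) -> float:
    """Mean percentage of window steps each patch holds >= 1 individual."""
    per_patch = np.empty(k)
    for j in range(k):
        per_patch[j] = (membership == j).any(axis=1).mean()
    return float(100.0 * per_patch.mean())


def pct_in_clusters(membership: np.ndarray) -> float:
    """Mean percentage of individuals inside any cluster, over window steps."""
    return float(100.0 * (membership >= 0).mean())


def patch_changes(
    events_per_ind: list[list[EmigrationEvent]], included: np.ndarray
) -> float:
    """Mean number of successful patch changes per included individual.

    A patch change is an emigration whose next entry is into a different
    cluster than the source; foray loops back to the source never count.
    """
    counts = [
        sum(
            e.destination is not None and e.destination != e.source
            for e in events_per_ind[i]
        )
        for i in np.flatnonzero(included)
    ]
    return float(np.mean(counts)) if counts else float("nan")


def dist_to_center(log, landscape: Landscape | None = None) -> float:
    """Mean distance to the patch center of in-cluster individuals, final step.

    Defined for single-cluster landscapes only; raises otherwise.  NaN when
    no individual is inside at the final logged step.
    """
    landscape = log.landscape if landscape is None else landscape
    if landscape.spec.k != 1:
        raise ValueError("dist_to_center is defined for single-cluster landscapes")
    inside = log.membership[-1] >= 0
    if not inside.any():
        return float("nan")
    pts = np.stack((log.x[-1, inside], log.y[-1, inside]), axis=-1)
    return float(
        torus_distance(pts, landscape.parents[0], landscape.spec.L).mean()
    )


def mean_abs_turn_inside_outside(log) -> tuple[float, float]:
    """Mean absolute turning angle for steps inside vs outside clusters.

    Turning angles are reconstructed from consecutive logged displacements;
    the turn executed at step t is attributed to the membership at t.  Used
    to check the movement-mode contrast (tortuous search inside patches,
    straight movement in the matrix).
    """
    L = log.landscape.spec.L
    dx = np.mod(np.diff(log.x, axis=0) + L / 2, L) - L / 2
    dy = np.mod(np.diff(log.y, axis=0) + L / 2, L) - L / 2
    headings = np.arctan2(dy, dx)  # (S-1, N)
    turns = wrap_angle(np.diff(headings, axis=0))  # (S-2, N), turn at step t
    member_at_turn = log.membership[1:-1]
    inside = member_at_turn >= 0
    turn_abs = np.abs(turns)
    mean_in = float(turn_abs[inside].mean()) if inside.any() else float("nan")
    mean_out = float(turn_abs[~inside].mean()) if (~inside).any() else float("nan")
    return mean_in, mean_out


def summarize(log, cutoff: int = FORAY_CUTOFF) -> ScenarioSummary:
    """All statistics for one replicate's analysis window."""
    membership = log.membership
    landscape = log.landscape
    included = apply_exclusions(membership)
    episodes_per_ind = _episodes_by_individual(membership)
    events_per_ind = [detect_events(eps, cutoff) for eps in episodes_per_ind]
    included_events = [
        e for i in np.flatnonzero(included) for e in events_per_ind[i]
    ]
    visit, search = visit_and_search_times(episodes_per_ind, included)
    return ScenarioSummary(
        foraging_success=foraging_success(log),
        clusters_harvested=clusters_harvested(log),
        visit_time=visit,
        search_time=search,
        pct_permanent_emigration=pct_permanent_emigration(included_events),
        occupancy=occupancy(membership, landscape.spec.k),
        pct_in_clusters=pct_in_clusters(membership),
        patch_changes=patch_changes(events_per_ind, included),
        dist_to_center=(
            dist_to_center(log) if landscape.spec.k == 1 else float("nan")
        ),
        n_excluded=int((~included).sum()),
    )


def summaries_to_frame(summaries: Iterable[ScenarioSummary]) -> pd.DataFrame:
    """One row per replicate summary."""
    return pd.DataFrame([s.as_dict() for s in summaries])
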