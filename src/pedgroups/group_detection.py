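"""Social-group detection from pairwise proximity and its stability in time.

Two pedestrians form a *social pair* when they spend a sufficient fraction
of their shared time on the platform close to each other.  With t_sim the
number of frames both are inside the measurement area (from their first and
last observed frames), t_contact the frames with pairwise distance at most
d_contact (1.5 m) and t_personal the frames at most d_personal (1.0 m)
apart, the pair qualifies when

    t_contact  >= alpha * t_sim      and      t_personal >= beta * t_sim

with validated fractions alpha = 0.85 and beta = 0.4.  Groups larger than
two arise as connected components of qualifying pairs, and a group's size
is the maximum number of members simultaneously present (robust against
id fragmentation inflating the member count).

Candidate pairs come from per-frame Delaunay triangulation of the positions
of all pedestrians present: members of a group are mutual nearest
neighbours, so restricting the distance bookkeeping to Delaunay edges
replaces the O(N^2) all-pairs distance computation with an O(N log N) one
without losing qualifying pairs in the sparse regimes where the criterion
is valid.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError

from .platform_geometry import (
    BOARDING,
    DEFAULT_SNAP_TOLERANCE,
    PlatformGeometry,
    classify_passenger,
)
from .trajectory_io import (
    DEFAULT_MIN_DURATION_S,
    Trajectory,
    TrajectoryDataset,
    filter_min_duration,
)

__all__ = [
    "PairCriterion",
    "ContactStats",
    "SocialGroup",
    "candidate_pairs",
    "contact_stats",
    "is_social_pair",
    "pair_statistics",
    "detect_groups",
    "group_size_distribution",
    "GroupSizeDistribution",
    "max_simultaneous_presence",
]

logger = logging.getLogger(__name__)

# Float guard for the boundary-inclusive comparisons of the pair criterion:
# alpha * t_sim may round just above an integer t_contact that equals the
# exact product.  The guard is ~1e-9 relative, orders of magnitude below the
# 0.05 grid granularity of the parameter study.
_BOUNDARY_EPS = 1e-9


@dataclass(frozen=True)
class PairCriterion:
    """Distance thresholds and minimum contact-time fractions."""

    d_contact: float = 1.5
    d_personal: float = 1.0
    alpha: float = 0.85
    beta: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.d_personal <= self.d_contact:
            raise ValueError("require 0 < d_personal <= d_contact")
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1):
            raise ValueError("alpha and beta must lie in [0, 1]")


@dataclass(frozen=True)
class ContactStats:
    """Frame counts underlying the pair criterion, symmetric in the pair."""

    ped_pair: tuple
    t_contact: int
    t_personal: int
    t_sim: int

    def __post_init__(self) -> None:
        if not 0 <= self.t_personal <= self.t_contact:
            raise ValueError("require 0 <= t_personal <= t_contact")


@dataclass(frozen=True)
class SocialGroup:
    """A connected set of pedestrians linked by qualifying pairs."""

    member_ids: frozenset
    qualifying_pairs: tuple
    size: int

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("a social group has at least two members")
        if not 2 <= self.size <= len(self.member_ids):
            raise ValueError("size must lie in [2, number of member ids]")
        graph = nx.Graph(self.qualifying_pairs)
        if set(graph.nodes) != set(self.member_ids) or not nx.is_connected(graph):
            raise ValueError("qualifying pairs must connect all member ids")


def _sorted_pair(a, b) -> tuple:
    return (a, b) if str(a) <= str(b) else (b, a)


def _frame_table(dataset: TrajectoryDataset, stride: int):
    """Concatenate all samples, sorted by frame; returns (frames, ids, xy)."""
    frames_list, ids_list, pos_list = [], [], []
    for traj in dataset:
        frames_list.append(traj.frames)
        ids_list.append(np.full(len(traj), fill_value=-1, dtype=object))
        ids_list[-1][:] = traj.ped_id
        pos_list.append(traj.positions)
    if not frames_list:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=object),
                np.empty((0, 2)))
    frames = np.concatenate(frames_list)
    ids = np.concatenate(ids_list)
    xy = np.concatenate(pos_list)
    if stride > 1:
        lo = dataset.observation_window[0]
        keep = (frames - lo) % stride == 0
        frames, ids, xy = frames[keep], ids[keep], xy[keep]
    order = np.argsort(frames, kind="stable")
    return frames[order], ids[order], xy[order]


def _delaunay_edges(pts: np.ndarray) -> set[tuple[int, int]]:
    """Index pairs of the Delaunay edges of a point set; degenerate input
    (collinear points, duplicates, fewer than 3 points) falls back to all
    pairs — correctness over speed for rare frames."""
    n = pts.shape[0]
    all_pairs = set(itertools.combinations(range(n), 2))
    if n < 3 or np.unique(pts, axis=0).shape[0] < n:
        return all_pairs
    try:
        tri = Delaunay(pts)
    except QhullError:
        return all_pairs
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for i, j in itertools.combinations(simplex, 2):
            edges.add((min(i, j), max(i, j)))
    return edges


def candidate_pairs(dataset: TrajectoryDataset, stride: int = 1) -> set[tuple]:
    """Union over frames of the Delaunay neighbour pairs.

    Each sampled frame contributes the Delaunay edges over the positions of
    the pedestrians present in it.  ``stride`` evaluates only every k-th
    frame of the observation window (an approximation knob; the default of
    1 is exact and used everywhere results matter).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames, ids, xy = _frame_table(dataset, stride)
    pairs: set[tuple] = set()
    boundaries = np.flatnonzero(np.diff(frames)) + 1
    for chunk_ids, chunk_xy in zip(
        np.split(ids, boundaries), np.split(xy, boundaries)
    ):
        if chunk_ids.size < 2:
            continue
        for i, j in _delaunay_edges(chunk_xy):
            pairs.add(_sorted_pair(chunk_ids[i], chunk_ids[j]))
    return pairs


def contact_stats(
    traj_i: Trajectory, traj_j: Trajectory, criterion: PairCriterion
) -> ContactStats:
    """Contact frame counts for one pair of trajectories.

    t_sim is the inclusive frame count between the later first frame and
    the earlier last frame of the two tracks; it may be non-positive when
    the tracks do not overlap in time.  Frames inside that window where
    either pedestrian is unsampled count toward t_sim but can never count
    as contact.
    """
    t_sim = int(
        min(traj_i.last_frame, traj_j.last_frame)
        - max(traj_i.first_frame, traj_j.first_frame)
        + 1
    )
    if t_sim <= 0:
        return ContactStats(_sorted_pair(traj_i.ped_id, traj_j.ped_id), 0, 0, t_sim)
    common, ii, jj = np.intersect1d(
        traj_i.frames, traj_j.frames, assume_unique=True, return_indices=True
    )
    if common.size == 0:
        t_contact = t_personal = 0
    else:
        diff = traj_i.positions[ii] - traj_j.positions[jj]
        dist = np.hypot(diff[:, 0], diff[:, 1])
        t_contact = int(np.count_nonzero(dist <= criterion.d_contact))
        t_personal = int(np.count_nonzero(dist <= criterion.d_personal))
    return ContactStats(
        _sorted_pair(traj_i.ped_id, traj_j.ped_id), t_contact, t_personal, t_sim
    )


def is_social_pair(stats: ContactStats, criterion: PairCriterion) -> bool:
    """Apply the fraction thresholds to one pair's contact statistics.

    Boundary inclusive: t_contact equal to alpha * t_sim qualifies.  A pair
    with no temporal overlap (t_sim <= 0) never qualifies — the thresholds
    would be vacuous there.
    """
    if stats.t_sim <= 0:
        return False
    eps = _BOUNDARY_EPS * stats.t_sim
    return (
        stats.t_contact >= criterion.alpha * stats.t_sim - eps
        and stats.t_personal >= criterion.beta * stats.t_sim - eps
    )


def pair_statistics(
    dataset: TrajectoryDataset,
    criterion: PairCriterion,
    stride: int = 1,
) -> dict[tuple, ContactStats]:
    """Contact statistics for every Delaunay candidate pair of a dataset."""
    stats: dict[tuple, ContactStats] = {}
    for pair in candidate_pairs(dataset, stride=stride):
        ti = dataset.trajectories[pair[0]]
        tj = dataset.trajectories[pair[1]]
        stats[pair] = contact_stats(ti, tj, criterion)
    return stats


def max_simultaneous_presence(trajectories: list[Trajectory]) -> int:
    """Maximum number of tracks whose [first, last] frame intervals overlap
    at any instant (sweep line over presence intervals)."""
    events: list[tuple[int, int]] = []
    for traj in trajectories:
        events.append((traj.first_frame, 1))
        events.append((traj.last_frame + 1, -1))
    events.sort()
    best = count = 0
    for _, delta in events:
        count += delta
        best = max(best, count)
    return best


def select_population(
    dataset: TrajectoryDataset,
    geometry: PlatformGeometry | None,
    restrict_to_boarding: bool,
    min_duration: float,
    snap_tolerance: float = DEFAULT_SNAP_TOLERANCE,
) -> TrajectoryDataset:
    """The detection population: duration-filtered and, optionally,
    boarding passengers only."""
    filtered = filter_min_duration(dataset, min_duration)
    logger.info(
        "duration filter (>= %.1f s): %d of %d trajectories kept",
        min_duration, len(filtered), len(dataset),
    )
    if not restrict_to_boarding:
        return filtered
    if geometry is None:
        raise ValueError("boarding restriction requires a platform geometry")
    boarding = [
        pid
        for pid, traj in filtered.trajectories.items()
        if classify_passenger(traj, geometry, snap_tolerance) == BOARDING
    ]
    logger.info("boarding restriction: %d trajectories kept", len(boarding))
    return filtered.subset(boarding)


def detect_groups(
    dataset: TrajectoryDataset,
    geometry: PlatformGeometry | None = None,
    criterion: PairCriterion = PairCriterion(),
    restrict_to_boarding: bool = True,
    min_duration: float = DEFAULT_MIN_DURATION_S,
    stride: int = 1,
    snap_tolerance: float = DEFAULT_SNAP_TOLERANCE,
) -> list[SocialGroup]:
    """Full detection pipeline: filter, restrict, pair, threshold, merge.

    Returns disjoint groups ordered by their smallest member id; the result
    is deterministic given the inputs (no randomness anywhere).
    """
    population = select_population(
        dataset, geometry, restrict_to_boarding, min_duration, snap_tolerance
    )
    if len(population) == 0:
        return []
    stats = pair_statistics(population, criterion, stride=stride)
    qualifying = [
        pair for pair, st in stats.items() if is_social_pair(st, criterion)
    ]
    logger.info(
        "candidate pairs: %d, qualifying pairs: %d", len(stats), len(qualifying)
    )
    graph = nx.Graph(qualifying)
    groups: list[SocialGroup] = []
    for component in nx.connected_components(graph):
        members = frozenset(component)
        edges = tuple(
            sorted(
                (p for p in qualifying if p[0] in members and p[1] in members),
                key=lambda p: (str(p[0]), str(p[1])),
            )
        )
        size = max_simultaneous_presence(
            [population.trajectories[pid] for pid in members]
        )
        groups.append(SocialGroup(members, edges, max(size, 2)))
    groups.sort(key=lambda g: min(str(pid) for pid in g.member_ids))
    logger.info("groups detected: %d", len(groups))
    return groups


@dataclass(frozen=True)
class GroupSizeDistribution:
    """Tallies of detected group sizes.

    ``group_pct`` weights every group once; ``member_pct`` weights each
    group by its size (members in groups of that size).  Percentages sum
    to 100 whenever any group is present.
    """

    group_counts: dict[int, int] = field(default_factory=dict)

    @property
    def group_pct(self) -> dict[int, float]:
        total = sum(self.group_counts.values())
        if total == 0:
            return {}
        return {s: 100.0 * n / total for s, n in sorted(self.group_counts.items())}

    @property
    def member_pct(self) -> dict[int, float]:
        total = sum(s * n for s, n in self.group_counts.items())
        if total == 0:
            return {}
        return {
            s: 100.0 * s * n / total for s, n in sorted(self.group_counts.items())
        }


def group_size_distribution(groups: list[SocialGroup]) -> GroupSizeDistribution:
    """Count detected groups per size (see :class:`GroupSizeDistribution`)."""
    counts: dict[int, int] = {}
    for group in groups:
        counts[group.size] = counts.get(group.size, 0) + 1
    return GroupSizeDistribution(counts)
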