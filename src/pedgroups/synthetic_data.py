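"""Synthetic platform scenarios with known ground truth.

The generator emulates the statistical structure the group detector
assumes: boarding passengers arrive at platform entries in a Poisson
stream, alone or in social groups whose size frequencies decrease with
size; each arrival party walks to a waiting anchor, jitters around it for a
sampled waiting time, then walks to a train door on the platform edge;
alighting passengers cross from a door to an entry without stopping.
Group members share one anchor, stand on a circle around it and arrive and
depart together.  Tracks can be fragmented into two ids to emulate sensor
re-detection.

Identifiability by construction
-------------------------------
The fraction-based pair criterion is only meaningful when unrelated
pedestrians cannot mimic sustained proximity.  The generator therefore
enforces two low-density constraints: waiting anchors of co-present
parties are at least ``anchor_separation_m`` apart (default 4 m), and the
co-presence window of two unrelated parties is either empty or at least
``min_stranger_overlap_s`` long (default 25 s).  Together with bounded
positional jitter and walk phases of bounded duration, these imply that no
stranger pair can be in contact for 85% of its shared time, so detection
at the validated fractions has precision 1 on clean scenarios — the basis
of the parameter-recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Point
from shapely.ops import nearest_points, unary_union
from shapely.prepared import prep

from .platform_geometry import ALIGHTING, BOARDING, PlatformGeometry, schematic_platform
from .trajectory_io import Trajectory, TrajectoryDataset

__all__ = [
    "WaitingTimeLaw",
    "ScenarioConfig",
    "LabelledScenario",
    "generate_scenario",
    "corrupt_tracks",
    "save_truth",
    "load_truth",
]

# Jitter process: per-axis AR(1) with unit-lag correlation _OU_RHO, scaled to
# the configured stationary sd and clipped at 3.5 sd (bounded random walk).
_OU_RHO = 0.9
_NOISE_CLIP_SD = 3.5
# Formation offsets shrink to this fraction at the track ends (members
# funnel through the entry / door) over _RAMP_S seconds.
_RAMP_FLOOR = 0.1
_RAMP_S = 2.0
# Walk targets are placed this far inside the entry/edge regions so that
# discretised, jittered endpoints remain plausibly inside them.
_TARGET_INSET_M = 0.3
# Hard cap on how far scheduling may delay a party's arrival.
_MAX_NUDGE_S = 90.0


@dataclass(frozen=True)
class WaitingTimeLaw:
    """Shifted-exponential pre-departure waiting time (seconds).

    A minimum dwell plus an exponential tail reproduces the observed mix of
    short-headway and long-wait passengers; with the defaults most waits
    fall below two minutes while a tail extends past ten.
    """

    min_s: float = 30.0
    mean_s: float = 90.0

    def sample(self, rng: np.random.Generator) -> float:
        return self.min_s + rng.exponential(max(self.mean_s - self.min_s, 1e-9))


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic platform scenario."""

    geometry: PlatformGeometry = field(default_factory=schematic_platform)
    duration_s: float = 2700.0
    frame_rate: float = 10.0
    arrival_rate_per_min: float = 6.0
    #: probability of arrival-party sizes 1..K; non-increasing in size
    group_size_pmf: tuple[float, ...] = (0.80, 0.12, 0.05, 0.02, 0.007, 0.003)
    intra_group_spacing_m: float = 0.5
    jitter_sd_m: float = 0.10
    walk_speed_mps: float = 1.2
    waiting_law: WaitingTimeLaw = field(default_factory=WaitingTimeLaw)
    alighting_rate_per_min: float = 6.0
    fragmentation_prob: float = 0.0
    min_stranger_overlap_s: float = 25.0
    anchor_separation_m: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        pmf = np.asarray(self.group_size_pmf, dtype=float)
        if pmf.size == 0 or np.any(pmf < 0) or abs(pmf.sum() - 1.0) > 1e-9:
            raise ValueError("group_size_pmf must be non-negative and sum to 1")
        if np.any(np.diff(pmf) > 1e-12):
            raise ValueError(
                "group_size_pmf must be non-increasing in group size"
            )
        for name in (
            "duration_s", "frame_rate", "walk_speed_mps",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "arrival_rate_per_min", "alighting_rate_per_min",
            "intra_group_spacing_m", "jitter_sd_m",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.fragmentation_prob <= 1.0:
            raise ValueError("fragmentation_prob must lie in [0, 1]")
        if not (self.geometry.entry_regions and self.geometry.edge_regions):
            raise ValueError(
                "geometry must define at least one entry and one edge region"
            )


@dataclass
class LabelledScenario:
    """A generated dataset plus its generator-known ground truth."""

    dataset: TrajectoryDataset
    geometry: PlatformGeometry
    truth_groups: list[frozenset]
    truth_class: dict
    truth_waiting: dict

    def __post_init__(self) -> None:
        known = set(self.dataset.trajectories)
        for group in self.truth_groups:
            if not set(group) <= known:
                raise ValueError("truth group references unknown ids")
        if not set(self.truth_class) <= known:
            raise ValueError("truth classes reference unknown ids")

    @property
    def truth_member_ids(self) -> frozenset:
        out: set = set()
        for group in self.truth_groups:
            out |= set(group)
        return frozenset(out)


# -- geometric sampling helpers --------------------------------------------


def _sample_in_polygon(poly, rng: np.random.Generator, margin: float = 0.15):
    """Uniform point inside ``poly`` shrunk by ``margin`` (rejection)."""
    core = poly.buffer(-margin)
    if core.is_empty:
        core = poly
        margin = 0.0
    xmin, ymin, xmax, ymax = core.bounds
    for _ in range(1000):
        p = Point(rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
        if core.covers(p):
            return np.array([p.x, p.y])
    c = core.centroid
    return np.array([c.x, c.y])


def _formation_offsets(
    k: int, spacing: float, rng: np.random.Generator
) -> np.ndarray:
    """Member offsets on a circle with adjacent members ~``spacing`` apart
    (groups form circles to keep eye contact)."""
    if k == 1:
        return np.zeros((1, 2))
    radius = spacing / (2.0 * math.sin(math.pi / k))
    phase = rng.uniform(0.0, 2.0 * math.pi)
    angles = phase + 2.0 * math.pi * np.arange(k) / k
    return radius * np.column_stack([np.cos(angles), np.sin(angles)])


def _ou_noise(
    n: int, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Bounded AR(1) positional jitter, shape (n, 2), starting at zero."""
    out = np.zeros((n, 2))
    if sd <= 0 or n == 0:
        return out
    scale = math.sqrt(1.0 - _OU_RHO**2) * sd
    steps = rng.normal(0.0, scale, size=(n, 2))
    for t in range(1, n):
        out[t] = np.clip(
            _OU_RHO * out[t - 1] + steps[t], -_NOISE_CLIP_SD * sd, _NOISE_CLIP_SD * sd
        )
    return out


def _inset_target(point, toward, region_union, inset: float):
    """Move ``point`` ``inset`` metres away from ``toward`` (deeper into the
    region it sits on) when the result stays inside the region."""
    vec = point - toward
    norm = float(np.hypot(*vec))
    if norm < 1e-9:
        return point
    candidate = point + vec / norm * inset
    if region_union.covers(Point(*candidate)):
        return candidate
    return point


@dataclass
class _Party:
    """One arrival event: a pedestrian or a social group sharing an anchor."""

    arrival_s: float
    size: int
    entry_point: np.ndarray
    wait_s: float
    anchor: np.ndarray | None = None
    door_point: np.ndarray | None = None
    walk_in_s: float = 0.0
    walk_out_s: float = 0.0

    @property
    def departure_s(self) -> float:
        return self.arrival_s + self.walk_in_s + self.wait_s + self.walk_out_s


def _poisson_times(
    rate_per_min: float, duration_s: float, rng: np.random.Generator
) -> list[float]:
    if rate_per_min <= 0:
        return []
    times, t = [], 0.0
    while True:
        t += rng.exponential(60.0 / rate_per_min)
        if t >= duration_s:
            return times
        times.append(t)


def _anchor_distance_range(size: int) -> tuple[float, float]:
    # Larger groups need open space and settle close to the entries;
    # individuals drift further out toward the stair sides and obstacles.
    if size >= 4:
        return 2.0, 6.0
    if size >= 2:
        return 3.0, 10.0
    return 4.0, 12.0


def generate_scenario(config: ScenarioConfig) -> LabelledScenario:
    """Generate one labelled scenario, fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    geom = config.geometry
    fps = config.frame_rate

    entry_names = sorted(geom.entry_regions)
    edge_union = unary_union(list(geom.edge_regions.values()))
    boundary_union = unary_union(list(geom.boundary_regions()))
    obstacle_union = unary_union(list(geom.obstacles.values())) if geom.obstacles \
        else None
    # anchors must stay clear of start/end regions (QC and fragmentation
    # semantics) and clear of obstacles (people do not stand inside walls)
    clearance = 1.2
    allowed = geom.measurement_area.difference(boundary_union.buffer(clearance))
    if obstacle_union is not None:
        allowed = allowed.difference(obstacle_union.buffer(0.6))
    if allowed.is_empty:
        raise ValueError("geometry leaves no room for waiting anchors")
    allowed_prep = prep(allowed)

    sizes = np.arange(1, len(config.group_size_pmf) + 1)

    # -- pass 1: arrival skeletons ------------------------------------
    parties: list[_Party] = []
    for t in _poisson_times(config.arrival_rate_per_min, config.duration_s, rng):
        size = int(rng.choice(sizes, p=config.group_size_pmf))
        entry = geom.entry_regions[entry_names[int(rng.integers(len(entry_names)))]]
        parties.append(
            _Party(
                arrival_s=t,
                size=size,
                entry_point=_sample_in_polygon(entry, rng),
                wait_s=config.waiting_law.sample(rng),
            )
        )

    # -- pass 2: anchors, doors, scheduling ----------------------------
    # Arrival nudges (below) only ever delay a party, by at most
    # _MAX_NUDGE_S, so a neighbour window padded by slightly more than that
    # is guaranteed to cover every party the final presence can overlap.
    placed: list[_Party] = []
    for party in parties:
        window = (party.arrival_s - 10.0,
                  party.arrival_s + party.wait_s + _MAX_NUDGE_S + 60.0)
        neighbours = [
            o for o in placed
            if min(window[1], o.departure_s) - max(window[0], o.arrival_s) > 0
        ]
        lo, hi = _anchor_distance_range(party.size)
        anchor = None
        for _ in range(800):
            d = rng.uniform(lo, hi)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            cand = party.entry_point + d * np.array(
                [math.cos(theta), math.sin(theta)]
            )
            if not allowed_prep.covers(Point(*cand)):
                continue
            if any(
                np.hypot(*(cand - o.anchor)) < config.anchor_separation_m
                for o in neighbours
            ):
                continue
            anchor = cand
            break
        if anchor is None:
            continue  # platform locally saturated; drop the party
        party.anchor = anchor

        near = nearest_points(edge_union, Point(*anchor))[0]
        door = _inset_target(
            np.array([near.x, near.y]), anchor, edge_union, _TARGET_INSET_M
        )
        party.door_point = door
        party.walk_in_s = float(
            np.hypot(*(anchor - party.entry_point)) / config.walk_speed_mps
        )
        party.walk_out_s = float(np.hypot(*(door - anchor)) / config.walk_speed_mps)

        # stranger co-presence must be empty or long enough that walking
        # phases cannot dominate the shared time
        nudged = 0.0
        for _ in range(50):
            conflict_shift = 0.0
            for o in placed:
                ov = min(party.departure_s, o.departure_s) - max(
                    party.arrival_s, o.arrival_s
                )
                if 0.0 < ov < config.min_stranger_overlap_s:
                    if o.departure_s <= party.departure_s:
                        # o ends inside our head: start just after o leaves
                        conflict_shift = o.departure_s + 0.5 - party.arrival_s
                    else:
                        # our tail clips o's start: stretch the overlap
                        conflict_shift = config.min_stranger_overlap_s - ov
                    break
            if conflict_shift <= 0.0:
                break
            party.arrival_s += conflict_shift
            nudged += conflict_shift
            if nudged > _MAX_NUDGE_S:
                break
        else:
            continue
        if nudged > _MAX_NUDGE_S or party.departure_s > config.duration_s:
            continue  # no admissible slot before the observation ends
        placed.append(party)

    placed.sort(key=lambda p: p.arrival_s)

    # -- pass 3: trajectory synthesis ----------------------------------
    trajectories: dict[int, Trajectory] = {}
    truth_groups: list[frozenset] = []
    truth_class: dict = {}
    truth_waiting: dict = {}
    next_id = 1

    for party in placed:
        offsets = _formation_offsets(party.size, config.intra_group_spacing_m, rng)
        f0 = math.ceil(party.arrival_s * fps)
        f1 = math.floor(party.departure_s * fps)
        if f1 <= f0:
            continue
        frames = np.arange(f0, f1 + 1, dtype=np.int64)
        times = frames / fps
        t_wait0 = party.arrival_s + party.walk_in_s
        t_wait1 = t_wait0 + party.wait_s
        base = np.empty((frames.size, 2))
        for axis in range(2):
            base[:, axis] = np.interp(
                times,
                [party.arrival_s, t_wait0, t_wait1, party.departure_s],
                [
                    party.entry_point[axis],
                    party.anchor[axis],
                    party.anchor[axis],
                    party.door_point[axis],
                ],
            )
        ramp = np.clip(
            np.minimum(times - party.arrival_s, party.departure_s - times)
            / _RAMP_S,
            _RAMP_FLOOR,
            1.0,
        )
        member_ids = []
        for offset in offsets:
            noise = _ou_noise(frames.size, config.jitter_sd_m, rng)
            positions = base + ramp[:, None] * offset[None, :] + noise
            pid = next_id
            next_id += 1
            trajectories[pid] = Trajectory(pid, frames.copy(), positions, fps)
            truth_class[pid] = BOARDING
            truth_waiting[pid] = (t_wait0, t_wait1)
            member_ids.append(pid)
        if party.size >= 2:
            truth_groups.append(frozenset(member_ids))

    for t in _poisson_times(config.alighting_rate_per_min, config.duration_s, rng):
        edge_name = sorted(geom.edge_regions)[int(rng.integers(len(geom.edge_regions)))]
        start = _sample_in_polygon(geom.edge_regions[edge_name], rng)
        entry_name = entry_names[int(rng.integers(len(entry_names)))]
        end = _sample_in_polygon(geom.entry_regions[entry_name], rng)
        cross_s = float(np.hypot(*(end - start)) / config.walk_speed_mps)
        if t + cross_s > config.duration_s:
            continue
        f0 = math.ceil(t * fps)
        f1 = math.floor((t + cross_s) * fps)
        if f1 <= f0:
            continue
        frames = np.arange(f0, f1 + 1, dtype=np.int64)
        frac = (frames / fps - t) / cross_s
        base = start[None, :] + frac[:, None] * (end - start)[None, :]
        noise = _ou_noise(frames.size, config.jitter_sd_m, rng)
        pid = next_id
        next_id += 1
        trajectories[pid] = Trajectory(pid, frames, base + noise, fps)
        truth_class[pid] = ALIGHTING

    window = (0, math.floor(config.duration_s * fps))
    if not trajectories:
        window = (0, 0)
    scenario = LabelledScenario(
        dataset=TrajectoryDataset(
            trajectories=trajectories,
            frame_rate=fps,
            observation_window=window,
        ),
        geometry=geom,
        truth_groups=truth_groups,
        truth_class=truth_class,
        truth_waiting=truth_waiting,
    )
    if config.fragmentation_prob > 0:
        child_seed = int(rng.integers(2**31))
        scenario = corrupt_tracks(scenario, config.fragmentation_prob, child_seed)
    return scenario


def corrupt_tracks(
    scenario: LabelledScenario, fragmentation_prob: float, seed: int
) -> LabelledScenario:
    """Split tracks to emulate sensor loss and re-detection.

    ``fragmentation_prob`` is the expected fraction of *output* tracks that
    are fragments: each input track is cut with probability
    q = p / (2 - p) at a frame where the pedestrian is away from any
    plausible start/end region, the first fragment keeping its id and the
    second receiving a fresh one.  Truth labels follow both fragments.
    Per-track decisions are drawn in fixed id order, so the set of cut
    tracks is nested across probabilities for a fixed seed.
    """
    if not 0.0 <= fragmentation_prob <= 1.0:
        raise ValueError("fragmentation_prob must lie in [0, 1]")
    if fragmentation_prob == 0.0:
        return scenario
    q = fragmentation_prob / (2.0 - fragmentation_prob)
    rng = np.random.default_rng(seed)
    plausible = prep(scenario.geometry.boundary_union(0.55))

    ids = sorted(scenario.dataset.trajectories, key=str)
    int_ids = [i for i in ids if isinstance(i, (int, np.integer))]
    next_id = (max(int_ids) + 1) if int_ids else 0

    new_trajs: dict = {}
    renames: dict = {}  # original id -> list of fragment ids
    for pid in ids:
        traj = scenario.dataset.trajectories[pid]
        u = rng.random()
        c = rng.random()
        cut_ids = None
        if u < q and len(traj) >= 4:
            interior = np.arange(2, len(traj) - 1)
            away = [
                i for i in interior
                if not plausible.covers(Point(*traj.positions[i]))
            ]
            if away:
                cut = away[int(c * len(away))]
                frag2_id: int | str = (
                    next_id if isinstance(pid, (int, np.integer)) else f"{pid}.b"
                )
                if isinstance(pid, (int, np.integer)):
                    next_id += 1
                new_trajs[pid] = Trajectory(
                    pid, traj.frames[:cut], traj.positions[:cut], traj.frame_rate
                )
                new_trajs[frag2_id] = Trajectory(
                    frag2_id,
                    traj.frames[cut:],
                    traj.positions[cut:],
                    traj.frame_rate,
                )
                cut_ids = [pid, frag2_id]
        if cut_ids is None:
            new_trajs[pid] = traj
            cut_ids = [pid]
        renames[pid] = cut_ids

    def expand(group):
        out = set()
        for pid in group:
            out.update(renames.get(pid, [pid]))
        return frozenset(out)

    new_class = {}
    new_waiting = {}
    for pid, frag_ids in renames.items():
        for fid in frag_ids:
            if pid in scenario.truth_class:
                new_class[fid] = scenario.truth_class[pid]
            if pid in scenario.truth_waiting:
                new_waiting[fid] = scenario.truth_waiting[pid]

    return LabelledScenario(
        dataset=TrajectoryDataset(
            trajectories=new_trajs,
            frame_rate=scenario.dataset.frame_rate,
            observation_window=scenario.dataset.observation_window,
        ),
        geometry=scenario.geometry,
        truth_groups=[expand(g) for g in scenario.truth_groups],
        truth_class=new_class,
        truth_waiting=new_waiting,
    )


# -- truth serialisation ----------------------------------------------------


def save_truth(scenario: LabelledScenario, sink: str | Path) -> None:
    doc = {
        "groups": [sorted(g, key=str) for g in scenario.truth_groups],
        "classes": {str(k): v for k, v in scenario.truth_class.items()},
        "waiting": {
            str(k): [float(a), float(b)]
            for k, (a, b) in scenario.truth_waiting.items()
        },
    }
    Path(sink).write_text(json.dumps(doc, indent=2) + "\n")


def load_truth(source: str | Path) -> dict:
    """Truth JSON as a dict with integer ids restored where possible."""
    doc = json.loads(Path(source).read_text())

    def fix(k):
        try:
            return int(k)
        except (TypeError, ValueError):
            return k

    return {
        "groups": [frozenset(fix(i) for i in g) for g in doc.get("groups", [])],
        "classes": {fix(k): v for k, v in doc.get("classes", {}).items()},
        "waiting": {
            fix(k): tuple(v) for k, v in doc.get("waiting", {}).items()
        },
    }
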