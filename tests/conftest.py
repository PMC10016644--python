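"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pedgroups import (
    ScenarioConfig,
    Trajectory,
    TrajectoryDataset,
    generate_scenario,
    schematic_platform,
)


def make_traj(ped_id, frames, positions, frame_rate=10.0) -> Trajectory:
    return Trajectory(
        ped_id,
        np.asarray(frames, dtype=np.int64),
        np.asarray(positions, dtype=np.float64),
        frame_rate,
    )


def straight_traj(ped_id, start, end, n_frames, first_frame=0, frame_rate=10.0):
    """Straight constant-speed track from start to end over n_frames samples."""
    frac = np.linspace(0.0, 1.0, n_frames)[:, None]
    pos = np.asarray(start)[None, :] + frac * (
        np.asarray(end) - np.asarray(start)
    )[None, :]
    frames = np.arange(first_frame, first_frame + n_frames)
    return make_traj(ped_id, frames, pos, frame_rate)


def dataset_of(*trajs, frame_rate=10.0) -> TrajectoryDataset:
    return TrajectoryDataset(
        trajectories={t.ped_id: t for t in trajs}, frame_rate=frame_rate
    )


def brute_force_pair_counts(ti, tj, d_contact, d_personal):
    """Frame-by-frame contact counting, independent of the library path."""
    t_sim = (
        min(ti.frames[-1], tj.frames[-1]) - max(ti.frames[0], tj.frames[0]) + 1
    )
    pos_j = {int(f): p for f, p in zip(tj.frames, tj.positions)}
    tc = tp = 0
    for f, p in zip(ti.frames, ti.positions):
        q = pos_j.get(int(f))
        if q is None:
            continue
        d = math.hypot(p[0] - q[0], p[1] - q[1])
        if d <= d_contact:
            tc += 1
        if d <= d_personal:
            tp += 1
    return tc, tp, int(t_sim)


def brute_force_qualifying_pairs(dataset, d_contact, d_personal, alpha, beta):
    """All-pairs qualifying-pair detection (the O(N^2) reference pipeline)."""
    ids = sorted(dataset.trajectories, key=str)
    out = set()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            ti = dataset.trajectories[ids[a]]
            tj = dataset.trajectories[ids[b]]
            tc, tp, t_sim = brute_force_pair_counts(ti, tj, d_contact, d_personal)
            if t_sim <= 0:
                continue
            if tc >= alpha * t_sim - 1e-9 and tp >= beta * t_sim - 1e-9:
                out.add(tuple(sorted((ids[a], ids[b]), key=str)))
    return out


@pytest.fixture(scope="session")
def geometry():
    return schematic_platform()


@pytest.fixture(scope="session")
def scenario():
    """The default labelled scenario used throughout the heavier tests."""
    return generate_scenario(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def small_scenario():
    """A lighter scenario for tests that re-run detection several times."""
    return generate_scenario(
        ScenarioConfig(seed=7, duration_s=900.0, arrival_rate_per_min=5.0,
                       alighting_rate_per_min=3.0)
    )
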