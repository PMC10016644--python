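"""Candidate pairing, contact statistics, pair criterion and group assembly."""

import numpy as np
import pytest

from conftest import (
    brute_force_qualifying_pairs,
    dataset_of,
    make_traj,
    straight_traj,
)
from pedgroups import (
    ContactStats,
    PairCriterion,
    candidate_pairs,
    contact_stats,
    detect_groups,
    group_size_distribution,
    is_social_pair,
)
from pedgroups.group_detection import max_simultaneous_presence, pair_statistics


def _one_frame_dataset(points):
    trajs = [
        make_traj(i, [0], np.asarray([p], dtype=float)) for i, p in enumerate(points)
    ]
    return dataset_of(*trajs)


def test_triangle_yields_all_three_pairs():
    ds = _one_frame_dataset([(0, 0), (1, 0), (0.5, 1.0)])
    assert candidate_pairs(ds) == {(0, 1), (0, 2), (1, 2)}


def test_two_pedestrians_yield_their_pair():
    ds = _one_frame_dataset([(0, 0), (3, 4)])
    assert candidate_pairs(ds) == {(0, 1)}


def test_single_pedestrian_yields_nothing():
    assert candidate_pairs(_one_frame_dataset([(0, 0)])) == set()


def test_square_with_centre_has_spokes_but_one_diagonal_at_most():
    pts = [(0, 0), (1, 0), (0, 1), (1, 1), (0.5, 0.5)]
    pairs = candidate_pairs(_one_frame_dataset(pts))
    centre = 4
    for corner in range(4):
        assert tuple(sorted((corner, centre))) in pairs
    diagonals = {(0, 3), (1, 2)}
    assert len(pairs & diagonals) <= 1


def test_collinear_frame_falls_back_to_all_pairs():
    ds = _one_frame_dataset([(0, 0), (1, 0), (2, 0), (3, 0)])
    assert len(candidate_pairs(ds)) == 6


def test_duplicate_positions_fall_back_to_all_pairs():
    ds = _one_frame_dataset([(0, 0), (0, 0), (1, 1), (2, 0)])
    assert len(candidate_pairs(ds)) == 6


def test_contact_stats_identical_tracks():
    a = straight_traj("a", (0, 0), (5, 0), 100)
    b = straight_traj("b", (0, 0), (5, 0), 100)
    st = contact_stats(a, b, PairCriterion())
    assert (st.t_contact, st.t_personal, st.t_sim) == (100, 100, 100)


def test_contact_stats_constant_offset():
    a = straight_traj("a", (0, 0), (5, 0), 100)
    b = straight_traj("b", (0, 0.8), (5, 0.8), 100)
    st = contact_stats(a, b, PairCriterion())
    assert (st.t_contact, st.t_personal, st.t_sim) == (100, 100, 100)


def test_contact_stats_linear_separation():
    # d(t) = 0.5 + 0.02 t for t = 0..100: contact until t=50, personal to t=25
    n = 101
    frames = np.arange(n)
    a = make_traj("a", frames, np.zeros((n, 2)))
    b = make_traj("b", frames, np.column_stack([np.zeros(n), 0.5 + 0.02 * frames]))
    st = contact_stats(a, b, PairCriterion())
    assert (st.t_contact, st.t_personal, st.t_sim) == (51, 26, 101)


def test_contact_stats_no_overlap_is_nonpositive():
    a = straight_traj("a", (0, 0), (1, 0), 50, first_frame=0)
    b = straight_traj("b", (0, 0), (1, 0), 50, first_frame=100)
    st = contact_stats(a, b, PairCriterion())
    assert st.t_sim <= 0
    assert not is_social_pair(st, PairCriterion())


def test_contact_stats_symmetric():
    rng = np.random.default_rng(2)
    a = make_traj("a", np.arange(80), rng.normal(size=(80, 2)))
    b = make_traj("b", np.arange(20, 120), rng.normal(size=(100, 2)))
    crit = PairCriterion()
    assert contact_stats(a, b, crit) == contact_stats(b, a, crit)


def test_gap_frames_count_toward_tsim_but_not_contact():
    # b is unsampled over frames 40..59 while staying "present" per its span
    frames_b = np.concatenate([np.arange(0, 40), np.arange(60, 100)])
    a = make_traj("a", np.arange(100), np.zeros((100, 2)))
    b = make_traj("b", frames_b, np.zeros((frames_b.size, 2)))
    st = contact_stats(a, b, PairCriterion())
    assert st.t_sim == 100
    assert st.t_contact == 80


@pytest.mark.parametrize(
    "t_contact,t_personal,expected",
    [(85, 40, True), (84, 40, False), (85, 39, False)],
)
def test_pair_criterion_boundary_inclusive(t_contact, t_personal, expected):
    stats = ContactStats(("a", "b"), t_contact, t_personal, 100)
    assert is_social_pair(stats, PairCriterion()) is expected


def test_degenerate_criterion_accepts_any_overlap():
    stats = ContactStats(("a", "b"), 0, 0, 1)
    crit = PairCriterion(alpha=0.0, beta=0.0)
    assert is_social_pair(stats, crit)


def test_detect_isolated_pair():
    pair_a = straight_traj("a", (0, 0), (0, 0.0), 300)
    pair_b = straight_traj("b", (0.6, 0), (0.6, 0.0), 300)
    loner = straight_traj("c", (10, 0), (10, 0.0), 300)
    groups = detect_groups(
        dataset_of(pair_a, pair_b, loner), restrict_to_boarding=False,
        min_duration=0.0,
    )
    assert len(groups) == 1
    assert groups[0].member_ids == frozenset({"a", "b"})
    assert groups[0].size == 2


def test_shared_member_merges_pairs_into_one_group():
    a = straight_traj("a", (0, 0), (0, 0), 300)
    b = straight_traj("b", (0.6, 0), (0.6, 0), 300)
    c = straight_traj("c", (1.2, 0), (1.2, 0), 300)  # close to b, 1.2 m from a
    groups = detect_groups(
        dataset_of(a, b, c), restrict_to_boarding=False, min_duration=0.0,
        criterion=PairCriterion(alpha=0.8, beta=0.8),
    )
    assert len(groups) == 1
    assert groups[0].member_ids == frozenset({"a", "b", "c"})


def test_group_size_is_max_simultaneous_presence():
    # presence windows [0,100], [50,150], [120,200]: never three at once
    a = straight_traj("a", (0, 0), (0, 0), 101, first_frame=0)
    b = straight_traj("b", (0.5, 0), (0.5, 0), 101, first_frame=50)
    c = straight_traj("c", (0, 0.5), (0, 0.5), 81, first_frame=120)
    assert max_simultaneous_presence([a, b, c]) == 2
    groups = detect_groups(
        dataset_of(a, b, c), restrict_to_boarding=False, min_duration=0.0,
        criterion=PairCriterion(alpha=0.3, beta=0.3),
    )
    assert len(groups) == 1
    assert groups[0].size == 2


def test_empty_population_gives_no_groups(geometry):
    assert detect_groups(dataset_of(), geometry) == []


def test_group_size_distribution_weightings():
    from pedgroups import SocialGroup

    groups = []
    for members in ({"a", "b"}, {"c", "d"}, {"e", "f", "g"}):
        ids = sorted(members)
        edges = tuple((ids[i], ids[i + 1]) for i in range(len(ids) - 1))
        groups.append(SocialGroup(frozenset(members), edges, len(members)))
    dist = group_size_distribution(groups)
    assert dist.group_pct[2] == pytest.approx(100 * 2 / 3)
    assert dist.group_pct[3] == pytest.approx(100 / 3)
    assert dist.member_pct[2] == pytest.approx(100 * 4 / 7)
    assert dist.member_pct[3] == pytest.approx(100 * 3 / 7)
    assert sum(dist.group_pct.values()) == pytest.approx(100.0)
    assert group_size_distribution([]).group_pct == {}


def test_monotone_in_alpha_beta(small_scenario):
    from pedgroups.group_detection import select_population

    population = select_population(
        small_scenario.dataset, small_scenario.geometry, True, 20.0
    )
    stats = pair_statistics(population, PairCriterion())
    levels = [0.0, 0.25, 0.5, 0.75, 1.0]

    def pairs_at(alpha, beta):
        crit = PairCriterion(alpha=alpha, beta=beta)
        return {p for p, s in stats.items() if is_social_pair(s, crit)}

    for beta in levels:
        sets = [pairs_at(alpha, beta) for alpha in levels]
        for tighter, looser in zip(sets[1:], sets):
            assert tighter <= looser
    for alpha in levels:
        sets = [pairs_at(alpha, beta) for beta in levels]
        for tighter, looser in zip(sets[1:], sets):
            assert tighter <= looser


def test_distance_thresholds_monotone():
    rng = np.random.default_rng(8)
    a = make_traj("a", np.arange(200), rng.normal(scale=0.5, size=(200, 2)))
    b = make_traj("b", np.arange(200), rng.normal(scale=0.5, size=(200, 2)))
    narrow = contact_stats(a, b, PairCriterion(d_contact=1.0, d_personal=0.5))
    wide = contact_stats(a, b, PairCriterion(d_contact=2.0, d_personal=1.0))
    assert narrow.t_contact <= wide.t_contact
    assert narrow.t_personal <= wide.t_personal


def test_delaunay_pipeline_matches_bruteforce_on_clustered_scene():
    # three tight clusters far apart, plus two rovers: identical pair sets
    rng = np.random.default_rng(17)
    centres = [(0.0, 0.0), (8.0, 0.0), (4.0, 7.0)]
    trajs = []
    pid = 0
    n = 150
    for cx, cy in centres:
        for _ in range(3):
            jitter = rng.normal(scale=0.08, size=(n, 2))
            base = np.array([cx, cy]) + rng.normal(scale=0.2, size=2)
            trajs.append(make_traj(pid, np.arange(n), base + jitter))
            pid += 1
    for _ in range(2):  # fast walkers crossing the scene
        start = rng.uniform(-2, 10, size=2)
        end = rng.uniform(-2, 10, size=2)
        trajs.append(straight_traj(pid, start, end, n))
        pid += 1
    ds = dataset_of(*trajs)
    crit = PairCriterion()
    stats = pair_statistics(ds, crit)
    ours = {p for p, s in stats.items() if is_social_pair(s, crit)}
    reference = brute_force_qualifying_pairs(ds, 1.5, 1.0, 0.85, 0.4)
    assert ours == reference


def test_detection_rigid_invariance():
    rng = np.random.default_rng(23)
    trajs = []
    for pid, centre in enumerate([(0, 0), (0.6, 0), (6, 3)]):
        jitter = rng.normal(scale=0.05, size=(200, 2))
        trajs.append(make_traj(pid, np.arange(200), np.array(centre) + jitter))
    ds = dataset_of(*trajs)
    theta = 1.1
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    moved = dataset_of(
        *[
            make_traj(t.ped_id, t.frames, t.positions @ rot.T + np.array([7.0, -2.0]))
            for t in trajs
        ]
    )
    kw = dict(restrict_to_boarding=False, min_duration=0.0)
    original = detect_groups(ds, **kw)
    transformed = detect_groups(moved, **kw)
    assert [g.member_ids for g in original] == [g.member_ids for g in transformed]
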