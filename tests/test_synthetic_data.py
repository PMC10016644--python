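"""Generator contracts: determinism, ground-truth labelling, separation,
group-size law and track fragmentation."""

import numpy as np
import pytest

from conftest import dataset_of, straight_traj
from pedgroups import (
    BOARDING,
    LabelledScenario,
    ScenarioConfig,
    classify_passenger,
    corrupt_tracks,
    generate_scenario,
    load_truth,
    save_truth,
)


def test_same_seed_is_bit_identical():
    cfg = ScenarioConfig(seed=5, duration_s=600.0)
    a = generate_scenario(cfg)
    b = generate_scenario(cfg)
    assert a.dataset == b.dataset
    assert a.truth_groups == b.truth_groups
    assert a.truth_class == b.truth_class


def test_different_seeds_differ():
    a = generate_scenario(ScenarioConfig(seed=5, duration_s=600.0))
    b = generate_scenario(ScenarioConfig(seed=6, duration_s=600.0))
    assert a.dataset != b.dataset


def test_zero_rates_give_empty_dataset():
    cfg = ScenarioConfig(
        seed=1, duration_s=300.0, arrival_rate_per_min=0.0,
        alighting_rate_per_min=0.0,
    )
    scenario = generate_scenario(cfg)
    assert len(scenario.dataset) == 0
    assert scenario.truth_groups == []


def test_pmf_must_be_non_increasing_and_normalised():
    with pytest.raises(ValueError):
        ScenarioConfig(group_size_pmf=(0.5, 0.6))
    with pytest.raises(ValueError):
        ScenarioConfig(group_size_pmf=(0.5, 0.4))


def test_geometry_without_entries_rejected(geometry):
    from pedgroups import PlatformGeometry

    bare = PlatformGeometry(
        measurement_area=geometry.measurement_area,
        entry_regions={},
        edge_regions=dict(geometry.edge_regions),
    )
    with pytest.raises(ValueError, match="entry"):
        ScenarioConfig(geometry=bare)


def test_truth_classes_match_endpoint_classification(scenario):
    sample = list(scenario.truth_class.items())[::7]
    for pid, label in sample:
        observed = classify_passenger(
            scenario.dataset.trajectories[pid], scenario.geometry
        )
        assert observed == label


def test_group_members_arrive_and_depart_together(scenario):
    for group in scenario.truth_groups:
        firsts = {scenario.dataset.trajectories[p].first_frame for p in group}
        lasts = {scenario.dataset.trajectories[p].last_frame for p in group}
        assert max(firsts) - min(firsts) <= 1
        assert max(lasts) - min(lasts) <= 1


def test_intra_group_proximity_dominates_shared_time(scenario):
    # adjacent members stand ~0.5 m apart; the personal-distance fraction
    # of their co-presence must be overwhelming by construction
    from conftest import brute_force_pair_counts

    checked = 0
    for group in scenario.truth_groups:
        members = sorted(group)
        ti = scenario.dataset.trajectories[members[0]]
        tj = scenario.dataset.trajectories[members[1]]
        tc, tp, t_sim = brute_force_pair_counts(ti, tj, 1.5, 1.0)
        assert t_sim > 0
        assert tc >= 0.95 * t_sim
        checked += 1
    assert checked >= 10


def test_stranger_waiting_anchors_separated(scenario):
    # no two truth waiting intervals of strangers overlap while their
    # tracks come within contact distance during the shared waiting phase
    from conftest import brute_force_qualifying_pairs

    pairs = brute_force_qualifying_pairs(scenario.dataset, 1.5, 1.0, 0.85, 0.4)
    member_pairs = set()
    for g in scenario.truth_groups:
        ids = sorted(g, key=str)
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                member_pairs.add((ids[a], ids[b]))
    boarding = {
        pid for pid, label in scenario.truth_class.items() if label == BOARDING
    }
    stranger_hits = {
        p for p in pairs
        if p not in member_pairs and p[0] in boarding and p[1] in boarding
    }
    assert stranger_hits == set()


def test_group_size_frequencies_follow_configured_law(scenario):
    cfg = ScenarioConfig()
    pmf = np.asarray(cfg.group_size_pmf)
    sizes = [len(g) for g in scenario.truth_groups]
    individuals = sum(
        1
        for pid, label in scenario.truth_class.items()
        if label == BOARDING and pid not in scenario.truth_member_ids
    )
    counts = np.zeros(pmf.size)
    counts[0] = individuals
    for s in sizes:
        counts[min(s, pmf.size) - 1] += 1
    n = counts.sum()
    freq = counts / n
    # multinomial 4-sigma band per category
    for k in range(pmf.size):
        band = 4.0 * np.sqrt(pmf[k] * (1 - pmf[k]) / n) + 1.0 / n
        assert abs(freq[k] - pmf[k]) <= band, (k, freq[k], pmf[k])


def test_corrupt_prob_zero_is_identity(scenario):
    assert corrupt_tracks(scenario, 0.0, seed=3) is scenario


def test_corrupt_prob_one_doubles_track_count(geometry):
    entry = next(iter(geometry.entry_regions.values())).centroid
    door = next(iter(geometry.edge_regions.values())).centroid
    trajs = [
        straight_traj(i, (entry.x, entry.y), (door.x, door.y), 200)
        for i in range(3)
    ]
    scenario = LabelledScenario(
        dataset=dataset_of(*trajs),
        geometry=geometry,
        truth_groups=[frozenset({0, 1})],
        truth_class={i: BOARDING for i in range(3)},
        truth_waiting={},
    )
    corrupted = corrupt_tracks(scenario, 1.0, seed=3)
    assert len(corrupted.dataset) == 6
    # labels follow fragments: the 2-member truth group now spans 4 ids
    assert len(corrupted.truth_groups[0]) == 4
    assert all(
        corrupted.truth_class[pid] == BOARDING
        for pid in corrupted.dataset.trajectories
    )


def test_cut_sets_nested_across_probabilities(scenario):
    light = corrupt_tracks(scenario, 0.2, seed=11)
    heavy = corrupt_tracks(scenario, 0.6, seed=11)
    original = set(scenario.dataset.trajectories)
    cut_light = {
        pid for pid in original
        if scenario.dataset.trajectories[pid] != light.dataset.trajectories[pid]
    }
    cut_heavy = {
        pid for pid in original
        if scenario.dataset.trajectories[pid] != heavy.dataset.trajectories[pid]
    }
    assert cut_light <= cut_heavy


def test_truth_roundtrip_through_json(tmp_path, small_scenario):
    path = tmp_path / "truth.json"
    save_truth(small_scenario, path)
    doc = load_truth(path)
    assert set(map(frozenset, doc["groups"])) == set(small_scenario.truth_groups)
    assert doc["classes"] == small_scenario.truth_class
    for pid, (a, b) in small_scenario.truth_waiting.items():
        assert doc["waiting"][pid] == pytest.approx((a, b))
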