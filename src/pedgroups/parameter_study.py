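"""Grid search over the contact-time fractions and ground-truth validation.

The fractions (alpha, beta) of the pair criterion are validated against a
ground truth of annotated group-member ids: the grid spans [0, 1] x [0, 1]
in configurable steps (default 0.05), every grid point is scored by the
number of detected member ids and the number of false positives (detected
ids outside the ground truth), and the selected parameters are the
zero-false-positive point detecting the most members,

    (alpha, beta) = argmax N(members)  subject to  N(false positives) = 0.

Contact statistics are computed once per candidate pair and reused across
the whole grid — each grid point is a pure threshold check — so scores are
consistent across the grid by construction and the detected sets are nested
under tightening fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .group_detection import (
    ContactStats,
    PairCriterion,
    is_social_pair,
    pair_statistics,
    select_population,
)
from .platform_geometry import DEFAULT_SNAP_TOLERANCE, PlatformGeometry
from .trajectory_io import DEFAULT_MIN_DURATION_S, TrajectoryDataset

__all__ = [
    "GroundTruth",
    "RaterAgreement",
    "GridResult",
    "rater_agreement",
    "grid_search",
    "select_parameters",
    "detection_coverage",
    "read_ground_truth",
]


@dataclass(frozen=True)
class GroundTruth:
    """Pedestrian ids annotated as members of social groups."""

    member_ids: frozenset

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class RaterAgreement:
    """Agreement between two annotators' id lists.

    The agreement percentage is intersection over union,
    100 * |A ∩ B| / |A ∪ B|; the consensus set A ∩ B serves as ground
    truth.  Two empty lists agree vacuously (100%).
    """

    n_a: int
    n_b: int
    n_both: int
    percent: float
    consensus: frozenset


def rater_agreement(ids_a, ids_b) -> RaterAgreement:
    """Compare two annotators' member-id sets."""
    a, b = frozenset(ids_a), frozenset(ids_b)
    union = a | b
    both = a & b
    percent = 100.0 if not union else 100.0 * len(both) / len(union)
    return RaterAgreement(len(a), len(b), len(both), percent, both)


@dataclass
class GridResult:
    """Scores for every (alpha, beta) grid point plus the cached pair
    statistics that produced them."""

    step: float
    d_contact: float
    d_personal: float
    table: pd.DataFrame
    selected: tuple[float, float] | None = None
    _stats: dict[tuple, ContactStats] = field(default_factory=dict, repr=False)
    _truth: frozenset = field(default_factory=frozenset, repr=False)

    def detected_ids(self, alpha: float, beta: float) -> frozenset:
        """Member ids detected at one parameter point (cached statistics)."""
        if not (0.0 <= alpha <= 1.0 and 0.0 <= beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")
        criterion = PairCriterion(self.d_contact, self.d_personal, alpha, beta)
        ids: set = set()
        for pair, stats in self._stats.items():
            if is_social_pair(stats, criterion):
                ids.update(pair)
        return frozenset(ids)


def _grid_values(step: float) -> np.ndarray:
    if not 0 < step <= 1:
        raise ValueError("step must lie in (0, 1]")
    n = int(round(1.0 / step))
    return np.round(np.linspace(0.0, n * step, n + 1), 10)


def grid_search(
    dataset: TrajectoryDataset,
    geometry: PlatformGeometry | None,
    ground_truth: GroundTruth,
    step: float = 0.05,
    d_contact: float = 1.5,
    d_personal: float = 1.0,
    restrict_to_boarding: bool = True,
    min_duration: float = DEFAULT_MIN_DURATION_S,
    stride: int = 1,
    snap_tolerance: float = DEFAULT_SNAP_TOLERANCE,
) -> GridResult:
    """Score the whole (alpha, beta) grid against a ground truth.

    Detected ids at a grid point are the union of the endpoints of
    qualifying pairs; false positives are detected ids not in the ground
    truth.  Ground-truth ids must come from the dataset.
    """
    unknown = ground_truth.member_ids - set(dataset.trajectories)
    if unknown:
        raise ValueError(
            f"{len(unknown)} ground-truth ids missing from the dataset"
        )
    population = select_population(
        dataset, geometry, restrict_to_boarding, min_duration, snap_tolerance
    )
    base = PairCriterion(d_contact, d_personal, 0.0, 0.0)
    stats = (
        pair_statistics(population, base, stride=stride) if len(population) else {}
    )
    values = _grid_values(step)
    truth = ground_truth.member_ids
    rows = []
    for alpha in values:
        for beta in values:
            criterion = PairCriterion(d_contact, d_personal, float(alpha), float(beta))
            detected: set = set()
            for pair, st in stats.items():
                if is_social_pair(st, criterion):
                    detected.update(pair)
            rows.append(
                {
                    "alpha": float(alpha),
                    "beta": float(beta),
                    "n_detected_members": len(detected),
                    "n_true_positives": len(detected & truth),
                    "n_false_positives": len(detected - truth),
                }
            )
    table = pd.DataFrame(rows)
    return GridResult(
        step=step,
        d_contact=d_contact,
        d_personal=d_personal,
        table=table,
        _stats=stats,
        _truth=frozenset(truth),
    )


def select_parameters(result: GridResult) -> tuple[float, float] | None:
    """Zero-false-positive argmax of detected members.

    Ties are broken toward larger alpha, then larger beta (the most
    conservative of the equally good points).  Returns ``None`` when no
    grid point is free of false positives.
    """
    feasible = result.table[result.table["n_false_positives"] == 0]
    if feasible.empty:
        result.selected = None
        return None
    best = feasible.sort_values(
        ["n_detected_members", "alpha", "beta"], ascending=False
    ).iloc[0]
    result.selected = (float(best["alpha"]), float(best["beta"]))
    return result.selected


def detection_coverage(detected, ground_truth: GroundTruth) -> float | None:
    """Percentage of ground-truth members found: 100 * |D ∩ T| / |T|.

    ``None`` (not applicable) when the ground truth is empty.
    """
    truth = ground_truth.member_ids
    if not truth:
        return None
    return 100.0 * len(frozenset(detected) & truth) / len(truth)


def read_ground_truth(source: str | Path) -> GroundTruth:
    """Read a ground-truth id list: one id per line ('#' comments allowed)."""
    ids = []
    for line in Path(source).read_text().splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        try:
            ids.append(int(token))
        except ValueError:
            ids.append(token)
    return GroundTruth(frozenset(ids))
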