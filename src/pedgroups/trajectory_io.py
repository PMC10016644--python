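"""Reading, validating, filtering and writing pedestrian trajectory datasets.

The on-disk format is plain-text, long format, one sample per row with
columns ``id frame x y`` (whitespace- or comma-delimited, autodetected),
optionally preceded by comment lines; a ``# framerate: <fps>`` comment is
honoured.  Internally each pedestrian is a :class:`Trajectory` with strictly
increasing integer frame indices and planar positions in metres.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .platform_geometry import DEFAULT_SNAP_TOLERANCE, PlatformGeometry

__all__ = [
    "Trajectory",
    "TrajectoryDataset",
    "QCReport",
    "TrajectoryParseError",
    "TrajectoryValidationError",
    "read_trajectories",
    "write_trajectories",
    "filter_min_duration",
    "qc_endpoints",
]

#: Trajectories shorter than this (seconds) are dropped before analysis;
#: shorter observation windows do not allow reliable assessment.
DEFAULT_MIN_DURATION_S = 20.0


class TrajectoryParseError(ValueError):
    """A trajectory file row could not be parsed."""


class TrajectoryValidationError(ValueError):
    """Parsed trajectory data violates a dataset invariant."""


@dataclass
class Trajectory:
    """One pedestrian's positions sampled on an integer frame clock.

    Frames are strictly increasing but need not be contiguous: the sensor
    may lose a pedestrian for a few frames without reassigning the id.
    """

    ped_id: int | str
    frames: np.ndarray
    positions: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.frames.ndim != 1 or self.frames.size < 1:
            raise TrajectoryValidationError(
                f"trajectory {self.ped_id!r}: needs at least one sample"
            )
        if self.positions.shape != (self.frames.size, 2):
            raise TrajectoryValidationError(
                f"trajectory {self.ped_id!r}: positions must be (n, 2)"
            )
        if np.any(np.diff(self.frames) <= 0):
            raise TrajectoryValidationError(
                f"trajectory {self.ped_id!r}: frames must be strictly increasing"
            )
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryValidationError(
                f"trajectory {self.ped_id!r}: non-finite coordinates"
            )
        if not self.frame_rate > 0:
            raise TrajectoryValidationError("frame_rate must be positive")

    def __len__(self) -> int:
        return int(self.frames.size)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Trajectory)
            and self.ped_id == other.ped_id
            and self.frame_rate == other.frame_rate
            and np.array_equal(self.frames, other.frames)
            and np.array_equal(self.positions, other.positions)
        )

    @property
    def first_frame(self) -> int:
        return int(self.frames[0])

    @property
    def last_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def duration_seconds(self) -> float:
        return (self.last_frame - self.first_frame) / self.frame_rate

    def positions_at(self, frames: np.ndarray) -> np.ndarray:
        """Positions at the requested frames (which must all be sampled)."""
        idx = np.searchsorted(self.frames, frames)
        if np.any(idx >= self.frames.size) or np.any(self.frames[idx] != frames):
            raise KeyError(f"trajectory {self.ped_id!r}: unsampled frame requested")
        return self.positions[idx]


@dataclass
class TrajectoryDataset:
    """A collection of trajectories sharing one frame clock."""

    trajectories: Mapping[int | str, Trajectory]
    frame_rate: float
    observation_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise TrajectoryValidationError("frame_rate must be positive")
        for pid, traj in self.trajectories.items():
            if pid != traj.ped_id:
                raise TrajectoryValidationError(
                    f"key {pid!r} does not match trajectory id {traj.ped_id!r}"
                )
        if self.observation_window is None:
            if self.trajectories:
                first = min(t.first_frame for t in self.trajectories.values())
                last = max(t.last_frame for t in self.trajectories.values())
                self.observation_window = (first, last)
            else:
                self.observation_window = (0, 0)
        lo, hi = self.observation_window
        for traj in self.trajectories.values():
            if traj.first_frame < lo or traj.last_frame > hi:
                raise TrajectoryValidationError(
                    f"trajectory {traj.ped_id!r} lies outside the "
                    "observation window"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories.values())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TrajectoryDataset)
            and self.frame_rate == other.frame_rate
            and set(self.trajectories) == set(other.trajectories)
            and all(
                self.trajectories[k] == other.trajectories[k]
                for k in self.trajectories
            )
        )

    @property
    def ids(self) -> list:
        return list(self.trajectories)

    @property
    def n_frames(self) -> int:
        """Total observation frames N_f (inclusive window span)."""
        lo, hi = self.observation_window
        return hi - lo + 1 if self.trajectories else 0

    def subset(self, ids) -> "TrajectoryDataset":
        keep = {pid: self.trajectories[pid] for pid in ids}
        return TrajectoryDataset(
            trajectories=keep,
            frame_rate=self.frame_rate,
            observation_window=self.observation_window,
        )


@dataclass(frozen=True)
class QCReport:
    """Endpoint-plausibility statistics for a dataset.

    A trajectory is *complete* when both its start and end points lie in a
    plausible boundary region (entry, platform edge or lateral boundary).
    """

    n_trajectories: int
    frac_start_plausible: float
    frac_end_plausible: float
    frac_complete: float

    def __post_init__(self) -> None:
        for f in (
            self.frac_start_plausible,
            self.frac_end_plausible,
            self.frac_complete,
        ):
            if not 0.0 <= f <= 1.0:
                raise TrajectoryValidationError("QC fractions must lie in [0, 1]")
        if self.frac_complete > min(
            self.frac_start_plausible, self.frac_end_plausible
        ) + 1e-12:
            raise TrajectoryValidationError(
                "frac_complete cannot exceed either marginal fraction"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_trajectories": self.n_trajectories,
                "frac_start_plausible": self.frac_start_plausible,
                "frac_end_plausible": self.frac_end_plausible,
                "frac_complete": self.frac_complete,
            },
            indent=2,
        )


# -- reading / writing -----------------------------------------------------


def _parse_id(token: str) -> int | str:
    try:
        return int(token)
    except ValueError:
        return token


def read_trajectories(
    source: str | Path | io.TextIOBase, frame_rate: float | None = None
) -> TrajectoryDataset:
    """Read a long-format trajectory file into a dataset.

    ``frame_rate`` may be omitted when the file carries a
    ``# framerate: <fps>`` comment.  Duplicate ``(id, frame)`` rows raise
    :class:`TrajectoryValidationError`; malformed rows raise
    :class:`TrajectoryParseError` naming the line.  An empty file yields an
    empty dataset.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        name = str(source)
    else:
        text = source.read()
        name = "<stream>"

    header_rate: float | None = None
    rows: list[tuple[int | str, int, float, float]] = []
    delimiter: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("framerate"):
                try:
                    header_rate = float(body.split(":", 1)[1])
                except (IndexError, ValueError) as exc:
                    raise TrajectoryParseError(
                        f"{name}:{lineno}: malformed framerate header {line!r}"
                    ) from exc
            continue
        if delimiter is None:
            delimiter = "," if "," in line else " "
        tokens = [t.strip() for t in
                  (line.split(",") if delimiter == "," else line.split())]
        tokens = [t for t in tokens if t]
        if not rows:
            # optional single header row ("id frame x y"): skip if the
            # frame column is not numeric
            try:
                float(tokens[1])
            except (ValueError, IndexError):
                continue
        if len(tokens) != 4:
            raise TrajectoryParseError(
                f"{name}:{lineno}: expected 4 columns (id frame x y), "
                f"got {len(tokens)}: {raw!r}"
            )
        try:
            frame = int(float(tokens[1]))
            if float(tokens[1]) != frame:
                raise ValueError("non-integer frame index")
            x = float(tokens[2])
            y = float(tokens[3])
        except ValueError as exc:
            raise TrajectoryParseError(f"{name}:{lineno}: {exc}: {raw!r}") from exc
        if not (math.isfinite(x) and math.isfinite(y)):
            raise TrajectoryParseError(
                f"{name}:{lineno}: non-finite coordinate: {raw!r}"
            )
        rows.append((_parse_id(tokens[0].strip()), frame, x, y))

    rate = frame_rate if frame_rate is not None else header_rate
    if rate is None:
        if not rows:  # empty file: rate is immaterial, yield an empty dataset
            rate = 1.0
        else:
            raise TrajectoryValidationError(
                f"{name}: no frame rate given and no '# framerate:' header found"
            )

    by_id: dict[int | str, list[tuple[int, float, float]]] = {}
    for pid, frame, x, y in rows:
        by_id.setdefault(pid, []).append((frame, x, y))

    trajectories: dict[int | str, Trajectory] = {}
    for pid, samples in by_id.items():
        samples.sort(key=lambda s: s[0])
        frames = np.array([s[0] for s in samples], dtype=np.int64)
        if np.any(np.diff(frames) == 0):
            dup = int(frames[np.nonzero(np.diff(frames) == 0)[0][0]])
            raise TrajectoryValidationError(
                f"{name}: duplicate sample for id {pid!r} at frame {dup}"
            )
        positions = np.array([(s[1], s[2]) for s in samples], dtype=np.float64)
        trajectories[pid] = Trajectory(pid, frames, positions, float(rate))

    return TrajectoryDataset(trajectories=trajectories, frame_rate=float(rate))


def write_trajectories(
    dataset: TrajectoryDataset, sink: str | Path | io.TextIOBase
) -> None:
    """Write a dataset as a long-format file, lossless under re-reading."""
    lines = [f"# framerate: {float(dataset.frame_rate)!r}", "id frame x y"]
    for pid in sorted(dataset.trajectories, key=lambda p: (str(type(p)), p)):
        traj = dataset.trajectories[pid]
        for frame, (x, y) in zip(traj.frames, traj.positions):
            lines.append(f"{pid} {int(frame)} {float(x)!r} {float(y)!r}")
    text = "\n".join(lines) + "\n"
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)


def filter_min_duration(
    dataset: TrajectoryDataset, min_seconds: float = DEFAULT_MIN_DURATION_S
) -> TrajectoryDataset:
    """Keep trajectories observed for at least ``min_seconds`` (inclusive)."""
    if min_seconds < 0:
        raise ValueError("min_seconds must be non-negative")
    keep = {
        pid: traj
        for pid, traj in dataset.trajectories.items()
        if traj.duration_seconds >= min_seconds
    }
    return TrajectoryDataset(
        trajectories=keep,
        frame_rate=dataset.frame_rate,
        observation_window=dataset.observation_window,
    )


def qc_endpoints(
    dataset: TrajectoryDataset,
    geometry: PlatformGeometry,
    tol: float = DEFAULT_SNAP_TOLERANCE,
) -> QCReport:
    """Endpoint plausibility of every trajectory against the geometry.

    On an empty dataset the fractions are vacuously 1.0.
    """
    n = len(dataset)
    if n == 0:
        return QCReport(0, 1.0, 1.0, 1.0)
    from shapely.geometry import Point
    from shapely.prepared import prep

    region = prep(geometry.boundary_union(tol))
    n_start = n_end = n_both = 0
    for traj in dataset:
        start_ok = region.covers(Point(*traj.positions[0]))
        end_ok = region.covers(Point(*traj.positions[-1]))
        n_start += start_ok
        n_end += end_ok
        n_both += start_ok and end_ok
    return QCReport(n, n_start / n, n_end / n, n_both / n)
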