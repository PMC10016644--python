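"""Per-frame speeds, waiting flags and waiting-time statistics.

The instantaneous speed of pedestrian *i* at frame *t* is estimated from
the displacement over a centred window of Δt' frames,

    v_i(t) = || x_i(t + Δt'/2) − x_i(t − Δt'/2) || / (Δt' / frame_rate),

i.e. a central difference in metres per second.  With the default window of
50 frames at 10 fps this averages motion over 5 s, which suppresses
measurement jitter while still resolving the walk/wait transition.  A
pedestrian counts as *waiting* at a frame when v_i(t) falls strictly below
a threshold (default 0.4 m/s, the separating minimum between the waiting
and walking modes of platform speed distributions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import Trajectory

__all__ = [
    "SpeedSeries",
    "WaitingProfile",
    "WAITING_BINS",
    "DEFAULT_SPEED_WINDOW_FRAMES",
    "DEFAULT_WAITING_THRESHOLD_MPS",
    "compute_speed",
    "waiting_profile",
    "waiting_bin",
    "mean_speed",
]

DEFAULT_SPEED_WINDOW_FRAMES = 50
DEFAULT_WAITING_THRESHOLD_MPS = 0.4

#: Waiting-time bins (labels and left-closed edges in seconds).
WAITING_BINS = ("<2min", "2-5min", "5-10min", ">=10min")
_BIN_EDGES_S = (120.0, 300.0, 600.0)


@dataclass
class SpeedSeries:
    """Central-difference speeds, defined only where both window endpoints
    are sampled."""

    ped_id: int | str
    frames: np.ndarray
    speeds: np.ndarray
    window_frames: int
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.speeds = np.asarray(self.speeds, dtype=np.float64)
        if self.frames.shape != self.speeds.shape:
            raise ValueError("frames and speeds must align")
        if self.speeds.size and (
            np.any(self.speeds < 0) or not np.all(np.isfinite(self.speeds))
        ):
            raise ValueError("speeds must be finite and non-negative")

    def __len__(self) -> int:
        return int(self.frames.size)


@dataclass
class WaitingProfile:
    """Per-frame waiting flags plus the total waiting time and its bin."""

    ped_id: int | str
    frames: np.ndarray
    waiting_flags: np.ndarray
    waiting_threshold: float
    frame_rate: float
    total_waiting_seconds: float
    bin: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.waiting_flags = np.asarray(self.waiting_flags, dtype=bool)
        if self.frames.shape != self.waiting_flags.shape:
            raise ValueError("frames and waiting_flags must align")

    @property
    def waiting_frames(self) -> np.ndarray:
        """Frame indices at which the pedestrian is flagged waiting."""
        return self.frames[self.waiting_flags]


def compute_speed(
    traj: Trajectory, window_frames: int = DEFAULT_SPEED_WINDOW_FRAMES
) -> SpeedSeries:
    """Central-difference speed series of one trajectory, in m/s.

    Speed is defined at frame t only when both t − Δt'/2 and t + Δt'/2 are
    sampled; frames near the track ends or adjacent to sensor gaps get no
    value rather than a shrunken window.  Trajectories shorter than the
    window yield an empty series.
    """
    if window_frames < 2 or window_frames % 2 != 0:
        raise ValueError("window_frames must be an even integer >= 2")
    half = window_frames // 2
    frames = traj.frames
    lo = np.searchsorted(frames, frames - half)
    hi = np.searchsorted(frames, frames + half)
    lo_ok = (lo < frames.size) & (frames[np.minimum(lo, frames.size - 1)] == frames - half)
    hi_ok = (hi < frames.size) & (frames[np.minimum(hi, frames.size - 1)] == frames + half)
    ok = lo_ok & hi_ok
    if not np.any(ok):
        return SpeedSeries(
            traj.ped_id,
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.float64),
            window_frames,
            traj.frame_rate,
        )
    disp = traj.positions[hi[ok]] - traj.positions[lo[ok]]
    dt_seconds = window_frames / traj.frame_rate
    speeds = np.hypot(disp[:, 0], disp[:, 1]) / dt_seconds
    return SpeedSeries(traj.ped_id, frames[ok], speeds, window_frames, traj.frame_rate)


def waiting_bin(total_waiting_seconds: float) -> str:
    """Waiting-time bin label; edges are left-closed at 2, 5 and 10 min."""
    for label, edge in zip(WAITING_BINS, _BIN_EDGES_S):
        if total_waiting_seconds < edge:
            return label
    return WAITING_BINS[-1]


def waiting_profile(
    speeds: SpeedSeries, threshold: float = DEFAULT_WAITING_THRESHOLD_MPS
) -> WaitingProfile:
    """Flag waiting frames (speed strictly below ``threshold``) and total
    them up.

    The total waiting time is the number of flagged frames divided by the
    frame rate; an empty speed series gives zero waiting time in the
    shortest bin.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    flags = speeds.speeds < threshold
    total = float(np.count_nonzero(flags)) / speeds.frame_rate
    return WaitingProfile(
        ped_id=speeds.ped_id,
        frames=speeds.frames,
        waiting_flags=flags,
        waiting_threshold=threshold,
        frame_rate=speeds.frame_rate,
        total_waiting_seconds=total,
        bin=waiting_bin(total),
    )


def mean_speed(speeds: SpeedSeries) -> float:
    """Mean of the defined speed values (NaN for an empty series)."""
    return float(np.mean(speeds.speeds)) if len(speeds) else float("nan")
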