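"""Vehicle kinematics from detection-line crossing records.

The raw input is a table of (vehicle_id, lane, line_index, frame_index)
rows: vehicle crossings of virtual detection lines spaced a fixed
distance apart, timestamped by video frame count.  From the frame gaps
this module recovers travel times, the speed at each interior line
(two-interval central estimate: v_b = 2s / (t_ab + t_bc)), headways at
each line, line-to-line accelerations, and a motion-state label per
line (0=accelerate, 1=decelerate, 2=maintain, 3=stop).

Line indices count upstream from the stop line: line ``i`` sits at
``i * line_spacing`` metres before the stop line, so a vehicle
approaching the intersection crosses lines in decreasing index order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretization import HEAD_CAR

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["vehicle_id", "lane", "line_index", "frame_index"]


@dataclass(frozen=True)
class KinematicsConfig:
    """Geometry, frame rate and state-classification thresholds.

    ``stop_speed_threshold`` (m/s) bounds the speed below which a
    vehicle is labeled stopped; ``accel_threshold`` (m/s^2) is the
    half-width of the dead band around zero acceleration inside which
    the driver is labeled as maintaining speed.
    """

    line_spacing: float = 2.92
    frames_per_second: int = 30
    stop_speed_threshold: float = 0.5
    accel_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.line_spacing <= 0:
            raise ValueError("line spacing must be positive")
        if self.frames_per_second < 1:
            raise ValueError("frame rate must be >= 1")
        if self.stop_speed_threshold < 0 or self.accel_threshold < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class TrackEntry:
    """One detection-line crossing of a vehicle, with derived kinematics."""

    line_index: int
    time_s: float
    speed: float | None = None
    headway: float | None = None
    head_car: bool = False
    accel: float | None = None
    state: int | None = None
    queue: str | None = None
    signal: str | None = None


@dataclass
class VehicleTrack:
    vehicle_id: int
    lane: int
    entries: list[TrackEntry] = field(default_factory=list)

    def times(self) -> np.ndarray:
        return np.array([e.time_s for e in self.entries])


def travel_time(frame_count: int, frames_per_second: int) -> float:
    """Seconds elapsed over ``frame_count`` video frames."""
    if frame_count < 1:
        raise ValueError(
            "zero-frame crossing gap would imply infinite speed"
        )
    return frame_count / frames_per_second


def speed_at_line(t_ab: float, t_bc: float, spacing: float) -> float:
    """Speed at line b from travel times over the flanking intervals."""
    total = t_ab + t_bc
    if total <= 0:
        raise ValueError("degenerate crossing: zero total travel time")
    return 2.0 * spacing / total


def headways(
    times: np.ndarray,
    cycle_length: float | None = None,
):
    """Headways of successive crossings at one detection line in one lane.

    ``times`` must be sorted ascending.  The first vehicle — and, when
    ``cycle_length`` is given, the first vehicle of each signal cycle —
    gets the :data:`~hmdm.discretization.HEAD_CAR` sentinel; every other
    vehicle gets the time gap to its predecessor.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (np.diff(times) < 0).any():
        raise ValueError("crossing times must be sorted ascending")
    out = []
    for i, t in enumerate(times):
        if i == 0:
            out.append(HEAD_CAR)
            continue
        prev = times[i - 1]
        if cycle_length is not None and int(t // cycle_length) != int(
            prev // cycle_length
        ):
            out.append(HEAD_CAR)
        else:
            out.append(float(t - prev))
    return out


def classify_motion_state(
    speed: float, accel: float, config: KinematicsConfig | None = None
) -> int:
    """Label a (speed, acceleration) pair with a motion state 0..3.

    The stop test takes precedence: a crawling vehicle is "stopped"
    regardless of its instantaneous acceleration.
    """
    config = config or KinematicsConfig()
    if speed < 0:
        raise ValueError("speed must be non-negative")
    if speed <= config.stop_speed_threshold:
        return 3
    if accel > config.accel_threshold:
        return 0
    if accel < -config.accel_threshold:
        return 1
    return 2


def read_detection_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns: {sorted(missing)}")
    return frame


def write_detection_csv(records: pd.DataFrame, path) -> None:
    records[DETECTION_COLUMNS].to_csv(path, index=False)


def build_tracks(
    records: pd.DataFrame,
    config: KinematicsConfig | None = None,
    cycle_length: float | None = None,
) -> list[VehicleTrack]:
    """Assemble per-vehicle tracks with speeds, headways, accelerations
    and motion states from raw detection records.

    Vehicles with fewer than 3 crossings are dropped (the two-interval
    speed estimate needs a line with neighbors on both sides) with a
    logged warning.  Interior-line accelerations are finite differences
    of the interior-line speeds over their time gaps; the endpoints of
    the interior run use one-sided differences.
    """
    config = config or KinematicsConfig()
    if records.duplicated(subset=["vehicle_id", "line_index"]).any():
        raise ValueError("duplicate (vehicle, line) detection records")

    tracks: list[VehicleTrack] = []
    for (vid, lane), grp in records.groupby(["vehicle_id", "lane"], sort=True):
        grp = grp.sort_values("frame_index")
        if len(grp) < 3:
            logger.warning(
                "vehicle %s: only %d crossings, dropped (need >= 3)", vid, len(grp)
            )
            continue
        frames = grp["frame_index"].to_numpy()
        lines = grp["line_index"].to_numpy()
        times = frames / config.frames_per_second
        if (np.diff(frames) < 1).any():
            raise ValueError(f"vehicle {vid}: frame indices not strictly increasing")

        track = VehicleTrack(vehicle_id=int(vid), lane=int(lane))
        for ln, t in zip(lines, times):
            track.entries.append(TrackEntry(line_index=int(ln), time_s=float(t)))

        # speeds at interior lines (need both flanking intervals)
        interior = range(1, len(track.entries) - 1)
        for i in interior:
            t_ab = times[i] - times[i - 1]
            t_bc = times[i + 1] - times[i]
            track.entries[i].speed = speed_at_line(t_ab, t_bc, config.line_spacing)

        # accelerations from interior speeds; states where both exist
        idx = list(interior)
        if len(idx) == 1:
            track.entries[idx[0]].accel = 0.0
        elif len(idx) >= 2:
            v = np.array([track.entries[i].speed for i in idx])
            tt = times[idx]
            acc = np.gradient(v, tt)
            for i, a in zip(idx, acc):
                track.entries[i].accel = float(a)
        for i in idx:
            e = track.entries[i]
            e.state = classify_motion_state(e.speed, e.accel, config)
        tracks.append(track)

    # headways per (lane, line) across vehicles
    by_key: dict[tuple[int, int], list[tuple[float, TrackEntry]]] = {}
    for track in tracks:
        for e in track.entries:
            by_key.setdefault((track.lane, e.line_index), []).append((e.time_s, e))
    for crossings in by_key.values():
        crossings.sort(key=lambda pair: pair[0])
        gaps = headways(np.array([t for t, _ in crossings]), cycle_length)
        for (_, entry), gap in zip(crossings, gaps):
            if gap == HEAD_CAR:
                entry.head_car = True
                entry.headway = None
            else:
                entry.headway = gap
    return tracks


def annotate_context(
    tracks: list[VehicleTrack],
    signal_phase_fn,
    config: KinematicsConfig | None = None,
) -> list[VehicleTrack]:
    """Attach the queue descriptor and signal phase to every track entry.

    ``signal_phase_fn(time_s)`` must return "green", "red" or "yellow".
    The queue descriptor at a crossing is "head_car" for the first
    vehicle at that (lane, line) in the cycle, "stopped_ahead" when the
    predecessor vehicle's last known speed before the crossing is at or
    below the stop threshold, and "no_stopped_ahead" otherwise.
    """
    config = config or KinematicsConfig()

    by_key: dict[tuple[int, int], list[tuple[float, VehicleTrack, TrackEntry]]] = {}
    for track in tracks:
        for e in track.entries:
            by_key.setdefault((track.lane, e.line_index), []).append((e.time_s, track, e))
    for crossings in by_key.values():
        crossings.sort(key=lambda item: item[0])
        for i, (t, _track, entry) in enumerate(crossings):
            entry.signal = signal_phase_fn(t)
            if entry.head_car or i == 0:
                entry.queue = HEAD_CAR
                continue
            _, pred_track, _ = crossings[i - 1]
            entry.queue = (
                "stopped_ahead"
                if _predecessor_stopped(pred_track, t, config)
                else "no_stopped_ahead"
            )
    return tracks


def _predecessor_stopped(
    track: VehicleTrack, at_time: float, config: KinematicsConfig
) -> bool:
    last_speed = None
    for e in track.entries:
        if e.time_s <= at_time and e.speed is not None:
            last_speed = e.speed
    return last_speed is not None and last_speed <= config.stop_speed_threshold


def tracks_to_frame(tracks: list[VehicleTrack]) -> pd.DataFrame:
    """Serialize tracks to the flat per-line CSV layout."""
    rows = []
    for track in tracks:
        for e in track.entries:
            rows.append(
                {
                    "vehicle_id": track.vehicle_id,
                    "lane": track.lane,
                    "line_index": e.line_index,
                    "time_s": e.time_s,
                    "speed_ms": e.speed,
                    "headway_s": e.headway,
                    "head_car": e.head_car,
                    "accel_ms2": e.accel,
                    "state": e.state if e.state is not None else -1,
                    "queue": e.queue,
                    "signal": e.signal,
                }
            )
    return pd.DataFrame(rows)
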