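"""Discretization of vehicle dynamics into the 81-symbol observation alphabet.

Four observed quantities — speed, headway, queue condition and signal
phase — are each binned into three categories, and the 3**4 = 81
category tuples are enumerated into a single symbol index.  The
enumeration runs with the signal phase varying fastest, then the queue
code, then the headway bin, then the speed bin, so that (1,1,1,1) -> 1
and (3,3,3,3) -> 81.  The approach to the stop line is partitioned into
three zones; the middle one (40-100 m out) is the Type-II dilemma zone,
where at yellow onset between 10% and 90% of drivers would stop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sequences import ObservationSequence

HEAD_CAR = "head_car"

#: queue-condition category names, in code order 1..3
QUEUE_CATEGORIES = (HEAD_CAR, "no_stopped_ahead", "stopped_ahead")
SIGNAL_CATEGORIES = ("green", "red", "yellow")


@dataclass(frozen=True)
class DiscretizationRules:
    """Category boundaries and code maps for the four observed variables.

    Speeds at or below ``speed_breaks[0]`` m/s are slow (bin 1), at or
    above ``speed_breaks[1]`` fast (bin 3).  A headway of exactly
    ``headway_break`` seconds falls in the long bin (3).
    """

    speed_breaks: tuple[float, float] = (8.0, 16.0)
    headway_break: float = 6.0
    signal_codes: dict = field(
        default_factory=lambda: {"green": 1, "red": 2, "yellow": 3}
    )
    queue_codes: dict = field(
        default_factory=lambda: {
            HEAD_CAR: 1,
            "no_stopped_ahead": 2,
            "stopped_ahead": 3,
        }
    )

    def __post_init__(self) -> None:
        lo, hi = self.speed_breaks
        if not (0 < lo < hi):
            raise ValueError("speed breaks must be positive and increasing")
        if self.headway_break <= 0:
            raise ValueError("headway break must be positive")
        for codes in (self.signal_codes, self.queue_codes):
            if sorted(codes.values()) != [1, 2, 3]:
                raise ValueError("code maps must be bijections onto {1,2,3}")


@dataclass(frozen=True)
class ZoneConfig:
    """Zone boundaries in metres upstream of the stop line."""

    boundaries: tuple[float, float, float] = (40.0, 100.0, 135.0)

    def __post_init__(self) -> None:
        b = self.boundaries
        if not (0 < b[0] < b[1] < b[2]):
            raise ValueError("zone boundaries must be positive and increasing")


def bin_speed(v: float, rules: DiscretizationRules | None = None) -> int:
    """Bin a speed (m/s) into slow/medium/fast (1/2/3)."""
    rules = rules or DiscretizationRules()
    if v < 0:
        raise ValueError(f"negative speed: {v}")
    lo, hi = rules.speed_breaks
    if v <= lo:
        return 1
    if v >= hi:
        return 3
    return 2


def bin_headway(gap, rules: DiscretizationRules | None = None) -> int:
    """Bin a headway into head-car/short/long (1/2/3).

    ``gap`` is either the :data:`HEAD_CAR` sentinel (the vehicle has no
    predecessor at this detection line in the current cycle) or a
    positive time gap in seconds.
    """
    rules = rules or DiscretizationRules()
    if gap == HEAD_CAR or gap is None:
        return 1
    gap = float(gap)
    if gap <= 0 or math.isnan(gap):
        raise ValueError(f"non-positive headway: {gap}")
    return 3 if gap >= rules.headway_break else 2


def bin_queue(descriptor: str, rules: DiscretizationRules | None = None) -> int:
    """Map a queue-condition category to its code (1/2/3)."""
    rules = rules or DiscretizationRules()
    try:
        return rules.queue_codes[descriptor]
    except KeyError:
        raise ValueError(f"unknown queue descriptor: {descriptor!r}") from None


def bin_signal(phase: str, rules: DiscretizationRules | None = None) -> int:
    """Map a signal phase (green/red/yellow) to its code (1/2/3)."""
    rules = rules or DiscretizationRules()
    try:
        return rules.signal_codes[phase]
    except KeyError:
        raise ValueError(f"unknown signal phase: {phase!r}") from None


def encode_observation(tpl: tuple[int, int, int, int]) -> int:
    """Encode a (speed, headway, queue, signal) bin tuple as a symbol 1..81.

    The signal bin varies fastest in the enumeration:
    ``index = 27*(speed-1) + 9*(headway-1) + 3*(queue-1) + signal``.
    """
    speed, headway, queue, signal = tpl
    for name, c in zip(("speed", "headway", "queue", "signal"), tpl):
        if c not in (1, 2, 3):
            raise ValueError(f"{name} bin out of range: {c}")
    return 27 * (speed - 1) + 9 * (headway - 1) + 3 * (queue - 1) + signal


def decode_observation(index: int) -> tuple[int, int, int, int]:
    """Inverse of :func:`encode_observation`."""
    index = int(index)
    if not 1 <= index <= 81:
        raise ValueError(f"symbol index out of range: {index}")
    r = index - 1
    speed, r = divmod(r, 27)
    headway, r = divmod(r, 9)
    queue, signal = divmod(r, 3)
    return (speed + 1, headway + 1, queue + 1, signal + 1)


def assign_zone(distance: float, zones: ZoneConfig | None = None) -> int:
    """Zone of a point ``distance`` metres upstream of the stop line.

    Zone 1 is [0, b1) nearest the stop line, zone 2 the dilemma zone
    [b1, b2), zone 3 the far zone [b2, b3] (closed at the outer edge).
    """
    zones = zones or ZoneConfig()
    b1, b2, b3 = zones.boundaries
    if distance < 0 or distance > b3:
        raise ValueError(f"distance {distance} outside study area [0, {b3}]")
    if distance < b1:
        return 1
    if distance < b2:
        return 2
    return 3


def tracks_to_sequences(
    tracks,
    rules: DiscretizationRules | None = None,
    zones: ZoneConfig | None = None,
    line_spacing: float = 2.92,
) -> list[ObservationSequence]:
    """Turn kinematic vehicle tracks into per-vehicle observation sequences.

    Each interior detection line of a track (where a speed is defined)
    yields one symbol from its (speed, headway, queue, signal) context.
    Symbols are tagged with the zone of the detection line.  Tracks must
    carry per-line headway, queue descriptor and signal phase; missing
    context raises.
    """
    rules = rules or DiscretizationRules()
    zones = zones or ZoneConfig()
    out: list[ObservationSequence] = []
    for track in tracks:
        symbols, zone_tags, lines, states = [], [], [], []
        for entry in track.entries:
            if entry.speed is None:
                continue  # first/last line: no speed estimate there
            if entry.queue is None or entry.signal is None:
                raise ValueError(
                    f"vehicle {track.vehicle_id}: missing queue/signal context "
                    f"at line {entry.line_index}"
                )
            gap = HEAD_CAR if entry.head_car else entry.headway
            tpl = (
                bin_speed(entry.speed, rules),
                bin_headway(gap, rules),
                bin_queue(entry.queue, rules),
                bin_signal(entry.signal, rules),
            )
            symbols.append(encode_observation(tpl))
            zone_tags.append(assign_zone(entry.line_index * line_spacing, zones))
            lines.append(entry.line_index)
            states.append(entry.state if entry.state is not None else -1)
        if not symbols:
            continue
        st = np.array(states)
        out.append(
            ObservationSequence(
                vehicle_id=track.vehicle_id,
                symbols=np.array(symbols),
                zones=np.array(zone_tags),
                states=st if (st >= 0).all() else None,
                line_index=np.array(lines),
            )
        )
    return out
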