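"""Per-vehicle observation sequences and their CSV round-trip.

An :class:`ObservationSequence` holds the ordered symbols (1..81) one
vehicle produced while approaching the stop line, together with the
intersection-approach zone of each symbol and, when known, the hidden
motion state (0=accelerate, 1=decelerate, 2=maintain, 3=stop) that
produced it.  Sequences with states attached ("labeled sequences") come
either from the synthetic generator (ground truth) or from Viterbi
decoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STATE_NAMES = {0: "accelerate", 1: "decelerate", 2: "maintain", 3: "stop"}
N_STATES = 4
N_SYMBOLS = 81

ZONE_WHOLE = "whole"
ZONE_IDS = (1, 2, 3)


@dataclass
class ObservationSequence:
    """Ordered observations of one vehicle.

    Parameters
    ----------
    vehicle_id : int
        Vehicle identifier, unique within a data set.
    symbols : ndarray of int
        Observation symbols, 1-based indices into the 81-symbol alphabet.
    zones : ndarray of int
        Zone id (1, 2 or 3) of each observation.
    states : ndarray of int, optional
        Hidden motion-state labels aligned with ``symbols``; ``None``
        when unlabeled.
    line_index : ndarray of int, optional
        Detection-line index of each observation, when the sequence was
        derived from detection-line crossings.
    """

    vehicle_id: int
    symbols: np.ndarray
    zones: np.ndarray
    states: np.ndarray | None = None
    line_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        self.zones = np.asarray(self.zones, dtype=np.int64)
        if self.symbols.shape != self.zones.shape:
            raise ValueError("symbols and zones must have equal length")
        if self.states is not None:
            self.states = np.asarray(self.states, dtype=np.int64)
            if self.states.shape != self.symbols.shape:
                raise ValueError("states must align with symbols")
        if self.line_index is not None:
            self.line_index = np.asarray(self.line_index, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.symbols.size)

    @property
    def is_labeled(self) -> bool:
        return self.states is not None


# A labeled sequence is an ObservationSequence whose ``states`` is set.
LabeledSequence = ObservationSequence


def sequences_to_frame(sequences: list[ObservationSequence]) -> pd.DataFrame:
    """Flatten sequences into a long table (one row per observation)."""
    rows = []
    for seq in sequences:
        for t in range(len(seq)):
            rows.append(
                {
                    "vehicle_id": seq.vehicle_id,
                    "zone": int(seq.zones[t]),
                    "t": t,
                    "symbol": int(seq.symbols[t]),
                    "state": int(seq.states[t]) if seq.states is not None else -1,
                }
            )
    return pd.DataFrame(rows, columns=["vehicle_id", "zone", "t", "symbol", "state"])


def frame_to_sequences(frame: pd.DataFrame) -> list[ObservationSequence]:
    """Rebuild per-vehicle sequences from the long-table CSV layout."""
    out: list[ObservationSequence] = []
    for vid, grp in frame.groupby("vehicle_id", sort=True):
        grp = grp.sort_values("t")
        states = None
        if "state" in grp.columns and (grp["state"] >= 0).all():
            states = grp["state"].to_numpy()
        out.append(
            ObservationSequence(
                vehicle_id=int(vid),
                symbols=grp["symbol"].to_numpy(),
                zones=grp["zone"].to_numpy(),
                states=states,
            )
        )
    return out


def write_sequences_csv(sequences: list[ObservationSequence], path) -> None:
    sequences_to_frame(sequences).to_csv(path, index=False)


def read_sequences_csv(path) -> list[ObservationSequence]:
    return frame_to_sequences(pd.read_csv(path))


def zone_subsequences(
    sequences: list[ObservationSequence],
) -> dict[int | str, list[ObservationSequence]]:
    """Split sequences by zone, keeping contiguous runs intact.

    Returns a mapping from zone id (1, 2, 3) to the per-zone contiguous
    subsequences, plus the key ``"whole"`` mapping to the unsplit input.
    A vehicle whose approach spans several zones contributes one
    subsequence per contiguous zone run, so the split conserves the
    total observation count.
    """
    by_zone: dict[int | str, list[ObservationSequence]] = {1: [], 2: [], 3: []}
    for seq in sequences:
        if len(seq) == 0:
            continue
        # boundaries of contiguous zone runs
        cuts = np.flatnonzero(np.diff(seq.zones) != 0) + 1
        for chunk in np.split(np.arange(len(seq)), cuts):
            zone = int(seq.zones[chunk[0]])
            by_zone[zone].append(
                ObservationSequence(
                    vehicle_id=seq.vehicle_id,
                    symbols=seq.symbols[chunk],
                    zones=seq.zones[chunk],
                    states=None if seq.states is None else seq.states[chunk],
                    line_index=None
                    if seq.line_index is None
                    else seq.line_index[chunk],
                )
            )
    by_zone[ZONE_WHOLE] = list(sequences)
    return by_zone
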