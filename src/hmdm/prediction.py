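"""Danger prediction and driver warnings.

Whenever a dangerous observation symbol occurs (fast approach at short
headway behind a stopped vehicle), the fitted model is used to infer
the driver's current most likely state from the emission matrix and to
predict the most likely next state from the transition matrix.  A
warning is severe when the predicted next action is not a slowing one
(decelerate or stop): accelerating or holding speed into a short-gap,
queued situation is the behavior the warning is meant to interrupt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .discretization import decode_observation
from .hmm import HmmParameters
from .metrics import default_dangerous_symbols
from .sequences import STATE_NAMES, ObservationSequence

#: states that count as a safe (slowing) next action
SAFE_NEXT_STATES = frozenset({1, 3})  # decelerate, stop


@dataclass(frozen=True)
class DriverWarning:
    vehicle_id: int
    t: int
    symbol: int
    observation: tuple[int, int, int, int]
    current_state: int
    current_state_name: str
    emission_probability: float
    predicted_state: int
    predicted_state_name: str
    transition_probability: float
    severe: bool


def is_dangerous(symbol: int, dangerous: frozenset[int] | None = None) -> bool:
    if not 1 <= symbol <= 81:
        raise ValueError(f"symbol out of range: {symbol}")
    return symbol in (default_dangerous_symbols() if dangerous is None else dangerous)


def most_likely_state(B: np.ndarray, symbol: int) -> tuple[int, float]:
    """State with the highest emission probability for ``symbol``.

    Ties break toward the lowest state index.
    """
    B = np.asarray(B, dtype=float)
    col = B[:, symbol - 1]
    state = int(np.argmax(col))
    return state, float(col[state])


def predict_next_state(A: np.ndarray, current_state: int) -> tuple[int, float]:
    """Most likely next state from the current state's transition row."""
    A = np.asarray(A, dtype=float)
    if not 0 <= current_state < A.shape[0]:
        raise ValueError(f"state out of range: {current_state}")
    row = A[current_state]
    state = int(np.argmax(row))
    return state, float(row[state])


def warning_report(
    params: HmmParameters,
    sequences: list[ObservationSequence],
    dangerous: frozenset[int] | None = None,
) -> list[DriverWarning]:
    """One warning per dangerous-symbol occurrence in the sequences.

    The report is a pure function of (params, sequences): every
    occurrence produces exactly one warning, with the inferred current
    state, the predicted next state, and the severity flag.
    """
    dangerous = default_dangerous_symbols() if dangerous is None else dangerous
    warnings: list[DriverWarning] = []
    for seq in sequences:
        for t, symbol in enumerate(seq.symbols):
            symbol = int(symbol)
            if symbol not in dangerous:
                continue
            cur, emit_p = most_likely_state(params.B, symbol)
            nxt, trans_p = predict_next_state(params.A, cur)
            warnings.append(
                DriverWarning(
                    vehicle_id=seq.vehicle_id,
                    t=t,
                    symbol=symbol,
                    observation=decode_observation(symbol),
                    current_state=cur,
                    current_state_name=STATE_NAMES[cur],
                    emission_probability=emit_p,
                    predicted_state=nxt,
                    predicted_state_name=STATE_NAMES[nxt],
                    transition_probability=trans_p,
                    severe=nxt not in SAFE_NEXT_STATES,
                )
            )
    return warnings


def warnings_to_frame(warnings: list[DriverWarning]) -> pd.DataFrame:
    cols = [f.name for f in DriverWarning.__dataclass_fields__.values()]
    return pd.DataFrame([asdict(w) for w in warnings], columns=cols)


def write_warnings(warnings: list[DriverWarning], csv_path=None, json_path=None) -> None:
    if csv_path is not None:
        warnings_to_frame(warnings).to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump([asdict(w) for w in warnings], fh, indent=1)
            fh.write("\n")
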