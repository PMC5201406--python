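"""Synthetic intersection-approach data with known ground truth.

Two generation paths are provided:

* :func:`sample_hmm_sequences` draws observation sequences exactly from
  a ground-truth HMM (state chain through A, symbols through B), the
  right input for estimator tests where the emission law must be known.
* :func:`simulate_approach` realizes the physical data-collection
  design: vehicles arrive by a Poisson process 135 m upstream of a
  signalized stop line, carry a hidden behavioral state that evolves by
  the zone-specific Markov chain at 1 s steps, accelerate or brake
  according to that state, never overtake their leader, and emit a
  detection record each time they cross one of the virtual lines spaced
  2.92 m apart (frame indices at 30 frames/s).  Observations for this
  path are produced downstream by the kinematics and discretization
  stages, not drawn from B.

The default ground truth loads the dilemma zone (zone 2) with extra
emission mass on the six dangerous symbols and flatter (less decisive)
emission rows, so the qualitative zone ordering of the behavior metrics
— dilemma zone riskiest and least stable — is reproducible from
synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretization import encode_observation
from .metrics import DANGEROUS_TUPLES
from .sequences import (
    N_STATES,
    N_SYMBOLS,
    ZONE_IDS,
    ZONE_WHOLE,
    ObservationSequence,
)

_ROW_TOL = 1e-9

#: state-conditional accelerations, m/s^2 (state 3 "stop" brakes to rest)
STATE_ACCELERATIONS = {0: 1.5, 1: -2.5, 2: 0.0, 3: -3.0}


@dataclass
class GroundTruth:
    """True HMM parameters per zone, for generating synthetic data."""

    pi: np.ndarray
    A_by_zone: dict
    B_by_zone: dict

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        for zone in list(self.A_by_zone) + list(self.B_by_zone):
            if zone not in (*ZONE_IDS, ZONE_WHOLE):
                raise ValueError(f"unknown zone id: {zone!r}")
        for name, group in (("A", self.A_by_zone), ("B", self.B_by_zone)):
            for zone, mat in group.items():
                mat = np.asarray(mat, dtype=float)
                group[zone] = mat
                if (mat < 0).any() or (mat > 1).any():
                    raise ValueError(f"{name}[{zone}] entries outside [0,1]")
                if not np.allclose(mat.sum(axis=1), 1.0, atol=_ROW_TOL, rtol=0):
                    raise ValueError(f"{name}[{zone}] rows must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=_ROW_TOL):
            raise ValueError("pi must sum to 1")

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "A_by_zone": {str(z): m.tolist() for z, m in self.A_by_zone.items()},
            "B_by_zone": {str(z): m.tolist() for z, m in self.B_by_zone.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        def key(z):
            return z if z == ZONE_WHOLE else int(z)

        return cls(
            pi=np.array(d["pi"]),
            A_by_zone={key(z): np.array(m) for z, m in d["A_by_zone"].items()},
            B_by_zone={key(z): np.array(m) for z, m in d["B_by_zone"].items()},
        )


@dataclass(frozen=True)
class SimConfig:
    """Signal timing, geometry and traffic parameters of the simulated
    intersection approach.

    Defaults mirror a large urban signalized intersection: a 190 s
    cycle with 35 s green, 60 km/h posted limit, detection lines every
    2.92 m over the outer 135 m of the approach, video sampled at 30
    frames/s.  ``arrival_rate`` is vehicles/hour over all simulated
    lanes.
    """

    cycle_length: float = 190.0
    green_time: float = 35.0
    yellow_time: float = 3.0
    line_spacing: float = 2.92
    frames_per_second: int = 30
    zone_boundaries: tuple[float, float, float] = (40.0, 100.0, 135.0)
    speed_limit_kmh: float = 60.0
    arrival_rate: float = 950.0
    n_lanes: int = 2
    min_gap_m: float = 2.0
    entry_speed_range: tuple[float, float] | None = None  # default (8, limit) m/s
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.cycle_length,
            self.green_time,
            self.yellow_time,
            self.line_spacing,
            self.speed_limit_kmh,
            self.arrival_rate,
        ) <= 0:
            raise ValueError("durations, distances and rates must be positive")
        if self.green_time + self.yellow_time >= self.cycle_length:
            raise ValueError("green + yellow must fit inside the cycle")
        b = self.zone_boundaries
        if not (0 < b[0] < b[1] < b[2]):
            raise ValueError("zone boundaries must be strictly increasing")
        if self.frames_per_second < 1 or self.n_lanes < 1:
            raise ValueError("frame rate and lane count must be >= 1")

    @property
    def speed_limit_ms(self) -> float:
        return self.speed_limit_kmh / 3.6

    def signal_phase(self, time_s: float) -> str:
        """Phase at ``time_s``: green, then yellow, then red, cyclic."""
        t = time_s % self.cycle_length
        if t < self.green_time:
            return "green"
        if t < self.green_time + self.yellow_time:
            return "yellow"
        return "red"


def _normalize_rows(mat: np.ndarray) -> np.ndarray:
    return mat / mat.sum(axis=1, keepdims=True)


def _base_emission_factors() -> dict[int, list[np.ndarray]]:
    """State-conditional category distributions over the four observed
    variables (speed, headway, queue, signal), combined by product."""
    return {
        0: [  # accelerate: medium/fast, green, little queue
            np.array([0.2, 0.5, 0.3]),
            np.array([0.2, 0.3, 0.5]),
            np.array([0.5, 0.4, 0.1]),
            np.array([0.7, 0.1, 0.2]),
        ],
        1: [  # decelerate: slowing, short headway, queue forming
            np.array([0.5, 0.4, 0.1]),
            np.array([0.1, 0.6, 0.3]),
            np.array([0.2, 0.4, 0.4]),
            np.array([0.2, 0.5, 0.3]),
        ],
        2: [  # maintain: medium speed, mixed context
            np.array([0.3, 0.5, 0.2]),
            np.array([0.3, 0.3, 0.4]),
            np.array([0.6, 0.3, 0.1]),
            np.array([0.6, 0.2, 0.2]),
        ],
        3: [  # stop: crawling, red, stopped queue ahead
            np.array([0.9, 0.08, 0.02]),
            np.array([0.3, 0.5, 0.2]),
            np.array([0.2, 0.2, 0.6]),
            np.array([0.1, 0.8, 0.1]),
        ],
    }


def _product_emission_rows() -> np.ndarray:
    """4 x 81 emission matrix from the per-variable factor distributions."""
    factors = _base_emission_factors()
    B = np.zeros((N_STATES, N_SYMBOLS))
    for j, (sp, hw, qu, sg) in factors.items():
        for a in (1, 2, 3):
            for b in (1, 2, 3):
                for c in (1, 2, 3):
                    for d in (1, 2, 3):
                        k = encode_observation((a, b, c, d))
                        B[j, k - 1] = sp[a - 1] * hw[b - 1] * qu[c - 1] * sg[d - 1]
    return B


def default_ground_truth() -> GroundTruth:
    """Fixed, documented ground truth for the three zones and the whole road.

    Zone emissions are the product-structured base matrix mixed toward
    uniform by a zone-specific diffuseness (the dilemma zone is much
    flatter: hesitant, indecisive behavior) and loaded with extra mass
    on the six dangerous symbols for the accelerate and maintain states
    (heaviest in the dilemma zone).  Transition matrices are decisive
    (diagonally dominant) in zones 1 and 3 and diffuse in zone 2.  The
    whole-road matrices are the equal-weight mixtures of the zone
    matrices.  Deterministic: repeated calls return identical values.
    """
    B_base = _product_emission_rows()
    uniform = np.full((N_STATES, N_SYMBOLS), 1.0 / N_SYMBOLS)
    danger_cols = np.array(
        [encode_observation(t) - 1 for t in DANGEROUS_TUPLES]
    )
    danger = np.zeros(N_SYMBOLS)
    danger[danger_cols] = 1.0 / danger_cols.size

    concentration = {1: 0.90, 2: 0.50, 3: 0.85}
    danger_mass = {1: 0.04, 2: 0.20, 3: 0.01}

    B_by_zone: dict = {}
    for zone in ZONE_IDS:
        c, d = concentration[zone], danger_mass[zone]
        B = c * B_base + (1 - c) * uniform
        for j in (0, 2):  # accelerate, maintain: the non-slowing states
            B[j] = (1 - d) * B[j] + d * danger
        B_by_zone[zone] = _normalize_rows(B)

    A_by_zone: dict = {
        # zone 1 (by the stop line): decisive, braking-oriented
        1: _normalize_rows(
            np.array(
                [
                    [0.55, 0.20, 0.15, 0.10],
                    [0.10, 0.55, 0.15, 0.20],
                    [0.10, 0.25, 0.55, 0.10],
                    [0.15, 0.05, 0.10, 0.70],
                ]
            )
        ),
        # zone 2 (dilemma zone): diffuse, hesitant switching
        2: _normalize_rows(
            np.array(
                [
                    [0.30, 0.25, 0.30, 0.15],
                    [0.30, 0.25, 0.30, 0.15],
                    [0.25, 0.25, 0.35, 0.15],
                    [0.20, 0.20, 0.25, 0.35],
                ]
            )
        ),
        # zone 3 (far upstream): settled cruising
        3: _normalize_rows(
            np.array(
                [
                    [0.60, 0.05, 0.30, 0.05],
                    [0.10, 0.60, 0.25, 0.05],
                    [0.10, 0.10, 0.75, 0.05],
                    [0.10, 0.10, 0.20, 0.60],
                ]
            )
        ),
    }
    A_by_zone[ZONE_WHOLE] = _normalize_rows(
        sum(A_by_zone[z] for z in ZONE_IDS) / 3.0
    )
    B_by_zone[ZONE_WHOLE] = _normalize_rows(
        sum(B_by_zone[z] for z in ZONE_IDS) / 3.0
    )
    pi = np.array([0.20, 0.25, 0.45, 0.10])
    return GroundTruth(pi=pi, A_by_zone=A_by_zone, B_by_zone=B_by_zone)


def sample_hmm_sequences(
    truth: GroundTruth,
    zone,
    n_sequences: int,
    length: int,
    seed: int,
) -> list[ObservationSequence]:
    """Draw labeled sequences exactly from the zone's HMM.

    state_1 ~ pi, state_{t+1} ~ A[state_t], symbol_t ~ B[state_t]; the
    true state labels are retained.  Fully reproducible from ``seed``.
    """
    if zone not in truth.A_by_zone:
        raise ValueError(f"unknown zone id: {zone!r}")
    if n_sequences < 1 or length < 1:
        raise ValueError("need n_sequences >= 1 and length >= 1")
    A = truth.A_by_zone[zone]
    B = truth.B_by_zone[zone]
    rng = np.random.default_rng(seed)
    zone_tag = 0 if zone == ZONE_WHOLE else int(zone)

    out = []
    n_states = truth.pi.size
    for vid in range(n_sequences):
        states = np.empty(length, dtype=np.int64)
        states[0] = rng.choice(n_states, p=truth.pi)
        for t in range(1, length):
            states[t] = rng.choice(n_states, p=A[states[t - 1]])
        symbols = np.empty(length, dtype=np.int64)
        for t in range(length):
            symbols[t] = rng.choice(B.shape[1], p=B[states[t]]) + 1
        out.append(
            ObservationSequence(
                vehicle_id=vid,
                symbols=symbols,
                zones=np.full(length, zone_tag),
                states=states,
            )
        )
    return out


@dataclass
class _Vehicle:
    vehicle_id: int
    lane: int
    entry_time: float
    speed: float
    position: float  # metres upstream of the stop line, decreasing
    state: int
    next_state_update: float
    states_at_lines: list = field(default_factory=list)
    lines_crossed: list = field(default_factory=list)
    frames: list = field(default_factory=list)
    done: bool = False


def simulate_approach(
    truth: GroundTruth,
    config: SimConfig | None = None,
    n_vehicles: int = 256,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[ObservationSequence]]:
    """Kinematic realization of the intersection approach.

    Vehicles arrive by a Poisson process, enter at the outer boundary
    with a random cruising speed, and integrate their motion at frame
    resolution.  The hidden behavioral state evolves once per second by
    the transition matrix of the zone the vehicle currently occupies
    and sets the acceleration (stop brakes to rest).  Followers never
    overtake: a follower closing within ``min_gap_m`` of its leader
    matches the leader's speed (or halts if the leader is stopped).
    Returns the detection-record table (vehicle_id, lane, line_index,
    frame_index) and per-vehicle state traces aligned with the lines
    crossed.
    """
    config = config or SimConfig()
    if n_vehicles < 1:
        raise ValueError("need at least one vehicle")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    from .discretization import ZoneConfig, assign_zone

    zones = ZoneConfig(boundaries=config.zone_boundaries)
    entry = config.zone_boundaries[2]
    dt = 1.0 / config.frames_per_second
    vmax = config.speed_limit_ms * 1.15  # mild speeding tolerated
    n_lines = int(np.floor(entry / config.line_spacing)) + 1
    per_second_rate = config.arrival_rate / 3600.0

    # Poisson arrivals over all lanes; lane assigned uniformly
    inter = rng.exponential(1.0 / per_second_rate, size=n_vehicles)
    arrival_times = np.cumsum(inter)
    lanes = rng.integers(0, config.n_lanes, size=n_vehicles)
    speed_lo, speed_hi = config.entry_speed_range or (8.0, config.speed_limit_ms)
    entry_speeds = rng.uniform(speed_lo, speed_hi, size=n_vehicles)

    vehicles = [
        _Vehicle(
            vehicle_id=i,
            lane=int(lanes[i]),
            entry_time=float(arrival_times[i]),
            speed=float(entry_speeds[i]),
            position=entry,
            state=int(rng.choice(truth.pi.size, p=truth.pi)),
            next_state_update=float(arrival_times[i]) + 1.0,
        )
        for i in range(n_vehicles)
    ]

    horizon = float(arrival_times[-1]) + 600.0
    t = 0.0
    active_by_lane: dict[int, list[_Vehicle]] = {ln: [] for ln in range(config.n_lanes)}
    pending = sorted(vehicles, key=lambda v: v.entry_time)
    pi_idx = 0
    n_active = 0
    while t <= horizon and (pi_idx < len(pending) or n_active > 0):
        while pi_idx < len(pending) and pending[pi_idx].entry_time <= t:
            active_by_lane[pending[pi_idx].lane].append(pending[pi_idx])
            n_active += 1
            pi_idx += 1
        for lane_vehicles in active_by_lane.values():
            leader: _Vehicle | None = None
            for v in lane_vehicles:  # entry order == leader order (no overtaking)
                # hidden state evolves at 1 s cadence, per current zone
                if t >= v.next_state_update:
                    zone = assign_zone(min(max(v.position, 0.0), entry), zones)
                    A = truth.A_by_zone[zone]
                    v.state = int(rng.choice(truth.pi.size, p=A[v.state]))
                    v.next_state_update += 1.0
                accel = STATE_ACCELERATIONS[v.state]
                new_speed = max(0.0, min(vmax, v.speed + accel * dt))
                if v.state == 3 and new_speed < 0.3:
                    new_speed = 0.0
                new_pos = v.position - new_speed * dt
                # car following: never pass the leader
                if leader is not None:
                    floor_pos = leader.position + config.min_gap_m
                    if new_pos < floor_pos:
                        new_pos = min(v.position, floor_pos)
                        new_speed = min(new_speed, leader.speed)
                # record crossings of detection lines (position passes i*s)
                if new_pos < v.position:
                    old_line = int(np.floor(v.position / config.line_spacing))
                    new_line = int(np.floor(new_pos / config.line_spacing))
                    for ln in range(min(old_line, n_lines - 1), new_line, -1):
                        if ln * config.line_spacing <= v.position:
                            fr = int(round((t + dt) * config.frames_per_second))
                            if v.frames and fr <= v.frames[-1]:
                                fr = v.frames[-1] + 1
                            v.lines_crossed.append(ln)
                            v.frames.append(fr)
                            v.states_at_lines.append(v.state)
                v.speed = new_speed
                v.position = new_pos
                if v.position <= 0.0:
                    v.done = True
                else:
                    leader = v
            if any(v.done for v in lane_vehicles):
                lane_vehicles[:] = [v for v in lane_vehicles if not v.done]
                n_active = sum(len(vs) for vs in active_by_lane.values())
        t += dt

    rows = []
    traces = []
    for v in vehicles:
        for ln, fr in zip(v.lines_crossed, v.frames):
            rows.append(
                {
                    "vehicle_id": v.vehicle_id,
                    "lane": v.lane,
                    "line_index": ln,
                    "frame_index": fr,
                }
            )
        if v.lines_crossed:
            lines = np.array(v.lines_crossed)
            traces.append(
                ObservationSequence(
                    vehicle_id=v.vehicle_id,
                    # symbols come from the kinematics/discretization stages;
                    # 0 marks "not yet observed"
                    symbols=np.zeros(lines.size, dtype=np.int64),
                    zones=np.array(
                        [
                            assign_zone(min(ln * config.line_spacing, entry), zones)
                            for ln in lines
                        ]
                    ),
                    states=np.array(v.states_at_lines),
                    line_index=lines,
                )
            )
    records = pd.DataFrame(
        rows, columns=["vehicle_id", "lane", "line_index", "frame_index"]
    )
    return records, traces
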