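"""End-to-end pipeline: generate, discretize, split, train, score, warn.

``run_pipeline`` produces a self-describing run directory: fitted
parameter JSONs for the three approach zones and the whole road, a
zone summary table (stability 2-norm, risk index, validation MAPE),
a warning report, the config snapshot and a stage log.  Every random
draw derives from the single config seed.

Two data sources are supported.  ``source="hmm"`` (default) draws each
vehicle's per-zone observation runs exactly from the ground-truth HMM
— the data-generating process the model assumes, and the path on which
estimation quality is meaningful.  ``source="physical"`` instead
simulates vehicle kinematics, extracts detection-line records, and
recovers observations through the kinematics and discretization
stages, exercising the full measurement chain.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from . import kinematics as kin
from .discretization import DiscretizationRules, ZoneConfig, tracks_to_sequences
from .hmm import FitConfig, baum_welch_fit, supervised_mle
from .metrics import (
    ZoneReport,
    align_states,
    default_dangerous_symbols,
    mape,
    risk_index,
    stability_2norm,
    summary_table,
)
from .prediction import warning_report, write_warnings
from .sequences import (
    N_STATES,
    N_SYMBOLS,
    ZONE_IDS,
    ZONE_WHOLE,
    ObservationSequence,
    write_sequences_csv,
    zone_subsequences,
)
from .synthetic import GroundTruth, SimConfig, default_ground_truth, sample_hmm_sequences, simulate_approach

logger = logging.getLogger(__name__)

#: per-zone observations per vehicle on the default geometry: interior
#: detection lines (2.92 m spacing) falling in each zone on a 135 m approach
DEFAULT_ZONE_LENGTHS = {3: 12, 2: 20, 1: 12}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a reproducible run needs."""

    sim: SimConfig = field(default_factory=SimConfig)
    rules: DiscretizationRules = field(default_factory=DiscretizationRules)
    zones: ZoneConfig = field(default_factory=ZoneConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    kin: kin.KinematicsConfig = field(default_factory=kin.KinematicsConfig)
    n_vehicles: int = 256
    zone_lengths: dict = field(default_factory=lambda: dict(DEFAULT_ZONE_LENGTHS))
    source: str = "hmm"
    train_fraction: float = 7480 / 11264
    seed: int = 0
    norm_kind: str = "spectral"
    risk_variant: str = "max"
    mape_min_reference: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")
        if self.source not in ("hmm", "physical"):
            raise ValueError("source must be 'hmm' or 'physical'")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = {}
        if "sim" in raw:
            sim = dict(raw["sim"])
            if "zone_boundaries" in sim:
                sim["zone_boundaries"] = tuple(sim["zone_boundaries"])
            kwargs["sim"] = SimConfig(**sim)
        if "rules" in raw:
            rules = dict(raw["rules"])
            if "speed_breaks" in rules:
                rules["speed_breaks"] = tuple(rules["speed_breaks"])
            kwargs["rules"] = DiscretizationRules(**rules)
        if "zones" in raw:
            kwargs["zones"] = ZoneConfig(boundaries=tuple(raw["zones"]["boundaries"]))
        if "fit" in raw:
            kwargs["fit"] = FitConfig(**raw["fit"])
        if "kinematics" in raw:
            kwargs["kin"] = kin.KinematicsConfig(**raw["kinematics"])
        if "zone_lengths" in raw:
            kwargs["zone_lengths"] = {int(k): v for k, v in raw["zone_lengths"].items()}
        for key in (
            "n_vehicles",
            "source",
            "train_fraction",
            "seed",
            "norm_kind",
            "risk_variant",
            "mape_min_reference",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def snapshot(self) -> dict:
        d = asdict(self)
        d["zone_lengths"] = {str(k): v for k, v in self.zone_lengths.items()}
        return d


def split_train_validation(
    sequences: list[ObservationSequence], train_fraction: float, seed: int
) -> tuple[list[ObservationSequence], list[ObservationSequence]]:
    """Seeded vehicle-level split: whole sequences, never within one.

    The realized record fractions differ slightly from the requested
    one because sequences are kept intact.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two vehicles to split")
    n_train = int(round(train_fraction * len(sequences)))
    if n_train == 0 or n_train == len(sequences):
        raise ValueError("train fraction leaves one side of the split empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sequences))
    train = [sequences[i] for i in sorted(order[:n_train])]
    valid = [sequences[i] for i in sorted(order[n_train:])]
    return train, valid


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def generate_hmm_sequences(
    truth: GroundTruth, config: PipelineConfig
) -> list[ObservationSequence]:
    """Per-vehicle approach sequences drawn zone-by-zone from the truth.

    Each vehicle traverses zone 3, then the dilemma zone, then zone 1;
    its sequence is the concatenation of the three per-zone HMM runs,
    tagged with their zones.
    """
    zone_order = [3, 2, 1]
    seeds = _derive_seeds(config.seed, len(zone_order))
    per_zone = {
        z: sample_hmm_sequences(
            truth, z, config.n_vehicles, config.zone_lengths[z], seed
        )
        for z, seed in zip(zone_order, seeds)
    }
    out = []
    for vid in range(config.n_vehicles):
        symbols = np.concatenate([per_zone[z][vid].symbols for z in zone_order])
        zones_arr = np.concatenate(
            [np.full(config.zone_lengths[z], z) for z in zone_order]
        )
        states = np.concatenate([per_zone[z][vid].states for z in zone_order])
        out.append(
            ObservationSequence(
                vehicle_id=vid, symbols=symbols, zones=zones_arr, states=states
            )
        )
    return out


def generate_physical_sequences(
    truth: GroundTruth, config: PipelineConfig
) -> tuple[list[ObservationSequence], "pd.DataFrame"]:
    """Simulate kinematics, then recover observations from the records."""
    records, _traces = simulate_approach(
        truth, config.sim, config.n_vehicles, seed=config.seed
    )
    tracks = kin.build_tracks(records, config.kin, cycle_length=config.sim.cycle_length)
    kin.annotate_context(tracks, config.sim.signal_phase, config.kin)
    seqs = tracks_to_sequences(
        tracks, config.rules, config.zones, line_spacing=config.kin.line_spacing
    )
    return seqs, records


def run_pipeline(config: PipelineConfig, outdir, truth: GroundTruth | None = None):
    """Train per-zone and whole-road models and write the run directory.

    Returns the list of :class:`~hmdm.metrics.ZoneReport` (zones 1-3
    and the whole road).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    truth = truth or default_ground_truth()
    if config.source == "hmm":
        sequences = generate_hmm_sequences(truth, config)
        log(f"generate[hmm]: {len(sequences)} vehicles, "
            f"{sum(len(s) for s in sequences)} observations")
    else:
        sequences, records = generate_physical_sequences(truth, config)
        kin.write_detection_csv(records, outdir / "detections.csv")
        log(f"generate[physical]: {len(records)} detection records, "
            f"{len(sequences)} usable vehicle sequences, "
            f"{sum(len(s) for s in sequences)} observations")
    write_sequences_csv(sequences, outdir / "sequences.csv")

    split_seed = _derive_seeds(config.seed + 1, 1)[0]
    train, valid = split_train_validation(sequences, config.train_fraction, split_seed)
    n_train = sum(len(s) for s in train)
    n_valid = sum(len(s) for s in valid)
    log(f"split: {len(train)} train vehicles ({n_train} records), "
        f"{len(valid)} validation vehicles ({n_valid} records)")

    train_by_zone = zone_subsequences(train)
    valid_by_zone = zone_subsequences(valid)
    all_by_zone = zone_subsequences(sequences)

    dangerous = default_dangerous_symbols()
    reports: list[ZoneReport] = []
    all_warnings = []
    fit_seeds = _derive_seeds(config.seed + 2, 4)
    for zone, fit_seed in zip([*ZONE_IDS, ZONE_WHOLE], fit_seeds):
        train_seqs = [s.symbols for s in train_by_zone[zone] if len(s) >= 2]
        if not train_seqs:
            raise RuntimeError(f"train: no usable sequences for zone {zone}")
        fit_cfg = replace(config.fit, seed=fit_seed)
        params, trace = baum_welch_fit(train_seqs, N_STATES, N_SYMBOLS, fit_cfg)
        log(f"train[zone {zone}]: {len(train_seqs)} sequences, "
            f"{len(trace)} EM evaluations, final loglik {trace[-1]:.2f}")

        val_mape = None
        labeled = [s for s in valid_by_zone[zone] if s.is_labeled and len(s) >= 2]
        if labeled:
            reference = supervised_mle(labeled, N_STATES, N_SYMBOLS)
            val_mape = mape(
                align_states(params, reference),
                reference,
                config.mape_min_reference,
            )
            log(f"validate[zone {zone}]: MAPE {val_mape:.2f}% "
                f"against supervised MLE on {len(labeled)} held-out sequences")

        report = ZoneReport(
            zone=zone,
            params=params,
            stability=stability_2norm(params.B, config.norm_kind),
            risk=risk_index(params.B, dangerous, config.risk_variant),
            validation_mape=val_mape,
            n_train_records=sum(len(s) for s in train_by_zone[zone]),
            n_validation_records=sum(len(s) for s in valid_by_zone[zone]),
        )
        reports.append(report)
        tag = f"zone_{zone}" if zone != ZONE_WHOLE else "whole"
        params.to_json(outdir / f"params_{tag}.json")
        report.to_json(outdir / f"report_{tag}.json")
        np.savetxt(outdir / f"loglik_trace_{tag}.csv", np.asarray(trace),
                   header="log_likelihood", comments="")

        if zone != ZONE_WHOLE:
            zone_warnings = warning_report(params, all_by_zone[zone], dangerous)
            all_warnings.extend(zone_warnings)
            log(f"predict[zone {zone}]: {len(zone_warnings)} warnings "
                f"({sum(w.severe for w in zone_warnings)} severe)")

    summary = summary_table(reports)
    summary.to_csv(outdir / "summary.csv", index=False)
    write_warnings(
        all_warnings, outdir / "warnings.csv", outdir / "warnings.json"
    )
    with open(outdir / "config_snapshot.json", "w") as fh:
        json.dump(config.snapshot(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return reports
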