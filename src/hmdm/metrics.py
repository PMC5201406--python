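"""Stability and risk measures for fitted driver-behavior models.

Stability of the decision process in a zone is summarized by the matrix
2-norm (largest singular value) of the emission matrix B: a peakier,
more decisive emission structure has a larger top singular value.  Risk
is summarized by the index alpha = sum_k log10(x_k) over the six
dangerous observation symbols (fast speed, short headway, stopped
vehicle ahead), where x_k is the emission probability of the dangerous
symbol under its most likely state; larger (less negative) alpha means
dangerous observations are more probable, i.e. riskier behavior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretization import encode_observation
from .hmm import HmmParameters, _check_stochastic

#: (speed, headway, queue, signal) bin tuples of the dangerous behaviors:
#: medium-or-fast speed, short headway, stopped vehicle ahead, any signal.
DANGEROUS_TUPLES = (
    (2, 2, 3, 1),
    (2, 2, 3, 2),
    (2, 2, 3, 3),
    (3, 2, 3, 1),
    (3, 2, 3, 2),
    (3, 2, 3, 3),
)


def default_dangerous_symbols() -> frozenset[int]:
    """Symbol indices of the six dangerous observation combinations."""
    return frozenset(encode_observation(t) for t in DANGEROUS_TUPLES)


def stability_2norm(B: np.ndarray, kind: str = "spectral") -> float:
    """Stability of an emission matrix: its matrix norm.

    ``kind="spectral"`` (default) is the matrix 2-norm, the largest
    singular value; ``kind="frobenius"`` is available as an alternative
    summary.  For a row-stochastic N x M matrix the spectral norm lies
    in [1/sqrt(M), sqrt(N)]: it is smallest for diffuse rows and grows
    as rows concentrate, so larger means more decisive behavior.
    """
    B = np.asarray(B, dtype=float)
    _check_stochastic(B, "B")
    if kind == "spectral":
        return float(np.linalg.norm(B, ord=2))
    if kind == "frobenius":
        return float(np.linalg.norm(B, ord="fro"))
    raise ValueError(f"unknown norm kind: {kind!r}")


def risk_index(
    B: np.ndarray,
    dangerous: frozenset[int] | set[int] | None = None,
    variant: str = "max",
    floor: float = 1e-10,
) -> float:
    """Risk index alpha = sum of log10 emission probabilities of the
    dangerous symbols.

    ``variant="max"`` (default) sums, over dangerous symbols, the log10
    of the emission probability under the most likely state for that
    symbol (six summands for the default set).  ``variant="all"`` sums
    over every (state, symbol) pair instead, which is systematically
    more negative.  Probabilities are floored at ``floor`` before the
    log so smoothed near-zeros stay finite.
    """
    B = np.asarray(B, dtype=float)
    _check_stochastic(B, "B")
    dangerous = default_dangerous_symbols() if dangerous is None else dangerous
    if not dangerous:
        raise ValueError("dangerous symbol set must be non-empty")
    cols = sorted(dangerous)
    if min(cols) < 1 or max(cols) > B.shape[1]:
        raise ValueError("dangerous symbol outside the alphabet")
    sub = B[:, [c - 1 for c in cols]]
    if variant == "max":
        probs = sub.max(axis=0)
    elif variant == "all":
        probs = sub.ravel()
    else:
        raise ValueError(f"unknown risk-index variant: {variant!r}")
    return float(np.log10(np.maximum(probs, floor)).sum())


def align_states(
    estimated: HmmParameters, reference: HmmParameters
) -> HmmParameters:
    """Relabel the estimated model's states to best match a reference.

    Unsupervised estimation identifies states only up to permutation.
    This searches all N! relabelings (N=4 here, so 24) for the one
    minimizing the total absolute difference between the emission
    matrices, and returns the estimated parameters with rows (and the
    transition matrix) permuted accordingly.  Needed before entrywise
    comparisons such as :func:`mape`.
    """
    from itertools import permutations

    n = reference.n_states
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(n)):
        p = list(perm)
        cost = np.abs(estimated.B[p] - reference.B).sum()
        if cost < best_cost:
            best_cost, best_perm = cost, p
    p = best_perm
    return HmmParameters(
        pi=estimated.pi[p],
        A=estimated.A[np.ix_(p, p)],
        B=estimated.B[p],
    )


def mape(
    estimated: HmmParameters,
    reference: HmmParameters,
    min_reference: float = 0.01,
) -> float:
    """Mean absolute percentage error between two parameter sets.

    Averages |est - ref| / ref over every entry of pi, A and B whose
    reference value is at least ``min_reference`` (near-zero reference
    probabilities are masked to avoid division blow-ups), and returns a
    percentage.
    """
    if (
        estimated.n_states != reference.n_states
        or estimated.n_symbols != reference.n_symbols
    ):
        raise ValueError("parameter sets have different dimensions")
    errs = []
    for est, ref in (
        (estimated.pi, reference.pi),
        (estimated.A, reference.A),
        (estimated.B, reference.B),
    ):
        mask = ref >= min_reference
        if mask.any():
            errs.append(np.abs(est[mask] - ref[mask]) / ref[mask])
    if not errs:
        raise ValueError("no reference entry exceeds min_reference")
    return float(np.concatenate([e.ravel() for e in errs]).mean() * 100.0)


@dataclass
class ZoneReport:
    """Per-zone model summary: fitted parameters and behavior metrics."""

    zone: int | str
    params: HmmParameters
    stability: float
    risk: float
    validation_mape: float | None = None
    n_train_records: int | None = None
    n_validation_records: int | None = None

    def to_dict(self) -> dict:
        return {
            "zone": self.zone,
            "stability_2norm": self.stability,
            "risk_index": self.risk,
            "validation_mape": self.validation_mape,
            "n_train_records": self.n_train_records,
            "n_validation_records": self.n_validation_records,
            "params": self.params.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def summary_table(reports: list[ZoneReport]) -> pd.DataFrame:
    """Zones x {2-norm, risk index, MAPE} summary, one row per model."""
    return pd.DataFrame(
        [
            {
                "zone": r.zone,
                "stability_2norm": r.stability,
                "risk_index": r.risk,
                "validation_mape": r.validation_mape,
            }
            for r in reports
        ]
    )
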