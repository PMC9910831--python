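"""Closed-form probability calculators for fluctuation-assay design.

These treat responder assignment as independent Bernoulli(p) per cell —
the stochastic null hypothesis, deliberately ignoring heritability.  The
contrast between these predictions and the lineage simulator's output is
the analytical point of the fluctuation test.

Baseline ``p = 0.02134`` is the measured per-cell responder probability;
a clone of generation g has ``2**g`` cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

__all__ = [
    "DesignParams",
    "DetectionProbability",
    "prob_no_responders",
    "expected_responders",
    "neighbor_prob",
    "min_generation_for_detection",
    "design_table",
]

#: measured per-cell responder probability (regular cultures)
RESPONDER_PROBABILITY = 0.02134
#: average number of neighboring cells assumed for the neighbor calculation
DEFAULT_N_NEIGHBORS = 4


@dataclass(frozen=True)
class DesignParams:
    p: float = RESPONDER_PROBABILITY
    generation: int = 6
    n_neighbors: int = DEFAULT_N_NEIGHBORS

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if self.generation < 0 or self.n_neighbors < 0:
            raise ValueError("generation and n_neighbors must be >= 0")


class DetectionProbability(NamedTuple):
    p_none: float
    p_at_least_one: float


def _validate_p(p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")


def prob_no_responders(p: float, generation: int) -> DetectionProbability:
    """P(no responders) = (1-p)**(2**g) in a generation-g clone, and its complement."""
    _validate_p(p)
    if generation < 0:
        raise ValueError("generation must be >= 0")
    # exp/log1p form avoids overflow of 2**g for large g
    if p == 0.0:
        p_none = 1.0
    elif p == 1.0:
        p_none = 0.0
    else:
        p_none = math.exp((2.0**generation) * math.log1p(-p))
    return DetectionProbability(p_none=p_none, p_at_least_one=1.0 - p_none)


def expected_responders(p: float, n_cells: float) -> float:
    """Expected responder count p * n_cells under the Bernoulli null."""
    _validate_p(p)
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    return p * n_cells


def neighbor_prob(p: float, n_neighbors: int = DEFAULT_N_NEIGHBORS) -> float:
    """P(at least one of n neighboring cells is a responder) = 1 - (1-p)**n."""
    _validate_p(p)
    if n_neighbors < 0:
        raise ValueError("n_neighbors must be >= 0")
    return 1.0 - (1.0 - p) ** n_neighbors


def min_generation_for_detection(p: float, target_prob: float) -> int:
    """Smallest generation g with P(>=1 responder among 2**g cells) >= target.

    Requires ``0 < p < 1`` and ``0 < target_prob < 1`` (the target is
    unreachable at p=0).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    if not 0.0 < target_prob < 1.0:
        raise ValueError(f"target_prob must lie strictly in (0, 1), got {target_prob}")
    g = 0
    while prob_no_responders(p, g).p_at_least_one < target_prob:
        g += 1
    return g


def design_table(
    p: float = RESPONDER_PROBABILITY,
    max_generation: int = 9,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
) -> pd.DataFrame:
    """Per-generation detection probabilities and expected responder counts."""
    rows = []
    for g in range(max_generation + 1):
        n_cells = 2**g
        det = prob_no_responders(p, g)
        rows.append(
            {
                "generation": g,
                "n_cells": n_cells,
                "p_at_least_one": det.p_at_least_one,
                "expected_responders": expected_responders(p, n_cells),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["neighbor_prob"] = neighbor_prob(p, n_neighbors)
    return df
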