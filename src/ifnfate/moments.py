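"""Deterministic across-colony moments of the responder fraction.

For a clone grown to generation g the responder fraction across colonies
has mean equal to the closed-form relaxation x(g*T) and a variance set by
shared ancestry: two leaves whose most recent common ancestor divided at
day ``a`` share the founder's history up to ``a`` and evolve independently
afterwards.  Summing the pair covariances over divergence depths gives the
exact inter-colony variance without simulation:

    Var(X) = N**-2 [ N m (1-m) + sum_{i != j} Cov(s_i, s_j) ],  N = 2**g,

where for an unordered leaf pair diverging at day a

    E[s_i s_j] = sum_z P(founder -> z over a) * P(z -> RESPONSIVE over g-a)**2

and the number of such unordered pairs is ``2**a * 2**(2*(g-a-1))``.

Technical noise combines with the model CV in quadrature at the CV level:
``CV_total**2 = CV_model**2 + CV_tech**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .switching import CellState, SwitchingRates, mean_fraction, transition_matrix

__all__ = [
    "ColonyMoments",
    "CVDecomposition",
    "CVCurve",
    "colony_moments",
    "cv_curve",
    "cv_peak_day",
    "pair_count",
]


class ColonyMoments(NamedTuple):
    mean: float
    variance: float
    cv: float


@dataclass(frozen=True)
class CVDecomposition:
    """Model/technical/total CV of the clone responder fraction at one generation."""

    generation: int
    day: float
    mean_fraction: float
    cv_model: float
    cv_tech: float
    cv_total: float


@dataclass(frozen=True)
class CVCurve:
    """Ordered per-generation CV decompositions (generation 0 included)."""

    points: tuple[CVDecomposition, ...]

    def __post_init__(self) -> None:
        gens = [p.generation for p in self.points]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("generations must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.points])


def pair_count(generation: int, a: int) -> int:
    """Unordered leaf pairs of a depth-g tree whose MRCA divided at day ``a``.

    The tree has 2**a nodes dividing at day a; each division separates two
    subtrees of 2**(g-a-1) leaves.  Summed over a this accounts for every
    one of C(2**g, 2) pairs exactly once.
    """
    if not 0 <= a < generation:
        raise ValueError(f"need 0 <= a < generation, got a={a}, g={generation}")
    return 2**a * 2 ** (2 * (generation - a - 1))


def colony_moments(
    rates: SwitchingRates,
    generation: int,
    initial_state: CellState = CellState.RESPONSIVE,
    division_interval: float = 1.0,
) -> ColonyMoments:
    """Exact mean, variance and CV of the clone responder fraction.

    Mean equals ``mean_fraction(g*T, rates, x0)`` exactly; the variance is
    the shared-ancestry pair decomposition described in the module
    docstring.  CV is NaN when the mean is zero.
    """
    if generation < 0:
        raise ValueError("generation must be >= 0")
    T = division_interval
    x0 = 1.0 if initial_state == CellState.RESPONSIVE else 0.0
    m = float(mean_fraction(generation * T, rates, x0))
    if generation == 0:
        # single deterministic founder
        cv = 0.0 if m > 0 else math.nan
        return ColonyMoments(mean=m, variance=0.0, cv=cv)
    g = generation
    N = 2**g
    s0 = int(initial_state)
    cov_sum = 0.0
    for a in range(g):
        ancestor_dist = transition_matrix(rates, a * T)[s0]
        q = transition_matrix(rates, (g - a) * T)[:, int(CellState.RESPONSIVE)]
        e_pair = float(ancestor_dist @ (q**2))
        cov_sum += pair_count(g, a) * (e_pair - m * m)
    var = (N * m * (1.0 - m) + 2.0 * cov_sum) / N**2
    var = max(var, 0.0)  # guard float round-off at the heritable limit
    cv = math.sqrt(var) / m if m > 0 else math.nan
    return ColonyMoments(mean=m, variance=var, cv=cv)


def cv_curve(
    rates: SwitchingRates,
    max_generation: int,
    cv_tech: float = 0.0,
    initial_state: CellState = CellState.RESPONSIVE,
    division_interval: float = 1.0,
) -> CVCurve:
    """Per-generation CV decomposition for generations 0..max_generation.

    ``cv_total = sqrt(cv_model**2 + cv_tech**2)`` (quadrature combination);
    in the ergodic tail the model CV decays and ``cv_total`` approaches the
    technical floor.
    """
    if max_generation < 1:
        raise ValueError("max_generation must be >= 1")
    if cv_tech < 0:
        raise ValueError("cv_tech must be >= 0")
    points = []
    for g in range(max_generation + 1):
        m, _, cvm = colony_moments(rates, g, initial_state, division_interval)
        cv_total = math.hypot(cvm, cv_tech) if not math.isnan(cvm) else math.nan
        points.append(
            CVDecomposition(
                generation=g,
                day=g * division_interval,
                mean_fraction=m,
                cv_model=cvm,
                cv_tech=cv_tech,
                cv_total=cv_total,
            )
        )
    return CVCurve(points=tuple(points))


def cv_peak_day(curve: CVCurve) -> float:
    """Day of maximal total CV (earliest day on ties; NaNs never win)."""
    if len(curve) == 0:
        raise ValueError("curve must be non-empty")
    totals = np.array([p.cv_total for p in curve.points])
    totals = np.where(np.isnan(totals), -np.inf, totals)
    idx = int(np.argmax(totals))
    return curve.points[idx].day
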