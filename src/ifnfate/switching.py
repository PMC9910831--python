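"""Two-state responsive/unresponsive switching model.

Single cells occupy one of two states, RESPONSIVE or UNRESPONSIVE, and
switch between them in continuous time with per-day rates ``kon``
(unresponsive -> responsive) and ``koff`` (responsive -> unresponsive).
The stationary responsive fraction is ``f = kon / (kon + koff)``, so the
model is fully determined by the pair ``(koff, f)`` with
``kon = koff * f / (1 - f)``.

The mean responsive fraction relaxes exponentially,

    x(t) = f + (x0 - f) * exp(-(kon + koff) * t),

and the exact two-state Markov transition probabilities over any interval
are available in closed form (:func:`transition_matrix`).  Rates are
continuous-time per-day quantities; switching over a cell-cycle interval is
always computed from the exact matrix exponential, never from a Bernoulli
approximation, so results are valid at any division interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "CellState",
    "DivisionClock",
    "SwitchingRates",
    "rates_from_f",
    "mean_fraction",
    "transition_matrix",
]

#: tolerance for the self-consistency of the (kon, koff, f) triple
_CONSISTENCY_TOL = 1e-9


class CellState(IntEnum):
    """Binary cell state; exactly two states exist."""

    RESPONSIVE = 0
    UNRESPONSIVE = 1


@dataclass(frozen=True)
class DivisionClock:
    """Maps generation number to elapsed time.

    Generation g corresponds to elapsed time ``g * division_interval``
    days; the default interval of 1.0 day reflects a ~24 h cell cycle.
    """

    division_interval: float = 1.0

    def __post_init__(self) -> None:
        if not self.division_interval > 0:
            raise ValueError(
                f"division_interval must be > 0, got {self.division_interval}"
            )

    def day(self, generation: float) -> float:
        return generation * self.division_interval


@dataclass(frozen=True)
class SwitchingRates:
    """Self-consistent (kon, koff, f) parameter triple.

    ``kon`` and ``koff`` are per-day rates (>= 0); ``f`` is the stationary
    responsive fraction and must equal ``kon / (kon + koff)`` whenever the
    total rate is positive.  When both rates are zero the dynamics are
    frozen, no stationary state exists, and ``f`` is retained purely as a
    bookkeeping value in [0, 1].

    Prefer the constructors :meth:`from_f` (the canonical ``(koff, f)``
    parameterization) and :meth:`from_rates`.
    """

    kon: float
    koff: float
    f: float

    def __post_init__(self) -> None:
        if self.kon < 0 or self.koff < 0:
            raise ValueError(f"rates must be >= 0, got kon={self.kon}, koff={self.koff}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        total = self.kon + self.koff
        if total > 0 and abs(self.f - self.kon / total) > _CONSISTENCY_TOL:
            raise ValueError(
                f"inconsistent triple: f={self.f} but kon/(kon+koff)={self.kon / total}"
            )

    @property
    def total_rate(self) -> float:
        """Relaxation rate kon + koff (per day)."""
        return self.kon + self.koff

    @classmethod
    def from_f(cls, koff: float, f: float) -> "SwitchingRates":
        """Build rates from ``koff`` and the stationary fraction ``f``.

        Uses ``kon = koff * f / (1 - f)``; requires ``koff > 0`` and
        ``0 < f < 1``.
        """
        if not koff > 0:
            raise ValueError(f"koff must be > 0, got {koff}")
        if not 0.0 < f < 1.0:
            raise ValueError(f"f must lie strictly in (0, 1), got {f}")
        return cls(kon=koff * f / (1.0 - f), koff=koff, f=f)

    @classmethod
    def from_rates(cls, kon: float, koff: float) -> "SwitchingRates":
        """Build rates from ``(kon, koff)``, deriving ``f``."""
        if kon < 0 or koff < 0:
            raise ValueError(f"rates must be >= 0, got kon={kon}, koff={koff}")
        total = kon + koff
        if total == 0:
            raise ValueError("kon + koff must be > 0 to define f; construct directly")
        return cls(kon=kon, koff=koff, f=kon / total)


def rates_from_f(koff: float, f: float) -> SwitchingRates:
    """Canonical constructor: derive kon from ``koff`` and ``f``."""
    return SwitchingRates.from_f(koff, f)


def mean_fraction(t, rates: SwitchingRates, x0: float = 1.0):
    """Mean responsive fraction x(t) = f + (x0 - f) exp(-(kon+koff) t).

    Parameters
    ----------
    t : float or array-like
        Elapsed time in days, >= 0.
    rates : SwitchingRates
    x0 : float
        Initial responsive fraction in [0, 1] (default 1.0, i.e. a
        responsive founder).

    Returns
    -------
    float or ndarray, monotone in t from x0 toward f.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if not 0.0 <= x0 <= 1.0:
        raise ValueError(f"x0 must lie in [0, 1], got {x0}")
    lam = rates.total_rate
    if lam == 0:
        out = np.broadcast_to(np.float64(x0), t.shape).copy()
    else:
        out = rates.f + (x0 - rates.f) * np.exp(-lam * t)
    return out.item() if out.ndim == 0 else out


def transition_matrix(rates: SwitchingRates, dt: float) -> np.ndarray:
    """Exact 2x2 row-stochastic transition matrix over an interval.

    Rows/columns are indexed by :class:`CellState` (RESPONSIVE=0,
    UNRESPONSIVE=1).  ``dt=0`` gives the identity; the stationary row
    vector is ``(f, 1-f)``.  Chapman-Kolmogorov composition holds exactly:
    ``P(dt1) @ P(dt2) == P(dt1 + dt2)``.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    lam = rates.total_rate
    if lam == 0:
        return np.eye(2)
    p = rates.kon / lam  # stationary responsive weight
    e = math.exp(-lam * dt)
    return np.array(
        [
            [p + (1.0 - p) * e, (1.0 - p) * (1.0 - e)],
            [p * (1.0 - e), (1.0 - p) + p * e],
        ]
    )
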