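"""Stochastic simulation of clones growing as binary trees with heritable states.

This is the in-silico fluctuation assay: a single founder cell divides
synchronously every division interval, daughters inherit the mother's state
at the moment of division, and state switching happens along each branch as
an exact two-state Markov draw over one interval.  A generation-g clone is
therefore 2**g leaves whose correlations come entirely from shared
ancestry - the Luria-Delbruck signature that distinguishes heritable from
per-cell stochastic responder determination.

Timing convention: the founder divides immediately at day 0, and divisions
are synchronous every interval thereafter, so leaves of a generation-g
clone are observed at day ``g * division_interval`` and each is separated
from the founder by g independent one-interval evolutions.  The moments in
:mod:`ifnfate.moments` use the same convention, so the two are comparable
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .switching import CellState, SwitchingRates, transition_matrix

__all__ = [
    "Clone",
    "FluctuationDataset",
    "SimulationConfig",
    "simulate_clone",
    "simulate_fluctuation_assay",
    "simulate_population",
    "apply_technical_noise",
]

#: canonical column order of the clone-level table
DATASET_COLUMNS = ["clone_id", "generation", "day", "n_cells", "n_responders", "fraction"]

InitialState = Literal["RESPONSIVE", "UNRESPONSIVE", "STATIONARY"]


@dataclass(frozen=True)
class Clone:
    """One simulated clone: 2**generation leaf states at observation time."""

    clone_id: str
    generation: int
    states: np.ndarray  # CellState values, length 2**generation

    def __post_init__(self) -> None:
        if len(self.states) != 2**self.generation:
            raise ValueError(
                f"clone of generation {self.generation} must have "
                f"{2**self.generation} cells, got {len(self.states)}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.states)

    @property
    def n_responders(self) -> int:
        return int(np.sum(np.asarray(self.states) == CellState.RESPONSIVE))

    @property
    def responder_fraction(self) -> float:
        return self.n_responders / self.n_cells


@dataclass
class FluctuationDataset:
    """Clone-level responder counts by generation, simulated or loaded.

    ``records`` is a table with columns ``clone_id, generation, day,
    n_cells, n_responders, fraction`` (one row per clone); ``metadata``
    records provenance (rates, seed, noise settings) when simulated.
    """

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        bad = self.records["n_responders"] > self.records["n_cells"]
        if bad.any():
            raise ValueError(
                f"n_responders > n_cells in rows {list(self.records.index[bad])}"
            )

    @property
    def generations(self) -> list[int]:
        return sorted(self.records["generation"].unique())

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one in-silico fluctuation experiment.

    The seed fully determines the output.  ``initial_state`` STATIONARY
    draws each founder from the stationary law Bernoulli(f); the
    fluctuation-assay replication default is RESPONSIVE because isolated
    founder cells were observed to be (nearly) all responsive.
    """

    generations: Sequence[int] = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9)
    n_clones_per_generation: int = 30
    seed: int = 0
    initial_state: InitialState = "RESPONSIVE"
    division_interval: float = 1.0
    cv_tech: float = 0.0

    def __post_init__(self) -> None:
        if self.n_clones_per_generation <= 0:
            raise ValueError("n_clones_per_generation must be > 0")
        if any(g < 0 for g in self.generations):
            raise ValueError("generations must be >= 0")
        if self.division_interval <= 0:
            raise ValueError("division_interval must be > 0")


def _founder_states(
    initial_state: InitialState | CellState,
    n: int,
    rates: SwitchingRates,
    rng: np.random.Generator,
) -> np.ndarray:
    if isinstance(initial_state, CellState):
        return np.full(n, int(initial_state), dtype=np.int8)
    if initial_state == "RESPONSIVE":
        return np.full(n, int(CellState.RESPONSIVE), dtype=np.int8)
    if initial_state == "UNRESPONSIVE":
        return np.full(n, int(CellState.UNRESPONSIVE), dtype=np.int8)
    if initial_state == "STATIONARY":
        return (rng.random(n) >= rates.f).astype(np.int8)  # 0=RESP w.p. f
    raise ValueError(f"unknown initial_state {initial_state!r}")


def _grow(
    founders: np.ndarray,
    rates: SwitchingRates,
    generation: int,
    division_interval: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow clones one synchronous division at a time, vectorized over clones.

    ``founders`` has shape (n_clones,); returns (n_clones, 2**generation)
    leaf states.  Each step duplicates every cell (inheritance) and then
    evolves every copy independently over one interval.
    """
    P = transition_matrix(rates, division_interval)
    p_stay_resp = P[0, 0]  # RESPONSIVE -> RESPONSIVE
    p_go_resp = P[1, 0]  # UNRESPONSIVE -> RESPONSIVE
    states = founders[:, None].astype(np.int8)
    for _ in range(generation):
        states = np.repeat(states, 2, axis=1)
        u = rng.random(states.shape)
        p_resp = np.where(states == 0, p_stay_resp, p_go_resp)
        states = (u >= p_resp).astype(np.int8)
    return states


def simulate_clone(
    rates: SwitchingRates,
    generation: int,
    initial_state: InitialState | CellState = CellState.RESPONSIVE,
    seed: int = 0,
) -> Clone:
    """Simulate one clone to depth ``generation`` (leaves at day g*interval)."""
    if generation < 0:
        raise ValueError("generation must be >= 0")
    rng = np.random.default_rng(seed)
    founders = _founder_states(initial_state, 1, rates, rng)
    states = _grow(founders, rates, generation, 1.0, rng)[0]
    return Clone(clone_id="clone", generation=generation, states=states)


def simulate_fluctuation_assay(
    config: SimulationConfig, rates: SwitchingRates
) -> FluctuationDataset:
    """Simulate the full fluctuation assay described by ``config``.

    Every listed generation gets ``n_clones_per_generation`` independent
    clones.  Output is deterministic given the seed.  If ``config.cv_tech``
    is positive, multiplicative technical noise is applied to the clone
    fractions (see :func:`apply_technical_noise`).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for g in config.generations:
        n = config.n_clones_per_generation
        founders = _founder_states(config.initial_state, n, rates, rng)
        states = _grow(founders, rates, g, config.division_interval, rng)
        n_cells = 2**g
        n_resp = (states == int(CellState.RESPONSIVE)).sum(axis=1)
        for i in range(n):
            rows.append(
                {
                    "clone_id": f"g{g}_c{i}",
                    "generation": g,
                    "day": g * config.division_interval,
                    "n_cells": n_cells,
                    "n_responders": int(n_resp[i]),
                    "fraction": n_resp[i] / n_cells,
                }
            )
    records = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    dataset = FluctuationDataset(
        records=records,
        metadata={
            "rates": {"kon": rates.kon, "koff": rates.koff, "f": rates.f},
            "seed": config.seed,
            "initial_state": str(config.initial_state),
            "division_interval": config.division_interval,
            "noise": None,
        },
    )
    if config.cv_tech > 0:
        # derive the noise stream from the same seed, offset to keep it
        # independent of the growth draws
        dataset = apply_technical_noise(dataset, config.cv_tech, seed=config.seed + 1)
    return dataset


def simulate_population(
    rates: SwitchingRates, n_cells: int, t: float, seed: int = 0
) -> float:
    """Responsive fraction of ``n_cells`` independent chains after time ``t``.

    Chains start from stationary initial states; with independent lineages
    the marginal stays Bernoulli(f), so the long-run fraction fluctuates
    around f with binomial error.  Time is advanced in one exact jump
    (the two-state chain is Markov, so a single transition-matrix draw
    over ``t`` is exact).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if t < 0:
        raise ValueError("t must be >= 0")
    rng = np.random.default_rng(seed)
    states = _founder_states("STATIONARY", n_cells, rates, rng)
    P = transition_matrix(rates, t)
    p_resp = np.where(states == 0, P[0, 0], P[1, 0])
    final = rng.random(n_cells) < p_resp
    return float(np.mean(final))


def apply_technical_noise(
    dataset: FluctuationDataset, cv_tech: float, seed: int = 0
) -> FluctuationDataset:
    """Multiply clone fractions by lognormal noise with mean 1 and CV ``cv_tech``.

    Emulates the between-sample technical variability of bulk responder
    fractions.  The noise is multiplicative (all-zero fractions stay zero)
    and noised fractions are clipped back to [0, 1].  Counts are left
    untouched; only ``fraction`` is noised, mirroring the fact that the
    technical component lives at the measured-fraction level.
    """
    if cv_tech < 0:
        raise ValueError("cv_tech must be >= 0")
    if cv_tech == 0:
        return dataset
    rng = np.random.default_rng(seed)
    records = dataset.records.copy()
    sigma2 = np.log1p(cv_tech**2)
    factors = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=len(records))
    records["fraction"] = np.clip(records["fraction"].to_numpy() * factors, 0.0, 1.0)
    metadata = dict(dataset.metadata)
    metadata["noise"] = {"model": "lognormal_mean1", "cv_tech": cv_tech, "seed": seed}
    return FluctuationDataset(records=records, metadata=metadata)
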