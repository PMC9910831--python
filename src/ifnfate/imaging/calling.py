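"""Translocation-ratio measurement and responder calling.

Re-implements the CellProfiler-style measurement chain: primary objects
(nuclei) from the nuclear-stain channel, secondary objects (cells) by
marker-seeded region growth on the CFP channel, tertiary objects
(cytoplasms) as cell minus nucleus.  Per cell, the IRF7 translocation
ratio is

    ratio = median CFP in nucleus / median CFP in cytoplasm,

a scale-invariant quantity (well above 1 indicates nuclear translocation,
i.e. a first responder).  A cell is called a responder iff its ratio is
strictly greater than an explicit threshold; the threshold is a recorded
parameter because in practice it is optimized per experiment.

Transfected cells are those whose mean labeled-stimulus intensity exceeds
the maximum observed in untransfected controls.  Responding sister pairs —
two neighboring responders presumed daughters of one mother — are found
with a distance cap and a cap on intervening non-responders, the latter
operationalized as a corridor count (the informal visual rule has no
stated geometry, so the corridor width is an explicit parameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology, segmentation

__all__ = [
    "CellMeasurement",
    "ResponderCall",
    "SisterCriteria",
    "SisterPairResult",
    "TransfectionStats",
    "segment_and_measure",
    "call_responders",
    "transfection_stats",
    "find_sister_pairs",
    "measurements_to_frame",
]

DEFAULT_RATIO_THRESHOLD = 1.3


@dataclass(frozen=True)
class CellMeasurement:
    """Per-cell intensity measurements; coordinates in micrometers."""

    cell_id: int
    x_um: float
    y_um: float
    nucleus_median_cfp: float
    cytoplasm_median_cfp: float
    rhodamine_mean: float
    total_cfp_mean: float

    @property
    def translocation_ratio(self) -> float:
        if self.cytoplasm_median_cfp <= 0:
            return math.nan
        return self.nucleus_median_cfp / self.cytoplasm_median_cfp


@dataclass(frozen=True)
class ResponderCall:
    cell_id: int
    is_responder: bool
    ratio_threshold_used: float


@dataclass(frozen=True)
class SisterCriteria:
    """Geometric criteria for assigning two responders as sister cells."""

    max_distance_um: float = 300.0
    max_intervening_nonresponders: int = 1
    corridor_width_um: float = 28.0  # one mean cell diameter

    def __post_init__(self) -> None:
        if self.max_distance_um <= 0:
            raise ValueError("max_distance_um must be > 0")
        if self.max_intervening_nonresponders < 0 or self.corridor_width_um <= 0:
            raise ValueError("invalid sister criteria")


class TransfectionStats(NamedTuple):
    threshold: float
    efficiency: float


@dataclass(frozen=True)
class SisterPairResult:
    pairs: tuple[tuple[int, int, float], ...]  # (cell_id_a, cell_id_b, distance_um)
    percent_responding_sisters: float


def segment_and_measure(
    hoechst: np.ndarray,
    cfp: np.ndarray,
    rhodamine: np.ndarray | None = None,
    um_per_px: float = 1.0,
    min_nucleus_area_px: int = 20,
) -> list[CellMeasurement]:
    """Segment nuclei/cells/cytoplasms and measure per-cell CFP medians.

    Nuclei: Otsu threshold on the nuclear channel + connected components
    with a minimum-area filter.  Cells: watershed region growth seeded at
    the nuclei, clipped by an Otsu foreground mask on the CFP channel.
    Cytoplasm: cell minus nucleus.  Cells whose cytoplasm is empty (the
    nucleus fills the cell) are excluded.  A blank image yields an empty
    list rather than an error.  Thresholding method: Otsu (global).
    """
    hoechst = np.asarray(hoechst, dtype=float)
    cfp = np.asarray(cfp, dtype=float)
    if hoechst.shape != cfp.shape:
        raise ValueError("channels must share shape")
    if rhodamine is not None:
        rhodamine = np.asarray(rhodamine, dtype=float)
        if rhodamine.shape != cfp.shape:
            raise ValueError("channels must share shape")

    if hoechst.max() == hoechst.min():
        return []
    nuclei_mask = hoechst > filters.threshold_otsu(hoechst)
    nuclei_mask = morphology.remove_small_objects(
        nuclei_mask, max_size=min_nucleus_area_px - 1
    )
    nuclei = measure.label(nuclei_mask)
    if nuclei.max() == 0:
        return []

    if cfp.max() > cfp.min():
        # Otsu on log intensity: cell-to-cell CFP brightness is roughly
        # lognormal, so the bimodal split is cleaner in log space and dim
        # cells are not dropped into background
        fg = cfp > np.expm1(filters.threshold_otsu(np.log1p(cfp)))
    else:
        fg = np.zeros_like(nuclei_mask)
    fg = fg | nuclei_mask  # cells always contain their nucleus
    cells = segmentation.watershed(-cfp, markers=nuclei, mask=fg)

    out: list[CellMeasurement] = []
    for prop in measure.regionprops(nuclei):
        lab = prop.label
        nuc_mask = nuclei == lab
        cell_mask = cells == lab
        cyto_mask = cell_mask & ~nuc_mask
        if not cyto_mask.any():
            continue  # nucleus fills cell: excluded from ratio statistics
        cy, cx = prop.centroid
        out.append(
            CellMeasurement(
                cell_id=int(lab),
                x_um=float(cx) * um_per_px,
                y_um=float(cy) * um_per_px,
                nucleus_median_cfp=float(np.median(cfp[nuc_mask])),
                cytoplasm_median_cfp=float(np.median(cfp[cyto_mask])),
                rhodamine_mean=(
                    float(np.mean(rhodamine[cell_mask])) if rhodamine is not None else math.nan
                ),
                total_cfp_mean=float(np.mean(cfp[cell_mask])),
            )
        )
    return out


def call_responders(
    measurements: Sequence[CellMeasurement],
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> tuple[list[ResponderCall], float | None]:
    """Strict-greater threshold on the translocation ratio.

    Returns the calls and the responder fraction (None for empty input).
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be > 0")
    calls = [
        ResponderCall(
            cell_id=m.cell_id,
            is_responder=bool(m.translocation_ratio > ratio_threshold),
            ratio_threshold_used=ratio_threshold,
        )
        for m in measurements
    ]
    if not calls:
        return calls, None
    fraction = sum(c.is_responder for c in calls) / len(calls)
    return calls, fraction


def transfection_stats(
    measurements: Sequence[CellMeasurement],
    control_measurements: Sequence[CellMeasurement],
) -> TransfectionStats:
    """Transfection threshold and efficiency.

    Threshold = maximum rhodamine mean over untransfected controls;
    efficiency = fraction of sample cells strictly above it.
    """
    if not control_measurements:
        raise ValueError("control measurement set must be non-empty")
    threshold = max(m.rhodamine_mean for m in control_measurements)
    if not measurements:
        return TransfectionStats(threshold=threshold, efficiency=0.0)
    eff = sum(m.rhodamine_mean > threshold for m in measurements) / len(measurements)
    return TransfectionStats(threshold=threshold, efficiency=eff)


def _corridor_count(
    a: np.ndarray, b: np.ndarray, others: np.ndarray, width: float
) -> int:
    """Non-responder centroids inside the rectangle of given width around segment ab."""
    if len(others) == 0:
        return 0
    v = b - a
    length = float(np.hypot(*v))
    if length == 0:
        return 0
    u = v / length
    rel = others - a
    along = rel @ u
    perp = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
    inside = (along >= 0) & (along <= length) & (perp <= width / 2.0)
    return int(np.count_nonzero(inside))


def find_sister_pairs(
    cells: pd.DataFrame | Sequence[dict],
    criteria: SisterCriteria = SisterCriteria(),
) -> SisterPairResult:
    """Pair up responders that plausibly share a mother cell.

    ``cells`` needs columns/keys ``cell_id, x_um, y_um, is_responder``.
    Candidate pairs are responder pairs within the distance cap whose
    corridor contains at most ``max_intervening_nonresponders``
    non-responder centroids.  Pairing is greedy by ascending distance and
    each responder joins at most one pair.  The summary statistic is the
    percentage of all responders that ended up in a retained pair.
    """
    df = pd.DataFrame(cells)
    resp = df[df["is_responder"].astype(bool)]
    nonresp_xy = df.loc[~df["is_responder"].astype(bool), ["x_um", "y_um"]].to_numpy(
        dtype=float
    )
    n_resp = len(resp)
    if n_resp < 2:
        return SisterPairResult(pairs=(), percent_responding_sisters=0.0)

    ids = resp["cell_id"].to_numpy()
    xy = resp[["x_um", "y_um"]].to_numpy(dtype=float)
    candidates = []
    for i in range(n_resp):
        for j in range(i + 1, n_resp):
            d = float(np.hypot(*(xy[i] - xy[j])))
            if d > criteria.max_distance_um:
                continue
            n_between = _corridor_count(
                xy[i], xy[j], nonresp_xy, criteria.corridor_width_um
            )
            if n_between <= criteria.max_intervening_nonresponders:
                candidates.append((d, i, j))
    candidates.sort()
    used: set[int] = set()
    pairs = []
    for d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append((int(ids[i]), int(ids[j]), d))
    percent = 100.0 * 2 * len(pairs) / n_resp
    return SisterPairResult(pairs=tuple(pairs), percent_responding_sisters=percent)


def measurements_to_frame(
    measurements: Sequence[CellMeasurement],
    calls: Sequence[ResponderCall] | None = None,
    transfection: TransfectionStats | None = None,
) -> pd.DataFrame:
    """Tabulate measurements (and optionally calls/transfection flags) for TSV output."""
    rows = []
    call_map = {c.cell_id: c for c in calls} if calls else {}
    for m in measurements:
        row = {
            "cell_id": m.cell_id,
            "x_um": m.x_um,
            "y_um": m.y_um,
            "nuc_median": m.nucleus_median_cfp,
            "cyto_median": m.cytoplasm_median_cfp,
            "ratio": m.translocation_ratio,
            "rhodamine_mean": m.rhodamine_mean,
        }
        if call_map:
            row["is_responder"] = call_map[m.cell_id].is_responder
        if transfection is not None:
            row["is_transfected"] = m.rhodamine_mean > transfection.threshold
        rows.append(row)
    return pd.DataFrame(rows)
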