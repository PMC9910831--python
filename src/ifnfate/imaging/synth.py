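"""Synthetic three-channel fluorescence images with ground truth.

Emulates the IRF7-CFP nuclear-translocation assay: a nuclear stain channel
(Hoechst), an IRF7-CFP channel in which responders show nuclear enrichment
of the fusion protein, and a rhodamine channel marking cells that took up
the labeled Poly(I:C) stimulus.  Cells are rendered as disks with
concentric disk nuclei on a sparse field (no touching cytoplasms by
default, matching sparse coverslip seeding), so segmentation is
unambiguous and the measurement itself — the translocation ratio — is what
gets tested.

Ground truth (per-cell responder/transfection flags and the true
nuclear:cytoplasmic enrichment) is returned alongside the pixel data.
Responders are planted by count, ``round(n_cells * responder_fraction)``,
so fixtures are exact; a Bernoulli mode exists for statistical tests.
Intensity units are arbitrary fixed-scale 16-bit; ``um_per_px`` is
recorded so micrometer distance criteria are testable.  Typical real CFP
intensity magnitudes are not documented anywhere authoritative, so the
defaults here are arbitrary (and stated as such).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticImageConfig", "ImageSet", "PackingError", "generate_image_set"]


class PackingError(RuntimeError):
    """Requested cell density cannot be placed without nucleus overlap."""


@dataclass(frozen=True)
class SyntheticImageConfig:
    """Parameters of one synthetic field of view.

    Geometry is in micrometers (converted through ``um_per_px``); the
    ratio laws give the true nuclear:cytoplasmic CFP enrichment for
    responders (mean 1.8) and non-responders (mean 1.0).
    """

    width: int = 1600
    height: int = 1600
    um_per_px: float = 1.3
    n_cells: int = 500
    responder_fraction: float = 0.02134
    transfected_fraction: float = 0.9
    nucleus_radius_um: float = 6.0
    nucleus_radius_jitter_um: float = 0.8
    cell_radius_um: float = 14.0
    cell_radius_jitter_um: float = 1.5
    responder_ratio_mean: float = 1.8
    responder_ratio_sd: float = 0.15
    nonresponder_ratio_mean: float = 1.0
    nonresponder_ratio_sd: float = 0.05
    irf7_heterogeneity_cv: float = 0.35
    cfp_baseline: float = 3000.0
    hoechst_intensity: float = 20000.0
    rhodamine_intensity: float = 6000.0
    rhodamine_cv: float = 0.25
    background: float = 200.0
    read_noise_sd: float = 30.0
    sister_pair_fraction: float = 0.0
    bernoulli_planting: bool = False
    margin_um: float = 2.0
    max_attempts_per_cell: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius_um >= self.cell_radius_um:
            raise ValueError("nucleus_radius_um must be < cell_radius_um")
        for name in ("responder_fraction", "transfected_fraction", "sister_pair_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class ImageSet:
    """Three intensity channels of equal shape plus per-cell ground truth."""

    hoechst: np.ndarray
    cfp: np.ndarray
    rhodamine: np.ndarray
    truth: pd.DataFrame
    um_per_px: float

    def __post_init__(self) -> None:
        if not (self.hoechst.shape == self.cfp.shape == self.rhodamine.shape):
            raise ValueError("channels must share shape")

    def write(self, out_dir) -> None:
        """One TIFF per channel plus the truth table as TSV."""
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / "hoechst.tif", self.hoechst)
        tifffile.imwrite(out / "cfp.tif", self.cfp)
        tifffile.imwrite(out / "rhodamine.tif", self.rhodamine)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def _place_cells(config: SyntheticImageConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping disk positions.

    Returns (x, y, cell_r, nuc_r, pair_id) arrays in pixel units (radii in
    um converted later).  Sister pairs are placed first as adjacent duos
    (centroid separation just under the sum of radii, so the pair reads as
    neighboring cells); the pair members are exempt from mutual overlap
    checks.
    """
    n = config.n_cells
    upp = config.um_per_px
    margin = config.margin_um / upp
    cr = (
        config.cell_radius_um
        + rng.uniform(-config.cell_radius_jitter_um, config.cell_radius_jitter_um, n)
    ) / upp
    nr = (
        config.nucleus_radius_um
        + rng.uniform(-config.nucleus_radius_jitter_um, config.nucleus_radius_jitter_um, n)
    ) / upp
    nr = np.minimum(nr, 0.85 * cr)

    n_resp = _planted_responder_count(config, rng)
    n_paired = 2 * int(round(config.sister_pair_fraction * n_resp / 2.0))
    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    pair_id = np.zeros(n, dtype=int)

    W, H = config.width, config.height
    budget = config.max_attempts_per_cell * max(n, 1)
    attempts = 0
    placed: list[int] = []

    def ok(i: int, x: float, y: float, skip: int | None = None) -> bool:
        if not (cr[i] + 1 <= x <= W - cr[i] - 1 and cr[i] + 1 <= y <= H - cr[i] - 1):
            return False
        for j in placed:
            if j == skip:
                continue
            min_d = cr[i] + cr[j] + margin
            if (x - xs[j]) ** 2 + (y - ys[j]) ** 2 < min_d**2:
                return False
        return True

    i = 0
    next_pair = 1
    while i < n:
        attempts += 1
        if attempts > budget:
            raise PackingError(
                f"could not place {n} cells in {W}x{H} px after {budget} attempts"
            )
        x = rng.uniform(0, W)
        y = rng.uniform(0, H)
        if not ok(i, x, y):
            continue
        if i + 1 < n_paired and pair_id[i] == 0 and i < n_paired:
            # place the sibling adjacent at separation just inside touching
            d = 0.98 * (cr[i] + cr[i + 1])
            sibling_placed = False
            for _ in range(50):
                theta = rng.uniform(0, 2 * math.pi)
                x2, y2 = x + d * math.cos(theta), y + d * math.sin(theta)
                xs[i], ys[i] = x, y
                placed.append(i)
                if ok(i + 1, x2, y2, skip=i):
                    xs[i + 1], ys[i + 1] = x2, y2
                    placed.append(i + 1)
                    pair_id[i] = pair_id[i + 1] = next_pair
                    next_pair += 1
                    sibling_placed = True
                    break
                placed.pop()
            if sibling_placed:
                i += 2
            continue
        xs[i], ys[i] = x, y
        placed.append(i)
        i += 1
    return xs, ys, cr, nr, pair_id, n_resp


def _planted_responder_count(
    config: SyntheticImageConfig, rng: np.random.Generator
) -> int:
    if config.bernoulli_planting:
        return int(rng.binomial(config.n_cells, config.responder_fraction))
    return int(round(config.n_cells * config.responder_fraction))


def generate_image_set(config: SyntheticImageConfig) -> ImageSet:
    """Render one synthetic field; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width
    n = config.n_cells

    xs, ys, cell_r, nuc_r, pair_id, n_resp = _place_cells(config, rng)

    is_resp = np.zeros(n, dtype=bool)
    is_resp[:n_resp] = True  # positions are random, so index order is unbiased
    n_trans = int(round(n * config.transfected_fraction))
    is_trans = np.zeros(n, dtype=bool)
    is_trans[rng.permutation(n)[:n_trans]] = True

    true_ratio = np.where(
        is_resp,
        rng.normal(config.responder_ratio_mean, config.responder_ratio_sd, n),
        rng.normal(config.nonresponder_ratio_mean, config.nonresponder_ratio_sd, n),
    )
    true_ratio = np.clip(true_ratio, 0.1, None)

    cv = config.irf7_heterogeneity_cv
    if cv > 0:
        sigma2 = math.log1p(cv**2)
        baseline = config.cfp_baseline * rng.lognormal(
            -sigma2 / 2, math.sqrt(sigma2), n
        )
    else:
        baseline = np.full(n, config.cfp_baseline)
    rho_cv = config.rhodamine_cv
    if rho_cv > 0:
        s2 = math.log1p(rho_cv**2)
        rho = config.rhodamine_intensity * rng.lognormal(-s2 / 2, math.sqrt(s2), n)
    else:
        rho = np.full(n, config.rhodamine_intensity)

    cfp = np.full((H, W), config.background, dtype=np.float64)
    hoechst = np.full((H, W), config.background, dtype=np.float64)
    rhodamine = np.full((H, W), config.background, dtype=np.float64)
    owner_dist = np.full((H, W), np.inf)
    owner = np.zeros((H, W), dtype=np.int32)

    for i in range(n):
        r = cell_r[i]
        x0, x1 = int(max(0, xs[i] - r - 1)), int(min(W, xs[i] + r + 2))
        y0, y1 = int(max(0, ys[i] - r - 1)), int(min(H, ys[i] + r + 2))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (xx - xs[i]) ** 2 + (yy - ys[i]) ** 2
        inside = d2 <= r**2
        closer = d2 < owner_dist[y0:y1, x0:x1]
        take = inside & closer
        sub = (slice(y0, y1), slice(x0, x1))
        owner[sub][take] = i + 1
        owner_dist[sub][take] = d2[take]
        nucleus = take & (d2 <= nuc_r[i] ** 2)
        cyto = take & ~nucleus
        cfp[sub][cyto] = config.background + baseline[i]
        cfp[sub][nucleus] = config.background + true_ratio[i] * baseline[i]
        hoechst[sub][nucleus] = config.background + config.hoechst_intensity
        if is_trans[i]:
            rhodamine[sub][take] = config.background + 0.3 * rho[i]
            # bright uptake puncta on top of the diffuse fill
            n_puncta = 3 + rng.poisson(6)
            for _ in range(n_puncta):
                pr = rng.uniform(0, 0.7 * r)
                pt = rng.uniform(0, 2 * math.pi)
                px, py = xs[i] + pr * math.cos(pt), ys[i] + pr * math.sin(pt)
                pyy, pxx = np.mgrid[
                    int(max(0, py - 2)) : int(min(H, py + 3)),
                    int(max(0, px - 2)) : int(min(W, px + 3)),
                ]
                pm = (pxx - px) ** 2 + (pyy - py) ** 2 <= 4.0
                rhodamine[
                    int(max(0, py - 2)) : int(min(H, py + 3)),
                    int(max(0, px - 2)) : int(min(W, px + 3)),
                ][pm] = config.background + 3.0 * rho[i]

    if config.read_noise_sd > 0:
        for channel in (hoechst, cfp, rhodamine):
            channel += rng.normal(0.0, config.read_noise_sd, channel.shape)

    def quantize(a: np.ndarray) -> np.ndarray:
        return np.clip(np.round(a), 0, 65535).astype(np.uint16)

    upp = config.um_per_px
    truth = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "x_um": xs * upp,
            "y_um": ys * upp,
            "nucleus_label": np.arange(1, n + 1),
            "is_responder": is_resp,
            "is_transfected": is_trans,
            "true_ratio": true_ratio,
            "cell_radius_um": cell_r * upp,
            "nucleus_radius_um": nuc_r * upp,
            "pair_id": pair_id,
        }
    )
    return ImageSet(
        hoechst=quantize(hoechst),
        cfp=quantize(cfp),
        rhodamine=quantize(rhodamine),
        truth=truth,
        um_per_px=upp,
    )
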