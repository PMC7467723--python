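"""Two-channel granule colocalization and PLA focus quantification.

The measurements mirror a standard confocal colocalization workflow:

* :func:`pearson_r` -- product-moment correlation of the two channels over
  the analysis mask.
* :func:`costes_threshold` -- the automatic-threshold variant of Pearson
  analysis: channel thresholds are set where the correlation of the
  *sub*-threshold pixels falls to zero, removing user bias, and the Pearson
  coefficient is recomputed over supra-threshold pixels.
* :func:`detect_foci` / :func:`pla_density` -- proximity-ligation-assay foci
  counted as thresholded connected components and reported per µm² of mask.

:func:`generate_granule_image` builds synthetic channel pairs with a known
colocalized fraction of Gaussian granules, standing in for confocal data so
the whole chain can be validated against generator truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

__all__ = [
    "ChannelPair",
    "ColocResult",
    "FociResult",
    "PlaResult",
    "generate_granule_image",
    "pearson_r",
    "costes_threshold",
    "detect_foci",
    "pla_density",
]


@dataclass
class ChannelPair:
    """Two registered single-section intensity images plus analysis mask."""

    ch1: np.ndarray
    ch2: np.ndarray
    pixel_size: float  # µm per pixel
    mask: np.ndarray | None = None
    truth: dict | None = None  # generator ground truth, when synthetic

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.ch1.shape != self.ch2.shape:
            raise ValueError("channel shapes must match")
        if (self.ch1 < 0).any() or (self.ch2 < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.mask is None:
            self.mask = np.ones(self.ch1.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.ch1.shape:
                raise ValueError("mask shape must match channels")


@dataclass(frozen=True)
class ColocResult:
    pearson_all: float
    costes_threshold_ch1: float
    costes_threshold_ch2: float
    pearson_above: float
    thresholds_at_minimum: bool = False  # scan exhausted without r<=0


@dataclass(frozen=True)
class FociResult:
    n_foci: int
    centroids: tuple[tuple[float, float], ...]
    areas_px: tuple[int, ...]
    labels: np.ndarray


@dataclass(frozen=True)
class PlaResult:
    n_foci: int
    mask_area_um2: float
    density_per_um2: float


def _stamp_spot(img: np.ndarray, y: float, x: float, sigma: float, amp: float) -> None:
    r = int(np.ceil(4 * sigma))
    yy = np.arange(max(0, int(y) - r), min(img.shape[0], int(y) + r + 1))
    xx = np.arange(max(0, int(x) - r), min(img.shape[1], int(x) + r + 1))
    if yy.size == 0 or xx.size == 0:
        return
    gy = np.exp(-0.5 * ((yy - y) / sigma) ** 2)
    gx = np.exp(-0.5 * ((xx - x) / sigma) ** 2)
    img[np.ix_(yy, xx)] += amp * np.outer(gy, gx)


def generate_granule_image(
    n_granules: int,
    coloc_fraction: float,
    granule_sigma: float = 2.0,
    noise_sd: float = 0.05,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 0.1,
    seed: int | None = None,
    amplitude: float = 1.0,
) -> ChannelPair:
    """Synthesize a two-channel granule image with known colocalization.

    Channel 1 receives ``n_granules`` Gaussian spots at uniformly random
    positions.  Channel 2 receives the same number of spots, of which a
    ``coloc_fraction`` share reuse channel-1 positions and the rest are
    placed independently.  Gaussian read noise (sd ``noise_sd``) is added
    and clipped at zero.  Ground-truth positions are attached as
    ``pair.truth``.
    """
    if not (0.0 <= coloc_fraction <= 1.0):
        raise ValueError("coloc_fraction must be in [0, 1]")
    if n_granules < 1:
        raise ValueError("n_granules must be >= 1")
    h, w = shape
    margin = 4 * granule_sigma
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError("image too small for granule size")
    # crude capacity check: spots need on average a 4-sigma-square footprint
    if n_granules * (4 * granule_sigma) ** 2 > h * w:
        raise ValueError("spot count exceeds placeable area")
    rng = np.random.default_rng(seed)

    pos1 = np.column_stack([
        rng.uniform(margin, h - margin, n_granules),
        rng.uniform(margin, w - margin, n_granules),
    ])
    n_shared = int(round(coloc_fraction * n_granules))
    shared_idx = rng.choice(n_granules, size=n_shared, replace=False)
    pos2 = np.column_stack([
        rng.uniform(margin, h - margin, n_granules),
        rng.uniform(margin, w - margin, n_granules),
    ])
    pos2[:n_shared] = pos1[shared_idx]

    ch1 = np.zeros(shape)
    ch2 = np.zeros(shape)
    for y, x in pos1:
        _stamp_spot(ch1, y, x, granule_sigma, amplitude)
    for y, x in pos2:
        _stamp_spot(ch2, y, x, granule_sigma, amplitude)
    if noise_sd > 0:
        ch1 = ch1 + rng.normal(0.0, noise_sd, shape)
        ch2 = ch2 + rng.normal(0.0, noise_sd, shape)
    ch1 = np.clip(ch1, 0.0, None)
    ch2 = np.clip(ch2, 0.0, None)
    return ChannelPair(
        ch1,
        ch2,
        pixel_size=pixel_size,
        truth={
            "positions_ch1": pos1,
            "positions_ch2": pos2,
            "n_shared": n_shared,
        },
    )


def pearson_r(pair: ChannelPair) -> float:
    """Pearson correlation of the two channels over the mask."""
    a = pair.ch1[pair.mask]
    b = pair.ch2[pair.mask]
    if a.size < 2:
        raise ValueError("need at least 2 mask pixels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson undefined: a channel has zero variance in mask")
    return float(np.corrcoef(a, b)[0, 1])


def _rma_regression(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Reduced-major-axis (orthogonal) regression b = slope*a + intercept.

    Chosen over OLS because the two channels play symmetric roles.
    """
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("regression undefined: constant channel")
    r = np.corrcoef(a, b)[0, 1]
    slope = np.sign(r) * sb / sa if r != 0 else sb / sa
    intercept = b.mean() - slope * a.mean()
    return float(slope), float(intercept)


def _quantization_step(values: np.ndarray) -> float:
    """One intensity level: 1 for integer-valued data, else range/256."""
    if np.allclose(values, np.round(values)):
        return 1.0
    rng_ = values.max() - values.min()
    return rng_ / 256.0 if rng_ > 0 else 1.0


def costes_threshold(
    pair: ChannelPair,
    above: str = "either",
    scan_step: float | None = None,
) -> ColocResult:
    """Automatic-threshold Pearson colocalization.

    Fits an orthogonal regression ch2 = a*ch1 + b over the mask, then scans
    the channel-1 threshold T1 downward from the maximum intensity (with
    T2 = a*T1 + b coupled) and stops at the largest T1 for which the Pearson
    correlation of pixels *below both* thresholds is <= 0.  The colocalization
    readout ``pearson_above`` is then the Pearson coefficient over pixels
    above threshold in ``either`` channel (default) or in ``both``.

    If the sub-threshold correlation never drops to zero (e.g. perfectly
    correlated channels), thresholds land at the minimum intensity and the
    result is flagged.
    """
    if above not in ("either", "both"):
        raise ValueError("above must be 'either' or 'both'")
    a = pair.ch1[pair.mask]
    b = pair.ch2[pair.mask]
    slope, intercept = _rma_regression(a, b)
    step = scan_step if scan_step is not None else _quantization_step(a)
    if step <= 0:
        raise ValueError("scan_step must be positive")

    t1 = float(a.max())
    t1_min = float(a.min())
    found = False
    while t1 > t1_min:
        t2 = slope * t1 + intercept
        below = (a < t1) & (b < t2)
        if below.sum() >= 2:
            sub_a, sub_b = a[below], b[below]
            if sub_a.std() > 0 and sub_b.std() > 0:
                r_below = np.corrcoef(sub_a, sub_b)[0, 1]
                if r_below <= 0:
                    found = True
                    break
        t1 -= step
    if not found:
        t1 = t1_min
    t2 = slope * t1 + intercept

    if above == "either":
        sel = (a >= t1) | (b >= t2)
    else:
        sel = (a >= t1) & (b >= t2)
    if sel.sum() >= 2 and a[sel].std() > 0 and b[sel].std() > 0:
        r_above = float(np.corrcoef(a[sel], b[sel])[0, 1])
    else:
        r_above = float("nan")
    return ColocResult(
        pearson_all=pearson_r(pair),
        costes_threshold_ch1=float(t1),
        costes_threshold_ch2=float(t2),
        pearson_above=r_above,
        thresholds_at_minimum=not found,
    )


def detect_foci(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    threshold_method: str | float = "otsu",
    min_area_px: int = 1,
) -> FociResult:
    """Threshold + connected-component focus detection (8-connectivity).

    ``threshold_method`` is ``"otsu"`` or a fixed intensity value; components
    smaller than ``min_area_px`` are discarded.
    """
    img = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if threshold_method == "otsu":
        thr = threshold_otsu(img[mask])
    else:
        thr = float(threshold_method)
    binary = (img > thr) & mask
    labels = cc_label(binary, connectivity=2)
    centroids, areas = [], []
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    next_id = 1
    for region in regionprops(labels):
        if region.area >= min_area_px:
            centroids.append(tuple(float(c) for c in region.centroid))
            areas.append(int(region.area))
            keep[region.label] = next_id
            next_id += 1
    relabeled = keep[labels]
    return FociResult(
        n_foci=len(areas),
        centroids=tuple(centroids),
        areas_px=tuple(areas),
        labels=relabeled,
    )


def pla_density(foci: FociResult, mask: np.ndarray, pixel_size: float) -> PlaResult:
    """PLA focus density per µm² of mask area."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("mask area is zero")
    area = n_px * pixel_size**2
    return PlaResult(
        n_foci=foci.n_foci,
        mask_area_um2=float(area),
        density_per_um2=float(foci.n_foci / area),
    )
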