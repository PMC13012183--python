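"""Window-transparency statistic: brain-masked Otsu vessel-area fraction.

At 530 nm hemoglobin absorbs strongly, so cortical vessels appear dark in
reflectance images; the fraction of brain-masked pixels that Otsu
thresholding assigns to the dark class is used as a transparency measure —
an opaque window hides vessels and lowers the fraction.  Vessels are fixed
as the BELOW-threshold class (``polarity="dark_vessels"``).

The threshold maximizes between-class variance over a 256-bin histogram of
the masked pixels spanning their min-max range, which makes the statistic
invariant (up to bin quantization) to affine intensity rescaling and
identical across 8- and 16-bit inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask

from ._exceptions import DegenerateInputError, GeometryError, ParamError

__all__ = [
    "BrainMask",
    "TransparencyRecord",
    "otsu_threshold",
    "vessel_area_fraction",
    "longitudinal_change",
]

_N_BINS = 256


@dataclass
class BrainMask:
    """Polygonal brain mask (and/or an explicit boolean mask)."""

    mask: np.ndarray
    provenance: str = "manual"

    @classmethod
    def from_polygon(cls, vertices: Sequence[tuple[float, float]],
                     shape: tuple[int, int]) -> "BrainMask":
        verts = np.asarray(vertices, float)
        if verts.ndim != 2 or verts.shape[0] < 3:
            raise GeometryError("polygon needs at least 3 (row, col) vertices")
        m = polygon2mask(shape, verts)
        if not m.any():
            raise GeometryError("polygon mask is empty")
        return cls(mask=m, provenance="manual")


@dataclass
class TransparencyRecord:
    """Per-image transparency measurement."""

    day_label: str
    vasculature_pct: float
    threshold_used: float
    n_masked_px: int

    def __post_init__(self) -> None:
        if not 0 <= self.vasculature_pct <= 100:
            raise ParamError("vasculature_pct must be within [0, 100]")


def otsu_threshold(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Otsu threshold of the masked pixels over a 256-bin histogram.

    The returned value is the upper edge of the optimal low class, so the
    dark class is ``image < threshold``.  A constant masked region raises
    :class:`DegenerateInputError`.  Ties in the between-class variance are
    broken toward the lowest threshold.
    """
    img = np.asarray(image, float)
    if mask is None:
        mask = np.ones(img.shape, bool)
    vals = img[np.asarray(mask, bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ParamError("mask selects no pixels")
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmin == vmax:
        raise DegenerateInputError("masked region is constant; no threshold exists")

    hist, edges = np.histogram(vals, bins=_N_BINS, range=(vmin, vmax))
    hist = hist.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(hist)                       # pixels in bins <= k
    w1 = w0[-1] - w0
    csum = np.cumsum(hist * centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (csum[-1] - csum) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[~np.isfinite(var_between)] = -np.inf
    k = int(np.argmax(var_between[:-1]))       # split must leave both classes non-empty
    return float(edges[k + 1])


def vessel_area_fraction(image: np.ndarray, mask: np.ndarray,
                         polarity: str = "dark_vessels",
                         exclude_polygons: Sequence[np.ndarray] | None = None,
                         day_label: str = "") -> TransparencyRecord:
    """Percent of masked pixels on the vessel (dark) side of the Otsu threshold.

    Artifact or inflammation regions can be removed from the statistic by
    passing exclusion polygons, which are subtracted from the mask before
    thresholding.
    """
    if polarity != "dark_vessels":
        raise ParamError(f"unsupported polarity {polarity!r}")
    img = np.asarray(image, float)
    m = np.asarray(mask, bool).copy()
    for poly in exclude_polygons or []:
        m &= ~polygon2mask(img.shape, np.asarray(poly, float))
    if not m.any():
        raise ParamError("mask empty after exclusions")
    thr = otsu_threshold(img, m)
    vessels = (img < thr) & m
    pct = 100.0 * vessels.sum() / m.sum()
    return TransparencyRecord(
        day_label=day_label,
        vasculature_pct=float(pct),
        threshold_used=thr,
        n_masked_px=int(m.sum()),
    )


def longitudinal_change(records: Sequence[TransparencyRecord],
                        reference_day: str = "Day 1") -> pd.DataFrame:
    """Per-day vasculature percent and its change versus a reference day.

    Returns columns ``day, vasculature_pct, delta_vs_reference`` in input
    order; the reference row has delta 0.  A missing reference raises.
    """
    days = [r.day_label for r in records]
    if reference_day not in days:
        raise ParamError(f"reference day {reference_day!r} not in {days}")
    ref_pct = next(r.vasculature_pct for r in records
                   if r.day_label == reference_day)
    return pd.DataFrame({
        "day": days,
        "vasculature_pct": [r.vasculature_pct for r in records],
        "delta_vs_reference": [r.vasculature_pct - ref_pct for r in records],
    })
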