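"""Laser speckle contrast imaging: contrast maps, flow indices, occlusion.

Speckle contrast K is the sample standard deviation over the local mean of
intensity in a sliding 7x7 window; faster flow blurs the speckle within the
exposure and lowers K.  K maps are converted to the inverse-correlation-time
flow index 1/K^2 ("ICT"), averaged in stacks of nine, and reduced to
relative-blood-flow traces (ROI mean normalized to a baseline window).

Border handling is valid-region only: no padding, pixels whose 7x7 window
does not fit are flagged invalid.  The sample standard deviation uses the
n-1 denominator (n = 49).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.draw import polygon2mask
from skimage.measure import label

from ._exceptions import GeometryError, ParamError
from .io_config import ImageStack

__all__ = [
    "SpeckleStack",
    "ContrastImage",
    "ICTImage",
    "compute_speckle_contrast",
    "contrast_to_ict",
    "average_ict_stack",
    "relative_flow_trace",
    "quantify_occlusion",
]


@dataclass
class SpeckleStack(ImageStack):
    """Raw speckle frames; one image set is ``set_size`` frames at
    ``exposure_ms`` exposure, and ``stack_size`` derived images are averaged
    per output."""

    set_size: int = 15
    stack_size: int = 9

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.exposure_ms is None or self.exposure_ms <= 0:
            raise ParamError("SpeckleStack requires exposure_ms > 0")


@dataclass
class ContrastImage:
    """Speckle contrast map with a validity mask (border + degenerate pixels)."""

    K: np.ndarray
    valid_mask: np.ndarray


@dataclass
class ICTImage:
    """Inverse-correlation-time flow index 1/K^2 with a validity mask."""

    ict: np.ndarray
    valid_mask: np.ndarray


def _window_stats(img: np.ndarray, w: int,
                  chunk_rows: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window mean and sample std (ddof=1), valid region only.

    Processed in row chunks so the windowed view never materializes for the
    whole image at once.
    """
    rows, cols = img.shape
    orows, ocols = rows - w + 1, cols - w + 1
    mean = np.empty((orows, ocols))
    std = np.empty((orows, ocols))
    for r0 in range(0, orows, chunk_rows):
        r1 = min(r0 + chunk_rows, orows)
        view = sliding_window_view(img[r0:r1 + w - 1], (w, w))
        mean[r0:r1] = view.mean(axis=(2, 3))
        std[r0:r1] = view.std(axis=(2, 3), ddof=1)
    return mean, std


def compute_speckle_contrast(stack: ImageStack | np.ndarray,
                             window_px: int = 7,
                             mode: str = "literal") -> ContrastImage:
    """Spatial speckle contrast K = std/mean over a sliding window.

    ``mode="literal"`` first averages the set's raw frames and computes K on
    the averaged image; ``mode="per_frame"`` computes K per raw frame and
    averages the K maps.  Field practice varies between the two; "literal"
    is the default here (note that averaging raw frames before K reduces the
    contrast of dynamic speckle relative to per-frame K).

    Pixels where the full window does not fit, or where the window mean is
    zero, are flagged invalid (NaN in ``K``), never silently zeroed.
    """
    frames = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack)
    if frames.ndim == 2:
        frames = frames[None]
    n, rows, cols = frames.shape
    w = window_px
    if w % 2 == 0 or w < 3:
        raise ParamError("window_px must be odd and >= 3")
    if w > min(rows, cols):
        raise ParamError(f"window {w} exceeds image size {(rows, cols)}")
    if mode not in ("literal", "per_frame"):
        raise ParamError(f"unknown mode {mode!r}")

    frames = frames.astype(np.float64, copy=False)
    half = (w - 1) // 2

    def _contrast(img: np.ndarray) -> np.ndarray:
        mean, std = _window_stats(img, w)
        out = np.full(img.shape, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(mean > 0, std / np.where(mean > 0, mean, 1.0), np.nan)
        out[half:rows - half, half:cols - half] = k
        return out

    if mode == "literal":
        K = _contrast(frames.mean(axis=0))
    else:
        stack_k = np.stack([_contrast(f) for f in frames])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN border
            K = np.nanmean(stack_k, axis=0)

    valid = np.isfinite(K)
    return ContrastImage(K=K, valid_mask=valid)


def contrast_to_ict(contrast: ContrastImage) -> ICTImage:
    """Flow index 1/K^2; pixels with K = 0 are flagged invalid."""
    K = contrast.K
    valid = contrast.valid_mask & (K > 0)
    ict = np.full(K.shape, np.nan)
    ict[valid] = 1.0 / K[valid] ** 2
    return ICTImage(ict=ict, valid_mask=valid)


def average_ict_stack(icts: Sequence[ICTImage], stack_size: int = 9) -> ICTImage:
    """Pixelwise mean of flow-index images (default nine per stack).

    Output pixels are valid where every input is valid; elsewhere the mean
    over the valid subset is reported with the pixel flagged invalid.
    """
    if len(icts) < stack_size:
        raise ParamError(f"need >= {stack_size} images, got {len(icts)}")
    shapes = {im.ict.shape for im in icts}
    if len(shapes) != 1:
        raise ParamError(f"shape mismatch across inputs: {shapes}")
    data = np.stack([im.ict for im in icts])
    valid = np.stack([im.valid_mask for im in icts]).all(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(data, axis=0)
    mean[~np.isfinite(mean)] = np.nan
    return ICTImage(ict=mean, valid_mask=valid)


def relative_flow_trace(ict_movie: Sequence[ICTImage] | np.ndarray,
                        roi: np.ndarray,
                        baseline: tuple[int, int]) -> np.ndarray:
    """Relative blood flow: ROI-mean flow index normalized to a baseline window.

    ``baseline`` is a ``(start, stop)`` frame range (stop exclusive) whose
    mean defines rBF = 1; the trace therefore averages 1 over the baseline.
    Scaling all intensities by a positive constant leaves rBF unchanged.
    """
    roi = np.asarray(roi, bool)
    if not roi.any():
        raise ParamError("ROI is empty")
    b0, b1 = baseline
    if b1 <= b0:
        raise ParamError("baseline range is empty")

    if isinstance(ict_movie, np.ndarray):
        frames = ict_movie.astype(np.float64, copy=False)
        trace = frames[:, roi].mean(axis=1)
    else:
        vals = []
        for im in ict_movie:
            sel = roi & im.valid_mask
            if not sel.any():
                raise ParamError("ROI has no valid pixels in some frame")
            vals.append(im.ict[sel].mean())
        trace = np.asarray(vals)
    if b1 > trace.size:
        raise ParamError("baseline range exceeds movie length")
    base = trace[b0:b1].mean()
    if base == 0:
        raise ParamError("baseline mean is zero")
    return trace / base


def quantify_occlusion(image: ICTImage | ContrastImage | np.ndarray,
                       window_mask: np.ndarray,
                       method: str = "auto",
                       polygons: Sequence[np.ndarray] | None = None,
                       dark_fraction: float = 0.02,
                       min_area_px: int = 50) -> dict:
    """Percent of the window occluded by near-black artifacts.

    ``method="polygons"`` takes the union of user-outlined polygons clipped
    to the window (the manual-delineation route); ``method="auto"`` flags
    pixels darker than ``dark_fraction`` of the robust (p1-p99) within-window
    intensity range and keeps connected components of at least
    ``min_area_px`` pixels, suppressing single-pixel noise.

    Returns ``{"occluded_pct", "occlusion_mask"}`` with
    ``occluded_pct = 100 * occluded / window``.
    """
    if isinstance(image, ICTImage):
        img = image.ict
    elif isinstance(image, ContrastImage):
        img = image.K
    else:
        img = np.asarray(image, float)
    window_mask = np.asarray(window_mask, bool)
    if not window_mask.any():
        raise ParamError("window mask is empty")

    if method == "polygons":
        occl = np.zeros(img.shape, bool)
        for poly in polygons or []:
            poly = np.asarray(poly, float)
            if (poly < 0).any() or (poly[:, 0] >= img.shape[0]).any() \
                    or (poly[:, 1] >= img.shape[1]).any():
                raise GeometryError("polygon vertex outside image")
            occl |= polygon2mask(img.shape, poly)
        occl &= window_mask
    elif method == "auto":
        vals = img[window_mask & np.isfinite(img)]
        lo, hi = np.percentile(vals, [1, 99])
        thr = lo + dark_fraction * (hi - lo)
        cand = (img < thr) & window_mask & np.isfinite(img)
        lab = label(cand, connectivity=2)
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_area_px
        keep[0] = False
        occl = keep[lab]
    else:
        raise ParamError(f"unknown method {method!r}")

    pct = 100.0 * occl.sum() / window_mask.sum()
    return {"occluded_pct": float(pct), "occlusion_mask": occl}
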