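"""Interhemispheric homotopic functional connectivity from reflectance movies.

The chain mirrors common widefield resting-state practice: spatially
downsample, temporally detrend, bandpass to the slow hemodynamic band
(0.035-0.08 Hz), regress out the global signal, then correlate every pixel
with its left-right mirror across the bregma-lambda midline.  Pearson r is
Fisher z-transformed (atanh) and averaged over paired pixels into a single
"interhemispheric homotopic connectivity index".

Mirror geometry: homotopic partners are obtained by reflecting each pixel
across the line through bregma and lambda (the anatomical midline), so left
pairs with right.  Partner lookup is nearest-pixel; no temporal resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from ._exceptions import (
    GeometryError,
    InsufficientFramesError,
    ParamError,
    DegenerateInputError,
)
from .io_config import ImageStack, read_json

__all__ = [
    "MidlineAxis",
    "ConnectivityMap",
    "ConnectivityIndex",
    "downsample_movie",
    "detrend_movie",
    "bandpass_movie",
    "global_signal_regression",
    "mirror_pixel",
    "hemisphere_sides",
    "build_pair_map",
    "homotopic_map",
    "connectivity_index",
    "preprocess_movie",
    "csd_block_analysis",
    "frame_bookkeeping",
]

_CLIP = 1.0 - 1e-7  # |r| clip before atanh


@dataclass(frozen=True)
class MidlineAxis:
    """Anatomical midline defined by the bregma and lambda landmarks (row, col)."""

    bregma: tuple[float, float]
    lambda_pt: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.bregma) == tuple(self.lambda_pt):
            raise GeometryError("bregma and lambda must differ")

    @classmethod
    def from_json(cls, path: str | Path) -> "MidlineAxis":
        data = read_json(path)
        try:
            return cls(bregma=tuple(data["bregma"]), lambda_pt=tuple(data["lambda"]))
        except KeyError as exc:
            raise GeometryError(f"landmark file {path} missing key {exc}") from exc

    def check_inside(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        for name, (r, c) in (("bregma", self.bregma), ("lambda", self.lambda_pt)):
            if not (0 <= r <= rows - 1 and 0 <= c <= cols - 1):
                raise GeometryError(f"{name} {(r, c)} outside image of shape {shape}")

    def scaled(self, factor: float) -> "MidlineAxis":
        """Midline in the coordinates of an image downsampled by ``factor``.

        Block-mean downsampling by f maps original pixel x to x/f - (f-1)/(2f)
        in output pixel-center coordinates.
        """
        off = (factor - 1.0) / (2.0 * factor)
        b = (self.bregma[0] / factor - off, self.bregma[1] / factor - off)
        l = (self.lambda_pt[0] / factor - off, self.lambda_pt[1] / factor - off)
        return MidlineAxis(bregma=b, lambda_pt=l)


@dataclass
class ConnectivityMap:
    """Per-pixel homotopic correlation (r), its Fisher z, and the paired mask."""

    r_map: np.ndarray
    z_map: np.ndarray
    paired_mask: np.ndarray


@dataclass
class ConnectivityIndex:
    """Mean Fisher z over paired pixels for one recording block."""

    value: float
    n_pixels: int
    block_label: str = ""
    n_frames: int = 0
    short: bool = False


def _frames(movie: ImageStack | np.ndarray) -> np.ndarray:
    arr = movie.frames if isinstance(movie, ImageStack) else np.asarray(movie)
    if arr.ndim != 3:
        raise ParamError(f"movie must be (frame, row, col); got shape {arr.shape}")
    return arr.astype(np.float64, copy=False)


def downsample_movie(movie: ImageStack | np.ndarray,
                     out_size: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Non-overlapping block-mean spatial downsampling (e.g. 512->128 is 4x4).

    Input dimensions must be integer multiples of ``out_size``; the frame
    count is unchanged and the per-frame spatial mean is preserved exactly.
    """
    arr = _frames(movie)
    n, rows, cols = arr.shape
    orr, occ = out_size
    if rows % orr or cols % occ:
        raise ParamError(
            f"image size {(rows, cols)} not an integer multiple of {out_size}"
        )
    fr, fc = rows // orr, cols // occ
    return arr.reshape(n, orr, fr, occ, fc).mean(axis=(2, 4))


def detrend_movie(movie: ImageStack | np.ndarray) -> np.ndarray:
    """Subtract the per-pixel least-squares line (intercept + slope * t)."""
    arr = _frames(movie)
    n = arr.shape[0]
    if n < 3:
        raise ParamError("detrending needs at least 3 frames")
    t = np.arange(n, dtype=np.float64) - (n - 1) / 2.0
    flat = arr.reshape(n, -1)
    mean = flat.mean(axis=0)
    slope = (t @ flat) / (t @ t)
    resid = flat - mean - t[:, None] * slope
    return resid.reshape(arr.shape)


def bandpass_movie(movie: ImageStack | np.ndarray,
                   frame_rate_hz: float | None = None,
                   low: float = 0.035, high: float = 0.08,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass along time, applied per pixel.

    Order-4 Butterworth, run forward-backward (sosfiltfilt) so band-interior
    components are not phase-shifted.
    """
    if frame_rate_hz is None:
        if isinstance(movie, ImageStack) and movie.frame_rate_hz:
            frame_rate_hz = movie.frame_rate_hz
        else:
            raise ParamError("frame_rate_hz required (not found on the movie)")
    if not 0 < low < high:
        raise ParamError("need 0 < low < high")
    if not high < frame_rate_hz / 2:
        raise ParamError(
            f"band edge {high} Hz not below Nyquist {frame_rate_hz / 2} Hz"
        )
    arr = _frames(movie)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=frame_rate_hz,
                     output="sos")
    return sps.sosfiltfilt(sos, arr, axis=0)


def global_signal_regression(movie: ImageStack | np.ndarray,
                             mask: np.ndarray | None = None) -> np.ndarray:
    """Regress each pixel's time series on the mask-mean time course.

    Per pixel an OLS fit on [intercept, global signal] is removed; residuals
    are exactly orthogonal to the global regressor.
    """
    arr = _frames(movie)
    n, rows, cols = arr.shape
    if mask is None:
        mask = np.ones((rows, cols), bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ParamError("mask is empty")
    g = arr[:, mask].mean(axis=1)
    gc = g - g.mean()
    denom = gc @ gc
    if denom <= 0:
        raise DegenerateInputError("global signal is constant")
    flat = arr.reshape(n, -1)
    beta = (gc @ flat) / denom
    resid = flat - flat.mean(axis=0) - gc[:, None] * beta
    return resid.reshape(arr.shape)


def mirror_pixel(p: tuple[float, float], midline: MidlineAxis,
                 shape: tuple[int, int] | None = None) -> tuple[int, int] | None:
    """Reflect pixel ``p`` across the bregma-lambda line, rounded to a pixel.

    Returns ``None`` when the reflection falls outside ``shape`` (if given).
    """
    b = np.asarray(midline.bregma, float)
    d = np.asarray(midline.lambda_pt, float) - b
    u = d / np.linalg.norm(d)
    v = np.asarray(p, float) - b
    refl = b + 2.0 * (v @ u) * u - v
    rr, cc = int(round(refl[0])), int(round(refl[1]))
    if shape is not None and not (0 <= rr < shape[0] and 0 <= cc < shape[1]):
        return None
    return (rr, cc)


def hemisphere_sides(shape: tuple[int, int], midline: MidlineAxis) -> np.ndarray:
    """Signed side of each pixel: -1 / +1 for the two hemispheres, 0 on the line."""
    rows, cols = shape
    b = np.asarray(midline.bregma, float)
    d = np.asarray(midline.lambda_pt, float) - b
    rr, cc = np.mgrid[0:rows, 0:cols]
    cross = d[0] * (cc - b[1]) - d[1] * (rr - b[0])
    return np.sign(np.where(np.abs(cross) < 1e-9, 0.0, cross)).astype(np.int8)


def build_pair_map(shape: tuple[int, int], midline: MidlineAxis,
                   mask: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Flat indices of homotopic pixel pairs ``(idx, partner_idx)``.

    Every masked off-midline pixel whose mirror lands inside the image, in the
    mask, and on the opposite side contributes one entry; pairing is symmetric
    (each pair appears once from each side).
    """
    midline.check_inside(shape)
    rows, cols = shape
    if mask is None:
        mask = np.ones(shape, bool)
    mask = np.asarray(mask, bool)
    side = hemisphere_sides(shape, midline)

    b = np.asarray(midline.bregma, float)
    d = np.asarray(midline.lambda_pt, float) - b
    u = d / np.linalg.norm(d)
    rr, cc = np.mgrid[0:rows, 0:cols]
    vr, vc = rr - b[0], cc - b[1]
    proj = vr * u[0] + vc * u[1]
    mr = np.rint(b[0] + 2 * proj * u[0] - vr).astype(np.int64)
    mc = np.rint(b[1] + 2 * proj * u[1] - vc).astype(np.int64)

    inside = (mr >= 0) & (mr < rows) & (mc >= 0) & (mc < cols)
    mrc = np.clip(mr, 0, rows - 1)
    mcc = np.clip(mc, 0, cols - 1)
    ok = (
        mask & inside & (side != 0)
        & mask[mrc, mcc]
        & (side[mrc, mcc] == -side)
    )
    idx = np.flatnonzero(ok.ravel())
    partner = (mrc * cols + mcc).ravel()[idx]
    return idx, partner


def homotopic_map(movie: ImageStack | np.ndarray, midline: MidlineAxis,
                  mask: np.ndarray | None = None) -> ConnectivityMap:
    """Correlate each masked pixel with its contralateral mirror pixel.

    Zero-variance pixels (either member of a pair) are dropped from the
    paired mask rather than raising.  r is clipped to ``|r| <= 1 - 1e-7``
    before the Fisher transform.
    """
    arr = _frames(movie)
    n, rows, cols = arr.shape
    idx, partner = build_pair_map((rows, cols), midline, mask)

    flat = arr.reshape(n, -1)
    r_map = np.full(rows * cols, np.nan)
    z_map = np.full(rows * cols, np.nan)
    paired = np.zeros(rows * cols, bool)

    if idx.size:
        a = flat[:, idx]
        bseries = flat[:, partner]
        a = a - a.mean(axis=0)
        bseries = bseries - bseries.mean(axis=0)
        sa = np.sqrt((a * a).sum(axis=0))
        sb = np.sqrt((bseries * bseries).sum(axis=0))
        good = (sa > 0) & (sb > 0)
        r = np.full(idx.size, np.nan)
        r[good] = (a[:, good] * bseries[:, good]).sum(axis=0) / (sa[good] * sb[good])
        keep = good
        r_map[idx[keep]] = r[keep]
        z_map[idx[keep]] = np.arctanh(np.clip(r[keep], -_CLIP, _CLIP))
        paired[idx[keep]] = True

    return ConnectivityMap(
        r_map=r_map.reshape(rows, cols),
        z_map=z_map.reshape(rows, cols),
        paired_mask=paired.reshape(rows, cols),
    )


def connectivity_index(cmap: ConnectivityMap, block_label: str = "",
                       n_frames: int = 0, short: bool = False) -> ConnectivityIndex:
    """Mean Fisher z over paired pixels (the homotopic connectivity index)."""
    if not cmap.paired_mask.any():
        raise ParamError("no paired pixels")
    value = float(np.mean(cmap.z_map[cmap.paired_mask]))
    return ConnectivityIndex(
        value=value,
        n_pixels=int(cmap.paired_mask.sum()),
        block_label=block_label,
        n_frames=n_frames,
        short=short,
    )


def preprocess_movie(movie: ImageStack | np.ndarray,
                     frame_rate_hz: float,
                     mask: np.ndarray | None = None,
                     out_size: tuple[int, int] | None = None,
                     band: tuple[float, float] = (0.035, 0.08),
                     do_detrend: bool = True,
                     do_bandpass: bool = True,
                     do_gsr: bool = True,
                     ) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Run the fixed preprocessing chain: downsample, detrend, bandpass, GSR.

    The stage order is fixed; stages can only be switched off, never
    reordered.  Returns ``(movie, mask, downsample_factor)`` in the output
    geometry.
    """
    arr = _frames(movie)
    factor = 1.0
    if out_size is not None:
        factor = arr.shape[1] / out_size[0]
        if arr.shape[2] / out_size[1] != factor:
            raise ParamError("anisotropic downsampling factors not supported")
        arr = downsample_movie(arr, out_size)
        if mask is not None:
            f = int(factor)
            mask = np.asarray(mask, bool)
            mask = (
                mask.reshape(out_size[0], f, out_size[1], f).mean(axis=(1, 3)) > 0.5
            )
    if do_detrend:
        arr = detrend_movie(arr)
    if do_bandpass:
        arr = bandpass_movie(arr, frame_rate_hz, low=band[0], high=band[1])
    if do_gsr:
        arr = global_signal_regression(arr, mask)
    return arr, mask, factor


def frame_bookkeeping(total_minutes: float = 32.7, fps: float = 3.0,
                      discard_frames: int = 500, block_minutes: float = 10.0,
                      n_blocks: int = 3) -> dict:
    """Frame accounting for the post-CSD block layout.

    With the defaults: a 32.7-min recording at 3 fps is 5886 frames; the
    500-frame discard spans 2.8 min; the remaining ~30 min are split into
    three 10-min (1800-frame) blocks, the last of which may run short.
    """
    total_frames = int(round(total_minutes * 60.0 * fps))
    block_len = int(round(block_minutes * 60.0 * fps))
    remaining = total_frames - discard_frames
    block_frames = [
        min(block_len, max(0, remaining - i * block_len)) for i in range(n_blocks)
    ]
    return {
        "total_frames": total_frames,
        "discard_frames": discard_frames,
        "discard_minutes": round(discard_frames / fps / 60.0, 1),
        "remaining_frames": remaining,
        "block_len": block_len,
        "analyzed_minutes": round(n_blocks * block_minutes, 1),
        "block_frames": block_frames,
        "short_blocks": [i for i, b in enumerate(block_frames) if b < block_len],
    }


def csd_block_analysis(movie: ImageStack, midline: MidlineAxis,
                       mask: np.ndarray | None = None,
                       fps: float | None = None,
                       discard_frames: int = 500,
                       block_minutes: float = 10.0,
                       n_blocks: int = 3,
                       baseline_movie: ImageStack | np.ndarray | None = None,
                       out_size: tuple[int, int] | None = None,
                       band: tuple[float, float] = (0.035, 0.08),
                       ) -> list[ConnectivityIndex]:
    """Homotopic connectivity index per post-CSD block (plus baseline).

    The first ``discard_frames`` (CSD wave still propagating) are dropped;
    the remainder is analyzed as ``n_blocks`` blocks of ``block_minutes``.
    A final block at least half-full is analyzed and flagged ``short``;
    anything shorter raises.  Each block (and the baseline recording) runs
    through the full chain: downsample, detrend, bandpass, GSR, homotopic
    correlation, Fisher z, mean.
    """
    if fps is None:
        fps = movie.frame_rate_hz
    if not fps:
        raise ParamError("frame rate required")
    arr = _frames(movie)
    block_len = int(round(block_minutes * 60.0 * fps))
    min_last = block_len // 2
    required = discard_frames + (n_blocks - 1) * block_len + min_last
    if arr.shape[0] < required:
        raise InsufficientFramesError(
            f"movie has {arr.shape[0]} frames; needs >= {required} "
            f"(discard {discard_frames} + {n_blocks - 1} full blocks of "
            f"{block_len} + >= {min_last} in the final block)"
        )

    def _index(block: np.ndarray, label: str, short: bool) -> ConnectivityIndex:
        pre, pmask, factor = preprocess_movie(
            block, fps, mask=mask, out_size=out_size, band=band
        )
        mid = midline.scaled(factor) if factor != 1.0 else midline
        cmap = homotopic_map(pre, mid, pmask)
        return connectivity_index(cmap, block_label=label,
                                  n_frames=block.shape[0], short=short)

    out: list[ConnectivityIndex] = []
    if baseline_movie is not None:
        out.append(_index(_frames(baseline_movie), "baseline", False))
    start = discard_frames
    for i in range(n_blocks):
        stop = min(start + block_len, arr.shape[0])
        block = arr[start:stop]
        out.append(_index(block, f"block{i + 1}", block.shape[0] < block_len))
        start = stop
    return out
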