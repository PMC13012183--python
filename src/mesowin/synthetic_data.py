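"""Synthetic inputs with recorded ground truth for every analysis stage.

Each generator emulates the statistical structure one pipeline stage
assumes — dynamic speckle with a controllable correlation time, bilateral
band-limited hemodynamics with a known mirror-pixel correlation, dark
curvilinear vessels with a known area fraction, near-black occlusion blobs,
a propagating CSD-like flow transient, and branched-cell morphologies with
known Sholl profiles.  All generators are seed-deterministic and return
``(data, truth)`` where ``truth`` holds every quantity a downstream
recovery test needs.

The speckle temporal model is a per-substep AR(1) process on the complex
field (Lorentzian-type decorrelation); the expected contrast for a given
``tau_c / T`` is obtained from :func:`expected_contrast_bruteforce`, a
many-realization single-pixel simulation, rather than a closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy import signal as sps
from skimage.draw import disk as draw_disk

from ._exceptions import GeometryError, ParamError, PlacementError
from .io_config import ImageStack
from .connectivity import MidlineAxis, build_pair_map, hemisphere_sides

__all__ = [
    "SpeckleSimParams",
    "BilateralSimParams",
    "CSDParams",
    "MorphologySimParams",
    "expected_contrast_bruteforce",
    "gen_speckle_stack",
    "gen_bilateral_movie",
    "gen_csd_movie",
    "gen_vessel_image",
    "gen_occluded_window",
    "gen_microglia_image",
]


# ---------------------------------------------------------------------------
# dynamic speckle
# ---------------------------------------------------------------------------

@dataclass
class SpeckleSimParams:
    """Parameters of the dynamic-speckle generator.

    ``tau_c_ms`` is the field correlation time; ``exposure_ms`` the camera
    exposure T integrated as the average of ``n_substeps`` sub-frames;
    ``beta`` the coherence factor (implemented as incoherent averaging of
    ``round(1/beta)`` independent speckle patterns); ``grain_px`` the
    speckle grain size set by a circular frequency-domain aperture.
    """

    shape: tuple[int, int, int] = (15, 128, 128)
    grain_px: float = 4.0
    tau_c_ms: float = 5.0
    exposure_ms: float = 5.0
    n_substeps: int = 16
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_c_ms <= 0:
            raise ParamError("tau_c_ms must be > 0 (use np.inf for static)")
        if self.n_substeps < 8:
            raise ParamError("n_substeps must be >= 8")
        if self.grain_px < 2:
            raise ParamError("grain_px must be >= 2")
        if not 0 < self.beta <= 1:
            raise ParamError("beta must be in (0, 1]")
        if len(self.shape) != 3:
            raise ParamError("shape must be (frames, rows, cols)")


def _aperture(rows: int, cols: int, grain_px: float) -> np.ndarray:
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    return np.sqrt(fy**2 + fx**2) <= 1.0 / (2.0 * grain_px)


def _speckle_field(rng: np.random.Generator, aperture: np.ndarray) -> np.ndarray:
    rows, cols = aperture.shape
    w = rng.standard_normal((rows, cols)) + 1j * rng.standard_normal((rows, cols))
    return np.fft.ifft2(w * aperture)


def expected_contrast_bruteforce(tau_c_ms: float, exposure_ms: float,
                                 n_substeps: int = 16, beta: float = 1.0,
                                 n_realizations: int = 4000,
                                 seed: int = 0) -> float:
    """Brute-force expected speckle contrast for the AR(1) temporal model.

    Simulates many independent single-pixel exposures at the same
    ``tau_c / T`` and returns std/mean of the integrated intensities.  This
    is the oracle the generator's ``expected_K`` ground truth comes from.
    """
    rng = np.random.default_rng(seed)
    m = max(1, round(1.0 / beta))
    dt = exposure_ms / n_substeps
    a = math.exp(-dt / tau_c_ms) if np.isfinite(tau_c_ms) else 1.0
    e = (rng.standard_normal((n_realizations, m))
         + 1j * rng.standard_normal((n_realizations, m))) / math.sqrt(2.0)
    intensity = np.abs(e) ** 2
    acc = intensity.mean(axis=1).copy()
    mix = math.sqrt(max(0.0, 1.0 - a * a))
    for _ in range(1, n_substeps):
        innov = (rng.standard_normal((n_realizations, m))
                 + 1j * rng.standard_normal((n_realizations, m))) / math.sqrt(2.0)
        e = a * e + mix * innov
        acc += (np.abs(e) ** 2).mean(axis=1)
    acc /= n_substeps
    return float(np.std(acc, ddof=1) / np.mean(acc))


def gen_speckle_stack(p: SpeckleSimParams) -> tuple[ImageStack, dict[str, Any]]:
    """Dynamic speckle frames plus ground truth ``{tau_c_ms, expected_K, ...}``.

    Intensities are |complex Gaussian field|^2 with grain size set by a
    circular frequency-domain aperture; temporal evolution is a per-substep
    AR(1) with coefficient exp(-dt/tau_c); each frame integrates the
    exposure as the mean of ``n_substeps`` sub-frames.  Output is quantized
    to 8 bits (mean intensity scaled to ~40 counts).
    """
    n_frames, rows, cols = p.shape
    rng = np.random.default_rng(p.seed)
    ap = _aperture(rows, cols, p.grain_px)
    m = max(1, round(1.0 / p.beta))
    dt = p.exposure_ms / p.n_substeps
    a = math.exp(-dt / p.tau_c_ms) if np.isfinite(p.tau_c_ms) else 1.0
    mix = math.sqrt(max(0.0, 1.0 - a * a))

    fields = [_speckle_field(rng, ap) for _ in range(m)]
    out = np.empty((n_frames, rows, cols))
    for f in range(n_frames):
        acc = np.zeros((rows, cols))
        for step in range(p.n_substeps):
            if f > 0 or step > 0:
                for i in range(m):
                    fields[i] = a * fields[i] + mix * _speckle_field(rng, ap)
            acc += sum(np.abs(fld) ** 2 for fld in fields) / m
        out[f] = acc / p.n_substeps

    scale = 40.0 / out.mean()
    frames8 = np.clip(np.rint(out * scale), 0, 255).astype(np.uint8)
    truth = {
        "tau_c_ms": p.tau_c_ms,
        "exposure_ms": p.exposure_ms,
        "beta": p.beta,
        "expected_K": expected_contrast_bruteforce(
            p.tau_c_ms, p.exposure_ms, p.n_substeps, p.beta, seed=p.seed + 1
        ),
        "intensity_scale": scale,
    }
    stack = ImageStack(frames=frames8, bit_depth=8, exposure_ms=p.exposure_ms)
    return stack, truth


# ---------------------------------------------------------------------------
# bilateral hemodynamic movies
# ---------------------------------------------------------------------------

@dataclass
class BilateralSimParams:
    """Bilateral band-limited hemodynamic movie parameters.

    Each homotopic pixel pair shares a band-limited signal ``s`` so that
    left = sqrt(rho)*s + sqrt(1-rho)*e_L and right = sqrt(rho)*s +
    sqrt(1-rho)*e_R, giving a mirror-pixel correlation of exactly ``rho``
    in expectation.  Linear drift, a common in-band global component and
    white noise can be layered on top.
    """

    n_frames: int = 1800
    shape: tuple[int, int] = (64, 64)
    frame_rate_hz: float = 3.0
    rho: float = 0.6
    band: tuple[float, float] = (0.035, 0.08)
    drift_slope: float = 0.0
    global_amp: float = 0.0
    noise_sd: float = 0.0
    midline: MidlineAxis | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise ParamError("rho must be in [0, 1]")
        lo, hi = self.band
        if not 0 < lo < hi < self.frame_rate_hz / 2:
            raise ParamError("band must satisfy 0 < low < high < Nyquist")
        if self.n_frames < 64:
            raise ParamError("n_frames too small for band-limited synthesis")

    def resolved_midline(self) -> MidlineAxis:
        if self.midline is not None:
            rows, cols = self.shape
            self.midline.check_inside((rows, cols))
            return self.midline
        rows, cols = self.shape
        c = (cols - 1) / 2.0
        return MidlineAxis(bregma=(0.0, c), lambda_pt=(float(rows - 1), c))


_GAIN = 18.0    # intensity counts per signal sd
_OFFSET = 128.0


def _band_noise(rng: np.random.Generator, n: int, m: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """``m`` independent unit-variance band-limited Gaussian series of length ``n``."""
    if m == 0:
        return np.zeros((n, 0))
    w = rng.standard_normal((n, m))
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, w, axis=0)
    x = x - x.mean(axis=0)
    return x / x.std(axis=0)


def _bilateral_parts(p: BilateralSimParams, rng: np.random.Generator) -> dict:
    rows, cols = p.shape
    mid = p.resolved_midline()
    idx, partner = build_pair_map((rows, cols), mid)
    side = hemisphere_sides((rows, cols), mid).ravel()
    neg = side[idx] < 0
    left_idx, right_idx = idx[neg], partner[neg]
    paired = np.zeros(rows * cols, bool)
    paired[left_idx] = True
    paired[right_idx] = True
    unpaired_idx = np.flatnonzero(~paired)

    n_pairs = left_idx.size
    s = _band_noise(rng, p.n_frames, n_pairs, p.frame_rate_hz, p.band)
    e_l = _band_noise(rng, p.n_frames, n_pairs, p.frame_rate_hz, p.band)
    e_r = _band_noise(rng, p.n_frames, n_pairs, p.frame_rate_hz, p.band)
    u = _band_noise(rng, p.n_frames, unpaired_idx.size, p.frame_rate_hz, p.band)
    g = _band_noise(rng, p.n_frames, 1, p.frame_rate_hz, p.band)[:, 0]
    noise = (rng.standard_normal((p.n_frames, rows * cols)) * p.noise_sd
             if p.noise_sd > 0 else 0.0)
    return {
        "midline": mid, "left_idx": left_idx, "right_idx": right_idx,
        "unpaired_idx": unpaired_idx, "s": s, "e_l": e_l, "e_r": e_r,
        "u": u, "g": g, "noise": noise, "side": side,
    }


def _compose(p: BilateralSimParams, parts: dict,
             att: np.ndarray | None = None,
             ipsi_is_left: bool | None = None) -> np.ndarray:
    """Float signal movie; ``att`` optionally attenuates the shared component
    on the ipsilateral side (variance-preserving mixing with ``e2``)."""
    n = p.n_frames
    rows, cols = p.shape
    sig = np.zeros((n, rows * cols))
    sq_r, sq_i = math.sqrt(p.rho), math.sqrt(1.0 - p.rho)
    left = sq_r * parts["s"] + sq_i * parts["e_l"]
    right = sq_r * parts["s"] + sq_i * parts["e_r"]
    if att is not None:
        keep = np.sqrt(np.clip(1.0 - att**2, 0.0, 1.0))[:, None]
        shared = att[:, None] * parts["s"] + keep * parts["e2"]
        if ipsi_is_left:
            left = sq_r * shared + sq_i * parts["e_l"]
        else:
            right = sq_r * shared + sq_i * parts["e_r"]
    sig[:, parts["left_idx"]] = left
    sig[:, parts["right_idx"]] = right
    sig[:, parts["unpaired_idx"]] = parts["u"]

    t = np.arange(n) - (n - 1) / 2.0
    sig += (p.drift_slope * t)[:, None]
    sig += p.global_amp * parts["g"][:, None]
    sig = sig + parts["noise"]
    return sig.reshape(n, rows, cols)


def _quantize_movie(sig: np.ndarray, frame_rate_hz: float) -> ImageStack:
    frames8 = np.clip(np.rint(_OFFSET + _GAIN * sig), 0, 255).astype(np.uint8)
    return ImageStack(frames=frames8, bit_depth=8, frame_rate_hz=frame_rate_hz)


def gen_bilateral_movie(p: BilateralSimParams) -> tuple[ImageStack, dict[str, Any]]:
    """Bilateral movie with known homotopic correlation ``rho``.

    Pair assignment is exactly mirror-symmetric about the bregma-lambda
    line; midline pixels and pixels whose mirror leaves the image get
    independent signals.  Ground truth records ``rho``, the midline, the
    brain mask and the paired-pixel indices.
    """
    rng = np.random.default_rng(p.seed)
    parts = _bilateral_parts(p, rng)
    sig = _compose(p, parts)
    stack = _quantize_movie(sig, p.frame_rate_hz)
    rows, cols = p.shape
    mid = parts["midline"]
    truth = {
        "rho": p.rho,
        "midline": {"bregma": list(mid.bregma), "lambda": list(mid.lambda_pt)},
        "mask": np.ones((rows, cols), bool),
        "left_idx": parts["left_idx"],
        "right_idx": parts["right_idx"],
        "gain": _GAIN,
        "offset": _OFFSET,
    }
    return stack, truth


@dataclass
class CSDParams:
    """Propagating CSD-like transient layered onto a bilateral movie.

    The flow wave multiplies intensity by ``hyper_gain`` for
    ``hyper_frames`` after its arrival at each ipsilateral pixel, then by
    ``oligemia_gain`` recovering linearly to 1 over ``recovery_frames``.
    The shared (homotopic) component on the ipsilateral side is attenuated
    to ``att_min`` at onset and restored linearly over ``recovery_frames``.
    """

    onset_frame: int = 50
    origin: tuple[int, int] = (10, 10)
    speed_px_per_frame: float = 0.5
    hyper_gain: float = 1.4
    oligemia_gain: float = 0.75
    hyper_frames: int = 30
    recovery_frames: int = 3600
    att_min: float = 0.15


def gen_csd_movie(p: BilateralSimParams, csd: CSDParams
                  ) -> tuple[ImageStack, dict[str, Any]]:
    """Bilateral movie plus a unilateral CSD-like propagating flow transient.

    The contralateral hemisphere is bit-identical to :func:`gen_bilateral_movie`
    run with the same parameters and seed; all CSD-specific randomness is
    drawn from an independent stream.
    """
    rows, cols = p.shape
    rng = np.random.default_rng(p.seed)
    parts = _bilateral_parts(p, rng)
    mid = parts["midline"]
    side = parts["side"].reshape(rows, cols)
    orow, ocol = csd.origin
    if not (0 <= orow < rows and 0 <= ocol < cols) or side[orow, ocol] == 0:
        raise GeometryError("CSD origin must lie inside one hemisphere")
    ipsi_sign = side[orow, ocol]
    ipsi_is_left = bool(
        parts["left_idx"].size
        and parts["side"][parts["left_idx"][0]] == ipsi_sign
    )

    n = p.n_frames
    rng_csd = np.random.default_rng([p.seed, 0x5CD])
    n_pairs = parts["left_idx"].size
    parts["e2"] = _band_noise(rng_csd, n, n_pairs, p.frame_rate_hz, p.band)

    t = np.arange(n)
    rel0 = np.clip(t - csd.onset_frame, 0, None).astype(float)
    att = np.where(
        t < csd.onset_frame, 1.0,
        csd.att_min + (1.0 - csd.att_min) * np.minimum(1.0, rel0 / csd.recovery_frames),
    )
    sig = _compose(p, parts, att=att, ipsi_is_left=ipsi_is_left)

    # radially propagating gain wave on the ipsilateral hemisphere
    rr, cc = np.mgrid[0:rows, 0:cols]
    dist = np.hypot(rr - orow, cc - ocol)
    ipsi_flat = np.flatnonzero((side == ipsi_sign).ravel())
    arrival = csd.onset_frame + dist.ravel()[ipsi_flat] / csd.speed_px_per_frame
    rel = t[:, None] - arrival[None, :]
    gain = np.where(
        rel < 0, 1.0,
        np.where(
            rel < csd.hyper_frames, csd.hyper_gain,
            csd.oligemia_gain + (1.0 - csd.oligemia_gain)
            * np.clip((rel - csd.hyper_frames) / csd.recovery_frames, 0.0, 1.0),
        ),
    )
    intensity = _OFFSET + _GAIN * sig.reshape(n, -1)
    intensity[:, ipsi_flat] *= gain
    frames8 = np.clip(np.rint(intensity), 0, 255).astype(np.uint8).reshape(n, rows, cols)
    stack = ImageStack(frames=frames8, bit_depth=8, frame_rate_hz=p.frame_rate_hz)

    truth = {
        "rho": p.rho,
        "midline": {"bregma": list(mid.bregma), "lambda": list(mid.lambda_pt)},
        "mask": np.ones((rows, cols), bool),
        "ipsi_mask": side == ipsi_sign,
        "attenuation": att,
        "onset_frame": csd.onset_frame,
        "origin": list(csd.origin),
        "arrival_frame_map": dict(zip(ipsi_flat.tolist(), arrival.tolist())),
        "csd": asdict(csd),
    }
    return stack, truth


# ---------------------------------------------------------------------------
# vessel / occlusion images
# ---------------------------------------------------------------------------

def gen_vessel_image(fraction: float, shape: tuple[int, int] = (256, 256),
                     width_px: int = 3, contrast: float = 0.8,
                     noise_sd: float = 3.0, seed: int = 0
                     ) -> tuple[np.ndarray, dict[str, Any]]:
    """Dark curvilinear vessels on a bright background, hitting ``fraction``.

    Smooth random walks are dilated to ``width_px`` and accumulated until
    the foreground fraction is within 0.01 of the target; the exact mask is
    returned as ground truth.
    """
    if not 0 <= fraction <= 0.6:
        raise ParamError("fraction must be in [0, 0.6]")
    rows, cols = shape
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, bool)
    area = rows * cols
    rad = max(1.0, width_px / 2.0)
    n_walks = 0
    while mask.sum() < (fraction - 0.005) * area:
        n_walks += 1
        if n_walks > 20000:
            raise ParamError(
                f"fraction {fraction} unreachable at width {width_px}px"
            )
        r = rng.uniform(0, rows)
        c = rng.uniform(0, cols)
        ang = rng.uniform(0, 2 * math.pi)
        for _ in range(25):
            ang += rng.normal(0, 0.3)
            r += 1.5 * math.sin(ang)
            c += 1.5 * math.cos(ang)
            if not (0 <= r < rows and 0 <= c < cols):
                break
            dd, cc2 = draw_disk((r, c), rad, shape=shape)
            mask[dd, cc2] = True

    bg, vessel = 200.0, 200.0 * (1.0 - contrast)
    img = np.where(mask, vessel, bg) + rng.normal(0, noise_sd, shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = {
        "f_target": fraction,
        "f_actual": float(mask.mean()),
        "vessel_mask": mask,
    }
    return img, truth


def gen_occluded_window(base_image: np.ndarray, occluded_fraction: float,
                        n_blobs: int = 6, window_mask: np.ndarray | None = None,
                        seed: int = 0) -> tuple[np.ndarray, dict[str, Any]]:
    """Superimpose near-black blobs totalling ``occluded_fraction`` of the window.

    Blobs (drying-artifact surrogates) are disks placed entirely inside the
    window mask; their union area is grown until it is within 0.005 of the
    target fraction.
    """
    if not 0 <= occluded_fraction < 1:
        raise ParamError("occluded_fraction must be in [0, 1)")
    img = np.asarray(base_image).copy()
    shape = img.shape
    if window_mask is None:
        window_mask = np.ones(shape, bool)
    window_mask = np.asarray(window_mask, bool)
    win_area = int(window_mask.sum())
    target = occluded_fraction * win_area

    rng = np.random.default_rng(seed)
    blob_mask = np.zeros(shape, bool)
    win_idx = np.flatnonzero(window_mask.ravel())
    tries = 0
    while occluded_fraction > 0 and blob_mask.sum() < target - 0.005 * win_area:
        tries += 1
        if tries > 5000:
            raise ParamError("could not place blobs to reach target fraction")
        remaining = target - blob_mask.sum()
        r_blob = math.sqrt(min(remaining, target / n_blobs) / math.pi)
        r_blob = max(2.0, r_blob)
        center = np.unravel_index(rng.choice(win_idx), shape)
        dd, cc = draw_disk(center, r_blob, shape=shape)
        if not window_mask[dd, cc].all():
            continue
        blob_mask[dd, cc] = True

    img[blob_mask] = rng.integers(0, 3, size=int(blob_mask.sum())).astype(img.dtype)
    truth = {
        "q_target": occluded_fraction,
        "q_actual": float(blob_mask.sum() / win_area),
        "blob_mask": blob_mask,
    }
    return img, truth


# ---------------------------------------------------------------------------
# microglia morphologies
# ---------------------------------------------------------------------------

@dataclass
class MorphologySimParams:
    """Branched-cell morphology parameters (units: um unless noted)."""

    n_cells: int = 3
    soma_radius_um: float = 4.0
    n_branches: int = 6
    branch_length_um: float = 20.0
    bifurcate_at_um: float | None = None
    branch_width_um: float = 2.0
    pixel_size_um: float = 0.5
    noise_level: float = 4.0
    shape: tuple[int, int] = (256, 256)
    angle_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.branch_length_um <= self.soma_radius_um:
            raise ParamError("branch_length_um must exceed soma_radius_um")
        if self.n_branches < 1:
            raise ParamError("n_branches must be >= 1")
        if self.bifurcate_at_um is not None and not (
            self.soma_radius_um < self.bifurcate_at_um < self.branch_length_um
        ):
            raise ParamError("bifurcate_at_um must lie between soma and branch tip")


def _draw_ray(canvas: np.ndarray, start: np.ndarray, direction: np.ndarray,
              center: np.ndarray, stop_radius_px: float, width_rad: float) -> None:
    """Draw a thick ray from ``start`` until radial distance from ``center``
    reaches ``stop_radius_px``."""
    pos = start.astype(float).copy()
    shape = canvas.shape
    for _ in range(10000):
        if np.hypot(*(pos - center)) >= stop_radius_px:
            break
        dd, cc = draw_disk(tuple(pos), max(1.0, width_rad), shape=shape)
        canvas[dd, cc] = True
        pos += 0.5 * direction


def gen_microglia_image(p: MorphologySimParams) -> tuple[np.ndarray, dict[str, Any]]:
    """Synthetic microglia field with known Sholl ground truth.

    Each cell is a disk soma plus ``n_branches`` straight radial branches of
    length ``branch_length_um`` at roughly even angles (optionally
    bifurcating at ``bifurcate_at_um``, doubling the distal branch count),
    rasterized at ``branch_width_um``.  A background gradient and additive
    noise exercise the preprocessing chain.  Cells are placed without
    touching; failure to place raises :class:`PlacementError`.
    """
    rng = np.random.default_rng(p.seed)
    rows, cols = p.shape
    px = 1.0 / p.pixel_size_um                      # pixels per um
    l_px = p.branch_length_um * px
    margin = l_px + 4
    if 2 * margin >= min(rows, cols):
        raise ParamError("cells do not fit in the frame")
    min_sep = 2 * l_px + 8

    centers: list[np.ndarray] = []
    for _ in range(p.n_cells):
        for attempt in range(2000):
            cand = np.array([rng.uniform(margin, rows - margin),
                             rng.uniform(margin, cols - margin)])
            if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
                centers.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place {p.n_cells} non-touching cells in {p.shape}"
            )

    canvas = np.zeros((rows, cols), bool)
    width_rad = max(1.0, p.branch_width_um * px / 2.0)
    all_angles = []
    for center in centers:
        base = rng.uniform(0, 2 * math.pi)
        angles = [
            base + 2 * math.pi * i / p.n_branches
            + p.angle_jitter * rng.uniform(-1, 1) * math.pi / p.n_branches
            for i in range(p.n_branches)
        ]
        all_angles.append(angles)
        dd, cc = draw_disk(tuple(center), p.soma_radius_um * px, shape=(rows, cols))
        canvas[dd, cc] = True
        for ang in angles:
            direction = np.array([math.sin(ang), math.cos(ang)])
            if p.bifurcate_at_um is None:
                _draw_ray(canvas, center, direction, center, l_px, width_rad)
            else:
                b_px = p.bifurcate_at_um * px
                _draw_ray(canvas, center, direction, center, b_px, width_rad)
                branch_pt = center + b_px * direction
                for delta in (-0.35, 0.35):
                    d2 = np.array([math.sin(ang + delta), math.cos(ang + delta)])
                    _draw_ray(canvas, branch_pt, d2, center, l_px, width_rad)

    gradient = np.linspace(0.0, 15.0, cols)[None, :] * np.ones((rows, 1))
    img = np.where(canvas, 200.0, 25.0) + gradient
    if p.noise_level > 0:
        img += rng.normal(0, p.noise_level, (rows, cols))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = {
        "centers_px": np.array(centers),
        "n_cells": p.n_cells,
        "n_branches": p.n_branches,
        "branch_length_um": p.branch_length_um,
        "soma_radius_um": p.soma_radius_um,
        "bifurcate_at_um": p.bifurcate_at_um,
        "angles": all_angles,
        "pixel_size_um": p.pixel_size_um,
        "cell_mask": canvas,
    }
    return img, truth
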