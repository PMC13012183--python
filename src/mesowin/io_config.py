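"""Image-stack, table and config I/O.

Conventions used throughout the package:

* images are row-major, 0-based, with pixel centers on integer coordinates
  and the row index increasing downward;
* a stack is a 3-D ``(frame, row, col)`` array, a single image a 1-frame stack;
* acquisition metadata travels in a JSON sidecar next to the TIFF
  (same basename, ``.json`` suffix), not in TIFF tags;
* derived floating-point images are written as 32-bit float TIFF, masks as
  8-bit ``{0, 255}``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from ._exceptions import FormatError, ParamError

__all__ = [
    "ImageStack",
    "AnalysisConfig",
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
    "read_json",
    "write_json",
    "write_mask",
    "write_run_log",
]

_METADATA_KEYS = ("pixel_size_um", "frame_rate_hz", "exposure_ms")


@dataclass
class ImageStack:
    """A grayscale image stack with optional acquisition metadata.

    Parameters
    ----------
    frames
        ``(n_frames, rows, cols)`` array of non-negative intensities.
    bit_depth
        Nominal acquisition depth, 8 or 16.  Values must fit the depth.
    pixel_size_um, frame_rate_hz, exposure_ms
        Optional acquisition metadata carried alongside the pixels.
    """

    frames: np.ndarray
    bit_depth: int = 8
    pixel_size_um: float | None = None
    frame_rate_hz: float | None = None
    exposure_ms: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ParamError(
                f"frames must be (frame, row, col); got ndim={self.frames.ndim}"
            )
        if self.bit_depth not in (8, 16):
            raise ParamError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.frames.size and float(self.frames.min()) < 0:
            raise ParamError("intensities must be non-negative")
        if self.frames.size and float(self.frames.max()) > 2**self.bit_depth - 1:
            raise ParamError(
                f"max intensity {self.frames.max()} exceeds {self.bit_depth}-bit range"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.frames.shape)  # type: ignore[return-value]

    def metadata(self) -> dict[str, Any]:
        return {
            "bit_depth": self.bit_depth,
            "pixel_size_um": self.pixel_size_um,
            "frame_rate_hz": self.frame_rate_hz,
            "exposure_ms": self.exposure_ms,
        }


@dataclass
class AnalysisConfig:
    """Printed analysis constants for the full pipeline.

    Defaults are the values used throughout: a 7x7 speckle-contrast window,
    the 0.035-0.08 Hz hemodynamic band, a 500-frame post-CSD discard,
    10-minute connectivity blocks and 5-um Sholl rings.
    """

    window_px: int = 7
    band_low_hz: float = 0.035
    band_high_hz: float = 0.08
    discard_frames: int = 500
    block_minutes: float = 10.0
    sholl_step_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise ParamError("window_px must be odd and >= 3")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ParamError("need 0 < band_low_hz < band_high_hz")
        if self.discard_frames <= 0 or self.block_minutes <= 0 or self.sholl_step_um <= 0:
            raise ParamError("counts and steps must be positive")

    def validate_for_rate(self, frame_rate_hz: float) -> None:
        if not self.band_high_hz < frame_rate_hz / 2:
            raise ParamError(
                f"band_high_hz={self.band_high_hz} must be below Nyquist "
                f"({frame_rate_hz / 2} Hz)"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        data = read_json(path)
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_json(self, path: str | Path) -> None:
        write_json(asdict(self), path)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def read_stack(path: str | Path) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Metadata is populated from the JSON sidecar (same basename) when present.
    Single images become 1-frame stacks.  Non-grayscale input, inconsistent
    page shapes or unreadable files raise :class:`FormatError`.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page0 = tif.pages[0]
            if page0.samplesperpixel != 1:
                raise FormatError(f"{path}: expected grayscale, got "
                                  f"{page0.samplesperpixel} samples/pixel")
            shapes = {p.shape for p in tif.pages}
            if len(shapes) != 1:
                raise FormatError(f"{path}: inconsistent page shapes {shapes}")
            frames = tif.asarray()
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises various types on bad files
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(f"{path}: expected grayscale pages, got shape {frames.shape}")

    meta: dict[str, Any] = {}
    side = _sidecar(path)
    if side.exists():
        raw = read_json(side)
        meta = {k: raw[k] for k in _METADATA_KEYS if raw.get(k) is not None}
        if raw.get("bit_depth") in (8, 16):
            meta["bit_depth"] = raw["bit_depth"]
    meta.setdefault("bit_depth", 16 if frames.dtype.itemsize > 1 else 8)
    return ImageStack(frames=frames, **meta)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as TIFF plus JSON metadata sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = stack.frames
    if frames.dtype.kind == "f":
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack")
    write_json(stack.metadata(), _sidecar(path))
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as an 8-bit {0,255} TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def _as_record(row: Any) -> Mapping[str, Any]:
    if isinstance(row, Mapping):
        return row
    if hasattr(row, "__dataclass_fields__"):
        return asdict(row)
    raise ParamError(f"cannot interpret record of type {type(row)!r}")


def write_table(rows: Iterable[Any], path: str | Path,
                columns: Sequence[str] | None = None) -> Path:
    """Write records (dicts or dataclasses sharing a schema) as CSV.

    Column order is taken from the first record (or ``columns``), so output
    is deterministic; numeric values round-trip through :func:`read_table`.
    An empty record list yields a header-only CSV when ``columns`` is given,
    otherwise an empty file with no rows.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [_as_record(r) for r in rows]
    if records and columns is None:
        columns = list(records[0])
    df = pd.DataFrame.from_records(records, columns=columns)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_json(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o: Any) -> Any:
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)!r}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_log(out_dir: str | Path, command: str,
                  config: Mapping[str, Any] | None = None,
                  seed: int | None = None,
                  inputs: Sequence[str | Path] = ()) -> Path:
    """Record command, config, seed and input hashes for reproducibility."""
    out_dir = Path(out_dir)
    log = {
        "command": command,
        "config": dict(config) if config else {},
        "seed": seed,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
    }
    return write_json(log, out_dir / f"{command}_run_log.json")
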