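"""Microglia counting and Sholl analysis of binarized arbors.

The preprocessing chain is applied in a fixed order: Gaussian blur
(sigma = 0.5 px), rolling-ball background subtraction (radius 50 px), Otsu
binarization, outlier removal (a pixel is replaced by the median of its
radius-2 disk neighborhood when it deviates from it by more than 50 on the
0-255 scale), removal of connected components smaller than 10 px, and a
radius-5 median filter.  Sholl profiles then count, for concentric circles
at 5-um steps around each soma center, the number of maximal contiguous
foreground arcs crossed by the circle.

Connected components use 8-connectivity throughout (particle filtering and
cell counting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage import filters, morphology as skmorph, restoration
from skimage.measure import label

from ._exceptions import GeometryError, ParamError

__all__ = [
    "BinaryCellImage",
    "ShollProfile",
    "preprocess_microglia",
    "sholl_profile",
    "count_cells",
    "fov_from_zoom",
]


@dataclass
class BinaryCellImage:
    """Binarized cell image with the ordered preprocessing provenance."""

    binary: np.ndarray
    pixel_size_um: float
    provenance: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.binary = np.asarray(self.binary, bool)


@dataclass
class ShollProfile:
    """Intersection counts per concentric radius for one cell."""

    center: tuple[float, float]
    radii_um: np.ndarray
    intersections: np.ndarray

    def __post_init__(self) -> None:
        self.radii_um = np.asarray(self.radii_um, float)
        self.intersections = np.asarray(self.intersections, int)
        if (self.intersections < 0).any():
            raise ParamError("intersection counts must be >= 0")
        if self.radii_um.size > 1:
            steps = np.diff(self.radii_um)
            if (steps <= 0).any() or not np.allclose(steps, steps[0]):
                raise ParamError("radii must increase with a constant step")

    def rows(self) -> list[dict]:
        """CSV-ready records ``{radius_um, intersections}``."""
        return [
            {"radius_um": float(r), "intersections": int(c)}
            for r, c in zip(self.radii_um, self.intersections)
        ]


def preprocess_microglia(image: np.ndarray, pixel_size_um: float,
                         gaussian_sigma: float = 0.5,
                         rolling_ball_radius: int = 50,
                         outlier_radius: int = 2,
                         outlier_threshold: float = 50.0,
                         min_particle_px: int = 10,
                         median_radius: int = 5) -> BinaryCellImage:
    """Full binarization chain for maximum-projection microglia images."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ParamError(f"expected a 2-D image, got shape {img.shape}")
    prov: list[tuple[str, dict]] = []
    work = img.astype(np.float64)

    work = ndi.gaussian_filter(work, sigma=gaussian_sigma)
    prov.append(("gaussian_blur", {"sigma": gaussian_sigma}))

    background = restoration.rolling_ball(work, radius=rolling_ball_radius)
    work = work - background
    prov.append(("rolling_ball_background", {"radius": rolling_ball_radius}))

    if work.max() == work.min():
        binary = np.zeros(work.shape, bool)          # featureless image
        prov.append(("otsu_binarize", {"threshold": None}))
    else:
        thr = filters.threshold_otsu(work)
        binary = work > thr
        prov.append(("otsu_binarize", {"threshold": float(thr)}))

    b255 = binary.astype(np.uint8) * 255
    med = ndi.median_filter(b255, footprint=skmorph.disk(outlier_radius))
    b255 = np.where(
        np.abs(b255.astype(np.int16) - med.astype(np.int16)) > outlier_threshold,
        med, b255,
    )
    binary = b255 > 127
    prov.append(("remove_outliers",
                 {"radius": outlier_radius, "threshold": outlier_threshold}))

    binary = skmorph.remove_small_objects(binary, max_size=min_particle_px - 1,
                                          connectivity=2)
    prov.append(("analyze_particles", {"min_size_px": min_particle_px}))

    binary = ndi.median_filter(binary.astype(np.uint8),
                               footprint=skmorph.disk(median_radius)) > 0
    prov.append(("median_filter", {"radius": median_radius}))

    return BinaryCellImage(binary=binary, pixel_size_um=pixel_size_um,
                           provenance=prov)


def sholl_profile(cell: BinaryCellImage, center: tuple[float, float],
                  step_um: float = 5.0,
                  max_radius_um: float | None = None) -> ShollProfile:
    """Intersections of the arbor with concentric circles at ``step_um`` steps.

    Each circle is sampled at <= 1-px arc spacing; maximal contiguous runs
    of foreground samples are counted as one intersection each, with runs
    wrapping the 0/2pi seam merged.  ``max_radius_um`` defaults to the
    distance from the center to the nearest image border.
    """
    binary = cell.binary
    rows, cols = binary.shape
    r0, c0 = center
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise GeometryError(f"center {center} outside image {binary.shape}")
    px_per_um = 1.0 / cell.pixel_size_um
    if step_um * px_per_um < 1.0:
        raise ParamError("step_um below one pixel at this pixel size")
    if max_radius_um is None:
        max_radius_um = min(r0, rows - 1 - r0, c0, cols - 1 - c0) / px_per_um

    radii = np.arange(step_um, max_radius_um + 1e-9, step_um)
    counts = np.zeros(radii.size, int)
    for i, r_um in enumerate(radii):
        r_px = r_um * px_per_um
        n_theta = max(16, int(np.ceil(2 * np.pi * r_px)))
        theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
        rr = np.rint(r0 + r_px * np.sin(theta)).astype(int)
        cc = np.rint(c0 + r_px * np.cos(theta)).astype(int)
        inside = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        fg = np.zeros(n_theta, bool)
        fg[inside] = binary[rr[inside], cc[inside]]
        if fg.all():
            counts[i] = 1
        else:
            starts = fg & ~np.roll(fg, 1)       # circular run starts
            counts[i] = int(starts.sum())
    return ShollProfile(center=(float(r0), float(c0)),
                        radii_um=radii, intersections=counts)


def count_cells(max_projections: list[np.ndarray], pixel_size_um: float,
                n_projections: int = 3, field_um: float = 443.0,
                min_soma_radius_um: float = 3.0) -> dict:
    """Mean cell count per field over maximum-projection images.

    Each image runs through :func:`preprocess_microglia`; cells are the
    remaining 8-connected components at least as large as a disk of
    ``min_soma_radius_um`` (gating out detached process fragments).  Counts
    are taken per image (by convention three sections, 40 um apart) and
    averaged.
    """
    if len(max_projections) == 0:
        raise ParamError("no projection images given")
    if len(max_projections) != n_projections:
        raise ParamError(
            f"expected {n_projections} projections, got {len(max_projections)}"
        )
    min_area = np.pi * (min_soma_radius_um / pixel_size_um) ** 2
    counts = []
    for img in max_projections:
        binary = preprocess_microglia(img, pixel_size_um).binary
        lab = label(binary, connectivity=2)
        sizes = np.bincount(lab.ravel())[1:]
        counts.append(int((sizes >= min_area).sum()))
    return {
        "per_image": counts,
        "mean": float(np.mean(counts)),
        "field_um": field_um,
    }


def fov_from_zoom(base_fov_um: float = 443.0, zoom: float = 2.5) -> float:
    """Field of view at a given optical zoom (443 um base, 177.2 um at 2.5x)."""
    if zoom <= 0:
        raise ParamError("zoom must be positive")
    return base_fov_um / zoom
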