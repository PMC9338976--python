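"""Green-dominance filtering and ROI statistics for fluorescence-mode RGB images.

Fluorescence laparoscopes render indocyanine-green (ICG) signal as a green
overlay on an 8-bit RGB frame.  Perfused tissue therefore shows up as pixels
whose green channel dominates red and blue; white specular reflections
(R = G = B = 255) and neutral grays fail that test and are discarded before
any statistic is computed.  This module implements the pixel filter, the
rectangular region-of-interest (ROI) machinery, and per-ROI / pooled
intensity statistics on the 0-255 scale.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image as PILImage

from .exceptions import (
    BoundsError,
    EmptyROIError,
    ImageFormatError,
    QuantificationError,
    SamplingError,
)

logger = logging.getLogger(__name__)

#: Green level at or above which a pixel is treated as a saturated vessel
#: highlight and excluded from automatic ROI placement.
DEFAULT_VESSEL_CUTOFF = 250

#: Minimum fraction of an ROI's pixels that must survive the green-dominance
#: filter for the ROI to be considered representative.
DEFAULT_MIN_RETAINED_FRACTION = 0.5

#: Side length (pixels) of the square ROIs used for segment sampling.
DEFAULT_ROI_SIZE = 10

#: Number of ROIs sampled per intestinal segment.
DEFAULT_N_ROIS = 10


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB image held as three equal-shape channel matrices.

    Parameters
    ----------
    pixels : numpy.ndarray
        Array of shape ``(height, width, 3)`` and dtype ``uint8``.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError(
                f"expected an (H, W, 3) array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError("image must be at least 1x1")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise ImageFormatError(
                    f"channel values must be 8-bit integers in [0, 255], got dtype {px.dtype}"
                )
        object.__setattr__(self, "pixels", px)

    @classmethod
    def from_channels(cls, r: np.ndarray, g: np.ndarray, b: np.ndarray) -> "RGBImage":
        r, g, b = (np.asarray(c) for c in (r, g, b))
        if not (r.shape == g.shape == b.shape):
            raise ImageFormatError(
                f"channel shapes differ: R{r.shape} G{g.shape} B{b.shape}"
            )
        return cls(np.stack([r, g, b], axis=-1).astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def r(self) -> np.ndarray:
        return self.pixels[:, :, 0]

    @property
    def g(self) -> np.ndarray:
        return self.pixels[:, :, 1]

    @property
    def b(self) -> np.ndarray:
        return self.pixels[:, :, 2]


@dataclass(frozen=True)
class ROI:
    """A rectangular region of interest.

    Coordinates are 0-based and the rectangle is half-open:
    rows ``[row0, row0 + height)`` by columns ``[col0, col0 + width)``.
    """

    row0: int
    col0: int
    height: int = DEFAULT_ROI_SIZE
    width: int = DEFAULT_ROI_SIZE
    roi_id: str = ""

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise BoundsError(f"ROI must be at least 1x1, got {self.height}x{self.width}")
        if self.row0 < 0 or self.col0 < 0:
            raise BoundsError(f"ROI origin must be non-negative, got ({self.row0}, {self.col0})")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def check_within(self, image_height: int, image_width: int) -> None:
        if self.row0 + self.height > image_height or self.col0 + self.width > image_width:
            raise BoundsError(
                f"ROI {self.roi_id or ''}[rows {self.row0}:{self.row0 + self.height}, "
                f"cols {self.col0}:{self.col0 + self.width}] exceeds image "
                f"bounds {image_height}x{image_width}"
            )

    def overlaps(self, other: "ROI") -> bool:
        return not (
            self.row0 + self.height <= other.row0
            or other.row0 + other.height <= self.row0
            or self.col0 + self.width <= other.col0
            or other.col0 + other.width <= self.col0
        )


@dataclass(frozen=True)
class ROIStats:
    """Central-tendency and dispersion summary of one ROI's retained green values."""

    n_total: int
    n_retained: int
    mean: float
    median: float
    q1: float
    q3: float
    min: int
    max: int
    sd: float
    histogram: np.ndarray = field(repr=False)
    low_retention: bool = False

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_total

    def to_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "n_retained": self.n_retained,
            "mean": self.mean,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "min": int(self.min),
            "max": int(self.max),
            "sd": self.sd,
            "low_retention": self.low_retention,
        }
        return d


@dataclass
class SegmentQuantification:
    """Result of quantifying one intestinal segment from a set of ROIs.

    ``pooled_mean`` is the pixel-weighted mean over the union of retained
    pixels across all ROIs, not a mean of per-ROI means.
    """

    rois: list[ROI]
    roi_stats: list[ROIStats]
    pooled_values: np.ndarray
    pooled_mean: float
    n_total: int
    n_retained: int

    def to_dict(self) -> dict:
        return {
            "pooled_mean": self.pooled_mean,
            "n_total": self.n_total,
            "n_retained": self.n_retained,
            "n_rois": len(self.rois),
            "quartile_convention": "linear interpolation between order statistics",
            "rois": [
                {
                    "roi_id": roi.roi_id or str(i),
                    "row0": roi.row0,
                    "col0": roi.col0,
                    "height": roi.height,
                    "width": roi.width,
                    **st.to_dict(),
                }
                for i, (roi, st) in enumerate(zip(self.rois, self.roi_stats))
            ],
        }


def load_image(path: str | Path) -> RGBImage:
    """Load an 8-bit RGB image (PNG or JPEG) from ``path``.

    An alpha channel, if present, is dropped with a warning.  Palette images
    are expanded to RGB.  Bit depths other than 8 per channel are rejected.
    """
    path = Path(path)
    try:
        with PILImage.open(path) as im:
            mode = im.mode
            if mode in ("RGBA", "LA", "PA"):
                logger.warning("dropping alpha channel while loading %s", path)
                im = im.convert("RGB")
            elif mode == "P":
                im = im.convert("RGB")
            elif mode == "L":
                im = im.convert("RGB")
            elif mode != "RGB":
                raise ImageFormatError(
                    f"{path}: unsupported image mode {mode!r}; 8-bit RGB required"
                )
            arr = np.asarray(im, dtype=np.uint8)
    except ImageFormatError:
        raise
    except FileNotFoundError as exc:
        raise IOError(f"cannot read image file: {path}") from exc
    except Exception as exc:  # PIL raises a zoo of decode errors
        raise IOError(f"cannot decode image file {path}: {exc}") from exc
    return RGBImage(arr)


def save_image(img: RGBImage, path: str | Path) -> None:
    """Write ``img`` losslessly as PNG."""
    PILImage.fromarray(img.pixels, mode="RGB").save(Path(path), format="PNG")


def green_dominance_mask(img: RGBImage) -> np.ndarray:
    """Boolean retain-map: True where green strictly dominates red and blue.

    A pixel is retained iff ``G > R`` and ``G > B``.  Ties are discarded, so
    neutral grays and pure white specular reflections (255, 255, 255) never
    pass.  The returned array has the image's height x width shape.
    """
    g = img.g
    return (g > img.r) & (g > img.b)


def extract_roi_values(
    img: RGBImage, roi: ROI, mask: np.ndarray | None = None
) -> np.ndarray:
    """Green values of the retained pixels inside ``roi``, row-major order."""
    roi.check_within(img.height, img.width)
    if mask is None:
        mask = green_dominance_mask(img)
    if mask.shape != (img.height, img.width):
        raise ValueError(
            f"mask shape {mask.shape} does not match image {img.height}x{img.width}"
        )
    rs, cs = roi.slices
    sub_g = img.g[rs, cs]
    sub_m = mask[rs, cs]
    return sub_g[sub_m].astype(np.int64).ravel()


def roi_statistics(
    values: Sequence[int] | np.ndarray,
    n_total: int,
    min_retained_fraction: float = DEFAULT_MIN_RETAINED_FRACTION,
) -> ROIStats:
    """Summarise retained green intensities of one ROI.

    Quartiles and the median use linear interpolation between order
    statistics; ``sd`` is the sample standard deviation (n-1 denominator,
    0 for a single value).  Raises :class:`EmptyROIError` when no pixel
    survived the filter.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    v = np.asarray(values, dtype=np.int64)
    if v.size > n_total:
        raise ValueError(f"{v.size} values exceed n_total={n_total}")
    if v.size == 0:
        raise EmptyROIError("ROI contains no retained (green-dominant) pixels")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    hist = np.bincount(v, minlength=256)
    return ROIStats(
        n_total=int(n_total),
        n_retained=int(v.size),
        mean=float(v.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=int(v.min()),
        max=int(v.max()),
        sd=sd,
        histogram=hist,
        low_retention=bool(v.size / n_total < min_retained_fraction),
    )


def quantify_segment(
    img: RGBImage,
    rois: Sequence[ROI],
    mask: np.ndarray | None = None,
    min_retained_fraction: float = DEFAULT_MIN_RETAINED_FRACTION,
) -> SegmentQuantification:
    """Quantify ICG intensity of one segment from a set of ROIs.

    Each ROI is summarised individually; the segment-level mean pools all
    retained pixels of all ROIs with equal (pixel) weight.  ROIs left empty
    by the filter are kept in the result with ``n_retained = 0`` flags only
    if at least one ROI yields pixels; if every ROI is empty a
    :class:`QuantificationError` is raised.
    """
    if len(rois) < 1:
        raise ValueError("at least one ROI is required")
    if mask is None:
        mask = green_dominance_mask(img)
    per_roi: list[ROIStats] = []
    chunks: list[np.ndarray] = []
    n_total = 0
    for roi in rois:
        vals = extract_roi_values(img, roi, mask)
        n_total += roi.n_pixels
        if vals.size == 0:
            logger.warning("ROI %s retained no pixels; excluded from pooling", roi.roi_id or roi)
            per_roi.append(
                ROIStats(
                    n_total=roi.n_pixels, n_retained=0, mean=float("nan"),
                    median=float("nan"), q1=float("nan"), q3=float("nan"),
                    min=0, max=0, sd=float("nan"),
                    histogram=np.zeros(256, dtype=np.int64), low_retention=True,
                )
            )
            continue
        per_roi.append(roi_statistics(vals, roi.n_pixels, min_retained_fraction))
        chunks.append(vals)
    if not chunks:
        raise QuantificationError("no ROI retained any green-dominant pixel")
    pooled = np.concatenate(chunks)
    return SegmentQuantification(
        rois=list(rois),
        roi_stats=per_roi,
        pooled_values=pooled,
        pooled_mean=float(pooled.mean()),
        n_total=n_total,
        n_retained=int(pooled.size),
    )


def auto_sample_rois(
    img: RGBImage,
    mask: np.ndarray | None = None,
    n: int = DEFAULT_N_ROIS,
    size: int = DEFAULT_ROI_SIZE,
    seed: int | np.random.Generator | None = 0,
    vessel_cutoff: int = DEFAULT_VESSEL_CUTOFF,
    min_retained_fraction: float = DEFAULT_MIN_RETAINED_FRACTION,
    max_attempts: int = 10_000,
) -> list[ROI]:
    """Place ``n`` non-overlapping square ROIs over representative tissue.

    Mirrors the manual sampling protocol: rectangles avoid saturated vessel
    highlights (any pixel with ``G >= vessel_cutoff``) and must keep a
    retained-pixel fraction of at least ``min_retained_fraction``.  Placement
    is rejection sampling, deterministic for a given ``seed``.
    """
    if n < 1 or size < 1:
        raise ValueError("n and size must be >= 1")
    if img.height < size or img.width < size:
        raise SamplingError(
            f"image {img.height}x{img.width} cannot hold a {size}x{size} ROI"
        )
    if mask is None:
        mask = green_dominance_mask(img)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    placed: list[ROI] = []
    g = img.g
    for _ in range(max_attempts):
        if len(placed) == n:
            break
        r0 = int(rng.integers(0, img.height - size + 1))
        c0 = int(rng.integers(0, img.width - size + 1))
        cand = ROI(r0, c0, size, size, roi_id=f"auto{len(placed) + 1}")
        rs, cs = cand.slices
        if (g[rs, cs] >= vessel_cutoff).any():
            continue
        if mask[rs, cs].mean() < min_retained_fraction:
            continue
        if any(cand.overlaps(p) for p in placed):
            continue
        placed.append(cand)
    if len(placed) < n:
        raise SamplingError(
            f"placed only {len(placed)} of {n} ROIs within {max_attempts} attempts"
        )
    return placed


def export_pixels(
    img: RGBImage,
    rois: Sequence[ROI],
    path: str | Path,
    mask: np.ndarray | None = None,
) -> int:
    """Export retained pixels inside ``rois`` to a CSV table.

    One row per retained pixel (``row,col,green`` in absolute image
    coordinates), followed by a ``#``-prefixed summary block so the file
    re-parses to exactly the data rows.  Returns the number of rows written.
    """
    if mask is None:
        mask = green_dominance_mask(img)
    rows: list[tuple[int, int, int]] = []
    for roi in rois:
        roi.check_within(img.height, img.width)
        rs, cs = roi.slices
        sub = mask[rs, cs]
        rr, cc = np.nonzero(sub)
        for i, j in zip(rr, cc):
            rows.append((roi.row0 + int(i), roi.col0 + int(j), int(img.g[roi.row0 + i, roi.col0 + j])))
    if not rows:
        raise EmptyROIError("nothing to export: no retained pixels in the given ROIs")
    values = np.array([g for _, _, g in rows])
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["row", "col", "green"])
            w.writerows(rows)
            fh.write(f"# n_retained,{len(rows)}\n")
            fh.write(f"# mean,{values.mean():.6f}\n")
            fh.write(f"# sd,{values.std(ddof=1) if len(rows) > 1 else 0.0:.6f}\n")
            fh.write(f"# min,{values.min()}\n")
            fh.write(f"# max,{values.max()}\n")
    except OSError as exc:
        raise IOError(f"cannot write pixel export to {path}: {exc}") from exc
    return len(rows)


def render_report(
    img: RGBImage,
    quant: SegmentQuantification,
    out_dir: str | Path,
    basename: str = "segment",
) -> dict[str, Path]:
    """Write the report bundle for one quantified segment.

    Produces four files in ``out_dir``: the image with ROI rectangles
    overlaid, a boxplot of per-ROI green values, a histogram of the pooled
    values, and a JSON summary of the central-tendency statistics.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create report directory {out_dir}: {exc}") from exc

    paths = {
        "overlay": out_dir / f"{basename}_overlay.png",
        "boxplot": out_dir / f"{basename}_boxplot.png",
        "histogram": out_dir / f"{basename}_histogram.png",
        "summary": out_dir / f"{basename}_summary.json",
    }

    # Overlay: write the raster back at native resolution with rectangles burned in.
    overlay = img.pixels.copy()
    for roi in quant.rois:
        r1, c1 = roi.row0, roi.col0
        r2, c2 = roi.row0 + roi.height - 1, roi.col0 + roi.width - 1
        overlay[r1, c1 : c2 + 1] = (255, 255, 0)
        overlay[r2, c1 : c2 + 1] = (255, 255, 0)
        overlay[r1 : r2 + 1, c1] = (255, 255, 0)
        overlay[r1 : r2 + 1, c2] = (255, 255, 0)
    PILImage.fromarray(overlay, mode="RGB").save(paths["overlay"])

    mask = green_dominance_mask(img)
    per_roi_values = [
        extract_roi_values(img, roi, mask) for roi in quant.rois
    ]
    fig, ax = plt.subplots(figsize=(max(4, len(per_roi_values)), 4))
    ax.boxplot(
        [v if v.size else np.array([np.nan]) for v in per_roi_values],
        tick_labels=[roi.roi_id or str(i + 1) for i, roi in enumerate(quant.rois)],
    )
    ax.set_ylabel("green intensity (0-255)")
    ax.set_xlabel("ROI")
    fig.tight_layout()
    fig.savefig(paths["boxplot"], metadata={"Software": None})
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(quant.pooled_values, bins=np.arange(257) - 0.5)
    ax.set_xlabel("green intensity (0-255)")
    ax.set_ylabel("pixel count")
    fig.tight_layout()
    fig.savefig(paths["histogram"], metadata={"Software": None})
    plt.close(fig)

    with open(paths["summary"], "w") as fh:
        json.dump(quant.to_dict(), fh, indent=2)
    return paths


def read_roi_csv(path: str | Path) -> list[ROI]:
    """Read an ROI specification CSV with columns roi_id,row0,col0,height,width."""
    rois: list[ROI] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"roi_id", "row0", "col0", "height", "width"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: ROI file must have columns roi_id,row0,col0,height,width"
            )
        for line in reader:
            rois.append(
                ROI(
                    row0=int(line["row0"]),
                    col0=int(line["col0"]),
                    height=int(line["height"]),
                    width=int(line["width"]),
                    roi_id=line["roi_id"],
                )
            )
    return rois


def write_roi_csv(rois: Sequence[ROI], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["roi_id", "row0", "col0", "height", "width"])
        for i, roi in enumerate(rois):
            w.writerow([roi.roi_id or str(i + 1), roi.row0, roi.col0, roi.height, roi.width])
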