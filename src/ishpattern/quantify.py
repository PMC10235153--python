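"""ROI densitometry of ISH section images.

Measurement follows the ImageJ-style workflow used for in situ hybridization
(ISH) sections: the grayscale image is inverted so that stronger staining
(more transcript) gives *higher* values, the mean gray value of each region
of interest (ROI) is taken, and that mean is normalized to a same-sized
background reference region (``REF``) on the same section.  Replicate
measurements of one ROI are modelled as small re-placements of the rectangle
(uniform pixel jitter), then averaged to one value per section x ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PLANES",
    "PLANE_ROIS",
    "ROI_NAMES",
    "SectionImage",
    "Roi",
    "invert_image",
    "mean_gray",
    "relative_intensity",
    "measure_dataset",
    "aggregate_measurements",
    "read_roi_table",
    "write_roi_table",
    "read_section_image",
    "write_section_image",
    "load_image_dir",
]

PLANES = ("rostral", "middle", "caudal")

#: Expression ROIs present on each coronal plane; every plane also carries REF.
PLANE_ROIS = {
    "rostral": ("RM", "RL"),
    "middle": ("MM", "MC", "ML"),
    "caudal": ("CM", "CL"),
}

ROI_NAMES = ("RM", "RL", "MM", "MC", "ML", "CM", "CL", "REF")

ROI_TABLE_COLUMNS = ["image_id", "plane", "roi_name", "x", "y", "width", "height"]

MEASUREMENT_COLUMNS = [
    "gene",
    "section_id",
    "plane",
    "roi_name",
    "replicate",
    "raw_mean",
    "ref_mean",
    "rel_intensity",
]


@dataclass
class SectionImage:
    """One coronal section: a 2-D grid of pixel intensities plus metadata.

    Pixels are stored stain-space up (dark staining on light tissue) exactly
    as acquired; :func:`invert_image` produces the intensity-space view used
    for measurement.
    """

    pixels: np.ndarray
    bit_depth: int
    plane: str
    section_id: str
    gene: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}, got {self.plane!r}")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > self.max_value
        ):
            raise ValueError(
                f"pixel values outside [0, {self.max_value}] for {self.bit_depth}-bit image"
            )

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Roi:
    """Axis-aligned pixel rectangle, 0-based, half-open ([x, x+w) x [y, y+h))."""

    name: str
    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"ROI {self.name!r} has non-positive area")

    @property
    def area(self) -> int:
        return self.width * self.height

    def fits(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return 0 <= self.x and 0 <= self.y and self.x + self.width <= w and self.y + self.height <= h


def invert_image(img: SectionImage) -> SectionImage:
    """Invert so the strongest staining becomes the brightest signal.

    Every pixel v maps to ``(2**bit_depth - 1) - v``; metadata is preserved.
    The operation is an involution.
    """
    inverted = img.max_value - img.pixels
    return replace(img, pixels=inverted)


def mean_gray(img: SectionImage, roi: Roi) -> float:
    """Exact arithmetic mean gray value of ``roi`` (no resampling)."""
    if not roi.fits(img.shape):
        raise ValueError(
            f"ROI {roi.name!r} at ({roi.x},{roi.y}) size {roi.width}x{roi.height} "
            f"does not fit image of shape {img.shape}"
        )
    patch = img.pixels[roi.y : roi.y + roi.height, roi.x : roi.x + roi.width]
    return float(patch.mean(dtype=np.float64))


def relative_intensity(raw_mean: float, ref_mean: float, *, mode: str = "ratio") -> float:
    """Normalize an ROI mean to its section's reference-region mean.

    The default is the ratio ``raw_mean / ref_mean`` (scale-invariant between
    slides); ``mode="subtract"`` gives ``raw_mean - ref_mean`` instead.
    """
    if mode == "ratio":
        if ref_mean <= 0:
            raise ValueError(
                f"degenerate reference mean {ref_mean} (must be > 0 for ratio "
                "normalization; the reference region may be saturated)"
            )
        return raw_mean / ref_mean
    if mode == "subtract":
        return raw_mean - ref_mean
    raise ValueError(f"unknown normalization mode {mode!r}")


def _jittered(roi: Roi, shape: tuple[int, int], jitter_px: int, rng: np.random.Generator) -> Roi:
    """Uniform integer offset within +/- jitter_px, clamped so the ROI stays inside."""
    if jitter_px == 0:
        return roi
    dx = int(rng.integers(-jitter_px, jitter_px + 1))
    dy = int(rng.integers(-jitter_px, jitter_px + 1))
    h, w = shape
    x = min(max(roi.x + dx, 0), w - roi.width)
    y = min(max(roi.y + dy, 0), h - roi.height)
    return replace(roi, x=x, y=y)


def measure_dataset(
    images: Mapping[str, SectionImage],
    roi_table: pd.DataFrame,
    params=None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Measure every ROI of every section; one row per replicate.

    For each (section, ROI) the configured number of replicates is recorded.
    Each replicate re-places both the ROI and the section's REF rectangle with
    an independent uniform jitter of at most ``params.jitter_px`` pixels,
    measures the mean gray value on the *inverted* image, and normalizes the
    ROI mean to the REF mean.

    Parameters
    ----------
    images
        Mapping from ``image_id`` (as referenced in the ROI table) to sections.
    roi_table
        DataFrame with columns ``image_id, plane, roi_name, x, y, width, height``.
    params
        :class:`~ishpattern.stats.AnalysisParams`; defaults are used when None.
    rng
        Generator or integer seed for replicate jitter placement.
    """
    from .stats import AnalysisParams  # local import to avoid a cycle

    if params is None:
        params = AnalysisParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    missing = set(roi_table["image_id"]) - set(images)
    if missing:
        raise ValueError(f"ROI table references missing images: {sorted(missing)}")

    rows = []
    for image_id, group in roi_table.groupby("image_id", sort=True):
        img = images[image_id]
        inv = invert_image(img)
        rois = {
            r.roi_name: Roi(r.roi_name, int(r.x), int(r.y), int(r.width), int(r.height))
            for r in group.itertuples()
        }
        if "REF" not in rois:
            raise ValueError(f"section {image_id!r} has no REF reference region")
        for roi in rois.values():
            if not roi.fits(img.shape):
                raise ValueError(f"ROI {roi.name!r} escapes image {image_id!r}")
        ref = rois["REF"]
        for name in sorted(n for n in rois if n != "REF"):
            roi = rois[name]
            for rep in range(1, params.n_replicates + 1):
                raw = mean_gray(inv, _jittered(roi, img.shape, params.jitter_px, rng))
                ref_mean = mean_gray(inv, _jittered(ref, img.shape, params.jitter_px, rng))
                rows.append(
                    {
                        "gene": img.gene,
                        "section_id": img.section_id,
                        "plane": img.plane,
                        "roi_name": name,
                        "replicate": rep,
                        "raw_mean": raw,
                        "ref_mean": ref_mean,
                        "rel_intensity": relative_intensity(
                            raw, ref_mean, mode=params.normalization
                        ),
                    }
                )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def aggregate_measurements(records: pd.DataFrame) -> pd.DataFrame:
    """Average replicates to one relative intensity per (section, ROI).

    Aggregating before testing keeps the sampling unit at the section level
    and avoids pseudoreplication of within-section re-reads.
    """
    agg = (
        records.groupby(["gene", "section_id", "plane", "roi_name"], sort=True)
        .agg(value=("rel_intensity", "mean"), n_replicates=("replicate", "size"))
        .reset_index()
    )
    return agg


# ---------------------------------------------------------------------------
# File I/O (TIFF / PNG images, CSV ROI tables)

def read_roi_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(ROI_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"ROI table {path} lacks columns: {sorted(missing)}")
    return table[ROI_TABLE_COLUMNS]


def write_roi_table(table: pd.DataFrame, path: str | Path) -> None:
    table[ROI_TABLE_COLUMNS].to_csv(path, index=False)


def write_section_image(img: SectionImage, path: str | Path) -> None:
    """Write a single-channel image; format chosen by suffix (.tif/.tiff/.png)."""
    path = Path(path)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    arr = img.pixels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray(arr).save(path)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")


def read_section_image(
    path: str | Path, plane: str, section_id: str, gene: str = ""
) -> SectionImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return SectionImage(arr, bit_depth, plane, section_id, gene)


def load_image_dir(directory: str | Path, roi_table: pd.DataFrame) -> dict[str, SectionImage]:
    """Load every image referenced by ``roi_table`` from ``directory``.

    Files are matched by stem (``{image_id}.tif`` or ``.png``); plane is taken
    from the table and gene from the leading token of the image id.
    """
    directory = Path(directory)
    images: dict[str, SectionImage] = {}
    meta = roi_table[["image_id", "plane"]].drop_duplicates()
    for image_id, plane in meta.itertuples(index=False):
        for suffix in (".tif", ".tiff", ".png"):
            candidate = directory / f"{image_id}{suffix}"
            if candidate.exists():
                gene = str(image_id).split("_")[0]
                images[image_id] = read_section_image(candidate, plane, str(image_id), gene)
                break
        else:
            raise FileNotFoundError(f"no image file for section {image_id!r} in {directory}")
    return images
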