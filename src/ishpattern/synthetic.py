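"""Seeded synthetic ISH section generator with ground truth.

Emulates the quantified study design: coronal sections of the embryonic
nucleus magnocellularis at three rostro-caudal planes, with plane-specific
ROI sets (RM/RL rostral, MM/MC/ML middle, CM/CL caudal) plus a background
reference region per section.  Rendering is stain-space (NBT/BCIP-like: more
transcript = darker pixels)::

    pixel = background_level - stain_gain * level * section_jitter + pixel_noise

clipped to the bit-depth range and rounded.  Two noise tiers: a multiplicative
per-section jitter shared by all ROIs of a section (biological variability
across slices/animals — this is what inference runs on) and additive per-pixel
Gaussian noise (camera/stain granularity).

Stain patches are painted with a margin around the nominal ROI rectangle, so
replicate measurements that re-place the ROI by a few pixels stay on
uniformly stained tissue.

Presets encode the reported E13 expression patterns of the five genes; their
numeric levels were fixed once so the default three-sections-per-plane design
recovers each pattern with high probability, and are frozen here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .patterns import EXPRESSION_ROIS, pattern_from_levels
from .quantify import (
    PLANE_ROIS,
    PLANES,
    ROI_TABLE_COLUMNS,
    Roi,
    SectionImage,
    write_roi_table,
    write_section_image,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "PRESETS",
    "make_preset",
    "roi_layout",
    "generate_section",
    "generate_dataset",
]

#: Stain is painted this many pixels beyond the ROI rectangle on every side.
STAIN_MARGIN = 4
#: Horizontal gap between stain patches.
PATCH_GAP = 8
#: Left/top inset of the first patch.
LAYOUT_INSET = 10

_PLANE_INDEX = {p: i for i, p in enumerate(PLANES)}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterisation of one synthetic dataset.

    ``roi_levels`` maps the seven expression ROIs to dimensionless expected
    expression levels (REF carries no level: it is unstained background).
    Intensity-scale parameters are in pixel-value units of the chosen bit
    depth.
    """

    roi_levels: Mapping[str, float]
    background_level: float = 200.0
    stain_gain: float = 60.0
    sigma_section: float = 0.05
    sigma_pixel: float = 4.0
    n_sections_per_plane: int = 3
    n_replicates: int = 3
    image_height: int = 80
    image_width: int = 240
    roi_size: int = 40
    bit_depth: int = 8
    seed: int = 0
    gene: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi_levels", MappingProxyType(dict(self.roi_levels)))
        missing = [r for r in EXPRESSION_ROIS if r not in self.roi_levels]
        if missing:
            raise ValueError(f"roi_levels must cover all expression ROIs; missing {missing}")
        if any(v <= 0 for v in self.roi_levels.values()):
            raise ValueError("all ROI levels must be > 0")
        if self.sigma_section < 0 or self.sigma_pixel < 0:
            raise ValueError("sigma values must be >= 0")
        if self.n_sections_per_plane < 1:
            raise ValueError("n_sections_per_plane must be >= 1")
        if not 2 <= self.n_replicates <= 4:
            raise ValueError(f"n_replicates must be in [2, 4], got {self.n_replicates}")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        max_level = max(self.roi_levels.values())
        if self.background_level - self.stain_gain * max_level < 0:
            raise ValueError(
                "expected stain pixel value is negative before clipping "
                f"(background {self.background_level} - gain {self.stain_gain} x "
                f"level {max_level}); use a smaller stain_gain"
            )
        for plane in PLANES:
            for roi in roi_layout(self, plane):
                if not roi.fits((self.image_height, self.image_width)):
                    raise ValueError(
                        f"ROI {roi.name!r} does not fit a "
                        f"{self.image_height}x{self.image_width} image; "
                        "increase image size or reduce roi_size"
                    )

    @property
    def max_pixel(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass(frozen=True)
class GroundTruth:
    """Realized per-section truth for recovery tests."""

    image_id: str
    plane: str
    section_index: int
    section_jitter: float
    realized_levels: Mapping[str, float]
    pattern: str
    direction: str
    medial_lateral_direction: str


def roi_layout(config: SyntheticConfig, plane: str) -> list[Roi]:
    """Equal-area square ROIs for one plane, REF in the last slot.

    Patches are laid out left to right with a fixed stride; the middle plane
    uses four slots (MM, MC, ML, REF), rostral and caudal use slots 0, 1 and 3
    (RM/RL or CM/CL plus REF), keeping REF at the same position on every plane.
    """
    if plane not in PLANES:
        raise ValueError(f"plane must be one of {PLANES}, got {plane!r}")
    stride = config.roi_size + 2 * STAIN_MARGIN + PATCH_GAP
    y = (config.image_height - config.roi_size) // 2

    names = list(PLANE_ROIS[plane])
    slots = list(range(len(names))) + [3]  # REF always in slot 3
    rois = []
    for name, slot in zip(names + ["REF"], slots):
        x = LAYOUT_INSET + STAIN_MARGIN + slot * stride
        rois.append(Roi(name, x, y, config.roi_size, config.roi_size))
    return rois


# --- Presets -----------------------------------------------------------------
# Ordinal structure of the five genes' E13 NM patterns; numeric levels frozen
# after a one-time power calibration of the default design (3 sections/plane,
# sigma_section 0.05, gain 60 on background 200).

def _levels(rostral, middle, caudal):
    if isinstance(middle, (int, float)):
        middle = (middle, middle, middle)
    mm, mc, ml = middle
    return {
        "RM": rostral, "RL": rostral,
        "MM": mm, "MC": mc, "ML": ml,
        "CM": caudal, "CL": caudal,
    }


PRESETS: Mapping[str, Mapping[str, float]] = MappingProxyType(
    {
        # caudal > rostral, flat middle plane
        "atoh7_e13": _levels(0.15, 0.60, 1.20),
        # rostral > caudal, flat middle plane
        "hes1_e13": _levels(1.20, 0.70, 0.30),
        # rostral > caudal, medial-high gradient MM > MC > ML
        "pax6_e13": _levels(1.30, (1.00, 0.70, 0.40), 0.50),
        "eya2_e13": _levels(1.25, (1.00, 0.70, 0.40), 0.55),
        # rostral > caudal, medially restricted: MM > MC = ML
        "ebf3_e13": _levels(1.25, (0.90, 0.35, 0.35), 0.25),
        # null: every ROI at the same level
        "homogeneous_null": _levels(0.80, 0.80, 0.80),
    }
)


def make_preset(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Build the named preset configuration.

    ``overrides`` replace any :class:`SyntheticConfig` field (including
    ``roi_levels``) after the preset defaults are applied.
    """
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(PRESETS))}"
        )
    gene = name.split("_")[0]
    fields = {"roi_levels": dict(PRESETS[name]), "seed": seed, "gene": gene}
    fields.update(overrides)
    return SyntheticConfig(**fields)


# --- Generation --------------------------------------------------------------

def _section_rng(config: SyntheticConfig, plane: str, section_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence((config.seed, _PLANE_INDEX[plane], section_index))
    return np.random.default_rng(ss)


def generate_section(
    config: SyntheticConfig,
    plane: str,
    section_index: int,
    rng: np.random.Generator | None = None,
) -> tuple[SectionImage, pd.DataFrame, GroundTruth]:
    """Render one section and its ROI table; deterministic in (config, plane, index)."""
    if rng is None:
        rng = _section_rng(config, plane, section_index)

    jitter = 1.0 + config.sigma_section * float(rng.standard_normal())
    jitter = max(jitter, 0.01)

    field_img = np.full(
        (config.image_height, config.image_width), config.background_level, dtype=np.float64
    )
    rois = roi_layout(config, plane)
    realized: dict[str, float] = {}
    for roi in rois:
        if roi.name == "REF":
            continue  # REF is untouched background tissue
        level = config.roi_levels[roi.name]
        realized[roi.name] = level * jitter
        y0 = roi.y - STAIN_MARGIN
        x0 = roi.x - STAIN_MARGIN
        y1 = roi.y + roi.height + STAIN_MARGIN
        x1 = roi.x + roi.width + STAIN_MARGIN
        field_img[y0:y1, x0:x1] = config.background_level - config.stain_gain * level * jitter

    if config.sigma_pixel > 0:
        field_img += config.sigma_pixel * rng.standard_normal(field_img.shape)

    pixels = np.clip(np.rint(field_img), 0, config.max_pixel)
    pixels = pixels.astype(np.uint8 if config.bit_depth == 8 else np.uint16)

    image_id = f"{config.gene}_{plane}_{section_index}"
    img = SectionImage(pixels, config.bit_depth, plane, image_id, config.gene)
    table = pd.DataFrame(
        [
            {
                "image_id": image_id,
                "plane": plane,
                "roi_name": roi.name,
                "x": roi.x,
                "y": roi.y,
                "width": roi.width,
                "height": roi.height,
            }
            for roi in rois
        ],
        columns=ROI_TABLE_COLUMNS,
    )
    pattern, direction, ml_direction = pattern_from_levels(dict(config.roi_levels))
    truth = GroundTruth(
        image_id=image_id,
        plane=plane,
        section_index=section_index,
        section_jitter=jitter,
        realized_levels=MappingProxyType(realized),
        pattern=pattern,
        direction=direction,
        medial_lateral_direction=ml_direction,
    )
    return img, table, truth


@dataclass
class SyntheticDataset:
    """A full simulated experiment: images, ROI table, ground truth, provenance."""

    config: SyntheticConfig
    images: dict[str, SectionImage]
    roi_table: pd.DataFrame
    ground_truth: list[GroundTruth]

    @property
    def pattern(self) -> str:
        return self.ground_truth[0].pattern

    def write(self, outdir: str | Path, image_format: str = "tif") -> None:
        """Write images ({gene}_{plane}_{i}.{fmt}), rois.csv and ground_truth.csv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for image_id, img in self.images.items():
            write_section_image(img, outdir / f"{image_id}.{image_format}")
        write_roi_table(self.roi_table, outdir / "rois.csv")
        truth_rows = []
        for gt in self.ground_truth:
            row = {
                "image_id": gt.image_id,
                "plane": gt.plane,
                "section_index": gt.section_index,
                "section_jitter": gt.section_jitter,
                "pattern": gt.pattern,
                "direction": gt.direction,
                "medial_lateral_direction": gt.medial_lateral_direction,
            }
            for roi, lvl in gt.realized_levels.items():
                row[f"level_{roi}"] = lvl
            truth_rows.append(row)
        pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate ``n_sections_per_plane`` sections per plane, deterministically."""
    images: dict[str, SectionImage] = {}
    tables = []
    truths = []
    for plane in PLANES:
        for i in range(config.n_sections_per_plane):
            img, table, truth = generate_section(config, plane, i)
            images[img.section_id] = img
            tables.append(table)
            truths.append(truth)
    roi_table = pd.concat(tables, ignore_index=True)
    return SyntheticDataset(config, images, roi_table, truths)
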