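"""Crown-sampling boxes, canopy pixel counts, and three-class size labels.

Individual crowns cannot be delineated in a semi-overlapping orchard, so each
tree's canopy is sampled inside a square box of side equal to the maximum
crown diameter centered on its planted position.  With 3 m boxes and 2 m
in-row spacing, neighboring boxes deliberately share a 1 m strip.  Canopy
pixels are counted per box, and trees are classified per parcel into
missing/weak (1), normal (2) and big (3) from the parcel's minimum, mean and
maximum counts:

    class 1:  min <= count < min + avg/5
    class 2:  min + avg/5 <= count < max - avg/5
    class 3:  max - avg/5 <= count <= max

Rules are evaluated in order 1, 2, 3 with the first match winning, which also
resolves the degenerate overlap that arises when max - min < 2*avg/5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .localization import TreeGrid
from .raster_io import ParcelImage, meters_to_pixels, pixel_to_geo
from .segmentation import CanopyMask


class TreeClass(IntEnum):
    MISSING_OR_WEAK = 1
    NORMAL = 2
    BIG = 3


@dataclass
class CrownBox:
    """One tree's sampling window: half-open pixel rectangle [r0,r1) x [c0,c1)."""

    tree_id: int
    row_index: int
    tree_index: int
    center: tuple[int, int]
    window: tuple[int, int, int, int]
    canopy_pixels: int | None = None

    @property
    def area_px(self) -> int:
        r0, r1, c0, c1 = self.window
        return (r1 - r0) * (c1 - c0)

    def canopy_area_m2(self, resolution: float) -> float:
        if self.canopy_pixels is None:
            raise ValueError("canopy_pixels not yet counted")
        return self.canopy_pixels * resolution ** 2


@dataclass(frozen=True)
class ClassThresholds:
    """Per-parcel canopy statistics (pixels) and the derived class boundaries.

    ``t1`` and ``t2`` are always recomputed from min/avg/max, never stored.
    """

    min_value: float
    avg_value: float
    max_value: float

    def __post_init__(self) -> None:
        if not (self.min_value <= self.avg_value <= self.max_value):
            raise ValueError(
                f"need min <= avg <= max, got ({self.min_value}, "
                f"{self.avg_value}, {self.max_value})")

    @property
    def t1(self) -> float:
        return self.min_value + self.avg_value / 5.0

    @property
    def t2(self) -> float:
        return self.max_value - self.avg_value / 5.0

    @property
    def degenerate(self) -> bool:
        return self.t1 > self.t2


def build_boxes(grid: TreeGrid, max_crown_diameter: float,
                img: ParcelImage) -> list[CrownBox]:
    """Build one square sampling box per tree, clipped to the raster.

    Side ``s = meters_to_pixels(max_crown_diameter)``; the window is anchored
    at ``center - floor(s/2)`` (an even side cannot center exactly on one
    pixel; the bias is at most half a pixel).
    """
    if max_crown_diameter <= 0:
        raise ValueError("max_crown_diameter must be > 0")
    if grid.n_trees == 0:
        raise ValueError("empty tree grid")
    s = meters_to_pixels(max_crown_diameter, img.resolution)
    n_rows_px, n_cols_px = img.shape
    boxes = []
    for tree_id, (ri, ti, (r, c)) in enumerate(grid.positions):
        r0, c0 = r - s // 2, c - s // 2
        window = (max(r0, 0), min(r0 + s, n_rows_px),
                  max(c0, 0), min(c0 + s, n_cols_px))
        boxes.append(CrownBox(tree_id=tree_id, row_index=ri, tree_index=ti,
                              center=(r, c), window=window))
    return boxes


def count_canopy(mask: CanopyMask, boxes: list[CrownBox]) -> list[CrownBox]:
    """Fill ``canopy_pixels`` for each box by counting mask-1 pixels inside it.

    Pixels in overlapping strips contribute to every box containing them.
    """
    m = mask.mask
    for box in boxes:
        r0, r1, c0, c1 = box.window
        if not (0 <= r0 <= r1 <= m.shape[0] and 0 <= c0 <= c1 <= m.shape[1]):
            raise ValueError(f"box {box.tree_id} window outside mask raster")
        box.canopy_pixels = int(m[r0:r1, c0:c1].sum())
    return boxes


def compute_thresholds(counts) -> ClassThresholds:
    """Per-parcel min / arithmetic-mean / max canopy counts."""
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0:
        raise ValueError("no canopy counts: cannot derive class thresholds")
    th = ClassThresholds(min_value=float(counts.min()),
                         avg_value=float(counts.mean()),
                         max_value=float(counts.max()))
    if th.degenerate:
        warnings.warn(
            f"degenerate thresholds (t1={th.t1:.2f} > t2={th.t2:.2f}): canopy "
            "spread is narrower than 2*avg/5; ordered rules still apply",
            stacklevel=2)
    return th


def classify_tree(count: float, th: ClassThresholds) -> TreeClass:
    """Assign the three-way size class; ordered rules, first match wins."""
    if count < th.min_value or count > th.max_value:
        raise ValueError(
            f"count {count} outside parcel range [{th.min_value}, {th.max_value}]")
    if count < th.t1:
        return TreeClass.MISSING_OR_WEAK
    if count < th.t2:
        return TreeClass.NORMAL
    return TreeClass.BIG


def classify_boxes(boxes: list[CrownBox],
                   th: ClassThresholds | None = None
                   ) -> tuple[list[TreeClass], ClassThresholds]:
    """Classify every counted box; thresholds default to this parcel's own."""
    counts = [b.canopy_pixels for b in boxes]
    if any(c is None for c in counts):
        raise ValueError("boxes must be counted before classification")
    if th is None:
        th = compute_thresholds(counts)
    return [classify_tree(c, th) for c in counts], th


def tree_table(boxes: list[CrownBox], classes: list[TreeClass],
               img: ParcelImage) -> pd.DataFrame:
    """Per-tree output table: identifiers, position, canopy size and class."""
    rows = []
    for box, cls in zip(boxes, classes, strict=True):
        x, y = pixel_to_geo(box.center, img.transform)
        rows.append((box.tree_id, box.row_index, box.tree_index,
                     box.center[0], box.center[1], x, y, box.canopy_pixels,
                     box.canopy_area_m2(img.resolution), int(cls)))
    return pd.DataFrame(rows, columns=[
        "tree_id", "row_index", "tree_index", "px_row", "px_col", "x", "y",
        "canopy_pixels", "canopy_m2", "class"])
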