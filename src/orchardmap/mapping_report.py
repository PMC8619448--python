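"""Classified-map rendering and per-row / per-parcel summaries.

The classified map starts from an all-zero raster and paints each tree's box
with its class value (1 missing/weak, 2 normal, 3 big; 0 background).  Where
boxes overlap, a pixel takes the class of the box whose center is nearest,
ties going to the lower tree id — a rule independent of iteration order, so
re-rendering with permuted boxes is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crown_classify import CrownBox, TreeClass

#: Map legend: red = missing/weak, blue = normal, yellow = big.
CLASS_COLORS: dict[int, tuple[int, int, int]] = {
    0: (0, 0, 0),
    int(TreeClass.MISSING_OR_WEAK): (255, 0, 0),
    int(TreeClass.NORMAL): (0, 0, 255),
    int(TreeClass.BIG): (255, 255, 0),
}


@dataclass
class ClassifiedMap:
    """Integer raster of box class values over a zero background."""

    values: np.ndarray
    color_table: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(CLASS_COLORS))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if not np.isin(self.values, (0, 1, 2, 3)).all():
            raise ValueError("class map values must be in {0, 1, 2, 3}")


def render_class_map(boxes: list[CrownBox], classes: list[TreeClass],
                     shape: tuple[int, int]) -> ClassifiedMap:
    """Paint each box's class over an all-zero raster of the given shape."""
    values = np.zeros(shape, dtype=np.uint8)
    best_d2 = np.full(shape, np.inf)
    order = np.argsort([b.tree_id for b in boxes], kind="stable")
    for idx in order:
        box, cls = boxes[idx], classes[idx]
        r0, r1, c0, c1 = box.window
        if not (0 <= r0 <= r1 <= shape[0] and 0 <= c0 <= c1 <= shape[1]):
            raise ValueError(f"box {box.tree_id} outside the raster")
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        d2 = (rr - box.center[0]) ** 2.0 + (cc - box.center[1]) ** 2.0
        win = best_d2[r0:r1, c0:c1]
        closer = d2 < win  # strict: equal distance keeps the lower tree_id
        values[r0:r1, c0:c1][closer] = int(cls)
        win[closer] = d2[closer]
    return ClassifiedMap(values=values)


def summarize(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-row class counts plus parcel totals.

    Returns ``(per_row, parcel)`` where ``per_row`` has one line per planting
    row (class counts, tree count, canopy pixel sum) and ``parcel`` holds the
    orchard-level totals.
    """
    if table.empty:
        raise ValueError("empty tree table")
    per_row = (
        table.assign(
            n_missing_weak=(table["class"] == 1).astype(int),
            n_normal=(table["class"] == 2).astype(int),
            n_big=(table["class"] == 3).astype(int),
        )
        .groupby("row_index", as_index=False)
        .agg(n_trees=("tree_id", "size"),
             n_missing_weak=("n_missing_weak", "sum"),
             n_normal=("n_normal", "sum"),
             n_big=("n_big", "sum"),
             canopy_pixels=("canopy_pixels", "sum"))
        .sort_values("row_index", ignore_index=True)
    )
    parcel = {
        "n_trees": int(len(table)),
        "n_rows": int(table["row_index"].nunique()),
        "n_missing_weak": int((table["class"] == 1).sum()),
        "n_normal": int((table["class"] == 2).sum()),
        "n_big": int((table["class"] == 3).sum()),
        "canopy_pixels": int(table["canopy_pixels"].sum()),
        "canopy_m2": float(table["canopy_m2"].sum()),
    }
    return per_row, parcel
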