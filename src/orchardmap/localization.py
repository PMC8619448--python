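"""Planting-grid tree localization from three anchor trunks.

Orchard planting follows a uniform lattice: a fixed intra-row spacing between
trunks and a fixed inter-row spacing between rows.  Given the pixel positions
of the first two trunks of row 1 and the first trunk of row 2, the lattice
directions come from the anchor geometry while the step *magnitudes* come from
the surveyed distances (anchors are clicked by a human and carry pixel-level
error; the distances are exact).  Candidate centers are generated over lattice
indices extended in both directions and kept wherever they land on an
in-bounds, non-nodata pixel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster_io import Affine, ParcelImage, meters_to_pixels, pixel_to_geo


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PlantingPattern:
    """Three anchor trunk positions plus the surveyed planting distances.

    Anchors are ``(row, col)`` pixel coordinates (fractions allowed);
    distances are meters.  Study values: 2 m between trunks within a row,
    6 m between rows, 3 m maximum crown diameter.
    """

    anchor_r1t1: tuple[float, float]
    anchor_r1t2: tuple[float, float]
    anchor_r2t1: tuple[float, float]
    d_intra: float = 2.0
    d_inter: float = 6.0
    max_crown_diameter: float = 3.0

    def __post_init__(self) -> None:
        if self.d_intra <= 0 or self.d_inter <= 0 or self.max_crown_diameter <= 0:
            raise ValueError("planting distances and crown diameter must be > 0")
        anchors = {tuple(self.anchor_r1t1), tuple(self.anchor_r1t2),
                   tuple(self.anchor_r2t1)}
        if len(anchors) != 3:
            raise ValueError("the three anchor positions must be distinct")


@dataclass
class TreeGrid:
    """All localized tree centers, indexed by (row_index, tree_index)."""

    positions: list[tuple[int, int, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r, t) for r, t, _ in self.positions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (row_index, tree_index) pairs")

    @property
    def n_trees(self) -> int:
        return len(self.positions)

    @property
    def n_rows(self) -> int:
        return len({r for r, _, _ in self.positions})

    @property
    def trees_per_row(self) -> list[int]:
        counts: dict[int, int] = {}
        for r, _, _ in self.positions:
            counts[r] = counts.get(r, 0) + 1
        return [counts[r] for r in sorted(counts)]

    def centers(self) -> np.ndarray:
        """(n, 2) array of (row, col) pixel centers, in position order."""
        return np.array([c for _, _, c in self.positions], dtype=int).reshape(-1, 2)

    def to_dataframe(self, transform: Affine | None = None) -> pd.DataFrame:
        rows = []
        for tree_id, (r, t, (pr, pc)) in enumerate(self.positions):
            x, y = pixel_to_geo((pr, pc), transform) if transform else (np.nan, np.nan)
            rows.append((tree_id, r, t, pr, pc, x, y))
        return pd.DataFrame(rows, columns=["tree_id", "row_index", "tree_index",
                                           "px_row", "px_col", "x", "y"])

    def to_geojson(self, transform: Affine, path: str | Path) -> Path:
        features = []
        for tree_id, (r, t, (pr, pc)) in enumerate(self.positions):
            x, y = pixel_to_geo((pr, pc), transform)
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {"tree_id": tree_id, "row_index": r,
                               "tree_index": t, "px_row": pr, "px_col": pc},
            })
        path = Path(path)
        path.write_text(json.dumps(
            {"type": "FeatureCollection", "features": features}, indent=1))
        return path


def localize_trees(pattern: PlantingPattern, img: ParcelImage) -> TreeGrid:
    """Generate the full grid of tree centers for a parcel.

    The in-row step is the unit vector from anchor r1t1 to r1t2 scaled to
    ``meters_to_pixels(d_intra)`` pixels; the row step likewise from r1t1 to
    r2t1 scaled to ``meters_to_pixels(d_inter)``.  The lattice is extended in
    both directions; a candidate is kept iff its rounded pixel is in-bounds
    and non-nodata.  Row and tree indices are renumbered to start at 0 from
    the minimal kept lattice indices.
    """
    res = img.resolution
    a1 = np.asarray(pattern.anchor_r1t1, dtype=float)
    du = np.asarray(pattern.anchor_r1t2, dtype=float) - a1
    dv = np.asarray(pattern.anchor_r2t1, dtype=float) - a1
    nu, nv = np.linalg.norm(du), np.linalg.norm(dv)
    if nu == 0 or nv == 0:
        raise ValueError("coincident anchors: zero-length step direction")
    u = du / nu * meters_to_pixels(pattern.d_intra, res)
    v = dv / nv * meters_to_pixels(pattern.d_inter, res)
    cross = u[0] * v[1] - u[1] * v[0]
    if abs(cross) < 1e-9:
        raise ValueError("collinear anchors: in-row and row directions coincide")

    n_rows_px, n_cols_px = img.shape
    r0 = int(_round_half_up(a1[0]))
    c0 = int(_round_half_up(a1[1]))
    if not (0 <= r0 < n_rows_px and 0 <= c0 < n_cols_px):
        raise ValueError("anchor r1t1 lies outside the raster")
    if img.nodata_mask[r0, c0]:
        raise ValueError("anchor r1t1 lies on a nodata pixel")

    # lattice index bounds: project the (slightly expanded) raster corners
    # onto the (u, v) basis
    basis = np.column_stack([u, v])
    corners = np.array([[-1.0, -1.0], [-1.0, n_cols_px], [n_rows_px, -1.0],
                        [n_rows_px, n_cols_px]]) - a1
    ij = np.linalg.solve(basis, corners.T)
    i_min, i_max = int(np.floor(ij[0].min())) - 1, int(np.ceil(ij[0].max())) + 1
    j_min, j_max = int(np.floor(ij[1].min())) - 1, int(np.ceil(ij[1].max())) + 1

    ii, jj = np.meshgrid(np.arange(i_min, i_max + 1),
                         np.arange(j_min, j_max + 1), indexing="ij")
    pts = (a1[None, :] + ii.reshape(-1, 1) * u[None, :]
           + jj.reshape(-1, 1) * v[None, :])
    rc = np.floor(pts + 0.5).astype(int)
    inb = ((rc[:, 0] >= 0) & (rc[:, 0] < n_rows_px)
           & (rc[:, 1] >= 0) & (rc[:, 1] < n_cols_px))
    keep = inb.copy()
    keep[inb] = ~img.nodata_mask[rc[inb, 0], rc[inb, 1]]
    if not keep.any():
        raise ValueError("no lattice candidate falls on a valid parcel pixel")

    ik, jk = ii.reshape(-1)[keep], jj.reshape(-1)[keep]
    rck = rc[keep]
    i_base, j_base = ik.min(), jk.min()
    order = np.lexsort((ik, jk))
    positions = [(int(jk[m] - j_base), int(ik[m] - i_base),
                  (int(rck[m, 0]), int(rck[m, 1]))) for m in order]
    return TreeGrid(positions=positions)


@dataclass(frozen=True)
class GridReport:
    """Tree-count bookkeeping for comparison with the field census."""

    n_rows: int
    trees_per_row: tuple[int, ...]
    total: int
    expected_count: int | None = None

    @property
    def count_matches(self) -> bool | None:
        if self.expected_count is None:
            return None
        return self.total == self.expected_count


def validate_grid(grid: TreeGrid, expected_count: int | None = None) -> GridReport:
    """Summarize a grid and, if a field tree count is given, flag mismatch."""
    return GridReport(n_rows=grid.n_rows,
                      trees_per_row=tuple(grid.trees_per_row),
                      total=grid.n_trees,
                      expected_count=expected_count)
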