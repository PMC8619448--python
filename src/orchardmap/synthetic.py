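"""Synthetic orchard scenes with full ground truth.

Generates georeferenced multispectral rasters that emulate the study
geometry: planting rows 6 m apart, trunks 2 m apart within rows, circular
crowns up to 3 m diameter (so neighboring crowns overlap by up to 1 m), an
occasional missing or weak tree, vegetation/soil spectral contrast with NDVI
around 0.7 vs 0.1, additive Gaussian noise, at 0.5 m/pixel.  Every scene
carries its ground truth — canopy mask, planted centers, per-tree crown
diameters, box counts and size classes — so each pipeline stage can be
scored offline.

The parcel is a (possibly rotated) rectangle padded by one crown radius
around the planting lattice; everything outside is either flagged nodata
(``background="nodata"``, the default, matching a clipped GeoTIFF) or filled
with a dark background spectrum (``background="fill"``), in which case the
scene holds three pixel strata and no nodata.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crown_classify import (ClassThresholds, build_boxes, classify_boxes,
                             count_canopy)
from .localization import PlantingPattern, TreeGrid
from .raster_io import (Affine, DEFAULT_BAND_NAMES, ParcelImage, load_mask,
                        load_parcel, write_mask, write_parcel)
from .segmentation import CanopyMask

# stratum codes in OrchardTruth.strata
STRATUM_BACKGROUND = 0
STRATUM_SOIL = 1
STRATUM_VEGETATION = 2

#: Default stratum spectra (blue, green, red, nir): NDVI ~0.71 for canopy,
#: ~0.10 for bare soil, near-black outside the parcel.
DEFAULT_BAND_MEANS: dict[str, tuple[float, ...]] = {
    "vegetation": (0.04, 0.08, 0.05, 0.30),
    "soil": (0.10, 0.14, 0.18, 0.22),
    "background": (0.01, 0.01, 0.01, 0.01),
}


@dataclass(frozen=True)
class CrownDiameterLaw:
    """Per-tree crown diameter distribution on [0, max diameter].

    ``p_missing`` is a point mass at zero diameter (missing/weak tree).  The
    remaining mass is ``uniform`` on [low, high], ``fixed`` at ``low``, or a
    discrete ``choice`` over ``values`` with ``probs``.
    """

    kind: str = "uniform"
    low: float = 1.8
    high: float = 3.0
    values: tuple[float, ...] = ()
    probs: tuple[float, ...] = ()
    p_missing: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_missing <= 1.0:
            raise ValueError("p_missing must be in [0, 1]")
        if self.kind not in ("uniform", "fixed", "choice"):
            raise ValueError(f"unknown diameter law kind {self.kind!r}")
        if self.kind == "choice" and len(self.values) == 0:
            raise ValueError("choice law needs values")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            d = np.full(n, float(self.low))
        elif self.kind == "uniform":
            d = rng.uniform(self.low, self.high, size=n)
        else:
            probs = np.asarray(self.probs, float) if self.probs else None
            d = rng.choice(np.asarray(self.values, float), size=n, p=probs)
        missing = rng.random(n) < self.p_missing
        d[missing] = 0.0
        return d


@dataclass(frozen=True)
class OrchardScenario:
    """Everything needed to generate one synthetic parcel deterministically."""

    n_rows: int = 10
    trees_per_row: int = 25
    d_intra: float = 2.0
    d_inter: float = 6.0
    max_crown_diameter: float = 3.0
    resolution: float = 0.5
    row_angle: float = 0.0
    crown_diameter_law: CrownDiameterLaw = field(
        default_factory=lambda: CrownDiameterLaw(p_missing=0.1))
    band_names: tuple[str, ...] = DEFAULT_BAND_NAMES
    band_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_BAND_MEANS.items()})
    noise_sd: float = 0.01
    background: str = "nodata"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.d_intra, self.d_inter, self.max_crown_diameter,
               self.resolution) <= 0:
            raise ValueError("distances and resolution must be > 0")
        if self.n_rows < 1 or self.trees_per_row < 1:
            raise ValueError("scene must hold at least one tree")
        if self.background not in ("nodata", "fill"):
            raise ValueError("background must be 'nodata' or 'fill'")
        nb = len(self.band_names)
        for stratum in ("vegetation", "soil", "background"):
            if len(self.band_means[stratum]) != nb:
                raise ValueError(
                    f"band_means[{stratum!r}] needs {nb} values")

    def spectral_separation_sds(self) -> float:
        """Vegetation/soil contrast in noise SDs: RMS per-band mean
        difference divided by the per-band noise SD."""
        d = (np.asarray(self.band_means["vegetation"])
             - np.asarray(self.band_means["soil"]))
        rms = float(np.sqrt(np.mean(d ** 2)))
        return math.inf if self.noise_sd == 0 else rms / self.noise_sd

    def with_separation_sds(self, sds: float) -> "OrchardScenario":
        """Scenario copy whose noise_sd gives the requested contrast."""
        d = (np.asarray(self.band_means["vegetation"])
             - np.asarray(self.band_means["soil"]))
        rms = float(np.sqrt(np.mean(d ** 2)))
        return replace(self, noise_sd=rms / sds)


@dataclass
class OrchardTruth:
    """A generated scene plus its complete ground truth."""

    image: ParcelImage
    canopy_truth: CanopyMask
    strata: np.ndarray
    centers: TreeGrid
    centers_float: np.ndarray
    pattern: PlantingPattern
    crown_diameters: np.ndarray
    true_counts: np.ndarray
    true_classes: np.ndarray
    thresholds: ClassThresholds
    scenario: OrchardScenario


def _round_half_up(a: np.ndarray) -> np.ndarray:
    return np.floor(a + 0.5).astype(int)


def generate_orchard(sc: OrchardScenario) -> OrchardTruth:
    """Generate one synthetic parcel with ground truth; deterministic per seed."""
    rng = np.random.default_rng(sc.seed)
    res = sc.resolution
    step_u = sc.d_intra / res          # px between trunks within a row
    step_v = sc.d_inter / res          # px between rows
    pad = sc.max_crown_diameter / (2 * res)  # crown radius, px
    if pad >= min(step_u, step_v):
        warnings.warn("crown radius exceeds the planting step; lattice "
                      "candidates beyond the row ends stay inside the parcel",
                      stacklevel=2)
    border = 2  # nodata/background frame, px

    # planting lattice in unrotated parcel coordinates (u along rows)
    extent_u = (sc.trees_per_row - 1) * step_u
    extent_v = (sc.n_rows - 1) * step_v
    theta = math.radians(sc.row_angle)
    cos_t, sin_t = math.cos(theta), math.sin(theta)

    # corners of the padded parcel rectangle, rotated into (row, col) space:
    # row = u*sin + v*cos, col = u*cos - v*sin
    def to_rc(u, v):
        return np.stack([u * sin_t + v * cos_t, u * cos_t - v * sin_t], axis=-1)

    corners = to_rc(np.array([-pad, -pad, extent_u + pad, extent_u + pad]),
                    np.array([-pad, extent_v + pad, -pad, extent_v + pad]))
    origin = corners.min(axis=0) - border
    size = np.ceil(corners.max(axis=0) - origin + border).astype(int) + 1
    n_rows_px, n_cols_px = int(size[0]), int(size[1])

    jj, ii = np.meshgrid(np.arange(sc.n_rows), np.arange(sc.trees_per_row),
                         indexing="ij")
    uu, vv = ii.ravel() * step_u, jj.ravel() * step_v
    centers_float = to_rc(uu, vv) - origin          # (n, 2) float (row, col)
    centers_int = _round_half_up(centers_float)

    # parcel membership by inverse rotation of the pixel grid
    pr, pc = np.meshgrid(np.arange(n_rows_px), np.arange(n_cols_px),
                         indexing="ij")
    rowf, colf = pr + origin[0], pc + origin[1]
    u_coord = rowf * sin_t + colf * cos_t
    v_coord = rowf * cos_t - colf * sin_t
    in_parcel = ((u_coord >= -pad) & (u_coord <= extent_u + pad)
                 & (v_coord >= -pad) & (v_coord <= extent_v + pad))

    diam = sc.crown_diameter_law.sample(rng, sc.n_rows * sc.trees_per_row)
    diam = np.minimum(diam, sc.max_crown_diameter)

    canopy = np.zeros((n_rows_px, n_cols_px), dtype=bool)
    for (cr, cc), d in zip(centers_float, diam):
        if d <= 0:
            continue
        r_px = d / (2 * res)
        r0 = max(int(math.floor(cr - r_px)) - 1, 0)
        r1 = min(int(math.ceil(cr + r_px)) + 2, n_rows_px)
        c0 = max(int(math.floor(cc - r_px)) - 1, 0)
        c1 = min(int(math.ceil(cc + r_px)) + 2, n_cols_px)
        wr, wc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        disk = (wr - cr) ** 2 + (wc - cc) ** 2 <= r_px ** 2
        canopy[r0:r1, c0:c1] |= disk
    canopy &= in_parcel

    strata = np.full((n_rows_px, n_cols_px), STRATUM_BACKGROUND, dtype=np.int8)
    strata[in_parcel] = STRATUM_SOIL
    strata[canopy] = STRATUM_VEGETATION

    nb = len(sc.band_names)
    bands = np.empty((nb, n_rows_px, n_cols_px), dtype=np.float32)
    means = {k: np.asarray(v, dtype=np.float32) for k, v in sc.band_means.items()}
    for b in range(nb):
        bands[b] = means["background"][b]
        bands[b][in_parcel] = means["soil"][b]
        bands[b][canopy] = means["vegetation"][b]
    if sc.noise_sd > 0:
        bands += rng.normal(0.0, sc.noise_sd, size=bands.shape).astype(np.float32)

    nodata_mask = (~in_parcel if sc.background == "nodata"
                   else np.zeros_like(in_parcel))
    if sc.background == "nodata":
        bands[:, nodata_mask] = -9999.0

    transform = Affine.north_up(res, 0.0, n_rows_px * res)
    image = ParcelImage(bands=bands, band_names=sc.band_names, resolution=res,
                        transform=transform, nodata_mask=nodata_mask,
                        nodata=-9999.0)
    truth_mask = CanopyMask(mask=canopy.astype(np.uint8),
                            nodata_mask=nodata_mask.copy())

    positions = [(int(jj.ravel()[m]), int(ii.ravel()[m]),
                  (int(centers_int[m, 0]), int(centers_int[m, 1])))
                 for m in range(centers_int.shape[0])]
    grid = TreeGrid(positions=positions)

    # centers_float ravel order is row-major over (row j, tree i)
    a_r1t1 = centers_float[0]
    a_r1t2 = (centers_float[1] if sc.trees_per_row > 1
              else a_r1t1 + to_rc(step_u, 0.0))
    a_r2t1 = (centers_float[sc.trees_per_row] if sc.n_rows > 1
              else a_r1t1 + to_rc(0.0, step_v))
    pattern = PlantingPattern(
        anchor_r1t1=tuple(a_r1t1), anchor_r1t2=tuple(a_r1t2),
        anchor_r2t1=tuple(a_r2t1),
        d_intra=sc.d_intra, d_inter=sc.d_inter,
        max_crown_diameter=sc.max_crown_diameter)

    boxes = build_boxes(grid, sc.max_crown_diameter, image)
    count_canopy(truth_mask, boxes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate thresholds possible at tiny n
        classes, thresholds = classify_boxes(boxes)
    true_counts = np.array([b.canopy_pixels for b in boxes])
    true_classes = np.array([int(c) for c in classes])

    return OrchardTruth(image=image, canopy_truth=truth_mask, strata=strata,
                        centers=grid, centers_float=centers_float,
                        pattern=pattern, crown_diameters=diam,
                        true_counts=true_counts, true_classes=true_classes,
                        thresholds=thresholds, scenario=sc)


def scenario_to_dict(sc: OrchardScenario) -> dict:
    d = asdict(sc)
    d["band_names"] = list(sc.band_names)
    d["band_means"] = {k: list(v) for k, v in sc.band_means.items()}
    law = d["crown_diameter_law"]
    law["values"] = list(law["values"])
    law["probs"] = list(law["probs"])
    return d


def scenario_from_dict(d: dict) -> OrchardScenario:
    d = dict(d)
    law = d.pop("crown_diameter_law", {})
    law = CrownDiameterLaw(
        kind=law.get("kind", "uniform"), low=law.get("low", 1.8),
        high=law.get("high", 3.0), values=tuple(law.get("values", ())),
        probs=tuple(law.get("probs", ())),
        p_missing=law.get("p_missing", 0.0))
    d["band_names"] = tuple(d.get("band_names", DEFAULT_BAND_NAMES))
    d["band_means"] = {k: tuple(v) for k, v in d.get(
        "band_means", DEFAULT_BAND_MEANS).items()}
    return OrchardScenario(crown_diameter_law=law, **d)


def write_fixture(truth: OrchardTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write a scene and its truth as a reloadable file set.

    Layout: ``image.tif`` (multiband GeoTIFF), ``truth_mask.tif`` (0/1),
    ``centers.geojson``, ``trees.csv`` (per-tree truth), ``scenario.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": write_parcel(truth.image, out_dir / "image.tif"),
        "mask": write_mask(truth.canopy_truth.mask, truth.image.transform,
                           out_dir / "truth_mask.tif",
                           nodata_mask=truth.canopy_truth.nodata_mask),
        "centers": truth.centers.to_geojson(truth.image.transform,
                                            out_dir / "centers.geojson"),
    }
    table = truth.centers.to_dataframe(truth.image.transform)
    table["crown_diameter_m"] = truth.crown_diameters
    table["canopy_pixels"] = truth.true_counts
    table["class"] = truth.true_classes
    trees_csv = out_dir / "trees.csv"
    table.to_csv(trees_csv, index=False)
    paths["trees"] = trees_csv
    scenario_yaml = out_dir / "scenario.yaml"
    scenario_yaml.write_text(
        yaml.safe_dump(scenario_to_dict(truth.scenario), sort_keys=True))
    paths["scenario"] = scenario_yaml
    anchors = out_dir / "anchors.json"
    anchors.write_text(json.dumps({
        "anchor_r1t1": list(truth.pattern.anchor_r1t1),
        "anchor_r1t2": list(truth.pattern.anchor_r1t2),
        "anchor_r2t1": list(truth.pattern.anchor_r2t1),
        "d_intra": truth.pattern.d_intra,
        "d_inter": truth.pattern.d_inter,
        "max_crown_diameter": truth.pattern.max_crown_diameter}, indent=1))
    paths["anchors"] = anchors
    return paths


def load_fixture(fixture_dir: str | Path) -> dict:
    """Reload a fixture directory: image, truth mask, tree table, scenario."""
    fixture_dir = Path(fixture_dir)
    sc = scenario_from_dict(yaml.safe_load(
        (fixture_dir / "scenario.yaml").read_text()))
    image = load_parcel(fixture_dir / "image.tif", band_names=sc.band_names)
    mask, mask_nodata, _ = load_mask(fixture_dir / "truth_mask.tif")
    anchors = json.loads((fixture_dir / "anchors.json").read_text())
    pattern = PlantingPattern(
        anchor_r1t1=tuple(anchors["anchor_r1t1"]),
        anchor_r1t2=tuple(anchors["anchor_r1t2"]),
        anchor_r2t1=tuple(anchors["anchor_r2t1"]),
        d_intra=anchors["d_intra"], d_inter=anchors["d_inter"],
        max_crown_diameter=anchors["max_crown_diameter"])
    return {
        "scenario": sc,
        "image": image,
        "truth_mask": CanopyMask(mask=mask, nodata_mask=mask_nodata),
        "trees": pd.read_csv(fixture_dir / "trees.csv"),
        "pattern": pattern,
    }
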