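"""Georeferenced raster I/O and coordinate conventions.

All pixel coordinates in this package are ``(row, col)``, 0-based.  Geographic
lookups use the pixel-*center* convention: integer pixel ``(row, col)`` maps to
the projected coordinate of the center of that cell.  Rasters are read and
written as GeoTIFFs through :mod:`tifffile`; the affine georeferencing is
carried in the standard GeoTIFF tags (ModelPixelScale + ModelTiepoint for
north-up rasters, ModelTransformation otherwise) and the nodata value in the
GDAL_NODATA ASCII tag.

The parcel is assumed to be already clipped: every pixel outside it holds the
nodata value in all bands, and is carried in-memory as an explicit boolean
``nodata_mask`` rather than a polygon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

DEFAULT_BAND_NAMES = ("blue", "green", "red", "nir")
DEFAULT_NODATA = -9999.0

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_MODEL_TRANSFORMATION = 34264
_TAG_GDAL_NODATA = 42113


def meters_to_pixels(length_m: float, resolution: float) -> int:
    """Convert a ground length in meters to a pixel count.

    Rounds to the nearest integer, ties half up, so a 2 m tree spacing at
    0.5 m/pixel is 4 pixels and a 6 m row spacing is 12 pixels.

    Parameters
    ----------
    length_m:
        Ground length in meters, >= 0.
    resolution:
        Ground sampling distance in meters per pixel, > 0.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be > 0, got {resolution}")
    if length_m < 0:
        raise ValueError(f"length_m must be >= 0, got {length_m}")
    return int(math.floor(length_m / resolution + 0.5))


@dataclass(frozen=True)
class Affine:
    """Affine pixel -> projected map, GDAL coefficient order.

    ``x = c + col*a + row*b`` and ``y = f + col*d + row*e`` for *corner*
    coordinates; :meth:`forward` adds the half-pixel offset so it returns
    pixel-center coordinates.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @staticmethod
    def north_up(resolution: float, x0: float = 0.0, y_top: float = 0.0) -> "Affine":
        return Affine(resolution, 0.0, x0, 0.0, -resolution, y_top)

    @property
    def det(self) -> float:
        return self.a * self.e - self.b * self.d

    @property
    def is_north_up(self) -> bool:
        return self.b == 0.0 and self.d == 0.0 and self.a > 0 and self.e < 0

    def forward(self, row: float, col: float) -> tuple[float, float]:
        """Projected (x, y) of the center of pixel (row, col)."""
        rc, cc = row + 0.5, col + 0.5
        return (self.c + cc * self.a + rc * self.b,
                self.f + cc * self.d + rc * self.e)

    def inverse(self, x: float, y: float) -> tuple[float, float]:
        """Fractional (row, col) whose center maps to projected (x, y)."""
        det = self.det
        if abs(det) < 1e-15:
            raise ValueError("singular geotransform")
        dx, dy = x - self.c, y - self.f
        col = (dx * self.e - dy * self.b) / det - 0.5
        row = (dy * self.a - dx * self.d) / det - 0.5
        return row, col

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)


def pixel_to_geo(point: tuple[float, float], transform: Affine) -> tuple[float, float]:
    """Projected (x, y) at the center of pixel ``(row, col)``."""
    return transform.forward(point[0], point[1])


def geo_to_pixel(xy: tuple[float, float], transform: Affine) -> tuple[int, int]:
    """Integer pixel (row, col) whose center is nearest to projected (x, y)."""
    row, col = transform.inverse(xy[0], xy[1])
    return int(math.floor(row + 0.5)), int(math.floor(col + 0.5))


@dataclass
class ParcelImage:
    """A clipped multispectral parcel raster.

    Attributes
    ----------
    bands:
        float array indexed ``(band, row, col)``.
    band_names:
        ordered spectral identifiers; NIR availability is detected by the
        presence of a band named ``"nir"``.
    resolution:
        ground sampling distance, meters/pixel.
    transform:
        affine pixel -> projected mapping.
    nodata_mask:
        boolean ``(row, col)`` raster, True outside the parcel.
    nodata:
        the fill value written into nodata pixels on disk.
    """

    bands: np.ndarray
    band_names: tuple[str, ...] = DEFAULT_BAND_NAMES
    resolution: float = 0.5
    transform: Affine = field(default_factory=lambda: Affine.north_up(0.5))
    nodata_mask: np.ndarray | None = None
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands)
        if self.bands.ndim != 3:
            raise ValueError("bands must be a 3-D (band, row, col) array")
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.bands.shape[1:], dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.bands.shape[1:]:
            raise ValueError(
                f"nodata_mask shape {self.nodata_mask.shape} does not match "
                f"band shape {self.bands.shape[1:]}")
        self.band_names = tuple(self.band_names)
        if len(self.band_names) != self.bands.shape[0]:
            raise ValueError(
                f"{len(self.band_names)} band names for {self.bands.shape[0]} bands")

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    @property
    def has_nir(self) -> bool:
        return "nir" in self.band_names

    def band(self, name: str) -> np.ndarray:
        """Return one band as a 2-D array by its spectral name."""
        try:
            idx = self.band_names.index(name)
        except ValueError:
            raise KeyError(f"no band named {name!r}; have {self.band_names}") from None
        return self.bands[idx]

    def copy(self) -> "ParcelImage":
        return replace(self, bands=self.bands.copy(),
                       nodata_mask=self.nodata_mask.copy())


def _geo_extratags(transform: Affine, nodata: float | int | None) -> list:
    tags = []
    if transform.is_north_up:
        tags.append((_TAG_MODEL_PIXEL_SCALE, "d", 3,
                     (transform.a, -transform.e, 0.0)))
        tags.append((_TAG_MODEL_TIEPOINT, "d", 6,
                     (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)))
    else:
        a, b, c, d, e, f = transform.as_tuple()
        tags.append((_TAG_MODEL_TRANSFORMATION, "d", 16,
                     (a, b, 0.0, c, d, e, 0.0, f,
                      0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0)))
    if nodata is not None:
        s = repr(float(nodata)) if isinstance(nodata, float) else str(nodata)
        tags.append((_TAG_GDAL_NODATA, "s", 0, s))
    return tags


def _read_transform(page) -> Affine | None:
    tags = page.tags
    if _TAG_MODEL_TRANSFORMATION in tags:
        m = tags[_TAG_MODEL_TRANSFORMATION].value
        return Affine(m[0], m[1], m[3], m[4], m[5], m[7])
    if _TAG_MODEL_PIXEL_SCALE in tags and _TAG_MODEL_TIEPOINT in tags:
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        tp = tags[_TAG_MODEL_TIEPOINT].value
        i, j, _, x, y = tp[0], tp[1], tp[2], tp[3], tp[4]
        # tiepoint gives raster (col=i, row=j) -> model (x, y); solve corner origin
        return Affine(sx, 0.0, x - i * sx, 0.0, -sy, y + j * sy)
    return None


def _read_nodata(page) -> float | None:
    if _TAG_GDAL_NODATA in page.tags:
        try:
            return float(str(page.tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
        except ValueError:
            return None
    return None


def write_parcel(img: ParcelImage, path: str | Path) -> Path:
    """Write a ParcelImage as a multiband GeoTIFF (nodata pixels filled)."""
    path = Path(path)
    data = img.bands.copy()
    data[:, img.nodata_mask] = img.nodata
    tifffile.imwrite(
        path, data,
        photometric="minisblack",
        planarconfig="separate",
        extratags=_geo_extratags(img.transform, img.nodata),
        metadata=None,
    )
    return path


def load_parcel(path: str | Path,
                band_names: list[str] | tuple[str, ...] | None = None,
                nodata: float | None = None,
                resolution: float | None = None) -> ParcelImage:
    """Read a multiband GeoTIFF into a :class:`ParcelImage`.

    The nodata mask is True exactly where *all* bands equal the nodata value
    (from the GDAL_NODATA tag unless overridden).  Band order is taken as
    stored; names default to (blue, green, red, nir) truncated/extended to the
    band count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        transform = _read_transform(page)
        file_nodata = _read_nodata(page)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"unsupported raster dimensionality {data.ndim}")
    # tifffile may return (rows, cols, bands) for contiguous files
    if data.shape[0] > 16 and data.shape[2] <= 16:
        data = np.moveaxis(data, -1, 0)
    n_bands = data.shape[0]
    if n_bands < 3:
        raise ValueError(
            f"{path} has {n_bands} band(s); at least 3 (e.g. RGB) are required")

    if transform is None:
        if resolution is None:
            raise ValueError(
                f"{path} carries no geotransform and no resolution was supplied")
        transform = Affine.north_up(resolution, 0.0, data.shape[1] * resolution)
    res = math.hypot(transform.a, transform.d)
    if res <= 0:
        raise ValueError(f"{path}: geotransform implies non-positive resolution")

    nd = nodata if nodata is not None else file_nodata
    if nd is None:
        nd = DEFAULT_NODATA
        mask = np.zeros(data.shape[1:], dtype=bool)
    else:
        mask = np.all(data == nd, axis=0)

    if band_names is None:
        names = list(DEFAULT_BAND_NAMES[:n_bands])
        names += [f"band{i}" for i in range(len(names), n_bands)]
    else:
        names = list(band_names)
    return ParcelImage(bands=data, band_names=tuple(names), resolution=res,
                       transform=transform, nodata_mask=mask, nodata=float(nd))


def write_mask(mask: np.ndarray, transform: Affine, path: str | Path,
               nodata_mask: np.ndarray | None = None) -> Path:
    """Write a binary canopy mask as a single-band 8-bit GeoTIFF (nodata=255)."""
    path = Path(path)
    out = np.asarray(mask, dtype=np.uint8).copy()
    if nodata_mask is not None:
        out[np.asarray(nodata_mask, dtype=bool)] = 255
    tifffile.imwrite(path, out, photometric="minisblack",
                     extratags=_geo_extratags(transform, 255), metadata=None)
    return path


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray, Affine | None]:
    """Read a 0/1 mask GeoTIFF; returns (mask, nodata_mask, transform)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        transform = _read_transform(page)
        nd = _read_nodata(page)
    if data.ndim != 2:
        raise ValueError("mask raster must be single-band")
    nodata_mask = (data == nd) if nd is not None else np.zeros(data.shape, bool)
    mask = np.where(nodata_mask, 0, data).astype(np.uint8)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"{path} is not a binary 0/1 mask")
    return mask, nodata_mask, transform


def write_class_map(values: np.ndarray, transform: Affine, path: str | Path,
                    color_table: dict[int, tuple[int, int, int]] | None = None) -> Path:
    """Write a classified map (0..3) as an 8-bit paletted GeoTIFF."""
    path = Path(path)
    values = np.asarray(values, dtype=np.uint8)
    cmap = np.zeros((3, 256), dtype=np.uint16)
    if color_table:
        for cls, rgb in color_table.items():
            cmap[:, cls] = [v * 257 for v in rgb]  # 8-bit -> 16-bit palette
    tifffile.imwrite(path, values, photometric="palette", colormap=cmap,
                     extratags=_geo_extratags(transform, None), metadata=None)
    return path


def write_png_quicklook(values: np.ndarray,
                        color_table: dict[int, tuple[int, int, int]],
                        path: str | Path) -> Path:
    """Write an RGB PNG rendering of a small classified/label raster."""
    from PIL import Image

    values = np.asarray(values)
    rgb = np.zeros(values.shape + (3,), dtype=np.uint8)
    for cls, color in color_table.items():
        rgb[values == cls] = color
    Image.fromarray(rgb, mode="RGB").save(Path(path))
    return Path(path)
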