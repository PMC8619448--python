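"""Canopy masking: k-means spectral clustering with a thresholding baseline.

A clipped parcel raster holds three spectral populations — tree canopy, bare
soil, and (when not flagged as nodata) the space outside the parcel.  k-means
with k=3 over the raw band vectors separates them; the vegetation cluster is
then recognized by its NDVI (or green reflectance when no NIR band exists) and
binarized into a canopy mask.  An Otsu-threshold baseline over a single
grayscale is provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .raster_io import ParcelImage

_EPS = 1e-9


@dataclass
class ClusterLabelRaster:
    """Per-pixel k-means cluster ids; -1 marks nodata pixels."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        valid = self.labels[self.labels >= 0]
        if valid.size and valid.max() >= self.k:
            raise ValueError("cluster label out of range")


@dataclass
class CanopyMask:
    """Binary canopy raster: 1 = tree canopy, 0 = soil; nodata forced to 0."""

    mask: np.ndarray
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.mask.shape != self.nodata_mask.shape:
            raise ValueError("mask and nodata_mask shapes differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        self.mask[self.nodata_mask] = 0

    @property
    def canopy_pixels(self) -> int:
        return int(self.mask.sum())


def segment_kmeans(img: ParcelImage, k: int = 3, seed: int = 0,
                   standardize: bool = False) -> ClusterLabelRaster:
    """Cluster non-nodata pixel spectra into k groups with k-means.

    Features are the raw band vectors (bands share one radiometric scale);
    pass ``standardize=True`` to z-score each band first.  Initialization is
    k-means++ seeded by ``seed``; nodata pixels are excluded from fitting and
    left labeled -1.  Final labels are the nearest-centroid assignment under
    the converged centroids, so re-assignment is a fixed point.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    valid = ~img.nodata_mask
    if not valid.any():
        raise ValueError("empty parcel: every pixel is nodata")
    X = img.bands[:, valid].T.astype(np.float64)
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(
            f"only {n_distinct} distinct spectral vectors for k={k} clusters")
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                tol=1e-4, random_state=seed)
    km.fit(X)
    flat = km.predict(X)  # fixed-point assignment under final centroids
    labels = np.full(img.shape, -1, dtype=np.int32)
    labels[valid] = flat
    return ClusterLabelRaster(labels=labels, k=k)


def _ndvi(img: ParcelImage) -> np.ndarray:
    nir = img.band("nir").astype(np.float64)
    red = img.band("red").astype(np.float64)
    return (nir - red) / (nir + red + _EPS)


def _vegetation_score_raster(img: ParcelImage) -> np.ndarray:
    """NDVI when a NIR band exists, otherwise the green band."""
    if img.has_nir:
        return _ndvi(img)
    name = "green" if "green" in img.band_names else img.band_names[min(1, img.n_bands - 1)]
    return img.band(name).astype(np.float64)


def identify_vegetation_cluster(labels: ClusterLabelRaster, img: ParcelImage) -> int:
    """Return the cluster id covering tree canopy.

    With a NIR band: the cluster of highest mean NDVI; without: highest mean
    green value.  Ties break to the lower cluster id.
    """
    score = _vegetation_score_raster(img)
    means = np.full(labels.k, -np.inf)
    for c in range(labels.k):
        sel = labels.labels == c
        if sel.any():
            means[c] = score[sel].mean()
    if not np.isfinite(means).any():
        raise ValueError("all clusters are empty")
    return int(np.argmax(means))  # argmax returns the lowest id on ties


def to_canopy_mask(labels: ClusterLabelRaster, veg_cluster: int,
                   nodata_mask: np.ndarray) -> CanopyMask:
    """Binarize cluster labels: 1 where the vegetation cluster, 0 elsewhere."""
    if not 0 <= veg_cluster < labels.k:
        raise ValueError(f"veg_cluster {veg_cluster} outside [0, {labels.k})")
    mask = (labels.labels == veg_cluster).astype(np.uint8)
    return CanopyMask(mask=mask, nodata_mask=nodata_mask)


def segment_canopy(img: ParcelImage, k: int = 3, seed: int = 0,
                   standardize: bool = False) -> CanopyMask:
    """Full clustering route: k-means, vegetation-cluster pick, binarize.

    On degenerate inputs with fewer distinct spectral vectors than k (e.g. a
    noise-free two-material parcel whose background is carried as nodata), k
    is clamped to the number of distinct vectors with a warning, so the
    pipeline still yields the exact canopy mask.
    """
    valid = ~img.nodata_mask
    if valid.any():
        n_distinct = np.unique(img.bands[:, valid].T, axis=0).shape[0]
        if n_distinct < k:
            warnings.warn(
                f"only {n_distinct} distinct spectral vectors; clamping k "
                f"from {k} to {n_distinct}", stacklevel=2)
            k = n_distinct
    labels = segment_kmeans(img, k=k, seed=seed, standardize=standardize)
    veg = identify_vegetation_cluster(labels, img)
    return to_canopy_mask(labels, veg, img.nodata_mask)


def segment_threshold(img: ParcelImage) -> CanopyMask:
    """Otsu-threshold baseline over a single grayscale.

    The grayscale is NDVI when NIR is present, else the mean of all bands.
    The side of the threshold with the higher vegetation score becomes canopy.
    A constant image yields an all-zero mask with a warning.
    """
    from skimage.filters import threshold_otsu

    valid = ~img.nodata_mask
    if not valid.any():
        raise ValueError("empty parcel: every pixel is nodata")
    gray = _ndvi(img) if img.has_nir else img.bands.mean(axis=0).astype(np.float64)
    vals = gray[valid]
    if np.ptp(vals) == 0:
        warnings.warn("constant image: no Otsu threshold exists; returning "
                      "an all-zero mask", stacklevel=2)
        return CanopyMask(mask=np.zeros(img.shape, np.uint8),
                          nodata_mask=img.nodata_mask)
    t = threshold_otsu(vals)
    above = valid & (gray > t)
    below = valid & ~(gray > t)
    score = _vegetation_score_raster(img)
    mean_above = score[above].mean() if above.any() else -np.inf
    mean_below = score[below].mean() if below.any() else -np.inf
    canopy = above if mean_above >= mean_below else below
    return CanopyMask(mask=canopy.astype(np.uint8), nodata_mask=img.nodata_mask)
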