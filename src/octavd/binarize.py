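"""Otsu thresholding of vesselness maps into binary vessel images.

The threshold maximises the between-class variance
``w0(t) * w1(t) * (mu0(t) - mu1(t))**2`` over an ``n_bins``-bin histogram;
ties break toward the smallest threshold, and the vessel class consists of
pixels whose quantized intensity is strictly greater than the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BinaryVesselMap", "otsu_threshold", "binarize_map"]


class DegenerateImageError(ValueError):
    """Raised when an image quantizes to a single intensity class."""


@dataclass(frozen=True)
class BinaryVesselMap:
    """Binary vessel image plus the threshold that produced it."""

    pixels: np.ndarray  # boolean grid, True = vessel
    threshold_used: float
    pixel_size_mm: float | None = None
    fovea_center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def vessel_fraction(self) -> float:
        return float(self.pixels.mean())


def _quantize(values: np.ndarray, n_bins: int, value_range=None):
    """Map values onto bin indices and return (indices, bin centers)."""
    if value_range is None:
        lo, hi = float(values.min()), float(values.max())
    else:
        lo, hi = map(float, value_range)
    if hi <= lo:
        raise DegenerateImageError(
            "degenerate image: all intensities identical, cannot threshold"
        )
    idx = np.clip(((values - lo) / (hi - lo) * n_bins).astype(np.int64), 0, n_bins - 1)
    centers = lo + (np.arange(n_bins) + 0.5) * (hi - lo) / n_bins
    return idx, centers


def otsu_threshold(values, n_bins: int = 256, value_range=None) -> float:
    """Otsu threshold of an intensity grid over an ``n_bins`` histogram.

    Parameters
    ----------
    values
        Array of intensities (any shape).
    n_bins
        Histogram bin count.
    value_range
        Optional ``(lo, hi)`` histogram range; defaults to the data range so
        the threshold is equivariant under affine intensity rescaling.

    Returns
    -------
    float
        The bin-center threshold ``t`` maximising the between-class variance,
        with ties broken toward the smallest ``t``.  Pixels strictly above
        ``t`` (after quantization) form the vessel class.

    Raises
    ------
    DegenerateImageError
        If the values quantize to a single class.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise ValueError("values must be non-empty and finite")
    idx, centers = _quantize(arr, n_bins, value_range)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    if np.count_nonzero(counts) < 2:
        raise DegenerateImageError(
            "degenerate image: fewer than two distinct quantized values"
        )

    total = counts.sum()
    # cumulative weight / mean of the low class for threshold after bin k
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    cum_mass = np.cumsum(counts * centers)[:-1]
    total_mass = (counts * centers).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, cum_mass / w0, 0.0)
        mu1 = np.where(w1 > 0, (total_mass - cum_mass) / w1, 0.0)
    between = w0 / total * w1 / total * (mu0 - mu1) ** 2
    k = int(np.argmax(between))  # argmax takes the first (smallest t) on ties
    return float(centers[k])


def binarize_map(vesselness, n_bins: int = 256, *, pixel_size_mm=None,
                 fovea_center=None) -> BinaryVesselMap:
    """Binarize a vesselness map in ``[0, 1]`` with a global Otsu threshold."""
    arr = np.asarray(vesselness, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D map, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("vesselness map must be finite and within [0, 1]")
    t = otsu_threshold(arr, n_bins=n_bins)
    idx, centers = _quantize(arr.ravel(), n_bins)
    quantized = centers[idx].reshape(arr.shape)
    return BinaryVesselMap(
        pixels=quantized > t,
        threshold_used=t,
        pixel_size_mm=pixel_size_mm,
        fovea_center=fovea_center,
    )
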