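"""Core image container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class AngiogramImage:
    """A fovea-centered grayscale en-face projection.

    Parameters
    ----------
    pixels
        Square 2-D array of intensities in ``[0, 1]``.
    pixel_size_mm
        Physical side length of one pixel in millimetres.
    fovea_center
        Continuous ``(x, y)`` position of the fovea in pixel units, with
        pixel ``i`` covering the interval ``[i, i + 1)``.  Defaults to the
        geometric image center ``(W / 2, H / 2)``.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    fovea_center: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"pixels must be a square 2-D grid, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        if not (self.pixel_size_mm > 0):
            raise ValueError(f"pixel_size_mm must be positive, got {self.pixel_size_mm}")
        object.__setattr__(self, "pixels", px)
        if self.fovea_center is None:
            h, w = px.shape
            object.__setattr__(self, "fovea_center", (w / 2.0, h / 2.0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def field_of_view_mm(self) -> float:
        """Physical side length of the imaged field."""
        return self.pixels.shape[1] * self.pixel_size_mm


def as_pixel_array(image) -> np.ndarray:
    """Accept an :class:`AngiogramImage` or a bare 2-D array."""
    if isinstance(image, AngiogramImage):
        return image.pixels
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr
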