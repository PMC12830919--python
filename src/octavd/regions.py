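"""Macular region masks and per-region vessel density.

The parafoveal zone is an annulus centered on the fovea (default outer
radius 1.45 mm, i.e. a 2.9 mm diameter circle) with the foveal avascular
zone excluded, split into 12 sectors of 30 degrees each (S1..S12).  The
perifoveal zone is everything outside the annulus, split into the four
corner quadrants (Q1..Q4) by the horizontal and vertical lines through the
fovea center.  Vessel density (VD) of a region is the percentage of vessel
pixels among all pixels of its mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binarize import BinaryVesselMap, binarize_map
from .enhance import VesselnessParams, frangi_vesselness
from .image import AngiogramImage

__all__ = [
    "RegionLayout",
    "FeatureVector",
    "make_region_layout",
    "vessel_density",
    "extract_features",
]

ZONES = ("parafoveal", "perifoveal")

#: Default FAZ-exclusion radius (ETDRS central-subfield radius).
DEFAULT_INNER_RADIUS_MM = 0.5
DEFAULT_OUTER_RADIUS_MM = 1.45


@dataclass(frozen=True)
class RegionLayout:
    """Named boolean masks S1..Sn (parafoveal sectors) and Q1..Q4 (quadrants)."""

    inner_radius_mm: float
    outer_radius_mm: float
    n_sectors: int
    sector_origin_deg: float
    clockwise: bool
    masks: dict[str, np.ndarray]
    faz_mask: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def sector_names(self) -> list[str]:
        return [f"S{i}" for i in range(1, self.n_sectors + 1)]

    @property
    def quadrant_names(self) -> list[str]:
        return ["Q1", "Q2", "Q3", "Q4"]

    def zone_names(self, zone: str) -> list[str]:
        if zone == "parafoveal":
            return self.sector_names
        if zone == "perifoveal":
            return self.quadrant_names
        raise ValueError(f"unknown zone {zone!r}; expected one of {ZONES}")

    def zone_mask(self, zone: str) -> np.ndarray:
        out = np.zeros_like(next(iter(self.masks.values())))
        for name in self.zone_names(zone):
            out |= self.masks[name]
        return out


@dataclass(frozen=True)
class FeatureVector:
    """Ordered per-region VD percentages for one (plexus, zone) method."""

    plexus: str
    zone: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if self.zone not in ZONES:
            raise ValueError(f"unknown zone {self.zone!r}")
        expected = 4 if self.zone == "perifoveal" else None
        if expected is not None and vals.size != expected:
            raise ValueError(f"{self.zone} feature vector must have {expected} values")
        if vals.min() < 0.0 or vals.max() > 100.0:
            raise ValueError("VD values must lie in [0, 100]")
        object.__setattr__(self, "values", vals)

    @property
    def method(self) -> str:
        return f"{self.plexus}_{self.zone}"


def make_region_layout(
    shape: tuple[int, int],
    pixel_size_mm: float,
    fovea_center: tuple[float, float] | None = None,
    inner_radius_mm: float = DEFAULT_INNER_RADIUS_MM,
    outer_radius_mm: float = DEFAULT_OUTER_RADIUS_MM,
    n_sectors: int = 12,
    sector_origin_deg: float = 90.0,
    clockwise: bool = True,
) -> RegionLayout:
    """Build the sector/quadrant masks for a given image geometry.

    Pixel membership is decided at the pixel-center coordinate
    ``(j + 0.5, i + 0.5)``: the FAZ disk is ``r <= inner``, the parafoveal
    annulus ``inner < r <= outer`` and the perifoveal zone ``r > outer``
    (half-open boundaries guarantee a true partition).  Sectors sweep equal
    angular arcs starting at ``sector_origin_deg`` (default 12 o'clock,
    clockwise); quadrants are split by the axis-aligned lines through the
    fovea center so Q1..Q4 correspond to the four image corners
    (upper-left, upper-right, lower-left, lower-right).
    """
    h, w = shape
    if pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be positive")
    if not (0 <= inner_radius_mm < outer_radius_mm):
        raise ValueError(
            f"need 0 <= inner_radius_mm < outer_radius_mm, got "
            f"{inner_radius_mm} and {outer_radius_mm}"
        )
    if n_sectors < 1:
        raise ValueError("n_sectors must be >= 1")
    if fovea_center is None:
        fovea_center = (w / 2.0, h / 2.0)
    fx, fy = fovea_center
    half_diag_mm = float(np.hypot(w / 2.0, h / 2.0)) * pixel_size_mm
    if outer_radius_mm > half_diag_mm:
        raise ValueError(
            f"outer_radius_mm={outer_radius_mm} exceeds the image "
            f"half-diagonal ({half_diag_mm:.3f} mm)"
        )

    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    dx = (jj + 0.5) - fx
    dy = (ii + 0.5) - fy
    r_mm = np.hypot(dx, dy) * pixel_size_mm

    faz = r_mm <= inner_radius_mm
    annulus = (r_mm > inner_radius_mm) & (r_mm <= outer_radius_mm)
    peri = r_mm > outer_radius_mm

    # angle measured with y pointing up so 90 deg is 12 o'clock on screen
    theta = np.degrees(np.arctan2(-dy, dx)) % 360.0
    sweep = (sector_origin_deg - theta) if clockwise else (theta - sector_origin_deg)
    sector_idx = np.floor((sweep % 360.0) / (360.0 / n_sectors)).astype(int)
    sector_idx = np.clip(sector_idx, 0, n_sectors - 1)

    masks: dict[str, np.ndarray] = {}
    for k in range(n_sectors):
        masks[f"S{k + 1}"] = annulus & (sector_idx == k)
    upper, left = dy < 0, dx < 0
    masks["Q1"] = peri & upper & left
    masks["Q2"] = peri & upper & ~left
    masks["Q3"] = peri & ~upper & left
    masks["Q4"] = peri & ~upper & ~left

    return RegionLayout(
        inner_radius_mm=inner_radius_mm,
        outer_radius_mm=outer_radius_mm,
        n_sectors=n_sectors,
        sector_origin_deg=sector_origin_deg,
        clockwise=clockwise,
        masks=masks,
        faz_mask=faz,
    )


def vessel_density(binary, mask: np.ndarray) -> float:
    """VD percentage: ``100 * vessel pixels in mask / mask pixels``."""
    pixels = binary.pixels if isinstance(binary, BinaryVesselMap) else np.asarray(binary, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pixels.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {pixels.shape}")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask is empty")
    return 100.0 * int(pixels[mask].sum()) / n


def extract_features(
    eye,
    layout: RegionLayout,
    params: VesselnessParams | None = None,
    n_bins: int = 256,
) -> dict[tuple[str, str], FeatureVector]:
    """Run enhance -> binarize -> per-region VD for every plexus of one eye.

    Returns a mapping ``(plexus, zone) -> FeatureVector`` with sector VDs
    ordered S1..S12 and quadrant VDs ordered Q1..Q4.  A degenerate image
    (single-class after enhancement) propagates its error.
    """
    out: dict[tuple[str, str], FeatureVector] = {}
    for plexus, image in eye.images.items():
        vmap = frangi_vesselness(image, params)
        bmap = binarize_map(vmap, n_bins=n_bins,
                            pixel_size_mm=image.pixel_size_mm,
                            fovea_center=image.fovea_center)
        for zone in ZONES:
            vals = [vessel_density(bmap, layout.masks[name])
                    for name in layout.zone_names(zone)]
            out[(plexus, zone)] = FeatureVector(plexus=plexus, zone=zone,
                                                values=np.asarray(vals))
    return out


def layout_for_image(image: AngiogramImage, **kwargs) -> RegionLayout:
    """Convenience: build the default layout matching an image's geometry."""
    return make_region_layout(image.shape, image.pixel_size_mm,
                              fovea_center=image.fovea_center, **kwargs)
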