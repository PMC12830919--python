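"""Synthetic en-face OCTA-like angiogram cohorts with known class structure.

Vessels are stochastic random walks rasterised as bright curvilinear
structures on a darker speckled background.  The superficial plexus (SVP)
additionally carries a few thick radially oriented vessels; the intermediate
and deep plexuses (ICP/DCP) are capillary mesh only.  No vessel centerline
enters the foveal avascular zone (FAZ) disk.

Glaucoma eyes are rendered with segment-wise vessel dropout: each generated
segment is removed with probability ``dropout_para`` if its midpoint lies in
the parafoveal annulus and ``dropout_peri`` outside it, scaled per plexus by
``plexus_effect_scale``.  Dropout happens before rasterisation so surviving
vessels keep their appearance, mimicking loss of whole capillaries.

Speckle is multiplicative: ``intensity * (1 + noise_level * g)`` with ``g``
standard normal, clipped to ``[0, 1]``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import AngiogramImage
from .regions import DEFAULT_OUTER_RADIUS_MM

__all__ = [
    "PLEXUSES",
    "SynthConfig",
    "EyeRecord",
    "Geometry",
    "render_vessel_network",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

PLEXUSES = ("SVP", "ICP", "DCP")
LABELS = ("healthy", "glaucoma")

_DEFAULT_PLEXUS_SCALE = {"SVP": 1.0, "ICP": 0.65, "DCP": 0.4}


def _require(cond: bool, fieldname: str, message: str) -> None:
    if not cond:
        raise ValueError(f"SynthConfig.{fieldname}: {message}")


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of a synthetic cohort.

    Defaults produce a 3 mm field of view; tests shrink ``image_size_px``
    (with ``pixel_size_mm`` rescaled accordingly) for desk-scale runtimes.
    """

    image_size_px: int = 526
    pixel_size_mm: float = 0.0057
    faz_radius_mm: float = 0.3
    n_patients: int = 40
    two_eye_fraction: float = 0.5
    dropout_para: float = 0.0
    dropout_peri: float = 0.0
    plexus_effect_scale: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PLEXUS_SCALE))
    noise_level: float = 0.15
    seed: int = 0
    parafoveal_outer_radius_mm: float = DEFAULT_OUTER_RADIUS_MM

    def __post_init__(self) -> None:
        _require(int(self.image_size_px) >= 64, "image_size_px", "must be >= 64")
        _require(self.pixel_size_mm > 0, "pixel_size_mm", "must be > 0")
        half_width_mm = self.image_size_px * self.pixel_size_mm / 2.0
        _require(0 < self.faz_radius_mm < self.parafoveal_outer_radius_mm,
                 "faz_radius_mm", "must lie in (0, parafoveal outer radius)")
        _require(self.parafoveal_outer_radius_mm < half_width_mm,
                 "parafoveal_outer_radius_mm",
                 f"must be < image half-width ({half_width_mm:.3f} mm)")
        _require(self.n_patients >= 1, "n_patients", "must be >= 1")
        for name in ("two_eye_fraction", "dropout_para", "dropout_peri"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, "must be a probability in [0, 1]")
        _require(self.noise_level >= 0, "noise_level", "must be >= 0")
        for plexus in PLEXUSES:
            _require(plexus in self.plexus_effect_scale, "plexus_effect_scale",
                     f"missing entry for {plexus}")
            _require(self.plexus_effect_scale[plexus] >= 0, "plexus_effect_scale",
                     f"{plexus} multiplier must be >= 0")

    @property
    def geometry(self) -> "Geometry":
        return Geometry(
            size_px=int(self.image_size_px),
            pixel_size_mm=float(self.pixel_size_mm),
            faz_radius_mm=float(self.faz_radius_mm),
            parafoveal_outer_radius_mm=float(self.parafoveal_outer_radius_mm),
        )


@dataclass(frozen=True)
class Geometry:
    """Image-plane geometry shared by all renders of a cohort."""

    size_px: int
    pixel_size_mm: float
    faz_radius_mm: float
    parafoveal_outer_radius_mm: float = DEFAULT_OUTER_RADIUS_MM

    @property
    def fovea_center(self) -> tuple[float, float]:
        return (self.size_px / 2.0, self.size_px / 2.0)

    @property
    def faz_radius_px(self) -> float:
        return self.faz_radius_mm / self.pixel_size_mm

    @property
    def parafoveal_outer_radius_px(self) -> float:
        return self.parafoveal_outer_radius_mm / self.pixel_size_mm


@dataclass(frozen=True)
class EyeRecord:
    """One eye: patient linkage, diagnosis label and per-plexus images."""

    patient_id: str
    eye: str  # "OD" (right) or "OS" (left)
    label: str  # "healthy" or "glaucoma"
    images: dict[str, AngiogramImage]
    sex: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        geoms = {(img.shape, img.pixel_size_mm) for img in self.images.values()}
        if len(geoms) > 1:
            raise ValueError("all plexus images of an eye must share one geometry")


# ---------------------------------------------------------------------------
# vessel network generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Segment:
    points: np.ndarray  # (n, 2) float, (x, y) pixel coordinates
    width_px: float

    @property
    def midpoint(self) -> np.ndarray:
        return self.points[len(self.points) // 2]


def _truncate_at_faz(points: np.ndarray, geometry: Geometry) -> np.ndarray:
    """Cut a polyline at the first point inside the FAZ or out of bounds."""
    fx, fy = geometry.fovea_center
    r = np.hypot(points[:, 0] - fx, points[:, 1] - fy)
    # keep centerlines a pixel clear of the avascular disk
    bad = (r <= geometry.faz_radius_px + 1.0) | \
          (points[:, 0] < 0) | (points[:, 0] >= geometry.size_px) | \
          (points[:, 1] < 0) | (points[:, 1] >= geometry.size_px)
    if bad.any():
        points = points[: int(np.argmax(bad))]
    return points


def _random_walk(start: np.ndarray, heading: float, n_steps: int,
                 wobble: float, rng: np.random.Generator) -> np.ndarray:
    headings = heading + np.cumsum(rng.normal(0.0, wobble, size=n_steps))
    steps = np.stack([np.cos(headings), np.sin(headings)], axis=1)
    return start + np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])


def _capillary_segments(geometry: Geometry, rng: np.random.Generator,
                        density: float = 0.26) -> list[_Segment]:
    """Short curvy walks forming the capillary mesh, FAZ excluded."""
    size = geometry.size_px
    n_segments = max(20, int(density * size * size / 30.0))
    fx, fy = geometry.fovea_center
    segments: list[_Segment] = []
    starts = rng.uniform(0, size, size=(n_segments, 2))
    headings = rng.uniform(0, 2 * np.pi, size=n_segments)
    lengths = rng.integers(15, 45, size=n_segments)
    for k in range(n_segments):
        sx, sy = starts[k]
        if np.hypot(sx - fx, sy - fy) <= geometry.faz_radius_px + 1.0:
            continue  # do not seed inside the avascular zone
        pts = _random_walk(starts[k], headings[k], int(lengths[k]),
                           wobble=0.35, rng=rng)
        pts = _truncate_at_faz(pts, geometry)
        if len(pts) >= 3:
            segments.append(_Segment(points=pts, width_px=1.0))
    return segments


def _major_vessel_segments(geometry: Geometry, rng: np.random.Generator,
                           n_major: int = 7) -> list[_Segment]:
    """Thick radially oriented arterioles growing from the border inward."""
    size = geometry.size_px
    fx, fy = geometry.fovea_center
    scale = size / 526.0  # widths quoted at the native 526 px resolution
    segments: list[_Segment] = []
    angles = rng.uniform(0, 2 * np.pi, size=n_major)
    for ang in angles:
        # start on the border in direction ang from the fovea
        radius = size / 2.0 + 2.0
        start = np.array([fx + radius * np.cos(ang), fy + radius * np.sin(ang)])
        heading = np.arctan2(fy - start[1], fx - start[0])  # toward fovea
        n_steps = int(size * 0.7)
        pts = _random_walk(start, heading, n_steps, wobble=0.08, rng=rng)
        pts = _truncate_at_faz(pts, geometry)
        # clip so arterioles stay resolvably thicker than capillaries even
        # in downscaled test renders
        width = max(2.5, rng.uniform(3.0, 5.0) * scale)
        if len(pts) >= 3:
            segments.append(_Segment(points=pts, width_px=width))
            # one side branch per arteriole, thinner
            if len(pts) > 10:
                j = rng.integers(5, len(pts) - 1)
                branch_heading = np.arctan2(pts[j, 1] - pts[j - 1, 1],
                                            pts[j, 0] - pts[j - 1, 0])
                branch_heading += rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)
                bpts = _random_walk(pts[j], branch_heading,
                                    int(n_steps * 0.4), wobble=0.15, rng=rng)
                bpts = _truncate_at_faz(bpts, geometry)
                if len(bpts) >= 3:
                    segments.append(_Segment(points=bpts, width_px=max(1.2, width * 0.5)))
    return segments


def _segment_zone(segment: _Segment, geometry: Geometry) -> str:
    fx, fy = geometry.fovea_center
    mx, my = segment.midpoint
    r_mm = float(np.hypot(mx - fx, my - fy)) * geometry.pixel_size_mm
    return "parafoveal" if r_mm <= geometry.parafoveal_outer_radius_mm else "perifoveal"


def _apply_dropout(segments: list[_Segment], geometry: Geometry,
                   dropout_para: float, dropout_peri: float,
                   rng: np.random.Generator) -> list[_Segment]:
    """Remove whole segments with a zone-dependent probability.

    A uniform is drawn for every segment regardless of the probabilities, so
    renders with different dropout settings but the same seed stay paired.
    """
    u = rng.uniform(size=len(segments))
    kept = []
    for seg, ui in zip(segments, u):
        p = dropout_para if _segment_zone(seg, geometry) == "parafoveal" else dropout_peri
        if ui >= p:
            kept.append(seg)
    return kept


def _rasterize(segments: list[_Segment], geometry: Geometry,
               noise_level: float, rng: np.random.Generator) -> np.ndarray:
    """Draw segments as Gaussian-profile ridges over a speckled background."""
    size = geometry.size_px
    canvases: dict[float, np.ndarray] = {}
    for seg in segments:
        w = round(float(seg.width_px), 2)
        canvas = canvases.setdefault(w, np.zeros((size, size)))
        cols = np.clip(seg.points[:, 0].astype(int), 0, size - 1)
        rows = np.clip(seg.points[:, 1].astype(int), 0, size - 1)
        canvas[rows, cols] = 1.0

    vessels = np.zeros((size, size))
    for w, canvas in canvases.items():
        sigma = max(0.5, w / 2.355)  # FWHM -> sigma
        blurred = ndimage.gaussian_filter(canvas, sigma, mode="constant")
        blurred *= sigma * np.sqrt(2.0 * np.pi)  # unit peak for an isolated line
        np.maximum(vessels, blurred, out=vessels)

    img = 0.12 + 0.75 * np.clip(vessels, 0.0, 1.0)
    img *= 1.0 + noise_level * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0)


def render_vessel_network(
    geometry: Geometry,
    plexus: str,
    rng: np.random.Generator,
    *,
    dropout_para: float = 0.0,
    dropout_peri: float = 0.0,
    noise_level: float = 0.15,
) -> AngiogramImage:
    """Render one plexus of one eye.

    The generator is split into three independent child streams (segments,
    dropout decisions, speckle) so that two renders with the same ``rng``
    seed but different dropout probabilities share segments and noise and
    differ only in which segments were removed.
    """
    if plexus not in PLEXUSES:
        raise ValueError(f"plexus must be one of {PLEXUSES}, got {plexus!r}")
    seg_rng, drop_rng, noise_rng = rng.spawn(3)

    segments = _capillary_segments(geometry, seg_rng)
    if plexus == "SVP":
        segments = _major_vessel_segments(geometry, seg_rng) + segments
    segments = _apply_dropout(segments, geometry, dropout_para, dropout_peri, drop_rng)
    pixels = _rasterize(segments, geometry, noise_level, noise_rng)
    return AngiogramImage(pixels=pixels, pixel_size_mm=geometry.pixel_size_mm,
                          fovea_center=geometry.fovea_center)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SynthConfig) -> list[EyeRecord]:
    """Generate a two-class cohort of eyes, deterministic for a fixed seed.

    Class labels are balanced at the patient level (both eyes of a patient
    share its label); each patient contributes a second eye with probability
    ``two_eye_fraction``.  Glaucoma eyes get zone-weighted segment dropout
    scaled per plexus.
    """
    geometry = config.geometry
    records: list[EyeRecord] = []
    for p_idx in range(config.n_patients):
        pid = f"P{p_idx:04d}"
        label = LABELS[p_idx % 2]  # balanced, deterministic
        patient_rng = np.random.default_rng([config.seed, 1000 + p_idx])
        two_eyes = patient_rng.uniform() < config.two_eye_fraction
        eyes = ("OD", "OS") if two_eyes else (str(patient_rng.choice(["OD", "OS"])),)
        sex = str(patient_rng.choice(["F", "M"]))
        age = float(np.round(patient_rng.uniform(40, 80), 1))
        for e_idx, eye in enumerate(eyes):
            images: dict[str, AngiogramImage] = {}
            for x_idx, plexus in enumerate(PLEXUSES):
                eye_rng = np.random.default_rng(
                    [config.seed, p_idx, e_idx, x_idx])
                if label == "glaucoma":
                    scale = config.plexus_effect_scale[plexus]
                    dp = min(1.0, config.dropout_para * scale)
                    dq = min(1.0, config.dropout_peri * scale)
                else:
                    dp = dq = 0.0
                images[plexus] = render_vessel_network(
                    geometry, plexus, eye_rng,
                    dropout_para=dp, dropout_peri=dq,
                    noise_level=config.noise_level)
            records.append(EyeRecord(patient_id=pid, eye=eye, label=label,
                                     images=images, sex=sex, age=age))
    return records


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

COHORT_CSV = "cohort.csv"
_CSV_FIELDS = ["patient_id", "eye", "label", "sex", "age", "plexus", "path"]


def write_cohort(cohort: list[EyeRecord], outdir) -> Path:
    """Write one 8-bit PNG per eye per plexus plus a cohort table CSV."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        for plexus, img in rec.images.items():
            fname = f"{rec.patient_id}_{rec.eye}_{plexus}.png"
            data = np.round(img.pixels * 255.0).astype(np.uint8)
            iio.imwrite(outdir / fname, data)
            rows.append({"patient_id": rec.patient_id, "eye": rec.eye,
                         "label": rec.label, "sex": rec.sex or "",
                         "age": "" if rec.age is None else rec.age,
                         "plexus": plexus, "path": fname})
    csv_path = outdir / COHORT_CSV
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        writer.writerows(rows)
    return csv_path


def read_cohort(indir, pixel_size_mm: float) -> list[EyeRecord]:
    """Load a cohort written by :func:`write_cohort`."""
    import imageio.v3 as iio

    indir = Path(indir)
    with open(indir / COHORT_CSV, newline="") as fh:
        rows = list(csv.DictReader(fh))
    by_eye: dict[tuple[str, str], dict] = {}
    for row in rows:
        key = (row["patient_id"], row["eye"])
        entry = by_eye.setdefault(key, {"label": row["label"],
                                        "sex": row["sex"] or None,
                                        "age": float(row["age"]) if row["age"] else None,
                                        "images": {}})
        data = iio.imread(indir / row["path"]).astype(float) / 255.0
        entry["images"][row["plexus"]] = AngiogramImage(
            pixels=data, pixel_size_mm=pixel_size_mm)
    return [EyeRecord(patient_id=pid, eye=eye, label=e["label"],
                      images=e["images"], sex=e["sex"], age=e["age"])
            for (pid, eye), e in sorted(by_eye.items())]
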