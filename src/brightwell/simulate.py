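"""Synthetic bright-field well-image generator with Hill dose-response structure.

Emulates a drug-dilution experiment on 96-well plates: three morphologically
distinct cell lines are dosed at 11 concentrations x 8 replicates x 3
experiment sets (264 wells per line).  Per-well cell density follows the
line's Hill dose-response curve, and the measured viability label is the
noiseless curve value corrupted by multiplicative lognormal plus additive
Gaussian noise, clipped to the OD-like [0, 2] scale.

Rendered wells look bright-field-like: anti-aliased elliptical cells with a
bright interior and a dark phase-halo rim, on a low-frequency textured
background with radial vignetting and Gaussian sensor noise.  Everything is
driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .hill import DoseResponseParams, hill_response

__all__ = [
    "CellLineProfile",
    "PlateDesign",
    "WellRecord",
    "PlateImage",
    "NoiseSpec",
    "DEFAULT_CONCENTRATIONS_UM",
    "BUILTIN_PROFILES",
    "simulate_plate",
    "render_well",
    "write_plate_csv",
    "read_plate_csv",
    "load_image",
    "save_image",
]

# the 11-dose ladder used throughout (µM)
DEFAULT_CONCENTRATIONS_UM: tuple[float, ...] = (
    0.0001, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 100.0
)

CSV_COLUMNS = [
    "well_id", "cell_line", "concentration_um", "replicate", "set",
    "measured_viability", "image_path",
]


@dataclass(frozen=True)
class CellLineProfile:
    """Morphology and dose-response of one synthetic cell line."""

    name: str
    blob_radius_px: float = 6.0
    radius_cv: float = 0.25
    elongation: float = 1.5
    clustering: float = 0.3
    base_density: float = 1200.0  # cells per megapixel at viability = Max
    dose_response: DoseResponseParams = field(
        default_factory=lambda: DoseResponseParams(1.8, 0.15, 0.4, 1.0)
    )

    def __post_init__(self) -> None:
        if not self.blob_radius_px > 0:
            raise ValueError("blob_radius_px must be positive")
        if not 0 <= self.clustering <= 1:
            raise ValueError("clustering must lie in [0, 1]")
        if not self.base_density > 0:
            raise ValueError("base_density must be positive")
        if self.elongation < 1:
            raise ValueError("elongation (axis ratio) must be >= 1")


@dataclass(frozen=True)
class PlateDesign:
    """Dose ladder, replication structure, and output resolution."""

    concentrations_um: tuple[float, ...] = DEFAULT_CONCENTRATIONS_UM
    replicates: int = 8
    sets: int = 3
    image_height_px: int = 432
    image_width_px: int = 512

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_um, dtype=float)
        if c.size == 0:
            raise ValueError("concentration list must not be empty")
        if np.any(c <= 0):
            raise ValueError("all concentrations must be positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.replicates < 1 or self.sets < 1:
            raise ValueError("replicates and sets must be >= 1")
        if self.image_height_px < 8 or self.image_width_px < 8:
            raise ValueError("image dimensions too small")

    @property
    def n_wells(self) -> int:
        return len(self.concentrations_um) * self.replicates * self.sets


@dataclass(frozen=True)
class NoiseSpec:
    """Well-to-well label noise and image sensor noise.

    Label noise mimics CCK-8 assay variability: lognormal multiplicative
    (sigma on the log scale) plus additive Gaussian, then clipped to [0, 2].
    """

    label_mult_sigma: float = 0.05
    label_add_sigma: float = 0.02
    sensor_sigma: float = 0.02
    background_sigma: float = 0.03
    vignette_strength: float = 0.10


@dataclass(frozen=True)
class WellRecord:
    """One well's metadata plus its measured viability label."""

    well_id: str
    cell_line: str
    concentration_um: float
    replicate_index: int
    set_index: int
    measured_viability: float
    image_path: str

    def __post_init__(self) -> None:
        if not 0 <= self.measured_viability <= 2:
            raise ValueError(
                f"measured_viability {self.measured_viability} outside [0, 2]"
            )


@dataclass
class PlateImage:
    """Pixel array for one well: H x W x 3 floats in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("PlateImage must be H x W x 3")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")
        self.pixels = px

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


# three shipped lines with distinct morphology and distinct true IC50
# (magnitudes echo typical doxorubicin sensitivities of lung/kidney lines)
BUILTIN_PROFILES: dict[str, CellLineProfile] = {
    "lineA": CellLineProfile(
        name="lineA", blob_radius_px=7.0, radius_cv=0.20, elongation=1.8,
        clustering=0.25, base_density=1100.0,
        dose_response=DoseResponseParams(1.8, 0.15, 0.4, 1.1),
    ),
    "lineB": CellLineProfile(
        name="lineB", blob_radius_px=4.5, radius_cv=0.30, elongation=1.2,
        clustering=0.55, base_density=1800.0,
        dose_response=DoseResponseParams(1.7, 0.10, 0.035, 0.9),
    ),
    "lineC": CellLineProfile(
        name="lineC", blob_radius_px=9.0, radius_cv=0.25, elongation=2.6,
        clustering=0.10, base_density=750.0,
        dose_response=DoseResponseParams(1.9, 0.20, 0.28, 1.4),
    ),
}


# ---------------------------------------------------------------------------
# rendering


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  coarse: int = 8) -> np.ndarray:
    """Perlin-like low-frequency field in [-1, 1]: coarse noise, upsampled."""
    from skimage.transform import resize

    grid = rng.standard_normal((coarse, coarse))
    fld = resize(grid, shape, order=3, mode="reflect", anti_aliasing=False)
    m = np.abs(fld).max()
    return fld / m if m > 0 else fld


def _sample_positions(n: int, h: int, w: int, clustering: float,
                      radius: float, rng: np.random.Generator) -> np.ndarray:
    """Cell centers; with probability `clustering` a cell seeds next to one."""
    pos = np.empty((n, 2))
    for i in range(n):
        if i > 0 and rng.random() < clustering:
            j = rng.integers(i)
            ang = rng.uniform(0, 2 * math.pi)
            dist = radius * rng.uniform(1.5, 2.5)
            p = pos[j] + dist * np.array([math.sin(ang), math.cos(ang)])
            pos[i] = np.clip(p, 0, [h - 1, w - 1])
        else:
            pos[i] = [rng.uniform(0, h - 1), rng.uniform(0, w - 1)]
    return pos


def render_well(profile: CellLineProfile, n_cells: int, height: int,
                width: int, noise: NoiseSpec, rng: np.random.Generator) -> PlateImage:
    """Render one bright-field-like well with ``n_cells`` cells."""
    base = 0.55 + noise.background_sigma * _smooth_field((height, width), rng)
    img = base.copy()

    positions = _sample_positions(
        n_cells, height, width, profile.clustering, profile.blob_radius_px, rng
    )
    radii = profile.blob_radius_px * np.exp(
        rng.standard_normal(n_cells) * profile.radius_cv
    )
    angles = rng.uniform(0, math.pi, n_cells)
    elong = 1.0 + rng.uniform(0, profile.elongation - 1.0, n_cells)

    rim_width = 1.5  # px, dark phase halo
    for (cy, cx), r, ang, e in zip(positions, radii, angles, elong):
        a = r * math.sqrt(e)   # semi-major
        b = r / math.sqrt(e)   # semi-minor; area preserved
        ext = int(math.ceil(a + rim_width + 2.0))
        y0, y1 = max(0, int(cy) - ext), min(height, int(cy) + ext + 1)
        x0, x1 = max(0, int(cx) - ext), min(width, int(cx) + ext + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        dy = (np.arange(y0, y1) - cy)[:, None]
        dx = (np.arange(x0, x1) - cx)[None, :]
        ca, sa = math.cos(ang), math.sin(ang)
        u = (ca * dx + sa * dy) / a
        v = (-sa * dx + ca * dy) / b
        d = np.sqrt(u * u + v * v) * r  # approx px distance from rim at d=r
        t_ = (d - r) / 0.7
        np.clip(t_, -30.0, 30.0, out=t_)
        interior = 1.0 / (1.0 + np.exp(t_))                      # AA edge
        rim = np.exp(-0.5 * ((d - r) / rim_width) ** 2)
        img[y0:y1, x0:x1] += 0.22 * interior - 0.18 * rim * (1 - interior * 0.5)

    # radial vignetting: falloff toward the corners
    yy, xx = np.mgrid[0:height, 0:width]
    ry = (yy - (height - 1) / 2) / ((height - 1) / 2)
    rx = (xx - (width - 1) / 2) / ((width - 1) / 2)
    img *= 1.0 - noise.vignette_strength * 0.5 * (ry * ry + rx * rx)

    # slight channel tint + per-pixel sensor noise
    tints = np.array([0.98, 1.0, 1.02])
    rgb = img[..., None] * tints[None, None, :]
    rgb += noise.sensor_sigma * rng.standard_normal(rgb.shape)
    return PlateImage(np.clip(rgb, 0.0, 1.0))


# ---------------------------------------------------------------------------
# image IO


def save_image(image: PlateImage, path: str | Path) -> None:
    """Write 8-bit RGB; PNG (lossless) by default, TIFF also supported."""
    arr = np.round(image.pixels * 255.0).astype(np.uint8)
    # low compression level: still lossless and deterministic, much faster
    Image.fromarray(arr, mode="RGB").save(path, compress_level=1)


def load_image(path: str | Path) -> PlateImage:
    """Read PNG/TIFF/JPG into [0, 1] floats; grayscale promoted to RGB."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return PlateImage(arr)


# ---------------------------------------------------------------------------
# plate simulation


def simulate_plate(
    profile: CellLineProfile,
    design: PlateDesign,
    out_dir: str | Path,
    seed: int,
    noise: NoiseSpec | None = None,
    write_images: bool = True,
    image_store: dict[str, PlateImage] | None = None,
) -> list[WellRecord]:
    """Generate one full plate for a cell line: images plus labeled records.

    One well per (concentration, replicate, set).  The expected cell count
    scales with the noiseless Hill response:

        E[count] = base_density * area_MP * true_viability / max_response

    and the actual count is Poisson.  The measured label is
    ``hill * lognormal(mult) + gaussian(add)``, clipped to [0, 2].  A fixed
    seed reproduces images and labels bit-for-bit.

    With ``write_images=False`` no rendering happens (labels only) unless an
    ``image_store`` dict is passed, in which case rendered images are placed
    there keyed by well id instead of being written to disk.
    """
    noise = noise or NoiseSpec()
    out_dir = Path(out_dir)
    if write_images:
        out_dir.mkdir(parents=True, exist_ok=True)

    area_mp = design.image_height_px * design.image_width_px / 1e6
    p = profile.dose_response
    records: list[WellRecord] = []
    children = np.random.SeedSequence(seed).spawn(design.n_wells)
    well_index = 0
    for set_idx in range(1, design.sets + 1):
        for rep_idx in range(1, design.replicates + 1):
            for conc in design.concentrations_um:
                rng = np.random.Generator(np.random.PCG64(children[well_index]))
                well_index += 1
                true_v = hill_response(p, conc)
                expected = profile.base_density * area_mp * true_v / p.max_response
                n_cells = int(rng.poisson(expected))
                label = true_v * math.exp(
                    rng.standard_normal() * noise.label_mult_sigma
                ) + rng.standard_normal() * noise.label_add_sigma
                label = float(np.clip(label, 0.0, 2.0))
                well_id = f"{profile.name}_s{set_idx}_r{rep_idx}_c{conc:g}"
                img_path = out_dir / f"{well_id}.png"
                if write_images or image_store is not None:
                    img = render_well(
                        profile, n_cells, design.image_height_px,
                        design.image_width_px, noise, rng,
                    )
                    if write_images:
                        save_image(img, img_path)
                    if image_store is not None:
                        # quantize to 8-bit so in-memory equals a disk round-trip
                        image_store[well_id] = PlateImage(
                            np.round(img.pixels * 255.0) / 255.0
                        )
                records.append(
                    WellRecord(
                        well_id=well_id,
                        cell_line=profile.name,
                        concentration_um=float(conc),
                        replicate_index=rep_idx,
                        set_index=set_idx,
                        measured_viability=label,
                        image_path=str(img_path),
                    )
                )
    return records


# ---------------------------------------------------------------------------
# plate metadata CSV


def write_plate_csv(records: Sequence[WellRecord], path: str | Path) -> None:
    """Write the plate metadata table with the fixed documented header."""
    df = pd.DataFrame(
        [
            {
                "well_id": r.well_id,
                "cell_line": r.cell_line,
                "concentration_um": r.concentration_um,
                "replicate": r.replicate_index,
                "set": r.set_index,
                "measured_viability": r.measured_viability,
                "image_path": r.image_path,
            }
            for r in records
        ],
        columns=CSV_COLUMNS,
    )
    # 17 significant digits guarantee exact float64 round-trip
    df.to_csv(path, index=False, float_format="%.17g")


def read_plate_csv(path: str | Path) -> list[WellRecord]:
    """Read and validate a plate metadata table.

    Raises ``ValueError`` naming the offending row index for out-of-range
    viability, non-numeric concentration, or duplicate well ids; missing
    columns are reported by name.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV missing columns: {missing}")
    records: list[WellRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        try:
            conc = float(row["concentration_um"])
            viab = float(row["measured_viability"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i}: non-numeric field ({exc})") from exc
        if math.isnan(conc):
            raise ValueError(f"row {i}: non-numeric concentration")
        wid = str(row["well_id"])
        if wid in seen:
            raise ValueError(f"row {i}: duplicate well_id {wid!r}")
        seen.add(wid)
        try:
            rec = WellRecord(
                well_id=wid,
                cell_line=str(row["cell_line"]),
                concentration_um=conc,
                replicate_index=int(row["replicate"]),
                set_index=int(row["set"]),
                measured_viability=viab,
                image_path=str(row["image_path"]),
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records
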