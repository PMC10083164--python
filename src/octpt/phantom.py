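"""Synthetic layered-retina speckle phantoms.

Real OCT B-scans of the two common volume-scan presets differ chiefly in the
number of repeated B-scans averaged per tomogram: the fast *Macular Cube*
preset averages 9 looks over a wide 20x20 degree patch (25 slices), while the
intensive *Seven Lines* preset averages 25 looks over a narrow 30x5 degree
strip (7 slices).  Averaging N independent speckle realisations divides the
intensity variance by N, so the two presets share anatomy but differ in
speckle statistics — exactly the contrast this generator reproduces.

The phantom is a stack of smooth layer interfaces (inner-limiting-membrane /
choroid analogues) with constant mean backscatter per layer.  Fully developed
speckle is modelled as multiplicative i.i.d. unit-mean exponential intensity
per look; the recorded image is the per-pixel mean over looks, optionally
log-compressed for display realism.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "PhantomSpec", "PresetProfile", "BScanImage", "MACULAR_CUBE", "SEVEN_LINES",
    "PRESETS", "sample_phantom_spec", "make_reflectivity_map", "simulate_bscan",
    "generate_dataset", "auto_annotation_rects", "load_manifest", "load_image",
]

LOG_COMPRESS_GAIN = 50.0  # display-style compression y = log(1+a*I)/log(1+a)


class PhantomError(ValueError):
    """Invalid phantom specification."""


@dataclass(frozen=True)
class PresetProfile:
    """Acquisition-preset parameters that matter to the simulator.

    ``slices`` and ``field_deg`` are volume-level metadata only; simulation
    acts on single B-scans.
    """

    name: str
    looks: int
    slices: int
    field_deg: tuple[float, float]
    log_compress: bool = True

    def __post_init__(self):
        if self.looks < 1:
            raise PhantomError(f"looks must be >= 1, got {self.looks}")
        if self.slices < 1:
            raise PhantomError(f"slices must be >= 1, got {self.slices}")


MACULAR_CUBE = PresetProfile("macular_cube", looks=9, slices=25, field_deg=(20.0, 20.0))
SEVEN_LINES = PresetProfile("seven_lines", looks=25, slices=7, field_deg=(30.0, 5.0))
PRESETS = {p.name: p for p in (MACULAR_CUBE, SEVEN_LINES)}


@dataclass(frozen=True)
class BScanImage:
    """One grayscale B-scan: depth along rows, values in [0, 1]."""

    pixels: np.ndarray
    preset: str
    provenance: str  # original | synthetic
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise PhantomError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise PhantomError("pixels contain non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise PhantomError("pixel values must lie in [0, 1]")
        if not self.preset:
            raise PhantomError("preset must be populated")
        if self.provenance not in ("original", "synthetic"):
            raise PhantomError(f"provenance must be original|synthetic, "
                               f"got {self.provenance!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and backscatter of one synthetic cross-section.

    ``layer_boundaries`` holds one depth profile per interface (pixels from the
    top, one value per column), strictly ordered in depth at every column.
    Reflectivities are dimensionless mean backscatter values in (0, 1];
    background (vitreous analogue) must be darker than every tissue layer.
    """

    height: int
    width: int
    layer_boundaries: tuple[np.ndarray, ...]
    layer_reflectivities: tuple[float, ...]
    background_reflectivity: float
    curvature: float = 0.0
    tilt: float = 0.0
    seed: int = 0

    def __post_init__(self):
        bounds = tuple(np.asarray(b, dtype=np.float64) for b in self.layer_boundaries)
        object.__setattr__(self, "layer_boundaries", bounds)
        object.__setattr__(self, "layer_reflectivities",
                           tuple(float(r) for r in self.layer_reflectivities))
        if self.height < 1 or self.width < 1:
            raise PhantomError("height and width must be positive")
        if len(bounds) != len(self.layer_reflectivities):
            raise PhantomError("need one reflectivity per boundary "
                               "(layer i spans boundary i to boundary i+1)")
        for b in bounds:
            if b.shape != (self.width,):
                raise PhantomError("each boundary needs one depth per column")
        for upper, lower in zip(bounds, bounds[1:]):
            if not np.all(lower > upper):
                raise PhantomError("layer boundaries cross: depths must be "
                                   "strictly ordered at every column")
        refl = self.layer_reflectivities
        if any(r <= 0 for r in refl) or self.background_reflectivity <= 0:
            raise PhantomError("all reflectivities must be strictly positive")
        if any(r > 1 for r in refl):
            raise PhantomError("layer reflectivities must lie in (0, 1]")
        if refl and self.background_reflectivity >= min(refl):
            raise PhantomError("background reflectivity must be below every "
                               "tissue reflectivity")


def sample_phantom_spec(rng: np.random.Generator, height: int = 128,
                        width: int = 128, n_layers: int = 4) -> PhantomSpec:
    """Draw a random layered phantom: smooth sinusoid + quadratic interfaces
    with per-image perturbation, brightest layers mid-depth as in retinal
    cross-sections."""
    cols = np.linspace(-1.0, 1.0, width)
    curvature = rng.uniform(-0.08, 0.08)
    tilt = rng.uniform(-0.06, 0.06)
    base = 0.30 + curvature * cols ** 2 + tilt * cols
    boundaries = []
    depth = base * height
    for k in range(n_layers):
        amp = rng.uniform(0.004, 0.015) * height
        phase = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(0.5, 2.0)
        wave = amp * np.sin(np.pi * freq * cols + phase)
        boundaries.append(depth + wave)
        # first layer kept thick enough to host a homogeneous ROI, with a
        # pixel floor so small phantoms stay annotatable
        if k == 0:
            gap_px = max(rng.uniform(0.13, 0.2) * height, 5.0)
        else:
            gap_px = max(rng.uniform(0.08, 0.16) * height, 3.0)
        depth = depth + gap_px
    # keep the last interface above the bottom edge
    overflow = boundaries[-1].max() - (height - 2)
    if overflow > 0:
        boundaries = [b - overflow for b in boundaries]
    refl = sorted(rng.uniform(0.35, 0.95, n_layers), reverse=True)
    if n_layers >= 2:  # brightest band just below the ILM analogue
        refl[0], refl[1] = refl[1], refl[0]
    return PhantomSpec(
        height=height, width=width,
        layer_boundaries=tuple(boundaries),
        layer_reflectivities=tuple(refl),
        background_reflectivity=0.04,
        curvature=curvature, tilt=tilt,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def make_reflectivity_map(spec: PhantomSpec) -> np.ndarray:
    """Noiseless mean-backscatter image: each pixel takes the reflectivity of
    the layer containing it (background above the first interface and below
    none applies only above; the last layer extends to the bottom edge)."""
    rows = np.arange(spec.height)[:, None]
    out = np.full((spec.height, spec.width), spec.background_reflectivity)
    for boundary, refl in zip(spec.layer_boundaries, spec.layer_reflectivities):
        out = np.where(rows >= boundary[None, :], refl, out)
    return out


def simulate_bscan(reflectivity: np.ndarray, preset: PresetProfile,
                   seed: int, *, log_compress: bool | None = None,
                   source_id: str = "") -> BScanImage:
    """Multi-look speckle simulation.

    Each of ``preset.looks`` frames is the reflectivity map times i.i.d.
    unit-mean exponential speckle; the recorded intensity is their per-pixel
    mean (ENL of a homogeneous region equals the look count, pre-compression).
    ``log_compress=None`` follows the preset flag.
    """
    refl = np.asarray(reflectivity, dtype=np.float64)
    if refl.ndim != 2 or np.any(refl <= 0):
        raise PhantomError("reflectivity map must be 2-D and strictly positive")
    if preset.looks < 1:
        raise PhantomError("looks must be >= 1")
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(refl)
    for _ in range(preset.looks):
        acc += refl * rng.exponential(1.0, size=refl.shape)
    img = acc / preset.looks
    compress = preset.log_compress if log_compress is None else log_compress
    if compress:
        img = np.log1p(LOG_COMPRESS_GAIN * img) / np.log1p(LOG_COMPRESS_GAIN)
    img = np.clip(img, 0.0, 1.0)
    return BScanImage(img, preset=preset.name, provenance="original",
                      source_id=source_id)


def auto_annotation_rects(spec: PhantomSpec,
                          size: int = 16) -> tuple[tuple[int, int, int, int],
                                                   tuple[int, int, int, int]]:
    """Derive (roi_rect, bg_rect) from phantom ground truth: ROI inside the
    first (homogeneous) tissue layer, BG in the tissue-free region above the
    first interface.  Rects are (row, col, height, width)."""
    first = spec.layer_boundaries[0]
    second = (spec.layer_boundaries[1] if len(spec.layer_boundaries) > 1
              else np.full(spec.width, spec.height))
    bg_h = int(first.min()) - 2
    if bg_h < 2:
        raise PhantomError("phantom has no usable background region")
    # pick the column window where the first layer is thickest, shrinking the
    # window if the phantom is small or strongly curved
    for win in (min(size, spec.width), 12, 8, 6):
        win = min(win, spec.width)
        best = None
        for c0 in range(0, spec.width - win + 1):
            r0 = int(np.ceil(first[c0:c0 + win].max())) + 1
            r1 = int(np.floor(second[c0:c0 + win].min())) - 1
            if best is None or r1 - r0 > best[0]:
                best = (r1 - r0, c0, r0, r1)
        thickness, c0, r0, r1 = best
        if thickness >= 2:
            bg = (0, c0, min(win, bg_h), win)
            roi = (r0, c0, min(win, thickness), win)
            return roi, bg
    raise PhantomError("first tissue layer too thin for an ROI")


def save_image(img: BScanImage, path: Path) -> None:
    arr = np.round(img.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_image(path: Path, preset: str, provenance: str = "original",
               source_id: str = "") -> BScanImage:
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0
    return BScanImage(arr, preset=preset, provenance=provenance,
                      source_id=source_id or Path(path).stem)


def generate_dataset(out_dir: Path, n_per_preset: int, *,
                     presets: tuple[PresetProfile, ...] = (MACULAR_CUBE, SEVEN_LINES),
                     seed: int = 0, height: int = 128, width: int = 128,
                     n_layers: int = 4, paired: bool = False,
                     log_compress: bool | None = None) -> list[dict]:
    """Write ``n_per_preset`` PNG B-scans per preset plus a CSV manifest (and a
    JSON mirror).

    Default is unpaired: each preset draws independent phantom anatomies,
    matching an unpaired-translation setting.  ``paired=True`` reuses the same
    anatomy across presets (useful for controlled comparisons only).
    Deterministic given ``seed``.
    """
    if n_per_preset < 1:
        raise PhantomError("n_per_preset must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    spec_rngs = {p.name: np.random.default_rng(master.integers(0, 2 ** 31 - 1))
                 for p in presets}
    if paired:
        shared_rng = spec_rngs[presets[0].name]
        shared_specs = [sample_phantom_spec(shared_rng, height, width, n_layers)
                        for _ in range(n_per_preset)]
    rows: list[dict] = []
    for preset in presets:
        rng = spec_rngs[preset.name]
        for i in range(n_per_preset):
            spec = shared_specs[i] if paired else sample_phantom_spec(
                rng, height, width, n_layers)
            refl = make_reflectivity_map(spec)
            img_seed = int(np.random.default_rng(spec.seed + 7919 * (i + 1)
                                                 ).integers(0, 2 ** 31 - 1))
            img = simulate_bscan(refl, preset, img_seed,
                                 log_compress=log_compress,
                                 source_id=f"{preset.name}_{i:04d}")
            fname = f"{preset.name}_{i:04d}.png"
            save_image(img, out_dir / fname)
            roi, bg = auto_annotation_rects(spec)
            rows.append({"path": fname, "preset": preset.name,
                         "provenance": "original", "seed": img_seed,
                         "roi_rect": list(roi), "bg_rect": list(bg)})
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "preset", "provenance",
                                                "seed", "roi_rect", "bg_rect"])
        writer.writeheader()
        for row in rows:
            writer.writerow({**row, "roi_rect": json.dumps(row["roi_rect"]),
                             "bg_rect": json.dumps(row["bg_rect"])})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(rows, fh, indent=1)
    return rows


def load_manifest(path: Path) -> list[dict]:
    """Read a dataset manifest (CSV or JSON) back into records."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return json.load(fh)
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            row["seed"] = int(row["seed"])
            for key in ("roi_rect", "bg_rect"):
                if row.get(key):
                    row[key] = json.loads(row[key])
            rows.append(row)
    return rows


def load_dataset(manifest_path: Path) -> list[BScanImage]:
    """Load every image referenced by a manifest."""
    manifest_path = Path(manifest_path)
    rows = load_manifest(manifest_path)
    base = manifest_path.parent
    return [load_image(base / r["path"], r["preset"], r["provenance"])
            for r in rows]
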