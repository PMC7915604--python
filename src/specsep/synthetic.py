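"""Synthetic two-sensor scene generation with known class statistics.

Generates labeled reflectance cubes for a hyperspectral-style sensor
preset ("hyper": 239 bands, 66 VNIR + 173 SWIR with 9 wavelength-
coincident pairs, 30 m) and a multispectral preset ("multi": the 10
land-monitoring bands b2-b8, b8a, b11, b12 at 30 m).  Each class draws
pixels independently per band from Normal(mean(lambda), sd(lambda)^2),
clipped to [0, 1].  Because the generating parameters are known, every
downstream stage has a closed-form oracle: extracted statistics must
recover the generator values, and separability maxima must land inside
the wavelength windows where class contrast was injected.

Class noise is independent across pixels and bands by default; an
optional AR(1) spectral correlation hook exists for experimentation but
is off by default, so the per-band Gaussian assumptions of the
separability criteria hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from shapely.geometry import box

from .cube_io import Affine, BandDef, ClassRegion, Scene, SensorModel

__all__ = [
    "ClassSpectrumSpec",
    "BlockSpec",
    "SceneSpec",
    "make_sensor",
    "generate_scene",
    "simulate_multi_from_hyper",
    "default_classes",
    "default_scene_spec",
]

SpectrumFn = Callable[[np.ndarray], np.ndarray]

# Sentinel-2A land-monitoring band centers (nm); b1/b9/b10 excluded.
_S2_BANDS = (
    ("b2", 492.4),
    ("b3", 559.8),
    ("b4", 664.6),
    ("b5", 704.1),
    ("b6", 740.5),
    ("b7", 782.8),
    ("b8", 832.8),
    ("b8a", 864.7),
    ("b11", 1613.7),
    ("b12", 2202.4),
)


def make_sensor(kind: str) -> SensorModel:
    """Build one of the two sensor presets.

    "hyper": 239 bands at 30 m — 66 VNIR spanning 400-1010 nm and 173
    SWIR spanning 920-2500 nm, with exactly 9 SWIR bands wavelength-
    coincident with the last 9 VNIR bands.  "multi": the 10 published
    Sentinel-2 land bands at 30 m.  Deterministic: repeated calls return
    identical band tables.
    """
    if kind == "hyper":
        vnir = np.linspace(400.0, 1010.0, 66)
        # 1 leading band at the SWIR range start, 9 coincident with the
        # top of VNIR, then 163 bands up to 2500 nm
        swir = np.concatenate([[920.0], vnir[-9:], np.linspace(1019.0, 2500.0, 163)])
        bands = [
            BandDef(i, float(w), "VNIR", f"vnir_{i + 1}") for i, w in enumerate(vnir)
        ]
        bands += [
            BandDef(66 + i, float(w), "SWIR", f"swir_{i + 1}") for i, w in enumerate(swir)
        ]
        return SensorModel("hyper", tuple(bands), 30.0)
    if kind == "multi":
        bands = tuple(
            BandDef(i, w, "MSI", name) for i, (name, w) in enumerate(_S2_BANDS)
        )
        return SensorModel("multi", bands, 30.0)
    raise ValueError(f"unknown sensor kind {kind!r}; expected 'hyper' or 'multi'")


@dataclass(frozen=True)
class ClassSpectrumSpec:
    """Generating spectrum of one class.

    The class mean at wavelength w is ``baseline(w)`` plus the offset of
    every contrast window containing w; the per-wavelength standard
    deviation is ``sd(w)``.  Contrast windows are (lo_nm, hi_nm, offset)
    triples, closed intervals.
    """

    class_code: str
    baseline: SpectrumFn
    sd: SpectrumFn
    contrast_windows: tuple[tuple[float, float, float], ...] = ()

    def mean_spectrum(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        w = np.asarray(wavelengths_nm, dtype=float)
        mu = np.asarray(self.baseline(w), dtype=float) * np.ones_like(w)
        for lo, hi, offset in self.contrast_windows:
            mu = mu + np.where((w >= lo) & (w <= hi), offset, 0.0)
        return mu

    def sd_spectrum(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        w = np.asarray(wavelengths_nm, dtype=float)
        sd = np.asarray(self.sd(w), dtype=float) * np.ones_like(w)
        if np.any(sd <= 0):
            raise ValueError(f"class {self.class_code}: sd spectrum must be positive")
        return sd

    def check(self, sensor: SensorModel) -> None:
        wl = sensor.wavelengths_nm
        mu = self.mean_spectrum(wl)
        if np.any((mu < 0) | (mu > 1)):
            raise ValueError(f"class {self.class_code}: mean spectrum outside [0, 1]")
        self.sd_spectrum(wl)
        lo_s, hi_s = wl.min(), wl.max()
        for lo, hi, _ in self.contrast_windows:
            if lo >= hi or lo < lo_s or hi > hi_s:
                raise ValueError(
                    f"class {self.class_code}: window ({lo}, {hi}) outside "
                    f"sensor range [{lo_s}, {hi_s}]"
                )


@dataclass(frozen=True)
class BlockSpec:
    """A rectangular labeled block: [row0, row1) x [col0, col1) pixels."""

    row0: int
    row1: int
    col0: int
    col1: int
    class_code: str

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("block must have positive extent")

    @property
    def n_pixels(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)


@dataclass(frozen=True)
class SceneSpec:
    """Full recipe for a synthetic labeled scene."""

    rows: int
    cols: int
    pixel_size_m: float
    origin: tuple[float, float]  # (west, north)
    crs: str
    layout: tuple[BlockSpec, ...]
    classes: tuple[ClassSpectrumSpec, ...]
    sensor: SensorModel
    seed: int
    background: float = 0.05  # reflectance of unlabeled pixels
    spectral_ar1: float = 0.0  # optional AR(1) band-noise correlation, off by default

    def __post_init__(self) -> None:
        codes = {c.class_code for c in self.classes}
        for blk in self.layout:
            if blk.class_code not in codes:
                raise ValueError(
                    f"layout references class {blk.class_code!r} missing from classes"
                )
            if blk.row1 > self.rows or blk.col1 > self.cols:
                raise ValueError(f"block for {blk.class_code} exceeds the grid")
        for c in self.classes:
            c.check(self.sensor)

    @property
    def transform(self) -> Affine:
        west, north = self.origin
        return Affine.from_origin(west, north, self.pixel_size_m, self.pixel_size_m)


def generate_scene(spec: SceneSpec) -> tuple[Scene, list[ClassRegion]]:
    """Draw a labeled scene and the polygons tracing its blocks.

    Pixels of class c in band b are independent draws from
    Normal(mean_c(lambda_b), sd_c(lambda_b)^2), clipped to [0, 1].
    Identical (spec, seed) give identical cubes.
    """
    rng = np.random.default_rng(spec.seed)
    wl = spec.sensor.wavelengths_nm
    nb = wl.size
    cube = np.full((spec.rows, spec.cols, nb), spec.background, dtype=np.float64)
    by_code = {c.class_code: c for c in spec.classes}

    regions: list[ClassRegion] = []
    t = spec.transform
    for k, blk in enumerate(spec.layout):
        cls = by_code[blk.class_code]
        mu = cls.mean_spectrum(wl)
        sd = cls.sd_spectrum(wl)
        shape = (blk.row1 - blk.row0, blk.col1 - blk.col0, nb)
        noise = rng.standard_normal(shape)
        if spec.spectral_ar1:
            rho = spec.spectral_ar1
            for b in range(1, nb):
                noise[:, :, b] = rho * noise[:, :, b - 1] + np.sqrt(1 - rho**2) * noise[:, :, b]
        cube[blk.row0 : blk.row1, blk.col0 : blk.col1, :] = mu + sd * noise

        x_lo, y_hi = t * (blk.col0, blk.row0)
        x_hi, y_lo = t * (blk.col1, blk.row1)
        regions.append(
            ClassRegion(
                geometry=box(x_lo, y_lo, x_hi, y_hi),
                class_code=blk.class_code,
                region_id=f"block_{k}",
            )
        )

    np.clip(cube, 0.0, 1.0, out=cube)
    scene = Scene(values=cube, transform=t, crs=spec.crs, sensor=spec.sensor)
    return scene, regions


def simulate_multi_from_hyper(
    hyper: Scene,
    multi_sensor: SensorModel,
    fwhm_nm: float | Sequence[float] = 60.0,
) -> Scene:
    """Aggregate a hyperspectral cube into a multispectral view.

    Each output band is the unweighted mean of the hyper bands whose
    centers fall in [center - fwhm/2, center + fwhm/2].  The grid is
    unchanged, so both "sensors" observe the same field.
    """
    centers = multi_sensor.wavelengths_nm
    fwhm = np.broadcast_to(np.asarray(fwhm_nm, dtype=float), centers.shape)
    hyper_wl = hyper.sensor.wavelengths_nm
    out = np.empty(hyper.values.shape[:2] + (centers.size,), dtype=np.float64)
    for j, (c, w) in enumerate(zip(centers, fwhm)):
        sel = np.abs(hyper_wl - c) <= w / 2.0
        if not sel.any():
            raise ValueError(
                f"band {multi_sensor.bands[j].name or j} at {c} nm: "
                f"no hyper band within +/- {w / 2} nm"
            )
        out[:, :, j] = hyper.values[:, :, sel].mean(axis=2)
    return Scene(
        values=out,
        transform=hyper.transform,
        crs=hyper.crs,
        sensor=multi_sensor,
        nodata=hyper.nodata,
    )


# ---------------------------------------------------------------------------
# Default study-like configuration


def _vegetation_baseline(w: np.ndarray) -> np.ndarray:
    """Smooth vegetation-like reflectance curve: low visible, NIR plateau,
    declining SWIR.  Values stay well inside [0, 1]."""
    w = np.asarray(w, dtype=float)
    green_bump = 0.04 * np.exp(-(((w - 555.0) / 40.0) ** 2))
    red_edge = 0.38 / (1.0 + np.exp(-(w - 715.0) / 18.0))
    swir_decline = -0.18 / (1.0 + np.exp(-(w - 1550.0) / 160.0))
    return 0.05 + green_bump + red_edge + swir_decline


def default_classes(
    sd: float = 0.02,
    contrast: float = 0.06,
    codes: Sequence[str] = ("3111", "3112", "3115", "3121", "3122"),
) -> tuple[ClassSpectrumSpec, ...]:
    """Five forest-type classes over a shared baseline.

    Each class after the first is offset from the baseline inside one
    discriminative window mimicking the regions where hyperspectral data
    discriminate forest types (blue ~450 nm, NIR ~970 and ~1370 nm, SWIR
    ~1822 nm).  The windows deliberately avoid the multispectral band
    centers (+/- 30 nm) so that contrast lives in hyper-only wavelengths
    and every pair's cross-sensor increment is positive by construction.
    """
    windows = (
        (),  # reference class on the baseline
        ((425.0, 460.0, contrast),),  # blue, below the b2 window
        ((940.0, 990.0, contrast),),  # NIR water-vapor shoulder, above b8a
        ((1350.0, 1390.0, contrast),),  # NIR plateau, between b8a and b11
        ((1800.0, 1845.0, contrast),),  # SWIR, between b11 and b12
    )
    sd_fn = (lambda s: (lambda w: np.full_like(np.asarray(w, float), s)))(sd)
    return tuple(
        ClassSpectrumSpec(code, _vegetation_baseline, sd_fn, win)
        for code, win in zip(codes, windows)
    )


def default_scene_spec(
    seed: int,
    block_px: int = 24,
    sd: float = 0.02,
    contrast: float = 0.06,
    sensor: SensorModel | None = None,
) -> SceneSpec:
    """One labeled field with five fourth-level classes in a row of blocks,
    aggregable to the two third-level groups (311x / 312x)."""
    classes = default_classes(sd=sd, contrast=contrast)
    layout = tuple(
        BlockSpec(0, block_px, i * block_px, (i + 1) * block_px, c.class_code)
        for i, c in enumerate(classes)
    )
    sensor = sensor or make_sensor("hyper")
    return SceneSpec(
        rows=block_px,
        cols=block_px * len(classes),
        pixel_size_m=sensor.ground_resolution_m,
        origin=(600000.0, 4800000.0),
        crs="EPSG:32632",
        layout=layout,
        classes=classes,
        sensor=sensor,
        seed=seed,
    )
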