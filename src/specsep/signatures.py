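"""Per-class sample extraction from labeled polygons and class statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import shapely

from .cube_io import ClassRegion, Scene, SensorModel

__all__ = [
    "ClassSampleSet",
    "ClassBandStats",
    "aggregate_code",
    "extract_class_samples",
    "class_band_stats",
    "median_signature",
]

log = logging.getLogger(__name__)

Level = Literal["third", "fourth"]


@dataclass
class ClassSampleSet:
    """All extracted pixels of one class: n_pixels x n_bands reflectance.

    ``provenance`` holds one (region_id, row, col) triple per sample, in
    sample order; columns follow the sensor band order.
    """

    class_code: str
    sample_matrix: np.ndarray
    provenance: list[tuple[str, int, int]]
    sensor: SensorModel

    def __post_init__(self) -> None:
        self.sample_matrix = np.atleast_2d(np.asarray(self.sample_matrix, dtype=float))
        if self.sample_matrix.shape[0] < 1:
            raise ValueError(f"class {self.class_code}: empty sample set")
        if self.sample_matrix.shape[1] != self.sensor.n_bands:
            raise ValueError(
                f"class {self.class_code}: sample columns "
                f"({self.sample_matrix.shape[1]}) != sensor bands ({self.sensor.n_bands})"
            )

    @property
    def n_pixels(self) -> int:
        return self.sample_matrix.shape[0]


@dataclass
class ClassBandStats:
    """Per-band sample statistics of one class.

    ``sigma`` uses the n-1 denominator; ``covariance`` (optional) is the
    sample covariance, whose diagonal equals sigma**2.
    """

    class_code: str
    n: int
    mu: np.ndarray
    sigma: np.ndarray
    sensor: SensorModel
    covariance: np.ndarray | None = None


def aggregate_code(code: str, level: Level) -> str:
    """Map a fourth-level nomenclature code to its parent at third level
    (e.g. 3111/3112/3115 -> 311); identity at fourth level."""
    if level == "fourth":
        return code
    if level == "third":
        return code[:3]
    raise ValueError(f"unknown nomenclature level {level!r}")


def extract_class_samples(
    scene: Scene,
    regions: Sequence[ClassRegion],
    level: Level = "fourth",
) -> list[ClassSampleSet]:
    """Extract the reflectance of every pixel whose center falls within a
    class polygon, one sample set per class present.

    A pixel belongs to a polygon when its center lies inside or on the
    boundary (shapely ``covers``).  Pixels claimed by polygons of two
    different classes are excluded and logged; pixels with nodata in any
    band are excluded.  A class whose polygons capture no pixel raises.
    """
    if not regions:
        raise ValueError("no regions supplied")
    rows, cols, _ = scene.shape
    xs, ys = scene.transform.pixel_centers(rows, cols)
    points = shapely.points(xs.ravel(), ys.ravel())

    # class claimed per pixel; -1 none, -2 conflicting claims
    claim = np.full(rows * cols, -1, dtype=int)
    owner_region = np.empty(rows * cols, dtype=object)
    codes = sorted({aggregate_code(r.class_code, level) for r in regions})
    code_idx = {c: i for i, c in enumerate(codes)}

    for region in regions:
        code = aggregate_code(region.class_code, level)
        mask = shapely.covers(region.geometry, points)
        idx = code_idx[code]
        hit = np.flatnonzero(mask)
        conflict = hit[(claim[hit] >= 0) & (claim[hit] != idx)]
        if conflict.size:
            log.warning(
                "%d pixels claimed by class %s conflict with another class; excluded",
                conflict.size,
                code,
            )
            claim[conflict] = -2
        ok = hit[claim[hit] == -1]
        claim[ok] = idx
        owner_region[ok] = region.region_id

    nodata_mask = np.any(scene.values == scene.nodata, axis=2).ravel()
    claim[nodata_mask & (claim >= 0)] = -1

    flat = scene.values.reshape(rows * cols, -1)
    out: list[ClassSampleSet] = []
    empty: list[str] = []
    for code in codes:
        sel = np.flatnonzero(claim == code_idx[code])
        if sel.size == 0:
            empty.append(code)
            continue
        prov = [
            (str(owner_region[i]), int(i // cols), int(i % cols)) for i in sel
        ]
        out.append(
            ClassSampleSet(
                class_code=code,
                sample_matrix=flat[sel],
                provenance=prov,
                sensor=scene.sensor,
            )
        )
    if empty:
        raise ValueError(
            f"classes with zero sampled pixels: {empty} "
            "(polygons contain no pixel centers or only nodata)"
        )
    return out


def class_band_stats(samples: ClassSampleSet, with_covariance: bool = False) -> ClassBandStats:
    """Per-band mean and sample standard deviation (n-1 denominator)."""
    n = samples.n_pixels
    if n < 2:
        raise ValueError(
            f"class {samples.class_code}: need at least 2 pixels for statistics, got {n}"
        )
    x = samples.sample_matrix
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=1)
    cov = np.cov(x, rowvar=False, ddof=1) if with_covariance else None
    return ClassBandStats(
        class_code=samples.class_code,
        n=n,
        mu=mu,
        sigma=sigma,
        sensor=samples.sensor,
        covariance=cov,
    )


def median_signature(samples: ClassSampleSet) -> np.ndarray:
    """Per-band median reflectance (midpoint of the central pair for even
    n).  Used for signature plots, not for the separability metrics."""
    return np.median(samples.sample_matrix, axis=0)


def signatures_to_records(sample_sets: Iterable[ClassSampleSet]) -> list[dict]:
    """Tidy rows (class_code, band_index, wavelength_nm, median) for CSV
    export of the signature curves."""
    rows = []
    for s in sample_sets:
        med = median_signature(s)
        for band in s.sensor.bands:
            rows.append(
                {
                    "class_code": s.class_code,
                    "band_index": band.index,
                    "wavelength_nm": band.center_nm,
                    "median_reflectance": float(med[band.index]),
                }
            )
    return rows
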