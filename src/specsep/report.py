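"""Cross-sensor comparison, run orchestration and artifact export.

The headline comparison statistic is the percentage increment of the
hyperspectral sensor's per-pair maximum separability over the
multispectral one's, per metric:

    I = 100 * (max_hyper - max_multi) / max_multi

Per-pair increments are averaged per metric and overall; cross-area
summaries are the arithmetic mean of per-area averages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cube_io, pipeline, signatures, synthetic
from .cube_io import GridDefinition, Scene
from .metrics import METRIC_NAMES
from .pipeline import PairBest

__all__ = [
    "RunConfig",
    "percent_increment",
    "increment_table",
    "summarize_across_areas",
    "run_analysis",
]

log = logging.getLogger(__name__)


def percent_increment(max_hyper: float, max_multi: float) -> float:
    """100 * (max_hyper - max_multi) / max_multi.

    Negative when the multispectral sensor wins.  Undefined (raises)
    when the multispectral maximum is not positive; callers flag such
    rows instead of zeroing them.
    """
    if max_multi <= 0:
        raise ValueError(
            f"increment undefined: multispectral maximum is {max_multi} (must be > 0)"
        )
    return 100.0 * (max_hyper - max_multi) / max_multi


def increment_table(
    best_hyper: Sequence[PairBest],
    best_multi: Sequence[PairBest],
) -> pd.DataFrame:
    """One increment row per (pair, metric) common key.

    Both inputs must cover exactly the same (pair, metric) keys.  Rows
    whose multispectral maximum is not positive carry NaN and
    ``undefined=True`` rather than being dropped.
    """
    kh = {(b.class_pair, b.metric): b for b in best_hyper}
    km = {(b.class_pair, b.metric): b for b in best_multi}
    if kh.keys() != km.keys():
        only_h = sorted(kh.keys() - km.keys())
        only_m = sorted(km.keys() - kh.keys())
        raise ValueError(
            f"pair/metric coverage mismatch: only-hyper={only_h}, only-multi={only_m}"
        )
    rows = []
    for (pair, metric), bh in sorted(kh.items()):
        bm = km[(pair, metric)]
        try:
            inc = percent_increment(bh.max_value, bm.max_value)
            undefined = False
        except ValueError:
            inc = np.nan
            undefined = True
        rows.append(
            {
                "class_a": pair[0],
                "class_b": pair[1],
                "metric": metric,
                "max_hyper": bh.max_value,
                "wavelength_hyper_nm": bh.argmax_wavelength_nm,
                "max_multi": bm.max_value,
                "wavelength_multi_nm": bm.argmax_wavelength_nm,
                "increment_percent": inc,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)


def increment_summary(table: pd.DataFrame) -> dict:
    """Mean increment per metric and overall, ignoring undefined rows."""
    ok = table[~table["undefined"]]
    per_metric = ok.groupby("metric")["increment_percent"].mean().to_dict()
    return {
        "per_metric": {m: float(v) for m, v in per_metric.items()},
        "overall": float(ok["increment_percent"].mean()),
        "n_undefined": int(table["undefined"].sum()),
    }


def summarize_across_areas(per_area_increments: Sequence[float]) -> float:
    """Arithmetic mean of per-area average increments (the cross-area
    headline figure)."""
    vals = [float(v) for v in per_area_increments]
    if not vals:
        raise ValueError("no per-area increments supplied")
    return float(np.mean(vals))


@dataclass
class RunConfig:
    """Configuration of one end-to-end comparison run."""

    hyper_path: str | None = None
    multi_path: str | None = None
    regions_path: str | None = None
    simulate_seed: int | None = None  # if set, inputs are simulated, not read
    level: str = "fourth"
    metrics: tuple[str, ...] = METRIC_NAMES
    jm_sqrt_convention: bool = False
    overlap_tolerance_nm: float = cube_io.DEFAULT_OVERLAP_TOLERANCE_NM
    ridge: float = 1e-10
    out_dir: str = "specsep_out"
    decimals: int = 2
    sim_block_px: int = 24
    sim_sd: float = 0.02
    sim_contrast: float = 0.06

    def __post_init__(self) -> None:
        if self.level not in ("third", "fourth"):
            raise ValueError(f"level must be 'third' or 'fourth', got {self.level!r}")
        bad = set(self.metrics) - set(METRIC_NAMES)
        if bad:
            raise ValueError(f"unknown metrics: {sorted(bad)}")


def _load_inputs(config: RunConfig):
    if config.simulate_seed is not None:
        spec = synthetic.default_scene_spec(
            seed=config.simulate_seed,
            block_px=config.sim_block_px,
            sd=config.sim_sd,
            contrast=config.sim_contrast,
        )
        hyper, regions = synthetic.generate_scene(spec)
        multi = synthetic.simulate_multi_from_hyper(hyper, synthetic.make_sensor("multi"))
        return hyper, multi, regions
    if not (config.hyper_path and config.multi_path and config.regions_path):
        raise ValueError("either simulate_seed or all three input paths must be set")
    hyper = cube_io.read_scene(config.hyper_path)
    multi = cube_io.read_scene(config.multi_path)
    regions = cube_io.read_regions(config.regions_path)
    return hyper, multi, regions


def _align_multi(hyper: Scene, multi: Scene) -> Scene:
    """Nearest-neighbor resample the multispectral scene onto the
    hyperspectral grid when the grids differ."""
    same = (
        multi.transform.to_tuple() == hyper.transform.to_tuple()
        and multi.shape[:2] == hyper.shape[:2]
    )
    if same:
        return multi
    target = GridDefinition(
        rows=hyper.shape[0],
        cols=hyper.shape[1],
        transform=hyper.transform,
        crs=hyper.crs,
    )
    return cube_io.resample_nearest(multi, target)


def _sensor_branch(scene: Scene, regions, config: RunConfig):
    """Extraction -> stats -> separability table -> per-pair maxima."""
    sample_sets = signatures.extract_class_samples(scene, regions, level=config.level)
    stats = [signatures.class_band_stats(s) for s in sample_sets]
    table = pipeline.pairwise_separability(
        stats,
        metrics=config.metrics,
        sqrt_convention=config.jm_sqrt_convention,
        ridge=config.ridge,
    )
    bests = pipeline.all_pair_bests(
        table, metrics=config.metrics, sensor_name=scene.sensor.name
    )
    return sample_sets, table, bests


def run_analysis(config: RunConfig) -> dict:
    """Execute the full two-sensor comparison and write the artifact bundle.

    Returns a dict of in-memory results; CSV/JSON artifacts land in
    ``config.out_dir``.  Deterministic for identical (config, seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    hyper, multi, regions = _load_inputs(config)

    # band bookkeeping: keep the VNIR member of each coincident pair
    sensor_after = cube_io.drop_overlap_bands(hyper.sensor, config.overlap_tolerance_nm)
    if sensor_after.n_bands != hyper.sensor.n_bands:
        log.info(
            "overlap handling: %d -> %d bands", hyper.sensor.n_bands, sensor_after.n_bands
        )
        hyper = cube_io.apply_band_subset(hyper, sensor_after)
    multi = _align_multi(hyper, multi)

    samples_h, table_h, bests_h = _sensor_branch(hyper, regions, config)
    samples_m, table_m, bests_m = _sensor_branch(multi, regions, config)

    inc = increment_table(bests_h, bests_m)
    summary = increment_summary(inc)

    pairs = sorted({b.class_pair for b in bests_h})
    best_wavelengths = pd.DataFrame(
        [
            {
                "class_a": p[0],
                "class_b": p[1],
                "sensor": name,
                "wavelength_nm": wl,
                "mean_normalized": val,
            }
            for name, table in (("hyper", table_h), ("multi", table_m))
            for p in pairs
            for wl, val in [pipeline.mean_metric_best_wavelength(table, p, config.metrics)]
        ]
    )

    dec = config.decimals
    table_h.round(dec).to_csv(out / "separability_hyper.csv", index=False)
    table_m.round(dec).to_csv(out / "separability_multi.csv", index=False)
    table_h.to_csv(out / "separability_hyper_full.csv", index=False)
    table_m.to_csv(out / "separability_multi_full.csv", index=False)
    inc.round(dec).to_csv(out / "increments.csv", index=False)
    best_wavelengths.round(dec).to_csv(out / "best_wavelengths.csv", index=False)
    pd.DataFrame(signatures.signatures_to_records(samples_h)).round(6).to_csv(
        out / "signatures_hyper.csv", index=False
    )
    pd.DataFrame(signatures.signatures_to_records(samples_m)).round(6).to_csv(
        out / "signatures_multi.csv", index=False
    )
    qc = pd.concat(
        [
            pipeline.qc_missing(table_h).assign(sensor="hyper"),
            pipeline.qc_missing(table_m).assign(sensor="multi"),
        ]
    )
    qc.to_csv(out / "qc_undefined.csv", index=False)

    run_log = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "hyper_bands": hyper.sensor.n_bands,
        "multi_bands": multi.sensor.n_bands,
        "classes": sorted({s.class_code for s in samples_h}),
        "jm_convention": "sqrt" if config.jm_sqrt_convention else "bound2",
        "increment_summary": summary,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))

    return {
        "hyper_scene": hyper,
        "multi_scene": multi,
        "separability_hyper": table_h,
        "separability_multi": table_m,
        "bests_hyper": bests_h,
        "bests_multi": bests_m,
        "increments": inc,
        "increment_summary": summary,
        "best_wavelengths": best_wavelengths,
    }
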