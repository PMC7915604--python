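"""specsep: band-by-band pairwise spectral class-separability analysis.

Pipeline: labeled reflectance cubes -> per-class samples -> per-band
class statistics -> four separability criteria per class pair and band
-> best-band selection -> cross-sensor percentage increments.  A
synthetic-scene generator with known class statistics provides a
ground-truth oracle for every stage.
"""

from .cube_io import (
    Affine,
    BandDef,
    ClassRegion,
    GridDefinition,
    Scene,
    SensorModel,
    drop_overlap_bands,
    read_regions,
    read_scene,
    resample_nearest,
    write_regions,
    write_scene,
)
from .metrics import (
    GaussianClassSummary,
    MetricValue,
    bhattacharyya,
    divergence,
    jeffries_matusita,
    m_statistic,
    normalize_metric,
    transformed_divergence,
)
from .pipeline import (
    PairBest,
    best_band,
    enumerate_pairs,
    mean_metric_best_wavelength,
    pairwise_separability,
)
from .report import (
    RunConfig,
    increment_table,
    percent_increment,
    run_analysis,
    summarize_across_areas,
)
from .signatures import (
    ClassBandStats,
    ClassSampleSet,
    class_band_stats,
    extract_class_samples,
    median_signature,
)
from .synthetic import (
    ClassSpectrumSpec,
    SceneSpec,
    generate_scene,
    make_sensor,
    simulate_multi_from_hyper,
)

__version__ = "0.1.0"

__all__ = [
    "Affine",
    "BandDef",
    "ClassBandStats",
    "ClassRegion",
    "ClassSampleSet",
    "ClassSpectrumSpec",
    "GaussianClassSummary",
    "GridDefinition",
    "MetricValue",
    "PairBest",
    "RunConfig",
    "Scene",
    "SceneSpec",
    "SensorModel",
    "best_band",
    "bhattacharyya",
    "class_band_stats",
    "divergence",
    "drop_overlap_bands",
    "enumerate_pairs",
    "extract_class_samples",
    "generate_scene",
    "increment_table",
    "jeffries_matusita",
    "m_statistic",
    "make_sensor",
    "mean_metric_best_wavelength",
    "median_signature",
    "normalize_metric",
    "pairwise_separability",
    "percent_increment",
    "read_regions",
    "read_scene",
    "resample_nearest",
    "run_analysis",
    "simulate_multi_from_hyper",
    "summarize_across_areas",
    "transformed_divergence",
    "write_regions",
    "write_scene",
]
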