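"""Band-by-band pairwise separability tables, per-pair maxima and
best-wavelength selection by the mean of the normalized metrics."""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES, GaussianClassSummary, all_metrics
from .signatures import ClassBandStats

__all__ = [
    "PairBest",
    "enumerate_pairs",
    "pairwise_separability",
    "best_band",
    "mean_metric_best_wavelength",
    "qc_missing",
]

#: SeparabilityTable column layout (tidy: one row per pair x band x metric)
TABLE_COLUMNS = (
    "class_a",
    "class_b",
    "band_index",
    "wavelength_nm",
    "metric",
    "value",
    "normalized",
)


@dataclass(frozen=True)
class PairBest:
    """Maximum of one metric over bands for one class pair."""

    class_pair: tuple[str, str]
    metric: str
    max_value: float
    argmax_wavelength_nm: float
    sensor_name: str


def enumerate_pairs(class_codes: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered pairs of distinct codes in canonical (sorted) order."""
    codes = sorted(set(class_codes))
    if len(codes) < 2:
        raise ValueError(f"need at least 2 distinct class codes, got {len(codes)}")
    return list(itertools.combinations(codes, 2))


def pairwise_separability(
    stats: Sequence[ClassBandStats],
    metrics: Sequence[str] = METRIC_NAMES,
    sqrt_convention: bool = False,
    ridge: float = 1e-10,
) -> pd.DataFrame:
    """Univariate metric values for every (class pair, band, metric).

    All classes must share the same band list.  Bands where a metric is
    undefined for a pair (degenerate variance surviving the ridge floor)
    are recorded as NaN rather than dropped, so QC can count them.
    """
    if len(stats) < 2:
        raise ValueError("need statistics for at least 2 classes")
    ref_wl = stats[0].sensor.wavelengths_nm
    for s in stats[1:]:
        if s.sensor.n_bands != ref_wl.size or not np.allclose(
            s.sensor.wavelengths_nm, ref_wl
        ):
            raise ValueError(
                f"band list of class {s.class_code} differs from class {stats[0].class_code}"
            )
    by_code = {s.class_code: s for s in stats}
    pairs = enumerate_pairs(list(by_code))
    rows = []
    for ca, cb in pairs:
        sa, sb = by_code[ca], by_code[cb]
        for b in range(ref_wl.size):
            ga = GaussianClassSummary.univariate(sa.mu[b], sa.sigma[b])
            gb = GaussianClassSummary.univariate(sb.mu[b], sb.sigma[b])
            try:
                vals = all_metrics(
                    ga, gb, tuple(metrics), sqrt_convention=sqrt_convention, ridge=ridge
                )
            except ValueError:
                vals = {}
            for m in metrics:
                mv = vals.get(m)
                rows.append(
                    (
                        ca,
                        cb,
                        b,
                        float(ref_wl[b]),
                        m,
                        mv.value if mv else np.nan,
                        mv.normalized if mv else np.nan,
                    )
                )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def _pair_rows(table: pd.DataFrame, pair: tuple[str, str]) -> pd.DataFrame:
    ca, cb = sorted(pair)
    sel = table[(table["class_a"] == ca) & (table["class_b"] == cb)]
    if sel.empty:
        raise ValueError(f"pair {ca}_{cb} not present in the table")
    return sel


def best_band(
    table: pd.DataFrame,
    pair: tuple[str, str],
    metric: str,
    sensor_name: str = "",
) -> PairBest:
    """Maximum value over bands for one pair and metric, with the
    wavelength attaining it; ties break toward the lowest wavelength.
    NaN (undefined) bands are excluded from the maximum."""
    sel = _pair_rows(table, pair)
    sel = sel[sel["metric"] == metric].dropna(subset=["value"])
    if sel.empty:
        raise ValueError(f"no defined values for pair {pair} metric {metric}")
    vmax = sel["value"].max()
    winners = sel[sel["value"] == vmax]
    wl = winners["wavelength_nm"].min()
    return PairBest(
        class_pair=tuple(sorted(pair)),
        metric=metric,
        max_value=float(vmax),
        argmax_wavelength_nm=float(wl),
        sensor_name=sensor_name,
    )


def mean_metric_best_wavelength(
    table: pd.DataFrame,
    pair: tuple[str, str],
    metrics: Sequence[str] = METRIC_NAMES,
) -> tuple[float, float]:
    """Wavelength maximizing the per-band arithmetic mean of the
    normalized metric values (lowest-wavelength tie-break).

    Returns (wavelength_nm, mean_normalized_value).  The normalized
    scale is required because the raw metrics live on different scales
    and a raw average would be dominated by the unbounded ones.
    """
    sel = _pair_rows(table, pair)
    present = set(sel["metric"].unique())
    missing = set(metrics) - present
    if missing:
        raise ValueError(f"pair {pair}: metrics missing from table: {sorted(missing)}")
    sub = sel[sel["metric"].isin(list(metrics))]
    per_band = sub.groupby("wavelength_nm")["normalized"].mean()
    best = per_band.max()
    wl = per_band[per_band == best].index.min()
    return float(wl), float(best)


def all_pair_bests(
    table: pd.DataFrame,
    metrics: Sequence[str] = METRIC_NAMES,
    sensor_name: str = "",
) -> list[PairBest]:
    """best_band for every pair and metric present in the table."""
    pairs = sorted(
        {(a, b) for a, b in zip(table["class_a"], table["class_b"])}
    )
    return [
        best_band(table, pair, m, sensor_name=sensor_name)
        for pair in pairs
        for m in metrics
    ]


def qc_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Count undefined (NaN) metric values per pair and metric."""
    t = table.copy()
    t["undefined"] = t["value"].isna()
    return (
        t.groupby(["class_a", "class_b", "metric"])["undefined"]
        .sum()
        .reset_index(name="n_undefined")
    )
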