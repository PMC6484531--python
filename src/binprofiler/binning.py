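"""Quantile binning of well populations against pooled plate controls.

For every plate and parameter, the pooled negative-control (DMSO) cell values
define ``k`` equal-occupancy bins: the interior cutoffs are the
``i * 100/k``-th percentiles (the 20th/40th/60th/80th for k=5).  Each
experimental well's cells are then counted into these bins, converted to
percentages of the well population, and standardized into z-scores against
the mean and standard deviation of the control wells' percentages.

Binning is scale-free per plate: any strictly increasing transform of a
parameter's values leaves every bin count unchanged, so the binned statistics
can be computed on unnormalized cell data.

Interval convention: bins are half-open ``[e_{i-1}, e_i)`` with the last bin
closed above; a value exactly on a cutoff goes to the upper bin.  Duplicated
cutoffs (discrete or near-constant parameters, e.g. nuclei count) create
zero-width bins that can hold no cells; only bins of nonzero width are
"instantiated" and carry statistics — uninstantiated bins yield missing
features, removed later by the fingerprint missing-column filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    CONCENTRATION,
    MOA,
    PLATE,
    TREATMENT,
    WELL,
    CellFeatureTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

BIN_COLUMNS = [PLATE, WELL, TREATMENT, "parameter", "bin", "count", "percent"]


@dataclass(frozen=True)
class BinEdgeSet:
    """Quantile cutoffs of one parameter on one plate.

    ``edges`` are the k-1 interior cutoffs (nondecreasing).  Bin ``i``
    (1-based) spans ``[edges[i-2], edges[i-1])``, with bin 1 open below and
    bin k closed above.  ``instantiated_bins`` lists bins of nonzero width.
    """

    plate: object
    parameter: str
    k: int
    edges: tuple[float, ...]
    instantiated_bins: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.edges) != self.k - 1:
            raise ValueError(f"expected {self.k - 1} interior edges, got {len(self.edges)}")
        if any(a > b for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be nondecreasing")


def _instantiated(edges: np.ndarray, k: int) -> tuple[int, ...]:
    # Bin 1 is open below and bin k closed above: always nonzero width.
    # An interior bin i (2..k-1) is zero-width iff its two edges coincide.
    bins = [1]
    for i in range(2, k):
        if edges[i - 2] < edges[i - 1]:
            bins.append(i)
    bins.append(k)
    return tuple(bins)


def compute_bin_edges(
    table: CellFeatureTable,
    k: int = 5,
    control: str | None = None,
    percentile_method: str = "linear",
    pool: str = "plate",
) -> dict[tuple[object, str], BinEdgeSet]:
    """Quantile cutoffs of the pooled control population per plate x parameter.

    ``pool="screen"`` pools controls across all plates instead (the same
    edges are then reused on every plate).  A (plate, parameter) whose
    control values are all missing is omitted with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    control = control if control is not None else table.control
    ctrl = table.data[table.data[TREATMENT] == control]
    if ctrl.empty:
        raise ValidationError("no control cells in table")
    qs = [100.0 * i / k for i in range(1, k)]
    out: dict[tuple[object, str], BinEdgeSet] = {}
    plates = sorted(table.data[PLATE].unique())

    def edges_for(values: np.ndarray) -> np.ndarray | None:
        values = values[~np.isnan(values)]
        if values.size == 0:
            return None
        return np.percentile(values, qs, method=percentile_method)

    if pool == "screen":
        for f in table.features:
            e = edges_for(ctrl[f].to_numpy(dtype=float))
            if e is None:
                logger.warning("parameter %r has no control values; omitted", f)
                continue
            for plate in plates:
                out[(plate, f)] = BinEdgeSet(plate, f, k, tuple(e), _instantiated(e, k))
        return out

    for plate, grp in ctrl.groupby(PLATE, observed=True):
        for f in table.features:
            e = edges_for(grp[f].to_numpy(dtype=float))
            if e is None:
                logger.warning(
                    "parameter %r has no control values on plate %r; omitted", f, plate
                )
                continue
            out[(plate, f)] = BinEdgeSet(plate, f, k, tuple(e), _instantiated(e, k))
    return out


def assign_bins(values: np.ndarray, edge_set: BinEdgeSet) -> np.ndarray:
    """Count values into the k bins of ``edge_set``.

    Missing values are skipped; counts over instantiated bins sum to the
    number of non-missing values.  A value equal to a cutoff goes to the
    upper bin, so zero-width bins receive no cells.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    idx = np.searchsorted(np.asarray(edge_set.edges), values, side="right")
    return np.bincount(idx, minlength=edge_set.k)


def bin_well_counts(
    table: CellFeatureTable,
    edges: Mapping[tuple[object, str], BinEdgeSet],
) -> pd.DataFrame:
    """Per-well bin counts and percentages, long format.

    One row per (plate, well, parameter, bin) for instantiated bins; the
    ``percent`` column is the share of the well's non-missing cells for that
    parameter.  Uninstantiated bins are not emitted (missing features).
    """
    df = table.data
    records: list[dict] = []
    carried = [c for c in (TREATMENT, MOA, CONCENTRATION) if c in df.columns]
    for (plate, well), grp in df.groupby([PLATE, WELL], observed=True, sort=True):
        meta = {PLATE: plate, WELL: well}
        for c in carried:
            meta[c] = grp[c].iloc[0]
        for f in table.features:
            es = edges.get((plate, f))
            if es is None:
                continue
            counts = assign_bins(grp[f].to_numpy(dtype=float), es)
            n = int(counts.sum())
            if n == 0:
                continue
            for b in es.instantiated_bins:
                records.append(
                    {
                        **meta,
                        "parameter": f,
                        "bin": b,
                        "count": int(counts[b - 1]),
                        "percent": 100.0 * counts[b - 1] / n,
                        "n_cells": n,
                    }
                )
    return pd.DataFrame.from_records(records)


def dmso_baseline(
    binned: pd.DataFrame, control: str = "DMSO"
) -> pd.DataFrame:
    """Mean and sample sd of control-well bin percentages.

    One row per (plate, parameter, bin) with ``mean_percent``, ``sd_percent``
    (n-1 denominator) and ``n_wells``.  An sd of zero flags a degenerate bin;
    its z-scores will be missing.
    """
    ctrl = binned[binned[TREATMENT] == control]
    if ctrl.empty:
        raise ValidationError("no control wells in binned data")
    n_wells = ctrl.groupby(PLATE, observed=True)[WELL].nunique()
    bad = [str(p) for p, n in n_wells.items() if n < 2]
    if bad:
        raise ValidationError(f"plate(s) {bad} have < 2 control wells")
    agg = (
        ctrl.groupby([PLATE, "parameter", "bin"], observed=True)["percent"]
        .agg(mean_percent="mean", sd_percent=lambda s: s.std(ddof=1), n_wells="size")
        .reset_index()
    )
    return agg


def bin_z_scores(binned: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``z`` column: (percent - mean_percent) / sd_percent.

    Bins with zero or missing baseline sd yield missing z.
    """
    merged = binned.merge(
        baseline[[PLATE, "parameter", "bin", "mean_percent", "sd_percent"]],
        on=[PLATE, "parameter", "bin"],
        how="left",
    )
    sd = merged["sd_percent"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (merged["percent"] - merged["mean_percent"]) / sd
    z[sd == 0] = np.nan
    out = binned.copy()
    out["z"] = np.asarray(z)
    return out


def bin_profiles(
    table: CellFeatureTable,
    k: int = 5,
    control: str | None = None,
    percentile_method: str = "linear",
    pool: str = "plate",
) -> tuple[pd.DataFrame, dict[tuple[object, str], BinEdgeSet]]:
    """End-to-end binning: edges, counts, control baseline, z-scores.

    Returns the long-format binned table (with ``z``) and the edge sets.
    """
    control = control if control is not None else table.control
    edges = compute_bin_edges(
        table, k=k, control=control, percentile_method=percentile_method, pool=pool
    )
    counts = bin_well_counts(table, edges)
    baseline = dmso_baseline(counts, control=control)
    return bin_z_scores(counts, baseline), edges


def bin_feature_name(parameter: str, bin_index: int) -> str:
    return f"{parameter}__bin{bin_index}__z"


def parse_bin_feature(name: str) -> tuple[str, int]:
    """Inverse of :func:`bin_feature_name`."""
    stem, _, _ = name.rpartition("__z")
    param, _, b = stem.rpartition("__bin")
    return param, int(b)


def to_wide(binned: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long binned table to one row per well.

    Columns are named ``<parameter>__bin<i>__z``; wells missing a
    (parameter, bin) get NaN there.
    """
    binned = binned.copy()
    binned["feature"] = [
        bin_feature_name(p, b) for p, b in zip(binned["parameter"], binned["bin"])
    ]
    carried = [c for c in (TREATMENT, MOA, CONCENTRATION) if c in binned.columns]
    wide = binned.pivot_table(
        index=[PLATE, WELL], columns="feature", values="z", aggfunc="first", dropna=False
    )
    meta = binned.groupby([PLATE, WELL], observed=True)[carried].first()
    out = pd.concat([meta, wide], axis=1).reset_index()
    out.columns.name = None
    return out
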