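"""Data model, readers/writers, and per-plate normalization schemes.

The central container is :class:`CellFeatureTable`: one row per segmented
cell, metadata columns identifying plate / well / treatment (and optionally
mode of action and concentration), and an arbitrary number of numeric
morphological feature columns ("parameters").  Two normalization schemes are
provided, both computed per plate against the negative-control (DMSO)
population:

* linear percentile scaling of single-cell values (control 1st percentile
  mapped to 0, 99th percentile to 1, no clipping), and
* z-normalization of well averages against the control well averages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved metadata column names used throughout the package.
PLATE = "plate"
WELL = "well"
TREATMENT = "treatment"
MOA = "moa"
CONCENTRATION = "concentration"
META_COLUMNS = (PLATE, WELL, TREATMENT, MOA, CONCENTRATION)

DEFAULT_CONTROL = "DMSO"


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """The table content violates an invariant (e.g. a plate without controls)."""


@dataclass(frozen=True)
class NormalizationSpec:
    """Configuration of a normalization scheme.

    scheme
        ``"linear_percentile"`` scales single-cell values so that the control
        ``low_percentile`` maps to 0 and ``high_percentile`` to 1;
        ``"zscore_vs_dmso"`` standardizes well averages against the control
        well averages of the same plate.
    level
        The granularity the scheme operates on (``"cell"`` or
        ``"well_average"``).
    percentile_method
        Quantile interpolation rule passed to :func:`numpy.percentile`.
    """

    scheme: str = "linear_percentile"
    low_percentile: float = 1.0
    high_percentile: float = 99.0
    level: str = "cell"
    percentile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.scheme not in ("linear_percentile", "zscore_vs_dmso"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not (0.0 < self.low_percentile < self.high_percentile < 100.0):
            raise ValueError(
                "percentiles must satisfy 0 < low < high < 100, got "
                f"({self.low_percentile}, {self.high_percentile})"
            )


@dataclass
class CellFeatureTable:
    """Per-cell feature table.

    ``data`` holds one row per cell with the metadata columns ``plate``,
    ``well``, ``treatment`` (and optionally ``moa``, ``concentration``)
    followed by numeric feature columns listed in ``features``.  Feature
    values are finite reals or NaN (explicitly missing).
    """

    data: pd.DataFrame
    features: tuple[str, ...]
    control: str = DEFAULT_CONTROL

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        validate_cell_table(self)

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def feature_frame(self) -> pd.DataFrame:
        return self.data[list(self.features)]

    def control_mask(self) -> pd.Series:
        return self.data[TREATMENT] == self.control

    def with_data(self, data: pd.DataFrame, features: Sequence[str] | None = None) -> "CellFeatureTable":
        return CellFeatureTable(
            data=data,
            features=tuple(features) if features is not None else self.features,
            control=self.control,
        )


def validate_cell_table(table: CellFeatureTable) -> None:
    df = table.data
    for col in (PLATE, WELL, TREATMENT):
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing")
    missing = [f for f in table.features if f not in df.columns]
    if missing:
        raise SchemaError(f"feature columns missing from data: {missing}")
    for f in table.features:
        if not pd.api.types.is_numeric_dtype(df[f]):
            raise SchemaError(f"feature column {f!r} is not numeric")
        values = df[f].to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValidationError(f"feature column {f!r} contains non-finite values")
    if len(df):
        has_control = df.groupby(PLATE, observed=True)[TREATMENT].apply(
            lambda s: (s == table.control).any()
        )
        bad = [str(p) for p, ok in has_control.items() if not ok]
        if bad:
            raise ValidationError(
                f"plate(s) {bad} have no {table.control!r} control wells"
            )


def read_cell_table(
    path: str | Path,
    schema: Mapping[str, object] | None = None,
    control: str = DEFAULT_CONTROL,
) -> CellFeatureTable:
    """Read a per-cell feature table from CSV or Parquet.

    ``schema`` maps column roles to column names in the file:
    ``{"plate": ..., "well": ..., "treatment": ..., "moa": ...,
    "concentration": ..., "features": [...]}``.  Roles other than the first
    three are optional; if ``features`` is omitted, every remaining numeric
    column is used and non-numeric extras are excluded.
    """
    path = Path(path)
    if path.suffix.lower() in (".parquet", ".pq"):
        raw = pd.read_parquet(path)
    else:
        raw = pd.read_csv(path)
    schema = dict(schema or {})
    rename: dict[str, str] = {}
    for role in (PLATE, WELL, TREATMENT, MOA, CONCENTRATION):
        src = schema.get(role, role if role in raw.columns else None)
        if src is None:
            if role in (PLATE, WELL, TREATMENT):
                raise SchemaError(f"schema does not name a {role!r} column")
            continue
        if src not in raw.columns:
            raise SchemaError(f"column {src!r} (role {role!r}) not found in {path.name}")
        rename[str(src)] = role
    df = raw.rename(columns=rename)
    meta_present = [c for c in META_COLUMNS if c in df.columns]
    if "features" in schema and schema["features"] is not None:
        features = [str(f) for f in schema["features"]]
        absent = [f for f in features if f not in df.columns]
        if absent:
            raise SchemaError(f"feature columns not found: {absent}")
    else:
        features = [
            c
            for c in df.columns
            if c not in meta_present and pd.api.types.is_numeric_dtype(df[c])
        ]
        dropped = [c for c in df.columns if c not in meta_present and c not in features]
        if dropped:
            logger.warning("excluding non-numeric columns: %s", dropped)
    df = df[meta_present + features].reset_index(drop=True)
    return CellFeatureTable(data=df, features=tuple(features), control=control)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as CSV or Parquet depending on the file suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".parquet", ".pq"):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def load_schema(path: str | Path) -> dict:
    """Load a JSON or YAML column-role schema."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_linear_percentile(
    table: CellFeatureTable, spec: NormalizationSpec | None = None
) -> CellFeatureTable:
    """Linearly scale single-cell values per plate against the controls.

    With ``p_lo``/``p_hi`` the control population's low/high percentiles of a
    parameter on a plate, every cell value ``x`` maps to
    ``(x - p_lo) / (p_hi - p_lo)``.  Values may leave [0, 1]; no clipping is
    applied.  Parameters whose control percentiles coincide on any plate are
    degenerate there and are dropped from the whole table (logged).
    """
    spec = spec or NormalizationSpec(scheme="linear_percentile")
    if spec.scheme != "linear_percentile":
        raise ValueError("spec.scheme must be 'linear_percentile'")
    df = table.data.copy()
    ctrl = df[table.control_mask()]
    if ctrl.empty:
        raise ValidationError("no control cells in table")
    degenerate: set[str] = set()
    for plate, grp in ctrl.groupby(PLATE, observed=True):
        for f in table.features:
            vals = grp[f].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                degenerate.add(f)
                continue
            lo, hi = np.percentile(
                vals,
                [spec.low_percentile, spec.high_percentile],
                method=spec.percentile_method,
            )
            if hi == lo:
                degenerate.add(f)
                continue
            mask = df[PLATE] == plate
            df.loc[mask, f] = (df.loc[mask, f] - lo) / (hi - lo)
    if degenerate:
        logger.warning(
            "dropping %d degenerate parameter(s) after percentile scaling: %s",
            len(degenerate),
            sorted(degenerate),
        )
    kept = tuple(f for f in table.features if f not in degenerate)
    if not kept:
        raise ValidationError("all parameters degenerate under percentile scaling")
    meta = [c for c in META_COLUMNS if c in df.columns]
    return table.with_data(df[meta + list(kept)], features=kept)


def well_average(
    table: CellFeatureTable, min_cells: int = 50
) -> pd.DataFrame:
    """Arithmetic mean of the single-cell data of each well.

    Returns one row per (plate, well) with the metadata, a ``n_cells``
    column, a ``low_cell_count`` flag for wells below ``min_cells``, and one
    column per parameter.  Missing cell values are skipped; empty wells are
    omitted with a warning.
    """
    if table.n_cells == 0:
        raise ValidationError("empty table")
    df = table.data
    keys = [PLATE, WELL]
    carried = [c for c in (TREATMENT, MOA, CONCENTRATION) if c in df.columns]
    grouped = df.groupby(keys, observed=True, sort=True)
    means = grouped[list(table.features)].mean()
    n_cells = grouped.size().rename("n_cells")
    meta = grouped[carried].first()
    out = pd.concat([meta, n_cells, means], axis=1).reset_index()
    out["low_cell_count"] = out["n_cells"] < min_cells
    if out["low_cell_count"].any():
        logger.warning(
            "%d well(s) have fewer than %d cells", int(out["low_cell_count"].sum()), min_cells
        )
    return out


def zscore_well_averages(
    profiles: pd.DataFrame,
    features: Sequence[str],
    control: str = DEFAULT_CONTROL,
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Z-normalize well averages per plate against the control wells.

    For each plate and parameter the control well averages define
    ``mean_DMSO`` and ``sd_DMSO`` (sample sd, n-1 denominator); every well
    average becomes ``(x - mean_DMSO) / sd_DMSO``.  Parameters whose control
    sd is zero on some plate are dropped table-wide.  Returns the transformed
    profiles and the retained feature names.
    """
    out = profiles.copy()
    dropped: set[str] = set()
    for plate, grp in profiles.groupby(PLATE, observed=True):
        ctrl = grp[grp[TREATMENT] == control]
        if len(ctrl) < 2:
            raise ValidationError(
                f"plate {plate!r} has {len(ctrl)} control well(s); need >= 2"
            )
        mask = out[PLATE] == plate
        for f in features:
            mu = ctrl[f].mean()
            sd = ctrl[f].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                dropped.add(f)
                continue
            out.loc[mask, f] = (out.loc[mask, f] - mu) / sd
    if dropped:
        logger.warning("dropping %d parameter(s) with zero control sd: %s", len(dropped), sorted(dropped))
    kept = tuple(f for f in features if f not in dropped)
    out = out.drop(columns=sorted(dropped))
    return out, kept


def median_replicates(
    profiles: pd.DataFrame,
    features: Sequence[str],
    group_keys: Sequence[str] = (TREATMENT, CONCENTRATION),
) -> pd.DataFrame:
    """Collapse replicate profiles to their componentwise median.

    Profiles are grouped by ``group_keys`` (default compound and
    concentration); each feature becomes the median over the group (even
    counts use the mean-of-middle convention of :func:`numpy.median`).  The
    mode-of-action label is carried through and must be consistent within a
    group.
    """
    keys = [k for k in group_keys if k in profiles.columns]
    if not keys:
        raise ValueError("no replicate grouping key present in profiles")
    if MOA in profiles.columns:
        n_labels = profiles.groupby(keys, observed=True, dropna=False)[MOA].nunique(dropna=False)
        bad = n_labels[n_labels > 1]
        if len(bad):
            raise ValidationError(f"conflicting MoA labels within replicate group(s): {list(bad.index)}")
    grouped = profiles.groupby(keys, observed=True, dropna=False, sort=True)
    med = grouped[list(features)].median()
    carried = [c for c in (MOA,) if c in profiles.columns]
    meta = grouped[carried].first() if carried else None
    parts = [meta, med] if meta is not None else [med]
    return pd.concat(parts, axis=1).reset_index()
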