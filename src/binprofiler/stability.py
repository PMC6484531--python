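"""Stable-parameter selection from negative controls only.

Sampling cells of a control well into k equal-occupancy bins is drawing with
replacement from an urn, so the per-well bin counts follow a multinomial with
equal expected occupancy over the instantiated bins.  A chi-square
goodness-of-fit test per (well, parameter), Bonferroni-adjusted within the
plate, classifies each well as consistent with the expected occupancy or not.
A parameter's *stability fraction* is the share of tested control wells whose
adjusted p-value exceeds the cutoff (0.05 by default): stable parameters sit
near 1, noisy parameters (well-to-well distributional drift) fall well below.

The threshold ladder removes parameters stepwise — first those whose
stability fraction is below 0.01, then 0.06, and so forth up to 0.96 in steps
of 0.05 — yielding 20 nested fingerprints of increasingly stable parameters.
Because only control wells enter, the selection is blind to treatment labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import PLATE, TREATMENT, WELL, ValidationError

logger = logging.getLogger(__name__)

#: The 20 ladder thresholds: 0.01, 0.06, ..., 0.96.
LADDER_THRESHOLDS = tuple(round(0.01 + 0.05 * i, 2) for i in range(20))

DEFAULT_CUTOFF = 0.05
DEFAULT_MIN_CELLS = 50


class UntestableError(ValueError):
    """The multinomial test is undefined (fewer than two occupied categories)."""


def multinomial_chisq(
    observed_counts: Sequence[int],
    expected_proportions: Sequence[float] | None = None,
) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit of bin counts against expected occupancy.

    ``chi2 = sum((O_i - E_i)^2 / E_i)`` with ``E_i = n * p_i`` over the given
    bins, ``df = len(counts) - 1``, and the p-value the upper chi-square tail.
    Default expectation is uniform occupancy.
    """
    obs = np.asarray(observed_counts, dtype=float)
    n = obs.sum()
    if n <= 0:
        raise ValueError("all counts are zero")
    if obs.size < 2:
        raise UntestableError("need at least two bins to test")
    if expected_proportions is None:
        p = np.full(obs.size, 1.0 / obs.size)
    else:
        p = np.asarray(expected_proportions, dtype=float)
        if p.size != obs.size:
            raise ValueError("expected_proportions length mismatch")
        if (p <= 0).any():
            raise ValueError("expected proportions must be positive")
        p = p / p.sum()
    expected = n * p
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def bonferroni_adjust(p_values: Iterable[float], family_size: int) -> np.ndarray:
    """Bonferroni adjustment: ``p_adj = min(1, p * family_size)``."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    p = np.asarray(list(p_values), dtype=float)
    return np.minimum(1.0, p * family_size)


def well_parameter_tests(
    binned: pd.DataFrame,
    control: str = "DMSO",
    min_cells: int = DEFAULT_MIN_CELLS,
    family: str = "plate",
) -> pd.DataFrame:
    """Chi-square tests of every control well x parameter against uniform occupancy.

    Expected occupancy is uniform over the instantiated bins present in the
    binned table (renormalized), keeping discrete parameters with fewer than
    k instantiated bins testable.  Wells with fewer than ``min_cells``
    non-missing cells for a parameter are excluded, as are parameters with a
    single instantiated bin (untestable).  Bonferroni family size is the
    number of computed tests per plate (``family="plate"``) or over the whole
    screen (``family="screen"``).
    """
    ctrl = binned[binned[TREATMENT] == control]
    if ctrl.empty:
        raise ValidationError("no control wells in binned data")
    records: list[dict] = []
    for (plate, well, param), grp in ctrl.groupby(
        [PLATE, WELL, "parameter"], observed=True, sort=True
    ):
        counts = grp["count"].to_numpy(dtype=float)
        n = counts.sum()
        if n < min_cells:
            continue
        if len(counts) < 2:
            continue  # single instantiated bin: untestable
        chi2, df, p = multinomial_chisq(counts)
        records.append(
            {
                PLATE: plate,
                WELL: well,
                "parameter": param,
                "n": int(n),
                "chi2": chi2,
                "df": df,
                "p": p,
            }
        )
    tests = pd.DataFrame.from_records(records)
    if tests.empty:
        return tests.reindex(columns=[PLATE, WELL, "parameter", "n", "chi2", "df", "p", "p_adj"])
    if family == "screen":
        tests["p_adj"] = bonferroni_adjust(tests["p"], len(tests))
    else:
        tests["p_adj"] = np.nan
        for plate, grp in tests.groupby(PLATE, observed=True):
            tests.loc[grp.index, "p_adj"] = bonferroni_adjust(grp["p"], len(grp))
    return tests


def stability_fractions(
    tests: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Per-parameter fraction of control wells consistent with uniform occupancy.

    A well passes when its Bonferroni-adjusted p-value exceeds ``cutoff``.
    Returns one row per parameter: ``wells_tested``, ``wells_passing``,
    ``fraction_passing``.
    """
    if tests.empty:
        raise ValidationError("no tests to summarize")
    agg = (
        tests.assign(passing=tests["p_adj"] > cutoff)
        .groupby("parameter", observed=True)["passing"]
        .agg(wells_tested="size", wells_passing="sum")
        .reset_index()
    )
    agg["wells_passing"] = agg["wells_passing"].astype(int)
    agg["fraction_passing"] = agg["wells_passing"] / agg["wells_tested"]
    return agg


def stability_ladder(
    reports: pd.DataFrame,
    thresholds: Sequence[float] = LADDER_THRESHOLDS,
) -> list[tuple[float, tuple[str, ...]]]:
    """Nested retained-parameter sets over the stability-threshold ladder.

    At threshold ``t`` the fingerprint keeps parameters whose
    ``fraction_passing >= t``; the 20 default thresholds run 0.01..0.96 in
    steps of 0.05, producing nonincreasing nested sets.  Parameters with no
    testable well are treated as unstable and never retained.
    """
    if reports.empty:
        raise ValidationError("empty stability report")
    tested = reports[reports["wells_tested"] > 0]
    out: list[tuple[float, tuple[str, ...]]] = []
    for t in thresholds:
        kept = tested.loc[tested["fraction_passing"] >= t, "parameter"]
        out.append((float(t), tuple(sorted(kept))))
    return out


def select_best_threshold(
    ladder: Sequence[tuple[float, tuple[str, ...]]],
    evaluate: Callable[[tuple[str, ...]], float],
) -> tuple[float, pd.DataFrame]:
    """Pick the ladder threshold whose fingerprint classifies best.

    ``evaluate`` maps a retained-parameter set to a classification accuracy
    (typically leave-one-out nearest-neighbor accuracy, see
    :func:`binprofiler.profiling.nn_loo_classify`).  Ties break toward the
    larger threshold (the sparser fingerprint); thresholds with an empty
    retained set are skipped.  Returns the winning threshold and the full
    scan table (threshold, n_parameters, accuracy).
    """
    rows: list[dict] = []
    best: tuple[float, float] | None = None
    for t, params in ladder:
        if not params:
            logger.warning("threshold %.2f retains no parameters; skipped", t)
            continue
        acc = float(evaluate(params))
        rows.append({"threshold": t, "n_parameters": len(params), "accuracy": acc})
        if best is None or acc > best[1] or (acc == best[1] and t > best[0]):
            best = (t, acc)
    if best is None:
        raise ValidationError("no threshold retained any parameters")
    return best[0], pd.DataFrame(rows)
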