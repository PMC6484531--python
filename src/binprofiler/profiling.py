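"""Fingerprint assembly and cosine nearest-neighbor mode-of-action classification.

A fingerprint is one feature vector per profile (a well, or the median over
replicates of a compound/concentration).  Three modes are supported:

* ``well_average`` — one feature per parameter (the z-normalized well mean),
* ``all_bins``     — one feature per (parameter, bin) z-score,
* ``extreme_bins`` — only the lowest and highest bins (the 20% and 100% bins
  for k = 5), where phenotype shifts concentrate.

Profiles are compared by cosine distance and classified by leave-one-out
nearest neighbor: each profile is assigned the mode of action of its nearest
candidate, where candidates exclude the profile itself and, under the default
not-same-compound policy, every profile of the same compound.  The held-out
class experiment retrains the feature selection without one class and then
classifies the full set, probing how well a selection generalizes to
phenotypes it has never seen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import bin_feature_name, parse_bin_feature
from .io_model import (
    CONCENTRATION,
    MOA,
    PLATE,
    TREATMENT,
    WELL,
    ValidationError,
    median_replicates,
)

logger = logging.getLogger(__name__)

PROFILE_ID = "profile_id"

MODES = ("well_average", "all_bins", "extreme_bins")


@dataclass
class FingerprintMatrix:
    """Profiles x features matrix with metadata.

    ``data`` holds one row per profile: a unique ``profile_id``, the
    metadata columns present (``treatment``, ``moa``, ...), and one numeric
    column per feature.  No feature value is missing.
    """

    data: pd.DataFrame
    features: tuple[str, ...]
    mode: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        if PROFILE_ID not in self.data.columns:
            raise ValidationError("fingerprint data must carry a profile_id column")
        if self.data[PROFILE_ID].duplicated().any():
            raise ValidationError("profile_id values must be unique")
        if not self.features:
            raise ValidationError("fingerprint matrix has no feature columns")
        # deterministic row order for tie-breaking
        self.data = self.data.sort_values(PROFILE_ID, kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data[list(self.features)].to_numpy(dtype=float)

    def ids(self) -> np.ndarray:
        return self.data[PROFILE_ID].to_numpy()

    def labels(self) -> np.ndarray:
        return self.data[MOA].to_numpy()

    def select_features(
        self, features: Sequence[str], provenance: Mapping | None = None
    ) -> "FingerprintMatrix":
        feats = tuple(features)
        unknown = [f for f in feats if f not in self.features]
        if unknown:
            raise ValidationError(f"unknown feature(s): {unknown}")
        if not feats:
            raise ValidationError("empty feature selection")
        meta = [c for c in self.data.columns if c not in self.features]
        prov = {**self.provenance, **(provenance or {})}
        return FingerprintMatrix(
            data=self.data[meta + list(feats)].copy(),
            features=feats,
            mode=self.mode,
            provenance=prov,
        )

    def feature_parameters(self) -> dict[str, str]:
        """Map each feature column to its underlying parameter name."""
        if self.mode == "well_average":
            return {f: f for f in self.features}
        return {f: parse_bin_feature(f)[0] for f in self.features}

    def select_parameters(
        self, parameters: Sequence[str], provenance: Mapping | None = None
    ) -> "FingerprintMatrix":
        """Keep only features derived from the given parameters."""
        wanted = set(parameters)
        fmap = self.feature_parameters()
        feats = [f for f in self.features if fmap[f] in wanted]
        if not feats:
            raise ValidationError("parameter selection retains no features")
        return self.select_features(feats, provenance=provenance)

    def subset_rows(self, mask: np.ndarray | pd.Series) -> "FingerprintMatrix":
        return FingerprintMatrix(
            data=self.data[np.asarray(mask)].copy(),
            features=self.features,
            mode=self.mode,
            provenance=dict(self.provenance),
        )

    def median_replicates(
        self, group_keys: Sequence[str] = (TREATMENT, CONCENTRATION)
    ) -> "FingerprintMatrix":
        """Collapse replicate profiles to their componentwise median."""
        keys = [k for k in group_keys if k in self.data.columns]
        med = median_replicates(self.data, self.features, group_keys=keys)
        med[PROFILE_ID] = med[keys].astype(str).agg("@".join, axis=1)
        return FingerprintMatrix(
            data=med,
            features=self.features,
            mode=self.mode,
            provenance={**self.provenance, "replicates": "median"},
        )


@dataclass
class ClassificationReport:
    """Leave-one-out nearest-neighbor results.

    ``per_profile`` has one row per query with its nearest candidate,
    distance, prediction and correctness; profiles with no eligible candidate
    are listed as unclassifiable and excluded from the accuracy denominator.
    """

    per_profile: pd.DataFrame
    n_profiles: int
    n_correct: int
    accuracy: float
    n_unclassifiable: int
    confusion: pd.DataFrame

    def summary(self) -> dict:
        return {
            "n_profiles": self.n_profiles,
            "n_correct": self.n_correct,
            "accuracy": self.accuracy,
            "n_unclassifiable": self.n_unclassifiable,
        }


def assemble_fingerprints(
    source: pd.DataFrame,
    mode: str,
    features: Sequence[str] | None = None,
    parameters: Sequence[str] | None = None,
    include_controls: bool = False,
    control: str = "DMSO",
    provenance: Mapping | None = None,
) -> FingerprintMatrix:
    """Build a fingerprint matrix from upstream profiles.

    ``mode="well_average"`` takes a wide well-profile table (one row per
    well; pass the parameter names as ``features``).  ``mode="all_bins"`` and
    ``"extreme_bins"`` take the long binned table with z-scores.  An optional
    ``parameters`` filter (e.g. a stability-ladder retained set) is applied,
    then every feature column containing a missing value is dropped (logged),
    and control wells are dropped unless ``include_controls``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "well_average":
        if features is None:
            raise ValueError("well_average mode requires the feature (parameter) names")
        wide = source.copy()
        feats = list(features)
    else:
        from .binning import to_wide

        binned = source
        if mode == "extreme_bins":
            k = int(binned["bin"].max())
            binned = binned[binned["bin"].isin([1, k])]
        wide = to_wide(binned)
        feats = [c for c in wide.columns if c.endswith("__z")]
    if parameters is not None:
        wanted = set(parameters)
        if mode == "well_average":
            feats = [f for f in feats if f in wanted]
        else:
            feats = [f for f in feats if parse_bin_feature(f)[0] in wanted]
    wide[PROFILE_ID] = wide[PLATE].astype(str) + "|" + wide[WELL].astype(str)
    if not include_controls and TREATMENT in wide.columns:
        wide = wide[wide[TREATMENT] != control]
    complete = [f for f in feats if not wide[f].isna().any()]
    dropped = sorted(set(feats) - set(complete))
    if dropped:
        logger.info("dropping %d feature column(s) with missing values", len(dropped))
    if not complete:
        raise ValidationError("every feature column contains missing values")
    meta = [c for c in (PROFILE_ID, PLATE, WELL, TREATMENT, MOA, CONCENTRATION) if c in wide.columns]
    return FingerprintMatrix(
        data=wide[meta + complete].reset_index(drop=True),
        features=tuple(complete),
        mode=mode,
        provenance=dict(provenance or {}),
    )


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance ``1 - u.v / (|u||v|)``, in [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    # rounding can push the similarity marginally outside [-1, 1]
    return float(1.0 - np.clip((u @ v) / (nu * nv), -1.0, 1.0))


def cosine_distance_matrix(matrix: FingerprintMatrix) -> np.ndarray:
    """All-pairs cosine distances between profiles."""
    X = matrix.values()
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        ids = matrix.ids()[zero]
        raise ValidationError(f"zero fingerprint vector(s) for profile(s): {list(ids)}")
    sim = (X / norms[:, None]) @ (X / norms[:, None]).T
    return 1.0 - np.clip(sim, -1.0, 1.0)


def nn_loo_classify(
    matrix: FingerprintMatrix, exclusion: str = "same_compound"
) -> ClassificationReport:
    """Leave-one-out nearest-neighbor classification by mode of action.

    For each profile the candidates are all other profiles; under
    ``exclusion="same_compound"`` (the not-same-compound protocol) every
    profile of the same treatment is also excluded, under ``"self_only"``
    only the query itself.  The prediction is the label of the
    minimum-distance candidate; exact ties resolve to the lexicographically
    smallest profile_id.  Queries with no candidate are reported as
    unclassifiable, not silently dropped.
    """
    if exclusion not in ("same_compound", "self_only"):
        raise ValueError("exclusion must be 'same_compound' or 'self_only'")
    if len(matrix) < 2:
        raise ValidationError("need at least two profiles")
    D = cosine_distance_matrix(matrix)
    ids = matrix.ids()
    labels = matrix.labels()
    treatments = matrix.data[TREATMENT].to_numpy() if TREATMENT in matrix.data.columns else ids
    rows: list[dict] = []
    for i in range(len(matrix)):
        if exclusion == "same_compound":
            eligible = treatments != treatments[i]
        else:
            eligible = np.ones(len(matrix), dtype=bool)
            eligible[i] = False
        if not eligible.any():
            rows.append(
                {
                    PROFILE_ID: ids[i],
                    "nn_id": None,
                    "nn_distance": np.nan,
                    "actual": labels[i],
                    "predicted": None,
                    "correct": False,
                    "unclassifiable": True,
                }
            )
            continue
        d = np.where(eligible, D[i], np.inf)
        j = int(np.argmin(d))  # rows are id-sorted: first minimum = smallest id
        rows.append(
            {
                PROFILE_ID: ids[i],
                "nn_id": ids[j],
                "nn_distance": float(d[j]),
                "actual": labels[i],
                "predicted": labels[j],
                "correct": bool(labels[j] == labels[i]),
                "unclassifiable": False,
            }
        )
    per_profile = pd.DataFrame(rows)
    classified = per_profile[~per_profile["unclassifiable"]]
    n_profiles = len(classified)
    n_correct = int(classified["correct"].sum())
    confusion = (
        classified.groupby(["actual", "predicted"], observed=True)
        .size()
        .unstack(fill_value=0)
        if n_profiles
        else pd.DataFrame()
    )
    return ClassificationReport(
        per_profile=per_profile,
        n_profiles=n_profiles,
        n_correct=n_correct,
        accuracy=n_correct / n_profiles if n_profiles else float("nan"),
        n_unclassifiable=int(per_profile["unclassifiable"].sum()),
        confusion=confusion,
    )


def loo_accuracy(
    matrix: FingerprintMatrix,
    features: Sequence[str] | None = None,
    parameters: Sequence[str] | None = None,
    exclusion: str = "same_compound",
) -> float:
    """Leave-one-out accuracy of a (possibly column-filtered) fingerprint."""
    m = matrix
    if parameters is not None:
        m = m.select_parameters(parameters)
    if features is not None:
        m = m.select_features(features)
    return nn_loo_classify(m, exclusion=exclusion).accuracy


@dataclass
class HoldoutResult:
    """Outcome of the held-out-class generalization experiment."""

    selection: str
    holdout_moa: object
    selected_features: tuple[str, ...]
    selected_at: float  # stability threshold or L1 alpha
    scan: pd.DataFrame
    report: ClassificationReport
    holdout_n: int
    holdout_misclassified: int


def holdout_class_experiment(
    matrix: FingerprintMatrix,
    holdout_moa: object,
    selection: str,
    stability_reports: pd.DataFrame | None = None,
    thresholds: Sequence[float] | None = None,
    alphas: Sequence[float] | None = None,
    exclusion: str = "same_compound",
    random_state: int = 0,
) -> HoldoutResult:
    """Retrain feature selection without one class, then classify everything.

    With ``selection="stability"`` the retained sets come from the
    control-only stability ladder (``stability_reports`` from
    :func:`binprofiler.stability.stability_fractions`) — by construction these
    sets ignore treatment labels entirely — and the best threshold is chosen
    by leave-one-out accuracy on the held-in profiles.  With
    ``selection="l1"`` the penalty ladder is fit on the held-in profiles and
    the best alpha chosen the same way.  The winning feature set is then
    applied to the full matrix (holdout class restored) and classified;
    unclassifiable holdout profiles count as misclassified.
    """
    from . import sparsity, stability  # local import: sparsity depends on this module

    labels = matrix.labels()
    held_in = matrix.subset_rows(labels != holdout_moa)
    if (labels == holdout_moa).sum() == 0:
        raise ValidationError(f"holdout class {holdout_moa!r} not present")
    if pd.unique(held_in.labels()).size < 2:
        raise ValidationError("need at least two remaining classes after holdout")

    if selection == "stability":
        if stability_reports is None:
            raise ValueError("stability selection requires stability_reports")
        ladder = stability.stability_ladder(
            stability_reports,
            thresholds=thresholds if thresholds is not None else stability.LADDER_THRESHOLDS,
        )
        # restrict ladder parameters to those actually present as features
        available = set(held_in.feature_parameters().values())
        ladder = [(t, tuple(p for p in params if p in available)) for t, params in ladder]
        best_t, scan = stability.select_best_threshold(
            ladder,
            evaluate=lambda params: loo_accuracy(held_in, parameters=params, exclusion=exclusion),
        )
        retained_params = dict(ladder)[best_t]
        selected = matrix.select_parameters(retained_params, provenance={"stability_threshold": best_t})
        feats = selected.features
        chosen = best_t
    elif selection == "l1":
        scan_results = sparsity.l1_scan(
            held_in,
            alphas=alphas if alphas is not None else sparsity.DEFAULT_ALPHAS,
            random_state=random_state,
        )
        chosen, scan = sparsity.best_alpha(
            scan_results,
            evaluate=lambda feats: loo_accuracy(held_in, features=feats, exclusion=exclusion),
        )
        feats = next(r.retained_features for r in scan_results if r.alpha == chosen)
        selected = matrix.select_features(feats, provenance={"l1_alpha": chosen})
    else:
        raise ValueError("selection must be 'stability' or 'l1'")

    report = nn_loo_classify(selected, exclusion=exclusion)
    holdout_rows = report.per_profile[report.per_profile["actual"] == holdout_moa]
    misclassified = int((~holdout_rows["correct"]).sum())
    return HoldoutResult(
        selection=selection,
        holdout_moa=holdout_moa,
        selected_features=tuple(feats),
        selected_at=float(chosen),
        scan=scan,
        report=report,
        holdout_n=len(holdout_rows),
        holdout_misclassified=misclassified,
    )
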