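"""L1-regularized logistic-regression baseline for parameter reduction.

Mode-of-action labels are regressed on the fingerprint features with an
L1-penalized multinomial (one-vs-rest) logistic model over a ladder of
penalty strengths alpha = 0.01, 0.05, 0.1, 0.5, 1, 2, 4, 6, 8, 10.  At each
alpha the features whose coefficients are driven to zero for every class are
dropped, yielding ten fingerprints of decreasing size; the best alpha is the
one whose fingerprint maximizes leave-one-out classification accuracy.

Alpha multiplies the L1 term in the per-sample-averaged loss,
``(1/n) sum_i loss_i + alpha * ||w||_1``, which maps to the common
inverse-regularization parameterization as ``C = 1 / (n * alpha)``.  Features
are standardized (zero mean, unit sd over profiles) before fitting and the
intercept is unpenalized.  Unlike the negative-control stability selection,
this selection depends on the training labels: a feature informative only for
an absent class is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier

from .profiling import FingerprintMatrix

logger = logging.getLogger(__name__)

#: Default penalty ladder.
DEFAULT_ALPHAS = (0.01, 0.05, 0.1, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)

ZERO_COEF_TOL = 1e-8


@dataclass(frozen=True)
class L1ScanResult:
    """Outcome of one penalized fit: the alpha, the surviving features, and
    the class x feature coefficient table (on the standardized scale)."""

    alpha: float
    retained_features: tuple[str, ...]
    coefficients: pd.DataFrame


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)  # constant columns carry no signal
    return (X - mu) / sd


def l1_scan(
    matrix: FingerprintMatrix,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    multi_class: str = "ovr",
    tol: float = 1e-6,
    max_iter: int = 10_000,
    random_state: int = 0,
) -> list[L1ScanResult]:
    """Fit the L1 ladder and record the surviving features per alpha.

    A feature is retained iff some class coefficient exceeds 1e-8 in
    magnitude.  ``multi_class="ovr"`` fits one-vs-rest with liblinear;
    ``"multinomial"`` fits a softmax model with saga.
    """
    labels = matrix.labels()
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two mode-of-action classes")
    X = matrix.values()
    bad = [f for f, ok in zip(matrix.features, np.isfinite(X).all(axis=0)) if not ok]
    if bad:
        raise ValueError(f"non-finite values in feature column(s): {bad}")
    Xs = _standardize(X)
    n = Xs.shape[0]
    results: list[L1ScanResult] = []
    for alpha in sorted(alphas):
        C = 1.0 / (alpha * n)
        if multi_class == "multinomial":
            model = LogisticRegression(
                l1_ratio=1.0, C=C, solver="saga", tol=tol, max_iter=max_iter,
                random_state=random_state,
            )
        else:
            model = OneVsRestClassifier(
                LogisticRegression(
                    l1_ratio=1.0, C=C, solver="liblinear", tol=tol,
                    max_iter=max_iter, random_state=random_state,
                )
            )
        model.fit(Xs, labels)
        raw = (
            np.vstack([est.coef_ for est in model.estimators_])
            if isinstance(model, OneVsRestClassifier)
            else model.coef_
        )
        # binary fits expose one coefficient row (for classes_[1])
        index = list(model.classes_)[1:] if raw.shape[0] == 1 else list(model.classes_)
        coef = pd.DataFrame(raw, index=index, columns=list(matrix.features))
        nonzero = (coef.abs() > ZERO_COEF_TOL).any(axis=0)
        retained = tuple(f for f in matrix.features if nonzero[f])
        results.append(L1ScanResult(alpha=float(alpha), retained_features=retained, coefficients=coef))
    return results


def apply_l1_selection(matrix: FingerprintMatrix, result: L1ScanResult) -> FingerprintMatrix:
    """Column-filter a fingerprint matrix to the features an L1 fit retained."""
    if not result.retained_features:
        raise ValueError(f"alpha={result.alpha}: empty retained set")
    unknown = [f for f in result.retained_features if f not in matrix.features]
    if unknown:
        raise ValueError(f"retained feature(s) absent from matrix: {unknown}")
    return matrix.select_features(result.retained_features, provenance={"l1_alpha": result.alpha})


def best_alpha(
    scan: Sequence[L1ScanResult],
    evaluate: Callable[[tuple[str, ...]], float],
) -> tuple[float, pd.DataFrame]:
    """Pick the alpha whose retained fingerprint classifies best.

    ``evaluate`` maps a retained feature set to a leave-one-out accuracy.
    Alphas with empty retained sets are skipped with a warning; ties break
    toward the larger alpha (the sparser fingerprint).  Returns the winning
    alpha and the scan table.
    """
    rows: list[dict] = []
    best: tuple[float, float] | None = None
    for res in scan:
        if not res.retained_features:
            logger.warning("alpha=%g retains no features; skipped", res.alpha)
            continue
        acc = float(evaluate(res.retained_features))
        rows.append({"alpha": res.alpha, "n_features": len(res.retained_features), "accuracy": acc})
        if best is None or acc > best[1] or (acc == best[1] and res.alpha > best[0]):
            best = (res.alpha, acc)
    if best is None:
        raise ValueError("no usable alpha: every retained set was empty")
    return best[0], pd.DataFrame(rows)
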