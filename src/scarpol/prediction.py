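"""Scar-area prediction: OLS fit, LOOCV, metrics, permutation control.

The model is linear in the z-scored early-month features,

    Scar_Area(6m) = beta0 + sum_{i in K} alpha_i Scar_Area_i
                          + gamma_i Hom_i + delta_i DOPSlope_i,

fitted by ordinary least squares.  Performance is measured under
leave-one-out cross-validation (one held-out prediction per wound) with
Pearson and Spearman correlations between predicted and actual month-6
areas plus the root-mean-square error RMSE = sqrt(mean((x - xhat)^2)).

Because n is small, an overfitting control shuffles the month-6 targets,
repeats the identical LOOCV analysis B times, and reports the empirical
p-value (1 + #{null >= observed}) / (B + 1) for each correlation; the
analytic two-sided p-values of the correlations are reported alongside
and neither is privileged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .cohort import Cohort, DesignMatrix, build_design, zscore_fit_transform

__all__ = [
    "ModelSpec",
    "MetricSet",
    "PredictionResult",
    "PermutationResult",
    "fit_ols",
    "loocv_predict",
    "evaluate",
    "permutation_control",
    "compare_models",
    "MODEL_VARIANTS",
]

#: the seven month-set variants, in report order
MODEL_VARIANTS: Tuple[Tuple[int, ...], ...] = (
    (1,),
    (2,),
    (3,),
    (1, 2),
    (1, 3),
    (2, 3),
    (1, 2, 3),
)


@dataclass
class ModelSpec:
    """Fitted linear model: intercept (mm^2) plus one coefficient per
    standardized feature column (mm^2 per z-unit)."""

    intercept: float
    coef: np.ndarray
    columns: Optional[List[str]] = None
    K: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef


@dataclass
class MetricSet:
    """Prediction-quality summary."""

    pearson: float
    pearson_p: float
    spearman: float
    spearman_p: float
    rmse: float

    def to_dict(self) -> Dict[str, float]:
        return {
            "pearson": self.pearson,
            "pearson_p": self.pearson_p,
            "spearman": self.spearman,
            "spearman_p": self.spearman_p,
            "rmse": self.rmse,
        }


@dataclass
class PredictionResult:
    """LOOCV predictions and their metrics for one month set K."""

    wound_ids: List[str]
    predicted: np.ndarray
    actual: np.ndarray
    metrics: MetricSet
    K: Tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "months": list(self.K),
            "wound_ids": list(self.wound_ids),
            "predicted_mm2": [float(v) for v in self.predicted],
            "actual_mm2": [float(v) for v in self.actual],
            "metrics": self.metrics.to_dict(),
        }


@dataclass
class PermutationResult:
    """Shuffled-outcome null distributions and empirical p-values."""

    B: int
    null_pearson: np.ndarray
    null_spearman: np.ndarray
    p_pearson: float
    p_spearman: float
    observed: MetricSet
    seed: int

    def __post_init__(self) -> None:
        if len(self.null_pearson) != self.B or len(self.null_spearman) != self.B:
            raise ValueError("null arrays must have length B")
        for p in (self.p_pearson, self.p_spearman):
            if not (0.0 < p <= 1.0):
                raise ValueError("empirical p must lie in (0, 1]")


def fit_ols(X: np.ndarray, y: np.ndarray, columns: Optional[List[str]] = None,
            K: Optional[Tuple[int, ...]] = None) -> ModelSpec:
    """Least-squares fit with intercept; raises on rank deficiency.

    No regularization is applied: a rank-deficient design is an error so
    that collinear feature sets fail loudly rather than silently.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need more rows ({n}) than coefficients ({k + 1})")
    Xa = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Xa, y, rcond=None)
    if rank < k + 1:
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {k + 1}); "
            "remove collinear columns"
        )
    return ModelSpec(intercept=float(beta[0]), coef=beta[1:], columns=columns, K=K)


def evaluate(pred: np.ndarray, actual: np.ndarray) -> MetricSet:
    """Pearson, Spearman (average ranks on ties), RMSE with 1/n.

    Analytic two-sided p-values accompany each correlation.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("prediction and actual vectors must have equal length")
    if len(pred) < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(pred) == 0 or np.std(actual) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    pr = stats.pearsonr(pred, actual)
    sr = stats.spearmanr(pred, actual)
    rmse = float(np.sqrt(np.mean((actual - pred) ** 2)))
    return MetricSet(
        pearson=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        rmse=rmse,
    )


def _standardized_design(
    cohort: Cohort, K: Sequence[int], ddof: int = 1
) -> DesignMatrix:
    design = build_design(cohort, K)
    standardized, _ = zscore_fit_transform(design, ddof=ddof)
    return standardized


def loocv_predict(
    cohort: Cohort,
    K: Sequence[int],
    zscore_mode: str = "pooled",
    ddof: int = 1,
) -> PredictionResult:
    """Leave-one-out predictions of the month-6 scar area.

    Each wound is predicted by a model refitted on the remaining wounds.
    ``zscore_mode="pooled"`` (default) fits the z-scoring moments on the
    whole cohort before splitting; ``"per_fold"`` refits them inside each
    training fold (strict mode, slightly more conservative).
    """
    if zscore_mode not in ("pooled", "per_fold"):
        raise ValueError(f"unknown zscore_mode {zscore_mode!r}")
    design = build_design(cohort, K)
    n, k = design.X.shape
    if n < 3 * len(design.K) + 3:
        raise ValueError(
            f"cohort of {n} wounds is too small for {3 * len(design.K)} features"
        )
    if zscore_mode == "pooled":
        std, _ = zscore_fit_transform(design, ddof=ddof)
        Xz = std.X
    y = design.y
    pred = np.empty(n)
    for i in range(n):
        train = np.arange(n) != i
        if zscore_mode == "pooled":
            X_tr, x_te = Xz[train], Xz[i]
        else:
            mu = design.X[train].mean(axis=0)
            sigma = design.X[train].std(axis=0, ddof=ddof)
            if np.any(sigma == 0):
                raise ValueError(f"zero-variance training column in fold {i}")
            X_tr = (design.X[train] - mu) / sigma
            x_te = (design.X[i] - mu) / sigma
        try:
            model = fit_ols(X_tr, y[train])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"fold {i}: {exc}") from exc
        pred[i] = model.predict(x_te[None, :])[0]
    metrics = evaluate(pred, y)
    return PredictionResult(
        wound_ids=list(design.wound_ids),
        predicted=pred,
        actual=y.copy(),
        metrics=metrics,
        K=design.K,
    )


def _loo_weight_matrix(Xz: np.ndarray) -> np.ndarray:
    """Per-fold prediction weights over the target vector.

    OLS predictions are linear in y, so fold i's held-out prediction is a
    fixed row vector applied to the training targets:
    ``pred_i = x_i^T (X_-i^T X_-i)^{-1} X_-i^T y_-i``.  Returns W with
    W[i, i] = 0 and ``pred = W @ y`` for any target assignment, which lets
    the shuffled-target control rerun the full LOOCV cheaply and exactly.
    """
    n, k = Xz.shape
    Xa = np.column_stack([np.ones(n), Xz])
    W = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        Xt = Xa[train]
        if np.linalg.matrix_rank(Xt) < k + 1:
            raise np.linalg.LinAlgError(f"fold {i}: rank-deficient design")
        W[i, train] = Xa[i] @ np.linalg.pinv(Xt)
    return W


def permutation_control(
    cohort: Cohort,
    K: Sequence[int],
    B: int = 1000,
    seed: int = 0,
    ddof: int = 1,
) -> PermutationResult:
    """Shuffled-outcome control for the LOOCV analysis.

    The month-6 targets are permuted uniformly at random (features and
    fold structure untouched), the identical LOOCV analysis is repeated,
    and the Pearson/Spearman of predicted vs (shuffled) actual populate
    the null distributions.  Empirical p = (1 + #{null >= observed}) /
    (B + 1), one-sided: the question is whether real targets are predicted
    better than shuffled ones.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    observed = loocv_predict(cohort, K, ddof=ddof)
    std = _standardized_design(cohort, K, ddof=ddof)
    W = _loo_weight_matrix(std.X)
    y = std.y
    rng = np.random.default_rng(seed)
    null_pearson = np.empty(B)
    null_spearman = np.empty(B)
    for b in range(B):
        y_shuf = y[rng.permutation(len(y))]
        pred = W @ y_shuf
        try:
            m = evaluate(pred, y_shuf)
        except ValueError as exc:
            raise ValueError(f"shuffle {b}: {exc}") from exc
        null_pearson[b] = m.pearson
        null_spearman[b] = m.spearman
    p_pearson = (1 + int(np.sum(null_pearson >= observed.metrics.pearson))) / (B + 1)
    p_spearman = (1 + int(np.sum(null_spearman >= observed.metrics.spearman))) / (B + 1)
    return PermutationResult(
        B=B,
        null_pearson=null_pearson,
        null_spearman=null_spearman,
        p_pearson=p_pearson,
        p_spearman=p_spearman,
        observed=observed.metrics,
        seed=int(seed),
    )


def compare_models(cohort: Cohort, B: int = 1000, seed: int = 0, ddof: int = 1):
    """Model-comparison table over the seven month-set variants.

    One row per K in {1},{2},{3},{1,2},{1,3},{2,3},{1,2,3} with the LOOCV
    Pearson/Spearman (analytic p-values), RMSE, and the shuffled-outcome
    empirical p-values.  No multiple-testing correction is applied across
    the variants.
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(len(MODEL_VARIANTS))]
    rows = []
    for K, s in zip(MODEL_VARIANTS, child_seeds):
        perm = permutation_control(cohort, K, B=B, seed=s, ddof=ddof)
        m = perm.observed
        rows.append(
            {
                "months": "&".join(str(k) for k in K),
                "pearson": m.pearson,
                "pearson_p": m.pearson_p,
                "spearman": m.spearman,
                "spearman_p": m.spearman_p,
                "rmse_mm2": m.rmse,
                "perm_p_pearson": perm.p_pearson,
                "perm_p_spearman": perm.p_spearman,
            }
        )
    return pd.DataFrame(rows)
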