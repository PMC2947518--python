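"""Predictor validation: five-fold cross-validation, permutation significance,
and the error metrics used to report prediction accuracy.

Cross-validation re-runs the whole training pipeline (sex filter + age
selection) inside each training split, so the reported error is unbiased by
gene selection.  The permutation test shuffles ages across samples (sex stays
attached to its sample) and reruns the full cross-validation per permutation;
its p-value is the fraction of permuted errors strictly below the observed
one and can be exactly zero.

Error metrics (years), computed over pooled held-out predictions:

* mean_abs_error    — mean |predicted - actual| (per-individual error)
* sd_abs_error      — sample SD of |predicted - actual|
* diff_of_medians   — |median(predicted) - median(actual)|
* median_of_diffs   — median |predicted - actual|

The error of a cohort *median* shrinks with cohort size like
individual_error / sqrt(n - 1), mirroring how a standard error shrinks
relative to a standard deviation; :func:`median_error_scaling` applies that
rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import ExpressionMatrix, SampleInfo
from .exceptions import BrainAgeError, TrainingError
from .predictor import AgePredictor

__all__ = [
    "CVResult",
    "PermutationResult",
    "crossvalidate",
    "error_metrics",
    "median_error_scaling",
    "permutation_p",
    "permutation_test",
]


def error_metrics(
    predicted: Sequence[float], actual: Sequence[float]
) -> tuple[float, float, float, float]:
    """Return (mean_abs_error, sd_abs_error, diff_of_medians, median_of_diffs)."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size == 0:
        raise BrainAgeError("predicted and actual must have equal nonzero length")
    abs_err = np.abs(p - a)
    sd = float(np.std(abs_err, ddof=1)) if abs_err.size > 1 else 0.0
    return (
        float(np.mean(abs_err)),
        sd,
        float(abs(np.median(p) - np.median(a))),
        float(np.median(abs_err)),
    )


def median_error_scaling(individual_error: float, n: int) -> float:
    """Error of a cohort-median age estimate: individual_error / sqrt(n - 1)."""
    if n < 2:
        raise BrainAgeError(f"cohort size must be >= 2, got {n}")
    if individual_error < 0:
        raise BrainAgeError("individual_error must be >= 0")
    return individual_error / math.sqrt(n - 1)


@dataclass
class CVResult:
    """Pooled held-out predictions and error metrics from k-fold CV.

    Arrays are ordered like the input sample list.  Samples in folds where
    training failed (no genes selected) carry NaN predictions and are
    excluded from the metrics; those folds are listed in ``failed_folds``.
    """

    fold_of_sample: np.ndarray
    predicted: np.ndarray
    actual: np.ndarray
    mean_abs_error: float
    sd_abs_error: float
    diff_of_medians: float
    median_of_diffs: float
    failed_folds: list[int] = field(default_factory=list)

    @property
    def k(self) -> int:
        return int(self.fold_of_sample.max()) + 1


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition of n samples into k folds with sizes differing by <= 1."""
    fold = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold[chunk] = f
    return fold


def crossvalidate(
    expr: ExpressionMatrix,
    samples: Sequence[SampleInfo],
    k: int = 5,
    alpha_age: float = 0.005,
    alpha_gender: float = 0.05,
    aggregation: str = "weighted_ls",
    seed: int = 0,
) -> CVResult:
    """Estimate prediction error by seeded k-fold cross-validation.

    Gene filtering and selection are re-run on every training split; the
    held-out 1/k of subjects is predicted with the resulting model.
    """
    samples = list(samples)
    n = len(samples)
    if n < 2 * k:
        raise BrainAgeError(f"need at least {2 * k} samples for {k}-fold CV, got {n}")
    rng = np.random.default_rng(seed)
    fold = _fold_assignment(n, k, rng)
    predicted = np.full(n, np.nan)
    actual = np.array([s.age for s in samples], dtype=float)
    failed: list[int] = []
    for f in range(k):
        test_idx = np.flatnonzero(fold == f)
        train_idx = np.flatnonzero(fold != f)
        train_samples = [samples[i] for i in train_idx]
        train_expr = expr.subset_samples([s.sample_id for s in train_samples])
        try:
            model = AgePredictor(
                train_expr, train_samples,
                alpha_age=alpha_age, alpha_gender=alpha_gender,
                aggregation=aggregation,
            ).fit()
        except TrainingError:
            failed.append(f)
            continue
        test_samples = [samples[i] for i in test_idx]
        test_expr = expr.subset_samples([s.sample_id for s in test_samples])
        preds = model.predict_matrix(test_expr, test_samples)
        predicted[test_idx] = preds.to_numpy()
    if len(failed) == k:
        raise TrainingError("training failed in every cross-validation fold")
    ok = ~np.isnan(predicted)
    mae, sd, dmed, medd = error_metrics(predicted[ok], actual[ok])
    return CVResult(
        fold_of_sample=fold,
        predicted=predicted,
        actual=actual,
        mean_abs_error=mae,
        sd_abs_error=sd,
        diff_of_medians=dmed,
        median_of_diffs=medd,
        failed_folds=failed,
    )


@dataclass
class PermutationResult:
    """Observed CV error against its permutation null distribution."""

    observed_error: float
    permuted_errors: np.ndarray
    p_value: float

    @property
    def n_perm(self) -> int:
        return len(self.permuted_errors)


def permutation_p(
    observed: float, permuted: Sequence[float], method: str = "strict"
) -> float:
    """Permutation p-value: fraction of permuted errors beating the observed.

    ``strict`` (default) counts permuted errors strictly below the observed
    error and can be exactly 0; ``add_one`` uses the positively biased
    (b + 1)/(m + 1) estimator that can never be 0.
    """
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise BrainAgeError("need at least one permutation")
    better = int(np.sum(permuted < observed))
    if method == "strict":
        return better / permuted.size
    if method == "add_one":
        return (better + 1) / (permuted.size + 1)
    raise BrainAgeError(f"unknown p-value method {method!r}")


def permutation_test(
    expr: ExpressionMatrix,
    samples: Sequence[SampleInfo],
    n_perm: int = 1000,
    k: int = 5,
    alpha_age: float = 0.005,
    alpha_gender: float = 0.05,
    aggregation: str = "weighted_ls",
    seed: int = 0,
    p_value_method: str = "strict",
) -> PermutationResult:
    """Assess CV-error significance by age-label permutation.

    Each permutation shuffles the ages across samples (sex labels stay with
    their samples) and reruns the full cross-validation.  A permutation in
    which training fails in every fold contributes an infinite error (it
    cannot beat the observed error).
    """
    samples = list(samples)
    observed = crossvalidate(
        expr, samples, k=k, alpha_age=alpha_age, alpha_gender=alpha_gender,
        aggregation=aggregation, seed=seed,
    ).mean_abs_error
    rng = np.random.default_rng(seed)
    ages = np.array([s.age for s in samples])
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = ages[rng.permutation(len(ages))]
        perm_samples = [
            SampleInfo(s.sample_id, float(a), s.sex, s.group)
            for s, a in zip(samples, shuffled)
        ]
        fold_seed = int(rng.integers(0, 2**31 - 1))
        try:
            permuted[b] = crossvalidate(
                expr, perm_samples, k=k, alpha_age=alpha_age,
                alpha_gender=alpha_gender, aggregation=aggregation,
                seed=fold_seed,
            ).mean_abs_error
        except TrainingError:
            permuted[b] = np.inf
    return PermutationResult(
        observed_error=observed,
        permuted_errors=permuted,
        p_value=permutation_p(observed, permuted, method=p_value_method),
    )
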