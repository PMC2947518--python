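"""Disease-cohort application: age acceleration and gene-list overlap.

A trained predictor applied to a patient cohort yields paired (chronological,
predicted) ages; "age acceleration" is the systematic excess of predicted
over chronological age, tested with a two-sided paired Wilcoxon signed-rank
test.  Overlap between age-correlated genes and disease-associated genes
(differential expression at p < 0.001 with fold change > 2) is tested with a
one-sided Fisher's exact (hypergeometric) enrichment test over a declared
gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import ExpressionMatrix, SampleInfo
from .exceptions import BrainAgeError
from .predictor import AgePredictorResults

__all__ = [
    "CohortComparison",
    "OverlapResult",
    "compare_cohort",
    "differential_genes",
    "gene_overlap_test",
    "wilcoxon_signed_rank",
]

EXACT_WILCOXON_MAX_N = 25


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Differences of exactly zero are dropped.  With at most
    ``EXACT_WILCOXON_MAX_N`` non-zero differences the exact sign-flip
    distribution of the positive-rank sum is enumerated by integer
    convolution (midranks doubled so ties stay on the integer lattice);
    beyond that a normal approximation with tie correction is used.
    If every difference is zero the test is vacuous and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise BrainAgeError("paired vectors must have equal nonzero length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", UserWarning, stacklevel=2)
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(np.sum(ranks[d > 0]))

    if n <= EXACT_WILCOXON_MAX_N:
        # work on 2*ranks so midranks from ties are integers
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        counts /= 2.0**n
        w2 = int(round(2 * w_pos))
        p_low = float(counts[: w2 + 1].sum())
        p_high = float(counts[w2:].sum())
        return min(1.0, 2.0 * min(p_low, p_high))

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_pos - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


@dataclass
class CohortComparison:
    """Paired chronological vs predicted ages for one cohort."""

    group_label: str
    chronological: np.ndarray
    predicted: np.ndarray
    median_chronological: float
    median_predicted: float
    wilcoxon_p: float

    @property
    def median_acceleration(self) -> float:
        """median(predicted - chronological), years."""
        return float(np.median(self.predicted - self.chronological))


def compare_cohort(
    model: AgePredictorResults,
    expr: ExpressionMatrix,
    samples: Sequence[SampleInfo],
    group: str,
) -> CohortComparison:
    """Predict ages for one group and test predicted vs chronological.

    ``expr`` must already be harmonised and offset-calibrated to the model's
    reference platform.  Requires at least 3 samples in the group.
    """
    members = [s for s in samples if s.group == group]
    if not members:
        available = sorted({s.group for s in samples})
        raise BrainAgeError(f"group {group!r} not found; available: {available}")
    if len(members) < 3:
        raise BrainAgeError(f"group {group!r} has {len(members)} samples; need >= 3")
    predicted = model.predict_matrix(expr, members).to_numpy()
    chronological = np.array([s.age for s in members])
    return CohortComparison(
        group_label=group,
        chronological=chronological,
        predicted=predicted,
        median_chronological=float(np.median(chronological)),
        median_predicted=float(np.median(predicted)),
        wilcoxon_p=wilcoxon_signed_rank(predicted, chronological),
    )


def differential_genes(
    expr: ExpressionMatrix,
    samples: Sequence[SampleInfo],
    case_label: str,
    control_label: str,
    alpha: float = 0.001,
    min_fold_change: float = 2.0,
) -> set[str]:
    """Disease-associated genes by Welch t-test and fold-change cut-offs.

    A gene qualifies when the per-gene unequal-variance t-test between the
    two groups has p < alpha AND the absolute mean log2 difference exceeds
    log2(min_fold_change).
    """
    case_ids = [s.sample_id for s in samples if s.group == case_label]
    ctrl_ids = [s.sample_id for s in samples if s.group == control_label]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise BrainAgeError(
            f"need >= 2 samples per group; got {len(case_ids)} {case_label!r}, "
            f"{len(ctrl_ids)} {control_label!r}"
        )
    case = expr.subset_samples(case_ids).values
    ctrl = expr.subset_samples(ctrl_ids).values
    with np.errstate(divide="ignore", invalid="ignore"):
        tres = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    pvals = np.nan_to_num(tres.pvalue, nan=1.0)
    log_diff = case.mean(axis=1) - ctrl.mean(axis=1)
    keep = (pvals < alpha) & (np.abs(log_diff) > np.log2(min_fold_change))
    gene_ids = np.asarray(expr.gene_ids, dtype=object)
    return set(gene_ids[keep])


@dataclass(frozen=True)
class OverlapResult:
    """2x2 overlap of two gene lists over a universe, with Fisher p-value."""

    n_universe: int
    n_list_a: int
    n_list_b: int
    n_overlap: int
    fisher_p: float


def gene_overlap_test(
    list_a: set[str],
    list_b: set[str],
    universe: set[str],
    alternative: str = "greater",
) -> OverlapResult:
    """Test whether two gene lists overlap more than chance.

    Builds the 2x2 membership table over ``universe`` and computes the
    hypergeometric tail P(overlap >= observed) (one-sided enrichment,
    default) or the two-sided Fisher exact p (``alternative='two-sided'``).
    """
    stray_a = sorted(list_a - universe)
    stray_b = sorted(list_b - universe)
    if stray_a or stray_b:
        raise BrainAgeError(
            f"gene lists must be subsets of the universe; offending IDs: "
            f"{(stray_a + stray_b)[:5]}"
        )
    if not universe:
        raise BrainAgeError("universe is empty")
    N, K, n = len(universe), len(list_a), len(list_b)
    k = len(list_a & list_b)
    if alternative == "greater":
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    elif alternative == "two-sided":
        table = [[k, K - k], [n - k, N - K - n + k]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise BrainAgeError(f"unknown alternative {alternative!r}")
    return OverlapResult(
        n_universe=N, n_list_a=K, n_list_b=n, n_overlap=k,
        fisher_p=min(1.0, p),
    )
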