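"""Per-gene linear aging models.

For each gene *i* the log2 expression of sample *j* is modelled as

    Y_ij = b0_i + b1_i * A_j + b2_i * S_j + b3_i * A_j * S_j + e_ij

with A_j the chronological age in years, S_j the sex indicator (female=0,
male=1) and Gaussian residuals e_ij.  b1 is the rate of change of expression
with age alone (log2 units/year), b2 a sex main effect and b3 the age-by-sex
interaction slope.  Coefficients are estimated by ordinary least squares and
tested with two-sided t-tests on n - p degrees of freedom.

Because every gene in a dataset shares the same design matrix, all genes are
fitted in one vectorised normal-equations solve; :func:`fit_gene_model` is
the single-gene view of the same computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, SampleInfo
from .exceptions import BrainAgeError, DegenerateFitWarning

MIN_SAMPLES = 5  # 4 coefficients + at least 1 residual df

_MODEL_COLUMNS = [
    "b0", "b1", "b2", "b3", "p1", "p2", "p3", "resid_var", "n", "degenerate",
]


@dataclass(frozen=True)
class GeneAgeModel:
    """Fitted aging model for one gene: coefficients, p-values, residual variance."""

    gene_id: str
    b0: float
    b1: float
    b2: float
    b3: float
    p1: float
    p2: float
    p3: float
    resid_var: float
    n: int
    degenerate: bool = False

    def effective_intercept(self, sex_code: int) -> float:
        """Model intercept for one sex: b0 + b2*S."""
        return self.b0 + self.b2 * sex_code

    def effective_slope(self, sex_code: int) -> float:
        """Age slope for one sex: b1 + b3*S, log2 units/year."""
        return self.b1 + self.b3 * sex_code


def design_matrix(samples: Sequence[SampleInfo], with_sex: bool = True) -> np.ndarray:
    """Build the OLS design [1, A, S, A*S] (or [1, A] for single-sex data)."""
    age = np.array([s.age for s in samples], dtype=float)
    if not with_sex:
        return np.column_stack([np.ones_like(age), age])
    sex = np.array([s.sex_code for s in samples], dtype=float)
    return np.column_stack([np.ones_like(age), age, sex, age * sex])


def _batch_ols(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of every row of Y (genes x n) on X (n x p).

    Returns (beta: genes x p, pvals: genes x p for slopes vs 0, resid_var: genes).
    Zero-residual fits give p=0 for nonzero coefficients and p=1 for zero ones.
    """
    n, p = X.shape
    dof = n - p
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = Y @ (X @ xtx_inv.T)  # genes x p
    resid = Y - beta @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    rss = np.maximum(rss, 0.0)
    resid_var = rss / dof
    se = np.sqrt(np.outer(resid_var, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    # exact fits: se == 0 -> p = 0 where the coefficient is nonzero, else 1
    zero_se = se <= 0
    pvals = np.where(zero_se & (np.abs(beta) > 1e-12), 0.0, pvals)
    pvals = np.where(zero_se & (np.abs(beta) <= 1e-12), 1.0, pvals)
    return beta, pvals, resid_var


def fit_gene_models(
    expr: ExpressionMatrix, samples: Sequence[SampleInfo]
) -> pd.DataFrame:
    """Fit the aging model for every gene of a matrix in one pass.

    ``samples`` must cover exactly the matrix columns (any order).  Returns a
    DataFrame indexed by gene_id with columns b0..b3, p1..p3, resid_var, n and
    a ``degenerate`` flag for constant-expression genes.  If all samples share
    one sex, the model drops the sex columns and reports b2=b3=0, p2=p3=1.
    """
    order = {s.sample_id: s for s in samples}
    missing = [c for c in expr.sample_ids if c not in order]
    if missing:
        raise BrainAgeError(f"samples missing metadata: {missing[:5]}")
    samples = [order[c] for c in expr.sample_ids]
    n = len(samples)
    if n < MIN_SAMPLES:
        raise BrainAgeError(f"need at least {MIN_SAMPLES} samples, got {n}")
    ages = np.array([s.age for s in samples])
    if np.unique(ages).size < 2:
        raise BrainAgeError("need at least 2 distinct ages to fit an age slope")

    sexes = {s.sex for s in samples}
    single_sex = len(sexes) == 1
    X = design_matrix(samples, with_sex=not single_sex)
    Y = expr.values
    beta, pvals, resid_var = _batch_ols(Y, X)

    G = Y.shape[0]
    out = pd.DataFrame(index=pd.Index(expr.gene_ids, name="gene_id"))
    if single_sex:
        out["b0"], out["b1"] = beta[:, 0], beta[:, 1]
        out["b2"] = 0.0
        out["b3"] = 0.0
        out["p1"] = pvals[:, 1]
        out["p2"] = 1.0
        out["p3"] = 1.0
    else:
        out[["b0", "b1", "b2", "b3"]] = beta
        out[["p1", "p2", "p3"]] = pvals[:, 1:]
    out["resid_var"] = resid_var
    out["n"] = n

    # constant-expression genes: no age information at all
    degenerate = Y.std(axis=1) <= 1e-12
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) have constant expression; "
            "slopes set to 0 and p-values to 1",
            DegenerateFitWarning,
            stacklevel=2,
        )
        out.loc[degenerate, ["b1", "b2", "b3"]] = 0.0
        out.loc[degenerate, ["p1", "p2", "p3"]] = 1.0
        out.loc[degenerate, "b0"] = Y[degenerate, 0]
    out["degenerate"] = degenerate
    return out[_MODEL_COLUMNS]


def fit_gene_model(
    gene_id: str, y: np.ndarray, samples: Sequence[SampleInfo]
) -> GeneAgeModel:
    """Fit the aging model for a single gene's expression vector."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(samples):
        raise BrainAgeError("expression vector length must equal sample count")
    expr = ExpressionMatrix.from_arrays(
        [gene_id], [s.sample_id for s in samples], y[None, :]
    )
    row = fit_gene_models(expr, samples).iloc[0]
    return GeneAgeModel(
        gene_id=gene_id,
        b0=float(row.b0), b1=float(row.b1), b2=float(row.b2), b3=float(row.b3),
        p1=float(row.p1), p2=float(row.p2), p3=float(row.p3),
        resid_var=float(row.resid_var), n=int(row.n),
        degenerate=bool(row.degenerate),
    )


def models_to_frame(models: Sequence[GeneAgeModel]) -> pd.DataFrame:
    """Tabulate a list of fitted gene models (index = gene_id)."""
    return pd.DataFrame(
        [
            {
                "b0": m.b0, "b1": m.b1, "b2": m.b2, "b3": m.b3,
                "p1": m.p1, "p2": m.p2, "p3": m.p3,
                "resid_var": m.resid_var, "n": m.n, "degenerate": m.degenerate,
            }
            for m in models
        ],
        index=pd.Index([m.gene_id for m in models], name="gene_id"),
    )


def frame_to_models(frame: pd.DataFrame) -> list[GeneAgeModel]:
    return [
        GeneAgeModel(
            gene_id=str(gid),
            b0=float(r.b0), b1=float(r.b1), b2=float(r.b2), b3=float(r.b3),
            p1=float(r.p1), p2=float(r.p2), p3=float(r.p3),
            resid_var=float(r.resid_var), n=int(r.n),
            degenerate=bool(getattr(r, "degenerate", False)),
        )
        for gid, r in frame.iterrows()
    ]


def filter_gender_neutral(
    models: Sequence[GeneAgeModel],
    alpha_gender: float = 0.05,
    literal: bool = False,
) -> list[GeneAgeModel]:
    """Drop genes whose sex terms interfere with age prediction.

    Default: keep genes with p2 > alpha_gender AND p3 > alpha_gender, i.e.
    remove any gene with a significant sex main effect or age-by-sex
    interaction.  ``literal=True`` inverts the rule (keep genes with BOTH sex
    p-values >= alpha_gender treated as the removal criterion), an alternative
    reading of the filter; it is not the default because it retains exactly
    the sex-confounded genes.  Order is preserved.
    """
    if not (0 <= alpha_gender < 1):
        raise BrainAgeError(f"alpha_gender must be in [0,1), got {alpha_gender}")
    if literal:
        return [m for m in models if not (m.p2 >= alpha_gender and m.p3 >= alpha_gender)]
    return [m for m in models if m.p2 > alpha_gender and m.p3 > alpha_gender]


def select_age_correlated(
    models: Sequence[GeneAgeModel], alpha_age: float = 0.005
) -> list[GeneAgeModel]:
    """Keep genes whose age slope is significant: p1 <= alpha_age (inclusive)."""
    if not (0 < alpha_age <= 1):
        raise BrainAgeError(f"alpha_age must be in (0,1], got {alpha_age}")
    return [m for m in models if m.p1 <= alpha_age]
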