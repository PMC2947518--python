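"""Synthetic expression data with the statistical structure the aging model
assumes, with full ground truth exposed for testing.

The generator draws, per gene, true coefficients (b0, b1, b2, b3) and emits
log2 expression Y = b0 + b1*A + b2*S + b3*A*S + N(0, noise_sd).  Gene roles
are disjoint by construction:

* *age genes* carry a nonzero age slope b1 drawn uniformly from
  +/-[slope_range] log2 units/year (both signs equally likely);
* *housekeeping genes* are flat in age and sex (b1 = b2 = b3 = 0) — the
  calibration anchors;
* a ``gender_fraction`` of the remaining genes carry a sex main effect b2
  (and half of those also an age-by-sex interaction b3) — the genes the sex
  filter should remove;
* all other genes are pure noise around their baseline.

Ages are sampled uniformly on ``age_range`` (default 20-95 years, so every
decade of adult life is represented) and sexes are Bernoulli(1/2).

:func:`synth_cohort` reuses a reference truth to build a two-group test
dataset: controls generated at their chronological ages and cases whose
expression mean is evaluated at (age + acceleration) — a "prematurely aged"
profile — with an optional constant between-dataset offset added to every
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleInfo
from .exceptions import BrainAgeError

# baseline expression and effect-size ranges (log2 units); sex effects are
# made large enough to be reliably detectable at the default cohort sizes
B0_RANGE = (4.0, 12.0)
B2_RANGE = (0.5, 1.5)
B3_RANGE = (0.02, 0.06)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a synthetic reference dataset."""

    coeffs: pd.DataFrame  # index gene_id; columns b0, b1, b2, b3
    noise_sd: float
    housekeeping_ids: frozenset[str]
    age_gene_ids: frozenset[str]
    offset_applied: float = 0.0
    acceleration: float = 0.0
    age_range: tuple[float, float] = (20.0, 95.0)
    gender_gene_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.age_gene_ids & self.housekeeping_ids:
            raise BrainAgeError("age genes and housekeeping genes must be disjoint")
        hk = self.coeffs.loc[sorted(self.housekeeping_ids)]
        if not (hk[["b1", "b2", "b3"]].to_numpy() == 0).all():
            raise BrainAgeError("housekeeping genes must have b1 = b2 = b3 = 0")


def _mean_expression(
    coeffs: pd.DataFrame, ages: np.ndarray, sex_codes: np.ndarray
) -> np.ndarray:
    """Noise-free model mean, genes x samples."""
    b = coeffs.to_numpy()  # G x 4
    design = np.column_stack(
        [np.ones_like(ages), ages, sex_codes, ages * sex_codes]
    )  # n x 4
    return b @ design.T


def synth_reference(
    n_samples: int = 120,
    n_genes: int = 500,
    n_age_genes: int = 50,
    n_housekeeping: int = 50,
    slope_range: tuple[float, float] = (0.01, 0.05),
    gender_fraction: float = 0.2,
    noise_sd: float = 0.3,
    age_range: tuple[float, float] = (20.0, 95.0),
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[SampleInfo], SyntheticTruth]:
    """Generate a reference dataset for training and validating the predictor.

    Returns (expression matrix, sample list, truth).  Gene roles (age,
    housekeeping, sex-affected, noise) are disjoint sets; sex-affected genes
    are drawn only from genes that are neither age- nor housekeeping genes so
    the sex filter does not eat true aging signal.
    """
    if n_age_genes + n_housekeeping > n_genes:
        raise BrainAgeError("n_age_genes + n_housekeeping must not exceed n_genes")
    if not (0 <= gender_fraction <= 1):
        raise BrainAgeError("gender_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    age_ids = gene_ids[:n_age_genes]
    hk_ids = gene_ids[n_age_genes : n_age_genes + n_housekeeping]
    other_ids = gene_ids[n_age_genes + n_housekeeping :]

    coeffs = pd.DataFrame(
        0.0, index=pd.Index(gene_ids, name="gene_id"), columns=["b0", "b1", "b2", "b3"]
    )
    coeffs["b0"] = rng.uniform(*B0_RANGE, size=n_genes)
    signs = rng.choice([-1.0, 1.0], size=n_age_genes)
    coeffs.loc[age_ids, "b1"] = signs * rng.uniform(*slope_range, size=n_age_genes)

    n_gender = int(round(gender_fraction * len(other_ids)))
    gender_ids = list(rng.choice(other_ids, size=n_gender, replace=False))
    if gender_ids:
        coeffs.loc[gender_ids, "b2"] = rng.choice(
            [-1.0, 1.0], size=n_gender
        ) * rng.uniform(*B2_RANGE, size=n_gender)
        n_inter = n_gender // 2
        inter_ids = gender_ids[:n_inter]
        coeffs.loc[inter_ids, "b3"] = rng.choice(
            [-1.0, 1.0], size=n_inter
        ) * rng.uniform(*B3_RANGE, size=n_inter)

    ages = rng.uniform(*age_range, size=n_samples)
    sex_codes = rng.integers(0, 2, size=n_samples)
    samples = [
        SampleInfo(
            sample_id=f"ref{j:04d}",
            age=float(ages[j]),
            sex="male" if sex_codes[j] else "female",
            group="control",
        )
        for j in range(n_samples)
    ]
    values = _mean_expression(coeffs, ages, sex_codes.astype(float))
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    expr = ExpressionMatrix.from_arrays(gene_ids, [s.sample_id for s in samples], values)
    truth = SyntheticTruth(
        coeffs=coeffs,
        noise_sd=noise_sd,
        housekeeping_ids=frozenset(hk_ids),
        age_gene_ids=frozenset(age_ids),
        age_range=age_range,
        gender_gene_ids=frozenset(gender_ids),
    )
    return expr, samples, truth


def synth_cohort(
    truth: SyntheticTruth,
    n_control: int = 20,
    n_case: int = 20,
    age_range: tuple[float, float] = (50.0, 90.0),
    acceleration: float = 10.0,
    dataset_offset: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[SampleInfo]]:
    """Generate a disease-cohort dataset from a reference truth.

    Controls are generated at their chronological ages; cases get the model
    mean evaluated at (chronological age + acceleration) — expression that
    looks ``acceleration`` years older than the subject.  ``dataset_offset``
    (log2 units) is added to every value to emulate a between-experiment
    baseline shift.  Groups are labelled 'control' and 'case'.
    """
    if acceleration < 0:
        raise BrainAgeError("acceleration must be >= 0")
    rng = np.random.default_rng(seed)
    n = n_control + n_case
    ages = rng.uniform(*age_range, size=n)
    sex_codes = rng.integers(0, 2, size=n)
    groups = ["control"] * n_control + ["case"] * n_case
    samples = [
        SampleInfo(
            sample_id=f"coh{j:04d}",
            age=float(ages[j]),
            sex="male" if sex_codes[j] else "female",
            group=groups[j],
        )
        for j in range(n)
    ]
    effective_ages = ages + np.where(np.array(groups) == "case", acceleration, 0.0)
    values = _mean_expression(truth.coeffs, effective_ages, sex_codes.astype(float))
    if truth.noise_sd > 0:
        values = values + rng.normal(0.0, truth.noise_sd, size=values.shape)
    values = values + dataset_offset
    expr = ExpressionMatrix.from_arrays(
        truth.coeffs.index.tolist(), [s.sample_id for s in samples], values
    )
    return expr, samples
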