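"""Physiological-age prediction from per-gene aging models.

Training fits the aging model to every gene of a reference dataset, removes
sex-confounded genes, keeps genes significantly correlated with age
(p <= alpha_age), and packages the surviving coefficient set as a predictor.
Prediction inverts the per-gene regressions: for a sample of sex S each
selected gene i has effective intercept c_i = b0_i + b2_i*S and effective
slope s_i = b1_i + b3_i*S, so its expression y_i votes for age
(y_i - c_i)/s_i.  Two aggregation rules are provided:

``weighted_ls``
    the age minimising sum_i w_i (y_i - c_i - s_i a)^2 with precision
    weights w_i = 1/resid_var_i — the maximum-likelihood age under the
    Gaussian aging model; closed form
    a = sum_i w_i s_i (y_i - c_i) / sum_i w_i s_i^2.
``median_inversion``
    the median of the per-gene inverted ages, robust to outlying genes.

Predicted ages are deliberately not clamped to the training age range: a
pathologically "old" expression profile may legitimately predict an age far
beyond any training subject.

Cross-platform use is supported by best-match probeset harmonisation
(:func:`harmonize`) and a constant housekeeping-gene offset
(:func:`estimate_offset` / :func:`apply_offset`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from os import PathLike
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ProbesetMap, SampleInfo
from .exceptions import (
    BrainAgeError,
    CalibrationError,
    HarmonizationError,
    PredictionError,
    TrainingError,
)
from .regression import (
    GeneAgeModel,
    filter_gender_neutral,
    fit_gene_models,
    frame_to_models,
    models_to_frame,
    select_age_correlated,
)

RESID_VAR_FLOOR = 1e-8
SLOPE_EPS = 1e-12

AGGREGATIONS = ("weighted_ls", "median_inversion")


class AgePredictor:
    """Transcriptomic age-predictor model specification.

    Parameters
    ----------
    expr
        Reference log2 expression matrix (genes x samples).
    samples
        Metadata for each matrix column; ages must span >= 2 distinct values.
    alpha_age
        Inclusive p-value threshold on the age slope b1 (default 0.005).
    alpha_gender
        Threshold for removing sex-confounded genes (default 0.05).
    aggregation
        'weighted_ls' (default) or 'median_inversion'.
    literal_gender_filter
        Use the inverted reading of the sex filter (see regression module).
    reference_label
        Free-text tag recorded in the fitted model.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        samples: Sequence[SampleInfo],
        alpha_age: float = 0.005,
        alpha_gender: float = 0.05,
        aggregation: str = "weighted_ls",
        literal_gender_filter: bool = False,
        reference_label: str = "",
    ):
        if aggregation not in AGGREGATIONS:
            raise BrainAgeError(f"aggregation must be one of {AGGREGATIONS}")
        if not (0 < alpha_age <= 1):
            raise BrainAgeError(f"alpha_age must be in (0,1], got {alpha_age}")
        if not (0 <= alpha_gender < 1):
            raise BrainAgeError(f"alpha_gender must be in [0,1), got {alpha_gender}")
        self.expr = expr
        self.samples = list(samples)
        self.alpha_age = alpha_age
        self.alpha_gender = alpha_gender
        self.aggregation = aggregation
        self.literal_gender_filter = literal_gender_filter
        self.reference_label = reference_label

    def fit(self) -> "AgePredictorResults":
        all_models = fit_gene_models(self.expr, self.samples)
        candidates = frame_to_models(all_models)
        neutral = filter_gender_neutral(
            candidates, self.alpha_gender, literal=self.literal_gender_filter
        )
        selected = select_age_correlated(neutral, self.alpha_age)
        counts = {
            "n_genes_total": len(candidates),
            "n_gender_neutral": len(neutral),
            "n_selected": len(selected),
        }
        if not selected:
            raise TrainingError(
                f"no gene passed the age-correlation threshold alpha_age="
                f"{self.alpha_age:g}; consider a larger alpha_age"
            )
        return AgePredictorResults(
            gene_table=models_to_frame(selected),
            alpha_age=self.alpha_age,
            alpha_gender=self.alpha_gender,
            aggregation=self.aggregation,
            reference_label=self.reference_label,
            stage_counts=counts,
        )


@dataclass
class AgePredictorResults:
    """Fitted age predictor: selected gene models plus thresholds.

    ``gene_table`` is indexed by gene_id with the regression columns
    (b0..b3, p1..p3, resid_var, n).
    """

    gene_table: pd.DataFrame
    alpha_age: float
    alpha_gender: float
    aggregation: str
    reference_label: str = ""
    stage_counts: dict | None = None

    def __post_init__(self) -> None:
        if self.gene_table.empty:
            raise TrainingError("predictor has no genes")

    # -- accessors ------------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return self.gene_table.index.tolist()

    @property
    def genes(self) -> list[GeneAgeModel]:
        return frame_to_models(self.gene_table)

    @property
    def n_genes(self) -> int:
        return len(self.gene_table)

    # -- prediction -----------------------------------------------------------

    def _effective(self, sex_code: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = self.gene_table
        c = t["b0"].to_numpy() + t["b2"].to_numpy() * sex_code
        s = t["b1"].to_numpy() + t["b3"].to_numpy() * sex_code
        w = 1.0 / np.maximum(t["resid_var"].to_numpy(), RESID_VAR_FLOOR)
        return c, s, w

    def predict(self, y: np.ndarray, sex: str | int) -> float:
        """Predict the physiological age (years) of one expression vector.

        ``y`` holds one finite log2 value per predictor gene, in gene_table
        order; ``sex`` is 'female'/'male' or the 0/1 code.
        """
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_genes,):
            raise PredictionError(
                f"expected expression vector of length {self.n_genes}, got {y.shape}"
            )
        if not np.all(np.isfinite(y)):
            raise PredictionError("expression vector contains non-finite values")
        sex_code = {"female": 0, "male": 1, 0: 0, 1: 1}.get(sex)
        if sex_code is None:
            raise PredictionError(f"unknown sex {sex!r}")
        c, s, w = self._effective(sex_code)
        if self.aggregation == "weighted_ls":
            denom = float(np.sum(w * s * s))
            if denom <= SLOPE_EPS:
                raise PredictionError("all effective age slopes are ~0")
            return float(np.sum(w * s * (y - c)) / denom)
        usable = np.abs(s) > SLOPE_EPS
        if not usable.any():
            raise PredictionError("all effective age slopes are ~0")
        return float(np.median((y[usable] - c[usable]) / s[usable]))

    def predict_matrix(
        self, expr: ExpressionMatrix, samples: Sequence[SampleInfo]
    ) -> pd.Series:
        """Predict ages for every sample of a harmonised/calibrated matrix.

        The matrix must contain every predictor gene as a row.  Returns a
        Series indexed by sample_id, in ``samples`` order.
        """
        sub = expr.subset_genes(self.gene_ids)
        col = {sid: i for i, sid in enumerate(sub.sample_ids)}
        missing = [s.sample_id for s in samples if s.sample_id not in col]
        if missing:
            raise PredictionError(f"samples absent from matrix: {missing[:5]}")
        values = sub.values
        idx = np.array([col[s.sample_id] for s in samples])
        sex_codes = np.array([s.sex_code for s in samples])
        ages = np.empty(len(samples))
        for sex_code in np.unique(sex_codes):
            c, s, w = self._effective(int(sex_code))
            mask = sex_codes == sex_code
            Y = values[:, idx[mask]]  # genes x members
            resid = Y - c[:, None]
            if self.aggregation == "weighted_ls":
                denom = float(np.sum(w * s * s))
                if denom <= SLOPE_EPS:
                    raise PredictionError("all effective age slopes are ~0")
                ages[mask] = (w * s) @ resid / denom
            else:
                usable = np.abs(s) > SLOPE_EPS
                if not usable.any():
                    raise PredictionError("all effective age slopes are ~0")
                ages[mask] = np.median(resid[usable] / s[usable, None], axis=0)
        return pd.Series(
            ages, index=pd.Index([s.sample_id for s in samples], name="sample_id"),
            name="predicted_age",
        )

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        """Human-readable description of the fitted predictor."""
        t = self.gene_table
        lines = [
            "Transcriptomic age predictor",
            "=" * 60,
            f"reference:            {self.reference_label or '(unlabelled)'}",
            f"aggregation:          {self.aggregation}",
            f"alpha_age / gender:   {self.alpha_age:g} / {self.alpha_gender:g}",
        ]
        if self.stage_counts:
            c = self.stage_counts
            lines.append(
                f"genes: {c['n_genes_total']} fitted -> "
                f"{c['n_gender_neutral']} sex-neutral -> {c['n_selected']} selected"
            )
        lines += [
            f"selected genes:       {self.n_genes}",
            f"median |b1|:          {t['b1'].abs().median():.4g} log2/year",
            f"median residual SD:   {np.sqrt(t['resid_var']).median():.4g} log2",
            "=" * 60,
        ]
        return "\n".join(lines)

    def to_json(self, path: str | PathLike) -> None:
        payload = {
            "alpha_age": self.alpha_age,
            "alpha_gender": self.alpha_gender,
            "aggregation": self.aggregation,
            "reference_label": self.reference_label,
            "stage_counts": self.stage_counts,
            "genes": self.gene_table.reset_index().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | PathLike) -> "AgePredictorResults":
        with open(path) as fh:
            payload = json.load(fh)
        table = pd.DataFrame(payload["genes"]).set_index("gene_id")
        return cls(
            gene_table=table,
            alpha_age=payload["alpha_age"],
            alpha_gender=payload["alpha_gender"],
            aggregation=payload["aggregation"],
            reference_label=payload.get("reference_label", ""),
            stage_counts=payload.get("stage_counts"),
        )

    def restricted_to(self, gene_ids: Sequence[str]) -> "AgePredictorResults":
        return AgePredictorResults(
            gene_table=self.gene_table.loc[list(gene_ids)],
            alpha_age=self.alpha_age,
            alpha_gender=self.alpha_gender,
            aggregation=self.aggregation,
            reference_label=self.reference_label,
            stage_counts=self.stage_counts,
        )


def train_predictor(
    ref: ExpressionMatrix,
    samples: Sequence[SampleInfo],
    alpha_age: float = 0.005,
    alpha_gender: float = 0.05,
    aggregation: str = "weighted_ls",
    **kwargs,
) -> AgePredictorResults:
    """Train an age predictor on a reference dataset (functional shorthand)."""
    return AgePredictor(
        ref, samples, alpha_age=alpha_age, alpha_gender=alpha_gender,
        aggregation=aggregation, **kwargs,
    ).fit()


def predict_age(model: AgePredictorResults, y: np.ndarray, sex: str | int) -> float:
    """Predict one sample's physiological age from a fitted predictor."""
    return model.predict(y, sex)


# -- cross-platform harmonisation and calibration -----------------------------


def harmonize(
    pmap: ProbesetMap,
    model: AgePredictorResults,
    target: ExpressionMatrix,
) -> tuple[AgePredictorResults, ExpressionMatrix]:
    """Align a target matrix from another platform with a fitted predictor.

    The best-match map relates the model's probeset IDs (platform A) to the
    target's (platform B).  The model is restricted to genes with at least one
    mapped target probeset; where a model gene maps to several target
    probesets their rows are averaged, so the aligned matrix has exactly one
    row per retained model gene, in model order.
    """
    target_rows = set(target.gene_ids)
    kept: list[str] = []
    rows: list[np.ndarray] = []
    for gid in model.gene_ids:
        mapped = [b for b in pmap.targets_of(gid) if b in target_rows]
        if not mapped:
            continue
        kept.append(gid)
        rows.append(target.data.loc[mapped].to_numpy().mean(axis=0))
    if not kept:
        raise HarmonizationError(
            "no predictor gene maps to any probeset of the target platform"
        )
    aligned = ExpressionMatrix.from_arrays(kept, target.sample_ids, np.vstack(rows))
    return model.restricted_to(kept), aligned


@dataclass(frozen=True)
class CalibrationOffset:
    """Constant baseline difference between two datasets (log2 units)."""

    offset: float
    n_genes_used: int
    per_gene_diffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.offset):
            raise CalibrationError("offset is not finite")
        if self.n_genes_used != len(self.per_gene_diffs) or self.n_genes_used < 1:
            raise CalibrationError("offset must be based on >= 1 housekeeping gene")


def estimate_offset(
    ref: ExpressionMatrix,
    target: ExpressionMatrix,
    housekeeping: set[str],
) -> CalibrationOffset:
    """Estimate the constant baseline offset between two datasets.

    For each housekeeping gene present in both matrices the difference of
    mean log2 expression (reference minus target) is computed; the offset is
    the median of these per-gene differences, robust to the occasional
    housekeeping gene that misbehaves in one dataset.
    """
    common = [g for g in ref.gene_ids if g in housekeeping and g in set(target.gene_ids)]
    if not common:
        raise CalibrationError(
            "no housekeeping gene is present in both datasets; cannot calibrate"
        )
    diffs = (
        ref.data.loc[common].mean(axis=1) - target.data.loc[common].mean(axis=1)
    ).to_numpy()
    return CalibrationOffset(
        offset=float(np.median(diffs)),
        n_genes_used=len(common),
        per_gene_diffs=tuple(float(d) for d in diffs),
    )


def apply_offset(m: ExpressionMatrix, offset: CalibrationOffset | float) -> ExpressionMatrix:
    """Add the calibration offset to every value of a matrix."""
    delta = offset.offset if isinstance(offset, CalibrationOffset) else float(offset)
    return m.shifted(delta)
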