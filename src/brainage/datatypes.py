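"""Core in-memory containers: expression matrices, sample metadata, probeset maps.

The expression matrix holds log2 expression values with genes (probesets) as
rows and samples as columns, the layout GEO series-matrix exports reduce to
after preprocessing.  Sample metadata records chronological age in years, sex
(coded female=0 / male=1 wherever a numeric code is needed) and a free-text
group label such as ``control`` or ``AD``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

AGE_MIN = 0.0
AGE_MAX = 150.0

_FEMALE_TOKENS = {"f", "female"}
_MALE_TOKENS = {"m", "male"}


def normalize_sex(token: str) -> str:
    """Map a sex token to the canonical ``'female'`` / ``'male'`` labels."""
    t = str(token).strip().lower()
    if t in _FEMALE_TOKENS:
        return "female"
    if t in _MALE_TOKENS:
        return "male"
    raise ValidationError(f"unknown sex token {token!r}; expected F/female or M/male")


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one subject: age in years, sex, diagnostic group."""

    sample_id: str
    age: float
    sex: str  # 'female' | 'male'
    group: str = "control"

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(
                f"sample {self.sample_id!r}: sex must be 'female' or 'male', got {self.sex!r}"
            )
        if not np.isfinite(self.age) or not (AGE_MIN <= self.age <= AGE_MAX):
            raise ValidationError(
                f"sample {self.sample_id!r}: age {self.age!r} outside [{AGE_MIN:g}, {AGE_MAX:g}]"
            )

    @property
    def sex_code(self) -> int:
        """Sex indicator used by the regression design: female=0, male=1."""
        return 0 if self.sex == "female" else 1


def samples_to_frame(samples: Sequence[SampleInfo]) -> pd.DataFrame:
    """Tabulate a sample list (index=sample_id; columns age, sex, sex_code, group)."""
    return pd.DataFrame(
        {
            "age": [s.age for s in samples],
            "sex": [s.sex for s in samples],
            "sex_code": [s.sex_code for s in samples],
            "group": [s.group for s in samples],
        },
        index=pd.Index([s.sample_id for s in samples], name="sample_id"),
    )


class ExpressionMatrix:
    """A log2 expression matrix, genes x samples.

    Thin validated wrapper around a :class:`pandas.DataFrame` (rows = gene or
    probeset IDs, columns = sample IDs).  All values must be finite and both
    ID axes unique.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        values = data.to_numpy(dtype=float, copy=False)
        if values.size and not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at gene {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        self._data = data.astype(float)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        gene_ids: Iterable[str],
        sample_ids: Iterable[str],
        values: np.ndarray,
    ) -> "ExpressionMatrix":
        return cls(
            pd.DataFrame(
                np.asarray(values, dtype=float),
                index=pd.Index(list(gene_ids), name="gene_id"),
                columns=pd.Index(list(sample_ids), name="sample_id"),
            )
        )

    # -- accessors ------------------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return self._data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self._data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self._data.loc[list(gene_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self._data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self._data[list(sample_ids)])

    def shifted(self, delta: float) -> "ExpressionMatrix":
        """Return a copy with ``delta`` added to every value."""
        return ExpressionMatrix(self._data + float(delta))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self._data.equals(other._data)

    def __repr__(self) -> str:
        g, s = self.shape
        return f"<ExpressionMatrix {g} genes x {s} samples>"


@dataclass(frozen=True)
class ProbesetMap:
    """Best-match correspondence between probeset IDs of two array platforms.

    Stored as a plain set of (platform-A ID, platform-B ID) pairs; vendor
    match-quality scores are not interpreted.
    """

    pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if not a or not b:
                raise ValidationError(f"empty probeset ID in pair ({a!r}, {b!r})")

    @classmethod
    def identity(cls, ids: Iterable[str]) -> "ProbesetMap":
        return cls(frozenset((i, i) for i in ids))

    def targets_of(self, a_id: str) -> list[str]:
        """All platform-B probesets matched to one platform-A probeset, sorted."""
        return sorted(b for a, b in self.pairs if a == a_id)

    def __len__(self) -> int:
        return len(self.pairs)
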