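"""Core in-memory containers: expression matrices and gene-set collections.

An :class:`ExpressionMatrix` is a genes × samples numeric matrix with unique
string identifiers on both axes and a unit tag recording where in the
normalisation chain it sits (``counts`` → ``TPM`` → ``log2TPM``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "TPM", "log2TPM")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class ExpressionMatrix:
    """Genes × samples expression matrix.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Expression values; non-negative for every supported unit, and
        integral when ``unit == "counts"``.
    gene_ids, sample_ids : sequences of unique strings.
    unit : {"counts", "TPM", "log2TPM"}
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    unit: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (genes × samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes / {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")
        if self.values.size and self.values.min() < 0:
            raise ValidationError(f"negative values not allowed for unit {self.unit}")
        if self.unit == "counts" and self.values.size and not np.allclose(
            self.values, np.round(self.values)
        ):
            raise ValidationError("counts must be integral")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), unit)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Row subset preserving the requested gene order."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(self.values[rows], list(genes), list(self.sample_ids), self.unit)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(self.values[:, cols], list(self.gene_ids), list(samples), self.unit)

    def sample_vector(self, sample_id: str) -> pd.Series:
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.values[:, j], index=self.gene_ids, name=sample_id)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), e.g. hallmark programs or marker panels."""

    sets: dict[str, set]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, set] = {}
        for name, members in self.sets.items():
            members = set(map(str, members))
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[name] = members
        self.sets = clean

    def __getitem__(self, name: str) -> set:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)
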