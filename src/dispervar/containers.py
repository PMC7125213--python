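"""In-memory containers shared by the analysis modules.

The package operates on three kinds of data: a continuous gene x sample
expression matrix with a two-group sample annotation, named gene-set
collections (GMT-backed), and a SNP x sample genotype dosage matrix.
All three are thin, validated wrappers around pandas objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "GenotypeMatrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when input data violate a container's contract."""


@dataclass
class ExpressionMatrix:
    """Normalized expression values (genes x samples) with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with one column per sample ID.
        Values must be finite floats (e.g. adjusted log-CPM); missing
        values are rejected.
    labels
        Series mapping sample ID -> group label. Must cover exactly the
        samples in ``values`` and carry at least two levels for the
        two-group analyses.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        try:
            self.values = self.values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric expression values: {exc}") from exc
        if not np.isfinite(self.values.to_numpy()).all():
            bad = self.values.index[~np.isfinite(self.values).all(axis=1)].tolist()
            raise ValidationError(f"non-finite expression values in genes: {bad[:10]}")
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise ValidationError(f"samples without a group label: {missing[:10]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def group_levels(self) -> list:
        return sorted(self.labels.unique())

    def group_samples(self, level) -> pd.Index:
        return self.labels.index[self.labels == level]

    def group_matrix(self, genes, level) -> np.ndarray:
        """Samples-by-genes array for one group, restricted to ``genes``."""
        sub = self.values.loc[list(genes), self.group_samples(level)]
        return sub.to_numpy().T


@dataclass
class GeneSetCollection:
    """Ordered, named gene sets as parsed from a GMT file."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def intersect(self, genes) -> "GeneSetCollection":
        """Restrict every set to genes present in ``genes`` (order kept)."""
        universe = set(genes)
        return GeneSetCollection(
            sets={name: [g for g in members if g in universe] for name, members in self.sets.items()},
            descriptions=dict(self.descriptions),
        )


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage codes (SNPs x samples); -1 marks missing.

    ``positions`` is an optional DataFrame (index snp_id, columns
    ``chrom`` and ``pos``; 1-based coordinates).
    """

    values: pd.DataFrame
    positions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate SNP IDs: {dups}")
        arr = self.values.to_numpy()
        allowed = np.isin(arr, (-1, 0, 1, 2))
        if not allowed.all():
            bad = sorted(set(arr[~allowed].tolist()))
            raise ValidationError(f"genotype codes outside {{-1,0,1,2}}: {bad}")
        self.values = self.values.astype(np.int8)

    @property
    def snps(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns
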