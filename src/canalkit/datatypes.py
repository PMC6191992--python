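"""Core containers shared across the pipeline.

All matrices are genes x samples. The design table is a plain pandas
DataFrame with one row per sequencing sample; container classes here are
thin dataclasses that carry the matrix plus the metadata the downstream
statistics need (gene lengths, normalization state, precision weights).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPECIES = ("human", "chimpanzee")

#: columns every design table must carry
DESIGN_COLUMNS = [
    "sample_id",
    "species",
    "individual",
    "day",
    "tech_rep",
    "batch",
    "sex",
    "purity",
    "lib_size",
]


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check design-table invariants; return the validated frame.

    Raises ``ValueError`` on duplicate sample ids, unknown species labels,
    or an individual recorded under two species.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns and c != "purity"]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        raise ValueError("sample_id values are not unique")
    bad = set(design["species"]) - set(SPECIES)
    if bad:
        raise ValueError(f"unknown species labels: {sorted(bad)}")
    per_ind = design.groupby("individual")["species"].nunique()
    if (per_ind > 1).any():
        raise ValueError("individual assigned to more than one species")
    if (design["lib_size"] <= 0).any():
        raise ValueError("library sizes must be positive")
    return design


@dataclass
class CountMatrix:
    """Raw read counts over orthologous gene models.

    ``counts`` is genes x samples; ``gene_length_bp`` is the summed length of
    the orthologous exons used for RPKM.
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        if self.gene_length_bp is not None:
            self.gene_length_bp = self.gene_length_bp.reindex(self.counts.index)
            if (self.gene_length_bp <= 0).any():
                raise ValueError("gene lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, genes) -> "CountMatrix":
        lengths = None if self.gene_length_bp is None else self.gene_length_bp.loc[genes]
        return CountMatrix(self.counts.loc[genes], lengths)


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes x samples.

    ``unit`` is one of ``log2cpm``, ``log2rpkm`` or ``residual``;
    ``norm_state`` records which normalizations have been applied.
    ``weights``, when present, are per-observation precision weights with the
    same shape as ``values``.
    """

    values: pd.DataFrame
    unit: str = "log2cpm"
    norm_state: dict = field(default_factory=dict)
    weights: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("expression values must be finite")
        if self.weights is not None:
            if self.weights.shape != self.values.shape:
                raise ValueError("weights shape must match values")
            if (self.weights.values <= 0).any():
                raise ValueError("weights must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def copy_with(self, values: pd.DataFrame, **kw) -> "ExpressionMatrix":
        state = dict(self.norm_state)
        state.update(kw.pop("norm_state", {}))
        return ExpressionMatrix(values, unit=kw.pop("unit", self.unit),
                                norm_state=state, weights=kw.pop("weights", self.weights))
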