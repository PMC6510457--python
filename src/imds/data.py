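"""Expression-matrix container and TSV I/O shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_DISEASES = {"CD", "UC", "none"}
VALID_GROUPS = {"NHV", "R", "NR"}
VALID_TIMEPOINTS = {"BL", "PT"}

ANNOTATION_COLUMNS = ("disease", "group", "timepoint")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression values plus per-sample annotations.

    ``values`` is a DataFrame indexed by gene symbol with sample ids as
    columns.  ``annotations`` is indexed by sample id and carries at least
    ``disease`` (CD/UC/none), ``group`` (NHV/R/NR) and ``timepoint`` (BL/PT);
    an optional ``subject`` column enables paired post- vs pre-treatment
    tests.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.values.columns)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups)[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = self.values.columns.difference(self.annotations.index)
        if len(missing):
            raise ValueError(f"samples missing annotations: {list(missing)[:5]}")
        for col, valid in (
            ("disease", VALID_DISEASES),
            ("group", VALID_GROUPS),
            ("timepoint", VALID_TIMEPOINTS),
        ):
            if col in self.annotations.columns:
                bad = set(self.annotations[col].dropna().unique()) - valid
                if bad:
                    raise ValueError(f"invalid {col} labels: {sorted(bad)}")

    # -- convenience -----------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_where(self, **conditions: str) -> list[str]:
        """Sample ids matching all annotation ``column=value`` conditions."""
        mask = np.ones(len(self.annotations), dtype=bool)
        for col, val in conditions.items():
            if col not in self.annotations.columns:
                raise KeyError(f"annotation column {col!r} not present")
            mask &= (self.annotations[col] == val).to_numpy()
        return list(self.annotations.index[mask])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[sample_ids], self.annotations.loc[sample_ids]
        )

    # -- I/O -------------------------------------------------------------

    def write(self, expr_path: str | Path, annot_path: str | Path | None = None) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="gene")
        if annot_path is not None:
            self.annotations.to_csv(annot_path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, expr_path: str | Path, annot_path: str | Path | None = None) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        annotations = None
        if annot_path is not None:
            annotations = pd.read_csv(annot_path, sep="\t", index_col=0)
            annotations.index = annotations.index.astype(str)
        return cls(values, annotations)
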