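"""Expression matrix container and TSV I/O.

The pipeline's substrate is a log2 expression matrix (genes x samples) with a
species tag and a per-sample class annotation.  On disk the matrix is a TSV
whose first column is ``gene_id`` and remaining columns are sample ids; the
annotation is a TSV with columns ``sample_id``, ``class``, ``species``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples, with sample class labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    species
        ``"mouse"`` or ``"human"``.
    class_of_sample
        Mapping from sample id to class label; must cover every sample.
    """

    values: pd.DataFrame
    species: str
    class_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.class_of_sample]
        if self.class_of_sample and missing:
            raise ValueError(f"samples without class annotation: {missing}")

    # -- basic accessors ---------------------------------------------------

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

    def classes(self) -> list[str]:
        """Class labels in order of first appearance among samples."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.class_of_sample[s], None)
        return list(seen)

    def samples_in_class(self, label: str) -> list[str]:
        out = [s for s in self.sample_ids if self.class_of_sample[s] == label]
        if not out:
            raise KeyError(f"unknown class label: {label!r}")
        return out

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values.loc[genes].copy(), self.species, dict(self.class_of_sample)
        )

    def standardized(self) -> pd.DataFrame:
        """Per-gene standardization (mean 0, sd 1 across samples).

        Genes with zero variance are mapped to all-zero profiles.
        """
        v = self.values.to_numpy(float)
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return pd.DataFrame(
            (v - mu) / sd, index=self.values.index, columns=self.values.columns
        )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, matrix_path: Path | str, annotations_path: Path | str) -> None:
        df = self.values.copy()
        df.insert(0, "gene_id", df.index)
        df.to_csv(matrix_path, sep="\t", index=False)
        ann = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "class": [self.class_of_sample[s] for s in self.sample_ids],
                "species": self.species,
            }
        )
        ann.to_csv(annotations_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, matrix_path: Path | str, annotations_path: Path | str
    ) -> "ExpressionMatrix":
        df = pd.read_csv(matrix_path, sep="\t")
        if "gene_id" not in df.columns:
            raise ValueError("matrix TSV must have a first column named 'gene_id'")
        df = df.set_index("gene_id")
        ann = pd.read_csv(annotations_path, sep="\t")
        for col in ("sample_id", "class", "species"):
            if col not in ann.columns:
                raise ValueError(f"annotation TSV missing column {col!r}")
        species = str(ann["species"].iloc[0])
        class_of_sample = dict(zip(ann["sample_id"].astype(str), ann["class"].astype(str)))
        return cls(df, species, class_of_sample)


def group_arrays(
    matrix: ExpressionMatrix, group_a: str, group_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Return the (genes x n_a, genes x n_b) value arrays for two classes."""
    a = matrix.values[matrix.samples_in_class(group_a)].to_numpy(float)
    b = matrix.values[matrix.samples_in_class(group_b)].to_numpy(float)
    return a, b
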