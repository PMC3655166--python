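"""Shared data containers: expression matrices with sample labels.

An :class:`ExpressionDataset` is the substrate of everything downstream —
network inference, differential-expression testing and classifier training
all consume a genes × samples matrix of (already normalized, log-scale)
expression values together with a control/tumor label per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

CONTROL = "control"
TUMOR = "tumor"


@dataclass
class ExpressionDataset:
    """Labeled genes × samples expression matrix.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier, one column per sample.
        Values are normalized log-scale intensities.
    labels
        Series mapping sample id to class label (``"control"``/``"tumor"``).
        ``None`` for unlabeled compendium datasets used only for network
        subtraction.
    name
        Dataset tag carried into networks inferred from it.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.columns)
            if self.labels.isna().any():
                missing = self.labels.index[self.labels.isna()].tolist()
                raise ValueError(f"samples without class label: {missing[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_columns(self, label: str) -> pd.DataFrame:
        """Sub-matrix of samples with the given class label."""
        if self.labels is None:
            raise ValueError(f"dataset {self.name!r} has no sample labels")
        return self.values.loc[:, self.labels[self.labels == label].index]

    def write_tsv(self, values_path: str | Path, labels_path: str | Path | None = None) -> None:
        """Write the matrix (and optionally labels) as tab-separated text."""
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        if labels_path is not None:
            if self.labels is None:
                raise ValueError("dataset has no labels to write")
            self.labels.rename("class").to_csv(labels_path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(
        cls,
        values_path: str | Path,
        labels_path: str | Path | None = None,
        name: str = "",
    ) -> "ExpressionDataset":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        labels = None
        if labels_path is not None:
            labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(values=values, labels=labels, name=name or Path(values_path).stem)


@dataclass
class CtTable:
    """Raw qPCR cycle-threshold values, genes × samples.

    CT values are PCR cycles (typically 15–40). Transcripts that produced no
    product within the run limit are censored at ``max_cycles`` (40 by
    convention) and flagged as undetected rather than imputed.
    """

    ct: pd.DataFrame
    reference_gene: str
    labels: pd.Series
    max_cycles: float = 40.0
    name: str = field(default="")

    def __post_init__(self) -> None:
        if self.reference_gene not in self.ct.index:
            raise ValueError(f"reference gene {self.reference_gene!r} absent from CT table")
        if (self.ct.to_numpy() <= 0).any():
            raise ValueError("CT values must be positive cycle counts")
        self.labels = self.labels.reindex(self.ct.columns)
        if self.labels.isna().any():
            raise ValueError("every CT sample needs a class label")

    @property
    def genes(self) -> pd.Index:
        return self.ct.index

    @property
    def samples(self) -> pd.Index:
        return self.ct.columns

    def detected(self) -> pd.DataFrame:
        """Boolean mask: True where the transcript amplified (CT < max_cycles)."""
        return self.ct < self.max_cycles

    def write_tsv(self, ct_path: str | Path, labels_path: str | Path | None = None) -> None:
        self.ct.to_csv(ct_path, sep="\t", index_label="gene")
        if labels_path is not None:
            self.labels.rename("class").to_csv(labels_path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(
        cls,
        ct_path: str | Path,
        labels_path: str | Path,
        reference_gene: str,
        max_cycles: float = 40.0,
        name: str = "",
    ) -> "CtTable":
        ct = pd.read_csv(ct_path, sep="\t", index_col=0)
        labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(ct=ct, reference_gene=reference_gene, labels=labels,
                   max_cycles=max_cycles, name=name)
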