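"""Shared in-memory containers for the analysis pipeline.

Expression data live in a genes x samples :class:`pandas.DataFrame` with a
per-sample group label series; derived per-gene statistics, signatures and
score results are thin dataclasses around pandas objects so they serialize
naturally to TSV.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE_LABEL = "BRCA2"
CONTROL_LABEL = "BRCAX"


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with two-group sample labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene/probeset ID with one column per sample.
    labels
        Series indexed by sample ID giving the group of each sample
        (by convention ``"BRCA2"`` = case, ``"BRCAX"`` = control).
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.labels = pd.Series(self.labels)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene IDs in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in expression matrix")
        missing = self.values.columns.difference(self.labels.index)
        if len(missing):
            raise ValueError(f"samples without labels: {list(missing)[:5]}")
        self.labels = self.labels.loc[self.values.columns]
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def group_columns(self, label: str) -> pd.DataFrame:
        """Sub-matrix of the samples carrying ``label``."""
        return self.values.loc[:, self.labels[self.labels == label].index]


@dataclass
class GeneStats:
    """Per-gene two-group moderated-t statistics.

    ``table`` is indexed by gene with columns ``mean_case``, ``mean_control``,
    ``s2`` (pooled residual variance), ``s2_post`` (posterior/moderated
    variance), ``t``, ``p_value``, ``p_adjusted`` and boolean
    ``zero_variance``.  ``df_prior``/``s2_prior`` are the empirical-Bayes
    hyperparameters shared across genes.
    """

    table: pd.DataFrame
    df_prior: float
    s2_prior: float
    df_residual: float
    n_case: int
    n_control: int

    @property
    def t(self) -> pd.Series:
        return self.table["t"]

    @property
    def p_adjusted(self) -> pd.Series:
        return self.table["p_adjusted"]

    def overall_means(self) -> pd.Series:
        """Per-gene mean over all samples (pooled across both groups)."""
        n1, n2 = self.n_case, self.n_control
        return (n1 * self.table["mean_case"] + n2 * self.table["mean_control"]) / (n1 + n2)


@dataclass
class Signature:
    """A weighted gene signature: genes, t-statistic weights, centering means."""

    weights: pd.Series
    reference_means: pd.Series

    def __post_init__(self) -> None:
        self.weights = pd.Series(self.weights, dtype=float)
        if self.weights.index.has_duplicates:
            raise ValueError("signature genes must be unique")
        if not np.isfinite(self.weights.to_numpy()).all():
            raise ValueError("signature weights must be finite")
        self.reference_means = pd.Series(self.reference_means, dtype=float).loc[
            self.weights.index
        ]
        if not np.isfinite(self.reference_means.to_numpy()).all():
            raise ValueError("signature reference means must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.weights.index

    def __len__(self) -> int:
        return len(self.weights)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "weight": self.weights.to_numpy(),
             "reference_mean": self.reference_means.to_numpy()}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Signature":
        frame = frame.set_index("gene") if "gene" in frame.columns else frame
        return cls(weights=frame["weight"], reference_means=frame["reference_mean"])


@dataclass
class ScoreResult:
    """Per-sample signature scores with ROC evaluation."""

    scores: pd.Series
    labels: pd.Series
    auc: float
    roc: pd.DataFrame = field(repr=False)  # columns fpr, tpr
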