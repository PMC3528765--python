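"""Sample-level signature scores and ROC/AUC evaluation.

The BRCA2 score of sample j is the t-weighted sum of mean-centered
expression values over the signature genes:

    S_j = sum_g  w_g * (x_gj - m_g)

Genes with reduced expression in deleted tumors carry negative weights, so
their product is positive in BRCA2-like tumors: higher score = more
BRCA2-like.  Classification is evaluated by the empirical ROC curve and the
Mann-Whitney AUC (ties counted 1/2), which equals the trapezoidal area under
the ROC curve.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_curve

from .containers import CASE_LABEL, ExpressionMatrix, ScoreResult, Signature

__all__ = ["score_samples", "rank_auc", "roc_auc", "SignatureScorer"]


def score_samples(matrix: ExpressionMatrix, signature: Signature,
                  center: str = "reference") -> pd.Series:
    """Per-sample t-weighted signature scores.

    Parameters
    ----------
    center
        ``"reference"``: center each gene on ``signature.reference_means``
        (training-cohort means, the choice for scoring an external
        validation cohort); ``"self"``: center on the scored cohort's own
        per-gene means (the within-set analysis).
    """
    missing = signature.genes.difference(matrix.gene_ids)
    if len(missing):
        raise KeyError(f"signature genes missing from matrix: {sorted(missing)}")
    x = matrix.values.loc[signature.genes]
    if center == "reference":
        m = signature.reference_means
    elif center == "self":
        m = x.mean(axis=1)
    else:
        raise ValueError("center must be 'reference' or 'self'")
    centered = x.sub(m, axis=0)
    scores = centered.mul(signature.weights, axis=0).sum(axis=0)
    scores.name = "score"
    return scores


def rank_auc(scores, labels, case_label=CASE_LABEL) -> float:
    """Mann-Whitney AUC: P(case score > control score) + P(equal)/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_case = labels == case_label
    n1, n2 = int(is_case.sum()), int((~is_case).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("AUC needs at least one case and one control")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[is_case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def roc_auc(scores, labels, case_label=CASE_LABEL) -> ScoreResult:
    """ROC curve plus rank-sum AUC for per-sample scores."""
    scores = pd.Series(scores)
    labels = pd.Series(labels)
    auc = rank_auc(scores.to_numpy(), labels.to_numpy(), case_label=case_label)
    fpr, tpr, _ = roc_curve(labels.to_numpy() == case_label, scores.to_numpy())
    return ScoreResult(scores=scores, labels=labels, auc=auc,
                       roc=pd.DataFrame({"fpr": fpr, "tpr": tpr}))


class SignatureScorer(BaseEstimator):
    """Sklearn-style scorer: freeze a signature's centering means, then score.

    With ``signature=None`` the signature itself is learned on ``fit`` by
    moderated-t selection at ``fdr_threshold``; otherwise the provided
    signature's weights are kept and only the reference (centering) means
    are re-learned from the training matrix.

    ``decision_function(X)`` returns the BRCA2 score per sample (higher =
    more case-like); ``score(X, y)`` returns the AUC.
    """

    def __init__(self, signature: Signature | None = None,
                 fdr_threshold: float = 0.01, case_label=CASE_LABEL):
        self.signature = signature
        self.fdr_threshold = fdr_threshold
        self.case_label = case_label

    def fit(self, X, y=None):
        X = self._as_frame(X)
        if self.signature is None:
            if y is None:
                raise ValueError("y is required to learn a signature")
            from .diffexp import moderated_t, select_signature

            matrix = ExpressionMatrix(values=X.T, labels=pd.Series(y, index=X.index))
            stats = moderated_t(matrix, case_label=self.case_label)
            self.signature_ = select_signature(stats, self.fdr_threshold)
        else:
            means = X.T.loc[self.signature.genes].mean(axis=1)
            self.signature_ = Signature(weights=self.signature.weights,
                                        reference_means=means)
        return self

    def decision_function(self, X) -> np.ndarray:
        X = self._as_frame(X)
        matrix = ExpressionMatrix(
            values=X.T, labels=pd.Series("?", index=X.index))
        return score_samples(matrix, self.signature_, center="reference").to_numpy()

    def score(self, X, y) -> float:
        return rank_auc(self.decision_function(X), np.asarray(y),
                        case_label=self.case_label)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        """Accept samples x genes frames or arrays."""
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, index=[f"s{i}" for i in range(X.shape[0])],
                            columns=[f"g{i}" for i in range(X.shape[1])])
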