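"""Signature performance: ROC/AUC, group comparison, severity trend, PCA.

Conventions: cases are the positive class and a higher severity score is
more disease-like; AUC uses the rank (Mann-Whitney) formulation with ties
counted half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score, roc_curve

from .data_model import CohortAnnotation, DegenerateInputError, ExpressionMatrix, Signature
from .scoring import ScoreVector, standardize_feature
from .screen import spearman_rho

__all__ = ["ROCResult", "PCAResult", "roc_auc", "group_ttest", "severity_trend", "pca_signature"]


@dataclass
class ROCResult:
    auc: float
    curve: list[tuple[float, float]]  # (FPR, TPR), (0,0) .. (1,1)
    n_pos: int
    n_neg: int


@dataclass
class PCAResult:
    sample_scores: np.ndarray  # samples x 2
    eigenvalues: np.ndarray  # variances of the first two components


def _align_binary(scores: ScoreVector | Sequence[float], labels: CohortAnnotation | Sequence[int]):
    if isinstance(scores, ScoreVector):
        s = scores.score
        if isinstance(labels, CohortAnnotation):
            y = labels.codes_for(scores.sample_ids)
        else:
            y = np.asarray(labels, dtype=int)
    else:
        s = np.asarray(scores, dtype=float)
        y = labels.severity_code if isinstance(labels, CohortAnnotation) else np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels have mismatched lengths")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1 (control/case)")
    return s, y


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC of a score for case-vs-control separation."""
    s, y = _align_binary(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    curve = list(zip(fpr.tolist(), tpr.tolist()))
    if curve[0] != (0.0, 0.0):
        curve.insert(0, (0.0, 0.0))
    return ROCResult(auc, curve, n_pos, n_neg)


def group_ttest(scores, labels, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test of case vs control scores (Welch by
    default). Returns ``(t, p)`` with t > 0 when cases score higher."""
    s, y = _align_binary(scores, labels)
    cases, controls = s[y == 1], s[y == 0]
    if cases.size < 2 or controls.size < 2:
        raise ValueError("need >= 2 samples per class")
    if cases.std(ddof=1) == 0 and controls.std(ddof=1) == 0:
        if np.isclose(cases.mean(), controls.mean()):
            return 0.0, 1.0
        raise DegenerateInputError("both classes constant with different means")
    t, p = stats.ttest_ind(cases, controls, equal_var=equal_var)
    return float(t), float(p)


def severity_trend(scores: ScoreVector, annotation: CohortAnnotation) -> tuple[float, float]:
    """Spearman correlation of the severity score with the ordinal severity
    code (the monotone-trend check on a discovery cohort)."""
    y = annotation.codes_for(scores.sample_ids)
    return spearman_rho(scores.score, y)


def pca_signature(matrix: ExpressionMatrix, signature: Signature) -> PCAResult:
    """PCA of the samples in standardized signature-feature space.

    Features are z-scored before decomposition (the signature mixes
    features of different scales). Component signs are fixed so the
    loading of the first present signature feature is non-negative.
    """
    present = [f for f in signature.feature_ids if f in set(matrix.feature_ids)]
    if len(present) < 2:
        raise ValueError("need >= 2 signature features present in the matrix")
    if matrix.n_samples < 3:
        raise ValueError("need >= 3 samples")
    z = np.vstack(
        [standardize_feature(matrix.values[matrix.feature_index(f)]) for f in present]
    ).T  # samples x features
    pca = PCA(n_components=2)
    scores = pca.fit_transform(z)
    loadings = pca.components_  # 2 x features
    for c in range(2):
        if loadings[c, 0] < 0:
            scores[:, c] *= -1
            loadings[c] *= -1
    return PCAResult(scores, pca.explained_variance_[:2].copy())
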