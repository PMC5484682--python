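"""Severity screening: rank-correlate each feature with ordinal disease
severity, control FDR, and filter.

Because the severity axis has only three distinct values (HC/US/CS), ties
dominate one side of every correlation; the Spearman statistic is therefore
computed as the Pearson correlation of mid-ranks (average ranks for ties),
never via the tie-free ``1 - 6*sum(d^2)/(n(n^2-1))`` shortcut. P-values use
the asymptotic t approximation ``t = rho*sqrt((n-2)/(1-rho^2))`` on n-2
degrees of freedom, two-sided — standard at the cohort sizes this screen
targets (n around 60-80).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data
from statsmodels.stats.multitest import multipletests

from .data_model import (
    CohortAnnotation,
    DegenerateInputError,
    DetectionMask,
    ExpressionMatrix,
    ScreenRecord,
)

__all__ = [
    "presence_filter",
    "spearman_rho",
    "spearman_matrix",
    "bh_adjust",
    "screen_features",
    "SeverityScreen",
]

logger = logging.getLogger(__name__)


def presence_filter(
    matrix: ExpressionMatrix, mask: DetectionMask, fraction: float = 2.0 / 3.0
) -> ExpressionMatrix:
    """Keep features detected in at least ``fraction`` of samples.

    The boundary is inclusive: a feature detected in exactly two of three
    samples passes the default two-thirds rule. Samples are never dropped.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not mask.aligned_with(matrix):
        raise ValueError("detection mask is not aligned with the expression matrix")
    counts = mask.detected.sum(axis=1)
    n = matrix.n_samples
    keep = counts / n >= fraction - 1e-12  # tolerate float 2/3
    kept_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    return ExpressionMatrix(
        matrix.values[keep], kept_ids, list(matrix.sample_ids), matrix.platform
    )


def _midrank_pearson(rank_rows: np.ndarray, rank_y: np.ndarray) -> np.ndarray:
    rx = rank_rows - rank_rows.mean(axis=-1, keepdims=True)
    ry = rank_y - rank_y.mean()
    denom = np.sqrt((rx**2).sum(axis=-1) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry) / denom
    return np.clip(rho, -1.0, 1.0)


def _t_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rho) >= 1.0, 0.0, p)


def spearman_matrix(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman correlation of a (features x samples) array against
    a single target vector. Returns ``(rho, p)`` arrays.

    Rows with zero variance yield ``rho = nan``; callers decide how to treat
    them (the screen logs and drops, :func:`spearman_rho` raises).
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if values.shape[-1] != n:
        raise ValueError("values and target have mismatched sample counts")
    rank_rows = stats.rankdata(values, axis=-1)
    rank_y = stats.rankdata(y)
    rho = _midrank_pearson(rank_rows, rank_y)
    return rho, _t_pvalue(rho, n)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation of two vectors with mid-rank tie handling.

    Raises
    ------
    DegenerateInputError
        If either vector is constant (the statistic is undefined) —
        deliberately not a silent NaN.
    ValueError
        On mismatched lengths or fewer than 4 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input vector: Spearman rho is undefined")
    rho, p = spearman_matrix(x[None, :], y)
    return float(rho[0]), float(p[0])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_features(
    matrix: ExpressionMatrix,
    annotation: CohortAnnotation,
    alpha: float,
) -> list[ScreenRecord]:
    """Screen every feature for monotone association with severity.

    Each feature's expression is Spearman-correlated with the sample
    severity codes; p-values are BH-adjusted over the full family of
    (non-constant) features on this platform; only features with
    ``adj_p < alpha`` (strict) are returned, in matrix row order.
    ``alpha >= 1`` keeps every tested feature.

    Constant features cannot be ranked against severity; they are logged
    and excluded from both the output and the adjustment family rather
    than failing the whole screen.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    missing = set(matrix.sample_ids) - set(annotation.sample_ids)
    if missing:
        raise ValueError(f"matrix samples absent from annotation: {sorted(missing)[:5]}")
    y = annotation.codes_for(matrix.sample_ids)
    if np.ptp(y) == 0:
        raise DegenerateInputError("all samples share one severity group")

    constant = np.ptp(matrix.values, axis=1) == 0
    if constant.any():
        logger.warning(
            "%d constant feature(s) excluded from the screen: %s",
            int(constant.sum()),
            [f for f, c in zip(matrix.feature_ids, constant) if c][:5],
        )
    tested = ~constant
    values = matrix.values[tested]
    ids = [f for f, t in zip(matrix.feature_ids, tested) if t]
    if not ids:
        return []
    rho, p = spearman_matrix(values, y)
    # the t approximation can return exactly 0 for |rho|=1; keep BH's domain
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    adj = bh_adjust(p)
    keep = np.ones_like(adj, dtype=bool) if alpha >= 1 else adj < alpha
    return [
        ScreenRecord(f, float(r), float(pv), float(ap))
        for f, r, pv, ap, k in zip(ids, rho, p, adj, keep)
        if k
    ]


class SeverityScreen(SelectorMixin, BaseEstimator):
    """Feature selector keeping features whose expression tracks ordinal
    severity.

    scikit-learn conventions apply: ``X`` is (n_samples, n_features) and
    ``y`` is the per-sample severity code. Fitting computes per-feature
    Spearman rho against ``y``, BH-adjusts the p-values over all
    non-constant features, and selects features with adjusted p below
    ``alpha`` (strict).

    Parameters
    ----------
    alpha : float, default 0.05
        Strict threshold on the BH-adjusted p-value; ``alpha >= 1`` keeps
        all non-constant features.

    Attributes
    ----------
    rho_, p_values_, adj_p_ : ndarray of shape (n_features,)
        Per-feature statistics; NaN for constant features.
    support_ : bool ndarray of shape (n_features,)
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_samples=4)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent numbers of samples")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if np.ptp(y) == 0:
            raise DegenerateInputError("y is constant")
        constant = np.ptp(X, axis=0) == 0
        rho = np.full(X.shape[1], np.nan)
        p = np.full(X.shape[1], np.nan)
        if (~constant).any():
            r, pv = spearman_matrix(X[:, ~constant].T, y)
            rho[~constant] = r
            p[~constant] = np.clip(pv, np.finfo(float).tiny, 1.0)
        adj = np.full(X.shape[1], np.nan)
        if (~constant).any():
            adj[~constant] = bh_adjust(p[~constant])
        self.rho_ = rho
        self.p_values_ = p
        self.adj_p_ = adj
        if self.alpha >= 1:
            self.support_ = ~constant
        else:
            with np.errstate(invalid="ignore"):
                self.support_ = np.where(np.isnan(adj), False, adj < self.alpha)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def records(self) -> list[ScreenRecord]:
        """Selected features as :class:`ScreenRecord` objects (library
        surface parity with :func:`screen_features`)."""
        check_is_fitted(self)
        names = getattr(
            self, "feature_names_in_", np.array([f"x{i}" for i in range(self.n_features_in_)])
        )
        return [
            ScreenRecord(str(names[i]), float(self.rho_[i]), float(self.p_values_[i]), float(self.adj_p_[i]))
            for i in np.flatnonzero(self.support_)
        ]
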