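"""Sign-weighted standardized-expression severity score.

For a signature with per-feature severity correlations ``rho_i`` and a
cohort expression matrix ``e``, each sample's score is

    S = sum_i sgn(rho_i) * (e_i - mu_i) / tau_i

where ``mu_i`` and ``tau_i`` are the mean and (n-1) standard deviation of
feature *i* across all samples of the cohort being scored. The
standardization is deliberately transductive — constants are recomputed on
every cohort, never frozen from a training set — so the score is invariant
to per-feature affine rescaling between platforms. Higher scores indicate a
more disease-like profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .data_model import DegenerateInputError, ExpressionMatrix, Signature

__all__ = ["ScoreVector", "standardize_feature", "score_cohort", "SignatureScorer"]

logger = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    """Per-sample severity scores for one signature on one cohort."""

    sample_ids: list[str]
    score: np.ndarray
    signature_name: str
    coverage: float  # fraction of signature features found in the matrix

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.sample_ids),):
            raise ValueError("one score per sample required")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")


def standardize_feature(values) -> np.ndarray:
    """Center and scale one feature's expression to mean 0, sample SD 1
    (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-d vector of at least 2 values")
    tau = v.std(ddof=1)
    if tau == 0:
        raise DegenerateInputError("constant feature: standard deviation is zero")
    return (v - v.mean()) / tau


def score_cohort(
    matrix: ExpressionMatrix,
    signature: Signature,
    missing_policy: str = "drop",
) -> ScoreVector:
    """Score every sample of a cohort with a signature.

    Parameters
    ----------
    missing_policy : {"drop", "error"}
        Signatures are applied across platforms, so features can be absent
        from a cohort matrix. ``"drop"`` (default) skips missing features
        with a logged warning and records the achieved coverage;
        ``"error"`` requires full coverage.
    """
    if missing_policy not in {"drop", "error"}:
        raise ValueError("missing_policy must be 'drop' or 'error'")
    present = [f for f in signature.feature_ids if f in set(matrix.feature_ids)]
    missing = [f for f in signature.feature_ids if f not in set(matrix.feature_ids)]
    if missing:
        if missing_policy == "error":
            raise KeyError(f"signature features missing from matrix: {missing}")
        for f in missing:
            logger.warning("signature feature %r absent from cohort matrix; dropped", f)
    if not present:
        raise ValueError("zero coverage: no signature feature present in the matrix")
    signs = signature.signs
    scores = np.zeros(matrix.n_samples)
    for f in present:
        row = matrix.values[matrix.feature_index(f)]
        scores += signs[f] * standardize_feature(row)
    return ScoreVector(
        list(matrix.sample_ids),
        scores,
        signature.name,
        coverage=len(present) / len(signature),
    )


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Transformer mapping (n_samples, n_features) expression to a single
    severity-score column.

    The score is transductive by design: standardization constants are
    computed on the data passed to :meth:`transform`, so ``fit`` only
    resolves which signature features are present and records coverage.
    Feature names are taken from a DataFrame's columns; on plain arrays the
    signature features are matched positionally against ``x0..x{n-1}``
    unless the signature's ids already look like column indices.

    Parameters
    ----------
    signature : Signature
    missing_policy : {"drop", "error"}, default "drop"
    """

    def __init__(self, signature: Signature = None, missing_policy: str = "drop"):
        self.signature = signature
        self.missing_policy = missing_policy

    def _resolve(self, names: list[str]) -> dict[str, int]:
        pos = {n: i for i, n in enumerate(names)}
        present = {f: pos[f] for f in self.signature.feature_ids if f in pos}
        missing = [f for f in self.signature.feature_ids if f not in pos]
        if missing and self.missing_policy == "error":
            raise KeyError(f"signature features missing from X: {missing}")
        if not present:
            raise ValueError("zero coverage: no signature feature present in X")
        return present

    def fit(self, X, y=None):
        if self.signature is None:
            raise ValueError("a Signature must be provided")
        if self.missing_policy not in {"drop", "error"}:
            raise ValueError("missing_policy must be 'drop' or 'error'")
        X = validate_data(self, X, ensure_min_samples=2)
        names = list(
            getattr(self, "feature_names_in_", [f"x{i}" for i in range(X.shape[1])])
        )
        self.feature_positions_ = self._resolve([str(n) for n in names])
        self.coverage_ = len(self.feature_positions_) / len(self.signature)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        signs = self.signature.signs
        scores = np.zeros(X.shape[0])
        for f, j in self.feature_positions_.items():
            scores += signs[f] * standardize_feature(X[:, j])
        return scores[:, None]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self)
        return np.array([f"{self.signature.name}_score"], dtype=object)
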