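"""Random-signature benchmarks.

A derived signature's summed AUC across validation cohorts is compared with
size-matched signatures drawn at random from (a) the whole feature universe
shared by the cohorts ("genome" pool) or (b) the severity-related feature
pool from the discovery screen. The empirical right-tailed p-value uses the
add-one rule, so it is never zero, and draws tying the observed statistic
count toward the tail (the conservative choice).

Random signatures need an orientation (a sign per feature) to be scorable.
When screen records are supplied the feature's severity-screen rho fixes the
sign — independent of the validation labels. Otherwise the sign of the
feature's Spearman correlation with the cohort's own labels is used, which
gives the random draws their best-case orientation per cohort and hence
makes the comparison against the fixed-orientation observed signature
conservative. Calibration analyses should supply screen records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .data_model import CohortAnnotation, ExpressionMatrix, ScreenRecord, Signature
from .evaluation import roc_auc
from .scoring import score_cohort
from .screen import spearman_matrix

__all__ = [
    "ResamplingOutcome",
    "signature_auc_sum",
    "draw_random_signatures",
    "empirical_p_right",
    "run_resampling_test",
]

Cohort = tuple[ExpressionMatrix, CohortAnnotation]


@dataclass
class ResamplingOutcome:
    observed: float
    null_draws: np.ndarray
    p_right: float
    pool: str  # "genome" | "disease_related"
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        self.null_draws = np.asarray(self.null_draws, dtype=float)
        if self.null_draws.shape != (self.n_resamples,):
            raise ValueError("null_draws length must equal n_resamples")


def signature_auc_sum(signature: Signature, cohorts: Sequence[Cohort]) -> float:
    """Sum of the signature's score AUC over validation cohorts (the
    multi-cohort classification-power statistic)."""
    if not cohorts:
        raise ValueError("need at least one cohort")
    total = 0.0
    for matrix, annotation in cohorts:
        sv = score_cohort(matrix, signature, missing_policy="drop")
        total += roc_auc(sv, annotation).auc
    return total


def draw_random_signatures(
    pool: Sequence[str],
    k: int,
    n_resamples: int,
    seed: int,
    rho_by_feature: dict[str, float] | None = None,
) -> list[Signature]:
    """Draw size-``k`` signatures uniformly without replacement from a
    feature pool.

    ``rho_by_feature`` supplies each feature's orientation (e.g. from the
    severity screen); features without an entry get a placeholder rho of
    +1, to be re-oriented by the caller. Deterministic given ``seed``.
    """
    pool = list(pool)
    if len(pool) < k:
        raise ValueError(f"pool of {len(pool)} features is smaller than k={k}")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rho_by_feature = rho_by_feature or {}
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_resamples):
        chosen = [pool[j] for j in rng.choice(len(pool), size=k, replace=False)]
        entries = [(f, rho_by_feature.get(f, 1.0)) for f in chosen]
        out.append(Signature(f"random-{i + 1}", "mRNA", entries))
    return out


def empirical_p_right(observed: float, null_draws: Sequence[float]) -> float:
    """Add-one right-tailed empirical p: ``(#{draws >= observed} + 1) /
    (n + 1)``."""
    null = np.asarray(null_draws, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return float((np.sum(null >= observed) + 1) / (null.size + 1))


def _cohort_arrays(matrix: ExpressionMatrix, annotation: CohortAnnotation):
    """Standardized expression, binary labels and label-correlation signs
    for the resampling inner loop."""
    y = annotation.codes_for(matrix.sample_ids).astype(float)
    sd = matrix.values.std(axis=1, ddof=1)
    usable = sd > 0
    z = (matrix.values[usable] - matrix.values[usable].mean(axis=1, keepdims=True)) / sd[
        usable, None
    ]
    ids = [f for f, u in zip(matrix.feature_ids, usable) if u]
    rho, _ = spearman_matrix(z, y)
    fallback_signs = np.where(rho >= 0, 1.0, -1.0)
    ranks_y = stats.rankdata(y)
    return ids, z, y, fallback_signs, ranks_y


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC with half-credit ties via mid-ranks."""
    r = stats.rankdata(scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def run_resampling_test(
    signature: Signature,
    cohorts: Sequence[Cohort],
    pool_kind: str,
    screen: Iterable[ScreenRecord] | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
) -> ResamplingOutcome:
    """Benchmark a signature against size-matched random signatures.

    ``pool_kind="genome"`` draws from all features shared by every cohort
    matrix; ``pool_kind="disease_related"`` restricts the pool to features
    with a severity-screen record (``screen`` is then required). Returns
    the observed sum of AUC, the null draws and the right-tailed add-one
    empirical p-value. Deterministic given ``seed``.
    """
    if pool_kind not in {"genome", "disease_related"}:
        raise ValueError("pool_kind must be 'genome' or 'disease_related'")
    if not cohorts:
        raise ValueError("need at least one cohort")
    screen_rho = {r.feature_id: r.rho for r in screen} if screen is not None else {}
    if pool_kind == "disease_related" and not screen_rho:
        raise ValueError("disease_related pool requires severity-screen records")

    prepared = [_cohort_arrays(m, a) for m, a in cohorts]
    shared: set[str] | None = None
    for ids, *_ in prepared:
        shared = set(ids) if shared is None else shared & set(ids)
    if pool_kind == "disease_related":
        shared &= set(screen_rho)
    pool = sorted(shared)
    k = len(signature)
    if len(pool) < k:
        raise ValueError(f"pool of {len(pool)} features is smaller than signature size {k}")

    observed = signature_auc_sum(signature, cohorts)

    rng = np.random.default_rng(seed)
    index_of = [{f: i for i, f in enumerate(ids)} for ids, *_ in prepared]
    null = np.empty(n_resamples)
    for d in range(n_resamples):
        chosen = [pool[j] for j in rng.choice(len(pool), size=k, replace=False)]
        total = 0.0
        for c, (ids, z, y, fallback, _) in enumerate(prepared):
            rows = np.array([index_of[c][f] for f in chosen])
            signs = np.array(
                [
                    np.sign(screen_rho[f]) if f in screen_rho else fallback[index_of[c][f]]
                    for f in chosen
                ]
            )
            total += _rank_auc(signs @ z[rows], y)
        null[d] = total
    return ResamplingOutcome(
        observed=observed,
        null_draws=null,
        p_right=empirical_p_right(observed, null),
        pool=pool_kind,
        n_resamples=n_resamples,
        seed=seed,
    )
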