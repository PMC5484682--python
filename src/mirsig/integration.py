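"""Derivation of miRNA-regulated signatures.

Predicted miRNA targets are filtered by mirSVR score, intersected with the
severity-screened miRNAs and genes, and tested for negative expression
correlation between the miRNA and its predicted target; the unique miRNAs
and genes of the surviving pairs form the two signatures, each feature
weighted by the sign of its own severity correlation.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .data_model import (
    ExpressionMatrix,
    RegulatoryPair,
    ScreenRecord,
    Signature,
    TargetPrediction,
)
from .screen import _midrank_pearson, _t_pvalue, bh_adjust

__all__ = [
    "MIRSVR_CUTOFF",
    "filter_predictions",
    "candidate_pairs",
    "pair_anticorrelation",
    "derive_signatures",
]

logger = logging.getLogger(__name__)

#: Default mirSVR cutoff: roughly the top 5% of predicted bindings.
MIRSVR_CUTOFF = -1.2


def filter_predictions(
    predictions: Sequence[TargetPrediction], cutoff: float = MIRSVR_CUTOFF
) -> list[TargetPrediction]:
    """Keep predictions with ``mirsvr_score <= cutoff`` (inclusive: a score
    of exactly -1.2, or -1.201 printed at coarser precision, passes)."""
    return [p for p in predictions if p.mirsvr_score <= cutoff]


def candidate_pairs(
    predictions: Sequence[TargetPrediction],
    de_mirnas: Iterable[ScreenRecord],
    de_genes: Iterable[ScreenRecord],
) -> list[TargetPrediction]:
    """Intersect predictions with the differentially expressed features:
    keep a prediction only if its miRNA passed the miRNA screen and its
    target gene passed the gene screen."""
    mirnas = {r.feature_id for r in de_mirnas}
    genes = {r.feature_id for r in de_genes}
    return [p for p in predictions if p.mirna_id in mirnas and p.gene_symbol in genes]


def pair_anticorrelation(
    candidates: Sequence[TargetPrediction],
    mirna_matrix: ExpressionMatrix,
    gene_matrix: ExpressionMatrix,
    alpha: float = 0.005,
) -> list[RegulatoryPair]:
    """Retain candidate pairs whose miRNA and target-gene expression are
    significantly negatively correlated.

    Spearman rho is computed across the sample intersection of the two
    platforms (the well-defined choice when the cohorts differ); p-values
    are BH-adjusted over the candidate family, and pairs with ``rho < 0``
    and ``adj_p < alpha`` (strict) are returned in candidate order.
    Candidates referencing a feature absent from its matrix are logged and
    skipped.
    """
    shared = [s for s in mirna_matrix.sample_ids if s in set(gene_matrix.sample_ids)]
    if len(shared) < 4:
        raise ValueError(
            f"need >= 4 shared samples for pair correlation, found {len(shared)}"
        )
    m_sub = mirna_matrix.subset_samples(shared)
    g_sub = gene_matrix.subset_samples(shared)
    mirna_pos = {f: i for i, f in enumerate(m_sub.feature_ids)}
    gene_pos = {f: i for i, f in enumerate(g_sub.feature_ids)}

    usable: list[TargetPrediction] = []
    for cand in candidates:
        if cand.mirna_id not in mirna_pos:
            logger.warning("candidate miRNA %r absent from miRNA matrix; skipped", cand.mirna_id)
            continue
        if cand.gene_symbol not in gene_pos:
            logger.warning("candidate gene %r absent from gene matrix; skipped", cand.gene_symbol)
            continue
        usable.append(cand)
    if not usable:
        return []

    # rank once per matrix, then vectorized mid-rank Pearson per pair
    m_ranks = stats.rankdata(m_sub.values, axis=1)
    g_ranks = stats.rankdata(g_sub.values, axis=1)
    rhos = np.empty(len(usable))
    for i, cand in enumerate(usable):
        rhos[i] = _midrank_pearson(
            m_ranks[mirna_pos[cand.mirna_id]][None, :], g_ranks[gene_pos[cand.gene_symbol]]
        )[0]
    p = np.clip(_t_pvalue(rhos, len(shared)), np.finfo(float).tiny, 1.0)
    adj = bh_adjust(p)
    return [
        RegulatoryPair(c.mirna_id, c.gene_symbol, c.mirsvr_score, float(r), float(a))
        for c, r, a in zip(usable, rhos, adj)
        if r < 0 and a < alpha
    ]


def derive_signatures(
    pairs: Sequence[RegulatoryPair],
    mirna_screen: Iterable[ScreenRecord],
    gene_screen: Iterable[ScreenRecord],
    mirna_name: str = "miRNA-signature",
    gene_name: str = "gene-signature",
) -> tuple[Signature, Signature]:
    """Collapse retained pairs to the unique miRNA and gene signatures.

    Each signature feature carries its *severity*-correlation rho from the
    screen (the score weights come from the severity direction, not from
    the pair correlation). Ordering follows first appearance in the pair
    list.
    """
    if not pairs:
        raise ValueError("no pairs to derive signatures from")
    mirna_rho = {r.feature_id: r.rho for r in mirna_screen}
    gene_rho = {r.feature_id: r.rho for r in gene_screen}
    mirna_entries: list[tuple[str, float]] = []
    gene_entries: list[tuple[str, float]] = []
    for pair in pairs:
        if pair.mirna_id not in mirna_rho:
            raise KeyError(f"no screen record for pair miRNA {pair.mirna_id!r}")
        if pair.gene_symbol not in gene_rho:
            raise KeyError(f"no screen record for pair gene {pair.gene_symbol!r}")
        if pair.mirna_id not in dict(mirna_entries):
            mirna_entries.append((pair.mirna_id, mirna_rho[pair.mirna_id]))
        if pair.gene_symbol not in dict(gene_entries):
            gene_entries.append((pair.gene_symbol, gene_rho[pair.gene_symbol]))
    return (
        Signature(mirna_name, "miRNA", mirna_entries),
        Signature(gene_name, "mRNA", gene_entries),
    )
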