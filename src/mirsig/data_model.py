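"""Domain types and tabular I/O for the signature-discovery pipeline.

All on-disk formats are plain TSV (tab-separated, UTF-8, ``.`` decimal,
no quoting). Unicode minus signs (U+2212), common in tables copied from
typeset documents, are normalized to ASCII ``-`` on read.

The core container is :class:`ExpressionMatrix`, a features x samples
matrix of (log-scale) expression values. Sample metadata lives in
:class:`CohortAnnotation`, which encodes the ordinal severity axis
healthy control (HC) -> uncomplicated sarcoidosis (US) -> complicated
sarcoidosis (CS) as integer codes 0/1/2, or binary control/case cohorts
as 0/1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DegenerateInputError",
    "ExpressionMatrix",
    "CohortAnnotation",
    "DetectionMask",
    "ScreenRecord",
    "TargetPrediction",
    "RegulatoryPair",
    "Signature",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_target_table",
    "write_target_table",
    "read_signature",
    "write_signature",
    "write_pairs",
    "read_pairs",
    "load_reference_table",
    "GROUP_CODES",
]


class FormatError(ValueError):
    """A tabular input file violates the expected TSV layout."""


class DegenerateInputError(ValueError):
    """An input is statistically degenerate (e.g. zero variance)."""


#: Ordinal encoding of sample groups. Spearman screening uses only the rank
#: order of the codes, so the equal spacing of 0/1/2 carries no assumption.
GROUP_CODES = {"HC": 0, "US": 1, "CS": 2, "control": 0, "case": 1}

Platform = Literal["miRNA", "mRNA"]


def _normalize_minus(text: str) -> str:
    return text.replace("−", "-").replace("–", "-")


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with a platform tag.

    Parameters
    ----------
    values : ndarray of shape (n_features, n_samples)
        Continuous (log-scale) expression values; must be finite.
    feature_ids : sequence of str
        Unique miRNA names or gene symbols, one per row.
    sample_ids : sequence of str
        Unique sample identifiers, one per column.
    platform : {"miRNA", "mRNA"}
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    platform: Platform = "mRNA"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional (features x samples)")
        n_feat, n_samp = self.values.shape
        if n_feat != len(self.feature_ids) or n_samp != len(self.sample_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match id lists "
                f"({len(self.feature_ids)} features, {len(self.sample_ids)} samples)"
            )
        if len(set(self.feature_ids)) != n_feat:
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != n_samp:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None

    def subset_features(self, keep: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.feature_index(f) for f in keep]
        return ExpressionMatrix(self.values[idx], list(keep), list(self.sample_ids), self.platform)

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return ExpressionMatrix(self.values[:, idx], list(self.feature_ids), list(keep), self.platform)


@dataclass
class CohortAnnotation:
    """Sample -> group mapping with a monotone ordinal severity code."""

    sample_ids: list[str]
    group: list[str]
    severity_code: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.group = [str(g) for g in self.group]
        if len(self.sample_ids) != len(self.group):
            raise ValueError("sample_ids and group must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in annotation")
        unknown = sorted(set(self.group) - set(GROUP_CODES))
        if unknown:
            raise ValueError(f"unknown group labels: {unknown}")
        if self.severity_code is None:
            self.severity_code = np.array([GROUP_CODES[g] for g in self.group], dtype=int)
        else:
            self.severity_code = np.asarray(self.severity_code, dtype=int)
        if len(set(self.group)) < 2:
            raise ValueError("annotation must contain at least two distinct groups")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def codes_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = dict(zip(self.sample_ids, self.severity_code))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples missing from annotation: {missing[:5]}")
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def is_binary(self) -> bool:
        return set(np.unique(self.severity_code)) <= {0, 1}


@dataclass
class DetectionMask:
    """Boolean detection calls aligned with an :class:`ExpressionMatrix`."""

    detected: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.detected.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("detection mask shape does not match id lists")

    @classmethod
    def all_true(cls, matrix: ExpressionMatrix) -> "DetectionMask":
        return cls(
            np.ones_like(matrix.values, dtype=bool),
            list(matrix.feature_ids),
            list(matrix.sample_ids),
        )

    def aligned_with(self, matrix: ExpressionMatrix) -> bool:
        return (
            self.feature_ids == matrix.feature_ids and self.sample_ids == matrix.sample_ids
        )


@dataclass
class ScreenRecord:
    """One feature's severity-correlation screening result."""

    feature_id: str
    rho: float
    p_value: float
    adj_p: float

    def __post_init__(self) -> None:
        if np.isnan(self.rho):
            raise ValueError("rho must not be NaN")

    @property
    def direction(self) -> str:
        return "up" if self.rho > 0 else "down"


@dataclass(frozen=True)
class TargetPrediction:
    """A predicted miRNA -> gene binding with its mirSVR score.

    More negative mirSVR means stronger predicted down-regulation; the
    pipeline's default cutoff of -1.2 keeps roughly the top 5% of
    predictions.
    """

    mirna_id: str
    gene_symbol: str
    mirsvr_score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mirsvr_score):
            raise ValueError("mirSVR score must be finite")


@dataclass(frozen=True)
class RegulatoryPair:
    """A retained miRNA-target pair: predicted binding plus observed
    negative expression correlation."""

    mirna_id: str
    gene_symbol: str
    mirsvr_score: float
    pair_rho: float
    pair_adj_p: float


@dataclass
class Signature:
    """An ordered expression signature.

    ``entries`` holds ``(feature_id, rho)`` where *rho* is the feature's
    Spearman correlation with disease severity; the severity score uses
    only ``sign(rho)`` as the feature weight.
    """

    name: str
    platform: Platform
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("signature must contain at least one feature")
        self.entries = [(str(f), float(r)) for f, r in self.entries]
        ids = [f for f, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in signature")
        if any(r == 0 for _, r in self.entries):
            raise ValueError("signature rho values must be nonzero")

    @property
    def feature_ids(self) -> list[str]:
        return [f for f, _ in self.entries]

    @property
    def rho(self) -> dict[str, float]:
        return dict(self.entries)

    @property
    def signs(self) -> dict[str, int]:
        return {f: (1 if r > 0 else -1) for f, r in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv_text(path) -> io.StringIO:
    with open(path, "r", encoding="utf-8") as fh:
        return io.StringIO(_normalize_minus(fh.read()))


def read_expression_matrix(path, platform: Platform = "mRNA") -> ExpressionMatrix:
    """Parse a features x samples TSV (header = sample ids, first column =
    feature id).

    Rows sharing a feature id (multiple probes per symbol) are collapsed by
    the per-feature arithmetic mean, preserving first-appearance order.

    Raises
    ------
    FormatError
        On an empty matrix, malformed header or a non-numeric cell; the
        message names the offending row and column.
    """
    raw = pd.read_csv(_read_tsv_text(path), sep="\t", dtype=str, index_col=0)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r} in header")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna() | raw.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at row {i + 2} (feature {raw.index[i]!r}, "
            f"column {raw.columns[j]!r})"
        )
    # collapse duplicate feature ids by mean, keeping first-appearance order
    if numeric.index.duplicated().any():
        order = pd.unique(numeric.index)
        numeric = numeric.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix(
        numeric.to_numpy(dtype=float),
        list(numeric.index.astype(str)),
        list(numeric.columns.astype(str)),
        platform,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id", float_format="%.17g")


def read_annotation(path) -> CohortAnnotation:
    """Parse a sample annotation TSV with columns ``sample_id`` and ``group``."""
    df = pd.read_csv(_read_tsv_text(path), sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    try:
        return CohortAnnotation(list(df["sample_id"]), list(df["group"]))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_annotation(annotation: CohortAnnotation, path) -> None:
    pd.DataFrame(
        {"sample_id": annotation.sample_ids, "group": annotation.group}
    ).to_csv(path, sep="\t", index=False)


def read_target_table(path) -> list[TargetPrediction]:
    """Parse a target-prediction TSV (``mirna_id``, ``gene_symbol``,
    ``mirsvr_score``).

    Duplicate (miRNA, gene) rows are collapsed keeping the most negative
    score — the conservative choice for a "score <= cutoff" filter.
    """
    df = pd.read_csv(_read_tsv_text(path), sep="\t", dtype=str)
    for col in ("mirna_id", "gene_symbol", "mirsvr_score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df.empty:
        return []
    scores = pd.to_numeric(df["mirsvr_score"], errors="coerce")
    if scores.isna().any():
        i = int(np.flatnonzero(scores.isna())[0])
        raise FormatError(f"{path}: non-numeric mirSVR score at row {i + 2}")
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for mirna, gene, score in zip(df["mirna_id"], df["gene_symbol"], scores):
        key = (str(mirna), str(gene))
        if key not in best:
            best[key] = float(score)
            order.append(key)
        else:
            best[key] = min(best[key], float(score))
    return [TargetPrediction(m, g, best[(m, g)]) for m, g in order]


def write_target_table(predictions: Iterable[TargetPrediction], path) -> None:
    pd.DataFrame(
        [(p.mirna_id, p.gene_symbol, p.mirsvr_score) for p in predictions],
        columns=["mirna_id", "gene_symbol", "mirsvr_score"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_signature(path, name: str = "signature", platform: Platform = "mRNA") -> Signature:
    df = pd.read_csv(_read_tsv_text(path), sep="\t")
    for col in ("feature_id", "rho"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return Signature(name, platform, list(zip(df["feature_id"].astype(str), df["rho"].astype(float))))


def write_signature(signature: Signature, path) -> None:
    pd.DataFrame(signature.entries, columns=["feature_id", "rho"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def write_pairs(pairs: Iterable[RegulatoryPair], path) -> None:
    pd.DataFrame(
        [(p.mirna_id, p.gene_symbol, p.mirsvr_score, p.pair_rho, p.pair_adj_p) for p in pairs],
        columns=["mirna_id", "gene_symbol", "mirsvr_score", "pair_rho", "pair_adj_p"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pairs(path) -> list[RegulatoryPair]:
    df = pd.read_csv(_read_tsv_text(path), sep="\t")
    return [
        RegulatoryPair(
            str(r.mirna_id),
            str(r.gene_symbol),
            float(r.mirsvr_score),
            float(r.pair_rho),
            float(r.pair_adj_p),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# packaged reference fixtures


def _fixture_path(filename: str):
    return resources.files("mirsig.fixtures").joinpath(filename)


def load_reference_table(which: str):
    """Load one of the packaged published reference tables.

    Parameters
    ----------
    which : {"pairs", "mirna_signature", "gene_signature"}
        ``pairs`` returns the 19 retained sarcoidosis miRNA-target pairs
        as a list of :class:`RegulatoryPair`; ``mirna_signature`` the
        8-miRNA severity signature and ``gene_signature`` the 17-gene
        severity signature, both as :class:`Signature` with the published
        severity-correlation rho per feature.
    """
    if which == "pairs":
        with resources.as_file(_fixture_path("reference_pairs.tsv")) as path:
            return read_pairs(path)
    if which == "mirna_signature":
        with resources.as_file(_fixture_path("reference_mirna_signature.tsv")) as path:
            return read_signature(path, name="8-miRNA", platform="miRNA")
    if which == "gene_signature":
        with resources.as_file(_fixture_path("reference_gene_signature.tsv")) as path:
            return read_signature(path, name="17-gene", platform="mRNA")
    raise ValueError(
        f"unknown reference table {which!r}; expected one of "
        "'pairs', 'mirna_signature', 'gene_signature'"
    )
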