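"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a severity-stratified discovery study: three ordered
groups (healthy control, uncomplicated, complicated), a miRNA platform and
an mRNA platform that share the control/uncomplicated samples but differ in
complicated-group size, planted miRNAs whose expression shifts monotonically
with severity, target genes generated *conditionally on the realized miRNA
expression* with a negative slope (so the planted pairs are guaranteed
anti-correlated and severity-associated with opposite sign), decoy features
that are pure noise, and a target-prediction table whose planted pairs carry
mirSVR scores passing the -1.2 cutoff while decoy predictions do not.

Values are Gaussian on a log-expression scale; probe effects, batch
structure and count noise of real arrays are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    CohortAnnotation,
    DetectionMask,
    ExpressionMatrix,
    Signature,
    TargetPrediction,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "DiscoveryData",
    "generate_discovery",
    "generate_target_table",
    "generate_validation",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic discovery study.

    Group sizes default to the emulated study design: 35/17/13 samples
    (HC/US/CS) on the miRNA platform and 35/17/22 on the mRNA platform.
    ``severity_effect`` is the per-severity-step mean shift of a planted
    miRNA in units of ``noise_sd``; ``coupling_strength`` is the magnitude
    of the negative regression slope of a planted target gene on its
    miRNA's realized expression.
    """

    n_per_group_mirna: tuple[int, int, int] = (35, 17, 13)
    n_per_group_gene: tuple[int, int, int] = (35, 17, 22)
    n_mirna_features: int = 300
    n_gene_features: int = 1000
    n_signal_mirnas: int = 8
    targets_per_signal_mirna: int = 2
    n_extra_severity_genes: int = 100
    severity_effect: float = 1.5
    coupling_strength: float = 1.0
    noise_sd: float = 1.0
    n_decoy_predictions: int = 200
    undetected_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirna_features", "n_gene_features", "n_signal_mirnas", "targets_per_signal_mirna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(n < 1 for n in self.n_per_group_mirna + self.n_per_group_gene):
            raise ValueError("group sizes must be >= 1")
        if self.n_decoy_predictions < 0:
            raise ValueError("n_decoy_predictions must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.undetected_fraction < 1:
            raise ValueError("undetected_fraction must be in [0, 1)")
        if self.n_signal_mirnas > self.n_mirna_features:
            raise ValueError("more signal miRNAs than miRNA features")
        if self.n_extra_severity_genes < 0:
            raise ValueError("n_extra_severity_genes must be >= 0")
        n_planted = self.n_signal_mirnas * self.targets_per_signal_mirna
        if n_planted + self.n_extra_severity_genes > self.n_gene_features:
            raise ValueError("planted target + extra severity genes exceed gene features")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic discovery dataset.

    ``extra_severity_genes`` are severity-associated genes that are *not*
    miRNA targets — the analogue of the large body of disease-related genes
    outside the miRNA-regulated signature; they populate the
    disease-related resampling pool.
    """

    signal_mirnas: dict[str, int]  # id -> planted severity direction (+1/-1)
    signal_genes: dict[str, int]
    planted_pairs: set[tuple[str, str]]
    extra_severity_genes: dict[str, int] = field(default_factory=dict)
    all_mirna_ids: list[str] = field(default_factory=list)
    all_gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for mirna, gene in self.planted_pairs:
            if mirna not in self.signal_mirnas or gene not in self.signal_genes:
                raise ValueError("planted pairs must connect signal miRNAs to signal genes")


@dataclass
class DiscoveryData:
    mirna: ExpressionMatrix
    genes: ExpressionMatrix
    annotation: CohortAnnotation
    mirna_mask: DetectionMask
    gene_mask: DetectionMask
    truth: GroundTruth


def _sample_ids(n_per_group: tuple[int, int, int]) -> tuple[list[str], list[str]]:
    groups = []
    ids = []
    for label, n in zip(("HC", "US", "CS"), n_per_group):
        for i in range(n):
            ids.append(f"{label}{i + 1:03d}")
            groups.append(label)
    return ids, groups


def _plant_mask(rng: np.random.Generator, shape: tuple[int, int], fraction: float) -> np.ndarray:
    detected = np.ones(shape, dtype=bool)
    if fraction > 0:
        detected &= rng.random(shape) >= fraction
    return detected


def generate_discovery(spec: SyntheticSpec) -> DiscoveryData:
    """Generate one synthetic discovery study.

    A single cohort covering the union of the two platforms' group sizes is
    drawn; the miRNA matrix exposes its 35/17/13-style subset and the gene
    matrix its 35/17/22-style subset, so downstream pair correlation uses
    the shared-sample intersection exactly as with real two-platform data.
    Planted miRNA *i* follows ``baseline + direction_i * severity_effect *
    severity_code + N(0, noise_sd)``; planted target genes follow
    ``baseline - coupling_strength * miRNA_expression + N(0, noise_sd)``;
    everything else is baseline plus noise. Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_union = tuple(
        max(a, b) for a, b in zip(spec.n_per_group_mirna, spec.n_per_group_gene)
    )
    all_ids, all_groups = _sample_ids(n_union)
    annotation = CohortAnnotation(all_ids, all_groups)
    codes = annotation.severity_code.astype(float)
    n_samples = len(all_ids)

    mirna_ids = [f"miR-syn-{i + 1:03d}" for i in range(spec.n_mirna_features)]
    gene_ids = [f"SYNG{i + 1:04d}" for i in range(spec.n_gene_features)]
    signal_mirnas = mirna_ids[: spec.n_signal_mirnas]
    directions = rng.choice([-1, 1], size=spec.n_signal_mirnas)
    n_signal_genes = spec.n_signal_mirnas * spec.targets_per_signal_mirna
    signal_genes = gene_ids[:n_signal_genes]

    # miRNA platform: baseline + planted monotone severity shift + noise
    mirna_baseline = rng.uniform(6.0, 10.0, size=spec.n_mirna_features)
    mirna_vals = mirna_baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_mirna_features, n_samples)
    )
    for k in range(spec.n_signal_mirnas):
        mirna_vals[k] += directions[k] * spec.severity_effect * codes

    # gene platform: planted targets regress negatively on their miRNA's
    # realized expression; remaining genes are noise
    gene_baseline = rng.uniform(6.0, 10.0, size=spec.n_gene_features)
    gene_vals = gene_baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_gene_features, n_samples)
    )
    pairs: set[tuple[str, str]] = set()
    truth_genes: dict[str, int] = {}
    g = 0
    for k, mirna in enumerate(signal_mirnas):
        for _ in range(spec.targets_per_signal_mirna):
            gene_vals[g] -= spec.coupling_strength * (mirna_vals[k] - mirna_baseline[k])
            pairs.add((mirna, gene_ids[g]))
            truth_genes[gene_ids[g]] = -int(directions[k])
            g += 1
    # severity-associated genes outside the miRNA-regulated set: shifted
    # with severity but coupled to no miRNA
    extra_dirs = rng.choice([-1, 1], size=spec.n_extra_severity_genes)
    extra_genes: dict[str, int] = {}
    for d in extra_dirs:
        gene_vals[g] += int(d) * spec.severity_effect * codes
        extra_genes[gene_ids[g]] = int(d)
        g += 1

    def subset(n_per_group: tuple[int, int, int]) -> list[str]:
        keep = []
        offset = 0
        for n_grp, n_take in zip(n_union, n_per_group):
            keep.extend(all_ids[offset : offset + n_take])
            offset += n_grp
        return keep

    mirna_samples = subset(spec.n_per_group_mirna)
    gene_samples = subset(spec.n_per_group_gene)
    mirna_matrix = ExpressionMatrix(mirna_vals, mirna_ids, all_ids, "miRNA").subset_samples(
        mirna_samples
    )
    gene_matrix = ExpressionMatrix(gene_vals, gene_ids, all_ids, "mRNA").subset_samples(
        gene_samples
    )

    truth = GroundTruth(
        signal_mirnas={m: int(d) for m, d in zip(signal_mirnas, directions)},
        signal_genes=truth_genes,
        planted_pairs=pairs,
        extra_severity_genes=extra_genes,
        all_mirna_ids=mirna_ids,
        all_gene_ids=gene_ids,
    )
    mirna_mask = DetectionMask(
        _plant_mask(rng, mirna_matrix.values.shape, spec.undetected_fraction),
        list(mirna_matrix.feature_ids),
        list(mirna_matrix.sample_ids),
    )
    gene_mask = DetectionMask(
        _plant_mask(rng, gene_matrix.values.shape, spec.undetected_fraction),
        list(gene_matrix.feature_ids),
        list(gene_matrix.sample_ids),
    )
    return DiscoveryData(mirna_matrix, gene_matrix, annotation, mirna_mask, gene_mask, truth)


def generate_target_table(truth: GroundTruth, spec: SyntheticSpec) -> list[TargetPrediction]:
    """Prediction table matched to a ground truth: planted pairs score
    uniformly in [-2.0, -1.2] (passing the cutoff); decoy predictions are
    random non-planted pairs scoring in (-1.2, -0.1). Deterministic given
    ``spec.seed``."""
    rng = np.random.default_rng([spec.seed, 7])
    table = [
        TargetPrediction(m, g, float(rng.uniform(-2.0, -1.2)))
        for m, g in sorted(truth.planted_pairs)
    ]
    planted = set(truth.planted_pairs)
    seen = set(planted)
    n_drawn = 0
    while n_drawn < spec.n_decoy_predictions:
        m = truth.all_mirna_ids[int(rng.integers(len(truth.all_mirna_ids)))]
        g = truth.all_gene_ids[int(rng.integers(len(truth.all_gene_ids)))]
        if (m, g) in seen:
            continue
        seen.add((m, g))
        table.append(TargetPrediction(m, g, float(rng.uniform(-1.199, -0.1))))
        n_drawn += 1
    return table


def generate_validation(
    signature: Signature,
    n_controls: int,
    n_cases: int,
    shift: float,
    noise_sd: float,
    seed: int,
    n_background: int = 200,
) -> tuple[ExpressionMatrix, CohortAnnotation]:
    """Generate a binary case/control validation cohort for a signature.

    Case samples are shifted by ``sign(rho_i) * shift`` on every signature
    feature (so cases score higher under the sign-weighted score);
    ``n_background`` extra features are pure noise. Deterministic given
    ``seed``.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if n_controls < 1 or n_cases < 1:
        raise ValueError("need at least one sample per class")
    rng = np.random.default_rng(seed)
    sample_ids = [f"C{i + 1:03d}" for i in range(n_controls)] + [
        f"P{i + 1:03d}" for i in range(n_cases)
    ]
    groups = ["control"] * n_controls + ["case"] * n_cases
    annotation = CohortAnnotation(sample_ids, groups)
    case = np.array([0.0] * n_controls + [1.0] * n_cases)

    feature_ids = list(signature.feature_ids) + [
        f"BG{i + 1:04d}" for i in range(n_background)
    ]
    n_features = len(feature_ids)
    baseline = rng.uniform(6.0, 10.0, size=n_features)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_features, len(sample_ids)))
    for i, (_, rho) in enumerate(signature.entries):
        values[i] += np.sign(rho) * shift * case
    return (
        ExpressionMatrix(values, feature_ids, sample_ids, signature.platform),
        annotation,
    )
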