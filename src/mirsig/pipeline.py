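"""End-to-end orchestration: simulate -> screen -> integrate -> score ->
evaluate -> resample, with every intermediate artifact written to disk and
a machine-readable manifest for reproducibility.

All thresholds default to the study design the package emulates: miRNA
screen at adjusted P < 0.05, gene screen at adjusted P < 0.0005, pair
anti-correlation at adjusted P < 0.005, mirSVR cutoff -1.2, presence
fraction 2/3. A rerun with the same config and seed is bitwise-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import data_model as dm
from .evaluation import group_ttest, roc_auc, severity_trend
from .integration import candidate_pairs, derive_signatures, filter_predictions, pair_anticorrelation
from .resampling import run_resampling_test
from .scoring import score_cohort
from .screen import presence_filter, screen_features
from .synthetic import SyntheticSpec, generate_discovery, generate_target_table, generate_validation

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception | str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Pipeline thresholds, inputs and run parameters.

    With no input paths the pipeline runs in synthetic mode, generating a
    discovery study and two validation cohorts. Real-data mode consumes
    TSV paths for the two matrices, the annotation and the target table
    (validation stages then require ``validation_paths``).
    """

    # thresholds (defaults = the emulated study design)
    mirna_alpha: float = 0.05
    gene_alpha: float = 0.0005
    pair_alpha: float = 0.005
    mirsvr_cutoff: float = -1.2
    presence_fraction: float = 2.0 / 3.0
    # resampling
    n_resamples: int = 1000
    # synthetic mode
    synthetic: SyntheticSpec | None = None
    validation_cohort_sizes: tuple[tuple[int, int], ...] = ((20, 40), (25, 12))
    validation_shift: float = 1.0
    # real-data mode
    mirna_matrix_path: str | None = None
    gene_matrix_path: str | None = None
    annotation_path: str | None = None
    target_table_path: str | None = None
    validation_paths: tuple[tuple[str, str], ...] = ()  # (matrix, annotation) pairs
    # run
    seed: int = 0
    outdir: str = "mirsig_run"

    def __post_init__(self) -> None:
        for name in ("mirna_alpha", "gene_alpha", "pair_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.presence_fraction <= 1:
            raise ValueError("presence_fraction must be in (0, 1]")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")

    @property
    def synthetic_mode(self) -> bool:
        return self.mirna_matrix_path is None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_keys = {f.name for f in dataclasses.fields(SyntheticSpec)}
        spec_kwargs = {k: raw.pop(k) for k in list(raw) if k in synth_keys}
        cfg_keys = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - cfg_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "validation_cohort_sizes" in raw:
            raw["validation_cohort_sizes"] = tuple(tuple(x) for x in raw["validation_cohort_sizes"])
        if "validation_paths" in raw:
            raw["validation_paths"] = tuple(tuple(x) for x in raw["validation_paths"])
        cfg = cls(**raw)
        if spec_kwargs:
            cfg.synthetic = SyntheticSpec(**spec_kwargs)
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_screen(records, path: Path) -> None:
    pd.DataFrame(
        [(r.feature_id, r.rho, r.p_value, r.adj_p, r.direction) for r in records],
        columns=["feature_id", "rho", "p", "adj_p", "direction"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage, writing artifacts and ``manifest.json`` to
    ``config.outdir``; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": config.to_jsonable(), "stages": []}

    def record_stage(name: str, outputs: list[Path], counts: dict) -> None:
        manifest["stages"].append(
            {
                "name": name,
                "outputs": {p.name: _sha256(p) for p in outputs},
                "counts": counts,
            }
        )
        logger.info("stage %s: %s", name, counts)

    # ------------------------------------------------------------- simulate
    try:
        if config.synthetic_mode:
            spec = config.synthetic or SyntheticSpec()
            spec = dataclasses.replace(spec, seed=config.seed)
            data = generate_discovery(spec)
            targets = generate_target_table(data.truth, spec)
            mirna, genes, annotation = data.mirna, data.genes, data.annotation
            mirna_mask, gene_mask = data.mirna_mask, data.gene_mask
            outs = []
            for name, writer in (
                ("mirna_matrix.tsv", lambda p: dm.write_expression_matrix(mirna, p)),
                ("gene_matrix.tsv", lambda p: dm.write_expression_matrix(genes, p)),
                ("annotation.tsv", lambda p: dm.write_annotation(annotation, p)),
                ("target_table.tsv", lambda p: dm.write_target_table(targets, p)),
            ):
                writer(outdir / name)
                outs.append(outdir / name)
            record_stage(
                "simulate",
                outs,
                {
                    "n_mirna_features": mirna.n_features,
                    "n_gene_features": genes.n_features,
                    "n_samples": annotation.n_samples,
                    "n_predictions": len(targets),
                },
            )
        else:
            record_stage("simulate", [], {"mode": "real-data inputs; nothing simulated"})
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("simulate", exc) from exc

    # --------------------------------------------------------------- screen
    try:
        if not config.synthetic_mode:
            # inputs are read where first consumed, so a corrupt file
            # aborts with the stage that needed it
            mirna = dm.read_expression_matrix(config.mirna_matrix_path, "miRNA")
            genes = dm.read_expression_matrix(config.gene_matrix_path, "mRNA")
            annotation = dm.read_annotation(config.annotation_path)
            targets = dm.read_target_table(config.target_table_path)
            mirna_mask = dm.DetectionMask.all_true(mirna)
            gene_mask = dm.DetectionMask.all_true(genes)
        mirna_kept = presence_filter(mirna, mirna_mask, config.presence_fraction)
        gene_kept = presence_filter(genes, gene_mask, config.presence_fraction)
        mirna_screen = screen_features(mirna_kept, annotation, config.mirna_alpha)
        gene_screen = screen_features(gene_kept, annotation, config.gene_alpha)
        _write_screen(mirna_screen, outdir / "screen_mirna.tsv")
        _write_screen(gene_screen, outdir / "screen_gene.tsv")
        record_stage(
            "screen",
            [outdir / "screen_mirna.tsv", outdir / "screen_gene.tsv"],
            {
                "mirna_features_in": mirna.n_features,
                "mirna_present": mirna_kept.n_features,
                "mirna_de": len(mirna_screen),
                "gene_features_in": genes.n_features,
                "gene_present": gene_kept.n_features,
                "gene_de": len(gene_screen),
            },
        )
    except Exception as exc:
        raise PipelineError("screen", exc) from exc

    # ------------------------------------------------------------ integrate
    try:
        predicted = filter_predictions(targets, config.mirsvr_cutoff)
        candidates = candidate_pairs(predicted, mirna_screen, gene_screen)
        pairs = pair_anticorrelation(candidates, mirna_kept, gene_kept, config.pair_alpha)
        if not pairs:
            raise ValueError("no regulatory pairs retained; cannot derive signatures")
        mirna_sig, gene_sig = derive_signatures(pairs, mirna_screen, gene_screen)
        dm.write_pairs(pairs, outdir / "pairs.tsv")
        dm.write_signature(mirna_sig, outdir / "signature_mirna.tsv")
        dm.write_signature(gene_sig, outdir / "signature_gene.tsv")
        record_stage(
            "integrate",
            [outdir / "pairs.tsv", outdir / "signature_mirna.tsv", outdir / "signature_gene.tsv"],
            {
                "predictions_in": len(targets),
                "passing_mirsvr": len(predicted),
                "candidate_pairs": len(candidates),
                "retained_pairs": len(pairs),
                "signature_mirnas": len(mirna_sig),
                "signature_genes": len(gene_sig),
            },
        )
    except Exception as exc:
        raise PipelineError("integrate", exc) from exc

    # ---------------------------------------------------------------- score
    try:
        mirna_scores = score_cohort(mirna_kept, mirna_sig)
        gene_scores = score_cohort(gene_kept, gene_sig)
        for name, sv in (("scores_mirna.tsv", mirna_scores), ("scores_gene.tsv", gene_scores)):
            pd.DataFrame({"sample_id": sv.sample_ids, "score": sv.score}).to_csv(
                outdir / name, sep="\t", index=False, float_format="%.17g"
            )
        record_stage(
            "score",
            [outdir / "scores_mirna.tsv", outdir / "scores_gene.tsv"],
            {"mirna_coverage": mirna_scores.coverage, "gene_coverage": gene_scores.coverage},
        )
    except Exception as exc:
        raise PipelineError("score", exc) from exc

    # ------------------------------------------------------------- evaluate
    try:
        rows = []
        rho_m, p_m = severity_trend(mirna_scores, annotation)
        rho_g, p_g = severity_trend(gene_scores, annotation)
        rows.append(("discovery", "trend_mirna", rho_m, p_m))
        rows.append(("discovery", "trend_gene", rho_g, p_g))
        if config.synthetic_mode:
            noise = (config.synthetic or SyntheticSpec()).noise_sd
            cohorts = [
                generate_validation(
                    gene_sig, n_con, n_case, config.validation_shift, noise, config.seed + 101 + i
                )
                for i, (n_con, n_case) in enumerate(config.validation_cohort_sizes)
            ]
        else:
            cohorts = [
                (dm.read_expression_matrix(mp, "mRNA"), dm.read_annotation(ap))
                for mp, ap in config.validation_paths
            ]
        for i, (vmat, vann) in enumerate(cohorts):
            sv = score_cohort(vmat, gene_sig)
            auc = roc_auc(sv, vann).auc
            t, p = group_ttest(sv, vann)
            rows.append((f"validation_{i + 1}", "auc", auc, float("nan")))
            rows.append((f"validation_{i + 1}", "ttest", t, p))
        pd.DataFrame(rows, columns=["cohort", "metric", "value", "p"]).to_csv(
            outdir / "evaluation.tsv", sep="\t", index=False, float_format="%.17g"
        )
        record_stage(
            "evaluate",
            [outdir / "evaluation.tsv"],
            {"trend_rho_mirna": rho_m, "trend_rho_gene": rho_g, "n_validation_cohorts": len(cohorts)},
        )
    except Exception as exc:
        raise PipelineError("evaluate", exc) from exc

    # ------------------------------------------------------------- resample
    try:
        if cohorts:
            outcome = run_resampling_test(
                gene_sig,
                cohorts,
                pool_kind="genome",
                screen=gene_screen,
                n_resamples=config.n_resamples,
                seed=config.seed + 301,
            )
            pd.DataFrame({"auc_sum": outcome.null_draws}).to_csv(
                outdir / "resampling_null.tsv", sep="\t", index=False, float_format="%.17g"
            )
            summary = {"observed": outcome.observed, "p_right": outcome.p_right}
            record_stage("resample", [outdir / "resampling_null.tsv"], summary)
        else:
            record_stage("resample", [], {"skipped": "no validation cohorts"})
    except Exception as exc:
        raise PipelineError("resample", exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
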