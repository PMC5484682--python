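import numpy as np
import pytest

from mirsig import (
    Signature,
    SyntheticSpec,
    generate_discovery,
    generate_target_table,
    generate_validation,
    roc_auc,
    score_cohort,
    screen_features,
)
from mirsig.screen import spearman_matrix


class TestSpecValidation:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(noise_sd=0)
        with pytest.raises(ValueError):
            SyntheticSpec(n_signal_mirnas=0)
        with pytest.raises(ValueError):
            SyntheticSpec(n_mirna_features=4, n_signal_mirnas=8)
        with pytest.raises(ValueError):
            SyntheticSpec(n_decoy_predictions=-1)


class TestGenerateDiscovery:
    def test_deterministic_given_seed(self, small_spec):
        a = generate_discovery(small_spec)
        b = generate_discovery(small_spec)
        np.testing.assert_array_equal(a.mirna.values, b.mirna.values)
        np.testing.assert_array_equal(a.genes.values, b.genes.values)
        assert a.truth.planted_pairs == b.truth.planted_pairs
        assert a.annotation.group == b.annotation.group

    def test_platform_cohort_structure(self, small_discovery, small_spec):
        d = small_discovery
        assert d.mirna.n_samples == sum(small_spec.n_per_group_mirna)
        assert d.genes.n_samples == sum(small_spec.n_per_group_gene)
        shared = set(d.mirna.sample_ids) & set(d.genes.sample_ids)
        assert len(shared) == 65 or len(shared) == sum(
            min(a, b) for a, b in zip(small_spec.n_per_group_mirna, small_spec.n_per_group_gene)
        )

    def test_truth_consistency(self, small_discovery, small_spec):
        truth = small_discovery.truth
        assert len(truth.signal_mirnas) == small_spec.n_signal_mirnas
        assert len(truth.planted_pairs) == (
            small_spec.n_signal_mirnas * small_spec.targets_per_signal_mirna
        )
        for mirna, gene in truth.planted_pairs:
            assert mirna in truth.signal_mirnas
            assert gene in truth.signal_genes
            # target direction opposes its miRNA's severity direction
            assert truth.signal_genes[gene] == -truth.signal_mirnas[mirna]

    def test_extra_severity_genes_are_de_but_never_paired(self, small_discovery):
        """Severity-associated genes outside the miRNA-regulated set are
        picked up by the gene screen yet never appear among planted pairs."""
        d = small_discovery
        flagged = {
            r.feature_id for r in screen_features(d.genes, d.annotation, alpha=0.0005)
        }
        extra = set(d.truth.extra_severity_genes)
        assert len(flagged & extra) >= 0.9 * len(extra)
        assert not extra & {g for _, g in d.truth.planted_pairs}
        assert not extra & set(d.truth.signal_genes)

    def test_null_coupling_gives_zero_pair_correlation(self):
        """With coupling_strength=0 the planted pairs are independent, so the
        mean pair Spearman rho over replicate datasets is 0 within 3 SE."""
        rhos = []
        for seed in range(300):
            spec = SyntheticSpec(
                n_mirna_features=2,
                n_gene_features=4,
                n_signal_mirnas=2,
                targets_per_signal_mirna=1,
                coupling_strength=0.0,
                n_extra_severity_genes=0,
                n_decoy_predictions=0,
                seed=seed,
            )
            d = generate_discovery(spec)
            shared = [s for s in d.mirna.sample_ids if s in set(d.genes.sample_ids)]
            m = d.mirna.subset_samples(shared)
            g = d.genes.subset_samples(shared)
            for mirna, gene in d.truth.planted_pairs:
                rho, _ = spearman_matrix(
                    m.values[m.feature_index(mirna)][None, :],
                    g.values[g.feature_index(gene)],
                )
                rhos.append(rho[0])
        rhos = np.asarray(rhos)
        se = rhos.std(ddof=1) / np.sqrt(rhos.size)
        assert abs(rhos.mean()) <= 3 * se + 1e-3

    def test_strong_effect_gives_high_severity_correlation(self):
        """severity_effect=2, noise_sd=1: every planted miRNA's Spearman rho
        with severity exceeds 0.5 in >=95% of seeded replicates."""
        ok = 0
        n_rep = 200
        for seed in range(n_rep):
            spec = SyntheticSpec(
                n_mirna_features=8,
                n_gene_features=16,
                n_signal_mirnas=4,
                n_extra_severity_genes=0,
                severity_effect=2.0,
                noise_sd=1.0,
                seed=10_000 + seed,
            )
            d = generate_discovery(spec)
            y = d.annotation.codes_for(d.mirna.sample_ids)
            rho, _ = spearman_matrix(d.mirna.values[: spec.n_signal_mirnas], y)
            signs = np.array(
                [d.truth.signal_mirnas[m] for m in d.mirna.feature_ids[: spec.n_signal_mirnas]]
            )
            ok += bool(np.all(signs * rho > 0.5))
        assert ok / n_rep >= 0.95

    def test_planted_direction_recovery_sensitivity(self):
        """Screen sensitivity >= 90% with false-discovery proportion <= 10%
        at severity_effect = 1.5 x noise_sd and study-scale n, averaged over
        50 seeds; flagged directions match the planted signs >= 95%."""
        sens, fdp, sign_ok, flagged_total = [], [], 0, 0
        for seed in range(50):
            spec = SyntheticSpec(
                n_mirna_features=100,
                n_gene_features=8,
                n_signal_mirnas=8,
                targets_per_signal_mirna=1,
                n_extra_severity_genes=0,
                severity_effect=1.5,
                noise_sd=1.0,
                seed=seed,
            )
            d = generate_discovery(spec)
            records = screen_features(d.mirna, d.annotation, alpha=0.05)
            flagged = {r.feature_id for r in records}
            signals = set(d.truth.signal_mirnas)
            sens.append(len(flagged & signals) / len(signals))
            fdp.append(len(flagged - signals) / max(len(flagged), 1))
            for r in records:
                if r.feature_id in signals:
                    flagged_total += 1
                    sign_ok += int(np.sign(r.rho) == d.truth.signal_mirnas[r.feature_id])
        assert np.mean(sens) >= 0.9
        assert np.mean(fdp) <= 0.1
        assert sign_ok / flagged_total >= 0.95


class TestTargetTable:
    def test_no_decoys_table_is_planted_pairs(self, small_discovery, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, n_decoy_predictions=0)
        table = generate_target_table(small_discovery.truth, spec)
        assert {(p.mirna_id, p.gene_symbol) for p in table} == small_discovery.truth.planted_pairs

    def test_score_ranges_partition_at_cutoff(self, small_discovery, small_spec):
        table = generate_target_table(small_discovery.truth, small_spec)
        planted = small_discovery.truth.planted_pairs
        for p in table:
            if (p.mirna_id, p.gene_symbol) in planted:
                assert p.mirsvr_score <= -1.2
            else:
                assert p.mirsvr_score > -1.2

    def test_deterministic(self, small_discovery, small_spec):
        t1 = generate_target_table(small_discovery.truth, small_spec)
        t2 = generate_target_table(small_discovery.truth, small_spec)
        assert t1 == t2


@pytest.fixture(scope="module")
def signature():
    rng = np.random.default_rng(0)
    return Signature(
        "v", "mRNA", [(f"f{i}", float(rng.choice([-1, 1]) * 0.5)) for i in range(6)]
    )


class TestGenerateValidation:
    def test_deterministic(self, signature):
        a = generate_validation(signature, 5, 5, 1.0, 1.0, seed=3)
        b = generate_validation(signature, 5, 5, 1.0, 1.0, seed=3)
        np.testing.assert_array_equal(a[0].values, b[0].values)

    def test_null_shift_auc_centers_at_half(self, signature):
        from scipy import stats

        aucs = []
        for seed in range(800):
            matrix, ann = generate_validation(
                signature, 20, 20, shift=0.0, noise_sd=1.0, seed=seed, n_background=5
            )
            aucs.append(roc_auc(score_cohort(matrix, signature), ann).auc)
        # one-sample t-test against the theoretical null mean of 0.5
        assert stats.ttest_1samp(aucs, 0.5).pvalue > 1e-3

    def test_large_shift_saturates_auc(self, signature):
        perfect = 0
        for seed in range(200):
            matrix, ann = generate_validation(
                signature, 8, 8, shift=5.0, noise_sd=1.0, seed=seed, n_background=5
            )
            perfect += roc_auc(score_cohort(matrix, signature), ann).auc == 1.0
        assert perfect / 200 >= 0.99

    def test_cases_score_higher_with_positive_shift(self, signature):
        for seed in range(10):
            matrix, ann = generate_validation(signature, 15, 15, 1.0, 1.0, seed=seed)
            sv = score_cohort(matrix, signature)
            y = ann.codes_for(sv.sample_ids)
            assert sv.score[y == 1].mean() > sv.score[y == 0].mean()
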