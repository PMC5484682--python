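import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirsig import (
    CohortAnnotation,
    DegenerateInputError,
    DetectionMask,
    ExpressionMatrix,
    SeverityScreen,
    bh_adjust,
    presence_filter,
    screen_features,
    spearman_rho,
)


def _matrix(values, platform="mRNA"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"f{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        platform,
    )


class TestPresenceFilter:
    @pytest.mark.parametrize(
        "detected_count,kept",
        [(3, True), (2, True), (1, False)],  # 2-of-3 is the inclusive boundary
    )
    def test_two_thirds_boundary(self, detected_count, kept):
        m = _matrix(np.ones((1, 3)))
        det = np.zeros((1, 3), dtype=bool)
        det[0, :detected_count] = True
        out = presence_filter(m, DetectionMask(det, m.feature_ids, m.sample_ids))
        assert (m.feature_ids[0] in out.feature_ids) is kept
        assert out.sample_ids == m.sample_ids

    def test_misaligned_mask_rejected(self, tiny_matrix):
        mask = DetectionMask(np.ones((3, 5), dtype=bool), ["a", "b", "c"], tiny_matrix.sample_ids)
        with pytest.raises(ValueError, match="aligned"):
            presence_filter(tiny_matrix, mask)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_tie_free_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (-2,1,1,-1,1) gives 0.6
        rho, _ = spearman_rho([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
        assert rho == pytest.approx(0.6)

    def test_constant_vector_raises(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho([1, 2, 3, 4], [5, 5, 5, 5])

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            rho, p = spearman_rho(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho, p = spearman_rho(x, y)
        rho2, p2 = spearman_rho(np.exp(3 * x), y**3)  # strictly increasing maps
        assert rho2 == pytest.approx(rho, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-12)


def _bh_bruteforce(p):
    """Literal step-up definition: adj_(i) = min_{j>=i} min(1, p_(j)*m/j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(min(1.0, p[order[j]] * m / (j + 1)) for j in range(i, m))
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


class TestBHAdjust:
    def test_singleton_identity(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_hand_stepup_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_bounds_and_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, size=30)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1)

    def test_matches_bruteforce_stepup(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            p = rng.uniform(1e-8, 1, size=int(rng.integers(1, 50)))
            np.testing.assert_allclose(bh_adjust(p), _bh_bruteforce(p), atol=1e-13)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestScreenFeatures:
    def _annotation(self, codes):
        groups = [["HC", "US", "CS"][c] for c in codes]
        return CohortAnnotation([f"s{j}" for j in range(len(codes))], groups)

    def test_perfect_feature_recovered_among_noise(self):
        rng = np.random.default_rng(0)
        codes = [0] * 10 + [1] * 10 + [2] * 10
        values = rng.normal(size=(999, 30))
        values = np.vstack([np.array(codes, dtype=float), values])
        ann = self._annotation(codes)
        records = screen_features(_matrix(values), ann, alpha=0.05)
        by_id = {r.feature_id: r for r in records}
        assert "f0" in by_id
        assert by_id["f0"].rho == pytest.approx(1.0)
        assert by_id["f0"].direction == "up"

    def test_alpha_one_returns_all_nonconstant(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(20, 12))
        values[5] = 2.5  # constant feature is excluded, not fatal
        codes = [0] * 4 + [1] * 4 + [2] * 4
        records = screen_features(_matrix(values), self._annotation(codes), alpha=1.0)
        assert len(records) == 19
        assert "f5" not in {r.feature_id for r in records}

    def test_antisymmetry_under_severity_negation(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(15, 18))
        codes = np.array([0] * 6 + [1] * 6 + [2] * 6)
        fwd = screen_features(_matrix(values), self._annotation(codes), alpha=1.0)
        rev = screen_features(_matrix(values), self._annotation(2 - codes), alpha=1.0)
        for a, b in zip(fwd, rev):
            assert a.feature_id == b.feature_id
            assert a.rho == pytest.approx(-b.rho, abs=1e-12)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_invariant_to_sample_and_feature_order(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(12, 15))
        values[0] += np.repeat([0.0, 1.5, 3.0], 5)
        codes = [0] * 5 + [1] * 5 + [2] * 5
        m = _matrix(values)
        ann = self._annotation(codes)
        base = {r.feature_id: (r.rho, r.adj_p) for r in screen_features(m, ann, 0.05)}

        perm_s = rng.permutation(m.n_samples)
        perm_f = rng.permutation(m.n_features)
        shuffled = ExpressionMatrix(
            values[np.ix_(perm_f, perm_s)],
            [m.feature_ids[i] for i in perm_f],
            [m.sample_ids[j] for j in perm_s],
            "mRNA",
        )
        other = {r.feature_id: (r.rho, r.adj_p) for r in screen_features(shuffled, ann, 0.05)}
        assert set(base) == set(other)
        for f in base:
            assert base[f][0] == pytest.approx(other[f][0], abs=1e-12)
            assert base[f][1] == pytest.approx(other[f][1], abs=1e-12)

    def test_disjoint_samples_rejected(self, tiny_matrix):
        ann = CohortAnnotation(["x1", "x2"], ["HC", "CS"])
        with pytest.raises(ValueError, match="absent"):
            screen_features(tiny_matrix, ann, 0.05)


class TestSeverityScreenEstimator:
    def test_matches_functional_screen(self):
        import pandas as pd

        rng = np.random.default_rng(2)
        codes = np.array([0] * 8 + [1] * 8 + [2] * 8)
        values = rng.normal(size=(50, 24))
        values[0] += 1.2 * codes
        m = _matrix(values)
        ann = CohortAnnotation(m.sample_ids, [["HC", "US", "CS"][c] for c in codes])
        records = screen_features(m, ann, 0.05)

        X = pd.DataFrame(values.T, columns=m.feature_ids)
        est = SeverityScreen(alpha=0.05).fit(X, codes)
        assert {r.feature_id for r in est.records()} == {r.feature_id for r in records}
        for r in est.records():
            ref = next(x for x in records if x.feature_id == r.feature_id)
            assert r.rho == pytest.approx(ref.rho, abs=1e-12)
            assert r.adj_p == pytest.approx(ref.adj_p, abs=1e-12)
        assert est.transform(X).shape == (24, int(est.support_.sum()))

    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = SeverityScreen(alpha=0.01)
        assert clone(est).get_params()["alpha"] == 0.01
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 5))
        y = np.repeat([0, 1, 2], 4)
        est.fit(X, y)
        assert est.support_.shape == (5,)
        assert est.get_support().dtype == bool
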