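"""Grid enumeration, execution, internal validation metrics and sanity check.

Quality-metric implementations are checked against independent
from-the-formula oracles written here.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amlmeta.grid import (
    DegenerateClusteringError,
    GridRunResult,
    collect_passing,
    compute_quality_metrics,
    default_registry,
    enumerate_grid,
    metric_ranges,
    reduced_registry,
    run_combination,
    sanity_check,
    summarize_results,
    AlgorithmRegistry,
)


# ---------------------------------------------------------------------------
# independent from-the-formula oracles


def silhouette_oracle(X, labels):
    X, labels = np.asarray(X, float), np.asarray(labels)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    s = np.zeros(len(X))
    for i in range(len(X)):
        own = (labels == labels[i]) & (np.arange(len(X)) != i)
        if not own.any():
            s[i] = 0.0
            continue
        a = d[i, own].mean()
        b = min(d[i, labels == k].mean() for k in np.unique(labels) if k != labels[i])
        s[i] = (b - a) / max(a, b)
    return s.mean()


def calinski_harabasz_oracle(X, labels):
    X, labels = np.asarray(X, float), np.asarray(labels)
    n, ks = len(X), np.unique(labels)
    c = X.mean(0)
    bet = sum((labels == k).sum() * ((X[labels == k].mean(0) - c) ** 2).sum() for k in ks)
    wit = sum(((X[labels == k] - X[labels == k].mean(0)) ** 2).sum() for k in ks)
    return (bet / (len(ks) - 1)) / (wit / (n - len(ks)))


def davies_bouldin_oracle(X, labels):
    X, labels = np.asarray(X, float), np.asarray(labels)
    ks = np.unique(labels)
    cents = np.array([X[labels == k].mean(0) for k in ks])
    scat = np.array(
        [np.sqrt(((X[labels == k] - cents[i]) ** 2).sum(1)).mean() for i, k in enumerate(ks)]
    )
    db = 0.0
    for i in range(len(ks)):
        r = max(
            (scat[i] + scat[j]) / np.sqrt(((cents[i] - cents[j]) ** 2).sum())
            for j in range(len(ks))
            if j != i
        )
        db += r
    return db / len(ks)


# ---------------------------------------------------------------------------


class TestEnumerate:
    def test_default_registry_605(self):
        reg = default_registry()
        assert len(reg.transforms) == 11 and len(reg.clusterers) == 11 and len(reg.dims) == 5
        assert len(enumerate_grid(reg)) == 605

    def test_small_registry_product(self):
        reg = default_registry()
        small = AlgorithmRegistry(reg.transforms[:2], (2, 3), reg.clusterers[:3])
        specs = enumerate_grid(small)
        assert len(specs) == 12
        assert len({s.combo_id for s in specs}) == 12

    def test_empty_component_rejected(self):
        reg = default_registry()
        with pytest.raises(ValueError):
            AlgorithmRegistry(reg.transforms, reg.dims, ())

    def test_per_combination_seeds_distinct_and_bounded(self):
        specs = enumerate_grid(reduced_registry(), master_seed=5)
        seeds = [s.seed_for(i) for s in specs for i in range(3)]
        assert len(set(seeds)) == len(seeds)
        assert all(0 <= s < 2**31 for s in seeds)


class TestQualityMetrics:
    def test_duplicated_points_perfect_separation(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0], [9.0, 9.0]])
        labels = np.array([0, 0, 1, 1])
        sil, ch, db = compute_quality_metrics(X, labels)
        assert sil == pytest.approx(1.0)
        assert db == pytest.approx(0.0)

    def test_four_point_worked_silhouette(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels = np.array([0, 0, 1, 1])
        sil, _, _ = compute_quality_metrics(X, labels)
        # by hand: a=1, b=(10+sqrt(101))/2 for every point
        b = (10.0 + np.sqrt(101.0)) / 2.0
        assert sil == pytest.approx((b - 1) / b, abs=1e-12)
        assert sil == pytest.approx(0.900, abs=1e-3)

    def test_matches_oracles_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(6, 21)
            k = rng.integers(2, min(4, n - 1) + 1)
            X = rng.normal(size=(n, rng.integers(2, 5)))
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                labels[0] = (labels[0] + 1) % k
            sil, ch, db = compute_quality_metrics(X, labels)
            assert sil == pytest.approx(silhouette_oracle(X, labels), abs=1e-9)
            assert ch == pytest.approx(calinski_harabasz_oracle(X, labels), abs=1e-9 * max(1, ch))
            assert db == pytest.approx(davies_bouldin_oracle(X, labels), abs=1e-9 * max(1, db))

    def test_degenerate_clusterings_signalled(self):
        X = np.random.default_rng(0).normal(size=(8, 2))
        with pytest.raises(DegenerateClusteringError):
            compute_quality_metrics(X, np.zeros(8))
        with pytest.raises(DegenerateClusteringError):
            compute_quality_metrics(X, np.arange(8))


class TestSanityCheck:
    @pytest.mark.parametrize(
        "sizes, expected",
        [
            ([50, 45, 5], False),  # smallest cluster below 10% of n=100
            ([60, 40], True),
            ([10] * 10, True),  # both boundaries inclusive
            ([100], False),  # single all-patient cluster
            ([9] * 4 + [8] * 8, False),  # 12 clusters exceeds the cap of 10
        ],
    )
    def test_rules(self, sizes, expected):
        labels = np.repeat(np.arange(len(sizes)), sizes)
        ok, reason = sanity_check(labels, n_patients=sum(sizes))
        assert ok is expected
        assert (reason is None) is expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sanity_check(np.zeros(5), n_patients=6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 6), min_size=20, max_size=80))
    def test_pass_implies_rules(self, labels):
        labels = np.asarray(labels)
        ok, _ = sanity_check(labels, len(labels))
        _, counts = np.unique(labels, return_counts=True)
        if ok:
            assert 2 <= len(counts) <= 10
            assert counts.min() >= int(np.ceil(0.10 * len(labels)))


@pytest.fixture(scope="module")
def small_matrix():
    rng = np.random.default_rng(2)
    centers = np.array([[0, 0, 0, 0], [6, 6, 0, 0], [0, 6, 6, 6]])
    return centers[rng.integers(0, 3, 90)] + rng.normal(scale=0.7, size=(90, 4))


class TestRunCombination:
    def test_seeded_determinism(self, small_matrix):
        spec = enumerate_grid(reduced_registry(), master_seed=9)[0]
        r1 = run_combination(spec, small_matrix, n_iterations=2)
        r2 = run_combination(spec, small_matrix, n_iterations=2)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.labels, b.labels)
            assert a.seed == b.seed and a.silhouette == b.silhouette

    def test_iteration_count(self, small_matrix):
        spec = enumerate_grid(reduced_registry(), master_seed=0)[0]
        results = run_combination(spec, small_matrix, n_iterations=10)
        assert len(results) == 10
        assert [r.iteration for r in results] == list(range(10))

    def test_impossible_embedding_captured_not_raised(self, small_matrix):
        reg = reduced_registry(transform_names=("pca",), dims=(40,), clusterer_names=("kmeans",))
        spec = enumerate_grid(reg)[0]  # 40 target dims > 4 input columns
        results = run_combination(spec, small_matrix, n_iterations=2)
        assert all(not r.sanity_pass for r in results)
        assert all(r.failure_reason for r in results)
        assert all(r.labels is None for r in results)

    def test_metrics_in_valid_ranges(self, recovery):
        for r in recovery.passing:
            assert -1.0 <= r.silhouette <= 1.0
            assert r.calinski_harabasz >= 0.0
            assert r.davies_bouldin >= 0.0


class TestCollectPassing:
    def _result(self, ok, sil=0.5):
        return GridRunResult(("t", 2, "c"), 0, 0, np.zeros(4), 2, sil, 1.0, 0.5, ok)

    def test_mixed(self):
        results = [self._result(True), self._result(False), self._result(True)]
        assert len(collect_passing(results)) == 2

    def test_all_failing_empty_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="amlmeta.grid"):
            out = collect_passing([self._result(False)])
        assert out == [] and "sanity" in caplog.text

    def test_metric_ranges_and_summary(self, recovery):
        ranges = metric_ranges(recovery.results)
        assert set(ranges) == {"silhouette", "calinski_harabasz", "davies_bouldin"}
        for lo, hi in ranges.values():
            assert lo <= hi
        df = summarize_results(recovery.results)
        assert len(df) == len(recovery.results)
        assert df["sanity_pass"].sum() == len(recovery.passing)
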