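import numpy as np
import pytest

from riskeq import (
    ValidationError,
    assign_multi,
    assign_traditional,
    build_multi_scheme,
    build_traditional_scheme,
    dxgroup_stats,
    interval_cluster,
    screen_dxgroups,
    ward_cluster_1d,
)
from riskeq.calibration import CalibratedModel
from riskeq.dcg import DxgroupStats, multi_columns, traditional_columns
from riskeq.synthetic import ClaimsHistory, DiagnosisClaims


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def greedy_ward_oracle(values, weights, k, ids):
    """Naive re-implementation: recompute all pair costs at every step."""
    clusters = [([ids[i]], float(weights[i]), float(values[i]))
                for i in range(len(values))]
    trace = []
    while len(clusters) > k:
        options = []
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ia, wa, ma = clusters[a]
                ib, wb, mb = clusters[b]
                delta = wa * wb / (wa + wb) * (ma - mb) ** 2
                mean = (wa * ma + wb * mb) / (wa + wb)
                options.append(((delta, mean, tuple(sorted(ia + ib))), a, b))
        (delta, _, _), a, b = min(options)
        ia, wa, ma = clusters[a]
        ib, wb, mb = clusters[b]
        trace.append((tuple(ia), tuple(ib), delta))
        merged = (ia + ib, wa + wb, (wa * ma + wb * mb) / (wa + wb))
        clusters = [c for j, c in enumerate(clusters) if j not in (a, b)]
        clusters.append(merged)
    return sorted(tuple(sorted(c[0])) for c in clusters), trace


def dp_min_clusters(sorted_values, max_range):
    """Minimum number of clusters over all contiguous partitions."""
    n = len(sorted_values)
    best = [0] + [n + 1] * n
    for i in range(1, n + 1):
        for j in range(i):
            if sorted_values[i - 1] - sorted_values[j] <= max_range:
                best[i] = min(best[i], best[j] + 1)
    return best[n]


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def history(entries):
    diagnoses = tuple(
        DiagnosisClaims(
            diagnosis_id=name,
            year1=frozenset(y1),
            year2=frozenset(y2),
            spending={i: s for i, s in zip(sorted(y1), spend)},
        )
        for name, y1, y2, spend in entries
    )
    return ClaimsHistory(n_persons=100, diagnoses=diagnoses)


class TestScreening:
    def test_low_persistence_excluded(self):
        # 3 of 10 year-1 patients return: below the one-third threshold
        h = history([("d", range(10), range(3), [1000.0] * 10)])
        report = screen_dxgroups(h, min_prevalence=0.01,
                                 min_mean_spending=100.0)
        assert report.excluded["d"] == ("persistence",)

    def test_thresholds_are_inclusive(self):
        h = history([("d", range(9), range(3), [500.0] * 9)])
        report = screen_dxgroups(h, persistence_threshold=1 / 3,
                                 min_prevalence=0.09,
                                 min_mean_spending=500.0)
        assert report.retained == ("d",)

    def test_single_failed_criterion_reported(self):
        h = history([("d", range(2), range(2), [9000.0, 9000.0])])
        report = screen_dxgroups(h, min_prevalence=0.5,
                                 min_mean_spending=100.0)
        assert report.excluded["d"] == ("prevalence",)

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValidationError):
            screen_dxgroups(ClaimsHistory(10, ()))


# ---------------------------------------------------------------------------
# per-dxgroup statistics
# ---------------------------------------------------------------------------


class TestDxgroupStats:
    def test_three_person_weighted_means(self, three_records):
        residuals = np.array([10.0, -20.0, 40.0])
        stats = dxgroup_stats(three_records, ("dx1", "dx3"),
                              residuals=residuals)
        by_id = {s.dxgroup_id: s for s in stats}
        # dx3 is carried by persons b (w=.5, r=-20) and c (w=.25, r=40)
        assert by_id["dx3"].mean_residual == pytest.approx(
            (0.5 * -20 + 0.25 * 40) / 0.75
        )
        assert by_id["dx3"].prevalence == pytest.approx(0.75 / 1.75)
        assert by_id["dx1"].mean_residual == pytest.approx(-20.0)

    def test_empty_dxgroup_flagged_undefined(self, three_records):
        with pytest.warns(UserWarning, match="dx5"):
            stats = dxgroup_stats(three_records, ("dx5",),
                                  residuals=np.zeros(3))
        assert not stats[0].defined


# ---------------------------------------------------------------------------
# ward clustering
# ---------------------------------------------------------------------------


class TestWard:
    def test_k_equals_n_is_identity(self):
        result = ward_cluster_1d([1.0, 5.0, 9.0], [1.0, 1.0, 1.0], 3)
        assert result.clusters == (("0",), ("1",), ("2",))
        assert result.merge_trace == ()

    def test_equal_means_merge_first_at_zero_cost(self):
        result = ward_cluster_1d([5.0, 1.0, 5.0], [1.0, 2.0, 3.0], 2)
        first = result.merge_trace[0]
        assert first[2] == 0.0
        assert set(first[0] + first[1]) == {"0", "2"}

    def test_two_plus_two_split(self):
        result = ward_cluster_1d([0.0, 10.0, 200.0, 210.0], [1.0] * 4, 2,
                                 ids=list("abcd"))
        assert result.clusters == (("a", "b"), ("c", "d"))

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        values = np.round(rng.uniform(0, 100, n), 1)
        weights = np.round(rng.uniform(0.5, 5, n), 2)
        k = int(rng.integers(1, n + 1))
        ids = [f"g{i}" for i in range(n)]
        result = ward_cluster_1d(values, weights, k, ids)
        oracle_clusters, oracle_trace = greedy_ward_oracle(
            values, weights, k, ids
        )
        assert sorted(result.clusters) == oracle_clusters
        got = [(a, b, pytest.approx(d)) for a, b, d in oracle_trace]
        assert list(result.merge_trace) == got

    def test_bad_k_rejected(self):
        with pytest.raises(ValidationError):
            ward_cluster_1d([1.0, 2.0], [1.0, 1.0], 0)
        with pytest.raises(ValidationError):
            ward_cluster_1d([1.0, 2.0], [1.0, 1.0], 3)


# ---------------------------------------------------------------------------
# interval clustering
# ---------------------------------------------------------------------------


class TestInterval:
    def test_worked_example(self):
        result = interval_cluster({"a": 0.0, "b": 400.0, "c": 600.0,
                                   "d": 1200.0}, max_range=500.0)
        assert result.clusters == (("a", "b"), ("c",), ("d",))

    def test_single_cluster_when_all_close(self):
        result = interval_cluster([100.0, 300.0, 550.0], max_range=500.0)
        assert len(result.clusters) == 1

    def test_all_singletons_when_far_apart(self):
        result = interval_cluster([0.0, 600.0, 1300.0], max_range=500.0)
        assert len(result.clusters) == 3

    @pytest.mark.parametrize("seed", range(50))
    def test_cluster_count_is_minimal(self, seed):
        rng = np.random.default_rng(1000 + seed)
        values = rng.uniform(0, 5000, int(rng.integers(1, 13)))
        max_range = float(rng.uniform(10, 2000))
        result = interval_cluster(values, max_range=max_range)
        assert len(result.clusters) == dp_min_clusters(
            np.sort(values), max_range
        )
        for cluster in result.clusters:
            vals = [values[int(i)] for i in cluster]
            assert max(vals) - min(vals) <= max_range

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            interval_cluster([1.0, np.nan])


# ---------------------------------------------------------------------------
# schemes
# ---------------------------------------------------------------------------


def stats_from(means, weights=None):
    weights = weights or [100.0] * len(means)
    return [
        DxgroupStats(f"g{i:02d}", 0.01, w, mean_residual=m)
        for i, (m, w) in enumerate(zip(means, weights))
    ]


class TestTraditionalScheme:
    def test_default_layer_sizes(self):
        means = list(np.linspace(0, 10_000, 22))
        scheme = build_traditional_scheme(stats_from(means))
        assert sum(1 for l in scheme.labels if l.startswith("pDCG")) == 15
        assert sum(1 for l in scheme.labels if l.startswith("sDCG")) == 7

    def test_singleton_primary_layer(self):
        means = [0.0, 100.0, 5000.0]
        scheme = build_traditional_scheme(stats_from(means), n_primary=3,
                                          n_secondary=1)
        primary = {v for k, v in scheme.mapping.items()}
        assert len(primary) == 3

    def test_layers_reproduce_direct_ward_calls(self):
        rng = np.random.default_rng(3)
        means = list(rng.uniform(0, 8000, 20))
        weights = list(rng.uniform(10, 500, 20))
        stats = stats_from(means, weights)
        scheme = build_traditional_scheme(stats, n_primary=6, n_secondary=3)
        ids = [s.dxgroup_id for s in stats]
        direct = ward_cluster_1d(means, weights, 6, ids)
        got = {}
        for g, label in scheme.mapping.items():
            got.setdefault(label, []).append(g)
        assert sorted(tuple(sorted(v)) for v in got.values()) == sorted(
            direct.clusters
        )

    def test_ranking_is_by_descending_mean_residual(self):
        means = [50.0, 900.0, 300.0]
        scheme = build_traditional_scheme(stats_from(means), n_primary=2,
                                          n_secondary=1)
        assert scheme.ranking == ("g01", "g02", "g00")

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValidationError):
            build_traditional_scheme(stats_from([1.0, 2.0]), n_primary=5,
                                     n_secondary=2)


class TestAssignTraditional:
    @pytest.fixture
    def scheme(self):
        return build_traditional_scheme(
            stats_from([100.0, 2000.0, 800.0, 5000.0]),
            n_primary=2, n_secondary=2,
        )

    def test_no_dxgroups(self, scheme):
        assert assign_traditional((), scheme) == (None, None)

    def test_one_dxgroup_only_primary(self, scheme):
        p, s = assign_traditional({"g00"}, scheme)
        assert p == scheme.mapping["g00"]
        assert s is None

    def test_three_dxgroups_third_ignored(self, scheme):
        # severity order: g03 (5000) > g01 (2000) > g02 (800) > g00 (100)
        p, s = assign_traditional({"g00", "g01", "g03"}, scheme)
        assert p == scheme.mapping["g03"]
        assert s == scheme.secondary_mapping["g01"]

    def test_unknown_dxgroup_rejected(self, scheme):
        with pytest.raises(ValidationError):
            assign_traditional({"zz"}, scheme)


def model_with_dx_coefs(coefs):
    columns = tuple(f"dx:{g}" for g in coefs)
    values = np.array(list(coefs.values()), dtype=float)
    return CalibratedModel(columns=columns, coefficients=values,
                           fitted=np.zeros(1), residuals=np.zeros(1),
                           weights=np.ones(1), diagnostics={})


class TestMultiScheme:
    def test_equal_coefficients_one_cluster(self):
        scheme = build_multi_scheme(model_with_dx_coefs(
            {"a": 700.0, "b": 700.0, "c": 700.0}
        ))
        assert len(scheme.labels) == 1

    def test_range_invariant_and_minimality(self):
        rng = np.random.default_rng(4)
        coefs = {f"g{i}": float(v)
                 for i, v in enumerate(rng.uniform(0, 13_000, 60))}
        scheme = build_multi_scheme(model_with_dx_coefs(coefs), max_range=500)
        for stats in scheme.cluster_stats.values():
            assert stats["max"] - stats["min"] <= 500.0
        assert len(scheme.labels) == dp_min_clusters(
            np.sort(list(coefs.values())), 500.0
        )

    def test_model_without_dx_columns_rejected(self):
        model = CalibratedModel(columns=("age_gender:M|18+",),
                                coefficients=np.zeros(1), fitted=np.zeros(1),
                                residuals=np.zeros(1), weights=np.ones(1),
                                diagnostics={})
        with pytest.raises(ValidationError):
            build_multi_scheme(model)


class TestAssignMulti:
    @pytest.fixture
    def scheme(self):
        return build_multi_scheme(model_with_dx_coefs(
            {"a": 100.0, "b": 200.0, "c": 5000.0}
        ))

    def test_counts_per_cluster(self, scheme):
        counts = assign_multi({"a", "b", "c"}, scheme)
        low = scheme.labels.index(scheme.mapping["a"])
        high = scheme.labels.index(scheme.mapping["c"])
        assert counts[low] == 2.0 and counts[high] == 1.0
        assert counts.sum() == 3.0

    def test_no_dxgroups_all_zero(self, scheme):
        assert assign_multi((), scheme).sum() == 0.0

    def test_repeat_concentration(self, scheme):
        counts = assign_multi(["a", "b"], scheme)
        assert counts.max() == 2.0

    def test_unknown_dxgroup_rejected(self, scheme):
        with pytest.raises(ValidationError):
            assign_multi({"zz"}, scheme)


def test_column_builders(three_records):
    trad = build_traditional_scheme(
        stats_from([100.0, 400.0, 900.0]), n_primary=2, n_secondary=2
    )
    # rename catalogue ids to match the fixture's dxgroups
    trad.mapping["dx1"] = trad.mapping.pop("g00")
    trad.mapping["dx2"] = trad.mapping.pop("g01")
    trad.mapping["dx3"] = trad.mapping.pop("g02")
    trad.secondary_mapping["dx1"] = trad.secondary_mapping.pop("g00")
    trad.secondary_mapping["dx2"] = trad.secondary_mapping.pop("g01")
    trad.secondary_mapping["dx3"] = trad.secondary_mapping.pop("g02")
    object.__setattr__(trad, "ranking", ("dx3", "dx2", "dx1"))
    labels, mat = traditional_columns(three_records, trad)
    dense = mat.toarray()
    assert dense[0].sum() == 0  # person a carries no dxgroups
    assert dense[1].sum() == 2  # person b: one pDCG and one sDCG flag
    assert dense[2].sum() == 1  # person c: single dxgroup, primary only

    multi = build_multi_scheme(model_with_dx_coefs(
        {"dx1": 100.0, "dx2": 150.0, "dx3": 9000.0}
    ))
    labels_m, mat_m = multi_columns(three_records, multi)
    assert mat_m.toarray().sum(axis=1).tolist() == [0.0, 2.0, 1.0]
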