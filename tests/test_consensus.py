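"""Consensus analysis: overlap tables, relation categories, threads,
agreement grouping, combination counts."""

import numpy as np
import pytest

from testaclust import consensus as cs
from testaclust.clustering import ClusteringRun
from testaclust.errors import InvalidInputError


def make_run(code, labels, k=None, ids=None):
    labels = np.asarray(labels)
    k = k or int(labels.max()) + 1
    ids = tuple(ids) if ids else tuple(f"i{j}" for j in range(len(labels)))
    return ClusteringRun(code=code, method="kmeans", representation="grayscale",
                         k=k, labels=labels, seed=0, image_ids=ids)


def random_partition(rng, n, k):
    labels = rng.integers(0, k, size=n)
    labels[:k] = np.arange(k)  # guarantee all clusters non-empty
    return rng.permutation(labels)


LOW = cs.OverlapConfig(tau_identical=0.9, tau_related=0.5, report_floor=0)


class TestContingency:
    def test_hand_example(self):
        A = make_run("A", [0, 0, 1, 1])
        B = make_run("B", [0, 1, 1, 1])
        assert np.array_equal(cs.contingency_table(A, B), [[1, 1], [0, 2]])

    def test_identical_partition_is_diagonal(self):
        A = make_run("A", [0, 1, 2, 0, 1, 2])
        table = cs.contingency_table(A, make_run("B", [0, 1, 2, 0, 1, 2]))
        assert np.array_equal(table, np.diag([2, 2, 2]))

    def test_marginals_on_random_partitions(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 30))
            la = random_partition(rng, n, int(rng.integers(2, 5)))
            lb = random_partition(rng, n, int(rng.integers(2, 5)))
            table = cs.contingency_table(make_run("A", la), make_run("B", lb))
            assert table.sum() == n
            assert np.array_equal(table.sum(axis=1), np.bincount(la))
            assert np.array_equal(table.sum(axis=0), np.bincount(lb))

    def test_mismatched_image_sets_rejected(self):
        A = make_run("A", [0, 1], ids=["a", "b"])
        B = make_run("B", [0, 1], ids=["a", "c"])
        with pytest.raises(InvalidInputError):
            cs.contingency_table(A, B)

    def test_alignment_by_image_id(self):
        A = make_run("A", [0, 0, 1, 1], ids=["a", "b", "c", "d"])
        B = make_run("B", [1, 1, 0, 0], ids=["c", "d", "a", "b"])
        # same partition, different image order -> diagonal up to permutation
        table = cs.contingency_table(A, B)
        assert sorted(table.ravel()) == [0, 0, 2, 2]


class TestClassifyRelations:
    @pytest.mark.parametrize("overlap,expected_jaccard,expected_category", [
        (95, 95 / 105, "identical"),
        (80, 80 / 120, "related"),
        (60, 60 / 140, "none"),
    ])
    def test_jaccard_categories_on_equal_sized_clusters(self, overlap,
                                                        expected_jaccard,
                                                        expected_category):
        table = np.array([[overlap, 100 - overlap],
                          [100 - overlap, overlap]])
        relations = cs.classify_relations(table, LOW)
        rel = next(r for r in relations if r.a == ("A", 0) and r.b == ("B", 0))
        assert rel.jaccard == pytest.approx(expected_jaccard)
        assert rel.category == expected_category

    def test_full_overlap_is_identical(self):
        relations = cs.classify_relations(np.diag([10, 20]), LOW)
        assert all(r.category == "identical" and r.jaccard == 1.0
                   for r in relations)

    def test_separation_index_ranks_by_descending_count(self):
        table = np.array([[50, 30, 0]])
        relations = cs.classify_relations(table, LOW)
        by_partner = {r.b[1]: r.separation_index for r in relations}
        assert by_partner == {0: 1, 1: 2}

    def test_separation_ties_break_by_partner_index(self):
        table = np.array([[25, 25]])
        relations = cs.classify_relations(table, LOW)
        assert {r.b[1]: r.separation_index for r in relations} == {0: 1, 1: 2}

    def test_report_floor_suppresses_small_overlaps(self):
        table = np.array([[600, 30], [10, 700]])
        relations = cs.classify_relations(table, cs.OverlapConfig())
        assert {(r.a[1], r.b[1]) for r in relations} == {(0, 0), (1, 1)}

    def test_symmetry_of_jaccard_and_category(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 40))
            A = make_run("A", random_partition(rng, n, 3))
            B = make_run("B", random_partition(rng, n, 4))
            fwd = {(r.a[1], r.b[1]): r for r in cs.relate_runs(A, B, LOW)}
            rev = {(r.b[1], r.a[1]): r for r in cs.relate_runs(B, A, LOW)}
            assert fwd.keys() == rev.keys()
            for key, r in fwd.items():
                assert r.jaccard == pytest.approx(rev[key].jaccard)
                assert r.category == rev[key].category
                assert r.overlap == rev[key].overlap

    def test_threshold_monotonicity(self, rng):
        """Raising tau_identical never promotes; lowering the floor never
        removes a relation."""
        for _ in range(50):
            n = int(rng.integers(10, 40))
            table = cs.contingency_table(
                make_run("A", random_partition(rng, n, 3)),
                make_run("B", random_partition(rng, n, 3)))
            base = cs.classify_relations(table, cs.OverlapConfig(
                tau_identical=0.8, tau_related=0.4, report_floor=2))
            stricter = cs.classify_relations(table, cs.OverlapConfig(
                tau_identical=0.95, tau_related=0.4, report_floor=2))
            floored = cs.classify_relations(table, cs.OverlapConfig(
                tau_identical=0.8, tau_related=0.4, report_floor=0))
            strict_by_key = {(r.a, r.b): r for r in stricter}
            for r in base:
                s = strict_by_key[(r.a, r.b)]
                if r.category == "none":
                    assert s.category in ("none",)
                if s.category == "identical":
                    assert r.category == "identical"
            assert {(r.a, r.b) for r in floored} >= {(r.a, r.b) for r in base}

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.OverlapConfig(tau_identical=0.4, tau_related=0.5)


class TestThreads:
    def _rel(self, a, b, jac=0.95):
        return cs.OverlapRelation(a=a, b=b, overlap=10, size_a=10, size_b=11,
                                  jaccard=jac, separation_index=1,
                                  category="identical" if jac >= 0.9 else "related")

    def test_chain_across_three_runs(self):
        relations = [self._rel(("EG", 0), ("EC", 0)),
                     self._rel(("EC", 0), ("SC", 0))]
        threads = cs.find_threads(relations)
        assert len(threads) == 1
        assert threads[0].runs_spanned == 3
        assert len(threads[0].nodes) == 3

    def test_no_relations_no_threads(self):
        assert cs.find_threads([]) == []

    def test_two_run_links_are_not_threads(self):
        relations = [self._rel(("EG", 0), ("EC", 0)),
                     self._rel(("EG", 1), ("EC", 1))]
        assert cs.find_threads(relations) == []

    def test_none_category_edges_excluded(self):
        relations = [self._rel(("EG", 0), ("EC", 0)),
                     cs.OverlapRelation(a=("EC", 0), b=("SC", 0), overlap=3,
                                        size_a=10, size_b=10, jaccard=3 / 17,
                                        separation_index=1, category="none")]
        assert cs.find_threads(relations) == []

    def test_each_thread_reported_once_with_distinct_runs(self, rng):
        for _ in range(30):
            codes = ["EG", "SG", "ET", "ST"]
            relations = []
            for i in range(len(codes)):
                for j in range(i + 1, len(codes)):
                    if rng.uniform() < 0.5:
                        relations.append(self._rel((codes[i], 0), (codes[j], 0)))
            threads = cs.find_threads(relations)
            seen = set()
            for t in threads:
                assert t.runs_spanned >= 3
                codes_in_path = [c for c, _ in t.nodes]
                assert len(codes_in_path) == len(set(codes_in_path))
                key = frozenset(t.nodes)
                canonical = min(t.nodes, t.nodes[::-1])
                assert canonical not in seen
                seen.add(canonical)


class TestAgreementGrouping:
    def test_six_identical_runs_all_si(self):
        labels = [0, 0, 1, 1, 2, 2]
        runs = [make_run(code, labels) for code in
                ("EG", "SG", "ET", "ST", "EC", "SC")]
        part = cs.agreement_grouping(runs)
        assert part.counts["SI"] == 6
        assert sum(part.counts.values()) == 6

    def test_five_agree_one_singleton_run_gives_ss(self):
        labels = [0, 0, 1, 1]
        runs = [make_run(code, labels) for code in ("EG", "SG", "ET", "ST", "EC")]
        runs.append(make_run("SC", [0, 1, 2, 3]))  # all singletons
        part = cs.agreement_grouping(runs)
        assert part.counts["SS"] == 4 and part.counts["SI"] == 0

    def test_wrong_run_count_rejected(self):
        runs = [make_run("EG", [0, 1])] * 5
        with pytest.raises(InvalidInputError):
            cs.agreement_grouping(runs)

    def test_counts_partition_the_images(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 15))
            runs = [make_run(code, random_partition(rng, n, 3))
                    for code in ("EG", "SG", "ET", "ST", "EC", "SC")]
            part = cs.agreement_grouping(runs)
            assert sum(part.counts.values()) == n
            assert set(part.assignment) == {f"i{j}" for j in range(n)}

    def test_level_matches_exhaustive_subset_oracle(self, rng):
        """Compare to brute force over all subsets of runs (n <= 12)."""
        from itertools import combinations

        for _ in range(100):
            n = int(rng.integers(4, 13))
            runs = [make_run(code, random_partition(rng, n, int(rng.integers(2, 4))))
                    for code in ("EG", "SG", "ET", "ST", "EC", "SC")]
            part = cs.agreement_grouping(runs)
            mates = []
            for run in runs:
                per = {}
                for img_idx in range(n):
                    same = {f"i{j}" for j in range(n)
                            if run.labels[j] == run.labels[img_idx]}
                    per[f"i{img_idx}"] = frozenset(same - {f"i{img_idx}"})
                mates.append(per)
            for img_idx in range(n):
                img = f"i{img_idx}"
                best = 1
                for size in range(2, 7):
                    for subset in combinations(range(6), size):
                        sets = {mates[r][img] for r in subset}
                        if len(sets) == 1:
                            best = max(best, size)
                assert part.level[img] == best

    def test_perturbation_never_increases_si(self, rng):
        """Relabelling a growing fraction of images can only erode SI."""
        n = 30
        base = random_partition(rng, n, 3)
        for seed in range(3):
            local = np.random.default_rng(seed)
            si_counts = []
            for frac in (0.0, 0.1, 0.3, 0.6):
                runs = []
                for code in ("EG", "SG", "ET", "ST", "EC", "SC"):
                    labels = base.copy()
                    n_flip = int(frac * n)
                    idx = local.choice(n, size=n_flip, replace=False)
                    labels[idx] = local.integers(0, 3, size=n_flip)
                    runs.append(make_run(code, labels, k=3))
                si_counts.append(cs.agreement_grouping(runs).counts["SI"])
            assert all(a >= b for a, b in zip(si_counts, si_counts[1:]))

    def test_planted_study_is_dominated_by_si(self, planted_report):
        counts = planted_report.agreement.counts
        assert counts["SI"] >= 0.9 * 60
        assert sum(counts.values()) == 60


class TestCombinationCount:
    @pytest.mark.parametrize("n,k,expected", [(6, 2, 15), (5, 2, 10),
                                              (4, 4, 1), (7, 0, 1)])
    def test_values(self, n, k, expected):
        assert cs.combination_count(n, k) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.combination_count(3, 4)
        with pytest.raises(InvalidInputError):
            cs.combination_count(-1, 0)


class TestCompareToHuman:
    def _truth(self, n_per=4):
        from testaclust.synthetic import WallClass

        classes = [WallClass("straight", "granule"),
                   WallClass("U", "small_verrucae"),
                   WallClass("omega", "large_verrucae")]
        truth = {}
        ids = []
        for c_idx, wc in enumerate(classes):
            for j in range(n_per):
                img = f"i{c_idx}_{j}"
                truth[img] = wc
                ids.append(img)
        return truth, ids

    def test_machine_run_matching_anticlinal_axis_is_identical(self):
        truth, ids = self._truth()
        labels = [i // 4 for i in range(12)]
        run = make_run("M1", labels, ids=ids)
        relations, threads, table = cs.compare_to_human(
            [run], truth, cs.OverlapConfig(report_floor=0))
        ant = [r for r in relations if r.a[0] == "H-ANT"]
        diag = [r for r in ant if r.overlap > 0 and r.jaccard == 1.0]
        assert len(diag) == 3
        assert all(r.category == "identical" for r in diag)

    def test_random_labels_yield_no_identical_relations(self):
        truth, ids = self._truth(n_per=20)
        rng = np.random.default_rng(8)
        run = make_run("M1", random_partition(rng, 60, 3), ids=ids)
        relations, _, _ = cs.compare_to_human(
            [run], truth, cs.OverlapConfig(report_floor=0))
        assert not any(r.category == "identical" for r in relations)

    def test_table_schema(self):
        truth, ids = self._truth()
        run = make_run("M1", [i // 4 for i in range(12)], ids=ids)
        _, _, table = cs.compare_to_human([run], truth,
                                          cs.OverlapConfig(report_floor=0))
        assert list(table.columns) == ["truth_axis", "truth_class", "run",
                                       "cluster", "overlap", "jaccard",
                                       "separation", "category"]
        assert set(table["truth_axis"]) == {"H-ANT", "H-PER"}

    def test_missing_truth_rejected(self):
        run = make_run("M1", [0, 1], ids=["a", "b"])
        with pytest.raises(InvalidInputError):
            cs.compare_to_human([run], {"a": None}, None)
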