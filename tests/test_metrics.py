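import math

import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

from cbparc import (
    ContingencyTable,
    EvaluationReport,
    SubjectParcellation,
    contingency,
    cramers_v,
    dice_multilabel,
    nmi,
    overlap_report,
    select_optimal_k,
    split_half_consistency,
    split_half_table,
    variation_of_information,
)

from .conftest import label_volume

# ---------------------------------------------------------------------------
# brute-force definitional oracles (independent of the implementation)


def oracle_chi2_v(counts):
    counts = np.asarray(counts, dtype=float)
    N = counts.sum()
    r, c = counts.shape
    chi2 = 0.0
    for i in range(r):
        for j in range(c):
            e = counts[i].sum() * counts[:, j].sum() / N
            if e > 0:
                chi2 += (counts[i, j] - e) ** 2 / e
    return math.sqrt(chi2 / (N * (min(r, c) - 1)))


def oracle_entropies(counts):
    counts = np.asarray(counts, dtype=float)
    N = counts.sum()
    hx = -sum(
        (row / N) * math.log(row / N) for row in counts.sum(axis=1) if row > 0
    )
    hy = -sum(
        (col / N) * math.log(col / N) for col in counts.sum(axis=0) if col > 0
    )
    mi = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            if counts[i, j] > 0:
                pij = counts[i, j] / N
                mi += pij * math.log(
                    pij / ((counts[i].sum() / N) * (counts[:, j].sum() / N))
                )
    return hx, hy, mi


def oracle_dice(a, b):
    labels = sorted((set(a.ravel()) | set(b.ravel())) - {0})
    per = {}
    for c in labels:
        na, nb = int((a == c).sum()), int((b == c).sum())
        if na + nb:
            per[c] = 2 * int(((a == c) & (b == c)).sum()) / (na + nb)
    return float(np.mean(list(per.values()))), per


def random_pair(rng, max_vox=200, max_labels=5):
    shape = tuple(rng.integers(2, 7, size=3))
    while np.prod(shape) > max_vox:
        shape = tuple(rng.integers(2, 7, size=3))
    k = int(rng.integers(2, max_labels + 1))
    a = rng.integers(0, k + 1, size=shape)
    b = rng.integers(0, k + 1, size=shape)
    # guarantee joint support
    a.flat[0] = b.flat[0] = 1
    a.flat[1] = b.flat[1] = 2
    return label_volume(a), label_volume(b)


# ---------------------------------------------------------------------------


class TestContingency:
    def test_identical_volumes_give_diagonal_table(self):
        a = label_volume(np.array([1, 1, 2, 2]).reshape(4, 1, 1))
        table = contingency(a, a)
        np.testing.assert_array_equal(table.counts, [[2, 0], [0, 2]])

    def test_crossed_pair_fills_all_cells(self):
        a = label_volume(np.array([1, 1, 2, 2]).reshape(4, 1, 1))
        b = label_volume(np.array([1, 2, 1, 2]).reshape(4, 1, 1))
        np.testing.assert_array_equal(contingency(a, b).counts, [[1, 1], [1, 1]])

    def test_total_equals_joint_support(self):
        rng = np.random.default_rng(0)
        a, b = random_pair(rng)
        table = contingency(a, b)
        assert table.total == int(((a.labels > 0) & (b.labels > 0)).sum())

    def test_empty_joint_support_rejected(self):
        a = label_volume(np.array([1, 0]).reshape(2, 1, 1))
        b = label_volume(np.array([0, 1]).reshape(2, 1, 1))
        with pytest.raises(ValueError, match="no voxels"):
            contingency(a, b)


class TestCramersV:
    def test_perfect_association(self):
        assert cramers_v(
            ContingencyTable(np.array([[2, 0], [0, 2]]), [1, 2], [1, 2])
        ) == pytest.approx(1.0)

    def test_exact_independence(self):
        assert cramers_v(
            ContingencyTable(np.array([[1, 1], [1, 1]]), [1, 2], [1, 2])
        ) == pytest.approx(0.0)

    def test_matches_definitional_chi2(self):
        counts = np.array([[10, 2], [3, 9]])
        table = ContingencyTable(counts, [1, 2], [1, 2])
        assert cramers_v(table) == pytest.approx(oracle_chi2_v(counts), abs=1e-12)

    def test_degenerate_marginal_returns_zero_with_warning(self, caplog):
        table = ContingencyTable(np.array([[3, 2], [0, 0]]), [1, 2], [1, 2])
        with caplog.at_level("WARNING", logger="cbparc.metrics"):
            assert cramers_v(table) == 0.0
        assert "degenerate" in caplog.text

    def test_single_row_table_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            cramers_v(ContingencyTable(np.array([[3, 2]]), [1], [1, 2]))


class TestNMIAndVI:
    def test_identical_partitions(self):
        table = ContingencyTable(np.array([[3, 0], [0, 5]]), [1, 2], [1, 2])
        assert nmi(table) == pytest.approx(1.0)
        assert variation_of_information(table) == pytest.approx(0.0)

    def test_independent_uniform(self):
        table = ContingencyTable(np.array([[1, 1], [1, 1]]), [1, 2], [1, 2])
        assert nmi(table) == pytest.approx(0.0)
        assert variation_of_information(table) == pytest.approx(2 * math.log(2))

    def test_matches_definitional_sums(self):
        counts = np.array([[3, 1], [1, 3]])
        table = ContingencyTable(counts, [1, 2], [1, 2])
        hx, hy, mi = oracle_entropies(counts)
        assert nmi(table) == pytest.approx(2 * mi / (hx + hy), abs=1e-12)
        assert variation_of_information(table) == pytest.approx(
            hx + hy - 2 * mi, abs=1e-12
        )

    def test_vi_conditional_entropy_identity(self):
        counts = np.array([[3, 1], [1, 3]])
        hx, hy, mi = oracle_entropies(counts)
        # VI = H(X|Y) + H(Y|X)
        assert variation_of_information(
            ContingencyTable(counts, [1, 2], [1, 2])
        ) == pytest.approx((hx - mi) + (hy - mi), abs=1e-12)

    def test_nmi_agrees_with_sklearn_on_label_vectors(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, size=200)
        y = rng.integers(0, 4, size=200)
        a = label_volume((x + 1).reshape(200, 1, 1))
        b = label_volume((y + 1).reshape(200, 1, 1))
        ours = nmi(contingency(a, b))
        theirs = normalized_mutual_info_score(x, y, average_method="arithmetic")
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_single_cluster_partitions_return_zero_with_warning(self, caplog):
        table = ContingencyTable(np.array([[7]]), [1], [1])
        with caplog.at_level("WARNING", logger="cbparc.metrics"):
            assert nmi(table) == 0.0
        assert "single-cluster" in caplog.text


class TestDiceAndOverlap:
    def test_identical_volumes_dice_one(self):
        a = label_volume(np.array([1, 2, 1, 2]).reshape(4, 1, 1))
        mean, per = dice_multilabel(a, a)
        assert mean == 1.0 and set(per.values()) == {1.0}

    def test_disjoint_supports_dice_zero(self):
        a = label_volume(np.array([1, 1, 0, 0]).reshape(4, 1, 1))
        b = label_volume(np.array([0, 0, 1, 1]).reshape(4, 1, 1))
        mean, _ = dice_multilabel(a, b)
        assert mean == 0.0

    def test_matches_direct_set_counting(self):
        a = label_volume(np.array([1, 1, 1, 1, 2, 2, 2, 2]).reshape(8, 1, 1))
        b = label_volume(np.array([1, 1, 1, 2, 2, 2, 2, 2]).reshape(8, 1, 1))
        mean, per = dice_multilabel(a, b)
        assert per[1] == pytest.approx(2 * 3 / (4 + 3))
        assert per[2] == pytest.approx(2 * 4 / (4 + 5))
        assert mean == pytest.approx((per[1] + per[2]) / 2)

    def test_overlap_report_perfect_and_disjoint(self):
        a = label_volume(np.array([1, 1, 0, 0]).reshape(4, 1, 1))
        rep = overlap_report(a, a, label=1)
        assert rep == {"dice": 1.0, "sensitivity": 1.0, "specificity": 1.0, "iou": 1.0}
        b = label_volume(np.array([0, 0, 1, 1]).reshape(4, 1, 1))
        rep = overlap_report(a, b, label=1)
        assert rep["dice"] == 0.0 and rep["sensitivity"] == 0.0 and rep["iou"] == 0.0

    def test_overlap_report_matches_set_arithmetic(self):
        # |A| = 100, |B| = 90, |A ∩ B| = 80 in a 1000-voxel domain
        a = np.zeros(1000, dtype=int)
        b = np.zeros(1000, dtype=int)
        a[:100] = 1
        b[20:110] = 1
        rep = overlap_report(
            label_volume(a.reshape(10, 10, 10)), label_volume(b.reshape(10, 10, 10)), 1
        )
        assert rep["dice"] == pytest.approx(2 * 80 / 190)
        assert rep["sensitivity"] == pytest.approx(80 / 100)
        assert rep["specificity"] == pytest.approx((900 - 10) / 900)
        assert rep["iou"] == pytest.approx(80 / 110)

    def test_label_absent_from_reference_rejected(self):
        a = label_volume(np.ones((2, 2, 2), dtype=int))
        with pytest.raises(ValueError, match="absent"):
            overlap_report(a, a, label=5)


class TestOracleEquivalenceAndInvariance:
    def test_metrics_match_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            a, b = random_pair(rng)
            table = contingency(a, b)
            hx, hy, mi = oracle_entropies(table.counts)
            if hx + hy > 0:
                assert nmi(table) == pytest.approx(
                    max(2 * mi / (hx + hy), 0.0), abs=1e-10
                )
            assert variation_of_information(table) == pytest.approx(
                max(hx + hy - 2 * mi, 0.0), abs=1e-10
            )
            nz_r = (table.counts.sum(axis=1) > 0).sum()
            nz_c = (table.counts.sum(axis=0) > 0).sum()
            if min(table.counts.shape) >= 2 and nz_r >= 2 and nz_c >= 2:
                assert cramers_v(table) == pytest.approx(
                    min(oracle_chi2_v(table.counts), 1.0), abs=1e-10
                )
            mean, per = dice_multilabel(a, b)
            o_mean, o_per = oracle_dice(a.labels, b.labels)
            assert mean == pytest.approx(o_mean, abs=1e-10)
            assert per == pytest.approx(o_per, abs=1e-10)

    def test_metrics_invariant_to_consistent_relabeling(self):
        rng = np.random.default_rng(17)
        a, b = random_pair(rng)
        perm = np.array([0, 3, 1, 2, 5, 4])[: max(a.label_set | b.label_set) + 1]
        a2 = label_volume(perm[a.labels])
        b2 = label_volume(perm[b.labels])
        t1, t2 = contingency(a, b), contingency(a2, b2)
        assert nmi(t1) == pytest.approx(nmi(t2), abs=1e-12)
        assert variation_of_information(t1) == pytest.approx(
            variation_of_information(t2), abs=1e-12
        )
        if min(t1.counts.shape) >= 2 and min(t2.counts.shape) >= 2:
            assert cramers_v(t1) == pytest.approx(cramers_v(t2), abs=1e-12)

    def test_vi_metric_axioms_on_sampled_triples(self):
        rng = np.random.default_rng(31)
        shape = (5, 5, 4)
        for _ in range(100):
            vols = [
                label_volume(rng.integers(1, 4, size=shape)) for _ in range(3)
            ]
            d = {}
            for i in range(3):
                for j in range(3):
                    d[i, j] = variation_of_information(contingency(vols[i], vols[j]))
            for i in range(3):
                assert d[i, i] == pytest.approx(0.0, abs=1e-12)
                for j in range(3):
                    assert d[i, j] == pytest.approx(d[j, i], abs=1e-12)
            assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-10


class TestSplitHalf:
    def _identical_parcs(self, n=6):
        labels = np.array([1, 1, 1, 2, 2, 2]).reshape(6, 1, 1)
        return [
            SubjectParcellation(f"s{i}", 2, label_volume(labels)) for i in range(n)
        ]

    def test_identical_subjects_give_perfect_dice(self):
        mean, sd = split_half_consistency(self._identical_parcs(), "dice", 20, 0)
        assert mean == 1.0 and sd == 0.0

    def test_same_seed_reproduces(self, small_cohort):
        from cbparc import ConnectivityParcellation

        res = ConnectivityParcellation.from_cohort(small_cohort).fit(
            k_range=(2, 2), n_reps=0
        )
        parcs = res.subject_parcellations[2]
        a = split_half_consistency(parcs, "nmi", 25, rng_seed=3)
        b = split_half_consistency(parcs, "nmi", 25, rng_seed=3)
        assert a == b

    def test_table_matches_per_metric_calls(self, small_cohort):
        from cbparc import ConnectivityParcellation

        res = ConnectivityParcellation.from_cohort(small_cohort).fit(
            k_range=(2, 2), n_reps=0
        )
        parcs = res.subject_parcellations[2]
        table = split_half_table(parcs, ["dice", "vi"], 10, rng_seed=4)
        assert table["dice"] == split_half_consistency(parcs, "dice", 10, 4)
        assert table["vi"] == split_half_consistency(parcs, "vi", 10, 4)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="4 subjects"):
            split_half_consistency(self._identical_parcs(3), "dice", 5, 0)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            split_half_consistency(self._identical_parcs(), "accuracy", 5, 0)


class TestSelectOptimalK:
    # The published per-K evaluation table for the two hemispheres.
    LEFT = dict(
        ks=[2, 3, 4, 5],
        cv=[0.521, 0.474, 0.438, 0.418],
        dice=[0.416, 0.360, 0.290, 0.234],
        nmi=[0.546, 0.536, 0.529, 0.526],
        vi=[0.002, 0.003, 0.003, 0.003],
    )
    RIGHT = dict(
        ks=[2, 3, 4, 5],
        cv=[0.424, 0.399, 0.386, 0.372],
        dice=[0.328, 0.282, 0.264, 0.231],
        nmi=[0.421, 0.418, 0.416, 0.405],
        vi=[0.0012, 0.0013, 0.0013, 0.0014],
    )

    @pytest.mark.parametrize("values", [LEFT, RIGHT], ids=["left", "right"])
    def test_published_hemisphere_tables_select_two_clusters(self, values):
        report = EvaluationReport.from_values(**values)
        assert select_optimal_k(report) == 2

    def test_dominating_k_wins(self):
        report = EvaluationReport.from_values(
            ks=[2, 3, 4],
            cv=[0.3, 0.9, 0.2],
            dice=[0.4, 0.8, 0.3],
            nmi=[0.5, 0.9, 0.4],
            vi=[0.5, 0.1, 0.6],
        )
        assert select_optimal_k(report) == 3

    def test_exact_tie_prefers_smaller_k(self, caplog):
        report = EvaluationReport.from_values(
            ks=[2, 3],
            cv=[0.5, 0.5],
            dice=[0.5, 0.5],
            nmi=[0.5, 0.5],
            vi=[0.5, 0.5],
        )
        with caplog.at_level("WARNING", logger="cbparc.metrics"):
            assert select_optimal_k(report) == 2
        assert "tie" in caplog.text

    def test_incomplete_report_rejected(self):
        report = EvaluationReport.from_values(
            ks=[2], cv=[0.5], dice=[0.5], nmi=[0.5], vi=[0.5]
        )
        with pytest.raises(ValueError, match="at least 2"):
            select_optimal_k(report)
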