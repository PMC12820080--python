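"""Fleiss' kappa, per-category kappa, and machine-rater folding."""

import numpy as np
import pandas as pd
import pytest

from semharm.agreement import (
    AgreementError,
    AssignmentMatrix,
    build_assignment_matrix,
    category_kappa,
    disagreement_ranking,
    fleiss_kappa,
    majority_machine_map,
)
from semharm.backbone import ClusterAssignment

# the hand-worked matrix: N=4 items, m=3 raters, k=2 categories
WORKED = AssignmentMatrix(
    items=("i1", "i2", "i3", "i4"),
    raters=("a", "b", "c"),
    categories=("1", "2"),
    counts=np.array([[3, 0], [0, 3], [2, 1], [1, 2]]),
)


def _random_matrix(rng, n=12, m=5, k=3):
    counts = rng.multinomial(m, np.ones(k) / k, size=n)
    return AssignmentMatrix(
        items=tuple(f"i{i}" for i in range(n)),
        raters=tuple(f"r{j}" for j in range(m)),
        categories=tuple(str(c + 1) for c in range(k)),
        counts=counts,
    )


def _kappa_oracle(counts):
    """Independently coded closed-form Fleiss kappa."""
    counts = np.asarray(counts, float)
    n, k = counts.shape
    m = counts[0].sum()
    p_bar = np.mean([(row @ row - m) / (m * (m - 1)) for row in counts])
    p = counts.sum(axis=0) / (n * m)
    pe = p @ p
    return (p_bar - pe) / (1 - pe)


def _category_kappa_oracle(counts, j):
    counts = np.asarray(counts, float)
    n, _ = counts.shape
    m = counts[0].sum()
    pj = counts[:, j].sum() / (n * m)
    num = sum(nij * (m - nij) for nij in counts[:, j])
    return 1 - num / (n * m * (m - 1) * pj * (1 - pj))


class TestFleissKappa:
    def test_hand_worked_matrix(self):
        res = fleiss_kappa(WORKED)
        assert res.kappa == pytest.approx(1 / 3)
        assert res.se > 0
        assert res.ci_low <= res.kappa <= res.ci_high

    def test_perfect_agreement(self):
        m = AssignmentMatrix(
            items=("i1", "i2"), raters=("a", "b", "c"),
            categories=("1", "2"),
            counts=np.array([[3, 0], [0, 3]]),
        )
        assert fleiss_kappa(m).kappa == pytest.approx(1.0)

    def test_single_category_undefined(self):
        m = AssignmentMatrix(
            items=("i1", "i2"), raters=("a", "b"),
            categories=("1", "2"),
            counts=np.array([[2, 0], [2, 0]]),
        )
        with pytest.raises(AgreementError, match="undefined"):
            fleiss_kappa(m)

    def test_matches_statsmodels_on_random_matrices(self, rng):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_kappa
        for _ in range(100):
            m = _random_matrix(rng, n=int(rng.integers(5, 30)),
                               m=int(rng.integers(2, 8)),
                               k=int(rng.integers(2, 5)))
            ours = fleiss_kappa(m).kappa
            assert ours == pytest.approx(sm_kappa(m.counts), abs=1e-12)
            assert ours == pytest.approx(_kappa_oracle(m.counts), abs=1e-12)

    def test_uniform_raters_near_zero(self):
        rng = np.random.default_rng(2024)
        m = _random_matrix(rng, n=500, m=6, k=4)
        assert abs(fleiss_kappa(m).kappa) < 0.05

    def test_invariant_to_category_relabel_and_item_reorder(self, rng):
        m = _random_matrix(rng)
        base = fleiss_kappa(m).kappa
        swapped = AssignmentMatrix(m.items, m.raters, m.categories[::-1],
                                   m.counts[:, ::-1])
        perm = rng.permutation(len(m.items))
        reordered = AssignmentMatrix(tuple(m.items[i] for i in perm),
                                     m.raters, m.categories, m.counts[perm])
        assert fleiss_kappa(swapped).kappa == pytest.approx(base)
        assert fleiss_kappa(reordered).kappa == pytest.approx(base)


class TestCategoryKappa:
    def test_binary_case_collapses_to_overall(self):
        overall = fleiss_kappa(WORKED).kappa
        assert category_kappa(WORKED, "1").kappa == pytest.approx(overall)
        assert category_kappa(WORKED, "2").kappa == pytest.approx(overall)
        assert overall == pytest.approx(1 / 3)

    def test_binary_collapse_on_random_matrices(self, rng):
        for _ in range(30):
            m = _random_matrix(rng, k=2)
            overall = fleiss_kappa(m).kappa
            for c in m.categories:
                assert category_kappa(m, c).kappa == pytest.approx(overall, abs=1e-12)

    def test_unanimous_category_use_gives_one(self):
        m = AssignmentMatrix(
            items=("i1", "i2", "i3", "i4"), raters=("a", "b", "c"),
            categories=("j", "other"),
            counts=np.array([[3, 0], [3, 0], [0, 3], [0, 3]]),
        )
        assert category_kappa(m, "j").kappa == pytest.approx(1.0)

    def test_matches_duplicate_implementation(self, rng):
        for _ in range(100):
            m = _random_matrix(rng, n=int(rng.integers(5, 25)),
                               m=int(rng.integers(2, 7)),
                               k=int(rng.integers(2, 5)))
            for j, c in enumerate(m.categories):
                p = m.counts[:, j].sum() / m.counts.sum()
                if p in (0.0, 1.0):
                    continue
                assert category_kappa(m, c).kappa == pytest.approx(
                    _category_kappa_oracle(m.counts, j), abs=1e-12)

    def test_unused_category_undefined(self):
        m = AssignmentMatrix(
            items=("i1",), raters=("a", "b"), categories=("1", "2"),
            counts=np.array([[2, 0]]),
        )
        with pytest.raises(AgreementError):
            category_kappa(m, "2")


def _expert_df(assignments):
    rows = [
        {"item_id": item, "rater_id": rater, "category": cat}
        for (item, rater), cat in assignments.items()
    ]
    return pd.DataFrame(rows)


class TestBuildMatrix:
    def test_unanimous_tally(self):
        df = _expert_df({(f"i{i}", r): "A"
                         for i in range(3) for r in ("r1", "r2")})
        df.loc[len(df)] = {"item_id": "i0", "rater_id": "r3", "category": "B"}
        df = pd.concat([df, _expert_df({(f"i{i}", "r3"): "B"
                                        for i in range(1, 3)})],
                       ignore_index=True)
        m = build_assignment_matrix(df)
        assert m.counts[:, list(m.categories).index("A")].tolist() == [2, 2, 2]

    def test_machine_increments_rater_count(self):
        df = _expert_df({(f"i{i}", r): str(i % 2 + 1)
                         for i in range(4) for r in ("r1", "r2")})
        machine = ClusterAssignment(
            labels={f"i{i}": i % 2 + 1 for i in range(4)}, n_clusters=2,
            method="components")
        m = build_assignment_matrix(df, machine=machine)
        assert m.n_raters == 3
        assert np.all(m.counts.sum(axis=1) == 3)

    def test_counts_equal_recount(self, rng):
        items = [f"i{i}" for i in range(10)]
        raters = [f"r{j}" for j in range(4)]
        cats = ["A", "B", "C"]
        table = {(i, r): cats[rng.integers(3)] for i in items for r in raters}
        m = build_assignment_matrix(_expert_df(table))
        for i, item in enumerate(m.items):
            for j, cat in enumerate(m.categories):
                expected = sum(1 for r in raters if table[(item, r)] == cat)
                assert m.counts[i, j] == expected

    def test_missing_rating_named(self):
        df = _expert_df({("i1", "r1"): "A", ("i1", "r2"): "A",
                         ("i2", "r1"): "B"})
        with pytest.raises(AgreementError, match="i2.*r2"):
            build_assignment_matrix(df)

    def test_machine_label_outside_expert_categories_needs_map(self):
        df = _expert_df({(f"i{i}", r): "theme_a"
                         for i in range(2) for r in ("r1", "r2")})
        df2 = _expert_df({(f"i{i}", "r3"): "theme_b" for i in range(2)})
        df = pd.concat([df, df2], ignore_index=True)
        machine = ClusterAssignment(labels={"i0": 1, "i1": 2}, n_clusters=2,
                                    method="components")
        with pytest.raises(AgreementError, match="machine_map"):
            build_assignment_matrix(df, machine=machine)
        mapped = build_assignment_matrix(
            df, machine=machine, machine_map={1: "theme_a", 2: "theme_b"})
        assert mapped.n_raters == 4


class TestMajorityMapAndRanking:
    def test_majority_map_recovers_correspondence(self):
        # experts unanimously call cluster-1 items "X" and cluster-2 items "Y"
        table = {}
        for i in range(4):
            for r in ("r1", "r2", "r3"):
                table[(f"i{i}", r)] = "X" if i < 2 else "Y"
        machine = ClusterAssignment(
            labels={"i0": 1, "i1": 1, "i2": 2, "i3": 2}, n_clusters=2,
            method="components")
        assert majority_machine_map(_expert_df(table), machine) == {1: "X", 2: "Y"}

    def test_ranking_extremes_and_oracle(self, rng):
        items = [f"i{i}" for i in range(8)]
        raters = ["r1", "r2", "r3", "r4"]
        machine = ClusterAssignment(
            labels={i: 1 for i in items}, n_clusters=1, method="components")
        table = {}
        for i, item in enumerate(items):
            for r in raters:
                if item == "i0":
                    table[(item, r)] = "1"        # all agree with machine
                elif item == "i1":
                    table[(item, r)] = "2"        # none agree
                else:
                    table[(item, r)] = str(rng.integers(1, 3))
        m = build_assignment_matrix(_expert_df(table))
        ranking = disagreement_ranking(m, machine)
        assert ranking[0] == ("i0", 1.0)
        assert ranking[-1][1] == 0.0
        # brute-force recount + sort oracle
        expected = sorted(
            ((item, sum(1 for r in raters if table[(item, r)] == "1") / 4)
             for item in items),
            key=lambda t: (-t[1], t[0]),
        )
        assert ranking == expected
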