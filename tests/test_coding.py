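"""Coding tables, inter-coder agreement, heatmaps and conflict reports."""

from __future__ import annotations

import numpy as np
import pytest

from causalmaps import (
    CodingTable,
    aggregate_agreement,
    conflict_report,
    heatmap_matrix,
    intercoder_agreement,
)
from causalmaps.coding import AXES, SEM_LEVELS, STRATEGIES, UndefinedAgreementError


class TestIntercoderAgreement:
    def test_one_shared_of_three_used(self):
        assert intercoder_agreement(
            {"environments", "prevent"}, {"environments", "coping"}
        ) == pytest.approx(1 / 3)

    def test_identical_sets(self):
        assert intercoder_agreement({"coping"}, {"coping"}) == 1.0

    def test_disjoint_sets(self):
        assert intercoder_agreement({"coping"}, {"care"}) == 0.0

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedAgreementError):
            intercoder_agreement(set(), set())

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_and_equals_jaccard(self, seed):
        rng = np.random.default_rng(seed)
        pool = list(STRATEGIES)
        s1 = {c for c in pool if rng.random() < 0.5}
        s2 = {c for c in pool if rng.random() < 0.5}
        if not s1 and not s2:
            s1 = {"coping"}
        a = intercoder_agreement(s1, s2)
        assert a == intercoder_agreement(s2, s1)
        assert a == len(s1 & s2) / len(s1 | s2)


def build_table(assignments):
    """assignments: {(coder, node): {axis: [categories]}}"""
    table = CodingTable()
    for (coder, node), axes in assignments.items():
        for axis, cats in axes.items():
            for cat in cats:
                table.assign(coder, node, axis, cat)
    return table


class TestAggregateAgreement:
    def test_perfect_agreement_is_100(self):
        table = build_table({
            ("c1", n): {"sem_level": ["individual"]} for n in ("A", "B")
        } | {
            ("c2", n): {"sem_level": ["individual"]} for n in ("A", "B")
        })
        result = aggregate_agreement(table, "c1", "c2", "sem_level")
        assert result["agreement_percent"] == 100.0

    def test_half_agreement(self):
        table = build_table({
            ("c1", "A"): {"sem_level": ["individual"]},
            ("c2", "A"): {"sem_level": ["individual"]},
            ("c1", "B"): {"sem_level": ["societal"]},
            ("c2", "B"): {"sem_level": ["community"]},
        })
        assert aggregate_agreement(table, "c1", "c2", "sem_level")[
            "agreement_percent"] == 50.0

    def test_planted_jaccard_recovered(self):
        # construct nodes whose pairwise Jaccard is exactly 1/3 each:
        # mean must come out at 100/3 %
        table = CodingTable()
        for i in range(30):
            node = f"n{i}"
            table.assign("c1", node, "strategy", "environments")
            table.assign("c1", node, "strategy", "prevent")
            table.assign("c2", node, "strategy", "environments")
            table.assign("c2", node, "strategy", "coping")
        result = aggregate_agreement(table, "c1", "c2", "strategy")
        assert result["agreement_percent"] == pytest.approx(100 / 3)
        assert result["n_nodes"] == 30

    def test_uncoded_by_both_skipped(self):
        table = build_table({
            ("c1", "A"): {"sem_level": ["individual"]},
            ("c2", "A"): {"sem_level": ["individual"]},
            ("c1", "B"): {"strategy": ["coping"]},  # no sem_level either side
            ("c2", "B"): {"strategy": ["coping"]},
        })
        result = aggregate_agreement(table, "c1", "c2", "sem_level")
        assert result["skipped_uncoded"] == ["B"]
        assert result["agreement_percent"] == 100.0

    def test_node_order_invariance(self):
        rng = np.random.default_rng(0)
        entries = {}
        for i in range(20):
            for coder in ("c1", "c2"):
                cats = [c for c in SEM_LEVELS if rng.random() < 0.5] or ["individual"]
                entries[(coder, f"n{i}")] = {"sem_level": cats}
        t1 = build_table(entries)
        t2 = build_table(dict(reversed(list(entries.items()))))
        assert aggregate_agreement(t1, "c1", "c2", "sem_level") == \
            aggregate_agreement(t2, "c1", "c2", "sem_level")

    def test_no_overlap_undefined(self):
        with pytest.raises(UndefinedAgreementError):
            aggregate_agreement(CodingTable(), "c1", "c2", "sem_level")


class TestHeatmap:
    def test_uniform_coding_fills_one_cell(self):
        table = CodingTable()
        for i in range(10):
            table.assign("c1", f"n{i}", "strategy", "coping")
            table.assign("c1", f"n{i}", "sem_level", "individual")
        matrix = heatmap_matrix(table, "c1")
        assert matrix.loc["coping", "individual"] == 100.0
        assert matrix.to_numpy().sum() == 100.0

    def test_multi_membership_counts_in_multiple_cells(self):
        table = CodingTable()
        table.assign("c1", "A", "strategy", "coping")
        table.assign("c1", "A", "sem_level", "individual")
        table.assign("c1", "A", "sem_level", "societal")
        matrix = heatmap_matrix(table, "c1")
        assert matrix.loc["coping", "individual"] == 100.0
        assert matrix.loc["coping", "societal"] == 100.0
        # totals may exceed 100% and are not clipped
        assert matrix.to_numpy().sum() == 200.0

    def test_explicit_denominator(self):
        table = CodingTable()
        table.assign("c1", "A", "strategy", "care")
        table.assign("c1", "A", "sem_level", "community")
        matrix = heatmap_matrix(table, "c1", total_nodes=4)
        assert matrix.loc["care", "community"] == 25.0

    def test_matrix_shape_and_bounds(self):
        rng = np.random.default_rng(1)
        table = CodingTable()
        for i in range(25):
            table.assign("c1", f"n{i}", "strategy",
                         STRATEGIES[int(rng.integers(len(STRATEGIES)))])
            table.assign("c1", f"n{i}", "sem_level",
                         SEM_LEVELS[int(rng.integers(len(SEM_LEVELS)))])
        matrix = heatmap_matrix(table, "c1")
        assert matrix.shape == (7, 4)
        assert ((matrix >= 0) & (matrix <= 100)).all().all()

    def test_matches_direct_count_oracle(self):
        rng = np.random.default_rng(2)
        table = CodingTable()
        truth: dict[str, tuple[set, set]] = {}
        for i in range(30):
            node = f"n{i}"
            strategies = {s for s in STRATEGIES if rng.random() < 0.3}
            levels = {l for l in SEM_LEVELS if rng.random() < 0.4}
            truth[node] = (strategies, levels)
            for s in strategies:
                table.assign("c1", node, "strategy", s)
            for l in levels:
                table.assign("c1", node, "sem_level", l)
        coded = [n for n, (s, l) in truth.items() if s or l]
        matrix = heatmap_matrix(table, "c1", total_nodes=len(coded))
        for s in STRATEGIES:
            for l in SEM_LEVELS:
                count = sum(1 for st, lv in truth.values() if s in st and l in lv)
                assert matrix.loc[s, l] == pytest.approx(100 * count / len(coded))


class TestConflictsAndIO:
    def test_identical_tables_no_conflicts(self):
        table = build_table({
            ("c1", "A"): {"sem_level": ["individual"]},
            ("c2", "A"): {"sem_level": ["individual"]},
        })
        assert conflict_report(table, "c1", "c2") == []

    def test_worked_conflict_lists_one_sided_categories(self):
        table = build_table({
            ("c1", "secrecy"): {"strategy": ["environments", "prevent"]},
            ("c2", "secrecy"): {"strategy": ["environments", "coping"]},
        })
        report = conflict_report(table, "c1", "c2")
        assert len(report) == 1
        rec = report[0]
        assert rec["only_c1"] == ["prevent"]
        assert rec["only_c2"] == ["coping"]
        assert rec["shared"] == ["environments"]

    def test_diff_matches_set_arithmetic(self):
        rng = np.random.default_rng(3)
        table = CodingTable()
        truth = {}
        for i in range(15):
            node = f"n{i}"
            s1 = {s for s in STRATEGIES if rng.random() < 0.4}
            s2 = {s for s in STRATEGIES if rng.random() < 0.4}
            truth[node] = (s1, s2)
            for s in s1:
                table.assign("c1", node, "strategy", s)
            for s in s2:
                table.assign("c2", node, "strategy", s)
        report = {r["node"]: r for r in conflict_report(table, "c1", "c2")
                  if r["axis"] == "strategy"}
        for node, (s1, s2) in truth.items():
            if s1 == s2:
                assert node not in report
            else:
                assert report[node]["only_c1"] == sorted(s1 - s2)
                assert report[node]["only_c2"] == sorted(s2 - s1)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            CodingTable().assign("c1", "A", "strategy", "parkour")
        with pytest.raises(ValueError, match="axis"):
            CodingTable().assign("c1", "A", "vibe", "coping")

    def test_csv_round_trip(self, tmp_path):
        table = build_table({
            ("c1", "A"): {"sem_level": ["individual"], "strategy": ["coping", "care"]},
            ("consensus", "A"): {"strategy": ["coping"]},
        })
        path = table.write_csv(tmp_path / "coding.csv")
        reloaded = CodingTable.read_csv(path)
        for coder in ("c1", "consensus"):
            for axis in AXES:
                assert reloaded.categories(coder, "A", axis) == \
                    table.categories(coder, "A", axis)
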