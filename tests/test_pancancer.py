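"""Driver∩DEG intersection, cross-condition sharing, FDR comparison and
overlap-percentage arithmetic."""

import numpy as np
import pandas as pd
import pytest

from driverplex.dea import DEGTable
from driverplex.pancancer import (
    benchmark_overlap,
    fdr_comparison,
    intersect_driver_degs,
    percentage,
    shared_driver_matrix,
)


def _deg_table(genes, is_deg=None, fdr=None, condition="C") -> DEGTable:
    n = len(genes)
    df = pd.DataFrame(
        {
            "gene": genes,
            "log_fc": np.full(n, 2.0),
            "p_value": np.full(n, 1e-4),
            "fdr": fdr if fdr is not None else np.full(n, 1e-3),
            "is_deg": is_deg if is_deg is not None else np.ones(n, dtype=bool),
        }
    )
    return DEGTable(condition_id=condition, df=df)


class TestIntersect:
    def test_empty_deg_table(self):
        table = _deg_table(["A", "B"], is_deg=[False, False])
        result = intersect_driver_degs({"A", "B", "C"}, table)
        assert result.driver_degs == set()

    def test_set_intersection(self):
        table = _deg_table(["B", "C", "D"])
        result = intersect_driver_degs({"A", "B", "C"}, table)
        assert result.driver_degs == {"B", "C"}
        assert result.pct_of_network_drivers == pytest.approx(66.7)

    def test_empty_driver_set_warns(self):
        table = _deg_table(["A"])
        with pytest.warns(UserWarning, match="empty"):
            result = intersect_driver_degs(set(), table)
        assert result.pct_of_network_drivers == 0.0

    def test_planted_overlap_recovered_exactly(self, sparse_bundle):
        truth = sparse_bundle["truth"]
        degs = truth.planted_de_genes
        table = _deg_table(sorted(degs))
        result = intersect_driver_degs(truth.planted_driver_genes, table)
        assert result.driver_degs == truth.driver_de_genes


class TestSharedMatrix:
    def _result(self, cid, genes):
        from driverplex.pancancer import ConditionDriverResult

        return ConditionDriverResult(cid, set(genes), set(genes), 0.0)

    def test_shared_count_and_diagonal(self):
        a = self._result("A", ["g1", "g2", "g3", "g4"])
        b = self._result("B", ["g2", "g3", "g4", "g9"])
        sm = shared_driver_matrix([a, b])
        assert sm.matrix.loc["A", "B"] == 3
        assert sm.matrix.loc["A", "A"] == 4
        assert sm.matrix.loc["B", "B"] == 4

    def test_duplicate_condition_ids_rejected(self):
        a = self._result("A", ["g1"])
        with pytest.raises(ValueError, match="duplicate"):
            shared_driver_matrix([a, a])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pairwise_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        results = [
            self._result(f"C{j}", [g for g in genes if rng.random() < 0.4])
            for j in range(4)
        ]
        sm = shared_driver_matrix(results)
        assert (sm.matrix.to_numpy() == sm.matrix.to_numpy().T).all()
        for a in results:
            for b in results:
                assert sm.matrix.loc[a.condition_id, b.condition_id] == len(
                    a.driver_degs & b.driver_degs
                )


class TestFdrComparison:
    def test_identical_groups_when_drivers_are_all_degs(self):
        fdr = np.array([1e-5, 1e-4, 5e-3])
        table = _deg_table(["A", "B", "C"], fdr=fdr)
        out = fdr_comparison(table, {"A", "B", "C"}).set_index("group")
        assert out.loc["all_degs", "median"] == out.loc["driver_degs", "median"]
        assert out.loc["all_degs", "mean"] == out.loc["driver_degs", "mean"]

    def test_single_driver_gene(self):
        table = _deg_table(["A", "B"], fdr=[1e-5, 8e-3])
        out = fdr_comparison(table, {"B"}).set_index("group")
        assert out.loc["driver_degs", "median"] == pytest.approx(8e-3)
        assert out.loc["driver_degs", "mean"] == pytest.approx(8e-3)

    def test_driver_group_has_lower_fdr_with_stronger_effects(self):
        """Drivers planted with stronger effects show a smaller median FDR."""
        rng = np.random.default_rng(17)
        n = 200
        genes = [f"g{i}" for i in range(n)]
        drivers = set(genes[:40])
        fdr = rng.uniform(1e-3, 9e-3, size=n)
        fdr[:40] = rng.uniform(1e-8, 1e-4, size=40)  # stronger planted effects
        table = _deg_table(genes, fdr=fdr)
        out = fdr_comparison(table, drivers).set_index("group")
        assert out.loc["driver_degs", "median"] <= out.loc["all_degs", "median"]

    def test_unknown_driver_gene_is_error(self):
        table = _deg_table(["A"])
        with pytest.raises(ValueError, match="absent"):
            fdr_comparison(table, {"Z"})

    def test_empty_driver_set_warns(self):
        table = _deg_table(["A"])
        with pytest.warns(UserWarning, match="empty"):
            out = fdr_comparison(table, set())
        assert list(out["group"]) == ["all_degs"]


class TestPercentage:
    @pytest.mark.parametrize(
        "num,den,mode,expected",
        [
            (319, 895, "round1", 35.6),
            (90, 895, "truncate_int", 10),
            (61, 895, "round1", 6.8),
            (29, 895, "round1", 3.2),
            (17, 895, "round1", 1.9),
            (10, 895, "round1", 1.1),
            (895, 1322, "truncate_int", 67),
            (0, 50, "round1", 0.0),
        ],
    )
    def test_printed_conventions(self, num, den, mode, expected):
        assert percentage(num, den, mode) == expected

    def test_zero_denominator_is_error(self):
        with pytest.raises(ValueError):
            percentage(1, 0)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            den = int(rng.integers(1, 1000))
            num = int(rng.integers(0, den + 1))
            for mode in ("round1", "truncate_int"):
                v = percentage(num, den, mode)
                assert 0 <= v <= 100


class TestBenchmarkOverlap:
    TOOLS = {
        "tool_a": {"g1", "g2", "g3"},
        "tool_b": {"g2", "g3", "g4"},
        "tool_c": {"g3", "g9"},
    }

    def test_min_tools_above_count_is_empty(self):
        assert benchmark_overlap({"g1", "g2", "g3"}, self.TOOLS, min_tools=4) == set()

    def test_gene_in_exactly_two_tools(self):
        assert "g2" in benchmark_overlap({"g2"}, self.TOOLS, min_tools=2)
        assert "g2" not in benchmark_overlap({"g2"}, self.TOOLS, min_tools=3)

    def test_monotone_in_min_tools(self):
        drivers = {"g1", "g2", "g3", "g4", "g9"}
        previous = None
        for t in (1, 2, 3):
            current = benchmark_overlap(drivers, self.TOOLS, min_tools=t)
            if previous is not None:
                assert current <= previous
            previous = current

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_membership_tally(self, seed):
        rng = np.random.default_rng(300 + seed)
        genes = [f"g{i}" for i in range(50)]
        tools = {
            f"tool{j}": {g for g in genes if rng.random() < 0.3} for j in range(6)
        }
        drivers = {g for g in genes if rng.random() < 0.5}
        for t in (1, 2, 3):
            expected = {
                g for g in drivers
                if sum(g in s for s in tools.values()) >= t
            }
            assert benchmark_overlap(drivers, tools, min_tools=t) == expected

    def test_empty_tool_mapping_is_error(self):
        with pytest.raises(ValueError):
            benchmark_overlap({"g1"}, {}, min_tools=1)
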