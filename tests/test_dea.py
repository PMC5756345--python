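"""Differential expression: normalisation formula, Welch test calibration,
BH adjustment vs an independent step-up oracle, and DEG selection rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driverplex.datatypes import ExpressionMatrix, SampleLabels
from driverplex.dea import (
    bh_adjust,
    differential_test,
    normalize_counts,
    run_dea,
    select_degs,
)
from driverplex.simulate import GroundTruth, SimulationConfig, simulate_expression

from conftest import bh_oracle


def _matrix(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(counts=pd.DataFrame(values, index=genes, columns=samples))


def _labels(n_normal, n_tumour) -> SampleLabels:
    mapping = {f"S{i}": ("normal" if i < n_normal else "tumour") for i in range(n_normal + n_tumour)}
    return SampleLabels.from_mapping(mapping)


class TestNormalize:
    def test_formula_instantiation(self):
        em = _matrix([[0], [9]])
        norm = normalize_counts(em)
        # value(g, s) = log2(1e6 * (count+1) / (libsize + n_genes))
        assert norm.iloc[0, 0] == pytest.approx(np.log2(1e6 * 1 / (9 + 2)))
        assert norm.iloc[1, 0] == pytest.approx(np.log2(1e6 * 10 / (9 + 2)))

    def test_identical_samples_identical_columns(self):
        em = _matrix([[5, 5], [7, 7], [0, 0]])
        norm = normalize_counts(em)
        assert np.allclose(norm.iloc[:, 0], norm.iloc[:, 1])

    def test_library_scaling_cancels_on_large_libraries(self):
        rng = np.random.default_rng(0)
        base = rng.integers(100, 5000, size=400)
        base = (base * (1_000_000 / base.sum())).astype(int) + 1
        em = _matrix(np.column_stack([base, 2 * base]))
        norm = normalize_counts(em)
        diff = (norm.iloc[:, 1] - norm.iloc[:, 0]).to_numpy()
        assert np.abs(diff).max() < 1e-2  # pseudo-count residual only

    def test_all_zero_sample_is_error(self):
        em = _matrix([[0, 5], [0, 2]])
        with pytest.raises(ValueError, match="S0"):
            normalize_counts(em)


class TestWelch:
    def test_constant_gene(self):
        em = _matrix(np.full((1, 8), 3.0))
        out = differential_test(em.counts, _labels(4, 4))
        assert out.loc[0, "log_fc"] == 0.0
        assert out.loc[0, "p_value"] == 1.0

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(42)
        norm = pd.DataFrame(
            rng.normal(size=(2000, 60)),
            index=[f"G{i}" for i in range(2000)],
            columns=[f"S{i}" for i in range(60)],
        )
        out = differential_test(norm, _labels(30, 30))
        frac = (out["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_fold_change_has_tiny_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(1, 30))
        b = rng.normal(2, 1, size=(1, 30))
        norm = pd.DataFrame(
            np.column_stack([a, b]),
            index=["G0"],
            columns=[f"S{i}" for i in range(60)],
        )
        out = differential_test(norm, _labels(30, 30))
        assert out.loc[0, "p_value"] < 1e-6
        assert out.loc[0, "log_fc"] == pytest.approx(2.0, abs=0.8)

    def test_small_class_is_error(self):
        em = _matrix(np.ones((2, 3)))
        with pytest.raises(ValueError, match=">=2 samples"):
            differential_test(em.counts, _labels(1, 2))


class TestBH:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal(self):
        out = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_textbook_example(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert np.allclose(bh_adjust(p), bh_oracle(p))

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_stepup_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 50)))
        assert np.allclose(bh_adjust(p), bh_oracle(p))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_stepup_property(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        assert np.allclose(adj, bh_oracle(p))


class TestSelectDegs:
    def _table(self, log_fc, p):
        return pd.DataFrame({"gene": [f"G{i}" for i in range(len(log_fc))],
                             "log_fc": log_fc, "p_value": p})

    def test_boundary_logfc_excluded(self):
        table = select_degs(self._table([1.0], [1e-9]))
        assert not table.df.loc[0, "is_deg"]

    def test_down_regulated_deg(self):
        table = select_degs(self._table([-1.5], [1e-9]))
        assert table.df.loc[0, "is_deg"]
        assert table.df.loc[0, "fdr"] < 0.01

    def test_counts_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        raw = self._table(rng.normal(0, 2, 300), rng.random(300) ** 3)
        base = len(select_degs(raw).degs)
        stricter_fc = len(select_degs(raw, logfc_thr=2).degs)
        stricter_fdr = len(select_degs(raw, fdr_thr=0.001).degs)
        assert stricter_fc <= base and stricter_fdr <= base

    def test_nonpositive_threshold_is_error(self):
        with pytest.raises(ValueError):
            select_degs(self._table([1.0], [0.5]), logfc_thr=0)


class TestEndToEndDEA:
    def test_planted_de_genes_recovered(self):
        """50 planted |logFC|=2 genes among 1000 at n=40/class: >=45 flagged."""
        config = SimulationConfig(
            n_genes=1000, n_pathways=2, pathway_size_range=(5, 10),
            planted_drivers=0, n_decoy_de=50, planted_log_fc=2.0,
            n_samples_per_class=40, seed=33,
        )
        truth = GroundTruth()
        expr, labels = simulate_expression(config, truth)
        table = run_dea(expr, labels, "sim")
        assert len(truth.planted_de_genes) == 50
        recovered = table.degs & truth.planted_de_genes
        assert len(recovered) >= 45

    def test_permuted_labels_yield_no_degs(self):
        """Label permutation on a null matrix: DEG count stays at noise level."""
        config = SimulationConfig(
            n_genes=500, n_pathways=2, pathway_size_range=(5, 10),
            planted_drivers=0, n_decoy_de=0, n_samples_per_class=25, seed=8,
        )
        expr, labels = simulate_expression(config, GroundTruth())
        rng = np.random.default_rng(8)
        counts = []
        for _ in range(5):
            permuted = SampleLabels(
                labels=pd.Series(
                    rng.permutation(labels.labels.to_numpy()),
                    index=labels.labels.index, dtype=object,
                )
            )
            counts.append(len(run_dea(expr, permuted, "perm").degs))
        assert np.mean(counts) <= 2

    def test_all_zero_genes_dropped_with_warning(self):
        values = np.vstack([np.zeros(8), np.arange(1, 9)])
        em = _matrix(values)
        with pytest.warns(UserWarning, match="all-zero"):
            table = run_dea(em, _labels(4, 4))
        assert set(table.df["gene"]) == {"G1"}
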