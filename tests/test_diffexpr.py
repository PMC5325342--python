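"""Audic-Claverie test, fold changes, RPKM, BH adjustment and PCA."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vpaglio.diffexpr import (
    ac_conditional,
    ac_pvalue,
    all_differential_tables,
    bh_adjust,
    differential_table,
    fold_change,
    pca_top_variable,
    rpkm,
)
from vpaglio.io import DataValidationError
from vpaglio.simulate import gen_counts

from conftest import tiny_count_matrix

TWO_LINES = [("L1", "adherent", "naive"), ("L1", "adherent", "vpa")]


def conditional_pmf_rows(x_max: int, y_max: int, ratio: float) -> np.ndarray:
    """Independent oracle: p(y|x) by the multiplicative recurrence.

    p(0|x) = (1/(1+r))^(x+1);  p(y+1|x) = p(y|x) * r/(1+r) * (x+y+1)/(y+1).
    """
    xs = np.arange(x_max + 1, dtype=float)
    pmf = np.zeros((x_max + 1, y_max + 1))
    pmf[:, 0] = (1.0 / (1.0 + ratio)) ** (xs + 1)
    f = ratio / (1.0 + ratio)
    for y in range(y_max):
        pmf[:, y + 1] = pmf[:, y] * f * (xs + y + 1) / (y + 1)
    return pmf


def rational_conditional(y: int, x: int, ratio: Fraction) -> Fraction:
    return (
        ratio**y
        * comb(x + y, x)
        / (Fraction(1) + ratio) ** (x + y + 1)
    )


class TestConditional:
    def test_zero_zero_equal_libraries(self):
        assert ac_conditional(0, 0, 10**6, 10**6) == pytest.approx(0.5, abs=1e-15)

    def test_closed_form_equal_libraries(self):
        # N1=N2: p(y|x) = C(x+y, x) / 2^(x+y+1); x=2, y=1 -> 3/16
        assert ac_conditional(1, 2, 5e6, 5e6) == pytest.approx(0.1875, rel=1e-12)

    @pytest.mark.parametrize("ratio", [0.1, 0.5, 1.0, 2.0, 10.0])
    def test_normalizes_over_y(self, ratio):
        pmf = conditional_pmf_rows(0, 0, ratio)  # unused; direct sum below
        for x in (0, 1, 5, 23, 50):
            y = np.arange(0, 4000)
            total = ac_conditional(y, np.full_like(y, x), 1e6, ratio * 1e6).sum()
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_rational_arithmetic(self):
        for ratio in (Fraction(1, 2), Fraction(1), Fraction(2)):
            for x in (0, 3, 11, 30):
                for y in (0, 1, 7, 30):
                    exact = rational_conditional(y, x, ratio)
                    got = ac_conditional(y, x, 10**6, int(10**6 * ratio))
                    assert got == pytest.approx(float(exact), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(DataValidationError):
            ac_conditional(-1, 0, 1e6, 1e6)


class TestPvalue:
    def test_full_tail_is_one(self):
        assert ac_pvalue(0, 0, 1e6, 1e6, "up") == 1.0

    def test_equal_counts_two_sided_large(self):
        assert ac_pvalue(10, 10, 1e6, 1e6, "two_sided") > 0.5

    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
    def test_matches_bruteforce_tails(self, ratio):
        x_max, y_max = 60, 60
        pmf = conditional_pmf_rows(x_max, 2000, ratio)
        up_suffix = pmf[:, ::-1].cumsum(axis=1)[:, ::-1]
        down_prefix = pmf.cumsum(axis=1)
        xs, ys = np.meshgrid(np.arange(x_max + 1), np.arange(y_max + 1), indexing="ij")
        up = ac_pvalue(xs.ravel(), ys.ravel(), 1e6, ratio * 1e6, "up").reshape(xs.shape)
        down = ac_pvalue(xs.ravel(), ys.ravel(), 1e6, ratio * 1e6, "down").reshape(xs.shape)
        np.testing.assert_allclose(up, up_suffix[:, : y_max + 1], rtol=1e-10)
        np.testing.assert_allclose(down, down_prefix[:, : y_max + 1], rtol=1e-10)

    def test_tails_partition_with_point_mass(self):
        # P(Y >= y) + P(Y <= y) = 1 + p(y|x): both tails include the point mass
        rng = np.random.default_rng(0)
        for _ in range(100):
            x, y = rng.integers(0, 300, 2)
            n1, n2 = rng.integers(10**5, 10**7, 2)
            up = ac_pvalue(x, y, n1, n2, "up")
            down = ac_pvalue(x, y, n1, n2, "down")
            pmf = ac_conditional(y, x, n1, n2)
            assert up + down == pytest.approx(1.0 + pmf, rel=1e-10)

    def test_up_tail_monotone_in_y(self):
        y = np.arange(0, 200)
        p = ac_pvalue(np.full_like(y, 20), y, 1e6, 2e6, "up")
        assert (np.diff(p) <= 1e-15).all()


class TestFoldChange:
    def test_definition(self):
        assert fold_change(10, 50, 1e6, 1e6, pseudo=0) == pytest.approx(5.0)

    def test_identity(self):
        assert fold_change(7, 7, 3e6, 3e6, pseudo=0.5) == pytest.approx(1.0)

    def test_zero_with_zero_pseudo_rejected(self):
        with pytest.raises(DataValidationError):
            fold_change(0, 5, 1e6, 1e6, pseudo=0)

    @given(
        x=st.integers(0, 1000),
        y=st.integers(0, 1000),
        p1=st.floats(0.01, 5),
        p2=st.floats(0.01, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_pseudo_moves_fc_toward_one(self, x, y, p1, p2):
        lo, hi = sorted([p1, p2])
        f_lo = fold_change(x, y, 1e6, 2e6, pseudo=lo)
        f_hi = fold_change(x, y, 1e6, 2e6, pseudo=hi)
        assert abs(np.log(f_hi)) <= abs(np.log(f_lo)) + 1e-12


class TestBH:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    def test_uniform_and_single(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(bh_adjust([0.07]), [0.07])

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(DataValidationError):
                bh_adjust(bad)


class TestRpkm:
    def test_definition_and_zero(self, small_annotation):
        g = small_annotation.gene_ids[0]
        length = small_annotation.table.loc[g, "exonic_length"]
        cm = tiny_count_matrix(np.array([[10, 0]]), [g], TWO_LINES)
        expr = rpkm(cm, small_annotation)
        assert expr.values.iloc[0, 0] == pytest.approx(10 * 1e9 / (length * 1e6))
        assert expr.values.iloc[0, 1] == 0.0

    def test_matches_per_cell_recomputation(self, small_annotation, poisson_dataset):
        cm, _ = poisson_dataset
        expr = rpkm(cm, small_annotation)
        rng = np.random.default_rng(1)
        for _ in range(30):
            gi = rng.integers(0, len(cm.gene_ids))
            si = rng.integers(0, len(cm.samples))
            g, s = cm.gene_ids[gi], cm.samples[si]
            expected = (
                cm.counts.iloc[gi, si]
                * 1e9
                / (small_annotation.table.loc[g, "exonic_length"] * s.library_size)
            )
            assert expr.values.iloc[gi, si] == pytest.approx(expected, rel=1e-12)

    def test_missing_annotation_listed(self, small_annotation):
        cm = tiny_count_matrix(np.array([[1, 1]]), ["NOPE"], TWO_LINES)
        with pytest.raises(DataValidationError, match="NOPE"):
            rpkm(cm, small_annotation)


class TestDifferentialTable:
    def test_planted_gene_flagged_up(self):
        x = np.full(200, 50)
        counts = np.column_stack([x, x.copy()])
        counts[0] = [5, 500]
        cm = tiny_count_matrix(counts, [f"g{i:03d}" for i in range(200)], TWO_LINES)
        df = differential_table(cm, "L1")
        row = df.set_index("gene_id").loc["g000"]
        assert row["direction"] == "up" and row["q"] < 0.01
        assert (df.set_index("gene_id")["direction"].drop("g000") == "none").all()

    def test_equal_counts_no_calls(self):
        counts = np.tile([[20, 20]], (50, 1))
        cm = tiny_count_matrix(counts, [f"g{i}" for i in range(50)], TWO_LINES)
        df = differential_table(cm, "L1")
        assert (df["direction"] == "none").all()

    def test_gene_order_permutation_only_permutes_rows(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(30, (40, 2))
        genes = [f"g{i}" for i in range(40)]
        cm = tiny_count_matrix(counts, genes, TWO_LINES)
        perm = rng.permutation(40)
        cm2 = tiny_count_matrix(counts[perm], [genes[i] for i in perm], TWO_LINES)
        a = differential_table(cm, "L1").set_index("gene_id").sort_index()
        b = differential_table(cm2, "L1").set_index("gene_id").sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_missing_condition_rejected(self):
        cm = tiny_count_matrix(
            np.ones((3, 2), dtype=int),
            ["a", "b", "c"],
            [("L1", "adherent", "naive"), ("L2", "adherent", "naive")],
        )
        with pytest.raises(DataValidationError, match="vpa"):
            differential_table(cm, "L1")

    def test_planted_recovery_sensitivity_and_fdr(self, small_annotation):
        """Poisson-mode calibration: >=4-fold planted genes recovered per line."""
        cm, truth = gen_counts(
            small_annotation, seed=33, noise="poisson", support_per_lineage=7,
            frac_up=0.1, effect_log2_range=(2.0, 3.0), family_size=10, n_family_planted=5,
            n_subtype_genes=0,  # no subtype blocks: planted genes are the only effects
        )
        planted = set(truth.planted_up)
        sens, fdrs = [], []
        for line, df in all_differential_tables(cm).items():
            called = set(df.loc[df["direction"] == "up", "gene_id"])
            sens.append(len(called & planted) / len(planted))
            fdrs.append(len(called - planted) / max(1, len(called)))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdrs) <= 0.05


class TestPca:
    def test_planted_groups_separate_on_pc1(self):
        """Two duplicated sample groups with a block of shifted genes split on PC1."""
        from vpaglio.diffexpr import ExpressionMatrix
        from vpaglio.io import SampleMeta

        rng = np.random.default_rng(9)
        n_genes, n_per_group = 500, 5
        base = rng.lognormal(2, 1, n_genes)
        cols, names = [], []
        for grp, shift in (("A", 1.0), ("B", 8.0)):
            for i in range(n_per_group):
                v = base.copy()
                v[:100] *= shift  # planted group-distinguishing block
                cols.append(v * rng.lognormal(0, 0.05, n_genes))
                names.append(f"{grp}{i}")
        samples = [
            SampleMeta(n, n, "adherent" if n.startswith("A") else "stem",
                       "naive", 10**6)
            for n in names
        ]
        vals = pd.DataFrame(np.column_stack(cols), index=[f"g{i:03d}" for i in range(n_genes)],
                            columns=names)
        expr = ExpressionMatrix(values=vals, samples=samples)
        scores, loadings, varexp = pca_top_variable(expr, n_top=300)
        a = scores.loc[[n for n in names if n.startswith("A")], "PC1"]
        b = scores.loc[[n for n in names if n.startswith("B")], "PC1"]
        assert a.max() < b.min() or b.max() < a.min()
        assert varexp.sum() <= 1.0 + 1e-12
        assert (np.diff(varexp) <= 1e-12).all()

    def test_constant_matrix_rejected(self):
        from vpaglio.diffexpr import ExpressionMatrix
        from vpaglio.io import SampleMeta

        samples = [
            SampleMeta(f"L{i}_naive", f"L{i}", "adherent", "naive", 100) for i in range(4)
        ]
        vals = pd.DataFrame(np.ones((10, 4)), index=[f"g{i}" for i in range(10)],
                            columns=[s.sample_id for s in samples])
        expr = ExpressionMatrix(values=vals, samples=samples)
        with pytest.raises(DataValidationError, match="constant"):
            pca_top_variable(expr, n_top=10)
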