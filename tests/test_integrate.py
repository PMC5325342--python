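"""Consensus filtering, fold-change tiers and family enrichment."""

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest

from vpaglio.integrate import (
    consensus_upregulated,
    euchromatin_consensus,
    family_enrichment,
    family_enrichment_counts,
    fc_tier_table,
)
from vpaglio.io import DataValidationError
from vpaglio.simulate import gen_annotation, gen_counts
from vpaglio.diffexpr import all_differential_tables


def de_table(line, support_genes, all_genes, fc=6.0, q=0.001):
    """Minimal DE table: support_genes called up at the given fc/q."""
    rows = []
    for g in all_genes:
        if g in support_genes:
            rows.append((g, line, fc, q, "up"))
        else:
            rows.append((g, line, 1.0, 1.0, "none"))
    return pd.DataFrame(rows, columns=["gene_id", "cell_line", "fc", "q", "direction"])


GENES = ["g1", "g2", "g3"]
LINEAGES_4 = {"A1": "adherent", "A2": "adherent", "S1": "stem", "S2": "stem"}


class TestConsensus:
    def test_full_support_included_and_boundary_excluded(self):
        lineages = {f"A{i}": "adherent" for i in range(1, 8)}
        lineages.update({f"S{i}": "stem" for i in range(1, 8)})
        # g1: 7/7 + 7/7; g2: 4/7 + 3/7 -> excluded under the 4-of-7-in-both rule
        tables = {}
        for i in range(1, 8):
            adh_sup = {"g1"} | ({"g2"} if i <= 4 else set())
            stem_sup = {"g1"} | ({"g2"} if i <= 3 else set())
            tables[f"A{i}"] = de_table(f"A{i}", adh_sup, GENES)
            tables[f"S{i}"] = de_table(f"S{i}", stem_sup, GENES)
        sig = consensus_upregulated(tables, lineages, fc_cutoff=5.0, min_support=4)
        assert sig.genes == ["g1"]
        assert sig.support.loc["g2"].tolist() == [4, 3]

    def test_exhaustive_toy_matches_enumeration(self):
        """All 2^12 support patterns of 3 genes x (2,2) lines, min_support 2."""
        lines = list(LINEAGES_4)
        for bits in range(2**12):
            pattern = [(bits >> k) & 1 for k in range(12)]
            support = {
                line: {GENES[j] for j in range(3) if pattern[i * 3 + j]}
                for i, line in enumerate(lines)
            }
            tables = {line: de_table(line, support[line], GENES) for line in lines}
            sig = consensus_upregulated(tables, LINEAGES_4, fc_cutoff=5.0, min_support=2)
            expected = [
                g
                for g in GENES
                if sum(g in support[l] for l in ("A1", "A2")) >= 2
                and sum(g in support[l] for l in ("S1", "S2")) >= 2
            ]
            assert sorted(sig.genes) == sorted(expected)

    def test_too_few_lines_rejected(self):
        tables = {l: de_table(l, set(), GENES) for l in LINEAGES_4}
        with pytest.raises(DataValidationError, match="fewer than min_support"):
            consensus_upregulated(tables, LINEAGES_4, min_support=3)

    def test_missing_gene_counts_as_nonsupporting(self):
        tables = {l: de_table(l, {"g1"}, GENES) for l in LINEAGES_4}
        tables["A1"] = tables["A1"][tables["A1"].gene_id != "g1"]  # g1 absent in A1
        sig = consensus_upregulated(tables, LINEAGES_4, fc_cutoff=5.0, min_support=2)
        assert sig.support.loc["g1", "n_adherent_up"] == 1
        assert sig.genes == []


class TestTierTable:
    def _random_tables(self, rng, n_genes=60):
        genes = [f"g{i}" for i in range(n_genes)]
        tables = {}
        for line in LINEAGES_4:
            fc = np.exp(rng.normal(0.5, 1.2, n_genes))
            q = np.where(rng.random(n_genes) < 0.4, 0.001, 0.5)
            tables[line] = pd.DataFrame(
                {"gene_id": genes, "cell_line": line, "fc": fc, "q": q,
                 "direction": np.where((q < 0.01) & (fc > 1), "up", "none")}
            )
        return genes, tables

    def test_nesting_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            genes, tables = self._random_tables(rng)
            tier_df, lists = fc_tier_table(tables, LINEAGES_4, min_support=2)
            sets = [set(lists[c]["expression"]) for c in (5.0, 4.0, 3.0, 2.0)]
            assert sets[0] <= sets[1] <= sets[2] <= sets[3]
            assert tier_df["n_expression"].is_monotonic_increasing

    def test_all_false_euchromatin_zero_intersections(self):
        rng = np.random.default_rng(1)
        genes, tables = self._random_tables(rng)
        eu = pd.DataFrame(False, index=genes, columns=list(LINEAGES_4))
        tier_df, lists = fc_tier_table(tables, LINEAGES_4, euchromatin=eu, min_support=2)
        assert (tier_df["n_expression_and_euchromatin"] == 0).all()

    def test_gene_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        genes, tables = self._random_tables(rng)
        eu = pd.DataFrame(True, index=genes[:10], columns=list(LINEAGES_4))
        with pytest.raises(DataValidationError, match="absent from euchromatin"):
            fc_tier_table(tables, LINEAGES_4, euchromatin=eu, min_support=2)

    def test_increasing_cutoffs_rejected(self):
        rng = np.random.default_rng(3)
        genes, tables = self._random_tables(rng)
        with pytest.raises(ValueError, match="strictly decreasing"):
            fc_tier_table(tables, LINEAGES_4, cutoffs=(2.0, 5.0), min_support=2)

    def test_planted_tier_structure_recovered(self, small_annotation, lineages14):
        """Genes planted at exact fold changes appear at the right tiers."""
        genes = small_annotation.gene_ids
        effects = {genes[i]: e for i, e in enumerate(
            [np.log2(8)] * 2 + [np.log2(4.5)] * 2 + [np.log2(3.5)] * 2 + [np.log2(2.5)] * 2
        )}
        cm, truth = gen_counts(
            small_annotation, seed=77, noise="poisson", support_per_lineage=7,
            planted_effects=effects, n_subtype_genes=0,
            planted_base_cpm_range=(20.0, 50.0),  # high enough that the CPM
            # pseudo-count barely shrinks the observed fold change
        )
        tables = all_differential_tables(cm)
        _, lists = fc_tier_table(tables, lineages14)
        got = [len(lists[c]["expression"]) for c in (5.0, 4.0, 3.0, 2.0)]
        assert got == [2, 4, 6, 8]


def enrichment_oracle(k, n, K, N):
    """Exhaustive hypergeometric tail with the margins of [[k, n-k], [K, N-K]]."""
    col1, col2, draws = k + K, (n - k) + (N - K), n
    total = comb(col1 + col2, draws)
    p = Fraction(0)
    for kk in range(k, min(draws, col1) + 1):
        if draws - kk <= col2:
            p += Fraction(comb(col1, kk) * comb(col2, draws - kk), total)
    return float(p)


class TestFamilyEnrichment:
    def test_zero_overlap_full_tail(self):
        assert family_enrichment_counts(0, 50, 10, 1000).p == pytest.approx(1.0)

    def test_matches_exhaustive_oracle_small(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(10, 61))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            got = family_enrichment_counts(k, n, K, N).p
            assert got == pytest.approx(enrichment_oracle(k, n, K, N), rel=1e-10)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(DataValidationError):
            family_enrichment_counts(20, 10, 30, 100)

    def test_order_and_duplicate_invariance(self):
        lst = [f"g{i}" for i in range(30)]
        fam = [f"g{i}" for i in range(20, 50)]
        a = family_enrichment(lst, fam, N=200)
        b = family_enrichment(lst[::-1], fam[::-1], N=200)
        with pytest.warns(UserWarning, match="duplicate"):
            c = family_enrichment(lst + lst[:3], fam, N=200)
        assert a.p == b.p == c.p and a.k == 10

    def test_expected_and_odds_ratio(self):
        res = family_enrichment_counts(16, 497, 397, 46111)
        assert res.expected == pytest.approx(497 * 397 / 46111)
        assert res.odds_ratio == pytest.approx((16 / 481) / (397 / 45714))


class TestEndToEndFamilyRecovery:
    def test_planted_family_enriched(self, lineages14):
        """30-member family, 12 planted across all lines: p < 1e-3 at fc >= 2."""
        ann = gen_annotation(1500, seed=55)
        cm, truth = gen_counts(ann, seed=56, family_size=30, n_family_planted=12)
        tables = all_differential_tables(cm)
        _, lists = fc_tier_table(tables, lineages14)
        res = family_enrichment(lists[2.0]["expression"], truth.family, N=1500)
        assert res.p < 1e-3


class TestEuchromatinConsensus:
    def test_majority_rule(self):
        cols = [f"A{i}" for i in range(1, 8)] + [f"S{i}" for i in range(1, 8)]
        lineages = {c: ("adherent" if c.startswith("A") else "stem") for c in cols}
        mat = pd.DataFrame(False, index=["g1", "g2"], columns=cols)
        mat.loc["g1", ["A1", "A2", "A3", "A4", "S1", "S2", "S3", "S4"]] = True
        mat.loc["g2", ["A1", "A2", "A3", "A4", "S1", "S2", "S3"]] = True
        assert euchromatin_consensus(mat, lineages, min_support=4) == ["g1"]
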