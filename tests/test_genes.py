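"""Closest-gene sets, promoter-window flags, RPKM/DE, odds ratio, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

import mscc
from mscc.genes import (
    ContingencyTable,
    EnrichmentInput,
    enrichment_fold,
    enrichment_test,
    flag_window_dm,
    hypergeom_tail,
    odds_ratio,
    rpkm,
)
from mscc.io import Gene


@pytest.fixture
def one_gene_plus():
    return [Gene("g1", "c", 5000, 7000, "+")]


@pytest.fixture
def one_gene_minus():
    # TSS at end-1 = 4999 so the strand-reflected window mirrors the plus case
    return [Gene("g1", "c", 3000, 5000, "-")]


class TestClosestGene:
    def test_single_methylated_dms(self, one_gene_plus):
        tab = pd.DataFrame({"direction": ["methylated"]}, index=["c:5100"])
        met, unmet = mscc.assign_closest_gene(tab, one_gene_plus)
        assert met == {"g1"} and unmet == set()

    def test_gene_can_sit_in_both_sets(self, one_gene_plus):
        tab = pd.DataFrame(
            {"direction": ["methylated", "demethylated"]}, index=["c:5100", "c:4900"]
        )
        met, unmet = mscc.assign_closest_gene(tab, one_gene_plus)
        assert met == {"g1"} and unmet == {"g1"}

    def test_matches_brute_force_nearest(self, default_dataset):
        ds = default_dataset
        tab = mscc.call_dms(ds.counts, ds.design, fdr=0.05)
        met, unmet = mscc.assign_closest_gene(tab, ds.genes)
        brute_met, brute_unmet = set(), set()
        for key, row in tab[tab["direction"] != "none"].iterrows():
            chrom, pos = key.rsplit(":", 1)
            pos = int(pos)
            cands = [
                (abs(pos - g.tss), g.gene_id) for g in ds.genes if g.chrom == chrom
            ]
            if not cands:
                continue
            _, gid = min(cands)
            (brute_met if row["direction"] == "methylated" else brute_unmet).add(gid)
        assert met == brute_met and unmet == brute_unmet


class TestWindowFlag:
    @pytest.mark.parametrize(
        "pos,expected",
        [(2000, True), (1999, False), (7000, True), (7001, False), (5000, True)],
    )
    def test_plus_strand_closed_boundaries(self, one_gene_plus, pos, expected):
        flags = flag_window_dm(one_gene_plus, [f"c:{pos}"])
        assert bool(flags["g1"]) is expected

    @pytest.mark.parametrize(
        "pos,expected",
        # minus-strand mirror: TSS 4999, upstream is larger coordinates
        [(7999, True), (8000, False), (2999, True), (2998, False), (4999, True)],
    )
    def test_minus_strand_mirror(self, one_gene_minus, pos, expected):
        flags = flag_window_dm(one_gene_minus, [f"c:{pos}"])
        assert bool(flags["g1"]) is expected

    def test_matches_brute_force_interval_search(self, default_dataset):
        ds = default_dataset
        sites = ds.catalog.site_keys()[::11]
        flags = flag_window_dm(ds.genes, sites, upstream=3000, downstream=2000)
        for g in ds.genes:
            expected = False
            for key in sites:
                chrom, pos = key.rsplit(":", 1)
                if chrom != g.chrom:
                    continue
                signed = (int(pos) - g.tss) if g.strand == "+" else (g.tss - int(pos))
                if -3000 <= signed <= 2000:
                    expected = True
                    break
            assert bool(flags[g.gene_id]) is expected


class TestRPKM:
    def test_unit_definition(self):
        assert rpkm(10, 1_000, 1_000_000) == pytest.approx(10.0)
        assert rpkm(0, 1_000, 1_000_000) == 0.0

    def test_scaling_laws(self):
        assert rpkm(10, 1_000, 2_000_000) == pytest.approx(5.0)
        assert rpkm(10, 2_000, 1_000_000) == pytest.approx(5.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


class TestCallDE:
    def test_identical_groups_no_calls(self, default_dataset):
        cfg = mscc.SimConfig(seed=21, de_fraction=0.0)
        counts, design, truth = mscc.simulate_expression_counts(default_dataset.genes, cfg)
        de = mscc.call_de(counts, design, truth["exon_length"])
        assert not de["is_de"].any() or de["is_de"].mean() < 0.1

    def test_planted_folds_recovered_with_concordant_direction(self, default_dataset):
        hits = total = 0
        for seed in range(10):
            cfg = mscc.SimConfig(seed=seed, de_fraction=0.3, de_fold=4.0,
                                 expression_depth=1e6)
            counts, design, truth = mscc.simulate_expression_counts(
                default_dataset.genes, cfg
            )
            de = mscc.call_de(counts, design, truth["exon_length"])
            planted = truth.index[truth["is_de"]]
            total += len(planted)
            hits += (
                de.loc[planted, "is_de"]
                & (de.loc[planted, "direction"] == truth.loc[planted, "direction"])
            ).sum()
        assert hits / total >= 0.95

    def test_infinite_fold_cut_empties_de_set(self, default_dataset):
        cfg = mscc.SimConfig(seed=3, de_fraction=0.2)
        counts, design, truth = mscc.simulate_expression_counts(default_dataset.genes, cfg)
        de = mscc.call_de(counts, design, truth["exon_length"], fold_cut=math.inf)
        assert not de["is_de"].any()


class TestOddsRatio:
    def test_no_association(self):
        assert odds_ratio(ContingencyTable(10, 10, 10, 10)) == 1.0

    def test_formula_read_off(self):
        assert odds_ratio(ContingencyTable(a=30, b=10, c=20, d=40)) == pytest.approx(6.0)

    def test_divergent_and_undefined(self):
        assert odds_ratio(ContingencyTable(5, 0, 3, 7)) == math.inf
        with pytest.raises(ValueError, match="margin"):
            odds_ratio(ContingencyTable(0, 0, 3, 7))

    @settings(max_examples=50, derandomize=True)
    @given(st.tuples(*[st.integers(min_value=1, max_value=500)] * 4))
    def test_algebraic_oracle_and_transpose_invariance(self, cells):
        a, b, c, d = cells
        t = ContingencyTable(a, b, c, d)
        assert odds_ratio(t) == pytest.approx((a * d) / (b * c))
        # swapping the roles of the two classifications transposes the table
        assert odds_ratio(ContingencyTable(a, c, b, d)) == pytest.approx(odds_ratio(t))


class TestEnrichmentFold:
    def test_published_worked_examples(self):
        assert enrichment_fold(EnrichmentInput(24410, 5797, 6216, 1688)) == pytest.approx(
            1.14, abs=0.005
        )
        assert enrichment_fold(EnrichmentInput(24113, 2, 760, 2)) == pytest.approx(
            31.73, abs=0.005
        )

    def test_no_enrichment_is_unity(self):
        assert enrichment_fold(EnrichmentInput(100, 20, 10, 2)) == pytest.approx(1.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            enrichment_fold(EnrichmentInput(10, 0, 5, 0))

    def test_full_regression_table(self):
        """Every stored (N,B,n,b) quadruple reproduces its published fold at
        two decimals."""
        tab = mscc.go_enrichment_examples()
        for row in tab.itertuples():
            fold = enrichment_fold(EnrichmentInput(row.N, row.B, row.n, row.b))
            assert round(fold, 2) == pytest.approx(row.fold, abs=1e-9), row.term


class TestEnrichmentTest:
    def test_extreme_overlap_combinatorial_oracle(self):
        # all 5 target genes carry the term held by 5 of 10 background genes
        p = hypergeom_tail(EnrichmentInput(10, 5, 5, 5))
        assert p == pytest.approx(1 / special.comb(10, 5), rel=1e-12)

    def test_whole_background_term_gives_p1_fold1(self):
        inp = EnrichmentInput(50, 50, 10, 10)
        assert hypergeom_tail(inp) == pytest.approx(1.0)
        assert enrichment_fold(inp) == pytest.approx(1.0)

    def test_tail_equals_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            N = int(rng.integers(5, 31))
            B = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            b = int(rng.integers(0, min(B, n) + 1))
            brute = sum(
                special.comb(B, k, exact=True) * special.comb(N - B, n - k, exact=True)
                for k in range(b, min(B, n) + 1)
            ) / special.comb(N, n, exact=True)
            assert hypergeom_tail(EnrichmentInput(N, B, n, b)) == pytest.approx(brute, rel=1e-9)

    def test_monotone_decreasing_in_b(self):
        ps = [hypergeom_tail(EnrichmentInput(100, 30, 20, b)) for b in range(0, 15)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_end_to_end_term_table(self):
        term_map = pd.DataFrame(
            {
                "term": ["stress"] * 4 + ["growth"] * 3,
                "gene": ["g1", "g2", "g3", "g4", "g4", "g5", "g6"],
            }
        )
        res = enrichment_test(["g1", "g2", "g3"], term_map)
        assert res.loc["stress", "b"] == 3 and res.loc["stress", "N"] == 6
        assert res.loc["growth", "b"] == 0
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_stray_target_gene_rejected(self):
        term_map = pd.DataFrame({"term": ["t"], "gene": ["g1"]})
        with pytest.raises(ValueError, match="absent"):
            enrichment_test(["gX"], term_map)
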