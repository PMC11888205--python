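"""Expression strata, gene association windows, colocalization, loops,
activity correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhancerkit.genes import (ExpressionTable, GeneModel, Loop,
                               associate_elements_to_genes, classify_stratum,
                               colocalization_fraction, distance_to_point,
                               filter_active_genes, loop_candidates,
                               normalize_counts, pearson_r, read_gene_models,
                               stratum_association_fractions)
from enhancerkit.intervals import Interval, IntervalSet
from .conftest import random_interval_set


class TestNormalizeCounts:
    def test_reference_depth_is_identity(self):
        df = pd.DataFrame({"s1": [10, 20]}, index=["g1", "g2"])
        out = normalize_counts(df, {"s1": 56.5e6})
        pd.testing.assert_frame_equal(out, df.astype(float))

    def test_double_depth_halves_counts(self):
        df = pd.DataFrame({"s1": [10.0, 20.0]}, index=["g1", "g2"])
        out = normalize_counts(df, {"s1": 113e6})
        assert list(out["s1"]) == [5.0, 10.0]

    def test_matches_elementwise_recomputation(self, rng):
        df = pd.DataFrame(rng.integers(0, 100, (5, 3)).astype(float),
                          columns=["a", "b", "c"])
        totals = {"a": 30e6, "b": 56.5e6, "c": 90e6}
        out = normalize_counts(df, totals)
        for col in df.columns:
            np.testing.assert_allclose(out[col], df[col] * 56.5e6 / totals[col])

    def test_nonpositive_totals_rejected(self):
        df = pd.DataFrame({"s1": [1.0]})
        with pytest.raises(ValueError, match="s1"):
            normalize_counts(df, {"s1": 0})


class TestActiveGeneFilter:
    def test_fpkm_threshold_is_inclusive(self):
        expr = ExpressionTable(fpkm=pd.DataFrame({"s1": [1.0, 0.999, 0.0]},
                                                 index=["a", "b", "c"]))
        assert filter_active_genes(expr, "fpkm") == ["a"]

    def test_mean_count_threshold_is_strict(self):
        expr = ExpressionTable(counts=pd.DataFrame(
            {"s1": [1.0, 1.5, 0.0]}, index=["a", "b", "c"]))
        assert filter_active_genes(expr, "mean_count") == ["b"]

    def test_missing_values_dropped_with_log(self, caplog):
        expr = ExpressionTable(fpkm=pd.DataFrame(
            {"s1": [2.0, np.nan], "s2": [2.0, 5.0]}, index=["a", "b"]))
        with caplog.at_level("INFO"):
            assert filter_active_genes(expr, "fpkm") == ["a"]


class TestClassifyStratum:
    @pytest.mark.parametrize("fpkm,expected", [
        (0.0, "inactive"), (0.99, "inactive"),
        (1.0, "low"), (4.99, "low"),
        (5.0, "mid"), (14.999, "mid"),
        (15.0, "high"), (1000.0, "high"),
    ])
    def test_boundaries(self, fpkm, expected):
        assert classify_stratum(fpkm) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_stratum(-0.1)

    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_total_partition(self, fpkm):
        assert classify_stratum(fpkm) in ("inactive", "low", "mid", "high")


class TestAssociation:
    def test_window_edge_inclusive(self):
        el = IntervalSet("e", [Interval("c", 140000, 141000)])
        genes = [GeneModel("g", "c", "+", 50000)]
        [a] = associate_elements_to_genes(el, genes, 100000)
        assert a.gene_id == "g" and a.distance == 90000

    def test_beyond_window_excluded(self):
        el = IntervalSet("e", [Interval("c", 0, 1000)])
        genes = [GeneModel("g", "c", "+", 1000 - 1 + 100001)]
        assert associate_elements_to_genes(el, genes, 100000) == []

    def test_all_genes_in_window_reported(self):
        el = IntervalSet("e", [Interval("c", 0, 1000)])
        genes = [GeneModel(f"g{i}", "c", "+", 2000 + i * 10000) for i in range(5)]
        assocs = associate_elements_to_genes(el, genes, 100000)
        assert {a.gene_id for a in assocs} == {f"g{i}" for i in range(5)}

    def test_matches_all_pairs_brute_force(self, rng):
        els = random_interval_set(rng, 60, 500_000)
        genes = [GeneModel(f"g{i}", "chrA", "+", int(rng.integers(0, 500_000)))
                 for i in range(60)]
        got = {(a.element, a.gene_id) for a in
               associate_elements_to_genes(els, genes, 50_000)}
        expected = {(iv, g.gene_id) for iv in els.intervals for g in genes
                    if iv.chrom == g.chrom
                    and distance_to_point(iv, g.tss) <= 50_000}
        assert got == expected


class TestStratumFractions:
    def test_every_element_near_high_gene(self):
        els = IntervalSet("e", [Interval("c", i * 1_000_000, i * 1_000_000 + 100)
                                for i in range(4)])
        genes = [GeneModel(f"g{i}", "c", "+", i * 1_000_000 + 500)
                 for i in range(4)]
        assoc = associate_elements_to_genes(els, genes)
        strata = {f"g{i}": "high" for i in range(4)}
        fracs = stratum_association_fractions(els, assoc, strata)
        assert fracs == {"inactive": 0.0, "low": 0.0, "mid": 0.0, "high": 1.0}

    def test_no_associations_all_zero(self):
        els = IntervalSet("e", [Interval("c", 0, 10)])
        fracs = stratum_association_fractions(els, [], {})
        assert set(fracs.values()) == {0.0}

    def test_zero_elements_rejected(self):
        with pytest.raises(ValueError):
            stratum_association_fractions(IntervalSet("e", []), [], {})


class TestColocalization:
    def test_full_cover_is_100(self):
        els = IntervalSet("e", [Interval("c", 10, 20), Interval("c", 50, 60)])
        occ = IntervalSet("o", [Interval("c", 0, 100)])
        assert colocalization_fraction(els, occ) == 100.0

    def test_empty_occupancy_is_0(self):
        els = IntervalSet("e", [Interval("c", 10, 20)])
        assert colocalization_fraction(els, IntervalSet("o", [])) == 0.0

    def test_invariant_to_shuffling_and_renaming(self, rng):
        els = random_interval_set(rng, 50, 50_000)
        occ = random_interval_set(rng, 20, 50_000)
        base = colocalization_fraction(els, occ)
        perm = rng.permutation(len(els.intervals))
        shuffled = IntervalSet("e", [els.intervals[i] for i in perm])
        assert colocalization_fraction(shuffled, occ) == base
        renamed = lambda s: IntervalSet(s.label, [
            Interval("chrZ", iv.start, iv.end) for iv in s.intervals])
        assert colocalization_fraction(renamed(els), renamed(occ)) == base


class TestLoopCandidates:
    def test_span_containment(self):
        loops = [Loop(Interval("c", 0, 10000), Interval("c", 90000, 100000))]
        gene = GeneModel("g", "c", "+", 5000)
        peaks = IntervalSet("p", [Interval("c", 20000, 21000),
                                  Interval("c", 150000, 151000)])
        sel, cands = loop_candidates(loops, gene, peaks)
        assert len(sel) == 1
        assert cands.intervals == [Interval("c", 20000, 21000)]

    def test_tss_outside_anchors_selects_nothing(self, caplog):
        loops = [Loop(Interval("c", 0, 10000), Interval("c", 90000, 100000))]
        gene = GeneModel("g", "c", "+", 200000)
        with caplog.at_level("INFO"):
            sel, cands = loop_candidates(loops, gene, IntervalSet("p", []))
        assert sel == [] and len(cands) == 0

    def test_trans_loop_rejected(self):
        with pytest.raises(ValueError, match="cis"):
            Loop(Interval("c1", 0, 10), Interval("c2", 0, 10))


class TestPearson:
    def test_perfect_correlation(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 0.75, sd_x = sd_y = sqrt(1.25) -> r = 0.6
        assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestGeneModelIO:
    def test_span_tsv_uses_strand_for_tss(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("gene_id\tchrom\tstrand\tstart\tend\n"
                     "a\tc\t+\t100\t200\nb\tc\t-\t100\t200\n")
        a, b = read_gene_models(p)
        assert a.tss == 100 and b.tss == 199

    def test_tss_column_overrides(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("gene_id\tchrom\tstrand\tstart\tend\ttss\n"
                     "a\tc\t-\t100\t200\t150\n")
        [g] = read_gene_models(p)
        assert g.tss == 150
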