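"""Synthetic-data generators: determinism, construction validity, truth tables."""

import numpy as np
import pandas as pd
import pytest

from enhancerkit.genes import (classify_stratum, colocalization_fraction,
                               loop_candidates, normalize_counts,
                               associate_elements_to_genes,
                               stratum_association_fractions)
from enhancerkit.intervals import IntervalSet
from enhancerkit.landscape import (LandscapeConfig, call_double_positive,
                                   call_super_enhancers, consensus)
from enhancerkit.perturb import (call_known_target, filter_single_grna,
                                 normalize_cells)
from enhancerkit.simulate import (SimulationConfig, generate_activity_expression,
                                  generate_genes_and_expression,
                                  generate_landscape, generate_occupancy_loops,
                                  generate_perturb, simulate_to_dir)


def dir_bytes(d):
    return {p.name: p.read_bytes() for p in sorted(d.iterdir())}


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path, small_cfg):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_to_dir(small_cfg, d1)
        simulate_to_dir(small_cfg, d2)
        assert dir_bytes(d1) == dir_bytes(d2)

    def test_different_seed_differs(self, tmp_path, small_cfg):
        import dataclasses
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_to_dir(small_cfg, d1)
        simulate_to_dir(dataclasses.replace(small_cfg, seed=small_cfg.seed + 1), d2)
        assert dir_bytes(d1) != dir_bytes(d2)


class TestLandscapeGenerator:
    def test_no_dropout_full_consensus(self):
        cfg = SimulationConfig(seed=2, dropout=0.0, jitter=0)
        land = generate_landscape(cfg)
        enh = [call_double_positive(land.k27[s], land.k4me1[s], sample_id=s)
               for s in land.sample_ids]
        cons = consensus(enh, len(enh))
        recovered = {iv for iv in cons.elements}
        assert recovered == set(land.truth.dp_regions)

    def test_dropout_closed_form_consensus_fraction(self):
        """3-way consensus fraction converges to (1-q)^3 over planted regions."""
        q = 0.3
        cfg = SimulationConfig(seed=13, n_double_positive=1000,
                               n_single_mark_decoys=0, n_se_clusters=0,
                               n_se_decoys=0, dropout=q, n_chromosomes=12,
                               chrom_length=30_000_000)
        land = generate_landscape(cfg)
        expected = land.truth.dp_present.all(axis=1).mean()
        assert expected == pytest.approx((1 - q) ** 3, abs=3 * np.sqrt(
            (1 - q) ** 3 * (1 - (1 - q) ** 3) / 1000))
        enh = [call_double_positive(land.k27[s], land.k4me1[s], sample_id=s)
               for s in land.sample_ids]
        cons = consensus(enh, 3)
        assert len(cons) / 1000 == pytest.approx(expected, abs=1e-9)

    def test_decoys_violate_exactly_one_condition(self):
        cfg = SimulationConfig(seed=7)
        land = generate_landscape(cfg)
        lcfg = LandscapeConfig()
        for span, kind in land.truth.se_decoy_regions:
            if kind == "span":
                assert span.length() <= lcfg.se_min_size
            else:
                assert span.length() > lcfg.se_min_size  # only the gap is violated

    def test_genome_too_small_raises(self):
        cfg = SimulationConfig(seed=0, n_chromosomes=3, chrom_length=400_000)
        with pytest.raises(ValueError, match="too small"):
            generate_landscape(cfg)


class TestGenesGenerator:
    def test_stratum_mixture_exact(self):
        cfg = SimulationConfig(seed=6, n_genes=400)
        land = generate_landscape(cfg)
        gdata = generate_genes_and_expression(cfg, land)
        strata = gdata.fpkm.mean(axis=1).map(classify_stratum)
        assert strata.value_counts().to_dict() == {
            "inactive": 100, "low": 100, "mid": 100, "high": 100}
        # emitted truth matches classification gene by gene
        assert (strata.loc[gdata.truth["gene_id"]].values
                == gdata.truth["stratum"].values).all()

    def test_planted_association_fractions_exact_at_truth_level(self):
        cfg = SimulationConfig(seed=6)
        land = generate_landscape(cfg)
        gdata = generate_genes_and_expression(cfg, land)
        elements = IntervalSet("truth", sorted(land.truth.dp_regions))
        assoc = associate_elements_to_genes(elements, gdata.genes,
                                            cfg.assoc_window)
        strata = pd.Series(gdata.truth["stratum"].values,
                           index=gdata.truth["gene_id"])
        fracs = stratum_association_fractions(elements, assoc, strata)
        n = len(elements)
        assert fracs["high"] == round(cfg.assoc_fractions["high"] * n) / n
        assert fracs["low"] == round(cfg.assoc_fractions["low"] * n) / n

    def test_reference_totals_make_normalization_identity(self):
        cfg = SimulationConfig(seed=6, total_pairs=(56.5e6,) * 3)
        land = generate_landscape(cfg)
        gdata = generate_genes_and_expression(cfg, land)
        norm = normalize_counts(gdata.counts, gdata.totals)
        pd.testing.assert_frame_equal(norm, gdata.counts.astype(float))


class TestOccupancyLoopsGenerator:
    @pytest.mark.parametrize("p_se,p_enh,expected_se,expected_enh",
                             [(1.0, 0.0, 100.0, 0.0), (0.0, 1.0, 0.0, 100.0)])
    def test_degenerate_probabilities(self, p_se, p_enh, expected_se,
                                      expected_enh):
        cfg = SimulationConfig(seed=3, p_occupancy_se=p_se,
                               p_occupancy_enh=p_enh)
        land = generate_landscape(cfg)
        odata = generate_occupancy_loops(cfg, land)
        ses = IntervalSet("se", sorted(land.truth.se_regions))
        enh = IntervalSet("enh", sorted(land.truth.dp_regions))
        assert colocalization_fraction(ses, odata.occupancy) == expected_se
        assert colocalization_fraction(enh, odata.occupancy) == expected_enh

    def test_planted_in_span_peaks_recovered(self):
        cfg = SimulationConfig(seed=3, n_loops=6, peaks_per_loop=7)
        land = generate_landscape(cfg)
        odata = generate_occupancy_loops(cfg, land)
        for i, gene in enumerate(odata.loop_genes):
            sel, cands = loop_candidates(odata.loops, gene, odata.loop_peaks)
            assert len(sel) == 1 and len(cands) == 7

    def test_occupancy_flags_match_colocalization(self):
        cfg = SimulationConfig(seed=19)
        land = generate_landscape(cfg)
        odata = generate_occupancy_loops(cfg, land)
        ses = IntervalSet("se", sorted(land.truth.se_regions))
        frac = colocalization_fraction(ses, odata.occupancy)
        assert frac >= 100.0 * np.mean(odata.se_occupied) - 1e-9


class TestPerturbGenerator:
    def test_no_multi_rate_keeps_all_assigned(self):
        cfg = SimulationConfig(seed=5, n_cells=500, p_multi_grna=0.0,
                               p_single_grna=0.8)
        pdata = generate_perturb(cfg)
        groups, fractions = filter_single_grna(pdata.experiment)
        assert fractions["multi"] == 0.0
        n_assigned = sum(1 for g in pdata.experiment.grna_assignments.values()
                         if len(g) > 0)
        assert sum(len(v) for v in groups.values()) == n_assigned

    def test_null_fc_not_called(self):
        cfg = SimulationConfig(seed=5, n_cells=2000,
                               planted_fc={("g1", "tgene000"): 1.0})
        pdata = generate_perturb(cfg)
        groups, _ = filter_single_grna(pdata.experiment)
        norm = normalize_cells(pdata.experiment.counts)
        call = call_known_target(norm, groups, "g1", "tgene000", "scramble")
        assert not call.activated

    def test_planted_3x_effect_called(self):
        cfg = SimulationConfig(seed=5, n_cells=3500,
                               planted_fc={("g1", "tgene000"): 3.0})
        pdata = generate_perturb(cfg)
        groups, _ = filter_single_grna(pdata.experiment)
        assert len(groups["g1"]) >= 200 and len(groups["scramble"]) >= 200
        norm = normalize_cells(pdata.experiment.counts)
        call = call_known_target(norm, groups, "g1", "tgene000", "scramble")
        assert call.activated


class TestActivityGenerator:
    def test_planted_correlation_within_sampling_band(self):
        cfg = SimulationConfig(seed=1, n_specimens=200, activity_rho=0.5)
        df = generate_activity_expression(cfg)
        r = np.corrcoef(df["activity_score"], df["expression"])[0, 1]
        se = (1 - 0.5 ** 2) / np.sqrt(200)
        assert abs(r - 0.5) < 3 * se
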