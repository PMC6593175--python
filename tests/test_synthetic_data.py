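"""Generator contracts: determinism, planted signal sizes, readability."""

import numpy as np
import pandas as pd
import pytest

from zgapipe import SimulationConfig
from zgapipe.genome_model import decompose_architecture
from zgapipe.occupancy import gene_body_enrichment, normalize_per_million
from zgapipe.synthetic_data import (
    LOF_CONDITIONS,
    simulate_annotation,
    simulate_bundle,
    simulate_counts_table,
    simulate_lof,
    simulate_timecourse,
)
from zgapipe.temporal import STAGE_TIMES_HPF


class TestDeterminism:
    def test_same_seed_identical_outputs(self, small_config, small_bundle):
        b2 = simulate_bundle(small_config)
        pd.testing.assert_frame_equal(small_bundle.truth, b2.truth)
        pd.testing.assert_frame_equal(small_bundle.lof_counts, b2.lof_counts)
        pd.testing.assert_frame_equal(small_bundle.timecourse.exonic, b2.timecourse.exonic)
        for s, cov in small_bundle.coverage.items():
            for c in cov.chip:
                np.testing.assert_array_equal(cov.chip[c], b2.coverage[s].chip[c])

    def test_different_seed_differs(self, small_config, small_bundle):
        cfg = SimulationConfig(**{**small_config.to_dict(), "seed": 99})
        b2 = simulate_bundle(cfg)
        assert not small_bundle.truth.gene_class_true.equals(b2.truth.gene_class_true)


class TestAnnotation:
    def test_length_medians_near_targets(self, default_bundle):
        truth = default_bundle.truth
        early = truth.length_bp_true[truth.early_true]
        late = truth.length_bp_true[~truth.early_true & (truth.gene_class_true != "silent")]
        cfg = default_bundle.config
        assert abs(early.median() - cfg.early_length_median_bp) / cfg.early_length_median_bp < 0.2
        assert abs(late.median() - cfg.late_length_median_bp) / cfg.late_length_median_bp < 0.2

    def test_early_genes_intron_poor(self, default_bundle):
        truth = default_bundle.truth
        arch = pd.DataFrame(
            [decompose_architecture(g).__dict__ for g in default_bundle.genes]
        ).set_index("gene_id")
        assert (
            arch.intron_count[truth.early_true].mean()
            < arch.intron_count[~truth.early_true].mean() / 3
        )

    def test_models_satisfy_invariants(self, small_bundle):
        for g in small_bundle.genes:
            d = decompose_architecture(g)
            assert d.exonic_bp + d.intron_total_bp == d.gene_length_bp
            if d.cds_length_bp is not None:
                assert d.utr5_bp + d.cds_length_bp + d.utr3_bp == d.exonic_bp

    def test_clustering_vs_none(self):
        cfg_c = SimulationConfig(seed=5, n_genes=800, cluster_fraction=1.0)
        cfg_0 = SimulationConfig(seed=5, n_genes=800, cluster_fraction=0.0)

        def min_gaps(cfg):
            layout, genes, truth = simulate_annotation(cfg)
            early = set(truth.index[truth.early_true])
            by_chrom: dict[str, list] = {}
            for g in genes:
                by_chrom.setdefault(g.chrom, []).append(g)
            gaps = []
            for glist in by_chrom.values():
                glist = sorted(glist, key=lambda g: g.start)
                for a, b in zip(glist, glist[1:]):
                    if a.gene_id in early and b.gene_id in early:
                        gaps.append(b.start - a.end)
            return gaps

        gaps_c = min_gaps(cfg_c)
        gaps_0 = min_gaps(cfg_0)
        assert sum(g < 10_000 for g in gaps_c) >= 10  # tandem clusters exist
        assert sum(g < 10_000 for g in gaps_0) <= 3  # chance-level adjacency only

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotation(SimulationConfig(n_genes=5))


class TestCoverage:
    def test_active_gene_fold_near_config(self, small_bundle):
        cfg = small_bundle.config
        truth = small_bundle.truth
        stage = "late-gastrula"
        track = normalize_per_million(small_bundle.coverage[stage])
        genes = {g.gene_id: g for g in small_bundle.genes}
        active = truth.index[
            (truth.activation_stage_true.notna())
            & truth.deactivation_stage_true.isna()
        ]
        folds = [
            np.mean(gene_body_enrichment(track, genes[g])) for g in active[:120]
        ]
        # cpm rescaling dilutes the raw fold; it must stay well above the
        # 2-fold call threshold and below the configured raw fold
        assert 2.4 < float(np.mean(folds)) <= cfg.enrichment_fold + 0.3

    def test_inactive_gene_near_unity(self, small_bundle):
        truth = small_bundle.truth
        track = normalize_per_million(small_bundle.coverage["32-cell"])
        genes = {g.gene_id: g for g in small_bundle.genes}
        silent = truth.index[truth.gene_class_true == "maternal-only"]
        folds = [np.mean(gene_body_enrichment(track, genes[g])) for g in silent[:60]]
        assert abs(np.mean(folds) - 1.0) < 0.15

    def test_decoy_enriched_only_at_promoter(self, small_bundle):
        truth = small_bundle.truth
        track = normalize_per_million(small_bundle.coverage["MBT"])
        genes = {g.gene_id: g for g in small_bundle.genes}
        for g in truth.index[truth.decoy][:10]:
            prof = gene_body_enrichment(track, genes[g])
            assert prof[:2].mean() > 2.0  # promoter bins enriched
            assert prof[5:].mean() < 1.5  # body at background


class TestTimecourse:
    def test_grid_and_nonnegative(self, small_bundle):
        tc = small_bundle.timecourse
        assert tc.times[0] == 0.0 and tc.times[-1] == 10.0
        np.testing.assert_allclose(np.diff(tc.times), 0.5)
        assert (tc.exonic.to_numpy() >= 0).all()

    def test_zygotic_only_silent_before_activation(self, small_bundle):
        truth = small_bundle.truth
        tc = small_bundle.timecourse
        zo = truth.index[truth.gene_class_true == "zygotic-only"]
        for g in zo:
            t_act = STAGE_TIMES_HPF[truth.activation_stage_true.loc[g]]
            before = tc.times < t_act - 0.26
            total = tc.exonic.loc[g].to_numpy() + tc.intronic.loc[g].to_numpy()
            assert (total[before] < 0.1).all()

    def test_maternal_decay_no_noise(self):
        cfg = SimulationConfig(seed=2, n_genes=60, noise_sd_log=0.0,
                               intergenic_gap_mean_bp=5000.0)
        _, _, truth = simulate_annotation(cfg)
        tc = simulate_timecourse(cfg, truth)
        mat = truth.index[truth.gene_class_true == "maternal-only"][0]
        series = tc.exonic.loc[mat].to_numpy()
        expect = truth.maternal_tpm0.loc[mat] * np.exp(-cfg.maternal_decay_rate * tc.times)
        np.testing.assert_allclose(series, expect, rtol=1e-9)

    def test_zero_decay_is_constant(self):
        cfg = SimulationConfig(seed=2, n_genes=60, noise_sd_log=0.0,
                               maternal_decay_rate=0.0, intergenic_gap_mean_bp=5000.0)
        _, _, truth = simulate_annotation(cfg)
        tc = simulate_timecourse(cfg, truth)
        mat = truth.index[truth.gene_class_true == "maternal-only"][0]
        series = tc.exonic.loc[mat].to_numpy()
        np.testing.assert_allclose(series, series[0])

    def test_intronic_leads_exonic_on_activation(self):
        cfg = SimulationConfig(seed=3, n_genes=300, noise_sd_log=0.0,
                               intergenic_gap_mean_bp=5000.0)
        _, _, truth = simulate_annotation(cfg)
        tc = simulate_timecourse(cfg, truth)
        # zygotic-only genes: no maternal exonic baseline masks the nascent lead
        picked = truth.index[
            (truth.gene_class_true == "zygotic-only") & truth.has_introns
            & (truth.activation_stage_true == "MBT")
        ]
        assert len(picked) > 0
        for g in picked[:15]:
            i = np.searchsorted(tc.times, 4.5)
            assert tc.intronic.loc[g].iloc[i] > tc.exonic.loc[g].iloc[i] - 1e-9

    def test_maternal_zygotic_presence_and_rise(self, small_bundle):
        truth = small_bundle.truth
        tc = small_bundle.timecourse
        mz = truth.index[truth.gene_class_true == "maternal-zygotic"]
        total = tc.exonic + tc.intronic
        first_hour = total.loc[mz, tc.times[tc.times <= 1.0]].mean(axis=1)
        assert (first_hour >= 0.1).all()


class TestLofTables:
    def test_control_condition_level_near_100(self, small_bundle):
        truth = small_bundle.truth
        zyg = truth.index[truth.activation_stage_true.notna()]
        assert (truth.loc[zyg, "true_level_control-MO"] == 100.0).all()

    def test_counts_reflect_true_effect(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(400)]
        means = pd.DataFrame({"exonic": 2000.0, "intronic": 0.0}, index=genes)
        levels = {"X": pd.DataFrame({"exonic": 0.5, "intronic": 1.0}, index=genes)}
        tidy = simulate_counts_table(means, levels, replicates=3, dispersion=0.01, rng=rng)
        sub = tidy[(tidy.signal_type == "exonic")]
        est = (
            sub[sub.arm == "condition"].groupby("gene_id")["count"].mean()
            / sub[sub.arm == "control"].groupby("gene_id")["count"].mean()
        )
        assert est.mean() == pytest.approx(0.5, abs=0.01)

    def test_amanitin_suppresses_active_zygotic_truth(self, small_bundle):
        truth = small_bundle.truth
        cfg = small_bundle.config
        active_by_assay = truth.activation_stage_true.map(
            lambda s: s is not None and not pd.isna(s) and STAGE_TIMES_HPF[s] <= cfg.lof_assay_hpf
        )
        zo = (truth.gene_class_true == "zygotic-only") & active_by_assay
        assert (truth.loc[zo, "true_level_amanitin"] <= 50.0).all()

    def test_synergy_genes_super_additive_by_construction(self, small_bundle):
        truth = small_bundle.truth
        syn = truth.index[truth.synergy_true]
        assert len(syn) > 0
        d = lambda col: 1 - truth.loc[syn, col] / 100.0
        assert (
            d("true_level_W+B") > (d("true_level_W") + d("true_level_B")) + 0.1
        ).all()

    def test_all_conditions_emitted_and_readable(self, small_bundle):
        counts = small_bundle.lof_counts
        assert set(counts.condition.unique()) == set(LOF_CONDITIONS)
        assert set(counts.arm.unique()) == {"condition", "control"}
        from zgapipe.lof import LofCondition

        c = LofCondition.from_tidy(counts, "W+N+B")
        assert c.exonic.shape[1] == small_bundle.config.replicates

    def test_regional_ratios_consistent_with_truth(self, small_bundle):
        truth, regional = small_bundle.truth, small_bundle.regional
        animal = truth.region_av_true == "animal"
        vegetal = truth.region_av_true == "vegetal"
        assert regional.log2_AV[animal].mean() > 1.5
        assert regional.log2_AV[vegetal].mean() < -1.5
        uniform = truth.region_av_true == "uniform"
        assert abs(regional.log2_AV[uniform].mean()) < 0.2
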