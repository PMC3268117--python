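"""Synthetic xenograft generator: reproducibility, the planted generative
structure, fold-change planting arithmetic and truth export."""

import numpy as np
import pandas as pd
import pytest

from xenosig import (
    EXPECTED_ACTIVITY_GAP,
    GeneLookupError,
    SimulationConfig,
    export_truth,
    generate_xenograft,
    load_truth,
    plant_fold_change,
)


class TestConfig:
    def test_group_sizes_must_sum(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=18, n_high=8, n_low=11)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=18, n_high=0, n_low=18)

    def test_transfection_counts_must_sum(self):
        with pytest.raises(ValueError):
            SimulationConfig(transfection_counts=(("INHBA", 3), ("control", 3)))


class TestGenerate:
    def test_same_seed_reproduces_everything(self, small_config):
        h1, m1, t1 = generate_xenograft(small_config)
        h2, m2, t2 = generate_xenograft(small_config)
        pd.testing.assert_frame_equal(h1.data, h2.data)
        pd.testing.assert_frame_equal(m1.data, m2.data)
        assert t1.activity == t2.activity and t1.loadings == t2.loadings

    def test_shared_sample_ids_and_species_prefixes(self, small_experiment):
        human, mouse, _ = small_experiment
        assert human.sample_ids == mouse.sample_ids
        assert all(p.startswith("HS_") for p in human.probe_ids)
        assert all(p.startswith("MM_") for p in mouse.probe_ids)

    def test_group_sizes_and_activity_gap(self, small_experiment):
        _, _, truth = small_experiment
        groups = list(truth.group.values())
        assert groups.count("high") == 7 and groups.count("low") == 11
        acts = np.array(list(truth.activity.values()))
        high = np.array([truth.group[s] == "high" for s in truth.activity])
        assert high.sum() == 7
        assert acts[high].min() >= 0.7 and acts[~high].max() <= 0.45

    def test_noiseless_signature_gene_is_affine_in_activity(self):
        cfg = SimulationConfig(
            n_human_genes=120, n_mouse_genes=50, noise_sd=0.0, loading_sd=0.0, seed=3
        )
        human, _, truth = generate_xenograft(cfg)
        a = np.array([truth.activity[s] for s in human.sample_ids])
        row = human.gene_row("THBS2").to_numpy()
        r = np.corrcoef(row, a)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_transfection_boost_hits_only_the_transfected_gene(self):
        cfg = SimulationConfig(n_human_genes=120, n_mouse_genes=50, noise_sd=0.0, seed=5)
        human, _, truth = generate_xenograft(cfg)
        a = np.array([truth.activity[s] for s in human.sample_ids])
        inhba = human.gene_row("INHBA").to_numpy() - truth.loadings["INHBA"] * a
        labels = np.array([truth.transfection[s] for s in human.sample_ids])
        boosted = inhba[labels == "INHBA"]
        rest = inhba[labels != "INHBA"]
        assert np.allclose(boosted, rest.mean() + cfg.transfection_boost, atol=1e-9)
        assert np.allclose(rest, rest.mean(), atol=1e-9)
        # FST transfection shifts the FST background row, nothing else
        fst = human.gene_row("FST").to_numpy()
        assert np.allclose(
            fst[labels == "FST"], fst[labels != "FST"].mean() + cfg.transfection_boost,
            atol=1e-9,
        )


class TestPlantFoldChange:
    def test_fc_one_gives_zero_loading(self, small_config):
        cfg = plant_fold_change(small_config, "SNAI2", 1.0)
        assert cfg.override_for("SNAI2") == 0.0

    def test_loading_arithmetic(self, small_config):
        cfg = plant_fold_change(small_config, "SNAI2", 2.0)
        assert cfg.override_for("SNAI2") == pytest.approx(np.log2(2.0) / EXPECTED_ACTIVITY_GAP)

    def test_planted_fc_is_exact_in_the_noiseless_limit(self):
        # compute the realized activity gap for this seed, then force the
        # SNAI2 loading so the group-mean log2 difference is log2(5.22)
        base = SimulationConfig(n_human_genes=120, n_mouse_genes=50, noise_sd=0.0, seed=11)
        _, _, truth = generate_xenograft(base)
        acts = truth.activity
        gap = np.mean([a for s, a in acts.items() if truth.group[s] == "high"]) - np.mean(
            [a for s, a in acts.items() if truth.group[s] == "low"]
        )
        lam = np.log2(5.22) / gap
        cfg = SimulationConfig(
            n_human_genes=120, n_mouse_genes=50, noise_sd=0.0, seed=11,
            loading_overrides=(("SNAI2", lam),),
        )
        human, _, truth2 = generate_xenograft(cfg)
        row = human.gene_row("SNAI2")
        hi = np.mean([row[s] for s in acts if truth2.group[s] == "high"])
        lo = np.mean([row[s] for s in acts if truth2.group[s] == "low"])
        assert 2 ** (hi - lo) == pytest.approx(5.22, abs=1e-9)

    def test_invalid_fc_rejected(self, small_config):
        with pytest.raises(ValueError):
            plant_fold_change(small_config, "SNAI2", 0.0)

    def test_unknown_gene_rejected(self, small_config):
        with pytest.raises(GeneLookupError):
            plant_fold_change(small_config, "NOT_A_GENE", 2.0)

    def test_mouse_marker_plantable(self, small_config):
        cfg = plant_fold_change(small_config, "ADIPOQ", 12.3)
        assert cfg.override_for("Adipoq") == pytest.approx(np.log2(12.3) / EXPECTED_ACTIVITY_GAP)


class TestTruthExport:
    def test_round_trip(self, small_experiment, tmp_path):
        _, _, truth = small_experiment
        export_truth(truth, tmp_path)
        per_sample, per_gene = load_truth(tmp_path)
        assert len(per_sample) == 18
        np.testing.assert_allclose(
            per_sample["activity"].to_numpy(),
            [truth.activity[s] for s in per_sample["sample_id"]],
            atol=1e-9,
        )
        assert set(truth.planted_signature_genes) <= set(per_gene["gene"])
        assert len(set(per_gene["gene"]) & set(truth.planted_adipocyte_genes)) == 3


class TestStatisticalStructure:
    def test_activity_drives_signature_mean(self):
        """Across seeds the planted latent activity and the mean planted
        signature expression stay tightly coupled."""
        rs = []
        for seed in range(20):
            cfg = SimulationConfig(n_human_genes=100, n_mouse_genes=50, seed=seed)
            human, _, truth = generate_xenograft(cfg)
            a = np.array([truth.activity[s] for s in human.sample_ids])
            sig_rows = human.data.iloc[:64].to_numpy()
            rs.append(np.corrcoef(sig_rows.mean(axis=0), a)[0, 1])
        assert min(rs) > 0.9

    def test_adipocyte_rows_anticorrelate_with_signature(self):
        rs = []
        for seed in range(20):
            cfg = SimulationConfig(n_human_genes=100, n_mouse_genes=50, seed=seed)
            human, mouse, truth = generate_xenograft(cfg)
            sig_mean = human.data.iloc[:64].to_numpy().mean(axis=0)
            for g in truth.planted_adipocyte_genes:
                rs.append(np.corrcoef(mouse.gene_row(g).to_numpy(), sig_mean)[0, 1])
        assert max(rs) < -0.5

    def test_transfection_independent_of_activity(self):
        """Transfection labels carry no information about the latent
        mesenchymal activity (the wet-lab observation that transfections
        did not affect the signature)."""
        diffs = []
        for seed in range(200):
            cfg = SimulationConfig(n_human_genes=70, n_mouse_genes=10, seed=seed)
            _, _, truth = generate_xenograft(cfg)
            acts = truth.activity
            inhba = [acts[s] for s, t in truth.transfection.items() if t == "INHBA"]
            ctrl = [acts[s] for s, t in truth.transfection.items() if t == "control"]
            diffs.append(np.mean(inhba) - np.mean(ctrl))
        assert abs(np.mean(diffs)) < 0.05
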