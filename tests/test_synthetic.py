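"""Generator contracts: determinism, hierarchy shape, planted structure,
missingness, spike-in pairing, viability decay."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from survscore import differential as de
from survscore import scoring as sc
from survscore.phenotype import fit_death_rate
from survscore.synthetic import (
    SimulationConfig,
    emit_gene_sets,
    generate_condition_hierarchy,
    simulate_peptide_matrix,
    simulate_spikein_matrix,
    simulate_viability_series,
)

from conftest import null_peptide_config, single_dataset_hierarchy


class TestHierarchyGeneration:
    def test_minimal_case_has_one_orderable_pair(self):
        h = generate_condition_hierarchy(1, 1, 2, seed=0)
        assert len(h) == 2
        rates = h.death_rates()
        from survscore.hierarchy import enumerate_ordered_pairs

        assert len(enumerate_ordered_pairs(rates)) == 1

    def test_carls_layout_yields_seven_datasets(self, carls_hierarchy):
        assert len(carls_hierarchy.dataset_ids) == 7
        assert carls_hierarchy.perturbations == list("CARLS")
        assert len(carls_hierarchy.datasets_of("C")) == 3

    def test_same_seed_reproduces_hierarchy(self):
        a = generate_condition_hierarchy(3, 2, 3, seed=11)
        b = generate_condition_hierarchy(3, 2, 3, seed=11)
        assert a.to_frame().equals(b.to_frame())

    def test_death_rates_within_range_and_reference_flagged(self, carls_hierarchy):
        for c in carls_hierarchy.conditions:
            assert 0.05 <= c.death_rate <= 1.6
        for ds in carls_hierarchy.dataset_ids:
            refs = [c for c in carls_hierarchy.conditions_of(ds) if c.is_reference]
            assert len(refs) == 1

    def test_growth_tracks_death_rate_by_perturbation_class(self, carls_hierarchy):
        # nutrient-class conditions grow faster when they die faster;
        # ribosome limitation is the orthogonal branch
        df = carls_hierarchy.to_frame()
        for pert, grp in df.groupby("perturbation"):
            if len(grp) < 2:
                continue
            rho = np.corrcoef(grp["growth_rate_per_h"], grp["death_rate_per_day"])[0, 1]
            assert rho > 0 if pert != "R" else rho < 0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_condition_hierarchy(0, 1, 2)
        with pytest.raises(ValueError):
            generate_condition_hierarchy(1, 1, 0)
        with pytest.raises(ValueError):
            generate_condition_hierarchy(1, 1, 2, death_rate_range=(-1.0, 1.0))


class TestPeptideMatrix:
    def test_deterministic_given_seed(self, chain3_hierarchy):
        cfg = SimulationConfig(hierarchy=chain3_hierarchy, seed=3, n_proteins=50, n_planted=5)
        t1, g1 = simulate_peptide_matrix(cfg)
        t2, g2 = simulate_peptide_matrix(cfg)
        assert_frame_equal(t1, t2)
        assert g1.planted_ids == g2.planted_ids

    def test_complete_table_when_missing_rate_zero(self, chain3_hierarchy):
        cfg = null_peptide_config(chain3_hierarchy, n_proteins=40, seed=1)
        table, _ = simulate_peptide_matrix(cfg)
        assert not table.isna().any().any()
        assert table.shape[1] == 3 * cfg.n_replicates

    def test_missingness_targets_rate_and_low_intensities(self, chain3_hierarchy):
        cfg = null_peptide_config(
            chain3_hierarchy, n_proteins=400, seed=2, missing_rate=0.25
        )
        table, _ = simulate_peptide_matrix(cfg)
        frac = float(table.isna().to_numpy().mean())
        assert abs(frac - 0.25) < 0.03
        # observed values sit higher than the generating distribution's centre
        present = np.log2(table.to_numpy()[np.isfinite(table.to_numpy())])
        assert present.mean() > cfg.base_log2_mean

    def test_planted_fold_change_matches_covariate_step(self):
        # two conditions, death 1.0 vs 0.1 per day, effect 1 log2-unit:
        # s spans [0, 1] within the perturbation, so E[log2FC] = +1
        h = single_dataset_hierarchy({"hi": 1.0, "lo": 0.1})
        cfg = SimulationConfig(
            hierarchy=h,
            seed=5,
            n_proteins=60,
            n_planted=60,
            effect_size=1.0,
            n_replicates=25,
            replicate_noise_sd=0.5,
            missing_rate=0.0,
        )
        table, truth = simulate_peptide_matrix(cfg)
        abund = de.protein_rollup(table)
        stats = de.pair_differential(abund, ("hi", "lo"))
        assert len(stats) == 60  # 60 proteins x 25 replicates > 1000 draws
        assert abs(stats["log2fc"].mean() - 1.0) < 0.05

    def test_planted_means_non_increasing_in_death_rate(self, carls_hierarchy):
        cfg = SimulationConfig(
            hierarchy=carls_hierarchy, seed=8, n_proteins=100, n_planted=30
        )
        _, truth = simulate_peptide_matrix(cfg)
        means = truth.condition_means.loc[sorted(truth.planted_ids)]
        df = carls_hierarchy.to_frame().set_index("condition_id")
        for pert in carls_hierarchy.perturbations:
            conds = df.index[df["perturbation"] == pert]
            order = df.loc[conds, "death_rate_per_day"].sort_values().index
            sub = means[order].to_numpy()
            assert (np.diff(sub, axis=1) <= 1e-12).all()

    def test_null_pipeline_scores_centred_at_zero(self, carls_hierarchy):
        cfg = null_peptide_config(carls_hierarchy, n_proteins=2000, seed=4)
        table, _ = simulate_peptide_matrix(cfg)
        stats = de.all_pair_stats(de.protein_rollup(table), carls_hierarchy)
        scores = sc.score_proteins(stats).scores["survival_score"]
        assert len(scores) >= 2000
        assert abs(scores.mean()) < 0.1

    def test_invalid_config_rejected(self, chain3_hierarchy):
        with pytest.raises(ValueError):
            SimulationConfig(hierarchy=chain3_hierarchy, n_proteins=10, n_planted=11)
        with pytest.raises(ValueError):
            SimulationConfig(hierarchy=chain3_hierarchy, missing_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(hierarchy=chain3_hierarchy, replicate_noise_sd=-0.1)


class TestSpikein:
    def test_heavy_paired_with_light_and_positive(self, chain3_hierarchy):
        cfg = SimulationConfig(
            hierarchy=chain3_hierarchy,
            seed=6,
            n_proteins=50,
            n_planted=5,
            missing_rate=0.2,
            spikein=True,
        )
        table, _ = simulate_spikein_matrix(cfg)
        light = table.xs("light", axis=1, level="channel")
        heavy = table.xs("heavy", axis=1, level="channel")
        assert (light.notna().to_numpy() == heavy.notna().to_numpy()).all()
        hv = heavy.to_numpy()
        assert (hv[np.isfinite(hv)] > 0).all()

    def test_deterministic_given_seed(self, chain3_hierarchy):
        cfg = SimulationConfig(
            hierarchy=chain3_hierarchy, seed=9, n_proteins=30, n_planted=3, spikein=True
        )
        t1, _ = simulate_spikein_matrix(cfg)
        t2, _ = simulate_spikein_matrix(cfg)
        assert_frame_equal(t1, t2)

    def test_condition_shuffled_heavy_leaves_fold_changes_unbiased(self):
        # the heavy channel is condition-independent, so permuting its
        # condition blocks must not move the planted fold changes
        h = single_dataset_hierarchy({"hi": 1.0, "lo": 0.1})
        cfg = SimulationConfig(
            hierarchy=h,
            seed=10,
            n_proteins=150,
            n_planted=150,
            effect_size=1.0,
            n_replicates=8,
            missing_rate=0.0,
            spikein=True,
        )
        table, truth = simulate_spikein_matrix(cfg)
        pseudo = de.spikein_pseudo_intensities(table)
        fc = de.pair_differential(de.protein_rollup(pseudo), ("hi", "lo"))["log2fc"]

        heavy = table.xs("heavy", axis=1, level="channel")
        light = table.xs("light", axis=1, level="channel")
        shuffled = heavy.rename(columns={"hi": "lo", "lo": "hi"}, level="condition")
        shuffled = shuffled[heavy.columns]
        swapped = pd.concat(
            {"light": light, "heavy": shuffled}, axis=1, names=["channel"]
        ).reorder_levels(["condition", "replicate", "channel"], axis=1)
        fc2 = de.pair_differential(
            de.protein_rollup(de.spikein_pseudo_intensities(swapped)), ("hi", "lo")
        )["log2fc"]
        assert abs(fc.mean() - 1.0) < 0.1
        assert abs(fc2.mean() - fc.mean()) < 0.1


class TestViability:
    def test_closed_form_decay(self):
        s = simulate_viability_series(0.2, 1e9, [0, 10], noise_cv=0.0, seed=0)
        assert s.cfu[1] == pytest.approx(1e9 * np.exp(-2.0), rel=1e-12)

    def test_zero_death_rate_constant(self):
        s = simulate_viability_series(0.0, 5e8, [0, 1, 2, 3], noise_cv=0.0, seed=0)
        assert np.allclose(s.cfu, 5e8)

    def test_noiseless_round_trip_recovers_rate(self):
        s = simulate_viability_series(0.37, 1e9, list(range(8)), noise_cv=0.0, seed=0)
        fit = fit_death_rate(s, floor=0.0)
        assert fit.death_rate == pytest.approx(0.37, abs=1e-12)

    def test_negative_days_rejected(self):
        with pytest.raises(ValueError):
            simulate_viability_series(0.2, 1e9, [-1, 0, 1], seed=0)


class TestGeneSets:
    def test_planted_set_holds_exactly_the_planted_proteins(self, chain3_hierarchy):
        cfg = SimulationConfig(
            hierarchy=chain3_hierarchy, seed=12, n_proteins=200, n_planted=50
        )
        _, truth = simulate_peptide_matrix(cfg)
        sets = emit_gene_sets(truth, n_decoy_sets=4, set_size=30, seed=1)
        assert sets[0].members == truth.planted_ids
        assert len(sets[0].members) == 50
        assert len(sets) == 5
        assert all(len(s.members) == 30 for s in sets[1:])

    def test_same_seed_identical_gmt_bytes(self, tmp_path, chain3_hierarchy):
        from survscore.io import write_gmt

        cfg = SimulationConfig(
            hierarchy=chain3_hierarchy, seed=13, n_proteins=100, n_planted=20
        )
        _, truth = simulate_peptide_matrix(cfg)
        p1, p2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
        write_gmt(emit_gene_sets(truth, 5, 10, seed=2), p1)
        write_gmt(emit_gene_sets(truth, 5, 10, seed=2), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_oversized_set_rejected(self, chain3_hierarchy):
        cfg = SimulationConfig(
            hierarchy=chain3_hierarchy, seed=14, n_proteins=20, n_planted=5
        )
        _, truth = simulate_peptide_matrix(cfg)
        with pytest.raises(ValueError):
            emit_gene_sets(truth, 1, set_size=21, seed=0)
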