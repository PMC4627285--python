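import numpy as np
import pandas as pd
import pytest

from synerscan import (
    ExpressionMatrix,
    SimConfig,
    SynergyCriteria,
    classify_inhibitor_dependent,
    classify_synergistic,
    condition_fold_changes,
    differential_lists,
    generate_design,
    generate_expression,
    synergy_factor,
    synergistic_targets,
)
from synerscan.synergy import FoldChangeTable


def _fc_table(genes, fc_drug, fc_ligand, fc_combo, genotype="vector", inhibitor="none"):
    df = pd.DataFrame(
        {"fc_drug": fc_drug, "fc_ligand": fc_ligand, "fc_combo": fc_combo}, index=genes
    )
    return FoldChangeTable(df, genotype, inhibitor)


class TestSynergyFactor:
    @pytest.mark.parametrize(
        "combo, drug, ligand, expected",
        [(12, 2, 3, 2.0), (6, 2, 3, 1.0), (1, 1, 1, 1.0), (16, 2, 2, 4.0)],
    )
    def test_arithmetic(self, combo, drug, ligand, expected):
        assert synergy_factor(combo, drug, ligand) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            synergy_factor(1.0, 0.0, 2.0)

    def test_invariant_to_constant_expression_rescaling(self):
        """Multiplying all of a gene's linear values by c leaves SF unchanged."""
        design = generate_design(2)
        rng = np.random.default_rng(0)
        log2_vals = rng.normal(8, 1, size=(3, len(design.sample_ids)))
        m1 = ExpressionMatrix(
            pd.DataFrame(log2_vals, index=["a", "b", "c"], columns=design.sample_ids),
            "log2",
        )
        m2 = ExpressionMatrix(m1.values + np.log2(37.0), "log2")  # linear x37
        fc1 = condition_fold_changes(m1, design, "vector").table
        fc2 = condition_fold_changes(m2, design, "vector").table
        sf1 = synergy_factor(fc1["fc_combo"], fc1["fc_drug"], fc1["fc_ligand"])
        sf2 = synergy_factor(fc2["fc_combo"], fc2["fc_drug"], fc2["fc_ligand"])
        assert np.allclose(sf1, sf2, atol=1e-12)


class TestConditionFoldChanges:
    def test_zero_noise_effects_give_expected_fcs(self, zero_noise_data):
        _, design, matrix, truth = zero_noise_data
        fc = condition_fold_changes(matrix, design, "vector").table
        gene = truth.genes_in_class("synergistic")[0]
        assert fc.loc[gene, "fc_drug"] == pytest.approx(2.0)
        assert fc.loc[gene, "fc_ligand"] == pytest.approx(2.0)
        assert fc.loc[gene, "fc_combo"] == pytest.approx(16.0)

    def test_null_gene_fc_is_one(self, zero_noise_data):
        _, design, matrix, truth = zero_noise_data
        fc = condition_fold_changes(matrix, design, "vector").table
        gene = truth.genes_in_class("null")[0]
        assert fc.loc[gene].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_linear_and_log2_inputs_agree(self, zero_noise_data):
        _, design, matrix, _ = zero_noise_data
        linear = ExpressionMatrix(2.0 ** matrix.values, "linear")
        fc_log = condition_fold_changes(matrix, design, "vector").table
        fc_lin = condition_fold_changes(linear, design, "vector").table
        assert np.allclose(fc_log.to_numpy(), fc_lin.to_numpy(), rtol=1e-12)

    def test_missing_cell_named_in_error(self, zero_noise_data):
        _, design, matrix, _ = zero_noise_data
        from synerscan.containers import SampleDesign

        no_combo = SampleDesign(
            design.table[
                ~(
                    (design.table["drug"] == "Nutlin")
                    & (design.table["ligand"] == "flagellin")
                )
            ]
        )
        with pytest.raises(ValueError, match="Nutlin.*flagellin"):
            condition_fold_changes(matrix, no_combo, "vector")


class TestClassification:
    def test_all_criteria_true_gives_target(self):
        fc_v = _fc_table(["g"], [2.0], [2.0], [16.0])
        fc_p = _fc_table(["g"], [1.0], [2.0], [2.0], genotype="p53i")
        res = classify_synergistic(fc_v, fc_p)
        assert res.loc["g", "sf"] == pytest.approx(4.0)
        assert res.loc["g", ["c1_combo_over_singles", "c2_synergy_factor",
                            "c3_genotype_dependence"]].all()
        assert res.loc["g", "classification"] == "synergistic_target"

    def test_bliss_null_gene_excluded_by_sf(self):
        fc_v = _fc_table(["g"], [2.0], [3.0], [6.0])
        fc_p = _fc_table(["g"], [1.0], [3.0], [1.0], genotype="p53i")
        res = classify_synergistic(fc_v, fc_p)
        assert res.loc["g", "sf"] == pytest.approx(1.0)
        assert not res.loc["g", "c2_synergy_factor"]
        assert res.loc["g", "classification"] == "not_synergistic"

    def test_genotype_independent_gene_excluded(self):
        fc_v = _fc_table(["g"], [2.0], [2.0], [16.0])
        fc_p = _fc_table(["g"], [2.0], [2.0], [16.0], genotype="p53i")
        res = classify_synergistic(fc_v, fc_p)
        assert not res.loc["g", "c3_genotype_dependence"]
        assert res.loc["g", "classification"] == "not_synergistic"

    def test_classification_is_conjunction_of_flags(self, noisy_data):
        _, design, matrix, _ = noisy_data
        fc_v = condition_fold_changes(matrix, design, "vector")
        fc_p = condition_fold_changes(matrix, design, "p53i")
        res = classify_synergistic(fc_v, fc_p)
        conj = (
            res["c1_combo_over_singles"]
            & res["c2_synergy_factor"]
            & res["c3_genotype_dependence"]
        )
        assert ((res["classification"] == "synergistic_target") == conj).all()

    def test_strict_inequality_at_exact_thresholds(self):
        # combo exactly 2x each single, SF exactly 1.5, genotype ratio exactly 2
        fc_v = _fc_table(["g"], [2.0], [2.0], [4.0])
        fc_p = _fc_table(["g"], [1.0], [2.0], [2.0], genotype="p53i")
        res = classify_synergistic(fc_v, fc_p)
        assert res.loc["g", "classification"] == "not_synergistic"

    def test_gene_mismatch_reported(self):
        fc_v = _fc_table(["g1", "g2"], [2, 2], [2, 2], [16, 16])
        fc_p = _fc_table(["g1"], [1], [2], [2], genotype="p53i")
        with pytest.raises(ValueError, match="g2"):
            classify_synergistic(fc_v, fc_p)

    def test_zero_noise_recovery_is_exact(self, zero_noise_data):
        _, design, matrix, truth = zero_noise_data
        fc_v = condition_fold_changes(matrix, design, "vector")
        fc_p = condition_fold_changes(matrix, design, "p53i")
        targets = set(synergistic_targets(classify_synergistic(fc_v, fc_p)))
        assert targets == set(truth.synergistic_genes)


class TestInhibitorDependence:
    def test_attenuated_target_flagged(self):
        res = classify_synergistic(
            _fc_table(["g"], [2.0], [2.0], [16.0]),
            _fc_table(["g"], [1.0], [2.0], [2.0], genotype="p53i"),
        )
        fc_inh = _fc_table(["g"], [2.0], [2.0], [2.0], inhibitor="SB203580")
        fc_no = _fc_table(["g"], [2.0], [2.0], [16.0])
        out = classify_inhibitor_dependent(res, fc_inh, fc_no)
        assert bool(out.loc["g", "inhibitor_dependent"])

    def test_unaffected_target_not_flagged(self):
        res = classify_synergistic(
            _fc_table(["g"], [2.0], [2.0], [16.0]),
            _fc_table(["g"], [1.0], [2.0], [2.0], genotype="p53i"),
        )
        fc_inh = _fc_table(["g"], [2.0], [2.0], [16.0], inhibitor="SB203580")
        fc_no = _fc_table(["g"], [2.0], [2.0], [16.0])
        out = classify_inhibitor_dependent(res, fc_inh, fc_no)
        assert not bool(out.loc["g", "inhibitor_dependent"])

    def test_non_targets_never_flagged(self, zero_noise_data):
        _, design, matrix, truth = zero_noise_data
        fc_v = condition_fold_changes(matrix, design, "vector")
        fc_p = condition_fold_changes(matrix, design, "p53i")
        fc_inh = condition_fold_changes(matrix, design, "vector", inhibitor="SB203580")
        res = classify_inhibitor_dependent(
            classify_synergistic(fc_v, fc_p), fc_inh, fc_v
        )
        flagged = set(res.index[res["inhibitor_dependent"]])
        assert flagged <= set(truth.synergistic_genes)
        assert flagged == set(truth.inhibitor_dependent_genes)

    def test_requires_inhibitor_arm_table(self):
        res = classify_synergistic(
            _fc_table(["g"], [2.0], [2.0], [16.0]),
            _fc_table(["g"], [1.0], [2.0], [2.0], genotype="p53i"),
        )
        not_arm = _fc_table(["g"], [2.0], [2.0], [2.0])  # inhibitor="none"
        with pytest.raises(ValueError, match="inhibitor arm"):
            classify_inhibitor_dependent(res, not_arm, not_arm)


class TestDifferentialLists:
    def test_zero_noise_lists_match_planted_classes(self):
        config = SimConfig(n_genes=300, n_replicates=2, noise_sd=0.0,
                           effect_drug=1.5, seed=8)
        design = generate_design(2)
        matrix, truth = generate_expression(config, design)
        fc_v = condition_fold_changes(matrix, design, "vector")
        lists = differential_lists(fc_v, up_fold=2.0, down_fold=2.0)
        drug_up_expected = set(truth.genes_in_class("p53_induced")) | set(
            truth.synergistic_genes
        )
        assert set(lists["drug_up"]) == drug_up_expected
        assert set(lists["drug_down"]) == set(truth.genes_in_class("p53_repressed"))

    def test_all_null_data_gives_empty_lists(self):
        config = SimConfig(n_genes=50, n_replicates=2, noise_sd=0.0,
                           class_fractions={"null": 1.0}, seed=1)
        design = generate_design(2)
        matrix, _ = generate_expression(config, design)
        lists = differential_lists(condition_fold_changes(matrix, design, "vector"))
        assert all(len(v) == 0 for v in lists.values())

    def test_boundary_fold_excluded(self):
        fc = _fc_table(["g"], [2.0], [1.0], [2.0])
        lists = differential_lists(fc, up_fold=2.0)
        assert lists["drug_up"] == []

    def test_fold_at_most_one_rejected(self):
        fc = _fc_table(["g"], [2.0], [1.0], [2.0])
        with pytest.raises(ValueError):
            differential_lists(fc, up_fold=1.0)


class TestParameterRecovery:
    def test_default_conditions_recall_and_precision(self):
        """Noisy recovery at the generator's default study conditions."""
        recalls, precisions = [], []
        for seed in range(3):
            config = SimConfig(seed=seed)
            design = generate_design(config.n_replicates)
            matrix, truth = generate_expression(config, design)
            fc_v = condition_fold_changes(matrix, design, "vector")
            fc_p = condition_fold_changes(matrix, design, "p53i")
            found = set(synergistic_targets(classify_synergistic(fc_v, fc_p)))
            planted = set(truth.synergistic_genes)
            recalls.append(len(found & planted) / len(planted))
            precisions.append(len(found & planted) / max(len(found), 1))
        assert np.mean(recalls) >= 0.90
        assert np.mean(precisions) >= 0.90

    def test_no_interaction_means_few_false_positives(self):
        config = SimConfig(effect_interaction=0.0, seed=13)
        design = generate_design(config.n_replicates)
        matrix, truth = generate_expression(config, design)
        fc_v = condition_fold_changes(matrix, design, "vector")
        fc_p = condition_fold_changes(matrix, design, "p53i")
        found = synergistic_targets(classify_synergistic(fc_v, fc_p))
        assert len(found) / config.n_genes <= 0.01
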