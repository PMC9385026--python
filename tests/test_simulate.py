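import numpy as np
import pandas as pd
import pytest

from ergpanel import (classify_panel, enrich_collection, simulate_experiment,
                      simulate_gene_sets, simulate_peak_evidence)
from ergpanel.simulate import (CLASS_NON_RESPONDER, CLASS_STABLE_DOWN,
                               CLASS_STABLE_UP, CLASS_UNSTABLE,
                               SimulationConfig)


def small_config(**overrides):
    defaults = dict(n_genes=300, n_replicates=6, frac_up=0.1, frac_down=0.1,
                    frac_unstable=0.1, seed=1)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestSimulateExperiment:
    def test_identical_seed_identical_output(self):
        exp_a, truth_a = simulate_experiment(small_config(n_genes=1000))
        exp_b, truth_b = simulate_experiment(small_config(n_genes=1000))
        np.testing.assert_array_equal(exp_a.treated, exp_b.treated)
        np.testing.assert_array_equal(exp_a.control, exp_b.control)
        pd.testing.assert_frame_equal(truth_a.table, truth_b.table)

    def test_different_seed_differs(self):
        exp_a, _ = simulate_experiment(small_config(seed=1))
        exp_b, _ = simulate_experiment(small_config(seed=2))
        assert not np.array_equal(exp_a.treated, exp_b.treated)

    def test_class_counts_are_rounded_fractions(self):
        config = small_config(n_genes=250, frac_up=0.1, frac_down=0.06,
                              frac_unstable=0.02)
        _, truth = simulate_experiment(config)
        counts = truth.table["gene_class"].value_counts()
        assert counts[CLASS_STABLE_UP] == 25
        assert counts[CLASS_STABLE_DOWN] == 15
        assert counts[CLASS_UNSTABLE] == 5
        assert counts[CLASS_NON_RESPONDER] == 205

    def test_zero_noise_limit_gives_identical_ratios(self):
        config = small_config(stable_sigma=0.0, unstable_sigma=0.0)
        experiment, truth = simulate_experiment(config)
        log_ratio = np.log2(experiment.treated) - np.log2(experiment.control)
        spread = log_ratio.max(axis=1) - log_ratio.min(axis=1)
        assert np.all(spread < 1e-9)
        up = truth.table["gene_class"] == CLASS_STABLE_UP
        np.testing.assert_allclose(
            log_ratio[up.to_numpy(), 0],
            truth.table.loc[up, "true_log2_effect"], atol=1e-9)

    def test_non_responder_mean_ratio_near_zero(self):
        experiment, truth = simulate_experiment(
            small_config(n_genes=2000, seed=6))
        log_ratio = np.log2(experiment.treated) - np.log2(experiment.control)
        mask = (truth.table["gene_class"] == CLASS_NON_RESPONDER).to_numpy()
        per_gene_means = log_ratio[mask].mean(axis=1)
        # Monte-Carlo: grand mean within 3 standard errors of zero
        se = per_gene_means.std(ddof=1) / np.sqrt(mask.sum())
        assert abs(per_gene_means.mean()) < 3 * se

    def test_empty_experiment_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)


class TestSimulatePeakEvidence:
    def test_evidence_consistent_with_planted_labels(self):
        _, truth = simulate_experiment(small_config())
        evidence = simulate_peak_evidence(truth, seed=5)
        by_gene = {r.gene: r for r in evidence}
        for gene, row in truth.table.iterrows():
            record = by_gene[gene]
            alpha_pos = record.q_plus > record.q_minus
            beta_pos = record.sn_ratio > 1.0
            expected = {"ERalpha": (True, False), "ERbeta": (False, True),
                        "ERalpha/beta": (True, True),
                        "other": (False, False)}[row["subtype"]]
            assert (alpha_pos, beta_pos) == expected

    def test_classifier_round_trip_recovers_all_labels(self):
        _, truth = simulate_experiment(small_config(n_genes=500, seed=2))
        evidence = simulate_peak_evidence(truth, seed=9)
        calls, _ = classify_panel(evidence)
        labels = truth.table["subtype"].to_dict()
        assert all(c.subtype == labels[c.gene] for c in calls)

    def test_deterministic_under_seed(self):
        _, truth = simulate_experiment(small_config())
        assert (simulate_peak_evidence(truth, seed=4)
                == simulate_peak_evidence(truth, seed=4))


class TestSimulateGeneSets:
    def test_deterministic_under_seed(self):
        _, truth = simulate_experiment(small_config())
        a = simulate_gene_sets(truth, n_sets=4, enriched_fraction=0.8, seed=3)
        b = simulate_gene_sets(truth, n_sets=4, enriched_fraction=0.8, seed=3)
        assert a == b

    def test_zero_sets_rejected(self):
        _, truth = simulate_experiment(small_config())
        with pytest.raises(ValueError):
            simulate_gene_sets(truth, n_sets=0, enriched_fraction=0.5, seed=1)

    @pytest.mark.parametrize("fraction", [0.0, 1.5, -0.2])
    def test_out_of_range_fraction_rejected(self, fraction):
        _, truth = simulate_experiment(small_config())
        with pytest.raises(ValueError, match="enriched_fraction"):
            simulate_gene_sets(truth, n_sets=2, enriched_fraction=fraction,
                               seed=1)

    def test_background_fraction_gives_background_share(self):
        _, truth = simulate_experiment(small_config(n_genes=1000, seed=4))
        background = len(truth.responders) / len(truth.table)
        sets = simulate_gene_sets(truth, n_sets=1,
                                  enriched_fraction=background, seed=5,
                                  set_size=100)
        members = set(sets["responder_module"].genes)
        share = len(members & set(truth.responders)) / len(members)
        assert abs(share - background) < 0.1

    def test_strongly_enriched_set_attains_smallest_ora_p(self):
        _, truth = simulate_experiment(small_config(n_genes=1000, seed=4))
        sets = simulate_gene_sets(truth, n_sets=8, enriched_fraction=0.9,
                                  seed=5, set_size=60)
        universe = list(truth.table.index)
        results = enrich_collection(truth.responders, sets, universe)
        best = results.sort_values("p").iloc[0]
        assert best["set"] == "responder_module"
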