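import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from ergpanel import (RunConfig, cv_statistic, mean_cv_by_set,
                      rank_by_stability, response_profile, select_panel,
                      stability_records)
from ergpanel.response import ResponseProfiles
from ergpanel.stability import StabilityRecord

from conftest import make_experiment


def record(gene, av, cv, sd=0.0):
    return StabilityRecord(gene=gene, av=av, sd=sd, cv=cv, cv_defined=True)


class TestCvStatistic:
    def test_constant_vector(self):
        stat = cv_statistic([1.0] * 6)
        assert (stat.av, stat.sd, stat.cv) == (1.0, 0.0, 0.0)

    def test_two_values_hand_arithmetic(self):
        stat = cv_statistic([2.0, 4.0])
        assert stat.av == pytest.approx(3.0)
        assert stat.sd == pytest.approx(math.sqrt(2), abs=1e-12)
        assert stat.cv == pytest.approx(0.4714, abs=1e-4)

    def test_zero_mean_flags_undefined(self):
        stat = cv_statistic([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0])
        assert stat.av == 0.0
        assert not stat.defined
        assert math.isnan(stat.cv)

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            cv_statistic([1.0])

    def test_matches_longhand_formula(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            vals = rng.normal(2, 1, rng.integers(2, 10))
            av, sd, cv = oracles.cv_by_hand(vals)
            stat = cv_statistic(vals)
            assert stat.av == pytest.approx(av, abs=1e-12)
            assert stat.sd == pytest.approx(sd, abs=1e-12)
            assert stat.cv == pytest.approx(cv, abs=1e-12)


class TestRanking:
    def test_ascending_cv_order(self):
        records = [record("A", 1.0, 0.3), record("B", 1.0, 0.1),
                   record("C", 1.0, 0.2)]
        ranked = rank_by_stability(records)
        assert [r.gene for r in ranked] == ["B", "C", "A"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_tie_broken_by_larger_abs_av(self):
        records = [record("A", 1.0, 0.2), record("B", -2.0, 0.2)]
        assert [r.gene for r in rank_by_stability(records)] == ["B", "A"]

    def test_remaining_tie_broken_by_gene_symbol(self):
        records = [record("ZZZ", 1.0, 0.2), record("AAA", 1.0, 0.2)]
        assert [r.gene for r in rank_by_stability(records)] == ["AAA", "ZZZ"]

    def test_undefined_cv_excluded_not_error(self):
        records = [record("A", 1.0, 0.2),
                   StabilityRecord(gene="Z", av=0.0, sd=1.0, cv=math.nan,
                                   cv_defined=False)]
        ranked = rank_by_stability(records)
        assert [r.gene for r in ranked] == ["A"]


class TestMeanCvBySet:
    def test_single_gene_set(self):
        ranked = rank_by_stability([record("A", 1.0, 0.12)])
        table = mean_cv_by_set(ranked, [1])
        assert table.loc[0, "mean_cv"] == pytest.approx(0.12)
        assert table.loc[0, "sd_cv"] == 0.0

    def test_oversized_set_rejected_naming_size(self):
        ranked = rank_by_stability([record("A", 1.0, 0.1),
                                    record("B", 1.0, 0.2)])
        with pytest.raises(ValueError, match="30"):
            mean_cv_by_set(ranked, [30])

    @given(st.lists(st.floats(min_value=0.0, max_value=10.0,
                              allow_nan=False), min_size=2, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_prefix_mean_monotone_on_sorted_cvs(self, cvs):
        records = [record(f"G{i:03d}", 1.0, cv) for i, cv in enumerate(cvs)]
        ranked = rank_by_stability(records)
        sizes = list(range(1, len(ranked) + 1))
        means = mean_cv_by_set(ranked, sizes)["mean_cv"].to_numpy()
        assert np.all(np.diff(means) >= -1e-12)


class TestSelectPanel:
    def _profiles(self, genes, p_values, control_fpkm=None):
        genes = list(genes)
        n = len(genes)
        summary = pd.DataFrame(
            {"mean_log2_ratio": np.zeros(n), "sd_log2_ratio": np.zeros(n),
             "p_value": p_values,
             "mean_control_fpkm": control_fpkm or [10.0] * n,
             "mean_treated_fpkm": [10.0] * n},
            index=pd.Index(genes, name="gene"))
        ratios = pd.DataFrame(np.zeros((n, 2)), index=summary.index)
        return ResponseProfiles(ratios=ratios, summary=summary)

    def test_toy_table(self):
        # E has the lowest cv but fails the fold-change filter.
        records = [record("A", 2.0, 0.1), record("B", 1.5, 0.5),
                   record("C", -2.0, 0.2), record("D", -1.0, 0.3),
                   record("E", 0.1, 0.05)]
        profiles = self._profiles("ABCDE", [0.01] * 5)
        config = RunConfig(n_up=1, n_down=1, top_k=2, fc_threshold=0.585)
        panel = select_panel(profiles, records, config)
        assert [r.gene for r in panel.up] == ["A"]
        assert [r.gene for r in panel.down] == ["C"]
        assert not panel.warnings

    def test_shortage_returns_all_with_warning(self):
        records = [record("A", 2.0, 0.1), record("B", 1.5, 0.2)]
        profiles = self._profiles("AB", [0.01, 0.01])
        panel = select_panel(profiles, records,
                             RunConfig(n_up=10, n_down=10, top_k=5))
        assert [r.gene for r in panel.up] == ["A", "B"]
        assert panel.down == ()
        assert len(panel.warnings) == 2

    def test_exact_sizes_on_synthetic_defaults(self, sim_data, run_config):
        experiment, _ = sim_data
        profiles = response_profile(experiment, run_config)
        records = stability_records(profiles, run_config)
        panel = select_panel(profiles, records, run_config)
        assert len(panel.up) == run_config.n_up
        assert len(panel.down) == run_config.n_down
        assert len(panel.top_k) == run_config.top_k
        assert set(r.gene for r in panel.top_k) <= set(panel.genes)

    def test_agrees_with_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(31)
        for trial in range(15):
            n = int(rng.integers(5, 51))
            genes = [f"G{i:02d}" for i in range(n)]
            avs = rng.normal(0, 1.5, n)
            cvs = np.abs(rng.normal(0.3, 0.2, n)) + 0.01
            pvals = rng.uniform(0, 0.2, n)
            fpkm = rng.uniform(0, 5, n)
            records = [StabilityRecord(gene=g, av=a, sd=abs(a) * c, cv=c,
                                       cv_defined=True)
                       for g, a, c in zip(genes, avs, cvs)]
            profiles = self._profiles(genes, pvals, list(fpkm))
            config = RunConfig(n_up=4, n_down=4, top_k=5,
                               fc_threshold=0.5, expression_floor=1.0)
            panel = select_panel(profiles, records, config)
            table = [{"gene": g, "av": a, "cv": c, "cv_defined": True,
                      "p": p, "mean_control_fpkm": f}
                     for g, a, c, p, f in zip(genes, avs, cvs, pvals, fpkm)]
            up, down, top = oracles.select_panel_bruteforce(
                table, 4, 4, 5, config.alpha, 0.5, 1.0)
            assert [r.gene for r in panel.up] == up
            assert [r.gene for r in panel.down] == down
            assert [r.gene for r in panel.top_k] == top


class TestScaleRobustness:
    def test_global_fpkm_scaling_preserves_cv_and_ranking(self):
        rng = np.random.default_rng(13)
        treated = rng.uniform(1, 100, (20, 6))
        control = rng.uniform(1, 100, (20, 6))
        config = RunConfig(pseudocount=1e-12)
        base = make_experiment(treated, control)
        scaled = make_experiment(treated * 37.0, control * 37.0)
        rec_a = stability_records(response_profile(base, config), config)
        rec_b = stability_records(response_profile(scaled, config), config)
        for a, b in zip(rec_a, rec_b):
            assert a.cv == pytest.approx(b.cv, rel=1e-9) or (
                math.isnan(a.cv) and math.isnan(b.cv))
        assert ([r.gene for r in rank_by_stability(rec_a)]
                == [r.gene for r in rank_by_stability(rec_b)])
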