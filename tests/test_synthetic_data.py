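"""Tests for the planted-activity scenario generator and recovery scoring."""

import dataclasses
import math

import numpy as np
import pytest

from regnetcompare.data_model import filter_significant, write_de_table
from regnetcompare.regulator_scoring import score_all
from regnetcompare.synthetic_data import (
    ContrastSpec,
    ScenarioConfig,
    SyntheticTruth,
    default_scenario,
    generate,
    truth_eval,
)
from regnetcompare.upr_selection import (
    UniquenessVerdict,
    Branch,
    Verdict,
    exclude_and_dedup,
    stringent_filter,
)

from conftest import small_config


class TestDeterminism:
    def test_same_seed_identical_output(self, tmp_path):
        s1 = generate(small_config(seed=3))
        s2 = generate(small_config(seed=3))
        assert s1.tables.keys() == s2.tables.keys()
        for cid in s1.tables:
            p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
            write_de_table(s1.tables[cid], p1)
            write_de_table(s2.tables[cid], p2)
            assert p1.read_bytes() == p2.read_bytes()
        assert s1.network.edges == s2.network.edges
        assert s1.truth.planted == s2.truth.planted

    def test_distinct_seeds_distinct_tables(self):
        s1 = generate(small_config(seed=3))
        s2 = generate(small_config(seed=4))
        cid = next(iter(s1.tables))
        t1, t2 = s1.tables[cid], s2.tables[cid]
        assert any(t1[g].log2fc != t2[g].log2fc for g in t1.universe)


class TestConfigValidation:
    def test_targets_exceeding_genes_rejected(self):
        cfg = dataclasses.replace(small_config(), targets_per_regulator=(600, 700))
        with pytest.raises(ValueError, match="exceeds n_genes"):
            generate(cfg)

    def test_unknown_planted_regulator_rejected(self):
        cfg = small_config()
        cfg.contrasts = [ContrastSpec("c", {"NOT_A_REG": 1})]
        with pytest.raises(ValueError, match="NOT_A_REG"):
            generate(cfg)

    def test_effect_below_noise_floor_rejected(self):
        cfg = small_config(effect_size=0.1)  # noise_sd default 0.25
        with pytest.raises(ValueError, match="noise floor"):
            generate(cfg)

    def test_duplicate_contrast_ids_rejected(self):
        cfg = small_config()
        cfg.contrasts = cfg.contrasts + [cfg.contrasts[0]]
        with pytest.raises(ValueError, match="duplicate contrast"):
            generate(cfg)

    def test_bad_sign_fraction_rejected(self):
        cfg = dataclasses.replace(small_config(), activation_sign_fraction=1.2)
        with pytest.raises(ValueError):
            generate(cfg)


class TestNullCalibration:
    def test_zero_effect_gives_nominal_significance_rate(self):
        cfg = small_config(effect_size=0.0)
        cfg = dataclasses.replace(cfg, n_genes=4000, baseline_bias=0.0)
        scenario = generate(cfg, seed=123)
        table = scenario.tables["modelA"]
        # with |FC| > 1 non-binding, the p < 0.001 filter admits ~0.1 % of genes
        frac = len(filter_significant(table, 1.0, 0.001)) / len(table)
        assert frac == pytest.approx(0.001, abs=0.002)
        assert scenario.truth.shifts["modelA"] == {}

    def test_no_planting_yields_no_stringent_uprs(self):
        zero = 0
        for seed in range(10):
            cfg = small_config(seed=seed)
            cfg.contrasts = [ContrastSpec("null", {})]
            scenario = generate(cfg)
            scored = score_all(scenario.tables["null"], scenario.network)
            scored = exclude_and_dedup(scored, scenario.network.annotations)
            zero += not stringent_filter(scored)
        assert zero == 10


class TestPlantedSignal:
    def test_noiseless_limit_z_is_sqrt_n(self):
        cfg = ScenarioConfig(
            n_genes=300, n_regulators=5, targets_per_regulator=(9, 9),
            activation_sign_fraction=1.0, zero_sign_fraction=0.0,
            noise_sd=0.01, baseline_bias=0.0,
            contrasts=[ContrastSpec("c", {"R000": 1}, effect_size=3.0)],
            panel_size=10, seed=0)
        scenario = generate(cfg)
        results = {u.regulator: u for u in score_all(scenario.tables["c"],
                                                     scenario.network)}
        u = results["R000"]
        assert u.n_targets == 9
        assert u.z == pytest.approx(math.sqrt(9))
        assert all(m.observed == m.expected for m in u.matched_targets)

    def test_default_scenario_responsive_fraction_near_target(self):
        fracs = []
        for seed in range(3):
            scenario = generate(default_scenario(seed))
            for cid, table in scenario.treated_tables.items():
                fracs.append(len(filter_significant(table)) / len(table))
        assert abs(np.mean(fracs) - 0.126) < 0.03

    def test_effect_size_ladder_monotone_sensitivity(self):
        sens = []
        for effect in (1.1, 1.6, 2.5):
            hits = total = 0
            for seed in (0, 1):
                scenario = generate(small_config(seed=seed, effect_size=effect))
                for cid, table in scenario.tables.items():
                    scored = exclude_and_dedup(score_all(table, scenario.network),
                                               scenario.network.annotations)
                    called = {u.regulator for u in stringent_filter(scored)}
                    planted = set(scenario.truth.planted[cid])
                    hits += len(called & planted)
                    total += len(planted)
            sens.append(hits / total)
        assert sens[0] <= sens[1] <= sens[2]

    def test_panel_overlaps_responsive_genes(self):
        scenario = generate(small_config(seed=6))
        responsive = set().union(*scenario.truth.responsive_genes.values())
        overlap = len(set(scenario.panel.members) & responsive)
        expected = round(scenario.config.panel_size
                         * scenario.config.panel_responsive_overlap)
        assert overlap == expected

    def test_coregulated_sets_are_regulator_targets(self):
        scenario = generate(small_config(seed=6))
        coreg = [s for s in scenario.gene_sets if s.set_id.startswith("COREG_")]
        assert coreg
        for s in coreg:
            reg = s.set_id.removeprefix("COREG_")
            assert s.members == frozenset(scenario.network.targets_of(reg))


class TestTruthEval:
    def truth(self):
        return SyntheticTruth(
            planted={"A": {"R1": 1, "R2": -1}, "B": {"R2": -1, "R3": 1}},
            shifts={"A": {"g1": 1, "g2": -1}, "B": {"g2": -1, "g3": 1}},
        )

    def test_perfect_recovery(self):
        rep = truth_eval(self.truth(), stringent={"A": ["R1", "R2"], "B": ["R2", "R3"]})
        assert rep.stringent_sensitivity == 1.0
        assert rep.stringent_fdp == 0.0

    def test_empty_output_zero_sensitivity(self):
        rep = truth_eval(self.truth(), stringent={"A": [], "B": []})
        assert rep.stringent_sensitivity == 0.0

    def test_false_positives_counted(self):
        rep = truth_eval(self.truth(), stringent={"A": ["R1", "R9"], "B": []})
        assert rep.stringent_fdp == pytest.approx(0.5)

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError, match="unknown contrast"):
            truth_eval(self.truth(), stringent={"Z": []})

    def verdict(self, reg, a, b, v):
        return UniquenessVerdict(reg, a, b, v, Branch.ABSENT, {})

    def test_uniqueness_scoring(self):
        verdicts = [
            self.verdict("R1", "A", "B", Verdict.UNIQUE_TO_A),   # planted A only: correct
            self.verdict("R2", "A", "B", Verdict.UNIQUE_TO_A),   # planted both: wrong
            self.verdict("R9", "A", "B", Verdict.UNIQUE_TO_A),   # unplanted: skipped
        ]
        rep = truth_eval(self.truth(), uniqueness=verdicts)
        assert rep.uniqueness_evaluated == 2
        assert rep.uniqueness_accuracy == pytest.approx(0.5)

    def test_specific_gene_scoring(self):
        # truth: up-specific to A vs B is g1 (g2 shifted down in both)
        rep = truth_eval(self.truth(), specific={("A", "B", "up"): {"g1"}})
        assert rep.specific_precision == 1.0 and rep.specific_recall == 1.0
        rep2 = truth_eval(self.truth(), specific={("A", "B", "up"): {"g1", "g3"}})
        assert rep2.specific_precision == pytest.approx(0.5)

    def test_shuffled_labels_recover_at_chance(self):
        scenario = generate(small_config(seed=8))
        rng = np.random.default_rng(0)
        regs = scenario.network.regulators
        accs = []
        for cid, planted in scenario.truth.planted.items():
            shuffled = [str(r) for r in rng.permutation(regs)[:len(planted)]]
            rep = truth_eval(scenario.truth, stringent={cid: shuffled})
            accs.append(rep.per_contrast[cid]["sensitivity"])
        # 4 planted of 30 regulators: chance sensitivity ~ 13 %
        assert np.mean(accs) < 0.5
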