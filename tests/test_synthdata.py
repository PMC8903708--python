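"""Synthetic-data generators: study-design structure, seeded determinism,
and statistical calibration of the planted signals."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from circscreen import splicing, survstats, synthdata
from circscreen.errors import ConfigError, GenerationError
from circscreen.synthdata import (
    AsSimConfig,
    ExprSimConfig,
    OrfSpec,
    SurvSimConfig,
    gen_as_counts,
    gen_circle,
    gen_expression,
    gen_genesets,
    gen_survival,
)


class TestGenExpression:
    def test_default_matches_study_design(self):
        data = gen_expression(synthdata.default_expression_config(seed=0))
        assert len(data.sample_ids) == 13
        counts = {g: len(data.samples_in_group(g)) for g in ("NPC", "IgD", "IgG")}
        assert counts == {"NPC": 3, "IgD": 5, "IgG": 5}
        assert (data.values.to_numpy() >= 0).all()

    def test_seeded_determinism(self):
        a = gen_expression(ExprSimConfig(seed=42))
        b = gen_expression(ExprSimConfig(seed=42))
        assert a.values.equals(b.values)
        assert a.groups == b.groups

    def test_within_module_correlation_calibrated(self):
        # one plain 50-probe module at target correlation 0.9, 50 samples
        cors = []
        for seed in range(20):
            cfg = ExprSimConfig(
                n_probes=50,
                group_sizes={"NPC": 25, "IgG": 25},
                n_modules=1,
                module_sizes=[50],
                within_module_cor=0.9,
                n_igd_up_modules=0,
                seed=seed,
            )
            data = gen_expression(cfg)
            x = np.log2(data.values.to_numpy() + 1)
            c = np.corrcoef(x)
            iu = np.triu_indices_from(c, k=1)
            cors.append(c[iu].mean())
        assert abs(np.mean(cors) - 0.9) < 0.1

    def test_truth_metadata_records_modules_and_trait(self):
        data = gen_expression(synthdata.coexpression_preset(seed=0))
        assert data.truth["igd_up_modules"] == ["M1", "M2"]
        labels = set(data.truth["module"].values())
        assert {"M1", "M2", "M3", "M4", "M5", "M6", "M7", ""} == labels

    def test_de_spec_shifts_target_group(self):
        cfg = ExprSimConfig(
            n_probes=20,
            n_modules=0,
            module_sizes=[],
            n_igd_up_modules=0,
            de_spec=[([0, 1], 2.0, "IgD")],
            seed=1,
        )
        data = gen_expression(cfg)
        base = gen_expression(replace(cfg, de_spec=[]))
        igd = data.samples_in_group("IgD")
        ratio = np.log2(data.values.loc["probe_00001", igd]) - np.log2(
            base.values.loc["probe_00001", igd]
        )
        assert np.allclose(ratio, 2.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"module_sizes": [100] * 7},  # exceeds n_probes
            {"within_module_cor": 1.5},
            {"noise_sd": 0.0},
            {"n_igd_up_modules": 8},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ExprSimConfig(n_probes=400, **kwargs)


class TestGenCircle:
    def test_direct_construction_small_circle(self):
        # product length counts the initiator M, so a 3-aa product on a
        # 12-nt circle occupies it exactly: AUG, two coding codons, stop
        circ = gen_circle(OrfSpec(circle_length=12, start_pos=1, product_length_aa=3))
        seq = circ.sequence
        assert len(seq) == 12
        assert seq[:3] == "AUG"
        assert seq[3:6] not in ("UAA", "UAG", "UGA")
        assert seq[6:9] not in ("UAA", "UAG", "UGA")
        assert seq[9:12] in ("UAA", "UAG", "UGA")

    def test_rolling_circle_spec_traversal_count(self):
        circ = gen_circle(OrfSpec(circle_length=10, start_pos=1, product_length_aa=7))
        calls = synthdata.find_circular_orfs(circ, min_length_aa=1)
        planted = [c for c in calls if c.start == 1][0]
        assert planted.length_aa == 7
        assert planted.traversals == 2

    def test_fixture_preset_recovers_planted_orf(self):
        circ = synthdata.circhnrnpu_preset(seed=0)
        assert len(circ) == 1733
        assert circ.ires == (201, 374)
        calls = synthdata.find_circular_orfs(circ)
        primary = synthdata.circorf.primary_orf(calls)
        assert (primary.start, primary.length_aa) == (380, 603)

    def test_finder_recovers_planted_orf_across_specs(self):
        # the generator's defining invariant, over a spread of geometries
        for L, start, n_aa, seed in [
            (60, 10, 12, 0),
            (61, 35, 25, 1),
            (50, 48, 20, 2),
            (100, 1, 40, 3),
        ]:
            circ = gen_circle(OrfSpec(L, start, n_aa, None, seed))
            calls = synthdata.find_circular_orfs(circ, min_length_aa=1)
            assert any(c.start == start and c.length_aa == n_aa for c in calls)

    def test_infeasible_spec_raises(self):
        # L=9, 3 codons + stop = 12 nt: the stop wraps onto the AUG itself
        with pytest.raises(GenerationError):
            gen_circle(OrfSpec(circle_length=9, start_pos=1, product_length_aa=3))

    def test_seeded_determinism(self):
        a = gen_circle(OrfSpec(seed=5))
        b = gen_circle(OrfSpec(seed=5))
        assert a.sequence == b.sequence


class TestGenAsCounts:
    def test_depth_zero_rejected(self):
        with pytest.raises(ConfigError):
            AsSimConfig(depth=0)

    def test_bad_category_probs_rejected(self):
        with pytest.raises(ConfigError):
            AsSimConfig(category_probs={"SE": 0.5, "RI": 0.4})

    def test_degenerate_categories(self):
        table = gen_as_counts(AsSimConfig(n_events=50, category_probs={"SE": 1.0}, seed=0))
        assert all(ev.event_type == "SE" for ev in table.events)

    def test_psi_estimate_consistent_at_high_depth(self):
        cfg = AsSimConfig(n_events=200, psi_cond1=0.3, psi_cond2=0.3, depth=10_000, seed=1)
        table = gen_as_counts(cfg)
        psis = []
        for ev in table.events:
            for s in ev.inclusion_counts:
                psis.append(
                    splicing.compute_psi(
                        ev.inclusion_counts[s], ev.skipping_counts[s],
                        ev.eff_len_inc, ev.eff_len_skip,
                    )
                )
        assert abs(np.mean(psis) - 0.3) < 0.01

    def test_null_false_positive_rate_controlled(self):
        # equal true PSI in both conditions: BH-significant fraction at
        # q < 0.05 stays at or below the nominal level
        rates = []
        for seed in range(10):
            cfg = AsSimConfig(n_events=1000, psi_cond1=0.5, psi_cond2=0.5, depth=50, seed=seed)
            events = splicing.differential_splicing(gen_as_counts(cfg))
            rates.append(np.mean([e.significant for e in events]))
        assert np.mean(rates) <= 0.05 + 0.01

    def test_seeded_determinism(self):
        a = gen_as_counts(AsSimConfig(n_events=20, seed=3))
        b = gen_as_counts(AsSimConfig(n_events=20, seed=3))
        assert [e.inclusion_counts for e in a.events] == [e.inclusion_counts for e in b.events]


class TestGenSurvival:
    def test_no_censoring_means_all_events(self):
        t = gen_survival(SurvSimConfig(n_subjects=50, censor_fraction=0.0, seed=0))
        assert (t.events == 1).all()

    def test_censor_fraction_approximately_achieved(self):
        t = gen_survival(SurvSimConfig(n_subjects=5000, censor_fraction=0.3, seed=1))
        assert abs(1 - t.events.mean() - 0.3) < 0.05

    def test_null_logrank_p_uniform(self):
        # hazard_ratio = 1: log-rank p across seeds ~ U(0,1)
        ps = []
        for seed in range(500):
            t = gen_survival(
                SurvSimConfig(n_subjects=60, hazard_ratio=1.0, censor_fraction=0.1, seed=seed)
            )
            strata = survstats.dichotomize_by_expression(t)
            groups = survstats.split_survival(t, strata)
            ps.append(survstats.logrank_test(groups["high"], groups["low"]).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_at_strong_hazard_ratio(self):
        hits = 0
        for seed in range(100):
            t = gen_survival(
                SurvSimConfig(n_subjects=200, hazard_ratio=3.0, censor_fraction=0.2, seed=seed)
            )
            strata = survstats.dichotomize_by_expression(t)
            groups = survstats.split_survival(t, strata)
            if survstats.logrank_test(groups["high"], groups["low"]).p < 0.05:
                hits += 1
        assert hits >= 90

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            SurvSimConfig(hazard_ratio=0)
        with pytest.raises(ConfigError):
            SurvSimConfig(censor_fraction=1.0)


class TestGenGenesets:
    def test_planted_set_ranks_first(self):
        coll, hits = gen_genesets(
            universe_size=20, n_sets=10, planted=(5, 4), n_hits=5,
            set_size_range=(4, 8), seed=0,
        )
        results = survstats.ora_enrichment(hits, coll)
        assert results[0].set_name == "planted_set"

    def test_empty_collection(self):
        coll, _ = gen_genesets(universe_size=10, n_sets=0, seed=0)
        assert coll.sets == {}

    def test_seeded_determinism(self):
        a, ha = gen_genesets(50, 5, planted=(10, 5), seed=9)
        b, hb = gen_genesets(50, 5, planted=(10, 5), seed=9)
        assert a.sets == b.sets and ha == hb

    def test_oversized_set_rejected(self):
        with pytest.raises(ConfigError):
            gen_genesets(universe_size=5, n_sets=1, planted=(10, 2), seed=0)
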