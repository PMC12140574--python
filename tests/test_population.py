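"""Population generator and the three experiment designs."""

import numpy as np
import pytest

from grouplearn.analysis import selectivity_from_records
from grouplearn.population import (
    DEMO_BETA,
    EXP2_CONDITIONS,
    GroupParams,
    build_experiment,
    exp2_groups,
    exp3_groups,
    generate_evidence,
    sample_dp_population,
    sample_population,
    sample_stick_weights,
    simulate_cohort,
    simulate_participant,
)
from grouplearn.strategies import StrategyId


class TestStickBreaking:
    def test_small_alpha_first_weight_near_one(self, rng):
        w = sample_stick_weights(1e-9, truncation=5, rng=rng)
        assert w.rho[0] > 0.999

    def test_partial_sums_bounded(self, rng):
        for _ in range(20):
            w = sample_stick_weights(2.0, truncation=20, rng=rng)
            assert np.all(w.rho >= 0)
            assert np.all(np.cumsum(w.rho) <= 1 + 1e-12)

    def test_mean_first_weight_alpha_one(self, rng):
        draws = np.array([
            sample_stick_weights(1.0, 1, rng).rho[0] for _ in range(100_000)
        ])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.5) < 3 * se


class TestSamplePopulation:
    def test_moment_recovery(self, rng):
        groups = {
            "red": GroupParams((0.85, 0.5), (0.08, 0.15), 0.2, 0.05),
            "blue": GroupParams((0.15, 0.5), (0.08, 0.15), 0.8, 0.05),
        }
        agents = sample_population(groups, 200, rng, balanced=True)
        for label, params in groups.items():
            cues = np.array([a.phi for a in agents if a.z == label])
            se = params.cue_sd / np.sqrt(len(cues))
            assert abs(cues.mean() - params.cue_mean) < 4 * se

    def test_single_group_degenerate(self, rng):
        groups = {"only": GroupParams((0.5, 0.5), (0.1, 0.1), 0.5, 0.1)}
        agents = sample_population(groups, 10, rng)
        assert all(a.z == "only" for a in agents)

    def test_group_separation_only_on_relevant_dim(self, rng):
        groups = exp2_groups(relevant_dim=0)
        agents = sample_population(groups, 400, rng, balanced=True)
        w = np.array([a.utility.weights for a in agents])
        z = np.array([a.z == "red" for a in agents])
        gap_colour = abs(w[z, 0].mean() - w[~z, 0].mean())
        gap_shape = abs(w[z, 1].mean() - w[~z, 1].mean())
        assert gap_colour > 0.5
        assert gap_shape < 0.1
        # within-group variation exists on both dimensions
        assert w[z, 0].std() > 0.02 and w[z, 1].std() > 0.05

    def test_dp_population_truncation(self, rng):
        agents, groups, sticks = sample_dp_population(1.0, 30, rng)
        assert len(agents) == 30
        assert len(sticks.rho) == len(groups) == 20


class TestDesignInvariants:
    def test_exp1_counts(self):
        d = build_experiment(1, seed=4)
        n_evidence = sum(len(lv.actors) for lv in d.evidence_levels)
        assert n_evidence == 8  # 4 per agent
        per_agent = {}
        for lv in d.evidence_levels:
            for a in lv.actors:
                per_agent[a] = per_agent.get(a, 0) + 1
        assert set(per_agent.values()) == {4}
        assert len(d.test_trials) == 2
        assert d.ego_cue is None

    def test_exp2_roster(self):
        d = build_experiment(2, 4, seed=4)
        cue_bearing = [a for a in d.agents.values()
                       if a.phi is not None and "_ev" in a.id]
        assert len(cue_bearing) == 4
        assert sum(a.z == "red" for a in cue_bearing) == 2
        novel = {a for t in d.test_trials if t.phase == 3
                 for a in t.demonstrators}
        assert novel == {"red_test", "blue_test"}

    def test_exp2_cue_assignment_per_condition(self):
        for cond, (relevance, cue_mode) in EXP2_CONDITIONS.items():
            d = build_experiment(2, cond, seed=9)
            if cue_mode == "invisible":
                assert d.ego_cue is None
            elif relevance == "relevant":
                aligned = "red" if not d.counterbalanced else "blue"
                other = "blue" if aligned == "red" else "red"
                expect = (d.groups[aligned].cue_mean if cue_mode == "matched"
                          else d.groups[other].cue_mean)
                assert d.ego_cue == expect
            else:
                assert d.ego_cue in (0.2, 0.8)

    def test_exp2_illegal_condition_rejected(self):
        with pytest.raises(ValueError):
            build_experiment(2, 6, seed=0)
        with pytest.raises(ValueError):
            build_experiment(2, None, seed=0)

    def test_exp3_contrast_counts(self):
        d = build_experiment(3, "invisible", seed=4)
        ctxs = [lv.context for lv in d.evidence_levels]
        assert ctxs.count((1, 0)) == 3  # colour-contrast choices
        assert ctxs.count((0, 1)) == 2  # shape-contrast choices
        test_ctxs = [t.context for t in d.test_trials]
        assert test_ctxs.count((1, 0)) == 4 and test_ctxs.count((0, 1)) == 4

    def test_exp3_context_flips_aligned_demonstrator(self):
        d = build_experiment(3, "invisible", seed=4)
        by_ctx = {}
        for t in d.test_trials:
            by_ctx.setdefault(t.context, set()).add(t.aligned)
        assert by_ctx[(1, 0)] != by_ctx[(0, 1)]

    def test_exp3_illegal_condition_rejected(self):
        with pytest.raises(ValueError):
            build_experiment(3, "matched", seed=0)

    def test_seed_reproducibility(self):
        a = build_experiment(2, 5, seed=13)
        b = build_experiment(2, 5, seed=13)
        assert a.ego_utility == b.ego_utility
        assert a.ego_cue == b.ego_cue
        assert [t.grid.signature() for t in a.test_trials] == [
            t.grid.signature() for t in b.test_trials
        ]


class TestSimulateParticipant:
    def test_indiscriminate_choices_roughly_uniform(self):
        d = build_experiment(1, seed=2)
        rng = np.random.default_rng(3)
        ev = generate_evidence(d, rng)
        chosen = []
        for i in range(150):
            recs = simulate_participant(
                d, StrategyId.S1_indiscriminate, rng=rng, evidence=ev,
                participant_id=f"p{i}")
            chosen += [r.chosen_demonstrator for r in recs]
        frac = np.mean([c == "aligned" for c in chosen])
        n = len(chosen)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_greedy_dyadic_always_copies_aligned(self):
        d = build_experiment(1, seed=2)
        rng = np.random.default_rng(3)
        ev = generate_evidence(d, rng)
        recs = simulate_participant(
            d, StrategyId.S2_rational_dyadic, beta_ego=1e-6, rng=rng,
            evidence=ev)
        assert all(r.chosen_demonstrator == "aligned" for r in recs)

    def test_records_carry_predictions_for_all_strategies(self):
        d = build_experiment(2, 5, seed=2)
        rng = np.random.default_rng(3)
        recs = simulate_participant(d, StrategyId.S4_rational_cue, rng=rng)
        for r in recs:
            assert set(r.predictions) == set(StrategyId)

    def test_participant_copies_demonstrator_path(self):
        d = build_experiment(1, seed=2)
        rng = np.random.default_rng(3)
        recs = simulate_participant(d, StrategyId.S2_rational_dyadic, rng=rng)
        for r in recs:
            chosen_traj = r.demo_trajectories[r.chosen_demonstrator]
            assert r.participant_trajectory.steps == chosen_traj.steps

    def test_cohort_reproducible_under_seed(self):
        d = build_experiment(3, "arbitrary", seed=5)
        recs1, _ = simulate_cohort(
            d, StrategyId.S4_rational_cue, 3, rng=np.random.default_rng(8))
        recs2, _ = simulate_cohort(
            d, StrategyId.S4_rational_cue, 3, rng=np.random.default_rng(8))
        assert [r.chosen_demonstrator for r in recs1] == [
            r.chosen_demonstrator for r in recs2
        ]


class TestCounterbalanceSymmetry:
    def test_mirrored_ego_mirrors_alignment(self):
        # find two seeds with opposite counterbalance draws
        designs = [build_experiment(2, 4, seed=s) for s in range(8)]
        a = next(d for d in designs if not d.counterbalanced)
        b = next(d for d in designs if d.counterbalanced)
        assert a.ego_utility.weights[0] > 0.5 > b.ego_utility.weights[0]
        a_aligned = {t.aligned for t in a.test_trials if t.phase == 3}
        b_aligned = {t.aligned for t in b.test_trials if t.phase == 3}
        assert a_aligned == {"red_test"} and b_aligned == {"blue_test"}

    def test_selectivity_invariant_to_counterbalance(self):
        # pooled aligned-selectivity is computed per record, so cohorts with
        # opposite counterbalancing produce comparable summaries
        rng = np.random.default_rng(0)
        from grouplearn.population import simulate_condition

        recs = simulate_condition(2, 4, StrategyId.S2_rational_dyadic, 20,
                                  rng=rng)
        sel = selectivity_from_records(recs, phase=2)
        assert 0.0 < sel.relative["target"] < 1.0
        assert sel.n <= 20 * 4
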