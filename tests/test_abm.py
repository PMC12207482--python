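"""Agent-based simulator: rosters, choice cascade, episodes, intervention."""

import dataclasses

import numpy as np
import pytest

from partnerchoice import abm, metrics, model
from partnerchoice.abm import (
    Agent,
    CommunitySpec,
    EpisodeConfig,
    InterventionSpec,
    StagHuntPayoffs,
)


def cell_counts(roster):
    out = {}
    for a in roster:
        out[(a.color, a.strategy)] = out.get((a.color, a.strategy), 0) + 1
    return out


class TestCommunity:
    @pytest.mark.parametrize(
        "bias, size, expected",
        [
            (1.0, 4, {("purple", "cooperator"): 2, ("teal", "defector"): 2}),
            (0.0, 8, {("purple", "cooperator"): 2, ("purple", "defector"): 2,
                      ("teal", "cooperator"): 2, ("teal", "defector"): 2}),
            (0.5, 8, {("purple", "cooperator"): 3, ("purple", "defector"): 1,
                      ("teal", "cooperator"): 1, ("teal", "defector"): 3}),
        ],
    )
    def test_cell_counts(self, bias, size, expected, rng):
        roster = abm.make_community(CommunitySpec(size=size, training_bias=bias),
                                    rng)
        assert cell_counts(roster) == expected

    def test_exact_marginals_and_unique_ids(self, rng):
        roster = abm.make_community(CommunitySpec(size=12, training_bias=0.5), rng)
        assert sum(a.color == "purple" for a in roster) == 6
        assert sum(a.is_cooperator for a in roster) == 6
        assert len({a.id for a in roster}) == 12

    def test_bias_to_population_mapping(self):
        pop = CommunitySpec(size=8, training_bias=0.5).population()
        assert pop.rho == pytest.approx(0.75)
        assert pop.tau == pytest.approx(0.25)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CommunitySpec(size=7, training_bias=0.0)
        with pytest.raises(ValueError):
            CommunitySpec(size=8)  # neither bias nor (rho, tau)
        with pytest.raises(ValueError):
            CommunitySpec(size=8, training_bias=0.5, rho=0.5, tau=0.5)


class TestPayoffs:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            StagHuntPayoffs(R=1, T=2, P=2, S=0)

    def test_cells(self):
        p = StagHuntPayoffs(R=4, T=3, P=3, S=1)
        assert p.payoff(True, True) == 4
        assert p.payoff(True, False) == 1
        assert p.payoff(False, True) == 3
        assert p.payoff(False, False) == 3


class TestFocalChoose:
    roster = [
        Agent(0, "purple", "cooperator"),
        Agent(1, "purple", "defector"),
        Agent(2, "teal", "defector"),
        Agent(3, "teal", "defector"),
    ]

    def test_full_stickiness_repairs(self, rng):
        focal = model.FocalParams(omega=0, s=1, b=0.5)
        prev = self.roster[2]
        for _ in range(20):
            assert abm.focal_choose(self.roster, prev, True, None, focal,
                                    rng) is prev

    def test_full_awareness_finds_single_cooperator(self, rng):
        focal = model.FocalParams(omega=1, s=0, b=0.5)
        for _ in range(20):
            chosen = abm.focal_choose(self.roster, None, False, None, focal, rng)
            assert chosen.is_cooperator

    def test_color_fallback_when_preferred_color_absent(self, rng):
        teal_only = [a for a in self.roster if a.color == "teal"]
        focal = model.FocalParams(omega=0, s=0, b=1.0)
        for _ in range(20):
            assert abm.focal_choose(teal_only, None, False, None, focal,
                                    rng).color == "teal"

    def test_empty_flag_set_falls_through_to_color(self, rng):
        focal = model.FocalParams(omega=1, s=0, b=1.0)
        chosen = abm.focal_choose(self.roster, None, False, set(), focal, rng)
        assert chosen.color == "purple"

    def test_empty_roster_rejected(self, rng):
        with pytest.raises(ValueError):
            abm.focal_choose([], None, False, None,
                             model.FocalParams(0, 0, 0.5), rng)


class TestEpisodes:
    def test_all_cooperator_roster_pays_r_every_race(self, rng):
        roster = [Agent(i, "purple" if i % 2 else "teal", "cooperator")
                  for i in range(5)]
        cfg = EpisodeConfig()
        rec = abm.run_episode(roster, cfg, model.FocalParams(0.5, 0.5, 0.5), rng)
        assert rec.payoff == [cfg.payoffs.R] * cfg.n_races

    def test_payoff_matches_partner_action(self, rng):
        roster = abm.make_community(CommunitySpec(size=8, training_bias=0.5), rng)
        cfg = EpisodeConfig(n_coplayers=5)
        rec = abm.run_episode(roster[:5], cfg, model.FocalParams(0.3, 0.6, 0.4),
                              rng)
        for coop, pay in zip(rec.partner_cooperated, rec.payoff):
            assert pay == (cfg.payoffs.R if coop else cfg.payoffs.S)

    def test_seed_determinism(self):
        spec = CommunitySpec(size=12, training_bias=0.5)
        community = abm.make_community(spec, np.random.default_rng(3))
        cfg = EpisodeConfig()
        focal = model.FocalParams(0.4, 0.6, 0.7)
        a = abm.simulate_episodes(community, cfg, focal, 5, seed=11)
        b = abm.simulate_episodes(community, cfg, focal, 5, seed=11)
        assert [r.to_json_dict() for r in a] == [r.to_json_dict() for r in b]

    def test_episode_count_growth_preserves_prefix(self):
        community = abm.make_community(
            CommunitySpec(size=12, training_bias=0.0), np.random.default_rng(3)
        )
        cfg = EpisodeConfig()
        focal = model.FocalParams(0.4, 0.6, 0.7)
        short = abm.simulate_episodes(community, cfg, focal, 3, seed=11)
        long = abm.simulate_episodes(community, cfg, focal, 6, seed=11)
        assert [r.to_json_dict() for r in short] == [
            r.to_json_dict() for r in long[:3]
        ]

    def test_race0_matches_p0_in_finite_mode(self):
        # awareness cannot act before any interaction: race-0 type
        # frequencies follow the color-bias-only P(0)
        focal = model.FocalParams(omega=1.0, s=0.0, b=1.0)
        spec = CommunitySpec(size=12, training_bias=0.0)
        community = abm.make_community(spec, np.random.default_rng(0))
        recs = abm.simulate_episodes(community, EpisodeConfig(), focal, 2000,
                                     seed=7)
        first = [r.partner_type[0] for r in recs]
        purple = np.mean([t in (model.PC, model.PD) for t in first])
        coop = np.mean([t in (model.PC, model.TC) for t in first])
        se = np.sqrt(0.25 / 2000)
        # b = 1 picks purple whenever any purple coplayer was sampled;
        # an all-teal sample (prob C(6,5)/C(12,5) ~ 0.0076) falls back
        p_no_purple = 6 / 792
        se_p = np.sqrt(p_no_purple * (1 - p_no_purple) / 2000)
        assert abs(purple - (1 - p_no_purple)) < 4 * se_p
        assert abs(coop - 0.5) < 4 * se   # strategy split untouched by omega


class TestInfiniteMode:
    def test_frequencies_track_recursion(self, focal_example, pop_example, rng):
        n = 30_000
        counts = abm.infinite_type_frequencies(focal_example, pop_example, n, 4,
                                               rng)
        traj = model.trajectory(focal_example, pop_example, 3)
        for r in range(4):
            p = traj[r]
            se = np.sqrt(p * (1 - p) / n)
            assert np.all(np.abs(counts[r] / n - p) < 4 * se + 1e-9)

    def test_scalar_infinite_episode_matches_p0_race0(self, pop_example, rng):
        focal = model.FocalParams(omega=0.0, s=0.0, b=0.5)
        recs = [
            abm.run_episode((), EpisodeConfig(), focal,
                            np.random.default_rng([9, i]), mode="infinite",
                            pop=pop_example)
            for i in range(4000)
        ]
        freq = np.bincount([r.partner_type[0] for r in recs], minlength=4) / 4000
        p0 = model.initial_distribution(focal, pop_example)
        se = np.sqrt(p0 * (1 - p0) / 4000)
        assert np.all(np.abs(freq - p0) < 4 * se + 1e-9)

    def test_stickiness_recovery_with_cooperating_partners(self):
        # all partners cooperate, so the re-pair rate estimates s directly
        pop = model.PopulationParams(1.0, 1.0)
        focal = model.FocalParams(omega=0.0, s=0.7, b=0.5)
        recs = abm.simulate_episodes((), EpisodeConfig(), focal, 4000, seed=13,
                                     mode="infinite", pop=pop)
        beh = metrics.empirical_behavior(recs)
        se = np.sqrt(0.7 * 0.3 / beh.n_stickiness)
        assert beh.awareness_hat == 1.0
        assert abs(beh.stickiness_hat - 0.7) < 4 * se


class TestIntervention:
    def test_q_mapping_monotone_with_anchors(self):
        assert InterventionSpec(beta=0.0).q == 1.0
        assert InterventionSpec(beta=0.002).q == pytest.approx(0.75)
        assert InterventionSpec(beta=0.005).q == pytest.approx(0.5)
        assert InterventionSpec(beta=0.02).q == 0.0
        assert InterventionSpec(beta=1.0).q == 0.0
        betas = np.linspace(0, 0.03, 40)
        qs = [InterventionSpec(beta=b).q for b in betas]
        assert all(a >= b for a, b in zip(qs, qs[1:]))
        assert InterventionSpec(beta=0.02, availability=0.9).q == 0.9

    def test_effective_awareness_contract(self):
        assert abm.effective_awareness(0.3, None) == 0.3
        assert abm.effective_awareness(0.3, InterventionSpec(beta=0.0)) == 1.0
        assert abm.effective_awareness(
            0.3, InterventionSpec(beta=0.02)
        ) == pytest.approx(0.3)
        assert abm.effective_awareness(
            0.4, InterventionSpec(availability=0.5)
        ) == pytest.approx(0.7)

    def test_race0_neutral_under_intervention(self):
        # crowns cannot exist before the first interaction, so race-0
        # choices are identical draw-for-draw with the oracle run
        spec = CommunitySpec(size=12, training_bias=0.0)
        community = abm.make_community(spec, np.random.default_rng(2))
        focal = model.FocalParams(omega=0.8, s=0.5, b=0.7)
        plain = abm.simulate_episodes(community, EpisodeConfig(), focal, 500,
                                      seed=21)
        crowned_cfg = EpisodeConfig(intervention=InterventionSpec(beta=0.0))
        crowned = abm.simulate_episodes(community, crowned_cfg, focal, 500,
                                        seed=21)
        assert [r.partner_type[0] for r in plain] == [
            r.partner_type[0] for r in crowned
        ]
        n = 500
        p_freq = np.bincount([r.partner_type[0] for r in plain], minlength=4) / n
        c_freq = np.bincount([r.partner_type[0] for r in crowned],
                             minlength=4) / n
        se = np.sqrt(np.maximum(p_freq * (1 - p_freq), 1e-12) / n)
        assert np.all(np.abs(p_freq - c_freq) <= 3 * np.sqrt(2) * se)

    def test_crown_mode_with_full_survival_tracks_cooperators(self):
        # q = 1 and omega = 1: from race 1 the focal always finds a
        # crowned (cooperating) partner
        spec = CommunitySpec(size=12, training_bias=0.0)
        community = abm.make_community(spec, np.random.default_rng(4))
        focal = model.FocalParams(omega=1.0, s=0.0, b=0.5)
        cfg = EpisodeConfig(intervention=InterventionSpec(beta=0.0))
        recs = abm.simulate_episodes(community, cfg, focal, 300, seed=8)
        for rec in recs:
            if any(a.is_cooperator for a in rec.roster):
                assert all(rec.partner_cooperated[1:])
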