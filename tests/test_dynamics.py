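"""Game payoffs, punish-or-migrate decisions, imitation, diffusion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from pggmob import (
    InitialComposition,
    PayoffLedger,
    Population,
    SimulationParams,
    fermi_probability,
    group_members,
    init_population,
    play_pgg,
    punisher_response,
    random_diffusion,
    run_generation,
    seed_kernel,
    synchronous_update,
)
from pggmob.strategy import EMPTY, is_contributor


def pop_from(text):
    return Population.from_text(text)


class TestPlayPgg:
    def test_one_cooperator_two_defectors(self, params):
        pop = pop_from(".....\n.....\n.DCD.\n.....\n.....")
        led = PayoffLedger(5)
        play_pgg(pop, (2, 2), params.replace(r=2.0), led)
        assert led[(2, 2)] == pytest.approx(2 / 3 - 1)  # C: r*n_c*c/G - c
        assert led[(2, 1)] == pytest.approx(2 / 3)
        assert led[(2, 3)] == pytest.approx(2 / 3)

    def test_all_defectors_empty_pot(self, params):
        pop = pop_from("DDD\nDDD\nDDD")
        led = PayoffLedger(3)
        play_pgg(pop, (1, 1), params, led)
        assert led.total() == 0.0

    def test_isolated_contributor_keeps_surplus(self, params):
        pop = pop_from(".....\n.....\n..C..\n.....\n.....")
        led = PayoffLedger(5)
        play_pgg(pop, (2, 2), params.replace(r=2.0), led)
        assert led[(2, 2)] == pytest.approx(1.0)  # r*c - c with G=1

    def test_empty_focal_rejected(self, params):
        pop = pop_from(".....\n.....\n..C..\n.....\n.....")
        with pytest.raises(ValueError, match="empty"):
            play_pgg(pop, (0, 0), params, PayoffLedger(5))

    @given(seed=hst.integers(0, 500))
    @settings(derandomize=True, max_examples=30)
    def test_payoff_sum_identity_without_punishment(self, seed):
        """A single punishment-free game redistributes exactly (r-1)*n_c*c."""
        rng = np.random.default_rng(seed)
        grid = rng.choice(np.array([EMPTY, 0, 1], dtype=np.int8), size=(6, 6), p=[0.4, 0.3, 0.3])
        occupied = list(zip(*np.nonzero(grid != EMPTY)))
        if not occupied:
            return
        pop = Population(grid)
        focal = occupied[rng.integers(len(occupied))]
        params = SimulationParams(L=6, r=float(rng.uniform(1.0, 6.0)), seed=0)
        led = PayoffLedger(6)
        play_pgg(pop, tuple(focal), params, led)
        n_c = sum(is_contributor(int(pop.grid[s])) for s in group_members(pop, tuple(focal)))
        assert led.total() == pytest.approx((params.r - 1.0) * n_c * params.c, abs=1e-9)


class TestPunisherResponse:
    def test_punishes_within_tolerance(self, params):
        # theta=2 punisher meets exactly 2 defectors: fines beta each, pays 2*gamma
        pop = pop_from(".....\n.....\n.D2D.\n.....\n.....")
        led = PayoffLedger(5)
        actions = punisher_response(pop, (2, 2), params.replace(beta=1.0, gamma=0.7), led)
        assert [a.decision for a in actions] == ["PUNISH"]
        assert led[(2, 2)] == pytest.approx(-1.4)
        assert led[(2, 1)] == pytest.approx(-1.0)
        assert led[(2, 3)] == pytest.approx(-1.0)

    def test_zero_tolerance_always_runs(self, params):
        # theta=0 with one defector: migrates, no fines, no cost
        pop = pop_from(".....\n.....\n.D0..\n.....\n.....")
        led = PayoffLedger(5)
        led.payoff[2, 2] = 1.5  # pre-existing payoff travels along
        actions = punisher_response(pop, (2, 2), params, led)
        assert [a.decision for a in actions] == ["MIGRATE"]
        dest = actions[0].destination
        assert pop.grid[2, 2] == EMPTY
        assert pop.grid[dest] == 2  # punisher code for theta=0
        assert led[dest] == pytest.approx(1.5)
        assert led[(2, 1)] == 0.0  # the defector was not fined

    def test_migration_destination_is_former_empty_neighbor(self, params):
        pop = pop_from(".....\n.....\n.D0..\n.....\n.....")
        led = PayoffLedger(5)
        from pggmob import moore_neighborhood

        (action,) = punisher_response(pop, (2, 2), params, led)
        assert action.destination in moore_neighborhood((2, 2), 5)

    def test_max_tolerance_never_migrates(self, params):
        # theta=8 surrounded by 8 defectors still stays and punishes all
        pop = pop_from(".....\n.DDD.\n.D8D.\n.DDD.\n.....")
        led = PayoffLedger(5)
        (action,) = punisher_response(pop, (2, 2), params.replace(beta=1.0, gamma=0.7), led)
        assert action.decision == "PUNISH"
        assert led[(2, 2)] == pytest.approx(-8 * 0.7)
        assert led[(1, 1)] == pytest.approx(-1.0)

    def test_no_defectors_is_idle(self, params):
        pop = pop_from(".....\n.....\n.C3..\n.....\n.....")
        led = PayoffLedger(5)
        (action,) = punisher_response(pop, (2, 2), params, led)
        assert action.decision == "STAY_IDLE"
        assert led.total() == 0.0

    def test_blocked_migration_stays_without_punishing(self, params):
        # theta=0 punisher wants to flee but has no empty neighbor
        pop = pop_from("DDDDD\nDDDDD\nDD0DD\nDDDDD\nDDDDD")
        led = PayoffLedger(5)
        actions = punisher_response(pop, (2, 2), params, led)
        focal_action = [a for a in actions if a.site == (2, 2)][0]
        assert focal_action.decision == "STAY_IDLE"
        assert led[(2, 2)] == 0.0

    def test_group_total_drops_by_nd_beta_plus_gamma_per_punisher(self, params):
        # two theta=8 punishers, three defectors: total falls by 2*3*(beta+gamma)
        p = params.replace(beta=1.0, gamma=0.4)
        pop = pop_from(".....\n.D8D.\n..8..\n..D..\n.....")
        led = PayoffLedger(5)
        punisher_response(pop, (2, 2), p, led)
        assert led.total() == pytest.approx(-2 * 3 * (1.0 + 0.4))

    def test_organizer_only_scope_restricts_deciders(self, params):
        p = params.replace(punish_scope="organizer_only", beta=1.0, gamma=0.4)
        pop = pop_from(".....\n.D8D.\n..8..\n..D..\n.....")
        led = PayoffLedger(5)
        actions = punisher_response(pop, (2, 2), p, led)
        assert len(actions) == 1 and actions[0].site == (2, 2)
        assert led.total() == pytest.approx(-3 * (1.0 + 0.4))


class TestFermi:
    def test_equal_payoffs_give_half(self):
        assert fermi_probability(3.0, 3.0, 0.1) == pytest.approx(0.5)

    def test_closed_form_at_delta_equal_kappa(self):
        assert fermi_probability(0.1, 0.0, 0.1) == pytest.approx(1 / (1 + math.e), rel=1e-12)

    def test_saturates_without_overflow(self):
        assert fermi_probability(-50.0, 0.0, 0.1) == pytest.approx(1.0)
        assert fermi_probability(50.0, 0.0, 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_kappa_must_be_positive(self):
        with pytest.raises(ValueError):
            fermi_probability(0.0, 0.0, 0.0)

    @given(
        a=hst.floats(-20, 20),
        b=hst.floats(-20, 20),
        kappa=hst.floats(0.01, 10.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_adoption_probabilities_sum_to_one(self, a, b, kappa):
        assert fermi_probability(a, b, kappa) + fermi_probability(b, a, kappa) == pytest.approx(1.0)


class TestRunGeneration:
    def test_all_defector_ledger_is_zero(self):
        p = SimulationParams(L=10, rho=0.5, r=3.0, seed=5)
        pop = init_population(p, InitialComposition({"D": 1.0}))
        led = run_generation(pop, p)
        assert led.total() == 0.0

    def test_neutralized_punisher_payoffs_match_cooperators(self):
        """With beta=gamma=0 and theta=8, punishers earn exactly what
        cooperators would in the same positions."""
        p = SimulationParams(L=12, rho=0.6, r=3.0, beta=0.0, gamma=0.0, seed=9)
        pop_p = init_population(p, InitialComposition.punishers_vs_defectors(theta=8))
        grid_c = pop_p.grid.copy()
        grid_c[grid_c == 10] = 0  # replace P8 with C site-by-site
        pop_c = Population(grid_c)
        seed_kernel(777)
        led_p = run_generation(pop_p, p)
        seed_kernel(777)
        led_c = run_generation(pop_c, p)
        np.testing.assert_allclose(led_p.payoff, led_c.payoff)

    def test_payoffs_reset_each_generation(self):
        p = SimulationParams(L=8, rho=0.5, r=2.0, seed=3)
        pop = init_population(p, InitialComposition({"D": 1.0}))
        led = PayoffLedger(8)
        led.payoff[:, :] = 42.0
        run_generation(pop, p, led)
        assert led.total() == 0.0


class TestSynchronousUpdate:
    def test_uniform_population_is_fixed_point(self, params):
        pop = pop_from("CCC\nCCC\nCCC")
        led = PayoffLedger(3)
        synchronous_update(pop, led, params)
        assert pop.class_counts()["C"] == 9

    def test_strong_selection_forces_adoption(self, params):
        # two adjacent agents; B's payoff exceeds A's by 50 >> kappa
        pop = pop_from("CD...\n.....\n.....\n.....\n.....")
        led = PayoffLedger(5)
        led.payoff[0, 1] = 50.0
        synchronous_update(pop, led, params)
        assert pop.grid[0, 0] == 1  # A adopted D
        assert pop.grid[0, 1] == 1  # B kept its strategy

    def test_update_uses_pre_update_state(self, params):
        """In a payoff gradient A > B > C, agent C must copy B's OLD strategy
        even when B itself flips to A's strategy in the same sweep."""
        for s in range(25):
            pop = Population.from_text("CD0..\n.....\n.....\n.....\n.....")
            # give C-agent (0,2) only one occupied neighbor (0,1) by placement:
            # (0,0) is not adjacent to (0,2); payoffs force deterministic copies
            led = PayoffLedger(5)
            led.payoff[0, 0] = 100.0
            led.payoff[0, 1] = 50.0
            led.payoff[0, 2] = 0.0
            seed_kernel(s)
            synchronous_update(pop, led, params)
            assert pop.grid[0, 2] == 1  # copied old B (defector), never C-kind
            assert pop.grid[0, 0] == 0  # top payoff keeps its strategy

    def test_punisher_theta_is_copied_with_the_kind(self, params):
        pop = pop_from("C5...\n.....\n.....\n.....\n.....")
        led = PayoffLedger(5)
        led.payoff[0, 1] = 50.0
        synchronous_update(pop, led, params)
        assert pop.grid[0, 0] == 7  # punisher code for theta=5

    def test_agent_without_neighbors_keeps_strategy(self, params):
        pop = pop_from(".....\n.....\n..C..\n.....\n.....")
        led = PayoffLedger(5)
        synchronous_update(pop, led, params)
        assert pop.grid[2, 2] == 0


class TestRandomDiffusion:
    def test_epsilon_zero_is_identity(self):
        p = SimulationParams(L=10, rho=0.5, seed=11)
        pop = init_population(p, InitialComposition.cooperators_vs_defectors())
        before = pop.grid.copy()
        random_diffusion(pop, 0.0)
        assert np.array_equal(pop.grid, before)

    def test_epsilon_one_moves_every_mobile_agent(self):
        pop = pop_from(".....\n.C.D.\n.....\n.0.8.\n.....")
        before = pop.grid.copy()
        random_diffusion(pop, 1.0)
        vacated = np.sum((before != EMPTY) & (pop.grid == EMPTY))
        # each of the 4 agents has empty neighbors and must move
        assert pop.occupancy_count == 4
        assert vacated >= 1  # origins freed (moves may chain into vacated sites)
        assert not np.array_equal(pop.grid, before)

    def test_mover_count_matches_binomial_rate(self):
        p = SimulationParams(L=20, rho=0.5, seed=13)
        pop = init_population(p, InitialComposition.cooperators_vs_defectors())
        seed_kernel(99)
        moves = 0
        trials = 300
        for _ in range(trials):
            before = pop.grid != EMPTY
            random_diffusion(pop, 0.01)
            moves += int(np.sum(before & (pop.grid == EMPTY)))
        rate = moves / (trials * pop.occupancy_count)
        assert 0.005 < rate <= 0.0151  # ~Binomial(N, <=0.01) per pass

    def test_occupancy_preserved(self):
        p = SimulationParams(L=15, rho=0.4, seed=17)
        pop = init_population(p, InitialComposition.punishers_vs_defectors(theta=1))
        n0 = pop.occupancy_count
        for _ in range(50):
            random_diffusion(pop, 0.5)
        assert pop.occupancy_count == n0
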