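import math
import random

import numpy as np
import pytest

from cosem.simulator import (
    AbsorbingStateError,
    RibosomeConfiguration,
    TranslationSystem,
    classify_regime,
    critical_corner,
    enumerate_events,
    estimate_synthesis_time,
    gillespie_step,
    ld_current,
    mc_current,
    mean_rates,
    simulate,
    simulate_fixed_timestep,
)


def uniform_system(L=300, alpha=0.1, beta=1.0, gamma=0.0, d=10):
    return TranslationSystem(
        rates=np.ones(L), init_rate=alpha, term_rate=beta, dropoff_rate=gamma,
        footprint=d,
    )


class TestEventProbabilities:
    def test_transition_probabilities_follow_rate_ratios(self):
        # one ribosome mid-sequence: move at 1/s, drop at 1/s, init at 2/s
        # -> probabilities 0.25 / 0.25 / 0.5
        sys = TranslationSystem(
            rates=np.ones(30), init_rate=2.0, term_rate=1.0, dropoff_rate=1.0,
            footprint=10,
        )
        config = RibosomeConfiguration(positions=[15], blocked=[False])
        events = enumerate_events(config, sys)
        total = sum(q for *_, q in events)
        probs = {kind: q / total for kind, _, q in events}
        assert probs == pytest.approx({"init": 0.5, "move": 0.25, "drop": 0.25})

    def test_empty_sequence_absorbing_state(self):
        live = TranslationSystem(rates=np.ones(30), init_rate=1.0, footprint=10)
        # alpha > 0: initiation keeps the chain alive
        new, dt = gillespie_step(RibosomeConfiguration(), live, rng=1)
        assert new.positions == [1] and dt > 0
        # no ribosomes and no initiation possible -> absorbing
        dead = TranslationSystem(rates=np.ones(30), init_rate=0.0, footprint=10)
        with pytest.raises(AbsorbingStateError):
            gillespie_step(RibosomeConfiguration(), dead, rng=1)

    def test_waiting_time_exponential_with_total_rate(self):
        sys = uniform_system(alpha=2.0)
        config = RibosomeConfiguration()
        rng = random.Random(0)
        dts = [gillespie_step(config, sys, rng)[1] for _ in range(4000)]
        assert np.mean(dts) == pytest.approx(1 / 2.0, rel=0.05)


class TestSimultaneousMove:
    def test_blocked_selection_sets_flag_then_pair_advances(self):
        # two ribosomes at the minimal gap d: the trailing one is selected,
        # gets flagged without moving; when the leader then steps forward,
        # both advance within that single event
        sys = TranslationSystem(
            rates=np.ones(40), init_rate=0.0, term_rate=1.0, footprint=10
        )
        start = RibosomeConfiguration(positions=[5, 15], blocked=[False, False])
        rng = random.Random(0)
        flagged = None
        for _ in range(100):  # retry until the trailing ribosome is selected
            new, _ = gillespie_step(start, sys, rng, simultaneous_move=True)
            if new.blocked == [True, False]:
                assert new.positions == [5, 15]  # no movement on the attempt
                flagged = new
                break
        assert flagged is not None, "trailing ribosome was never flagged"
        # from the flagged state, the leader's forward step carries the
        # flagged follower along in the same event and clears its flag
        for _ in range(100):
            new, _ = gillespie_step(flagged, sys, rng, simultaneous_move=True)
            if new.positions != [5, 15]:
                assert new.positions == [6, 16]
                assert new.blocked == [False, False]
                return
        pytest.fail("leader never advanced")

    def test_rejection_discipline_never_flags(self):
        sys = TranslationSystem(
            rates=np.ones(40), init_rate=0.5, term_rate=1.0, footprint=10
        )
        config = RibosomeConfiguration(positions=[1, 11], blocked=[False, False])
        rng = random.Random(3)
        for _ in range(200):
            config, _ = gillespie_step(config, sys, rng)
            assert not any(config.blocked)
            assert not config.init_blocked


class TestExclusionAndConservation:
    def test_exclusion_invariant_along_trajectory(self):
        sys = uniform_system(L=60, alpha=0.5, beta=0.3, d=10)
        # check_invariants asserts min A-site gap >= d after every event
        simulate(sys, burn_in=5, measure=200, seed=5, check_invariants=True)

    def test_flux_balance_exact(self):
        sys = uniform_system(L=100, alpha=0.3, beta=0.5, gamma=0.02, d=10)
        res = simulate(sys, burn_in=10, measure=500, seed=8)
        assert res.initiations_total == (
            res.completions_total + res.dropoffs_total + res.ribosomes_final
        )

    def test_density_profile_bounded(self):
        sys = uniform_system(L=80, alpha=0.4, beta=0.2, d=10)
        res = simulate(sys, burn_in=20, measure=300, seed=9)
        assert np.all(res.density_profile >= 0)
        assert np.all(res.density_profile <= 1 + 1e-12)
        assert 0 <= res.average_density <= 1

    def test_reproducible_given_seed(self):
        sys = uniform_system(L=60, alpha=0.2)
        r1 = simulate(sys, burn_in=5, measure=100, seed=123)
        r2 = simulate(sys, burn_in=5, measure=100, seed=123)
        assert r1.current == r2.current
        assert np.array_equal(r1.density_profile, r2.density_profile)


class TestCurrents:
    def test_initiation_limited_current_approaches_alpha(self):
        # deep LD: p_j ~ alpha (injection-limited)
        sys = uniform_system(L=300, alpha=0.01, beta=1.0, d=10)
        res = simulate(sys, measure=150_000, seed=1, collect_profile=False)
        se = math.sqrt(max(res.completions, 1)) / res.measure_time
        assert res.current == pytest.approx(ld_current(0.01, 10), abs=3 * se)

    def test_large_dropoff_kills_current(self):
        sys = uniform_system(L=50, alpha=0.5, beta=1.0, gamma=50.0, d=10)
        res = simulate(sys, burn_in=10, measure=500, seed=2, collect_profile=False)
        assert res.current == 0.0
        assert res.dropoffs_total > 0

    def test_current_monotone_in_dropoff(self):
        currents = []
        for gamma in (0.0, 0.01, 0.05):
            sys = uniform_system(L=100, alpha=0.2, beta=1.0, gamma=gamma, d=10)
            res = simulate(sys, measure=4000, seed=77, collect_profile=False)
            currents.append(res.current)
        assert currents[0] > currents[1] > currents[2]

    def test_dropoff_survival_product(self):
        # single-ribosome regime: completion fraction ~ prod_i w_i/(w_i+gamma)
        rates = np.full(60, 2.0)
        gamma = 0.08
        sys = TranslationSystem(
            rates=rates, init_rate=0.01, dropoff_rate=gamma, footprint=10
        )
        res = simulate(sys, measure=200_000, seed=4, collect_profile=False)
        total = res.completions_total + res.dropoffs_total
        expected = float(np.prod(rates[:-1] / (rates[:-1] + gamma)))
        se = math.sqrt(expected * (1 - expected) / total)
        assert res.completions_total / total == pytest.approx(expected, abs=4 * se)


class TestFixedTimestep:
    def test_dt_precondition(self):
        sys = uniform_system(L=50, alpha=0.1)
        with pytest.raises(ValueError, match="dt too large"):
            simulate_fixed_timestep(sys, dt=0.2, total=100, seed=0)

    def test_preloaded_single_ribosome_completes_exactly_once(self):
        rates = np.full(30, 5.0)
        sys = TranslationSystem(
            rates=rates, init_rate=0.0, term_rate=5.0, dropoff_rate=0.0,
            footprint=10,
        )
        res = simulate_fixed_timestep(
            sys, dt=0.002, total=200, seed=1, burn_in=0, initial_positions=[1]
        )
        assert res.completions_total == 1
        assert res.dropoffs_total == 0

    def test_matches_gillespie_current(self):
        sys = uniform_system(L=100, alpha=0.15, beta=0.8, d=10)
        g = simulate(sys, measure=15_000, seed=11, collect_profile=False)
        f = simulate_fixed_timestep(sys, dt=0.05, total=16_000, seed=12)
        se = math.sqrt(
            g.completions / g.measure_time**2 + f.completions / f.measure_time**2
        )
        assert g.current == pytest.approx(f.current, abs=3 * se)


class TestAnalytics:
    @pytest.mark.parametrize(
        "d,expected", [(10, 1 / (math.sqrt(10) + 1)), (1, 0.5), (4, 1 / 3)]
    )
    def test_critical_corner(self, d, expected):
        assert critical_corner(d) == pytest.approx(expected)

    def test_mean_rates(self):
        assert mean_rates([2, 2]) == pytest.approx((2.0, 2.0))
        assert mean_rates([1, 3]) == pytest.approx((2.0, 1.5))

    @pytest.mark.parametrize("seed", range(5))
    def test_am_hm_inequality(self, seed):
        rng = np.random.default_rng(seed)
        profile = rng.uniform(0.5, 40, size=50)
        am, hm = mean_rates(profile)
        assert hm <= am
        am_u, hm_u = mean_rates(np.full(20, 7.0))
        assert am_u == pytest.approx(hm_u)

    def test_estimate_synthesis_time(self):
        sys = TranslationSystem(
            rates=np.array([1.0, 1.0, 1.0] + [1e9] * 7), init_rate=1e9,
            term_rate=1e9, footprint=10,
        )
        assert estimate_synthesis_time(sys) == pytest.approx(3.0, rel=1e-6)
        sys2 = TranslationSystem(
            rates=np.array([2.0, 4.0] + [1e12] * 8), init_rate=1e12,
            term_rate=1e12, footprint=10,
        )
        assert estimate_synthesis_time(sys2) == pytest.approx(0.75, rel=1e-6)

    def test_regime_labels(self):
        assert classify_regime(0.1, 0.2, 10) == "LD"
        assert classify_regime(0.2, 0.1, 10) == "HD"
        assert classify_regime(0.5, 0.5, 10) == "MC"
        assert classify_regime(0.4, 0.6, 1) == "LD"  # below the d=1 corner of 0.5

    def test_mc_current_value(self):
        assert mc_current(1) == pytest.approx(0.25)
        assert mc_current(10) == pytest.approx(1 / (math.sqrt(10) + 1) ** 2)
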