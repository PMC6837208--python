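import math

import numpy as np
import pytest
from scipy.stats import truncnorm

import ttbsearch as tb
from ttbsearch.agents import (
    AgentParams,
    configure_exploitation,
    current_radius,
    d_optimal,
    draw_exploration_range,
    init_state,
    n_free_params,
    step,
)
from ttbsearch.landscape import Landscape
from ttbsearch.ttb import StateError, chebyshev


@pytest.mark.parametrize("t_left,expected", [(30, 15), (5, 2), (1, 0), (0, 0)])
def test_d_optimal(t_left, expected):
    assert d_optimal(t_left) == expected


def test_d_optimal_rejects_negative():
    with pytest.raises(StateError):
        d_optimal(-1)


def test_exploration_range_arithmetic(rng):
    """With the stop branch disabled and a pinned safety level the radius is
    s0 * floor(t_left/2) exactly."""
    params = AgentParams(k=0.0, exploitation_model="returning",
                         ignore_disabled=True, s0_fixed=0.8)
    R, s0, branch = draw_exploration_range(50, 20, params, rng)
    assert branch == "return"
    assert s0 == 0.8
    assert R == pytest.approx(0.8 * 10)


def test_branch_frequencies_and_s0_moments():
    """At X_best=50 under the exploitation-phase defaults the stop branch
    fires with probability k*50 = 0.255, the ignore branch clips to zero
    (1 - 0.027*50 < 0), and S0 follows the stated truncated normal."""
    rng = np.random.default_rng(77)
    params = AgentParams(exploitation_model="returning")
    n = 100_000
    counts = {"stop": 0, "ignore": 0, "return": 0}
    s0s = []
    for _ in range(n):
        _, s0, branch = draw_exploration_range(50, 20, params, rng)
        counts[branch] += 1
        if s0 is not None:
            s0s.append(s0)
    p_stop = 0.0051 * 50
    assert abs(counts["stop"] / n - p_stop) < 3 * math.sqrt(p_stop * (1 - p_stop) / n)
    assert counts["ignore"] == 0
    sigma = math.sqrt(0.364)
    a, b = (0 - 0.806) / sigma, (1 - 0.806) / sigma
    m, v = truncnorm.mean(a, b, 0.806, sigma), truncnorm.var(a, b, 0.806, sigma)
    assert np.mean(s0s) == pytest.approx(m, abs=3 * math.sqrt(v / len(s0s)))
    assert np.var(s0s) == pytest.approx(v, rel=0.05)


def test_ignore_probability_clips_to_one_at_zero_payoff():
    params = AgentParams(exploitation_model="returning", k=0.0)
    rng = np.random.default_rng(1)
    for _ in range(50):
        _, _, branch = draw_exploration_range(0, 20, params, rng)
        assert branch == "ignore"  # clip(1 + l*0) = 1


@pytest.mark.parametrize(
    "which,expected_params",
    [("returning", 4), ("simple_returning", 3), ("early_stop", 0), ("normative", 0)],
)
def test_exploitation_variant_parameter_counts(which, expected_params):
    eff = configure_exploitation(which, AgentParams(exploration_model="hill_climbing"))
    assert n_free_params(eff) == expected_params


def test_simple_returning_never_ignores(rng):
    eff = configure_exploitation("simple_returning", AgentParams())
    branches = {draw_exploration_range(5, 20, eff, rng)[2] for _ in range(20_000)}
    assert "ignore" not in branches


def test_normative_is_deterministic_full_range(rng):
    eff = configure_exploitation("normative", AgentParams())
    for x_best in (1, 30, 80):
        R, s0, branch = draw_exploration_range(x_best, 20, eff, rng)
        assert (branch, s0, R) == ("return", 1.0, 10)


# ---------------------------------------------------------------------------
# stepping behaviour

def test_first_move_from_fresh_start_is_diagonal(zero_landscape):
    """With not-visited and pay-off tied everywhere, novelty (5 > 3) makes
    the first exploration move diagonal."""
    params = AgentParams(epsilon=0.0)
    for seed in range(20):
        rng = np.random.default_rng(seed)
        state = init_state((32, 32), zero_landscape, 30, params, rng)
        state, decision = step(state, zero_landscape, params, rng)
        dr, dc = decision.chosen.move
        assert abs(dr) == 1 and abs(dc) == 1
        assert decision.deciding_cue in ("novelty", "random_tiebreak")


def test_revisit_avoidance_without_noise(zero_landscape):
    """eps=0: a visited cell is never chosen while unvisited options exist."""
    params = AgentParams(epsilon=0.0)
    rng = np.random.default_rng(4)
    state = init_state((32, 32), zero_landscape, 30, params, rng)
    for _ in range(30):
        before = set(state.visited)
        pos = state.position
        state, decision = step(state, zero_landscape, params, rng)
        unvisited_exists = any(o.target not in before
                               for o in tb.legal_options(pos, zero_landscape.dims))
        if unvisited_exists:
            assert state.position not in before


def test_x_best_monotone_and_consistent(poor_landscape):
    params = AgentParams(epsilon=0.17)
    rng = np.random.default_rng(8)
    state = init_state((32, 32), poor_landscape, 30, params, rng)
    prev = state.x_best
    for _ in range(30):
        state, _ = step(state, poor_landscape, params, rng)
        assert state.x_best >= prev
        assert state.x_best == max(poor_landscape.payoff_at(p) for p in state.visited)
        prev = state.x_best


def test_hill_climbing_absorbs_at_local_max():
    payoffs = np.zeros((9, 9), dtype=int)
    payoffs[4, 4] = 10
    payoffs[3, 4] = 5
    ls = Landscape(payoffs=payoffs, n_peaks=1, scale_max=10)
    params = AgentParams(exploration_model="hill_climbing", exploitation_model="none")
    rng = np.random.default_rng(2)
    state = init_state((3, 5), ls, 30, params, rng)  # (4,4) 0-based = (4,5)? start near peak
    seq = [ls.payoff_at(state.position)]
    for _ in range(30):
        state, _ = step(state, ls, params, rng)
        seq.append(ls.payoff_at(state.position))
    assert seq == sorted(seq)  # non-decreasing pay-off sequence
    assert state.position == (5, 5)  # settled on the peak (1-based)


def test_random_model_uniform_over_options(zero_landscape):
    params = AgentParams(exploration_model="random", exploitation_model="none")
    rng = np.random.default_rng(6)
    counts = {}
    n = 30_000
    for _ in range(n):
        state = init_state((32, 32), zero_landscape, 30, params, rng)
        state, decision = step(state, zero_landscape, params, rng)
        counts[decision.chosen.move] = counts.get(decision.chosen.move, 0) + 1
    freqs = np.array(list(counts.values())) / n
    assert len(counts) == 9
    assert np.all(np.abs(freqs - 1 / 9) < 3 * np.sqrt((1 / 9) * (8 / 9) / n))


def test_probabilistic_model_crossover_point():
    """The printed logistic coefficients put the pay-off/novelty toss at
    p = 0.5 when the best neighbouring pay-off is ~5.013."""
    from scipy.special import expit
    params = AgentParams()
    assert expit(params.beta0 + params.beta1 * 5.013) == pytest.approx(0.5, abs=1e-3)


def test_probabilistic_model_uses_payoff_more_with_rich_neighbours():
    """High neighbouring pay-offs should push the probabilistic agent onto
    the pay-off cue: on a steep bump it climbs more often than on a flat
    landscape."""
    payoffs = np.zeros((9, 9), dtype=int)
    payoffs[4, 4] = 60
    payoffs[4, 5] = 40
    ls = Landscape(payoffs=payoffs, n_peaks=1, scale_max=60)
    params = AgentParams(exploration_model="probabilistic", exploitation_model="none")
    rng = np.random.default_rng(9)
    climbs = 0
    n = 2000
    for _ in range(n):
        state = init_state((5, 6), ls, 30, params, rng)  # next to the 40-point cell
        state, decision = step(state, ls, params, rng)
        climbs += decision.chosen.target == (5, 5)
    # pn_max = 60 -> p(use pay-off cue) = expit(-1.509 + 0.301*60) ~ 1.0
    assert climbs / n > 0.9


def test_radius_fallback_steers_to_p_best():
    """An agent stranded outside its radius moves straight back towards the
    best position."""
    payoffs = np.zeros((1, 63), dtype=int)
    payoffs[0, 4] = 10
    ls = Landscape(payoffs=payoffs, n_peaks=1, scale_max=10)
    params = AgentParams(epsilon=0.0, exploitation_model="returning",
                         k=0.0, ignore_disabled=True, s0_fixed=0.5)
    rng = np.random.default_rng(3)
    state = init_state((1, 1), ls, 30, params, rng)
    state.x_best, state.p_best = 10, (1, 5)
    state.branch, state.s0 = "return", 0.1   # radius ~ 1.5
    state.position = (1, 20)                  # far outside
    state.visited.add((1, 20))
    d0 = chebyshev(state.position, state.p_best)
    state, decision = step(state, ls, params, rng)
    assert decision.deciding_cue == "radius"
    assert chebyshev(state.position, state.p_best) == d0 - 1


def test_early_stop_latches_on_first_visible_peak():
    payoffs = np.zeros((1, 63), dtype=int)
    payoffs[0, 9] = 10      # lone peak at x=10 (1-based)
    ls = Landscape(payoffs=payoffs, n_peaks=1, scale_max=10)
    params = AgentParams(epsilon=0.0, exploitation_model="early_stop")
    rng = np.random.default_rng(0)
    state = init_state((1, 1), ls, 30, params, rng)
    for _ in range(30):
        assert current_radius(state, params) in (1.0, math.inf)
        state, _ = step(state, ls, params, rng)
    assert state.stopped
    assert state.position == (1, 10)  # settled on the peak


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        AgentParams(epsilon=1.5)
    with pytest.raises(ValueError):
        AgentParams(exploration_model="greedy")
    with pytest.raises(ValueError):
        AgentParams(exploitation_model="returning", mu=-1.0)
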