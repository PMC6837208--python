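import math

import numpy as np
import pytest

import ttbsearch as tb
from ttbsearch.landscape import Landscape
from ttbsearch.metrics import (
    InputError,
    cue_usage,
    density_map,
    diagonal_contrast,
    dist_density,
    dist_payoff,
    immediate_novelty,
    kfold_cv,
    log_density,
    payoff_curve,
    revisit_fraction,
    safety_levels,
    ModelSpec,
)
from ttbsearch.simulate import PhaseConfig, Trajectory, run_trial


def _manual_trajectory(positions, landscape, phase="exploration"):
    """Build a trajectory record-by-record from a position list (oracle input)."""
    records = []
    x_best, p_best = 0, None
    for i, pos in enumerate(positions):
        pay = landscape.payoff_at(pos)
        if pay > x_best:
            x_best, p_best = pay, pos
        records.append({
            "round": i, "row": pos[0], "col": pos[1], "payoff": pay,
            "x_best": x_best, "p_best_row": p_best[0] if p_best else None,
            "p_best_col": p_best[1] if p_best else None, "R": math.inf,
            "deciding_cue": "" if i == 0 else "payoff", "noise_flag": False,
        })
    reward = x_best
    m = landscape.max_payoff
    return Trajectory(records=records, reward=reward,
                      normalized_reward=reward / m if m else 0.0,
                      phase=phase, landscape=landscape, params=tb.AgentParams())


@pytest.fixture(scope="module")
def bump_line():
    payoffs = np.zeros((1, 63), dtype=int)
    payoffs[0, [4, 14]] = [6, 20]
    return Landscape(payoffs=payoffs, n_peaks=2, scale_max=20)


def test_payoff_curve_matches_hand_rolled_mean(poor_landscape):
    phase = PhaseConfig.preset("exploration", "poor")
    trajs = [run_trial(phase, tb.AgentParams(), poor_landscape, np.random.default_rng(s))
             for s in range(3)]
    curve = payoff_curve(trajs, "best_so_far")
    m = poor_landscape.max_payoff
    expected = np.mean(
        [[rec["x_best"] / m for rec in t.records[1:]] for t in trajs], axis=0)
    assert np.allclose(curve, expected)
    assert np.all(np.diff(curve) >= 0)  # best-so-far is non-decreasing
    assert len(curve) == 30


def test_payoff_curve_on_global_peak_is_one(bump_line):
    traj = _manual_trajectory([(1, 15)] * 31, bump_line)
    assert np.allclose(payoff_curve([traj], "current"), 1.0)
    with pytest.raises(InputError):
        payoff_curve([])


def test_density_map_counts_and_conservation(zero_landscape):
    stay = _manual_trajectory([(5, 5)] * 31, zero_landscape)
    dm = density_map([stay], (63, 63))
    assert dm[4, 4] == 31
    assert dm.sum() == 31
    phase = PhaseConfig.preset("exploration")
    trajs = [run_trial(phase, tb.AgentParams(), zero_landscape, np.random.default_rng(s))
             for s in range(4)]
    dm = density_map(trajs, (63, 63))
    assert dm.sum() == 4 * 31


def test_revisit_fraction_edge_cases(zero_landscape):
    stay = _manual_trajectory([(5, 5)] * 31, zero_landscape)
    assert revisit_fraction(stay) == 1.0
    path = _manual_trajectory([(1, c) for c in range(1, 32)], zero_landscape)
    assert revisit_fraction(path) == 0.0


def test_immediate_novelty_move_classes():
    dims = (63, 63)
    assert immediate_novelty((33, 33), (32, 32), dims) == 5
    assert immediate_novelty((32, 33), (32, 32), dims) == 3
    assert immediate_novelty((32, 32), (32, 32), dims) == 0


def test_cue_usage_fresh_ttb_agent_follows_not_visited(zero_landscape):
    phase = PhaseConfig.preset("exploration")
    trajs = [run_trial(phase, tb.AgentParams(epsilon=0.0), zero_landscape,
                       np.random.default_rng(s)) for s in range(5)]
    a, b, c = cue_usage(trajs)
    assert a == 1.0            # never revisits while unvisited options remain
    assert b <= a
    assert 0.0 <= c <= 1.0


def test_cue_usage_matches_step_classification_oracle(ttb_exploration_batch):
    """(b) <= (a) and both agree with a direct per-decision reclassification."""
    a, b, c = cue_usage(ttb_exploration_batch)
    n = a_hits = 0
    for t in ttb_exploration_batch:
        visited = {t.positions[0]}
        for pos in t.positions[1:]:
            n += 1
            a_hits += pos not in visited
            visited.add(pos)
    assert a == pytest.approx(a_hits / n)
    assert b <= a


# ---------------------------------------------------------------------------
# safety levels

def test_safety_level_excursion_narrative(bump_line):
    """A peak found with 15 rounds left (D_optimal = 7), explored 3 cells
    further and then returned, scores S = 3/7."""
    positions = [(1, 1), (1, 1)]            # one stay so the peak falls on round 15
    for c in range(2, 16):
        positions.append((1, c))            # reach the x=15 peak at round 15
    for c in (16, 17, 18):
        positions.append((1, c))            # 3 rounds out
    for c in (17, 16, 15):
        positions.append((1, c))            # return
    while len(positions) < 31:
        positions.append((1, 15))           # settle
    payoffs = np.zeros((1, 63), dtype=int)
    payoffs[0, 14] = 20
    ls = Landscape(payoffs=payoffs, n_peaks=1, scale_max=20)
    records = safety_levels(_manual_trajectory(positions, ls, phase="exploitation"))
    assert len(records) == 1
    rec = records[0]
    assert rec.discovery_round == 15
    assert rec.d_optimal == 7
    assert rec.realized_R == 3
    assert rec.S == pytest.approx(3 / 7)
    assert rec.censored == "none"


def test_safety_level_immediate_settle_and_no_return(bump_line):
    settle = [(1, c) for c in range(1, 6)] + [(1, 5)] * 26
    payoffs = np.zeros((1, 63), dtype=int)
    payoffs[0, 4] = 9
    ls = Landscape(payoffs=payoffs, n_peaks=1, scale_max=9)
    [rec] = safety_levels(_manual_trajectory(settle, ls))
    assert rec.realized_R == 0 and rec.S == 0.0 and rec.returned

    away = [(1, c) for c in range(1, 32)]   # walks through x=5 and keeps going
    [rec2] = safety_levels(_manual_trajectory(away, ls))
    assert not rec2.returned
    assert rec2.censored == "no_return"


def test_safety_level_superseded_episode(bump_line):
    through = [(1, c) for c in range(1, 17)] + [(1, 15)] * 15  # 6pt then 20pt peak
    recs = safety_levels(_manual_trajectory(through, bump_line))
    assert [r.censored for r in recs] == ["superseded", "none"]
    assert recs[1].x_best == 20


# ---------------------------------------------------------------------------
# distances

def test_dist_payoff_identities():
    a = np.linspace(0, 1, 30)
    assert dist_payoff(a, a) == 0.0
    assert dist_payoff(a, a + 0.1) == pytest.approx(30 * 0.1**2)
    assert dist_payoff({"poor": a, "rich": a}, {"poor": a + 0.1, "rich": a}) == (
        pytest.approx(30 * 0.01))
    with pytest.raises(InputError):
        dist_payoff(a, a[:-1])
    with pytest.raises(InputError):
        dist_payoff({"poor": a}, {"rich": a})


def test_dist_density_identities(rng):
    a = rng.integers(0, 50, size=(63, 63))
    b = rng.integers(0, 50, size=(63, 63))
    assert dist_density(a, a) == 0.0
    assert dist_density(a, b) == pytest.approx(dist_density(b, a))
    assert dist_density(a, b) >= 0
    manual = np.abs(log_density(a) - log_density(b)).mean()
    assert dist_density(a, b) == pytest.approx(manual)
    with pytest.raises(InputError):
        dist_density(a, b[:10])


def test_diagonal_contrast_prefers_x_pattern():
    counts = np.ones((63, 63))
    for d in range(1, 15):
        for sr in (-1, 1):
            for sc in (-1, 1):
                counts[31 + sr * d, 31 + sc * d] += 30
    assert diagonal_contrast(counts, (32, 32)) > 5
    assert diagonal_contrast(np.ones((63, 63)), (32, 32)) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# cross-validation

def test_kfold_partition_and_zero_param_model(ttb_exploration_batch):
    model = ModelSpec("ttb", ttb_exploration_batch.params)
    res = kfold_cv(ttb_exploration_batch, model, k=5, master_seed=1)
    assert res.folds == 5
    assert res.dist_payoff >= 0 and res.dist_density >= 0
    assert res.n_params == 1 and res.n_cues == 3
    with pytest.raises(InputError):
        kfold_cv(ttb_exploration_batch, model, k=1)


def test_self_model_beats_random_on_payoff(ttb_exploration_batch):
    """TTB-generated data are predicted better by the TTB model than by
    random search (out-of-sample dist_payoff contrast)."""
    base = ttb_exploration_batch.params
    from dataclasses import replace
    ttb_model = ModelSpec("ttb", base)
    rnd_model = ModelSpec("random", replace(base, exploration_model="random"))
    r_ttb = kfold_cv(ttb_exploration_batch, ttb_model, k=5, master_seed=2)
    r_rnd = kfold_cv(ttb_exploration_batch, rnd_model, k=5, master_seed=2)
    assert r_ttb.dist_payoff < r_rnd.dist_payoff
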