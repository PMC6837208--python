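"""Descriptive statistics and model-comparison distances over trajectories.

Everything here operates on simulated or externally supplied trajectories:
per-round pay-off curves, aggregate visit-density maps, revisit fractions,
observable cue-usage proportions, safety-level episodes (how far an agent
kept exploring after finding its best solution), and the two distances used
to compare models — ``dist_payoff`` (squared difference between pay-off
curves) and ``dist_density`` (mean absolute per-cell difference between
log-scaled density maps) — together with a k-fold cross-validation driver.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import KFold

from .agents import AgentParams, d_optimal, n_free_params
from .simulate import PhaseConfig, Trajectory, TrajectorySet, run_trial
from .ttb import chebyshev, cue_novelty, legal_options, neighbourhood

__all__ = [
    "payoff_curve",
    "density_map",
    "revisit_fraction",
    "cue_usage",
    "deciding_cue_frequencies",
    "SafetyRecord",
    "safety_levels",
    "dist_payoff",
    "dist_density",
    "log_density",
    "diagonal_contrast",
    "ModelSpec",
    "ComparisonResult",
    "kfold_cv",
    "compare_models",
]


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Descriptive statistics

def payoff_curve(
    trajectories: Sequence[Trajectory] | TrajectorySet,
    mode: str = "best_so_far",
) -> np.ndarray:
    """Per-round mean normalized pay-off (length = rounds).

    ``best_so_far`` tracks the highest pay-off found up to each round (the
    exploration-phase reward); ``current`` tracks the pay-off of the
    occupied cell (the exploitation/combined reward).  Pay-offs are
    normalized by each trajectory's own landscape maximum.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise InputError("payoff_curve needs at least one trajectory")
    curves = []
    for t in trajectories:
        m = t.landscape.max_payoff
        key = "x_best" if mode == "best_so_far" else "payoff"
        if mode not in ("best_so_far", "current"):
            raise InputError(f"unknown mode {mode!r}")
        vals = np.array([rec[key] for rec in t.records[1:]], dtype=float)
        curves.append(vals / m if m > 0 else vals)
    return np.mean(curves, axis=0)


def density_map(
    trajectories: Sequence[Trajectory] | TrajectorySet,
    dims: tuple[int, int],
) -> np.ndarray:
    """Raw per-cell visit counts aggregated over trajectories.

    Includes the start position, so the counts sum to
    ``sum(len(trajectory))`` over the set.  Log-scaling is applied only for
    display / distance computation (:func:`log_density`).
    """
    counts = np.zeros(dims, dtype=int)
    for t in trajectories:
        for r, c in t.positions:
            counts[r - 1, c - 1] += 1
    return counts


def revisit_fraction(trajectory: Trajectory) -> float:
    """Fraction of distinct occupied cells that were occupied in >= 2 rounds."""
    occupancy = Counter(trajectory.positions)
    return sum(1 for v in occupancy.values() if v >= 2) / len(occupancy)


def deciding_cue_frequencies(trajectories: Sequence[Trajectory] | TrajectorySet) -> dict[str, float]:
    """Relative frequency of each recorded deciding cue (model-internal view)."""
    counts: Counter[str] = Counter()
    for t in trajectories:
        counts.update(rec["deciding_cue"] for rec in t.records[1:])
    total = sum(counts.values())
    return {cue: n / total for cue, n in sorted(counts.items())}


def _replay_contexts(trajectory: Trajectory):
    """Re-derive the option set / visited / seen context of every decision."""
    landscape = trajectory.landscape
    dims = landscape.dims
    positions = trajectory.positions
    visited = {positions[0]}
    seen = set(neighbourhood(positions[0], dims))
    for round_no in range(1, len(positions)):
        options = legal_options(positions[round_no - 1], dims)
        if trajectory.phase == "exploitation" and round_no == 1:
            options = [o for o in options if o.move[1] == 1]
        yield round_no, positions[round_no - 1], positions[round_no], options, visited, seen
        visited.add(positions[round_no])
        seen.update(neighbourhood(positions[round_no], dims))


def immediate_novelty(target: tuple[int, int], position: tuple[int, int],
                      dims: tuple[int, int]) -> int:
    """Cells a move reveals relative to the current view.

    The screen shows the 3x3 block around the occupied cell, so moving
    diagonally brings up to 5 new cells into view, orthogonally up to 3,
    and staying none (fewer at the grid border).
    """
    current_view = set(neighbourhood(position, dims))
    return sum(1 for p in neighbourhood(target, dims) if p not in current_view)


def cue_usage(
    trajectories: Sequence[Trajectory] | TrajectorySet,
    *,
    novelty_accounting: str = "immediate",
) -> tuple[float, float, float]:
    """Observable cue-consistency proportions ``(prop_a, prop_b, prop_c)``.

    (a) proportion of movements towards a non-visited cell;
    (b) proportion of movements towards a non-visited cell that also carries
        the highest pay-off among the non-visited options;
    (c) among decisions where neither the not-visited nor the pay-off cue
        leaves a unique option, the proportion of choices attaining the
        maximal number of newly revealed cells within the surviving set.

    ``novelty_accounting`` controls what "newly revealed" means in (c):
    ``"immediate"`` (default) counts cells entering the current 3x3 view —
    the per-movement reveal a spectator can score without tracking history;
    ``"accumulated"`` counts cells never shown at any earlier round, the
    bookkeeping the model's novelty cue itself uses.

    All decisions are classified from the observable record (positions and
    landscape); the model-internal provenance is available separately via
    :func:`deciding_cue_frequencies`.
    """
    if novelty_accounting not in ("immediate", "accumulated"):
        raise InputError(f"unknown novelty accounting {novelty_accounting!r}")
    n_moves = a_hits = b_hits = c_eligible = c_hits = 0
    for t in trajectories:
        landscape = t.landscape
        dims = landscape.dims
        for _, current, chosen, options, visited, seen in _replay_contexts(t):
            n_moves += 1
            unvisited = [o for o in options if o.target not in visited]
            if chosen not in visited:
                a_hits += 1
                if unvisited:
                    best_pay = max(landscape.payoff_at(o.target) for o in unvisited)
                    if landscape.payoff_at(chosen) == best_pay:
                        b_hits += 1
            # survivors after the not-visited and pay-off filters
            survivors = unvisited if unvisited else options
            best_pay = max(landscape.payoff_at(o.target) for o in survivors)
            survivors = [o for o in survivors if landscape.payoff_at(o.target) == best_pay]
            if len(survivors) > 1:
                if novelty_accounting == "immediate":
                    novelty = {o.target: immediate_novelty(o.target, current, dims)
                               for o in options}
                else:
                    novelty = {o.target: cue_novelty(o, seen, dims) for o in options}
                c_eligible += 1
                if novelty[chosen] == max(novelty[o.target] for o in survivors):
                    c_hits += 1
    if n_moves == 0:
        raise InputError("cue_usage needs at least one decision")
    prop_c = c_hits / c_eligible if c_eligible else float("nan")
    return a_hits / n_moves, b_hits / n_moves, prop_c


# ---------------------------------------------------------------------------
# Safety levels

@dataclass
class SafetyRecord:
    """One peak-discovery episode and its realized safety level.

    ``S = realized_R / d_optimal``: 0 means the agent settled immediately,
    1 means it used the whole feasible excursion, and episodes that never
    re-occupied ``P_best`` are censored as ``no_return`` (the behavioural
    reading of S > 1).
    """

    x_best: int
    discovery_round: int
    d_optimal: int
    realized_R: int
    S: float
    returned: bool
    censored: str  # none | no_return | short_horizon | superseded


def safety_levels(trajectory: Trajectory) -> list[SafetyRecord]:
    """Extract one :class:`SafetyRecord` per strict improvement of X_best.

    An episode runs from a discovery until the first re-occupation of the
    discovered position.  Episodes cut short by a strictly better discovery
    are censored as ``superseded``; episodes with ``d_optimal <= 2`` as
    ``short_horizon`` (too little time to distinguish returning from
    staying).  Distances are Chebyshev (|dx| on a line).
    """
    recs = trajectory.records
    rounds_total = len(recs) - 1
    # discovery indices: round 0 if the start pays off, plus strict improvements
    discoveries = []
    for i, rec in enumerate(recs):
        if rec["x_best"] > 0 and (i == 0 or rec["x_best"] > recs[i - 1]["x_best"]):
            discoveries.append(i)
    out = []
    for d_idx, i in enumerate(discoveries):
        p_best = (recs[i]["row"], recs[i]["col"])
        end = discoveries[d_idx + 1] if d_idx + 1 < len(discoveries) else None
        t_left = rounds_total - i
        d_opt = d_optimal(t_left)
        max_dist = 0
        returned = False
        superseded = False
        j = i + 1
        while j <= (end if end is not None else rounds_total):
            pos = (recs[j]["row"], recs[j]["col"])
            if pos == p_best:
                returned = True
                break
            max_dist = max(max_dist, chebyshev(pos, p_best))
            j += 1
        else:
            if end is not None:
                superseded = True
        if j == i + 1 and returned:
            max_dist = 0  # stayed put
        if superseded and not returned:
            censored = "superseded"
        elif not returned:
            censored = "no_return"
        elif d_opt <= 2:
            censored = "short_horizon"
        else:
            censored = "none"
        s = max_dist / d_opt if d_opt > 0 else float("nan")
        out.append(
            SafetyRecord(
                x_best=recs[i]["x_best"],
                discovery_round=i,
                d_optimal=d_opt,
                realized_R=max_dist,
                S=s,
                returned=returned,
                censored=censored,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Model-comparison distances

def dist_payoff(observed, predicted) -> float:
    """Sum of squared differences between mean pay-off curves.

    Accepts single curves or dicts of curves keyed by landscape kind (the
    kinds are summed).
    """
    if isinstance(observed, dict) != isinstance(predicted, dict):
        raise InputError("observed and predicted must have the same structure")
    if isinstance(observed, dict):
        if set(observed) != set(predicted):
            raise InputError("curve dictionaries must share their keys")
        return sum(dist_payoff(observed[k], predicted[k]) for k in observed)
    obs, pred = np.asarray(observed, float), np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise InputError(f"curve length mismatch: {obs.shape} vs {pred.shape}")
    return float(np.sum((obs - pred) ** 2))


def log_density(counts: np.ndarray) -> np.ndarray:
    """Log10 relative visit frequency with a +1 pseudo-count per cell."""
    counts = np.asarray(counts, float)
    rel = (counts + 1.0) / (counts.sum() + counts.size)
    return np.log10(rel)


def dist_density(observed: np.ndarray, predicted: np.ndarray, *, log_scale: bool = True) -> float:
    """Mean absolute per-cell difference between two density maps.

    By default both count maps are converted to log10 relative frequencies
    first (density maps are compared on the logarithmic display scale).
    """
    obs, pred = np.asarray(observed, float), np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise InputError(f"density map shape mismatch: {obs.shape} vs {pred.shape}")
    if log_scale:
        obs, pred = log_density(obs), log_density(pred)
    return float(np.mean(np.abs(obs - pred)))


def diagonal_contrast(counts: np.ndarray, start: tuple[int, int], radii: range | None = None) -> float:
    """Diagonal-vs-off-diagonal visit-density contrast around the start.

    For each Chebyshev ring of radius ``rho`` around the start, compares the
    mean count on the four diagonal cells (|dr| = |dc| = rho) with the mean
    count on the rest of the ring; returns the ratio of the summed diagonal
    means to the summed off-diagonal means.  > 1 indicates the X-shaped
    exploration pattern.
    """
    rows, cols = counts.shape
    r0, c0 = start
    if radii is None:
        radii = range(2, 13)
    diag_total = off_total = 0.0
    for rho in radii:
        diag, off = [], []
        for r in range(max(1, r0 - rho), min(rows, r0 + rho) + 1):
            for c in range(max(1, c0 - rho), min(cols, c0 + rho) + 1):
                dr, dc = abs(r - r0), abs(c - c0)
                if max(dr, dc) != rho:
                    continue
                (diag if dr == dc else off).append(counts[r - 1, c - 1])
        diag_total += float(np.mean(diag))
        off_total += float(np.mean(off))
    return diag_total / off_total if off_total > 0 else float("inf")


# ---------------------------------------------------------------------------
# k-fold cross-validated model comparison

@dataclass
class ModelSpec:
    """A model entry for comparison: parameters plus an optional fitter.

    ``fit(train_trajectories, rng) -> AgentParams`` re-estimates the free
    parameters on a training fold; models without free parameters leave it
    ``None``.
    """

    name: str
    params: AgentParams
    fit: Callable[[list[Trajectory], np.random.Generator], AgentParams] | None = None
    #: override the free-parameter / cue counts reported in tables (e.g. to
    #: count only the component being varied); None = derive from ``params``
    n_params: int | None = None
    n_cues: int | None = None


@dataclass
class ComparisonResult:
    model: str
    dist_payoff: float
    dist_density: float
    n_params: int
    n_cues: int
    folds: int
    meta: dict | None = None


#: cues used by each exploration mechanism (the full model adds the radius cue)
N_CUES_EXPLORATION = {"ttb": 3, "probabilistic": 2, "hill_climbing": 1, "blind": 1, "random": 0}
#: cues used by each exploitation mechanism (1 = the exploration-radius cue)
N_CUES_EXPLOITATION = {"returning": 1, "simple_returning": 1, "early_stop": 0,
                       "normative": 1, "none": 0}


def _simulate_like(
    trajectories: list[Trajectory],
    phase: PhaseConfig,
    params: AgentParams,
    rng: np.random.Generator,
) -> list[Trajectory]:
    """Simulate one trajectory per held-out trajectory, on its landscape."""
    out = []
    for t in trajectories:
        out.append(run_trial(phase, params, t.landscape, rng,
                             trial_id=t.trial_id, landscape_id=t.landscape_id))
    return out


def kfold_cv(
    data: TrajectorySet,
    model: ModelSpec,
    k: int = 5,
    master_seed: int = 0,
    *,
    payoff_mode: str | None = None,
) -> ComparisonResult:
    """Out-of-sample evaluation of a model against a trajectory set.

    The free parameters are fitted on k-1 folds, the model is simulated on
    the held-out fold's landscapes (one simulated trajectory per held-out
    one, so density scales are comparable), and ``dist_payoff`` /
    ``dist_density`` are computed on the held-out fold.  Fold scores are
    averaged.
    """
    trajectories = list(data)
    if k < 2:
        raise InputError("k must be >= 2")
    if len(trajectories) < k:
        raise InputError(f"need at least k={k} trajectories, got {len(trajectories)}")
    if payoff_mode is None:
        payoff_mode = "best_so_far" if data.phase.reward_rule == "highest_payoff" else "current"
    dims = data.phase.dims
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 0xCF]))
    pay_scores, den_scores = [], []
    for train_idx, test_idx in KFold(n_splits=k).split(trajectories):
        train = [trajectories[i] for i in train_idx]
        test = [trajectories[i] for i in test_idx]
        params = model.fit(train, rng) if model.fit is not None else model.params
        simulated = _simulate_like(test, data.phase, params, rng)
        pay_scores.append(
            dist_payoff(payoff_curve(test, payoff_mode), payoff_curve(simulated, payoff_mode))
        )
        den_scores.append(
            dist_density(density_map(test, dims), density_map(simulated, dims))
        )
    return ComparisonResult(
        model=model.name,
        dist_payoff=float(np.mean(pay_scores)),
        dist_density=float(np.mean(den_scores)),
        n_params=model.n_params if model.n_params is not None else n_free_params(model.params),
        n_cues=(model.n_cues if model.n_cues is not None
                else N_CUES_EXPLORATION[model.params.exploration_model]),
        folds=k,
        meta={"payoff_mode": payoff_mode, "n_trajectories": len(trajectories)},
    )


def compare_models(
    data: TrajectorySet,
    models: Sequence[ModelSpec],
    k: int = 5,
    master_seed: int = 0,
) -> list[ComparisonResult]:
    """Cross-validate several models against the same trajectory set."""
    return [kfold_cv(data, m, k=k, master_seed=master_seed + i) for i, m in enumerate(models)]
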