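"""Search agents: the full take-the-best model and the alternative models.

The full model couples two mechanisms:

* **Exploration** — a take-the-best cascade over the cues
  ``[exploration-radius, not-visited, pay-off, novelty]`` with a uniform
  noise probability ``epsilon`` (see :mod:`ttbsearch.ttb`).

* **Exploitation (stopping / returning)** — whenever a new best pay-off
  ``X_best`` is discovered, the agent draws an exploration radius ``R``
  around its position ``P_best``:

  - ``R = 1`` ("stop here") with probability ``k * X_best``,
  - ``R = inf`` ("ignore this peak") with probability ``1 + l * X_best``
    (``l`` is negative, so low pay-offs are ignored often, good ones rarely;
    both probabilities are clipped into [0, 1]),
  - ``R = S0 * D_optimal`` otherwise, with safety propensity
    ``S0 ~ N(mu, sigma2)`` truncated to (0, 1] and
    ``D_optimal = floor(T_left / 2)`` the farthest excursion that still
    allows returning to ``P_best`` by the final round.

  On the "return" branch the radius is recomputed every round from the
  current remaining time, so it shrinks towards ``P_best`` as the deadline
  approaches and the agent is driven back without any explicit return rule.

Alternative exploration models (each evaluated with the radius mechanism
unchanged): *probabilistic* (chooses between a pay-off-driven and a
novelty-driven cascade with probability ``logistic(beta0 + beta1*pn_max)``
of the former, ``pn_max`` the best neighbouring pay-off), *hill-climbing*
(always to the most-rewarding adjacent cell, staying allowed), *blind
search* (novelty only) and *random search* (uniform over the legal options).

Alternative exploitation models: *normative* (always return, safety level
1), *early-stop* (settle on the first positive local maximum encountered),
*simple returning* (never ignore a peak) and the full *returning* model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

from .landscape import Landscape
from .ttb import (
    Decision,
    Option,
    StateError,
    chebyshev,
    cue_in_radius,
    cue_not_visited,
    cue_novelty,
    cue_payoff,
    legal_options,
    neighbourhood,
    ttb_decide,
)

__all__ = [
    "AgentParams",
    "SearchState",
    "d_optimal",
    "draw_exploration_range",
    "configure_exploitation",
    "current_radius",
    "init_state",
    "step",
    "EXPLOITATION_PHASE_PARAMS",
    "COMBINED_PHASE_PARAMS",
    "n_free_params",
]

Position = tuple[int, int]

ExplorationModel = Literal["ttb", "probabilistic", "hill_climbing", "blind", "random"]
ExploitationModel = Literal["returning", "simple_returning", "early_stop", "normative", "none"]

#: Free parameters of each model variant (used in comparison tables).
_N_PARAMS_EXPLORATION = {"ttb": 1, "probabilistic": 2, "hill_climbing": 0, "blind": 0, "random": 0}
_N_PARAMS_EXPLOITATION = {"returning": 4, "simple_returning": 3, "early_stop": 0, "normative": 0, "none": 0}


@dataclass
class AgentParams:
    """All model parameters plus the model-variant selectors.

    Defaults are the fitted values for the exploitation phase; the combined
    phase re-fits ``k``, ``l``, ``mu`` and ``sigma2`` (see
    :data:`COMBINED_PHASE_PARAMS`).
    """

    epsilon: float = 0.17       # per-decision probability of a uniform random choice
    k: float = 0.0051           # per-point slope of the stop probability k * X_best
    l: float = -0.027           # per-point slope of the ignore probability 1 + l * X_best
    mu: float = 0.806           # mean of the safety propensity S0
    sigma2: float = 0.364       # variance of S0
    beta0: float = -1.509       # logistic intercept (probabilistic model)
    beta1: float = 0.301        # logistic slope on pn_max (probabilistic model)
    exploration_model: ExplorationModel = "ttb"
    exploitation_model: ExploitationModel = "none"
    alt_epsilon: float = 0.0    # noise level used by the probabilistic model
    # effective-model flags set by configure_exploitation()
    ignore_disabled: bool = field(default=False)
    s0_fixed: float | None = field(default=None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be a probability, got {self.epsilon}")
        if self.exploration_model not in _N_PARAMS_EXPLORATION:
            raise ValueError(f"unknown exploration model {self.exploration_model!r}")
        if self.exploitation_model not in _N_PARAMS_EXPLOITATION:
            raise ValueError(f"unknown exploitation model {self.exploitation_model!r}")
        if self.exploitation_model in ("returning", "simple_returning", "normative"):
            if self.s0_fixed is None and (self.mu <= 0 or self.sigma2 <= 0):
                raise ValueError("mu and sigma2 must be positive for the S0 draw")


#: Fitted stopping/returning parameters for the 1-D exploitation phase.
EXPLOITATION_PHASE_PARAMS = dict(k=0.0051, l=-0.027, mu=0.806, sigma2=0.364)
#: Re-fitted stopping/returning parameters for the 2-D combined phase.
COMBINED_PHASE_PARAMS = dict(k=0.011, l=-0.022, mu=0.386, sigma2=0.275)


def n_free_params(params: AgentParams, component: str = "both") -> int:
    """Number of free parameters of the configured model combination.

    ``component`` restricts the count to the ``"exploration"`` or
    ``"exploitation"`` mechanism (useful in comparison tables where the
    other mechanism is held fixed).
    """
    exploration = _N_PARAMS_EXPLORATION[params.exploration_model]
    exploitation = _N_PARAMS_EXPLOITATION[params.exploitation_model]
    if component == "exploration":
        return exploration
    if component == "exploitation":
        return exploitation
    if component == "both":
        return exploration + exploitation
    raise ValueError(f"unknown component {component!r}")


@dataclass
class SearchState:
    """An agent's evolving situation within one trial."""

    position: Position
    visited: set[Position]
    seen: set[Position]
    x_best: int
    p_best: Position | None
    t_left: int
    branch: str | None = None      # stop | ignore | return, None before any draw
    s0: float | None = None
    stopped: bool = False          # early-stop trigger latch


def d_optimal(t_left: int) -> int:
    """Farthest excursion still allowing return by the deadline: floor(T_left / 2)."""
    if t_left < 0:
        raise StateError(f"t_left must be non-negative, got {t_left}")
    return t_left // 2


def _clip01(p: float) -> float:
    return min(1.0, max(0.0, p))


def draw_exploration_range(
    x_best: int,
    t_left: int,
    params: AgentParams,
    rng: np.random.Generator,
) -> tuple[float, float | None, str]:
    """Draw the exploration radius after a new best pay-off is found.

    Returns ``(R, s0, branch)`` with ``branch`` one of ``stop`` (R = 1),
    ``ignore`` (R = inf) or ``return`` (R = s0 * D_optimal).  The branches
    are tested sequentially: stop first, then ignore, then the safety draw.
    """
    p_stop = _clip01(params.k * x_best)
    if rng.random() < p_stop:
        return 1.0, None, "stop"
    p_ignore = 0.0 if params.ignore_disabled else _clip01(1.0 + params.l * x_best)
    if rng.random() < p_ignore:
        return math.inf, None, "ignore"
    if params.s0_fixed is not None:
        s0 = params.s0_fixed
    else:
        sigma = math.sqrt(params.sigma2)
        a, b = (0.0 - params.mu) / sigma, (1.0 - params.mu) / sigma
        s0 = float(truncnorm.rvs(a, b, loc=params.mu, scale=sigma, random_state=rng))
    return s0 * d_optimal(t_left), s0, "return"


def configure_exploitation(which: ExploitationModel, params: AgentParams) -> AgentParams:
    """Effective parameters for an exploitation-model variant.

    normative         always return with the full horizon: k = 0, never
                      ignore, S0 pinned at 1.
    early_stop        no stochastic draw at all; the radius snaps to 1 when
                      the first positive visible local maximum is occupied.
    simple_returning  the ignore branch is removed, stop and return kept.
    returning         the full three-branch draw.
    """
    if which == "normative":
        return replace(params, exploitation_model=which, k=0.0, ignore_disabled=True, s0_fixed=1.0)
    if which == "simple_returning":
        return replace(params, exploitation_model=which, ignore_disabled=True)
    if which in ("returning", "early_stop", "none"):
        return replace(params, exploitation_model=which)
    raise ValueError(f"unknown exploitation model {which!r}")


def current_radius(state: SearchState, params: AgentParams) -> float:
    """The exploration radius in force for the upcoming decision."""
    if params.exploitation_model == "none" or state.p_best is None:
        return math.inf
    if params.exploitation_model == "early_stop":
        return 1.0 if state.stopped else math.inf
    if state.branch == "stop":
        return 1.0
    if state.branch == "return":
        return state.s0 * d_optimal(state.t_left)
    return math.inf  # ignore branch, or no draw yet


def init_state(
    start: Position,
    landscape: Landscape,
    rounds: int,
    params: AgentParams,
    rng: np.random.Generator,
) -> SearchState:
    """Fresh state: the start cell is visited and its neighbourhood seen.

    A positive pay-off on the start cell counts as a discovery, so the
    stopping/returning draw fires immediately for exploitation-type models.
    """
    payoff0 = landscape.payoff_at(start)
    state = SearchState(
        position=start,
        visited={start},
        seen=set(neighbourhood(start, landscape.dims)),
        x_best=payoff0,
        p_best=start if payoff0 > 0 else None,
        t_left=rounds,
    )
    if payoff0 > 0:
        _on_discovery(state, landscape, params, rng)
    return state


def _on_discovery(
    state: SearchState,
    landscape: Landscape,
    params: AgentParams,
    rng: np.random.Generator,
) -> None:
    if params.exploitation_model in ("returning", "simple_returning", "normative"):
        _, s0, branch = draw_exploration_range(state.x_best, state.t_left, params, rng)
        state.branch, state.s0 = branch, s0


def _is_visible_local_max(position: Position, landscape: Landscape) -> bool:
    p = landscape.payoff_at(position)
    return p > 0 and all(
        p >= landscape.payoff_at(q) for q in neighbourhood(position, landscape.dims)
    )


def _choose(
    state: SearchState,
    landscape: Landscape,
    params: AgentParams,
    rng: np.random.Generator,
    options: list[Option],
) -> Decision:
    dims = landscape.dims
    model = params.exploration_model

    # epsilon-noise fires over ALL available options, radius ignored: random
    # excursions can carry the agent outside R (the radius fallback below
    # then steers it back).
    if model == "ttb" and params.epsilon > 0 and rng.random() < params.epsilon:
        chosen = options[rng.integers(len(options))]
        return Decision(chosen=chosen, deciding_cue="noise", n_remaining_at_decision=len(options))
    if model == "random":
        chosen = options[rng.integers(len(options))]
        return Decision(chosen=chosen, deciding_cue="random_tiebreak",
                        n_remaining_at_decision=len(options))

    radius = current_radius(state, params)
    feasible = [o for o in options if cue_in_radius(o, state.p_best, radius)]
    if not feasible:
        # only possible after a noise excursion beyond R: head back to P_best
        dists = [chebyshev(o.target, state.p_best) for o in options]
        best = min(dists)
        closest = [o for o, d in zip(options, dists) if d == best]
        chosen = closest[rng.integers(len(closest))]
        return Decision(chosen=chosen, deciding_cue="radius", n_remaining_at_decision=len(closest))
    if len(feasible) == 1 and len(feasible) < len(options):
        return Decision(chosen=feasible[0], deciding_cue="radius", n_remaining_at_decision=1)

    not_visited = ("not_visited", lambda o: cue_not_visited(o, state.visited))
    payoff = ("payoff", lambda o: cue_payoff(o, landscape))
    novelty = ("novelty", lambda o: cue_novelty(o, state.seen, dims))

    if model == "ttb":
        return ttb_decide(feasible, [not_visited, payoff, novelty], 0.0, rng)
    if model == "probabilistic":
        neighbour_payoffs = [cue_payoff(o, landscape) for o in options if not o.is_stay]
        pn_max = max(neighbour_payoffs) if neighbour_payoffs else 0
        use_payoff = rng.random() < expit(params.beta0 + params.beta1 * pn_max)
        order = [not_visited, payoff] if use_payoff else [not_visited, novelty]
        return ttb_decide(feasible, order, params.alt_epsilon, rng)
    if model == "hill_climbing":
        return ttb_decide(feasible, [payoff], 0.0, rng)
    if model == "blind":
        return ttb_decide(feasible, [not_visited, novelty], 0.0, rng)
    raise ValueError(f"unknown exploration model {model!r}")


def step(
    state: SearchState,
    landscape: Landscape,
    params: AgentParams,
    rng: np.random.Generator,
    options: list[Option] | None = None,
) -> tuple[SearchState, Decision]:
    """Make one decision, apply the move and update the state in place.

    ``options`` overrides the legal option set (phase rules such as the
    rightward-only first move of the 1-D phase restrict it).
    """
    if state.t_left < 1:
        raise StateError("no rounds left")
    if options is None:
        options = legal_options(state.position, landscape.dims)
    decision = _choose(state, landscape, params, rng, options)

    target = decision.chosen.target
    state.position = target
    state.visited.add(target)
    state.seen.update(neighbourhood(target, landscape.dims))
    state.t_left -= 1

    payoff = landscape.payoff_at(target)
    if payoff > state.x_best:
        state.x_best = payoff
        state.p_best = target
        _on_discovery(state, landscape, params, rng)
    if (
        params.exploitation_model == "early_stop"
        and not state.stopped
        and _is_visible_local_max(target, landscape)
    ):
        state.stopped = True
    return state, decision
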