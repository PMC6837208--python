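"""Lexicographic take-the-best (TTB) decision engine.

Each round the agent chooses among at most nine options: staying put or
moving to one of the (in-bounds) Moore neighbours of its current cell.  The
choice is made by a cue cascade: cues are consulted one at a time in a fixed
order, and each cue retains the subset of options with the maximal cue value.
As soon as a single option survives, it is chosen and later cues are never
evaluated.  If several options survive every cue, one is drawn uniformly at
random.  A noise parameter ``epsilon`` gives, on every decision, a small
probability of choosing uniformly among all available options instead of
running the cascade (undirected exploration).

Cues
----
in_radius    binary; 1 iff the option lies within the current exploration
             radius ``R`` of the best position found so far (Chebyshev
             distance).  Inert (all 1) while no positive pay-off has been
             discovered.
not_visited  binary; 1 iff the option's target cell has never been occupied.
payoff       the pay-off of the target cell.
novelty      how many cells would newly enter the visible ("seen") set: the
             screen shows the 3x3 neighbourhood of the occupied cell, so a
             diagonal move can reveal up to 5 new cells, an orthogonal move
             up to 3, and staying 0.

Binary cues use the same argmax-subset semantics as numeric ones: if at
least one option scores 1 the zero-scored options are dropped; if all score
0 the cue does not discriminate and every option survives.

Positions are 1-based ``(row, col)`` tuples; a 1-D landscape is a 1 x N grid
so the same code handles both (the Chebyshev distance degenerates to |dx|).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .landscape import Landscape

__all__ = [
    "Option",
    "Decision",
    "legal_options",
    "neighbourhood",
    "chebyshev",
    "cue_not_visited",
    "cue_payoff",
    "cue_novelty",
    "cue_in_radius",
    "ttb_decide",
]

Position = tuple[int, int]


class StateError(RuntimeError):
    """Raised when a decision is requested from an inconsistent state."""


@dataclass(frozen=True)
class Option:
    """One candidate action: a move offset and its target cell."""

    move: tuple[int, int]
    target: Position

    @property
    def is_stay(self) -> bool:
        return self.move == (0, 0)


@dataclass(frozen=True)
class Decision:
    """Outcome of one decision, with provenance of the deciding cue."""

    chosen: Option
    deciding_cue: str  # radius | not_visited | payoff | novelty | random_tiebreak | noise
    n_remaining_at_decision: int


def chebyshev(a: Position, b: Position) -> int:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def legal_options(position: Position, dims: tuple[int, int]) -> list[Option]:
    """Stay plus every in-bounds Moore neighbour, as Option objects."""
    rows, cols = dims
    r, c = position
    if not (1 <= r <= rows and 1 <= c <= cols):
        raise StateError(f"position {position} outside a {rows} x {cols} grid")
    opts = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            tr, tc = r + dr, c + dc
            if 1 <= tr <= rows and 1 <= tc <= cols:
                opts.append(Option(move=(dr, dc), target=(tr, tc)))
    return opts


def neighbourhood(position: Position, dims: tuple[int, int]) -> list[Position]:
    """In-bounds 3x3 block around a cell — what the screen shows there."""
    rows, cols = dims
    r, c = position
    return [
        (r + dr, c + dc)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if 1 <= r + dr <= rows and 1 <= c + dc <= cols
    ]


# ---------------------------------------------------------------------------
# Cues

def cue_not_visited(option: Option, visited: set[Position]) -> int:
    return 0 if option.target in visited else 1


def cue_payoff(option: Option, landscape: Landscape) -> int:
    return landscape.payoff_at(option.target)


def cue_novelty(option: Option, seen: set[Position], dims: tuple[int, int]) -> int:
    """Number of cells that would newly become visible after the move."""
    return sum(1 for p in neighbourhood(option.target, dims) if p not in seen)


def cue_in_radius(
    option: Option,
    p_best: Position | None,
    radius: float,
) -> int:
    """1 iff the option's target is within ``radius`` of the best position.

    With ``p_best`` undefined (no positive pay-off found yet) or an infinite
    radius the cue is inert and every option passes.
    """
    if radius < 0:
        raise ValueError(f"exploration radius must be non-negative, got {radius}")
    if p_best is None or math.isinf(radius):
        return 1
    return 1 if chebyshev(option.target, p_best) <= radius else 0


# ---------------------------------------------------------------------------
# Cascade

CueFn = Callable[[Option], float]


def _filter_argmax(options: Sequence[Option], cue: CueFn) -> list[Option]:
    vals = [cue(o) for o in options]
    best = max(vals)
    return [o for o, v in zip(options, vals) if v == best]


def ttb_decide(
    options: Sequence[Option],
    cue_order: Iterable[tuple[str, CueFn]],
    epsilon: float,
    rng: np.random.Generator,
) -> Decision:
    """Run the noisy take-the-best cascade over a set of options.

    With probability ``epsilon`` the decision is a uniform draw over all
    options (``deciding_cue='noise'``).  Otherwise each cue in order retains
    the argmax subset of the survivors; the first cue leaving one survivor
    decides.  A full tie after the last cue is broken uniformly at random.
    """
    options = list(options)
    if not options:
        raise StateError("cannot decide between zero options")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    if epsilon > 0 and rng.random() < epsilon:
        chosen = options[rng.integers(len(options))]
        return Decision(chosen=chosen, deciding_cue="noise", n_remaining_at_decision=len(options))
    survivors = options
    for name, cue in cue_order:
        survivors = _filter_argmax(survivors, cue)
        if len(survivors) == 1:
            return Decision(chosen=survivors[0], deciding_cue=name, n_remaining_at_decision=1)
    chosen = survivors[rng.integers(len(survivors))]
    return Decision(
        chosen=chosen, deciding_cue="random_tiebreak", n_remaining_at_decision=len(survivors)
    )
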