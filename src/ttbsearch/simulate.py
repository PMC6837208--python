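"""Trial simulation for the three experimental phases.

Each trial is 30 rounds of search on one landscape.  The phases differ in
dimensionality, start position and reward rule:

=============  ==============  =========  =====================
phase          landscape       start      reward
=============  ==============  =========  =====================
exploration    2-D, 63 x 63    (32, 32)   highest pay-off found
exploitation   1-D, 1 x 63     x = 1      pay-off in last round
combined       2-D, 63 x 63    (32, 32)   pay-off in last round
=============  ==============  =========  =====================

In the exploitation phase the first move is restricted to the right (no
staying, no moving left), mirroring the start at the left end of the line.

Seeding: a batch takes one master seed; every landscape and trial derives
its own :class:`numpy.random.SeedSequence` from ``(master_seed, indices)``
so that any single trajectory can be regenerated in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import AgentParams, configure_exploitation, current_radius, init_state, step
from .landscape import Landscape, generate_1d_landscape, generate_landscape, n_peaks_for_kind
from .ttb import legal_options

__all__ = [
    "PhaseConfig",
    "Trajectory",
    "TrajectorySet",
    "run_trial",
    "run_batch",
    "trajectories_to_frame",
    "save_trajectories",
    "load_trajectories",
]

Position = tuple[int, int]

ROUNDS = 30

_PHASE_PRESETS = {
    "exploration": dict(dims=(63, 63), start=(32, 32), reward_rule="highest_payoff"),
    "exploitation": dict(dims=(1, 63), start=(1, 1), reward_rule="last_round_payoff"),
    "combined": dict(dims=(63, 63), start=(32, 32), reward_rule="last_round_payoff"),
}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PhaseConfig:
    phase: str
    dims: tuple[int, int] = (63, 63)
    start: Position = (32, 32)
    rounds: int = ROUNDS
    reward_rule: str = "highest_payoff"
    landscape_kind: str = "poor"

    @classmethod
    def preset(cls, phase: str, landscape_kind: str = "poor", rounds: int = ROUNDS) -> "PhaseConfig":
        """The canonical configuration of one of the three phases."""
        if phase not in _PHASE_PRESETS:
            raise ConfigurationError(
                f"unknown phase {phase!r}; expected exploration, exploitation or combined"
            )
        p = _PHASE_PRESETS[phase]
        return cls(phase=phase, landscape_kind=landscape_kind, rounds=rounds, **p)

    def generate_landscape(self, rng: np.random.Generator, *, seed: int | None = None) -> Landscape:
        n_peaks = n_peaks_for_kind(self.landscape_kind)
        if self.dims[0] == 1:
            return generate_1d_landscape(n_peaks, rng, dims=(63, self.dims[1]), seed=seed)
        return generate_landscape(self.dims, n_peaks, rng, seed=seed)


@dataclass
class Trajectory:
    """Per-round record of one trial plus its reward and provenance.

    ``records`` holds ``rounds + 1`` entries: the start state (round 0) and
    one entry per decision.  ``R`` is the exploration radius in force at the
    decision (``inf`` when inert or on the ignore branch).
    """

    records: list[dict]
    reward: int
    normalized_reward: float
    phase: str
    landscape: Landscape
    params: AgentParams
    seed: object = None
    trial_id: int = 0
    landscape_id: int = 0

    @property
    def positions(self) -> list[Position]:
        return [(rec["row"], rec["col"]) for rec in self.records]

    @property
    def payoffs(self) -> list[int]:
        return [rec["payoff"] for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class TrajectorySet:
    trajectories: list[Trajectory]
    phase: PhaseConfig
    params: AgentParams
    master_seed: int | None = None

    def __iter__(self):
        return iter(self.trajectories)

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def landscapes(self) -> list[Landscape]:
        seen: dict[int, Landscape] = {}
        for t in self.trajectories:
            seen.setdefault(t.landscape_id, t.landscape)
        return [seen[k] for k in sorted(seen)]


def _phase_options(phase: PhaseConfig, state, landscape: Landscape, round_no: int):
    options = legal_options(state.position, landscape.dims)
    if phase.phase == "exploitation" and round_no == 1:
        # first round of the 1-D phase: rightward movement only
        options = [o for o in options if o.move[1] == 1]
    return options


def run_trial(
    phase: PhaseConfig,
    params: AgentParams,
    landscape: Landscape,
    rng: np.random.Generator,
    *,
    trial_id: int = 0,
    landscape_id: int = 0,
    seed: object = None,
) -> Trajectory:
    """Simulate one 30-round trial and return the full trajectory."""
    if tuple(landscape.dims) != tuple(phase.dims):
        raise ConfigurationError(
            f"landscape dims {landscape.dims} do not match phase dims {phase.dims}"
        )
    eff = configure_exploitation(params.exploitation_model, params)
    state = init_state(phase.start, landscape, phase.rounds, eff, rng)

    def record(round_no: int, decision=None) -> dict:
        r, c = state.position
        pb = state.p_best
        return {
            "round": round_no,
            "row": r,
            "col": c,
            "payoff": landscape.payoff_at(state.position),
            "x_best": state.x_best,
            "p_best_row": pb[0] if pb else None,
            "p_best_col": pb[1] if pb else None,
            "R": radius_at_decision if decision is not None else math.inf,
            "deciding_cue": decision.deciding_cue if decision is not None else "",
            "noise_flag": decision is not None and decision.deciding_cue == "noise",
        }

    radius_at_decision = math.inf
    records = [record(0)]
    for round_no in range(1, phase.rounds + 1):
        options = _phase_options(phase, state, landscape, round_no)
        radius_at_decision = current_radius(state, eff)
        state, decision = step(state, landscape, eff, rng, options=options)
        records.append(record(round_no, decision))

    if phase.reward_rule == "highest_payoff":
        reward = state.x_best
    elif phase.reward_rule == "last_round_payoff":
        reward = landscape.payoff_at(state.position)
    else:
        raise ConfigurationError(f"unknown reward rule {phase.reward_rule!r}")
    max_payoff = landscape.max_payoff
    normalized = reward / max_payoff if max_payoff > 0 else 0.0
    return Trajectory(
        records=records,
        reward=int(reward),
        normalized_reward=normalized,
        phase=phase.phase,
        landscape=landscape,
        params=eff,
        seed=seed,
        trial_id=trial_id,
        landscape_id=landscape_id,
    )


def run_batch(
    phase: PhaseConfig,
    params: AgentParams,
    n_landscapes: int,
    trials_per_landscape: int,
    master_seed: int,
    *,
    landscape_seed: int | None = None,
) -> TrajectorySet:
    """Simulate ``n_landscapes * trials_per_landscape`` independent trials.

    Landscape ``i`` is generated from ``SeedSequence([landscape_seed, i, 0])``
    and its trial ``j`` runs on ``SeedSequence([master_seed, i, 1 + j])``.
    ``landscape_seed`` defaults to ``master_seed``; passing it separately
    lets two batches share their environments while drawing independent
    decisions (used to compare agents on a common set of landscapes).
    """
    if n_landscapes < 1 or trials_per_landscape < 1:
        raise ConfigurationError("batch sizes must be >= 1")
    if landscape_seed is None:
        landscape_seed = master_seed
    trajectories: list[Trajectory] = []
    trial_id = 0
    for i in range(n_landscapes):
        ls_rng = np.random.default_rng(np.random.SeedSequence([landscape_seed, i, 0]))
        landscape = phase.generate_landscape(ls_rng, seed=master_seed)
        for j in range(trials_per_landscape):
            seed_key = [master_seed, i, 1 + j]
            rng = np.random.default_rng(np.random.SeedSequence(seed_key))
            trajectories.append(
                run_trial(
                    phase, params, landscape, rng,
                    trial_id=trial_id, landscape_id=i, seed=tuple(seed_key),
                )
            )
            trial_id += 1
    return TrajectorySet(trajectories=trajectories, phase=phase, params=params,
                         master_seed=master_seed)


# ---------------------------------------------------------------------------
# Serialization

_CSV_COLUMNS = [
    "trial_id", "phase", "landscape_id", "round", "row", "col", "payoff",
    "x_best", "p_best_row", "p_best_col", "R", "deciding_cue", "noise_flag",
]


def trajectories_to_frame(trajectories: list[Trajectory] | TrajectorySet) -> pd.DataFrame:
    rows = []
    for t in trajectories:
        for rec in t.records:
            rows.append({
                "trial_id": t.trial_id,
                "phase": t.phase,
                "landscape_id": t.landscape_id,
                **rec,
            })
    frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    # R = inf serialized as an empty field
    frame["R"] = frame["R"].map(lambda r: "" if math.isinf(r) else r)
    return frame


def save_trajectories(
    trajectories: TrajectorySet,
    path: str | Path,
    *,
    manifest: bool = True,
) -> None:
    path = Path(path)
    trajectories_to_frame(trajectories).to_csv(path, index=False)
    if manifest:
        meta = {
            "phase": asdict(trajectories.phase),
            "params": asdict(trajectories.params),
            "master_seed": trajectories.master_seed,
            "n_trajectories": len(trajectories),
        }
        path.with_suffix(".manifest.json").write_text(json.dumps(meta, indent=1))


def load_trajectories(path: str | Path) -> pd.DataFrame:
    """Load a trajectory CSV as a flat frame (one row per round record)."""
    frame = pd.read_csv(path, keep_default_na=False, na_values=[])
    frame["R"] = frame["R"].map(lambda r: math.inf if r == "" else float(r))
    return frame
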