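"""Simulate the exploration phase with the 3-cue take-the-best model.

The agent chooses among stay + 8 neighbours by the cascade
[not-visited, pay-off, novelty] with decision noise epsilon = 0.17, and is
rewarded by the best pay-off it encounters in 30 rounds.  The script prints
the pay-off curve, the cue-usage proportions and the diagonal density
contrast that produces the X-shaped exploration pattern in poor landscapes.
"""

import numpy as np

from ttbsearch import (
    AgentParams, PhaseConfig, cue_usage, density_map, diagonal_contrast,
    payoff_curve, revisit_fraction, run_batch,
)

params = AgentParams()  # ttb exploration, epsilon=0.17, no exploitation component

for kind in ("poor", "rich"):
    phase = PhaseConfig.preset("exploration", landscape_kind=kind)
    batch = run_batch(phase, params, n_landscapes=50, trials_per_landscape=4,
                      master_seed=2)
    curve = payoff_curve(batch, "best_so_far")
    a, b, c = cue_usage(batch)
    contrast = diagonal_contrast(density_map(batch, (63, 63)), (32, 32))
    revisit = np.mean([revisit_fraction(t) for t in batch])
    print(f"{kind:>5}: best-so-far pay-off round 10/20/30 = "
          f"{curve[9]:.2f}/{curve[19]:.2f}/{curve[29]:.2f}   "
          f"cue usage a={a:.2f} b={b:.2f} c={c:.2f}   "
          f"diagonal contrast {contrast:.2f}   revisit fraction {revisit:.2f}")

print("\na = moves to unvisited cells, b = ... with the best unvisited pay-off,")
print("c = novelty-maximizing choices when earlier cues tie.  A diagonal")
print("contrast above 1 is the X-shaped exploration pattern; it is stronger")
print("in poor landscapes, where pay-offs rarely discriminate and the")
print("novelty cue (diagonal moves reveal 5 cells, orthogonal 3) takes over.")
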