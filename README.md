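# ttbsearch

Agent-based models of human search in **gradually explorable pay-off
landscapes** — environments where you can only move to neighbouring
solutions (no jumps) and your reward comes from a single solution you
eventually commit to.  Think of scanning a city block by block for the best
restaurant: you evaluate what is adjacent, you remember the best place
found so far, and at some point you stop wandering and walk back to it.

The package is aimed at cognitive-science and decision-making researchers
who want to simulate, fit and compare heuristic search strategies on grid
landscapes: it bundles the landscape generator, a lexicographic
(take-the-best) decision engine, a family of exploration and
stopping/returning models, trajectory metrics, distance-based model
comparison with cross-validation, and parameter-estimation routines.

## The model

An agent lives on an integer pay-off grid (63×63, or a 1×63 line), sees
the pay-offs in the 3×3 block around its cell, and each of 30 rounds picks
one of at most nine options (stay or move to a Moore neighbour).  The
choice is a **take-the-best cue cascade**: cues are consulted one at a
time, each retains the options with the maximal cue value, and the first
cue leaving a single option decides:

1. **exploration radius** — is the option within distance *R* of the best
   position found so far, *P*<sub>best</sub>?
2. **not visited** — has the option's cell never been occupied?
3. **pay-off** — the cell's pay-off;
4. **novelty** — how many cells would newly become visible (up to 5 for a
   diagonal move, 3 for an orthogonal one)?

Ties at the end are broken uniformly; with probability ε (= 0.17) the
agent instead picks uniformly among all options (undirected exploration).

The stopping/returning component sets *R* whenever a new best pay-off
*X*<sub>best</sub> is found:

- *R* = 1 ("stop here") with probability *k·X*<sub>best</sub>,
- *R* = ∞ ("ignore this peak") with probability 1 + *l·X*<sub>best</sub>
  (*l* < 0, so only poor peaks get ignored),
- otherwise *R* = *S*₀ · *D*<sub>optimal</sub>, with safety propensity
  *S*₀ ~ N(μ, σ²) truncated to (0, 1] and
  *D*<sub>optimal</sub> = ⌊*T*<sub>left</sub>/2⌋ the farthest excursion
  that still allows returning by the deadline.

The return radius is recomputed every round from the remaining time, so it
shrinks towards *P*<sub>best</sub> and the agent is pulled back without
any explicit return rule.  Alternative exploration models (probabilistic
cue choice, hill climbing, blind novelty search, random search) and
exploitation models (normative, early-stop, simple returning) are built on
the same machinery for comparison.

## Worked example

```python
import numpy as np
from ttbsearch import (AgentParams, PhaseConfig, run_batch, payoff_curve,
                       cue_usage, density_map, diagonal_contrast)

phase = PhaseConfig.preset("exploration", landscape_kind="poor")
batch = run_batch(phase, AgentParams(), n_landscapes=50,
                  trials_per_landscape=4, master_seed=2)
curve = payoff_curve(batch, "best_so_far")
a, b, c = cue_usage(batch)
contrast = diagonal_contrast(density_map(batch, (63, 63)), (32, 32))
print(f"final best-so-far pay-off {curve[-1]:.2f}, cue usage "
      f"a={a:.2f} b={b:.2f} c={c:.2f}, diagonal contrast {contrast:.2f}")
```

prints

```
final best-so-far pay-off 0.34, cue usage a=0.95 b=0.91 c=0.89, diagonal contrast 2.49
```

meaning: on poor landscapes the agent ends with ~34% of the maximal
pay-off on average; 95% of its moves go to unvisited cells, 91% to the
best-paying unvisited cell, and 89% of tied decisions maximize newly
revealed cells; the diagonal contrast of 2.49 (> 1) is the X-shaped
exploration pattern — visit density concentrates on the diagonals because
diagonal moves reveal more new cells.  On rich landscapes the same run
gives a contrast of 0.73: frequent pay-off differences let the pay-off cue
decide before novelty, and the X pattern disappears.

The `examples/` directory has one narrative script per capability
(landscape generation, exploration, exploitation/safety levels, model
comparison, parameter recovery); each prints the numbers it computes with
a short interpretation.  A thin CLI mirrors the workflow:

```bash
ttbsearch generate --kind poor --n 10 --seed 1 --out landscapes
ttbsearch simulate --phase combined --kind rich --n-landscapes 20 --seed 1 --out trajs.csv
ttbsearch compare --which exploitation --n-landscapes 20 --seed 1
```

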