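# Methods

This note documents the models implemented in `ttbsearch`, the choices
made where the design was genuinely open, and what the synthetic data can
and cannot show.

## Landscapes

A 2-D landscape is built from `n_peaks` sub-landscapes on a 63×63 grid:
each is zero except for one uniformly placed cell holding `z**2`,
`z ~ N(0, 1)`, smoothed by an isotropic Gaussian filter with σ = 1 (zero
padded, truncated at 4σ — scipy's default).  Sub-landscapes are merged by
the cell-wise maximum, linearly rescaled so min → 0 and max → `scale_max`
(a uniform integer in {30, …, 80}), and rounded to integers.  `n_peaks =
32` gives "poor", `n_peaks = 512` "rich" landscapes.  1-D landscapes are
one uniformly chosen row of a fresh 2-D landscape of the same kind.

Choices worth stating:

- **Scale before rounding.**  Rounding first and then rescaling would
  destroy integrality; scaling first keeps the grid integral with an
  exact maximum of `scale_max` (the maximum maps to `scale_max` exactly
  and survives rounding).
- **`scale_max` is an integer.**  The target of the rescaling is drawn as
  a uniform *integer* in 30…80; a continuous draw would be
  indistinguishable in play but worse for reproducibility.
- **Boundary mode.**  Constant-zero padding for the filter; peaks near
  the border simply lose mass off-grid.  Agents starting at the centre of
  a 63×63 grid cannot reach the border in 30 rounds, so the mode is
  inconsequential in the 2-D phases.
- **Peak collisions** are allowed (two sub-landscapes may pick the same
  cell); the max-merge resolves them.
- **Implementation.**  Because each sub-landscape is a single smoothed
  impulse, the merge is computed by stamping the 9×9 truncated kernel
  patch per peak and keeping a running maximum — algebraically identical
  to filtering full matrices (the test suite checks cell-for-cell
  equality against a full `gaussian_filter` construction), and ~50×
  faster for rich landscapes.
- **Coordinates are 1-based `(row, col)`**, so the centre of the grid is
  (32, 32) and the 1-D start is x = 1.  Serialized files state this.

## The decision engine

Options are stay plus all in-bounds Moore neighbours (9 in the 2-D
interior; 3 in the 1-D interior; fewer at borders).  The cascade retains,
cue by cue, the subset of options with the maximal cue value and stops as
soon as one option survives; survivors of the last cue are resolved
uniformly at random.  Binary cues follow the same argmax rule: if no
option scores 1 the cue does not discriminate and all survive.  This
*subset-filtering* semantics (survivors of cue *i* are the candidate set
of cue *i*+1) matches the worked narrative of the cue-table example the
model is defined by; classical "skip the cue entirely if it does not
discriminate" semantics would differ only when a cue partially separates
options.

Cue definitions:

- `not_visited`: target never occupied.  The start cell counts as visited
  before the first decision.
- `payoff`: the target cell's pay-off (always visible — the screen shows
  the 3×3 block around the agent).
- `novelty`: number of cells in the 3×3 block around the target that have
  never been visible, where the *seen* set is the union of 3×3 blocks of
  all visited positions.  This accumulated bookkeeping makes novelty
  directional (the cell pointing away from explored territory wins) and
  produces the diagonal (up to 5 new cells) vs orthogonal (up to 3)
  asymmetry driving the X-shaped density pattern.
- `in_radius`: Chebyshev distance to `P_best` at most *R* (|Δx| on a
  line).  Inert while no positive pay-off has been discovered.

ε-noise applies per decision at the top level: with probability ε the
choice is uniform over **all** phase-legal options, including those
outside the exploration radius; a stranded agent (empty radius-feasible
set) falls back to the legal option closest to `P_best`, which restores
the return guarantee after noise excursions.

## Stopping and returning

On every strict improvement of `X_best` (including a positive pay-off on
the start cell) the agent draws sequentially: stop (probability
`clip(k·X_best, 0, 1)`, radius 1), else ignore (probability
`clip(1 + l·X_best, 0, 1)`, radius ∞), else return with `S0` drawn from
N(μ, σ²) truncated to (0, 1].

- **The ignore probability is `1 + l·X_best`**, not `1 − l·X_best` as a
  literal reading of the printed formula would give: with `l = −0.027`
  the literal form exceeds 1 for every positive pay-off, while the
  implemented form starts at 1 for worthless peaks and hits 0 near
  `X_best ≈ 37` — consistent with ignoring being concentrated on
  low-value peaks (ignored peaks average ~10 points in simulation).
- **The return radius is recomputed every round** as
  `R_t = S0 · ⌊T_left/2⌋`, where `T_left` counts the rounds not yet
  played.  The radius therefore shrinks ~`S0/2` per round and drags the
  agent back to `P_best`, arriving exactly as the radius reaches zero on
  the final round.  A consequence worth knowing: the *realized* excursion
  of an outward-moving agent turns around at roughly
  `2·S0/(2+S0) · D_optimal`, not at `S0 · D_optimal` — the safety
  propensity `S0` and the measured safety level `S` are related but not
  identical quantities, even for the noise-free "normative" agent
  (`S0 ≡ 1` yields realized `S ≈ 0.67–0.8`).
- **Branch and `S0` are redrawn at every strict improvement**; between
  improvements only the radius is recomputed.
- `X_best` is defined over *occupied* cells (the reward pays the occupied
  cell), not over merely seen ones.

Exploitation variants: *normative* (`k = 0`, never ignore, `S0 ≡ 1`),
*simple returning* (ignore branch removed), *early stop* (no draw at all;
the radius latches to 1 when the agent first occupies a cell with
positive pay-off that weakly dominates its visible neighbours — the
minimal reading of "stopping at the first peak"), and *none* (pure
exploration; radius cue inert).

Alternative exploration mechanisms share the radius machinery and differ
only in the choice rule on the feasible set: *probabilistic* runs the
cascade [not-visited, pay-off] with probability
`logistic(β₀ + β₁·pn_max)` — `pn_max` the best pay-off among neighbour
options — and [not-visited, novelty] otherwise (the printed coefficient
string is read as the standard logistic; it crosses p = 0.5 at
`pn_max ≈ 5.0` and increases with `pn_max`, the only reading that stays
in (0, 1)); *hill climbing* maximizes pay-off over options including
stay (hence absorbs at visible local maxima); *blind* runs [not-visited,
novelty]; *random* is uniform over all legal options.  The alternatives
carry no ε-noise (keeping their free-parameter counts at 0, and 2 for
the probabilistic model); a noise level for the probabilistic model is
exposed as `alt_epsilon` but defaults to 0.

## Phases and simulation

Three phase presets: exploration (2-D, start (32, 32), reward = best
pay-off found), exploitation (1-D, start x = 1, reward = final-round
pay-off, first move restricted to the right — stay is also disallowed in
that round), combined (2-D, reward = final-round pay-off).  30 decisions
per trial; the trajectory stores the start state plus one record per
round (position, pay-off, `X_best`, `P_best`, radius in force, deciding
cue, noise flag).  Batches derive per-landscape and per-trial seeds from
`SeedSequence([master_seed, landscape_index, trial_index])`, so any
single trajectory is reproducible in isolation; `run_batch` can pin the
landscape population to a separate `landscape_seed` so different agents
(or different parameter values) can be compared on identical
environments.

## Metrics

- **Pay-off curves** are per-round means of the normalized pay-off
  (current or best-so-far), normalized by each trajectory's landscape
  maximum; length 30 (the start state is excluded).
- **Density maps** are raw visit counts including the start;
  `log_density` converts to log10 relative frequency with a +1
  pseudo-count per cell, the scale on which maps are displayed and
  compared.  `dist_density` is the mean absolute per-cell difference of
  log-densities (a raw-count option is retained behind a flag);
  `dist_payoff` is the summed squared difference between curves, summed
  over landscape kinds when curves are given per kind.
- **Revisit fraction**: distinct occupied cells occupied in ≥ 2 of the 31
  rounds, divided by distinct occupied cells.
- **Cue usage** classifies every decision observably (from positions and
  the landscape, not from model internals): (a) share of moves to
  unvisited cells; (b) share of moves to unvisited cells that also carry
  the maximal pay-off among unvisited options; (c) among decisions where
  the not-visited and pay-off filters leave more than one option, the
  share of choices attaining maximal *newly revealed* cells.  "Newly
  revealed" in (c) defaults to the immediate view change (cells entering
  the 3×3 window: 5/3/0 for diagonal/orthogonal/stay in the interior),
  which is what an observer can score per movement; the accumulated
  whole-trajectory bookkeeping used by the model's novelty *cue* is
  available via `novelty_accounting="accumulated"`.  Under the immediate
  accounting a random searcher scores ~44% on poor landscapes (its choice
  happens to be one of the maximal-reveal options about 4 times in 9);
  under the accumulated accounting the baseline drops to ~17%.
  Model-internal provenance (which cue actually fired, including noise)
  is reported separately by `deciding_cue_frequencies`.
- **Safety levels**: one episode per strict `X_best` improvement.
  `realized_R` is the maximal Chebyshev distance from `P_best` before its
  first re-occupation; `S = realized_R / D_optimal` with `D_optimal`
  evaluated at the discovery.  Episodes are censored as `no_return`
  (never re-occupied `P_best`; the behavioural reading of S > 1),
  `short_horizon` (`D_optimal ≤ 2`, too short to distinguish staying
  from returning), or `superseded` (a strictly better discovery occurred
  before any return; these are neither stop nor ignore evidence and are
  excluded from the slope fits).

## Fitting

- **ε** — grid search: for each grid value, simulate trajectories (split
  across landscape kinds), compare best-so-far curves to the observed
  ones by `dist_payoff`, return the argmin.  One master seed is shared by
  all grid points (common random numbers), and the landscape population
  can be pinned to the observed data's population; both choices remove
  variance that is orthogonal to ε and make the objective cleanly
  unimodal at moderate simulation sizes (recovery of ε = 0.17 within one
  grid step succeeds at 2000 simulated trajectories per grid point).
- **k** — through-origin linear-probability fit of the indicator
  {immediate stop} on `X_best` (the model for P(stop) has no intercept
  by construction).  **l** — linear-probability fit with intercept of
  {never returned} on `X_best`; the slope is reported.  Episode-level
  indicators; superseded episodes excluded.
- **μ, σ²** — maximum likelihood for the (0, 1]-truncated normal on the
  safety levels with 0 < S ≤ 1, via Nelder–Mead on (μ, log σ); standard
  errors from the finite-difference observed information with a delta
  step to the σ² scale.  A 120-replicate calibration check gives z-score
  dispersion ≈ 1.05–1.09 and 95%-interval coverage of 92–94%.
- **β₀, β₁** — binomial logistic regression (statsmodels) of
  pay-off-cue use on `pn_max`; perfect separation is detected (failed
  convergence or exploding standard errors) and handled by an
  L2-penalized refit flagged in the result.

Fitting the slope parameters back from *full simulations* (rather than
from synthesized episodes) recovers distorted values: drawn radii below 1
cell register as immediate stops (inflating k) and superseded ignore
episodes are censored (shrinking |l|).  This is a property of the
episode-extraction observables, not of the estimators, and it equally
affects estimates obtained from behavioural data by the same rules.

## Model comparison

`kfold_cv` fits a model's free parameters on k−1 folds (models without a
fitter keep their given parameters), simulates one trajectory per
held-out trajectory *on the held-out landscapes* (keeping density scales
comparable), and averages `dist_payoff` and `dist_density` across the
k = 5 folds.  Comparison tables report free-parameter counts for the
component being varied (exploration: take-the-best 1, probabilistic 2,
others 0; exploitation: returning 4, simple returning 3, early-stop and
normative 0).

## Scope of the synthetic evidence

All tests run on simulated data.  The generator reproduces the task's
structure (grid sizes, start positions, reward rules, peak statistics)
but not behavioural heterogeneity: every simulated agent shares one
parameter vector, whereas real participants vary (only `S0` is drawn per
episode).  Passing parameter-recovery tests shows the estimators invert
the generative model at realistic sample sizes; it does not validate the
parameter values against human behaviour, and the comparison-table
distances computed here quantify distinguishability between simulated
models, not model–human fit.  Problem sizes used by the default test run
(e.g. 2000 trajectories per ε-grid point, 10⁴ draws for the truncated
normal, 50 replicate batches for the density-contrast test) were chosen
as the smallest sizes at which the corresponding statistics are stable.

## Known limitations

- Patchy landscapes (clustered peaks) and varying peak widths/heights
  are out of scope; the generator exposes no hook for them.
- The model has no within-trial learning and no time dependence of the
  safety propensity.
- The early-stop variant's "first peak" is the minimal reading (first
  visited positive cell weakly dominating its visible neighbours); with
  that trigger the radius centres on `P_best`, which coincides with the
  triggering cell except in contrived landscapes.
- On an all-zero landscape normalized rewards are reported as 0 and
  normalized pay-off curves as raw zeros (the normalization is
  undefined); `normalize_payoff` raises instead of guessing.
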