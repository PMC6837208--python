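"""Cross-validated comparison of the exploration-model menagerie.

Reference trajectories are simulated from the full take-the-best model in
the combined phase; each alternative exploration mechanism (probabilistic
cue choice, hill climbing, blind novelty search, random search) is then
scored out-of-sample by dist_payoff (squared pay-off-curve difference) and
dist_density (mean absolute log-density difference) with 5-fold CV.
"""

from dataclasses import replace

from ttbsearch import (
    AgentParams, COMBINED_PHASE_PARAMS, ModelSpec, PhaseConfig, compare_models,
    run_batch,
)

phase = PhaseConfig.preset("combined", landscape_kind="poor")
reference = AgentParams(exploration_model="ttb", exploitation_model="returning",
                        **COMBINED_PHASE_PARAMS)
data = run_batch(phase, reference, n_landscapes=40, trials_per_landscape=2,
                 master_seed=4)

models = [ModelSpec(name, replace(reference, exploration_model=name))
          for name in ("ttb", "probabilistic", "hill_climbing", "blind", "random")]
results = compare_models(data, models, k=5, master_seed=5)

print(f"{'model':>15} {'dist_payoff':>12} {'dist_density':>13} {'params':>7} {'cues':>5}")
for r in sorted(results, key=lambda r: r.dist_payoff):
    print(f"{r.model:>15} {r.dist_payoff:12.3f} {r.dist_density:13.4f} "
          f"{r.n_params:7d} {r.n_cues:5d}")

print("\nLower is better.  Models lacking the pay-off cue (blind, random)")
print("fall far behind on dist_payoff because they rarely find or hold good")
print("solutions; ttb, probabilistic and hill climbing all track the pay-off")
print("curve closely, so separating them also needs the density map, where")
print("only novelty-guided exploration reproduces the X-shaped pattern.")
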