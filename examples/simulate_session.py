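"""Simulate one two-step session and score it.

A hybrid agent (model-based weight w = 0.6) plays 300 trials: 150 with
drifting reward probabilities, then 150 with fixed ones.  Stay frequencies
are tabulated by the previous trial's reward and transition, and reduced to
the two learning scores.
"""

from twostep import AgentParams, TaskConfig, simulate_session, tabulate_stays
from twostep.metrics import learning_scores, total_coins

config = TaskConfig()
log = simulate_session(AgentParams(), config, seed=42)

for phase in ("drift", "stable"):
    table = tabulate_stays(log, phase)
    scores = learning_scores(table)
    pct = table.stay_pct
    print(f"{phase} phase ({table.n_total} stay observations):")
    for cell, value in pct.items():
        print(f"  stay after {cell.replace('_', ' '):<18}: {value:5.1f}%  (n={table.n_obs[cell]})")
    print(f"  model-free score : {scores.model_free:6.1f}")
    print(f"  model-based score: {scores.model_based:6.1f}")
    print(f"  coins won        : {total_coins(log, phase)}")
    print()

print(
    "The model-free score is the main effect of previous reward on staying;\n"
    "the model-based score is the reward-by-transition interaction.  Positive\n"
    "values of both mean the agent mixes habitual and planning strategies."
)
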