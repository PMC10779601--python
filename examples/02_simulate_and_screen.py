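"""Simulate a scenario with planted proximal modules and screen it.

Generates a 2,000-node preferential-attachment interactome, plants 5 of 25
modules inside the 1-hop neighbourhood of a 46-gene target set, then runs
the permutation screen and compares the flagged modules with the ground
truth.  Uses 1,000 permutations per module to keep the demo quick; real
screens default to 10,000.
"""

from endoprox import generate_graph, plant_scenario, screen_modules

SEED = 7

g = generate_graph(n_nodes=2000, m_attach=3, seed=SEED)
scenario = plant_scenario(g, seed=SEED)
print(
    f"graph: {g.n_nodes} nodes / {g.n_edges} edges; "
    f"{len(scenario.targets)} targets; {len(scenario.catalog)} modules "
    f"({len(scenario.planted)} planted proximal)"
)

table = screen_modules(
    g, scenario.targets, scenario.catalog, n_permutations=1000, seed=SEED
)
df = table.to_frame()
print("\nmost proximal modules (z ascending):")
print(df.head(8).to_string(index=False))

flagged = set(table.significant_modules)
print(f"\nflagged significant (z < -1.8 and p < 0.05): {sorted(flagged)}")
print(f"planted ground truth:                        {sorted(scenario.planted)}")
tp = len(flagged & scenario.planted)
fp = len(flagged & scenario.decoys)
print(
    f"-> {tp}/{len(scenario.planted)} planted modules recovered, "
    f"{fp} decoys wrongly flagged."
)
print(
    "A strongly negative z means the targets sit much closer to the module\n"
    "than degree-matched random sets do; p is the one-sided permutation "
    "p-value."
)
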