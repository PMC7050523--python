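"""Summarize a multi-condition screen as a matrix and a network.

Two drug concentrations share one target and each has a private one.
The logFC matrix (heatmap input) shows per-condition effect sizes; the
bipartite network's gene degrees show which hits generalize across
concentrations.
"""

from tnxpress.aggregate import build_matrix, build_network
from tnxpress.classify import classify_effects
from tnxpress.compare import RegionCountTable, compare_condition
from tnxpress.simlib import EffectSpec, SimConfig, apply_condition, simulate_library

control, genes, truth = simulate_library(SimConfig(seed=1))
noness = [g.gene_id for g in genes if not truth.essential[g.gene_id]]
shared, only_low, only_high = noness[0], noness[2], noness[4]
truth.add_condition("low", [EffectSpec(shared, "knockout_fitness", 6.0),
                            EffectSpec(only_low, "knockout_fitness", 8.0)])
truth.add_condition("high", [EffectSpec(shared, "knockout_fitness", 10.0),
                             EffectSpec(only_high, "knockout_fitness", 8.0)])

profiles = {"c1": apply_condition(control, truth, "control", seed=51),
            "c2": apply_condition(control, truth, "control", seed=52)}
records, calls = {}, {}
for cond, s in (("low", 60), ("high", 70)):
    profiles[f"{cond}_1"] = apply_condition(control, truth, cond, seed=s + 1)
    profiles[f"{cond}_2"] = apply_condition(control, truth, cond, seed=s + 2)
table = RegionCountTable.from_profiles(profiles, genes)
for cond in ("low", "high"):
    records[cond] = compare_condition(table, ["c1", "c2"], [f"{cond}_1", f"{cond}_2"])
    calls[cond] = classify_effects(records[cond], genes, condition=cond)

matrix = build_matrix(records)
print("gene x condition logFC matrix (0 = not significant):")
print(matrix.round(2).to_string())

network = build_network(calls)
degrees = {n: d for n, d in network.degree() if network.nodes[n]["kind"] == "gene"}
print("\ngene degrees in the gene-condition network:", degrees)
# the shared target has degree 2 (hit at both concentrations); private
# targets have degree 1
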