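"""Interpret significant signals as biological effects.

Three designed effects are planted: a knockout advantage (gene-body
enrichment), a promoter-driven up-regulation benefit (toward-gene
insertions in the upstream flank) and an antisense knockdown benefit
(antisense insertions in the downstream flank).  The classifier should
name each one correctly from orientation and region alone.
"""

from tnxpress.classify import classify_effects
from tnxpress.compare import RegionCountTable, compare_condition
from tnxpress.simlib import EffectSpec, SimConfig, apply_condition, simulate_library

control, genes, truth = simulate_library(SimConfig(seed=1))
noness = [g.gene_id for g in genes if not truth.essential[g.gene_id]]
designed = {
    noness[0]: "knockout_fitness",
    noness[2]: "upstream_promoter",
    noness[4]: "downstream_antisense",
}
truth.add_condition("drug", [EffectSpec(g, kind, 8.0) for g, kind in designed.items()])

profiles = {
    "c1": apply_condition(control, truth, "control", seed=31),
    "c2": apply_condition(control, truth, "control", seed=32),
    "d1": apply_condition(control, truth, "drug", seed=41),
    "d2": apply_condition(control, truth, "drug", seed=42),
}
table = RegionCountTable.from_profiles(profiles, genes)
records = compare_condition(table, ["c1", "c2"], ["d1", "d2"])
calls = classify_effects(records, genes, condition="drug")

for call in calls:
    rows = ", ".join(f"{s.region}/{s.channel} logFC={s.logFC:.2f}" for s in call.support)
    print(f"{call.gene_id}: {call.call}  [{rows}]  designed={designed.get(call.gene_id, '-')}")
# knockout -> inactivation_advantage; upstream_promoter ->
# increased_expression_advantage; downstream_antisense ->
# decreased_expression_advantage
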