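"""Simulate a saturating transposon library and inspect its coverage.

The simulator tiles a genome with genes, withholds insertion sites from
essential-gene interiors, and draws read counts per site from a negative
binomial.  Printed numbers: total unique insertion sites, the realized
site spacing (a saturating reference library has one site every ~6 bp),
and the number of essential genes with zero interior insertions.
"""

from tnxpress.simlib import SimConfig, simulate_library

config = SimConfig(seed=1)
control, genes, truth = simulate_library(config)

n_sites = int((control.combined() > 0).sum())
print(f"genome length: {config.genome_length:,} bp, genes: {len(genes)}")
print(f"unique insertion sites: {n_sites:,} (one every {config.genome_length / n_sites:.1f} bp)")
print(f"total reads: {control.total_reads:,}")

essential = truth.essential_gene_ids()
zero_interior = sum(
    1 for g in genes
    if g.gene_id in essential and control.combined()[g.start:g.end].sum() == 0
)
print(f"essential genes: {len(essential)}, with zero interior insertions: {zero_interior}")
# every essential gene is insertion-free by construction: that gap in the
# site distribution is the signal the essentiality caller exploits
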