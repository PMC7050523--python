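"""Cross-condition synthesis: gene x condition matrices and bipartite networks.

The per-condition comparison and classification results are combined into
two complementary views: a signed log2-fold-change matrix (the input of
the usual condition-response heatmap; zero where a gene is not significant
in a condition) and a bipartite gene-condition network whose edges record
which genes matter under which conditions.  Both outputs are deterministic
and stable under permutation of the inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from tnxpress.classify import EffectCall


def build_matrix(records_by_condition: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Gene x condition matrix of signed logFC; 0 where non-significant.

    Each cell holds the logFC of the significant gene-region-channel row
    with the largest |logFC| for that gene in that condition.  Rows cover
    the union of significant genes, ordered by number of conditions hit
    (descending) then gene name; columns are condition names, sorted.
    """
    conditions = list(records_by_condition)
    if len(set(conditions)) != len(conditions):
        raise ValueError("duplicate condition labels")
    if not conditions:
        raise ValueError("need at least one condition")

    cells: dict[str, dict[str, float]] = {}
    for cond in conditions:
        sig = records_by_condition[cond]
        sig = sig[sig["significant"]]
        for gene_id, rec in sig.groupby("gene_id"):
            best = rec.loc[rec["logFC"].abs().idxmax()]
            cells.setdefault(str(gene_id), {})[cond] = float(best["logFC"])

    cols = sorted(conditions)
    matrix = pd.DataFrame(0.0, index=sorted(cells), columns=cols)
    for gene_id, per_cond in cells.items():
        for cond, v in per_cond.items():
            matrix.loc[gene_id, cond] = v
    n_hits = (matrix != 0).sum(axis=1)
    order = sorted(matrix.index, key=lambda g: (-int(n_hits[g]), g))
    return matrix.loc[order]


def build_network(calls_by_condition: Mapping[str, Sequence[EffectCall]]) -> nx.Graph:
    """Bipartite gene-condition network from effect calls.

    One node per called gene (``kind='gene'``) and per condition
    (``kind='condition'``); one edge per (gene, condition) with at least
    one call, annotated with the calls made and the largest supporting
    |logFC|.
    """
    g = nx.Graph()
    for cond in sorted(calls_by_condition):
        g.add_node(cond, kind="condition", bipartite=1)
        per_gene: dict[str, list[EffectCall]] = {}
        for call in calls_by_condition[cond]:
            per_gene.setdefault(call.gene_id, []).append(call)
        for gene_id, calls in sorted(per_gene.items()):
            if gene_id not in g:
                g.add_node(gene_id, kind="gene", bipartite=0)
            max_lfc = max(
                (abs(s.logFC) for c in calls for s in c.support), default=0.0
            )
            g.add_edge(
                gene_id,
                cond,
                calls=";".join(sorted({c.call for c in calls})),
                max_abs_logfc=float(max_lfc),
            )
    return g


def write_network(graph: nx.Graph, graphml_path: str | Path, edges_path: str | Path) -> None:
    """Export the network as GraphML plus a tidy edge-list TSV."""
    nx.write_graphml(graph, str(graphml_path))
    rows = []
    for gene, cond, data in sorted(graph.edges(data=True)):
        if graph.nodes[gene].get("kind") == "condition":
            gene, cond = cond, gene
        rows.append(
            {
                "gene_id": gene,
                "condition": cond,
                "calls": data.get("calls", ""),
                "max_abs_logfc": data.get("max_abs_logfc", 0.0),
            }
        )
    pd.DataFrame(rows, columns=["gene_id", "condition", "calls", "max_abs_logfc"]).to_csv(
        edges_path, sep="\t", index=False
    )
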