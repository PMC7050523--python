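"""Translate significant gene-region-channel signals into biological effect calls.

Interpretation rules for a transposon carrying an outward-facing inducible
promoter:

1. Significant change of insertions in the **gene body** (combined
   channel): enrichment means mutants lacking the gene are selected
   (*inactivation_advantage*); depletion means loss of the gene carries a
   fitness cost under the condition (*inactivation_cost*).
2. Significant enrichment in the **upstream** flank restricted to the
   channel whose outward promoter transcribes *toward* the gene (forward
   for + genes, reverse for - genes), without a comparable increase in the
   opposite orientation: promoter-driven up-regulation of the gene is
   beneficial (*increased_expression_advantage*).
3. Significant enrichment in the **downstream** flank restricted to the
   channel transcribing *antisense* into the gene (reverse for + genes,
   forward for - genes): knockdown via an interfering antisense transcript
   is beneficial (*decreased_expression_advantage*).
4. Any remaining significant signal yields *unclassified*, with its
   supporting rows attached.

"Without a comparable increase" is operationalized as: the opposite
channel in the same region is non-significant, or its logFC is less than
half the signal channel's logFC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from tnxpress.formats import GeneModel

CALLS = (
    "inactivation_advantage",
    "inactivation_cost",
    "increased_expression_advantage",
    "decreased_expression_advantage",
    "unclassified",
)


@dataclass(frozen=True)
class SupportRow:
    region: str
    channel: str
    logFC: float
    q_value: float


@dataclass(frozen=True)
class EffectCall:
    gene_id: str
    condition: str
    call: str
    support: tuple[SupportRow, ...] = field(default_factory=tuple)

    def key(self) -> tuple[str, str, str]:
        return (self.gene_id, self.condition, self.call)


def _toward_channel(strand: str) -> str:
    """Channel whose outward promoter points into the gene from upstream."""
    return "forward" if strand == "+" else "reverse"


def _antisense_channel(strand: str) -> str:
    """Channel transcribing against the gene's sense from downstream."""
    return "reverse" if strand == "+" else "forward"


def _row(records: pd.DataFrame, region: str, channel: str) -> pd.Series | None:
    sel = records[(records["region"] == region) & (records["channel"] == channel)]
    if sel.empty:
        return None
    return sel.iloc[0]


def _support(row: pd.Series) -> SupportRow:
    return SupportRow(
        region=str(row["region"]),
        channel=str(row["channel"]),
        logFC=float(row["logFC"]),
        q_value=float(row["q_value"]),
    )


def classify_effects(
    records: pd.DataFrame,
    genes: Sequence[GeneModel],
    condition: str = "condition",
) -> list[EffectCall]:
    """Apply the orientation rules to one condition's comparison records.

    ``records`` is the output of :func:`tnxpress.compare.compare_condition`.
    A gene may carry several calls in one condition (e.g. inactivation and
    up-regulation signals at once); every call is backed by at least one
    significant row, so stripping all significance flags yields no calls.
    """
    by_id = {g.gene_id: g for g in genes}
    unknown = set(records["gene_id"]) - set(by_id)
    if unknown:
        raise ValueError(f"records reference unknown genes: {sorted(unknown)[:5]}")

    calls: list[EffectCall] = []
    sig = records[records["significant"]]
    for gene_id, rec in sig.groupby("gene_id", sort=True):
        gene = by_id[str(gene_id)]
        gene_records = records[records["gene_id"] == gene_id]
        used_idx: set[int] = set()
        gene_calls: list[EffectCall] = []

        body = _row(rec, "gene", "combined")
        if body is not None:
            call = "inactivation_advantage" if body["logFC"] > 0 else "inactivation_cost"
            gene_calls.append(EffectCall(str(gene_id), condition, call, (_support(body),)))
            used_idx.update(
                rec[(rec["region"] == "gene")].index
            )

        up = _row(rec, "upstream", _toward_channel(gene.strand))
        if up is not None and up["logFC"] > 0:
            # opposite upstream channel = the one pointing away from the gene
            opp_channel = "reverse" if gene.strand == "+" else "forward"
            opposite = _row(gene_records, "upstream", opp_channel)
            mirrored = (
                opposite is not None
                and bool(opposite["significant"])
                and float(opposite["logFC"]) >= float(up["logFC"]) / 2.0
            )
            if not mirrored:
                gene_calls.append(
                    EffectCall(str(gene_id), condition, "increased_expression_advantage", (_support(up),))
                )
                used_idx.add(int(up.name))

        down = _row(rec, "downstream", _antisense_channel(gene.strand))
        if down is not None and down["logFC"] > 0:
            gene_calls.append(
                EffectCall(str(gene_id), condition, "decreased_expression_advantage", (_support(down),))
            )
            used_idx.add(int(down.name))

        leftover = rec.loc[[i for i in rec.index if i not in used_idx]]
        # combined-channel flank rows merely restate their oriented parts
        leftover = leftover[
            ~((leftover["region"].isin(["upstream", "downstream"])) & (leftover["channel"] == "combined"))
        ]
        if not gene_calls and not leftover.empty:
            gene_calls.append(
                EffectCall(
                    str(gene_id),
                    condition,
                    "unclassified",
                    tuple(_support(r) for _, r in leftover.iterrows()),
                )
            )
        calls.extend(gene_calls)
    return calls


def calls_to_frame(calls: Sequence[EffectCall]) -> pd.DataFrame:
    """Flatten effect calls to a tidy table (one row per supporting record)."""
    rows = []
    for c in calls:
        for s in c.support:
            rows.append(
                {
                    "gene_id": c.gene_id,
                    "condition": c.condition,
                    "call": c.call,
                    "region": s.region,
                    "channel": s.channel,
                    "logFC": s.logFC,
                    "q_value": s.q_value,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "condition", "call", "region", "channel", "logFC", "q_value"])


@dataclass(frozen=True)
class InductionGain:
    """Target yield with versus without induction of the outward promoter."""

    n_induced: int
    n_uninduced: int
    pct_gain: float | None  # None when undefined (no uninduced targets)
    gained: frozenset[str]
    lost: frozenset[str]

    @property
    def undefined(self) -> bool:
        return self.pct_gain is None


def induction_gain(targets_induced: set[str], targets_uninduced: set[str]) -> InductionGain:
    """Percentage gain in identified targets when the outward promoter is induced.

    pct_gain = 100 * (|induced| - |uninduced|) / |uninduced|; undefined
    (flagged, no division) when the uninduced set is empty.
    """
    n_i, n_u = len(targets_induced), len(targets_uninduced)
    pct = None if n_u == 0 else 100.0 * (n_i - n_u) / n_u
    return InductionGain(
        n_induced=n_i,
        n_uninduced=n_u,
        pct_gain=pct,
        gained=frozenset(targets_induced - targets_uninduced),
        lost=frozenset(targets_uninduced - targets_induced),
    )
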