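"""Effect-call rules: orientation logic, recovery on designed effects, induction gain."""

from __future__ import annotations

import pandas as pd
import pytest

from tnxpress.classify import classify_effects, induction_gain
from tnxpress.formats import GeneModel

CONTRADICTIONS = {
    "inactivation_advantage": {"inactivation_cost"},
    "inactivation_cost": {"inactivation_advantage"},
    "increased_expression_advantage": {"decreased_expression_advantage"},
    "decreased_expression_advantage": {"increased_expression_advantage"},
}


def record_frame(rows):
    """Build a comparison-record frame; unspecified cells default to a null row."""
    full = []
    for row in rows:
        base = dict(
            logFC=0.0, logCPM=10.0, p_value=1.0, q_value=1.0,
            significant=False, direction="enriched", ctrl_reads=100, cond_reads=100,
        )
        base.update(row)
        full.append(base)
    return pd.DataFrame(full)


PLUS = GeneModel("gA", "gA", 1000, 2000, "+")
MINUS = GeneModel("gB", "gB", 4000, 5000, "-")


class TestRules:
    def test_upstream_toward_enrichment_calls_increased_expression(self):
        """Upstream/forward enrichment of a + gene, with the away channel
        quiet, signals promoter-driven up-regulation."""
        rec = record_frame(
            [
                dict(gene_id="gA", region="upstream", channel="forward",
                     logFC=4.0, q_value=0.001, significant=True),
                dict(gene_id="gA", region="upstream", channel="reverse"),
            ]
        )
        calls = classify_effects(rec, [PLUS])
        assert [c.call for c in calls] == ["increased_expression_advantage"]
        assert calls[0].support[0].region == "upstream"

    def test_minus_strand_downstream_forward_is_antisense_knockdown(self):
        """For a - gene the downstream flank is leftward; forward-channel
        enrichment there transcribes antisense into the gene."""
        rec = record_frame(
            [
                dict(gene_id="gB", region="downstream", channel="forward",
                     logFC=3.0, q_value=0.01, significant=True),
            ]
        )
        calls = classify_effects(rec, [MINUS])
        assert [c.call for c in calls] == ["decreased_expression_advantage"]

    def test_gene_body_enrichment_and_depletion(self):
        rec = record_frame(
            [
                dict(gene_id="gA", region="gene", channel="combined",
                     logFC=2.5, q_value=0.001, significant=True),
                dict(gene_id="gB", region="gene", channel="combined",
                     logFC=-2.5, q_value=0.001, significant=True, direction="depleted"),
            ]
        )
        calls = classify_effects(rec, [PLUS, MINUS])
        by_gene = {c.gene_id: c.call for c in calls}
        assert by_gene == {"gA": "inactivation_advantage", "gB": "inactivation_cost"}

    def test_mirrored_upstream_enrichment_is_not_expression_call(self):
        """Comparable enrichment in both upstream orientations is not a
        preferential promoter effect; it falls through to unclassified."""
        rec = record_frame(
            [
                dict(gene_id="gA", region="upstream", channel="forward",
                     logFC=3.0, q_value=0.001, significant=True),
                dict(gene_id="gA", region="upstream", channel="reverse",
                     logFC=2.9, q_value=0.001, significant=True),
            ]
        )
        calls = classify_effects(rec, [PLUS])
        assert {c.call for c in calls} == {"unclassified"}

    def test_no_significant_rows_yields_no_calls(self):
        rec = record_frame(
            [dict(gene_id="gA", region="gene", channel="combined", logFC=5.0)]
        )
        assert classify_effects(rec, [PLUS]) == []

    def test_unknown_gene_rejected(self):
        rec = record_frame(
            [dict(gene_id="ghost", region="gene", channel="combined", significant=True)]
        )
        with pytest.raises(ValueError, match="unknown genes"):
            classify_effects(rec, [PLUS])

    def test_every_call_backed_by_significant_support(self, screen, treated_calls):
        sig = screen.records_treated[screen.records_treated["significant"]]
        sig_keys = set(zip(sig["gene_id"], sig["region"], sig["channel"]))
        for call in treated_calls:
            assert call.support
            for s in call.support:
                assert (call.gene_id, s.region, s.channel) in sig_keys


class TestRecoveryOnDesignedEffects:
    def test_designed_effects_recovered_without_contradictions(self, screen, treated_calls):
        want = (
            {g: "inactivation_advantage" for g in screen.ko_genes}
            | {g: "increased_expression_advantage" for g in screen.up_genes}
            | {g: "decreased_expression_advantage" for g in screen.down_genes}
        )
        got: dict[str, set[str]] = {}
        for c in treated_calls:
            got.setdefault(c.gene_id, set()).add(c.call)
        recovered = sum(1 for g, w in want.items() if w in got.get(g, set()))
        assert recovered >= 0.9 * len(want)
        for g, w in want.items():
            assert not (got.get(g, set()) & CONTRADICTIONS[w]), f"contradictory call on {g}"

    def test_null_condition_produces_few_spurious_calls(self, screen, null_calls):
        called = {c.gene_id for c in null_calls}
        assert len(called) / len(screen.genes) <= 0.05

    def test_strand_equivariance_under_genome_mirroring(self, screen, treated_calls):
        """Reverse-complementing the genome (flip coordinates, swap strands
        and channels) must leave every effect call invariant."""
        from tnxpress.compare import RegionCountTable, compare_condition
        from tnxpress.simlib import apply_condition

        L = screen.config.genome_length
        genes_m = [g.mirror(L) for g in screen.genes]
        originals = {
            "control_1": apply_condition(screen.control, screen.truth, "control", seed=101),
            "control_2": apply_condition(screen.control, screen.truth, "control", seed=102),
            "treated_1": apply_condition(screen.control, screen.truth, "treated", seed=201),
            "treated_2": apply_condition(screen.control, screen.truth, "treated", seed=202),
        }
        mirrored = {name: p.mirror() for name, p in originals.items()}

        table_o = RegionCountTable.from_profiles(originals, screen.genes)
        table_m = RegionCountTable.from_profiles(mirrored, genes_m)
        rec_o = compare_condition(table_o, ["control_1", "control_2"], ["treated_1", "treated_2"])
        rec_m = compare_condition(table_m, ["control_1", "control_2"], ["treated_1", "treated_2"])
        calls_o = {c.key() for c in classify_effects(rec_o, screen.genes, condition="t")}
        calls_m = {c.key() for c in classify_effects(rec_m, genes_m, condition="t")}
        assert calls_o == calls_m


class TestInductionGain:
    def test_percentage_gain_arithmetic(self):
        gain = induction_gain({f"g{i}" for i in range(121)}, {f"g{i}" for i in range(100)})
        assert gain.pct_gain == pytest.approx(21.0)
        assert gain.n_induced == 121 and gain.n_uninduced == 100
        assert len(gain.gained) == 21 and not gain.lost

    def test_identical_sets_give_zero_gain(self):
        s = {"a", "b"}
        assert induction_gain(s, s).pct_gain == 0.0

    def test_empty_uninduced_set_is_undefined(self):
        gain = induction_gain({"a"}, set())
        assert gain.undefined and gain.pct_gain is None
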