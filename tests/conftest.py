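"""Shared fixtures: one seeded synthetic screen reused across the suite."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from tnxpress.classify import classify_effects
from tnxpress.compare import RegionCountTable, compare_condition
from tnxpress.simlib import EffectSpec, SimConfig, apply_condition, simulate_library

N_EFFECT_GENES = 10  # per effect kind
EFFECT_MULTIPLIER = 8.0


@dataclass
class Screen:
    """A complete simulated screen with ground truth and analysis results."""

    config: SimConfig
    control: object
    genes: list
    truth: object
    table: RegionCountTable
    records_treated: object
    records_null: object
    ko_genes: list[str]
    up_genes: list[str]
    down_genes: list[str]


@pytest.fixture(scope="session")
def screen() -> Screen:
    """300-gene library (30 essential, site density 1/6, mean 10 reads/site)
    with duplicate cultures for control, a designed-effect condition
    (10 knockouts, 10 upstream-promoter, 10 downstream-antisense targets,
    all at multiplier 8) and a null condition."""
    config = SimConfig(seed=1)
    control, genes, truth = simulate_library(config)
    noness = [g.gene_id for g in genes if not truth.essential[g.gene_id]]
    ko = noness[:N_EFFECT_GENES]
    up = noness[N_EFFECT_GENES : 2 * N_EFFECT_GENES]
    down = noness[2 * N_EFFECT_GENES : 3 * N_EFFECT_GENES]
    effects = (
        [EffectSpec(g, "knockout_fitness", EFFECT_MULTIPLIER) for g in ko]
        + [EffectSpec(g, "upstream_promoter", EFFECT_MULTIPLIER) for g in up]
        + [EffectSpec(g, "downstream_antisense", EFFECT_MULTIPLIER) for g in down]
    )
    truth.add_condition("treated", effects)
    truth.add_condition("null", [])

    profiles = {f"control_{i}": apply_condition(control, truth, "control", seed=100 + i) for i in (1, 2)}
    profiles.update(
        {f"treated_{i}": apply_condition(control, truth, "treated", seed=200 + i) for i in (1, 2)}
    )
    profiles.update(
        {f"null_{i}": apply_condition(control, truth, "null", seed=300 + i) for i in (1, 2)}
    )
    table = RegionCountTable.from_profiles(profiles, genes)
    controls = ["control_1", "control_2"]
    records_treated = compare_condition(table, controls, ["treated_1", "treated_2"])
    records_null = compare_condition(table, controls, ["null_1", "null_2"])
    return Screen(
        config=config,
        control=control,
        genes=genes,
        truth=truth,
        table=table,
        records_treated=records_treated,
        records_null=records_null,
        ko_genes=ko,
        up_genes=up,
        down_genes=down,
    )


@pytest.fixture(scope="session")
def treated_calls(screen):
    return classify_effects(screen.records_treated, screen.genes, condition="treated")


@pytest.fixture(scope="session")
def null_calls(screen):
    return classify_effects(screen.records_null, screen.genes, condition="null")
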