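"""End-to-end pipeline wiring with a single configuration object.

Runs the stages in dependency order — annotation + profiles in,
essentiality on the control library, per-condition comparison,
effect classification, cross-condition aggregation — and writes every
result as TSV (plus GraphML for the network).  Outputs are staged in a
temporary directory and moved into place only on success, so a failed run
leaves no partial results; every table carries a header comment with the
package version, a hash of the configuration, and the seed.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

import tnxpress
from tnxpress.aggregate import build_matrix, build_network, write_network
from tnxpress.classify import calls_to_frame, classify_effects
from tnxpress.compare import Cutoffs, RegionCountTable, compare_condition
from tnxpress.essentiality import call_essentiality
from tnxpress.formats import read_annotation, read_plot


@dataclass
class RunConfig:
    """All tunables of one pipeline run; round-trips losslessly through YAML."""

    window: int = 198
    q_cut: float = 0.05
    logfc_cut: float = 1.0
    logcpm_cut: float = 8.0
    prior: float = 0.5
    dispersion: float | None = None  # None: estimate from replicates
    log_odds_cut: float = 2.0
    min_mapq: int = 10
    seed: int = 0
    outdir: str = "tnxpress_out"

    def __post_init__(self) -> None:
        if self.window <= 0 or self.q_cut <= 0 or self.logfc_cut <= 0:
            raise ValueError("window and cut-offs must be positive")

    def cutoffs(self) -> Cutoffs:
        return Cutoffs(q=self.q_cut, logfc=self.logfc_cut, logcpm=self.logcpm_cut)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        params = asdict(self)
        params.pop("outdir")  # where results land does not change what they are
        return hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class InputManifest:
    """File inputs of one run: GFF3 annotation, control plots, condition plots."""

    gff: Path
    controls: list[Path]
    conditions: dict[str, list[Path]] = field(default_factory=dict)

    def validate(self) -> None:
        missing = [
            p
            for p in [self.gff, *self.controls, *(q for ps in self.conditions.values() for q in ps)]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {[str(m) for m in missing]}")
        if not self.controls:
            raise ValueError("need at least one control plot")


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# tnxpress {tnxpress.__version__} config={config.digest()} seed={config.seed}\n"
        )
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig, inputs: InputManifest) -> dict[str, Path]:
    """Run all stages; returns the output manifest (name -> final path)."""
    inputs.validate()
    genes = read_annotation(inputs.gff)
    control_profiles = {f"control_{i}": read_plot(p) for i, p in enumerate(inputs.controls, 1)}
    condition_profiles = {
        cond: {f"{cond}_{i}": read_plot(p) for i, p in enumerate(paths, 1)}
        for cond, paths in inputs.conditions.items()
    }

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".tnxpress_staging_", dir=outdir))
    outputs: dict[str, Path] = {}
    try:
        # essentiality on the pooled control library
        first_control = next(iter(control_profiles.values()))
        calls, fit = call_essentiality(first_control, genes, log_odds_cut=config.log_odds_cut)
        ess = pd.DataFrame(
            {
                "gene_id": [c.gene_id for c in calls],
                "length": [g.length for g in genes],
                "unique_sites": [round(c.insertion_index * g.length) for c, g in zip(calls, genes)],
                "insertion_index": [c.insertion_index for c in calls],
                "log_odds": [c.log_odds for c in calls],
                "class": [c.classification for c in calls],
            }
        )
        _write_tsv(ess, staging / "essentiality.tsv", config)
        outputs["essentiality"] = outdir / "essentiality.tsv"

        records_by_condition: dict[str, pd.DataFrame] = {}
        calls_by_condition: dict[str, list] = {}
        for cond, profiles in condition_profiles.items():
            table = RegionCountTable.from_profiles(
                {**control_profiles, **profiles}, genes, window=config.window
            )
            rec = compare_condition(
                table,
                list(control_profiles),
                list(profiles),
                cutoffs=config.cutoffs(),
                prior=config.prior,
                dispersion=config.dispersion,
            )
            records_by_condition[cond] = rec
            _write_tsv(rec, staging / f"compare_{cond}.tsv", config)
            outputs[f"compare_{cond}"] = outdir / f"compare_{cond}.tsv"

            cond_calls = classify_effects(rec, genes, condition=cond)
            calls_by_condition[cond] = cond_calls
            _write_tsv(calls_to_frame(cond_calls), staging / f"effects_{cond}.tsv", config)
            outputs[f"effects_{cond}"] = outdir / f"effects_{cond}.tsv"

        if records_by_condition:
            matrix = build_matrix(records_by_condition)
            _write_tsv(matrix, staging / "logfc_matrix.tsv", config, index=True)
            outputs["logfc_matrix"] = outdir / "logfc_matrix.tsv"

            network = build_network(calls_by_condition)
            write_network(network, staging / "network.graphml", staging / "network_edges.tsv")
            outputs["network_graphml"] = outdir / "network.graphml"
            outputs["network_edges"] = outdir / "network_edges.tsv"

        for name, final in outputs.items():
            shutil.move(str(staging / final.name), str(final))
    finally:
        shutil.rmtree(staging, ignore_errors=True)
    return outputs
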