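"""Synthetic transposon-library simulator with known ground truth.

Emulates a saturating transposon mutant pool grown under control and
treatment conditions, so every downstream stage (essentiality calling,
differential insertion testing, effect classification) can be validated
against a known answer:

* a multi-kb genome tiled with non-overlapping genes;
* unique insertion sites scattered at a target density (the reference
  scale for a saturating library is about one site every 6 bp), each with
  a fair-coin promoter orientation;
* essential genes whose interiors host **no** insertion sites;
* per-condition effects that scale expected read counts of specific
  region x channel combinations: whole-gene fitness effects of knockouts,
  promoter-driven effects restricted to toward-gene-oriented sites in the
  upstream flank, and antisense-knockdown effects restricted to
  antisense-oriented sites in the downstream flank.

The library (site positions and orientations) is fixed once at creation
and shared by all conditions — the biological pool is a single library
split across growth conditions — only read abundances are re-drawn.

Negative-binomial parameterization used throughout the package: mean mu
and dispersion phi with variance mu + phi * mu**2; phi = 0 is Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from tnxpress.formats import GeneModel, InsertionProfile, write_annotation, write_plot

EFFECT_KINDS = ("knockout_fitness", "upstream_promoter", "downstream_antisense")

#: Width (bp) of the flanking windows, shared with the analysis side so
#: that recovery tests are exact.
DEFAULT_WINDOW = 198


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic library.

    site_density is the probability that a permissive base hosts a unique
    insertion site (reference scale 1/6 per bp for a saturating library);
    mean_reads_per_site and read_dispersion set the NB read-count model.

    Default geometry tiles 300 genes of 300 bp with 400 bp intergenic
    gaps, so the 198 bp flanking windows of neighbouring genes are
    pairwise disjoint and never reach into a neighbour's body — designed
    flank effects then map one-to-one onto analysis windows.
    """

    genome_length: int = 210_000
    n_genes: int = 300
    gene_length: int = 300
    essential_fraction: float = 0.1
    site_density: float = 1.0 / 6.0
    mean_reads_per_site: float = 10.0
    read_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.essential_fraction <= 1:
            raise ValueError("essential_fraction must be in [0, 1]")
        if self.site_density <= 0 or self.mean_reads_per_site <= 0:
            raise ValueError("site_density and mean_reads_per_site must be > 0")
        if self.read_dispersion < 0:
            raise ValueError("read_dispersion must be >= 0")
        if self.n_genes * self.gene_length > self.genome_length:
            raise ValueError(
                f"cannot place {self.n_genes} non-overlapping genes of {self.gene_length} bp "
                f"in a {self.genome_length} bp genome"
            )


@dataclass(frozen=True)
class EffectSpec:
    """One designed condition-dependent effect on one gene.

    ``multiplier`` scales the expected read count of the affected
    positions/channel in the treated condition; which region x channel is
    affected follows from ``effect_kind``.
    """

    gene_id: str
    effect_kind: str
    multiplier: float

    def __post_init__(self) -> None:
        if self.effect_kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect_kind {self.effect_kind!r}")
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of a simulated library: essentiality, designed effects, and the site registry."""

    config: SimConfig
    genes: list[GeneModel]
    essential: dict[str, bool]
    conditions: dict[str, list[EffectSpec]] = field(default_factory=dict)
    window: int = DEFAULT_WINDOW

    def add_condition(self, name: str, effects: Sequence[EffectSpec] = ()) -> None:
        if name in self.conditions:
            raise ValueError(f"condition {name!r} already defined")
        unknown = {e.gene_id for e in effects} - {g.gene_id for g in self.genes}
        if unknown:
            raise ValueError(f"effects reference unknown genes: {sorted(unknown)}")
        self.conditions[name] = list(effects)

    def essential_gene_ids(self) -> set[str]:
        return {g for g, flag in self.essential.items() if flag}


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, phi: float, truncate: bool) -> np.ndarray:
    """Draw NB(mean, phi) counts; optionally zero-truncated via inverse CDF."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    mu = mean[pos]
    if phi == 0:
        dist = stats.poisson(mu)
    else:
        r = 1.0 / phi
        dist = stats.nbinom(r, r / (r + mu))
    if truncate:
        p0 = dist.cdf(0)
        u = rng.uniform(p0, 1.0)
        out[pos] = np.maximum(1, dist.ppf(u).astype(np.int64))
    else:
        if phi == 0:
            out[pos] = rng.poisson(mu)
        else:
            r = 1.0 / phi
            out[pos] = rng.negative_binomial(r, r / (r + mu))
    return out


def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Tile genes evenly along the genome with random strands."""
    unit = config.genome_length // config.n_genes
    gap = unit - config.gene_length
    if gap < 0:
        raise ValueError("gene_length exceeds per-gene spacing")
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)
    width = len(str(config.n_genes))
    genes = []
    for i in range(config.n_genes):
        start = i * unit + gap // 2
        genes.append(
            GeneModel(
                gene_id=f"g{i:0{width}d}",
                name=f"g{i:0{width}d}",
                start=start,
                end=start + config.gene_length,
                strand=str(strands[i]),
                replicon_id="sim",
            )
        )
    return genes


def simulate_library(config: SimConfig) -> tuple[InsertionProfile, list[GeneModel], SimTruth]:
    """Create a synthetic library: control profile, annotation, and ground truth.

    Every base outside an essential-gene interior hosts a unique insertion
    site with probability ``site_density``; each site gets a fair-coin
    orientation and a zero-truncated NB read count (so every site of the
    library is visible in the control profile).  Deterministic for a fixed
    ``config.seed``.  The returned truth carries a pre-registered
    ``control`` condition with no effects, usable for drawing control
    replicates with :func:`apply_condition`.
    """
    rng = np.random.default_rng(config.seed)
    genes = _place_genes(config, rng)

    n_ess = round(config.essential_fraction * config.n_genes)
    ess_idx = rng.choice(config.n_genes, size=n_ess, replace=False)
    essential = {g.gene_id: False for g in genes}
    for i in ess_idx:
        essential[genes[i].gene_id] = True

    permissive = np.ones(config.genome_length, dtype=bool)
    for g in genes:
        if essential[g.gene_id]:
            permissive[g.start : g.end] = False

    is_site = permissive & (rng.random(config.genome_length) < min(1.0, config.site_density))
    site_fwd = rng.random(config.genome_length) < 0.5

    mean = np.where(is_site, config.mean_reads_per_site, 0.0)
    counts = _draw_nb(rng, mean, config.read_dispersion, truncate=True)
    fwd = np.where(is_site & site_fwd, counts, 0)
    rev = np.where(is_site & ~site_fwd, counts, 0)

    control = InsertionProfile(replicon_id="sim", reads_fwd=fwd, reads_rev=rev)
    truth = SimTruth(config=config, genes=genes, essential=essential)
    truth.add_condition("control")
    return control, genes, truth


def _effect_mean_arrays(
    control: InsertionProfile, truth: SimTruth, effects: Sequence[EffectSpec]
) -> tuple[np.ndarray, np.ndarray]:
    """Expected per-base read counts (fwd, rev) after applying the designed effects."""
    cfg = truth.config
    L = control.length
    mean_fwd = np.where(control.reads_fwd > 0, cfg.mean_reads_per_site, 0.0)
    mean_rev = np.where(control.reads_rev > 0, cfg.mean_reads_per_site, 0.0)
    by_id = {g.gene_id: g for g in truth.genes}
    w = truth.window
    for eff in effects:
        g = by_id[eff.gene_id]
        if eff.effect_kind == "knockout_fitness":
            sl = slice(g.start, g.end)
            mean_fwd[sl] *= eff.multiplier
            mean_rev[sl] *= eff.multiplier
        elif eff.effect_kind == "upstream_promoter":
            # only sites whose outward promoter points toward the gene
            if g.strand == "+":
                sl = slice(max(0, g.start - w), g.start)
                mean_fwd[sl] *= eff.multiplier
            else:
                sl = slice(g.end, min(L, g.end + w))
                mean_rev[sl] *= eff.multiplier
        else:  # downstream_antisense: promoter transcribes against the gene's sense
            if g.strand == "+":
                sl = slice(g.end, min(L, g.end + w))
                mean_rev[sl] *= eff.multiplier
            else:
                sl = slice(max(0, g.start - w), g.start)
                mean_fwd[sl] *= eff.multiplier
    return mean_fwd, mean_rev


def apply_condition(
    control: InsertionProfile, truth: SimTruth, condition: str, seed: int
) -> InsertionProfile:
    """Draw one treated (or control-replicate) profile from the library.

    Expected read counts at each site of the fixed library are scaled
    according to the condition's designed effects, then all site counts are
    re-drawn NB (not truncated: selection can drive a site to zero reads).
    Untouched sites are re-drawn with unchanged mean, modelling independent
    sequencing of a separately grown culture.
    """
    if condition not in truth.conditions:
        raise KeyError(f"unknown condition {condition!r}; known: {sorted(truth.conditions)}")
    rng = np.random.default_rng(seed)
    mean_fwd, mean_rev = _effect_mean_arrays(control, truth, truth.conditions[condition])
    phi = truth.config.read_dispersion
    fwd = _draw_nb(rng, mean_fwd, phi, truncate=False)
    rev = _draw_nb(rng, mean_rev, phi, truncate=False)
    return InsertionProfile(replicon_id=control.replicon_id, reads_fwd=fwd, reads_rev=rev)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Write ground truth as a tidy TSV: gene_id, essential, condition, effect_kind, multiplier."""
    rows = ["gene_id\tessential\tcondition\teffect_kind\tmultiplier"]
    effects_by_gene: dict[str, list[tuple[str, EffectSpec]]] = {}
    for cond, effects in truth.conditions.items():
        for eff in effects:
            effects_by_gene.setdefault(eff.gene_id, []).append((cond, eff))
    for g in truth.genes:
        ess = int(truth.essential[g.gene_id])
        entries = effects_by_gene.get(g.gene_id)
        if entries:
            for cond, eff in entries:
                rows.append(f"{g.gene_id}\t{ess}\t{cond}\t{eff.effect_kind}\t{eff.multiplier}")
        else:
            rows.append(f"{g.gene_id}\t{ess}\t\t\t")
    Path(path).write_text("\n".join(rows) + "\n")


def simulate_to_dir(
    config: SimConfig,
    conditions: Mapping[str, Sequence[EffectSpec]],
    n_replicates: int,
    outdir: str | Path,
) -> dict[str, list[Path]]:
    """Simulate a full experiment and write plots, GFF3 annotation and truth TSV.

    Writes ``control_rep<i>.plot`` and ``<condition>_rep<i>.plot`` for each
    condition, plus ``annotation.gff3``, ``library.plot`` (the underlying
    library) and ``truth.tsv``.  Returns the plot paths per condition.
    Replicate seeds are derived deterministically from ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    control, genes, truth = simulate_library(config)
    for name, effects in conditions.items():
        truth.add_condition(name, effects)

    write_plot(control, outdir / "library.plot")
    write_annotation(genes, outdir / "annotation.gff3", genome_length=config.genome_length)
    write_truth(truth, outdir / "truth.tsv")

    seed_seq = np.random.SeedSequence(config.seed)
    all_conditions = ["control"] + [c for c in conditions if c != "control"]
    child_seeds = seed_seq.spawn(len(all_conditions) * n_replicates)
    manifest: dict[str, list[Path]] = {}
    k = 0
    for name in all_conditions:
        paths = []
        for rep in range(1, n_replicates + 1):
            seed = int(child_seeds[k].generate_state(1)[0] % (2**31))
            k += 1
            prof = apply_condition(control, truth, name, seed=seed)
            p = outdir / f"{name}_rep{rep}.plot"
            write_plot(prof, p)
            paths.append(p)
        manifest[name] = paths
    return manifest
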