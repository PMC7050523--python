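"""Orientation-aware differential insertion analysis between conditions.

For every gene, reads are counted in nine cells — three regions (the gene
body and fixed-width flanking windows upstream and downstream of it,
default 198 bp, strand-aware and clamped at replicon ends) times three
orientation channels (forward, reverse, combined).  Read counts per cell
are compared between condition and control with an exact test that models
counts as negative binomial and conditions on the cell's total, in the
spirit of edgeR's exact test for two-group count data, followed by
Benjamini-Hochberg correction across all cells of one comparison and a
triple cut-off filter (default q <= 0.05, |logFC| >= 1, logCPM > 8).

Replicate handling: each sample's counts are scaled to the geometric-mean
library size, summed within group, and rounded; a group of n replicates is
then modelled as NB with mean n*mu and dispersion phi/n (the sum of n iid
NB(mu, phi) variables matched by moments).  This replaces edgeR's
quantile adjustment with a simpler, exactly reproducible scheme.

NB parameterization: mean mu, dispersion phi, variance mu + phi*mu**2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln, logsumexp

from tnxpress.formats import GeneModel, InsertionProfile

REGIONS = ("gene", "upstream", "downstream")
CHANNELS = ("forward", "reverse", "combined")

DEFAULT_WINDOW = 198
DEFAULT_PRIOR = 0.5
DEFAULT_DISPERSION = 0.1  # fallback when estimation is impossible

_TIE_REL_TOL = 1e-8  # splits with prob <= observed*(1+tol) count as extreme


@dataclass(frozen=True)
class Cutoffs:
    """Significance filter: BH q-value, absolute log2 fold change, log2 CPM abundance."""

    q: float = 0.05
    logfc: float = 1.0
    logcpm: float = 8.0


def _region_bounds(gene: GeneModel, length: int, window: int) -> dict[str, tuple[int, int]]:
    """Strand-aware region intervals, clamped to [0, length)."""
    left = (max(0, gene.start - window), gene.start)
    right = (gene.end, min(length, gene.end + window))
    if gene.strand == "+":
        upstream, downstream = left, right
    else:
        upstream, downstream = right, left
    return {"gene": (gene.start, gene.end), "upstream": upstream, "downstream": downstream}


def count_regions(
    profile: InsertionProfile, genes: Sequence[GeneModel], window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Count reads and unique sites per (gene, region, channel) for one sample.

    Returns a DataFrame indexed by (gene_id, region, channel) with columns
    ``reads`` and ``sites``.  The combined channel is the sum of forward
    and reverse in both columns (an insertion site is orientation-specific).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    L = profile.length
    cum = {}
    for channel, arr in (("forward", profile.reads_fwd), ("reverse", profile.reads_rev)):
        cum[channel, "reads"] = np.concatenate([[0], np.cumsum(arr)])
        cum[channel, "sites"] = np.concatenate([[0], np.cumsum(arr > 0)])

    idx, reads, sites = [], [], []
    for gene in genes:
        if gene.start < 0 or gene.end > L:
            raise ValueError(f"gene {gene.gene_id} outside profile bounds")
        bounds = _region_bounds(gene, L, window)
        for region in REGIONS:
            s, e = bounds[region]
            per_channel = {}
            for channel in ("forward", "reverse"):
                per_channel[channel] = (
                    int(cum[channel, "reads"][e] - cum[channel, "reads"][s]),
                    int(cum[channel, "sites"][e] - cum[channel, "sites"][s]),
                )
            for channel in CHANNELS:
                idx.append((gene.gene_id, region, channel))
                if channel == "combined":
                    reads.append(per_channel["forward"][0] + per_channel["reverse"][0])
                    sites.append(per_channel["forward"][1] + per_channel["reverse"][1])
                else:
                    reads.append(per_channel[channel][0])
                    sites.append(per_channel[channel][1])
    index = pd.MultiIndex.from_tuples(idx, names=["gene_id", "region", "channel"])
    return pd.DataFrame({"reads": reads, "sites": sites}, index=index)


@dataclass
class RegionCountTable:
    """Per-(gene, region, channel) counts across samples, plus library sizes.

    ``reads``/``sites`` are DataFrames indexed by (gene_id, region,
    channel) with one column per sample; ``library_sizes`` maps each
    sample to its total mapped reads.
    """

    reads: pd.DataFrame
    sites: pd.DataFrame
    library_sizes: dict[str, int]
    window: int = DEFAULT_WINDOW

    @classmethod
    def from_profiles(
        cls,
        profiles: Mapping[str, InsertionProfile],
        genes: Sequence[GeneModel],
        window: int = DEFAULT_WINDOW,
    ) -> "RegionCountTable":
        per_sample = {name: count_regions(p, genes, window) for name, p in profiles.items()}
        reads = pd.DataFrame({name: df["reads"] for name, df in per_sample.items()})
        sites = pd.DataFrame({name: df["sites"] for name, df in per_sample.items()})
        libs = {name: p.total_reads for name, p in profiles.items()}
        return cls(reads=reads, sites=sites, library_sizes=libs, window=window)

    @property
    def samples(self) -> list[str]:
        return list(self.reads.columns)


def log_cpm(read_count: float, library_size: int, prior: float = DEFAULT_PRIOR) -> float:
    """log2 counts-per-million with a prior count guarding log(0)."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return float(np.log2((read_count + prior) / (library_size + 2.0 * prior) * 1e6))


def _nb_logpmf(x: np.ndarray, mu: float, phi: float) -> np.ndarray:
    """log NB(x; mu, phi) with variance mu + phi*mu^2; phi = 0 is Poisson."""
    x = np.asarray(x, dtype=float)
    if mu <= 0:
        return np.where(x == 0, 0.0, -np.inf)
    if phi == 0:
        return x * np.log(mu) - mu - gammaln(x + 1)
    r = 1.0 / phi
    logp = np.log(r) - np.log(r + mu)
    log1mp = np.log(mu) - np.log(r + mu)
    return gammaln(x + r) - gammaln(r) - gammaln(x + 1) + r * logp + x * log1mp


def nb_exact_test(
    count_a: int, count_b: int, phi: float, n_a: int = 1, n_b: int = 1
) -> float:
    """Two-sided exact test for a difference between two NB counts.

    ``count_a`` and ``count_b`` are library-size-equalized group sums; a
    group of ``n`` replicates is modelled NB(n*mu, phi/n).  Conditioning on
    the total t = a + b, each split (x, t - x) has probability proportional
    to NB(x) * NB(t - x); the two-sided p-value sums the probabilities of
    all splits no more probable than the observed one (with a relative tie
    tolerance of 1e-8).  Always in (0, 1].
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    a, b = int(count_a), int(count_b)
    if a < 0 or b < 0:
        raise ValueError("counts must be >= 0")
    t = a + b
    if t == 0:
        return 1.0
    x = np.arange(t + 1)
    share_a = n_a / (n_a + n_b)
    log_probs = _nb_logpmf(x, t * share_a, phi / n_a) + _nb_logpmf(
        t - x, t * (1.0 - share_a), phi / n_b
    )
    log_probs -= logsumexp(log_probs)
    probs = np.exp(log_probs)
    p_obs = probs[a]
    p = float(probs[probs <= p_obs * (1.0 + _TIE_REL_TOL)].sum())
    return min(max(p, p_obs), 1.0)


def _equalized_counts(table: RegionCountTable, samples: Sequence[str]) -> pd.DataFrame:
    libs = np.array([table.library_sizes[s] for s in samples], dtype=float)
    if (libs <= 0).any():
        bad = [s for s in samples if table.library_sizes[s] <= 0]
        raise ValueError(f"zero library size for samples: {bad}")
    common = float(np.exp(np.mean(np.log(libs))))
    scaled = table.reads[list(samples)] * (common / libs)
    return scaled


def _group_conditional_loglik(counts: np.ndarray, phi: float) -> float:
    """Log-likelihood of within-group replicate splits given group totals.

    For n iid NB(mu, phi) replicates, the distribution of the counts given
    their total is free of mu (Dirichlet-multinomial-like), enabling a
    common-dispersion conditional ML estimate.  ``counts`` is rows x
    replicates; phi-independent terms are dropped.
    """
    r = 1.0 / phi
    n = counts.shape[1]
    z = counts.sum(axis=1)
    return float(
        (gammaln(counts + r).sum(axis=1) - n * gammaln(r) + gammaln(n * r) - gammaln(z + n * r)).sum()
    )


def estimate_dispersion(
    table: RegionCountTable,
    control_samples: Sequence[str],
    condition_samples: Sequence[str],
    default: float = DEFAULT_DISPERSION,
    boundary: float = 1e-4,
) -> float:
    """Common NB dispersion by conditional maximum likelihood on replicate splits.

    Library sizes are equalized first; rows with zero total are dropped.
    Groups with a single replicate carry no dispersion information; if no
    group has >= 2 replicates (or no usable rows remain), the configured
    default is returned with a warning.  An optimum at the Poisson
    boundary returns exactly 0.
    """
    group_counts = []
    for samples in (control_samples, condition_samples):
        if len(samples) < 2:
            continue
        scaled = np.rint(_equalized_counts(table, samples).to_numpy()).astype(np.int64)
        scaled = scaled[scaled.sum(axis=1) > 0]
        if scaled.size:
            group_counts.append(scaled)
    if not group_counts:
        warnings.warn(
            f"no replicated group with usable rows; falling back to dispersion {default}",
            stacklevel=2,
        )
        return default

    def neg_ll(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        return -sum(_group_conditional_loglik(c, phi) for c in group_counts)

    res = optimize.minimize_scalar(neg_ll, bounds=(np.log(1e-6), np.log(50.0)), method="bounded")
    phi = float(np.exp(res.x))
    if phi <= boundary:
        return 0.0
    return phi


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    # m*p/m can round one ulp below p; the step-up value never drops below p
    return np.maximum(q, p)


def compare_condition(
    table: RegionCountTable,
    control_samples: Sequence[str],
    condition_samples: Sequence[str],
    cutoffs: Cutoffs = Cutoffs(),
    prior: float = DEFAULT_PRIOR,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Exact-test comparison of one condition against control, row by row.

    Returns a DataFrame with one row per (gene_id, region, channel):
    equalized group read sums, log2 fold change (condition over control,
    prior-damped), mean log2 CPM over all samples, exact-test p-value, BH
    q-value over all rows jointly, the significance flag under the triple
    cut-off, and the direction (enriched/depleted) of significant rows.
    """
    control_samples = list(control_samples)
    condition_samples = list(condition_samples)
    if not control_samples or not condition_samples:
        raise ValueError("need at least one control and one condition sample")

    all_samples = control_samples + condition_samples
    scaled = _equalized_counts(table, all_samples)
    n_a, n_b = len(control_samples), len(condition_samples)
    n_eff = float(np.sqrt(n_a * n_b))
    ctrl_sum = np.rint(scaled[control_samples].sum(axis=1) * (n_eff / n_a)).astype(np.int64)
    cond_sum = np.rint(scaled[condition_samples].sum(axis=1) * (n_eff / n_b)).astype(np.int64)

    phi = (
        dispersion
        if dispersion is not None
        else estimate_dispersion(table, control_samples, condition_samples)
    )

    p_values = np.array(
        [
            nb_exact_test(int(a), int(b), phi, n_a=n_eff, n_b=n_eff)
            for a, b in zip(ctrl_sum, cond_sum)
        ]
    )
    logfc = np.log2((cond_sum + prior) / (ctrl_sum + prior))
    raw = table.reads[all_samples]
    cpm_per_sample = np.column_stack(
        [
            np.log2((raw[s] + prior) / (table.library_sizes[s] + 2 * prior) * 1e6)
            for s in all_samples
        ]
    )
    logcpm = cpm_per_sample.mean(axis=1)
    q_values = bh_adjust(p_values)
    significant = (q_values <= cutoffs.q) & (np.abs(logfc) >= cutoffs.logfc) & (logcpm > cutoffs.logcpm)

    out = pd.DataFrame(
        {
            "ctrl_reads": ctrl_sum,
            "cond_reads": cond_sum,
            "logFC": logfc,
            "logCPM": logcpm,
            "p_value": p_values,
            "q_value": q_values,
            "significant": significant,
            "direction": np.where(logfc > 0, "enriched", "depleted"),
        },
        index=table.reads.index,
    )
    return out.reset_index()
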