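# Methods

This note documents the models, conventions and numerical choices behind
tnxpress, and what the synthetic-data validation does and does not show.

## Data model and orientation convention

An insertion profile stores, per replicon base, two junction read counts:
the **forward** channel for insertions whose transposon-borne outward
promoter transcribes toward increasing coordinates, and **reverse** for
the opposite. When profiles are built from SAM records, mapping
orientation is the proxy for promoter orientation: a forward-mapped read's
junction is its leftmost aligned reference base, a reverse-mapped read's
its rightmost. This proxy is a declared convention — if a library
preparation inverts it, every "upstream promoter" call becomes a
"downstream antisense" call and vice versa, so the convention is fixed in
one place (`tnxpress.formats`) and tested for self-consistency (genome
mirroring leaves all calls invariant).

Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted only at the parsing boundary. Plot files follow
the Bio-TraDIS insert-site-plot dialect (one line per base, two integers),
so outputs remain loadable as genome-browser user plots. Read counts (not
deduplicated fragments) are modelled throughout; duplicate reads are not
collapsed. The default SAM mapping-quality cut-off is 10.

## Essentiality calling

The insertion index `ii = unique interior sites / gene length` is bimodal
over a saturating library. We model it as

    w · Exponential(λ)  +  (1 − w) · Gamma(k, θ),

fitted by EM with deterministic initialization (split at one fifth of the
mean index). Zero indices are floored at 1e-6 so both densities stay
finite; a floored zero still sits far into the essential mode.
Classification uses the log-odds
`ln[(1−w)·g(ii)] − ln[w·e(ii)]` with a symmetric cut (default 2, about
e²:1 odds): below −2 essential, above +2 non-essential, otherwise
ambiguous. Genes shorter than 100 bp are excluded from fitting (their
indices are too noisy) but still classified. The mixture's functional
forms are this package's own reproducible realization of the
bimodal-threshold approach used by established insertion-sequencing
essentiality callers, which do not publish a closed recipe; it is
validated by parameter recovery on simulated mixtures and by
recall/precision on the simulator's ground truth, not against any
third-party tool's output.

EM convergence is declared at a relative log-likelihood change below
1e-8 (max 500 iterations; non-convergence is an error, not a silent
result). An essential weight collapsing below 0.02 raises a unimodality
warning — the data then do not support an essential mode.

## Region counting and the exact test

Per gene, reads and unique sites are counted in nine cells: regions
{gene body, upstream flank, downstream flank} × channels {forward,
reverse, combined}. Flanks are 198 bp, clamped at replicon ends and
strand-flipped for − genes. The combined channel is the sum of the two
orientations in both measures (a site is orientation-specific, so a base
carrying both orientations counts as two sites). Unique-site counts are
reported but not tested; the statistics run on read counts.

The negative binomial is parameterized by mean μ and dispersion φ with
variance μ + φμ² (φ = 0 is Poisson). Replicates are handled by scaling
each sample's counts to the geometric-mean library size, summing within
group and rounding; the sum of n equalized replicates is modelled as
NB(nμ, φ/n) (moment-matching the iid sum). With unequal group sizes both
group sums are further rescaled to the geometric-mean replicate count.
This scheme is a documented simplification of edgeR's quantile
adjustment: exactly reproducible, and in cross-checks on shared fixtures
it agrees with edgeR's exact test (rejection region "smallp") to
release-level precision.

The test conditions on the cell total t = a + b: each split (x, t − x)
has probability ∝ NB(x; t/2, φ') · NB(t − x; t/2, φ'), and the two-sided
p-value sums all splits whose probability does not exceed the observed
one, with a relative tie tolerance of 1e-8 guarding floating-point ties.
Enumeration is exact (no saddlepoint shortcut); cell totals in practice
are small enough that the O(t) sum per cell is negligible.

The common dispersion is estimated by conditional maximum likelihood on
within-group replicate splits: for n iid NB replicates the distribution
of the counts given their total is free of μ (Dirichlet-multinomial
form), so the summed conditional log-likelihood is maximized over φ by
bounded scalar search on log φ in [1e-6, 50]. An optimum below 1e-4
returns exactly 0 (Poisson boundary). With no replicated group the
estimator falls back to φ = 0.1 with a warning — a deliberately
conservative mid-range default for insertion-library counts.

Benjamini–Hochberg correction is applied across all cells of one
condition-vs-control comparison jointly (one family per comparison; the
choice of family is a design decision, documented here because different
tools differ). Significance requires the triple default
q ≤ 0.05, |log2FC| ≥ 1, log2CPM > 8; the prior count 0.5 damps both logFC
and logCPM. logCPM is averaged over all samples of the comparison.

## Effect classification

Significant cells are interpreted per gene, strand-aware:

1. gene body (combined) enriched → inactivation advantage; depleted →
   inactivation cost;
2. upstream flank enriched in the toward-gene channel (forward for +
   genes, reverse for −), and not mirrored in the opposite channel →
   increased-expression advantage;
3. downstream flank enriched in the antisense channel (reverse for +,
   forward for −) → decreased-expression advantage;
4. any remaining significant signal → unclassified, with its rows
   attached.

"Not mirrored" is operationalized as: the opposite upstream channel is
non-significant, or its logFC is below half the signal channel's. The
literature describes a "preferential" orientation bias without a formula;
the half-logFC rule is the package's concrete choice and is exercised by
the divergent-promoter case (both orientations enriched → no expression
call). Combined-channel flank cells are treated as restatements of their
oriented parts and never drive an unclassified call on their own.

An "identified target" for induced-vs-uninduced comparisons is a distinct
gene with at least one effect call.

## Synthetic-library simulator

The simulator emulates one pooled saturating library grown under several
conditions: unique sites are placed once (each permissive base is a site
with probability `site_density`, fair-coin orientation) and shared by all
conditions; only read abundances are re-drawn per culture. Essential-gene
interiors receive no sites. Control read counts are zero-truncated NB
(every library site is visible in the control); treated counts are
untruncated NB with per-site means scaled by the designed effects, so
selection can drive a site to zero. Effects scale exactly the region ×
channel a real effect would: knockouts scale the whole gene body,
upstream-promoter effects only toward-gene-oriented sites in the 198 bp
upstream window, antisense effects only antisense-oriented sites in the
downstream window. The analysis and the simulator share the 198 bp
constant so recovery tests are exact.

Default conditions: 300 genes of 300 bp on a 210 kb genome (400 bp
intergenic gaps), 10% essential, site density 1/6 per bp (the saturating
reference scale), mean 10 reads per site, dispersion 0.1. The 400 bp gap
is deliberate: it keeps the 198 bp flank windows of neighbouring genes
disjoint, so each designed flank effect maps onto exactly one analysis
window. Real genomes violate this — operons overlap, divergent promoters
share intergenic space, and a flank window often reaches into a
neighbouring gene — so passing recovery tests demonstrate the
orientation logic is correct, not that real screens are free of
neighbour confounding. Other realism gaps: no insertion-site sequence
bias, no transposon target preference, no chromosomal replication
gradient in read depth, and conditions are drawn independently rather
than through serial passaging.

At these defaults the problem sizes used throughout the tests and the
acceptance script (300 genes, ~33k sites, duplicate cultures) run the
full pipeline in seconds while leaving all recovery margins wide.

## Growth-curve fitness

iAUC is the trapezoidal integral of max(0, OD(t) − OD(t₀)): the baseline
is the well's own first reading (self-baselining removes inoculum
differences; a blank-well baseline is not required), and dips below
baseline contribute zero. The fitness ratio is
iAUC(treated) / mean(iAUC of the drug-free references), clamped to
[0, 1] and flagged when it was clamped from above or undefined (both
references zero). Whether to clamp or let a downstream beta-family model
absorb values above 1 is genuinely open; we clamp and flag so the table
is usable either way. The data-set-wide zero-avoidance shift (add the
smallest nonzero ratio to every value) prepares ratios for beta-link
modelling, which is itself out of scope — the package emits descriptive
per-strain summaries (mean ratio, difference vs parent, >20% change
flag) instead of a hierarchical fit.

## Determinism

Every stochastic step funnels through a seeded `numpy` generator;
replicate seeds are spawned from one root via `SeedSequence`. The
pipeline stages results in a temporary directory and moves them into
place only on success, and each output table carries the package version,
a hash of the analysis parameters and the seed, so a run can be
re-executed bit-identically.
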