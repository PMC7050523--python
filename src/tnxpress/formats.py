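"""Readers and writers for the standard file formats of transposon insertion screens.

Three external representations are handled here and nowhere else:

* **Insertion plots** — the Bio-TraDIS "insert site plot" dialect: one line
  per genome base, two whitespace-separated integers giving the number of
  transposon-junction reads in the forward and the reverse orientation at
  that base.  Files ending in ``.gz`` are read and written gzip-compressed
  transparently.
* **GFF3** gene annotation, converted at this boundary from 1-based
  inclusive to the package-internal 0-based half-open convention.
* **SAM** alignments of junction reads, reduced to per-base strand-split
  profiles.

Orientation convention
----------------------
The *forward* channel holds insertions whose transposon-borne outward
promoter transcribes in the direction of increasing reference coordinates;
*reverse* is the opposite.  Read mapping orientation is used as the proxy
for promoter orientation: a forward-mapped junction read contributes to the
forward channel at its leftmost aligned reference base, a reverse-mapped
read to the reverse channel at its rightmost aligned base.  This convention
is load-bearing for everything downstream (which flank of a gene an
insertion can up-regulate, and whether a flanking insert is sense or
antisense to the gene), so it is fixed here once.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np

logger = logging.getLogger(__name__)


class PlotParseError(ValueError):
    """Raised when an insertion plot file is malformed."""


class AnnotationError(ValueError):
    """Raised when a GFF3 file violates the package's annotation contract."""


@dataclass
class InsertionProfile:
    """Per-base, strand-split transposon junction read counts for one replicon.

    ``reads_fwd[p]`` counts junction reads at base ``p`` whose outward
    promoter points toward increasing coordinates; ``reads_rev[p]`` the
    opposite orientation.
    """

    replicon_id: str
    reads_fwd: np.ndarray
    reads_rev: np.ndarray

    def __post_init__(self) -> None:
        self.reads_fwd = np.asarray(self.reads_fwd, dtype=np.int64)
        self.reads_rev = np.asarray(self.reads_rev, dtype=np.int64)
        if self.reads_fwd.ndim != 1 or self.reads_rev.ndim != 1:
            raise ValueError("read count vectors must be 1-D")
        if self.reads_fwd.shape != self.reads_rev.shape:
            raise ValueError("forward and reverse vectors must have equal length")
        if (self.reads_fwd < 0).any() or (self.reads_rev < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def length(self) -> int:
        return int(self.reads_fwd.shape[0])

    @property
    def total_reads(self) -> int:
        return int(self.reads_fwd.sum() + self.reads_rev.sum())

    def combined(self) -> np.ndarray:
        """Orientation-summed read counts per base."""
        return self.reads_fwd + self.reads_rev

    def mirror(self) -> "InsertionProfile":
        """Reverse-complement view: coordinates flipped, channels swapped.

        A forward-oriented insertion at base ``p`` becomes a
        reverse-oriented insertion at base ``L - 1 - p``.
        """
        return InsertionProfile(
            replicon_id=self.replicon_id,
            reads_fwd=self.reads_rev[::-1].copy(),
            reads_rev=self.reads_fwd[::-1].copy(),
        )


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene: 0-based half-open coordinates and strand."""

    gene_id: str
    name: str
    start: int
    end: int
    strand: str
    replicon_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def mirror(self, genome_length: int) -> "GeneModel":
        """The same gene on the reverse-complemented replicon."""
        return GeneModel(
            gene_id=self.gene_id,
            name=self.name,
            start=genome_length - self.end,
            end=genome_length - self.start,
            strand="-" if self.strand == "+" else "+",
            replicon_id=self.replicon_id,
        )


def _open_text(path: Union[str, Path], mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_plot(path: Union[str, Path], replicon_id: str = "") -> InsertionProfile:
    """Read a strand-split insertion plot file.

    One line per base, two whitespace-separated non-negative integers
    (forward then reverse reads).  Line ``i`` (1-based) fills position
    ``i - 1``.  An empty file yields a valid length-0 profile.

    Raises
    ------
    PlotParseError
        Naming the offending 1-based line number on any malformed line.
    """
    fwd: list[int] = []
    rev: list[int] = []
    with _open_text(path, "r") as handle:
        for lineno, line in enumerate(handle, start=1):
            parts = line.split()
            if len(parts) != 2:
                raise PlotParseError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(parts)}"
                )
            try:
                f, r = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise PlotParseError(f"{path}: line {lineno}: non-integer field") from exc
            if f < 0 or r < 0:
                raise PlotParseError(f"{path}: line {lineno}: negative count")
            fwd.append(f)
            rev.append(r)
    return InsertionProfile(
        replicon_id=replicon_id or Path(path).stem,
        reads_fwd=np.asarray(fwd, dtype=np.int64),
        reads_rev=np.asarray(rev, dtype=np.int64),
    )


def write_plot(profile: InsertionProfile, path: Union[str, Path]) -> None:
    """Write ``profile`` in the insertion-plot dialect; exact inverse of :func:`read_plot`."""
    with _open_text(path, "w") as handle:
        for f, r in zip(profile.reads_fwd.tolist(), profile.reads_rev.tolist()):
            handle.write(f"{f} {r}\n")


def read_annotation(path: Union[str, Path]) -> list[GeneModel]:
    """Parse gene models from a GFF3 file.

    Features of type ``gene`` are used; if the file contains none, ``CDS``
    features are used as a fallback.  The identifier is taken from
    ``locus_tag`` if present, else ``ID``; ``Name``/``gene`` attributes
    populate the display name.  GFF3 1-based inclusive coordinates are
    converted to 0-based half-open.  The returned list is sorted by start.

    Raises
    ------
    AnnotationError
        On duplicate gene identifiers or a feature extending past its
        declared ``##sequence-region`` length.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    featuretype = "gene"
    if sum(1 for _ in db.features_of_type("gene")) == 0:
        featuretype = "CDS"

    region_lengths: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            region_lengths[parts[1]] = int(parts[3])

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type(featuretype):
        gene_id = feat.attributes.get("locus_tag", feat.attributes.get("ID", [feat.id]))[0]
        name = feat.attributes.get("Name", feat.attributes.get("gene", [gene_id]))[0]
        if gene_id in seen:
            raise AnnotationError(f"duplicate gene identifier {gene_id!r}")
        seen.add(gene_id)
        seqlen = region_lengths.get(feat.seqid)
        if seqlen is not None and feat.end > seqlen:
            raise AnnotationError(
                f"gene {gene_id!r} ends at {feat.end} beyond sequence-region length {seqlen}"
            )
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                name=name,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=strand,
                replicon_id=feat.seqid,
            )
        )
    if not genes:
        warnings.warn(f"{path}: no gene or CDS features found", stacklevel=2)
    genes.sort(key=lambda g: (g.replicon_id, g.start, g.gene_id))
    return genes


def write_annotation(genes: Iterable[GeneModel], path: Union[str, Path], genome_length: int | None = None) -> None:
    """Write gene models as a minimal GFF3 file (inverse of :func:`read_annotation`)."""
    genes = list(genes)
    with _open_text(path, "w") as handle:
        handle.write("##gff-version 3\n")
        if genome_length is not None and genes:
            handle.write(f"##sequence-region {genes[0].replicon_id or 'chr'} 1 {genome_length}\n")
        for g in genes:
            seqid = g.replicon_id or "chr"
            attrs = f"ID={g.gene_id};locus_tag={g.gene_id};Name={g.name}"
            handle.write(
                f"{seqid}\ttnxpress\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


@dataclass
class SamConversionStats:
    """Bookkeeping for :func:`sam_to_profile`: how many records were used or skipped."""

    accepted: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_supplementary: int = 0
    skipped_low_mapq: int = 0
    skipped_other_replicon: int = 0

    @property
    def skipped(self) -> int:
        return (
            self.skipped_unmapped
            + self.skipped_secondary
            + self.skipped_supplementary
            + self.skipped_low_mapq
            + self.skipped_other_replicon
        )


def sam_to_profile(
    alignments: Union[str, Path, Iterable],
    replicon_id: str,
    length: int,
    min_mapq: int = 10,
) -> tuple[InsertionProfile, SamConversionStats]:
    """Reduce SAM alignment records to a strand-split insertion profile.

    The transposon junction of a forward-mapped read is its leftmost aligned
    reference base (increments the forward channel); for a reverse-mapped
    read it is the rightmost aligned base (reverse channel).  Unmapped,
    secondary and supplementary records, records below ``min_mapq`` and
    records on other replicons are skipped and counted.

    ``alignments`` may be a SAM/BAM path or an iterable of
    :class:`pysam.AlignedSegment`.
    """
    import pysam

    if isinstance(alignments, (str, Path)):
        handle = pysam.AlignmentFile(str(alignments), check_sq=False)
        records: Iterable = handle
    else:
        records = alignments

    fwd = np.zeros(length, dtype=np.int64)
    rev = np.zeros(length, dtype=np.int64)
    stats = SamConversionStats()
    for rec in records:
        if rec.is_unmapped:
            stats.skipped_unmapped += 1
            continue
        if rec.is_secondary:
            stats.skipped_secondary += 1
            continue
        if rec.is_supplementary:
            stats.skipped_supplementary += 1
            continue
        if rec.mapping_quality < min_mapq:
            stats.skipped_low_mapq += 1
            continue
        if rec.reference_name != replicon_id:
            stats.skipped_other_replicon += 1
            continue
        if rec.is_reverse:
            junction = rec.reference_end - 1  # rightmost aligned base
            channel = rev
        else:
            junction = rec.reference_start  # leftmost aligned base
            channel = fwd
        if not (0 <= junction < length):
            raise ValueError(
                f"record {rec.query_name!r}: junction {junction} outside [0, {length})"
            )
        channel[junction] += 1
        stats.accepted += 1
    if stats.skipped:
        logger.info("sam_to_profile: accepted %d, skipped %d records", stats.accepted, stats.skipped)
    return InsertionProfile(replicon_id=replicon_id, reads_fwd=fwd, reads_rev=rev), stats
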