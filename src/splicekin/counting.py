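"""Intron discovery from split reads and the three characteristic bond
counts.

Every intron is characterised by three read classes over an alignment
sample: reads whose aligned blocks contiguously span the exon-intron
boundary (donor bond), reads spanning the intron-exon boundary (acceptor
bond), and split reads whose skipped interval matches the intron
coordinates exactly (junction bond).  Counting these classes over a
labeling time series is what turns alignments into bond-level kinetic
data.

Coordinates are 0-based half-open throughout, matching SAM/BAM block
conventions.  Spanning a bond means one aligned block covers both flanking
bases; a read carrying a skip that overlaps an intron without matching it
exactly contributes to none of that intron's classes.  Mates of a pair are
evaluated independently and a fragment contributes at most once per
(intron, class).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
import pysam

DEFAULT_MIN_SPLIT_READS = 10
DEFAULT_MAPQ = 255

CATEGORIES = (
    "annotated",
    "novel_combination",
    "novel_donor",
    "novel_acceptor",
    "novel_both_intragenic",
    "novel_both_intergenic",
)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Intron:
    """An intron with its two boundary bonds.

    The donor bond joins the last exonic and first intronic base at the 5'
    splice site in transcript orientation; the acceptor bond joins the last
    intronic and first exonic base at the 3' splice site.  On the plus
    strand the donor bond therefore sits at the interval start, on the
    minus strand at the interval end.
    """

    interval: GenomicInterval
    category: str | None = None
    n_split_reads: int = 0

    @property
    def id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}"

    @property
    def donor_bond(self) -> tuple[int, int]:
        """Genomic positions of the two bases flanking the donor bond."""
        iv = self.interval
        return (iv.start - 1, iv.start) if iv.strand == "+" else (iv.end - 1, iv.end)

    @property
    def acceptor_bond(self) -> tuple[int, int]:
        iv = self.interval
        return (iv.end - 1, iv.end) if iv.strand == "+" else (iv.start - 1, iv.start)

    @property
    def donor_site(self) -> int:
        """Genomic position of the first intronic base at the donor side."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def acceptor_site(self) -> int:
        """Genomic position of the last intronic base at the acceptor side."""
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start


def fragment_strand(read: pysam.AlignedSegment, strandedness: str = "rf") -> str:
    """Transcript strand of a read's fragment under the library protocol.

    ``rf`` (first read reverse, the default for dUTP-style kits): read 1
    aligns antisense to the transcript.  ``fr``: read 1 aligns sense.
    Unpaired reads are treated as read 1.
    """
    if strandedness not in ("rf", "fr"):
        raise ValueError(f"strandedness must be 'rf' or 'fr', got {strandedness!r}")
    first = read.is_read1 or not read.is_paired
    sense_reverse = (strandedness == "rf") == first
    return ("+" if read.is_reverse else "-") if sense_reverse else ("-" if read.is_reverse else "+")


def _passes(read: pysam.AlignedSegment, mapq: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and (mapq is None or read.mapping_quality == mapq)
        and read.cigartuples is not None
    )


def _blocks_and_skips(read: pysam.AlignedSegment):
    """Aligned reference blocks and skipped (N) intervals of a read."""
    blocks, skips = [], []
    pos = read.reference_start
    block_start = pos
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X consume both
            pos += length
        elif op == 2:  # D consumes reference but stays contiguous
            pos += length
        elif op == 3:  # N: splice skip
            if pos > block_start:
                blocks.append((block_start, pos))
            skips.append((pos, pos + length))
            pos += length
            block_start = pos
        # I, S, H, P do not consume reference
    if pos > block_start:
        blocks.append((block_start, pos))
    return blocks, skips


def _iter_reads(alignments, mapq):
    if isinstance(alignments, (str,)):
        alignments = pysam.AlignmentFile(alignments)
    if isinstance(alignments, pysam.AlignmentFile):
        it = alignments.fetch(until_eof=True)
    else:
        it = alignments
    for read in it:
        if _passes(read, mapq):
            yield read


def discover_introns(
    alignments,
    min_split_reads: int = DEFAULT_MIN_SPLIT_READS,
    mapq: int = DEFAULT_MAPQ,
    strandedness: str = "rf",
) -> list[Intron]:
    """Collect every distinct skipped interval supported by at least
    ``min_split_reads`` fragments passing the quality filters.

    ``alignments`` may be a SAM/BAM path, an open ``pysam.AlignmentFile``,
    or an iterable of aligned segments.  Fragments (not mates) are counted:
    a pair whose two mates span the same junction supports it once.
    """
    if min_split_reads < 1:
        raise ValueError("min_split_reads must be >= 1")
    support: dict[tuple, set] = defaultdict(set)
    for read in _iter_reads(alignments, mapq):
        _, skips = _blocks_and_skips(read)
        if not skips:
            continue
        strand = fragment_strand(read, strandedness)
        for s, e in skips:
            support[(read.reference_name, s, e, strand)].add(read.query_name)
    out = []
    for (chrom, s, e, strand), names in sorted(support.items()):
        if len(names) >= min_split_reads:
            out.append(
                Intron(GenomicInterval(chrom, s, e, strand), n_split_reads=len(names))
            )
    return out


def count_bond_reads(
    alignments,
    introns: list[Intron],
    sample_id: str = "sample",
    mapq: int = DEFAULT_MAPQ,
    strandedness: str = "rf",
) -> pd.DataFrame:
    """Count donor-, acceptor- and junction-class reads per intron.

    Returns a long table with one row per intron: ``intron_id, sample_id,
    donor, acceptor, junction``.  A fragment contributes at most once per
    (intron, class); a read whose skip overlaps an intron without matching
    it exactly is excluded from all three classes of that intron.
    """
    donor_at: dict[tuple, list[int]] = defaultdict(list)
    acceptor_at: dict[tuple, list[int]] = defaultdict(list)
    junction_at: dict[tuple, list[int]] = {}
    intervals: list[GenomicInterval] = []
    for idx, intron in enumerate(introns):
        iv = intron.interval
        intervals.append(iv)
        donor_at[(iv.chrom, intron.donor_bond, iv.strand)].append(idx)
        acceptor_at[(iv.chrom, intron.acceptor_bond, iv.strand)].append(idx)
        junction_at[(iv.chrom, iv.start, iv.end, iv.strand)] = idx

    seen: list[dict[str, set]] = [
        {"donor": set(), "acceptor": set(), "junction": set()} for _ in introns
    ]

    def overlapping_skip(skips, iv):
        for s, e in skips:
            if s < iv.end and e > iv.start and (s, e) != (iv.start, iv.end):
                return True
        return False

    for read in _iter_reads(alignments, mapq):
        blocks, skips = _blocks_and_skips(read)
        strand = fragment_strand(read, strandedness)
        chrom = read.reference_name
        name = read.query_name
        candidates: set[int] = set()
        for block in blocks:
            lo, hi = block
            # a block spans a bond (a, a+1) when it covers both bases
            for pos in range(max(lo, 0), hi - 1):
                bond = (pos, pos + 1)
                for idx in donor_at.get((chrom, bond, strand), ()):
                    candidates.add((idx, "donor"))
                for idx in acceptor_at.get((chrom, bond, strand), ()):
                    candidates.add((idx, "acceptor"))
        for s, e in skips:
            idx = junction_at.get((chrom, s, e, strand))
            if idx is not None:
                candidates.add((idx, "junction"))
        for idx, cls in candidates:
            if overlapping_skip(skips, intervals[idx]):
                continue
            seen[idx][cls].add(name)

    rows = []
    for intron, classes in zip(introns, seen):
        rows.append(
            {
                "intron_id": intron.id,
                "sample_id": sample_id,
                "donor": len(classes["donor"]),
                "acceptor": len(classes["acceptor"]),
                "junction": len(classes["junction"]),
            }
        )
    return pd.DataFrame(rows)


def introns_to_bed(introns: list[Intron]) -> pd.DataFrame:
    """BED6-style table (plus category and split-read support columns)."""
    return pd.DataFrame(
        {
            "chrom": [i.interval.chrom for i in introns],
            "start": [i.interval.start for i in introns],
            "end": [i.interval.end for i in introns],
            "name": [i.id for i in introns],
            "score": [i.n_split_reads for i in introns],
            "strand": [i.interval.strand for i in introns],
            "category": [i.category or "" for i in introns],
        }
    )
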