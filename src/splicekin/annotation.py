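"""Gene-model annotation: GTF reading and intron classification.

Discovered introns are classified against an annotation into six
categories: ``annotated`` (the exact intron is known), ``novel_combination``
(both splice sites known but never paired), ``novel_donor`` /
``novel_acceptor`` (one site unannotated), and ``novel_both_intragenic`` /
``novel_both_intergenic`` (neither site known, inside or outside any
annotated gene body on either strand).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from splicekin.counting import Intron

_GTF_COLUMNS = [
    "chrom",
    "source",
    "feature",
    "start",
    "end",
    "score",
    "strand",
    "frame",
    "attributes",
]


def read_gtf(path, features=("exon", "gene")) -> pd.DataFrame:
    """Read a GENCODE-dialect GTF into a table of the requested features.

    Coordinates are converted from GTF's 1-based inclusive convention to
    0-based half-open.  ``gene_id`` and ``transcript_id`` are pulled out of
    the attribute string.  Records without a usable strand are dropped with
    a warning.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=_GTF_COLUMNS,
        dtype={"chrom": str},
    )
    df = df[df["feature"].isin(features)].copy()
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        warnings.warn(f"skipping {int(bad.sum())} GTF records without strand")
        df = df[~bad]
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    df["gene_id"] = df["attributes"].str.extract(r'gene_id "([^"]+)"')
    df["transcript_id"] = df["attributes"].str.extract(r'transcript_id "([^"]+)"')
    return df.drop(columns=["attributes"])


@dataclass
class Annotation:
    """Splice-site level view of a gene annotation.

    ``donors`` and ``acceptors`` hold (chrom, position-of-first/last
    intronic base, strand); ``introns`` the full (chrom, start, end,
    strand) tuples; ``genes`` the gene extents used for the
    intragenic/intergenic call (strand-blind).
    """

    donors: set = field(default_factory=set)
    acceptors: set = field(default_factory=set)
    introns: set = field(default_factory=set)
    genes: list = field(default_factory=list)

    @classmethod
    def from_gtf(cls, path) -> "Annotation":
        df = read_gtf(path)
        ann = cls()
        genes = df[df["feature"] == "gene"]
        exons = df[df["feature"] == "exon"]
        if genes.empty and not exons.empty:
            genes = (
                exons.groupby("gene_id")
                .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
                .reset_index()
            )
        for row in genes.itertuples():
            ann.genes.append((row.chrom, row.start, row.end))
        for (_, strand), tx in exons.groupby(["transcript_id", "strand"]):
            starts = sorted(zip(tx["start"], tx["end"]))
            chrom = tx["chrom"].iloc[0]
            for (s1, e1), (s2, e2) in zip(starts, starts[1:]):
                if e1 >= s2:  # overlapping/adjacent exons leave no intron
                    continue
                ann.add_intron(chrom, e1, s2, strand)
        return ann

    def add_intron(self, chrom: str, start: int, end: int, strand: str) -> None:
        self.introns.add((chrom, start, end, strand))
        if strand == "+":
            self.donors.add((chrom, start, strand))
            self.acceptors.add((chrom, end - 1, strand))
        else:
            self.donors.add((chrom, end - 1, strand))
            self.acceptors.add((chrom, start, strand))

    def overlaps_gene(self, chrom: str, start: int, end: int) -> bool:
        return any(c == chrom and s < end and e > start for c, s, e in self.genes)


def classify_intron(intron: Intron, annotation: Annotation) -> str:
    """Assign one of the six novelty categories (see module docstring)."""
    iv = intron.interval
    key = (iv.chrom, iv.start, iv.end, iv.strand)
    donor_known = (iv.chrom, intron.donor_site, iv.strand) in annotation.donors
    acceptor_known = (iv.chrom, intron.acceptor_site, iv.strand) in annotation.acceptors
    if key in annotation.introns:
        category = "annotated"
    elif donor_known and acceptor_known:
        category = "novel_combination"
    elif acceptor_known:
        category = "novel_donor"
    elif donor_known:
        category = "novel_acceptor"
    elif annotation.overlaps_gene(iv.chrom, iv.start, iv.end):
        category = "novel_both_intragenic"
    else:
        category = "novel_both_intergenic"
    intron.category = category
    return category
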