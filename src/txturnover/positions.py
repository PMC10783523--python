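"""Genomic-position classification of de novo transcripts.

Each transcript is assigned exactly one of six categories relative to a
reference annotation of established genes, pseudogenes and non-coding RNAs:

- ``intronic``:    fully contained in a single intron of a gene (any strand);
- ``pseudogenic``: overlaps an annotated pseudogene;
- ``ncRNA``:       overlaps an annotated ncRNA but extends beyond it
                   (initiation upstream or termination downstream of it);
- ``exon_longer``: overlaps a gene fragment in the same direction (and, being
                   longer than the overlap, also intergenic sequence);
- ``antisense``:   overlaps a gene fragment in the opposite direction only;
- ``intergenic``:  overlaps nothing annotated.

When several classes overlap, the precedence is the order above; a transcript
overlapping genes on both strands is classed ``exon_longer`` (sense wins).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from intervaltree import IntervalTree

from .catalog import Transcript, TranscriptCatalog, _parse_gtf_attributes, GtfParseError

logger = logging.getLogger(__name__)

__all__ = [
    "PositionCategory",
    "AnnotationIndex",
    "build_annotation_index",
    "classify_transcript",
    "classify_catalog",
]


class PositionCategory(str, enum.Enum):
    EXON_LONGER = "exon_longer"
    INTERGENIC = "intergenic"
    ANTISENSE = "antisense"
    PSEUDOGENIC = "pseudogenic"
    NCRNA = "ncRNA"
    INTRONIC = "intronic"


#: default precedence when a transcript overlaps several annotation classes
DEFAULT_PRECEDENCE = (
    PositionCategory.INTRONIC,
    PositionCategory.PSEUDOGENIC,
    PositionCategory.NCRNA,
    PositionCategory.EXON_LONGER,
    PositionCategory.ANTISENSE,
    PositionCategory.INTERGENIC,
)


@dataclass
class AnnotationIndex:
    """Per-chromosome interval trees over the reference annotation.

    ``genes`` intervals carry the gene strand as data; ``introns`` are derived
    per gene as the gene span minus its exon union.  Positions covered by none
    of the trees are implicitly intergenic.
    """

    genes: dict[str, IntervalTree] = field(default_factory=dict)
    introns: dict[str, IntervalTree] = field(default_factory=dict)
    pseudogenes: dict[str, IntervalTree] = field(default_factory=dict)
    ncrnas: dict[str, IntervalTree] = field(default_factory=dict)

    def sizes(self) -> tuple[int, int, int]:
        """(number of genes, pseudogenes, ncRNAs) indexed."""
        return (
            sum(len(t) for t in self.genes.values()),
            sum(len(t) for t in self.pseudogenes.values()),
            sum(len(t) for t in self.ncrnas.values()),
        )


_GENE_FEATURES = {"gene", "protein_coding_gene"}
_PSEUDO_FEATURES = {"pseudogene"}
_NCRNA_FEATURES = {"ncRNA", "ncrna", "lnc_RNA", "lncRNA"}


def build_annotation_index(annotation_gtf) -> AnnotationIndex:
    """Index a reference annotation GTF for overlap queries.

    Recognises ``gene`` features (with child ``exon`` features linked by
    ``gene_id``), ``pseudogene`` and ``ncRNA`` features.  Introns are the
    gene span minus the union of that gene's exons; a gene without exons is
    treated as single-exon (no introns) and logged.
    """
    genes: dict[str, tuple[str, int, int, str]] = {}   # gene_id -> (chrom, s, e, strand)
    exons: dict[str, list[tuple[int, int]]] = {}
    index = AnnotationIndex()

    with open(annotation_gtf) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"annotation line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr = fields
            try:
                start, end = int(start_s) - 1, int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"annotation line {lineno}: non-integer coordinates") from None
            attrs = _parse_gtf_attributes(attr)
            gid = attrs.get("gene_id", f"feat{lineno}")
            if feature in _GENE_FEATURES:
                genes[gid] = (chrom, start, end, strand)
            elif feature == "exon":
                exons.setdefault(gid, []).append((start, end))
            elif feature in _PSEUDO_FEATURES:
                index.pseudogenes.setdefault(chrom, IntervalTree()).addi(start, end, gid)
            elif feature in _NCRNA_FEATURES:
                index.ncrnas.setdefault(chrom, IntervalTree()).addi(start, end, gid)

    for gid, (chrom, start, end, strand) in genes.items():
        index.genes.setdefault(chrom, IntervalTree()).addi(start, end, strand)
        gene_exons = sorted(exons.get(gid, []))
        if not gene_exons:
            logger.info("gene %s has no exons; treated as single-exon", gid)
            continue
        # introns = gene span minus exon union
        cursor = start
        for es, ee in gene_exons:
            if es > cursor:
                index.introns.setdefault(chrom, IntervalTree()).addi(cursor, es, gid)
            cursor = max(cursor, ee)
        if cursor < end:
            index.introns.setdefault(chrom, IntervalTree()).addi(cursor, end, gid)
    return index


def classify_transcript(tx: Transcript, index: AnnotationIndex) -> PositionCategory:
    """Assign the single genomic-position category of one transcript."""
    chrom_known = any(
        tx.chrom in trees
        for trees in (index.genes, index.introns, index.pseudogenes, index.ncrnas)
    )
    if not chrom_known:
        logger.warning("chromosome %s absent from annotation; %s -> intergenic",
                       tx.chrom, tx.id)
        return PositionCategory.INTERGENIC

    s, e = tx.start, tx.end

    # intronic: full containment inside one intron, any strand
    for iv in index.introns.get(tx.chrom, IntervalTree()).overlap(s, e):
        if iv.begin <= s and e <= iv.end:
            return PositionCategory.INTRONIC

    if index.pseudogenes.get(tx.chrom, IntervalTree()).overlap(s, e):
        return PositionCategory.PSEUDOGENIC

    # ncRNA: overlaps an ncRNA but extends beyond it
    for iv in index.ncrnas.get(tx.chrom, IntervalTree()).overlap(s, e):
        if s < iv.begin or e > iv.end:
            return PositionCategory.NCRNA

    gene_hits = index.genes.get(tx.chrom, IntervalTree()).overlap(s, e)
    if gene_hits:
        strands = {iv.data for iv in gene_hits}
        if tx.strand in strands:
            if len(strands) > 1:
                logger.info("%s overlaps genes on both strands; sense wins", tx.id)
            return PositionCategory.EXON_LONGER
        return PositionCategory.ANTISENSE
    return PositionCategory.INTERGENIC


def classify_catalog(catalog: TranscriptCatalog,
                     index: AnnotationIndex) -> pd.DataFrame:
    """Classify a whole catalog.

    Returns a tidy frame with one row per transcript
    (``transcript_id, sample, category``); per-category counts and
    proportions are attached as ``df.attrs["counts"]`` /
    ``df.attrs["proportions"]``.
    """
    rows = [
        {"transcript_id": t.id, "sample": t.sample,
         "category": classify_transcript(t, index).value}
        for t in catalog
    ]
    df = pd.DataFrame(rows, columns=["transcript_id", "sample", "category"])
    counts = df["category"].value_counts().to_dict() if len(df) else {}
    total = sum(counts.values())
    df.attrs["counts"] = counts
    df.attrs["proportions"] = (
        {c: v / total for c, v in counts.items()} if total else {}
    )
    return df
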