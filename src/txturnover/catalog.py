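"""Per-sample transcript catalogs and de novo transcript filters.

Reads StringTie-style transcript GTFs into :class:`TranscriptCatalog`
objects, removes lowly expressed transcripts (TPM threshold), removes
transcripts with homology hits in outgroup transcriptomes (BLAST tabular
input, E-value cutoff, forward orientation), and merges splice variants of
one precursor into a single unspliced transcript.

Coordinates are stored 0-based half-open internally; GTF I/O converts
from/to the 1-based inclusive convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Transcript",
    "HomologyHit",
    "TranscriptCatalog",
    "GtfParseError",
    "read_transcript_gtf",
    "read_blast_tabular",
    "filter_by_tpm",
    "filter_by_homology",
    "merge_splice_variants",
]

BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; carries the 1-based line number."""


@dataclass(frozen=True)
class Transcript:
    """One assembled transcript of one sample.

    ``start``/``end`` and exon intervals are 0-based half-open genomic
    coordinates.  ``precursor_id`` groups splice variants of one locus
    (the GTF ``gene_id``).  ``tpm`` is expression in Transcripts Per Million.
    """

    id: str
    sample: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    precursor_id: str = ""
    tpm: float = 0.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-'")
        if self.tpm < 0:
            raise ValueError(f"{self.id}: tpm must be >= 0")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        prev_end = None
        for s, e in exons:
            if s >= e:
                raise ValueError(f"{self.id}: empty exon {s}..{e}")
            if s < self.start or e > self.end:
                raise ValueError(
                    f"{self.id}: exon {s}..{e} outside transcript span "
                    f"{self.start}..{self.end}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.id}: overlapping exons")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def unspliced_length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (5' end)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Strand-aware termination site (3' end)."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class HomologyHit:
    """One BLAST-style alignment of a query transcript to a subject."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")

    @property
    def forward(self) -> bool:
        """True iff the subject coordinates ascend (plus-strand hit)."""
        return self.subject_start <= self.subject_end


@dataclass(frozen=True)
class TranscriptCatalog:
    """All transcripts of one sample plus a record of applied filters."""

    sample: str
    transcripts: tuple[Transcript, ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [t.id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate transcript ids in catalog {self.sample}")
        for t in self.transcripts:
            if t.sample != self.sample:
                raise ValueError(
                    f"transcript {t.id} carries sample {t.sample!r}, "
                    f"catalog is {self.sample!r}")

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def ids(self) -> set[str]:
        return {t.id for t in self.transcripts}

    def with_transcripts(self, transcripts: Iterable[Transcript],
                         note: str) -> "TranscriptCatalog":
        return TranscriptCatalog(
            sample=self.sample,
            transcripts=tuple(transcripts),
            provenance=self.provenance + (note,),
        )


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            continue
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_transcript_gtf(path, sample_label: str) -> TranscriptCatalog:
    """Read a StringTie-style GTF into a catalog of ``sample_label``.

    Expects ``transcript`` and ``exon`` features carrying ``transcript_id``
    and ``gene_id`` attributes; a ``TPM`` attribute on the transcript line is
    parsed when present, else 0.  1-based inclusive GTF coordinates are
    converted to the internal 0-based half-open convention.
    """
    path = Path(path)
    transcripts: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path.name} line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path.name} line {lineno}: non-integer coordinates "
                    f"{start_s!r}..{end_s!r}") from None
            attrs = _parse_gtf_attributes(attr)
            tid = attrs.get("transcript_id")
            if feature not in ("transcript", "exon"):
                continue
            if tid is None:
                raise GtfParseError(
                    f"{path.name} line {lineno}: {feature} without transcript_id")
            start, end = start1 - 1, end1  # to 0-based half-open
            if tid not in transcripts:
                transcripts[tid] = {
                    "chrom": chrom, "strand": strand,
                    "start": None, "end": None,
                    "gene_id": attrs.get("gene_id", tid),
                    "tpm": 0.0, "exons": [],
                }
                order.append(tid)
            rec = transcripts[tid]
            if feature == "transcript":
                rec["start"], rec["end"] = start, end
                rec["chrom"], rec["strand"] = chrom, strand
                rec["gene_id"] = attrs.get("gene_id", tid)
                if "TPM" in attrs:
                    try:
                        rec["tpm"] = float(attrs["TPM"])
                    except ValueError:
                        raise GtfParseError(
                            f"{path.name} line {lineno}: non-numeric TPM "
                            f"{attrs['TPM']!r}") from None
            else:
                rec["exons"].append((start, end))

    out = []
    for tid in order:
        rec = transcripts[tid]
        exons = rec["exons"]
        if rec["start"] is None:
            # no transcript line; derive the span from the exons
            if not exons:
                continue
            rec["start"] = min(s for s, _ in exons)
            rec["end"] = max(e for _, e in exons)
        if not exons:
            exons = [(rec["start"], rec["end"])]
        out.append(Transcript(
            id=tid, sample=sample_label, chrom=rec["chrom"],
            start=rec["start"], end=rec["end"], strand=rec["strand"],
            exons=tuple(exons), precursor_id=rec["gene_id"], tpm=rec["tpm"],
        ))
    return TranscriptCatalog(
        sample=sample_label, transcripts=tuple(out),
        provenance=(f"read_transcript_gtf({path.name})",),
    )


def write_transcript_gtf(catalog: TranscriptCatalog, path) -> None:
    """Write a catalog as GTF (1-based inclusive, transcript + exon lines)."""
    with open(path, "w") as fh:
        for t in catalog:
            attrs = (f'gene_id "{t.precursor_id or t.id}"; '
                     f'transcript_id "{t.id}"; TPM "{t.tpm:.6g}";')
            fh.write("\t".join([
                t.chrom, "txturnover", "transcript", str(t.start + 1),
                str(t.end), ".", t.strand, ".", attrs]) + "\n")
            for s, e in t.exons:
                fh.write("\t".join([
                    t.chrom, "txturnover", "exon", str(s + 1), str(e),
                    ".", t.strand, ".", attrs]) + "\n")


def read_blast_tabular(path) -> list[HomologyHit]:
    """Parse 12-column BLAST tabular output (outfmt 6) into hits."""
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=BLAST6_COLUMNS, usecols=range(12),
            dtype={
                "qseqid": str, "sseqid": str, "pident": float, "length": int,
                "mismatch": int, "gapopen": int, "qstart": int, "qend": int,
                "sstart": int, "send": int, "evalue": float, "bitscore": float,
            },
        )
    except pd.errors.EmptyDataError:
        return []
    except ValueError as exc:
        raise ValueError(f"malformed BLAST tabular file {path}: {exc}") from exc
    return [
        HomologyHit(
            query_id=row.qseqid, subject_id=row.sseqid,
            percent_identity=row.pident, alignment_length=row.length,
            query_start=row.qstart, query_end=row.qend,
            subject_start=row.sstart, subject_end=row.send,
            evalue=row.evalue, bitscore=row.bitscore,
        )
        for row in df.itertuples(index=False)
    ]


def filter_by_tpm(catalog: TranscriptCatalog, threshold: float = 0.5) -> TranscriptCatalog:
    """Drop transcripts below the TPM expression threshold.

    A transcript with TPM exactly equal to the threshold is kept (only
    strictly lower expression is removed).
    """
    if threshold < 0:
        raise ValueError("TPM threshold must be non-negative")
    kept = [t for t in catalog if t.tpm >= threshold]
    return catalog.with_transcripts(kept, f"filter_by_tpm(threshold={threshold})")


def filter_by_homology(catalog: TranscriptCatalog, hits: Sequence[HomologyHit],
                       evalue_cutoff: float = 1e-2,
                       forward_only: bool = True) -> TranscriptCatalog:
    """Drop transcripts with a qualifying homology hit.

    A hit qualifies when its E-value is at most ``evalue_cutoff`` and, with
    ``forward_only``, when the subject is matched in the forward orientation.
    Applying this twice with two hit tables reproduces a staged homology
    screen (e.g. close outgroups, then more distant ones).  Hits naming
    unknown query ids are ignored with a warning.
    """
    known = catalog.ids()
    flagged: set[str] = set()
    unknown: set[str] = set()
    for h in hits:
        if h.query_id not in known:
            unknown.add(h.query_id)
            continue
        if h.evalue <= evalue_cutoff and (h.forward or not forward_only):
            flagged.add(h.query_id)
    if unknown:
        logger.warning(
            "filter_by_homology: %d hit query ids not in catalog %s (ignored)",
            len(unknown), catalog.sample)
    kept = [t for t in catalog if t.id not in flagged]
    return catalog.with_transcripts(
        kept,
        f"filter_by_homology(evalue<={evalue_cutoff}, forward_only={forward_only}, "
        f"removed={len(catalog) - len(kept)})")


def merge_splice_variants(catalog: TranscriptCatalog) -> TranscriptCatalog:
    """Collapse splice variants of one precursor into an unspliced transcript.

    The merged transcript spans min(start)..max(end) of its variants as a
    single exon, inherits the shared strand, and carries the maximum TPM over
    variants.  Already-unspliced catalogs pass through unchanged in count, so
    the operation is idempotent.
    """
    groups: dict[str, list[Transcript]] = {}
    order: list[str] = []
    for t in catalog:
        pid = t.precursor_id or t.id
        if pid not in groups:
            groups[pid] = []
            order.append(pid)
        groups[pid].append(t)

    merged = []
    for pid in order:
        variants = groups[pid]
        chroms = {t.chrom for t in variants}
        strands = {t.strand for t in variants}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"precursor {pid}: splice variants disagree on "
                f"chrom/strand ({chroms}, {strands})")
        start = min(t.start for t in variants)
        end = max(t.end for t in variants)
        merged.append(Transcript(
            id=pid, sample=catalog.sample, chrom=variants[0].chrom,
            start=start, end=end, strand=variants[0].strand,
            exons=((start, end),), precursor_id=pid,
            tpm=max(t.tpm for t in variants),
        ))
    return catalog.with_transcripts(
        merged, f"merge_splice_variants(tpm=max; {len(catalog)}->{len(merged)})")
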