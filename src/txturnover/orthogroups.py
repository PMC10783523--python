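"""Cross-sample orthogroup clustering of de novo transcripts.

Three orthology definitions are implemented:

1. reciprocal sequence similarity of the spliced transcripts (>= 70%
   coverage on both sides, >= 75% identity);
2. Definition 1 plus the requirement that all transcription initiation
   sites fall in a 500 bp window;
3. positional only: the unspliced transcripts start within a 500 bp window
   and end within a 500 bp window (no sequence similarity).

Pairwise criteria are turned into orthogroups by connected components of
the qualifying-pair graph; components violating the group-wide window are
split greedily, and components that are not cliques are flagged.  The
module also derives the transcript frequency spectrum and the per-position
nucleotide-sharing counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import HomologyHit, Transcript, TranscriptCatalog
from .spectra import FrequencySpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityRecord",
    "Orthogroup",
    "similarity_from_hits",
    "cluster_definition1",
    "cluster_definition2",
    "cluster_definition3",
    "nucleotide_sharing",
    "spectrum_from_orthogroups",
]


@dataclass(frozen=True)
class SimilarityRecord:
    """Best reciprocal alignment between two transcripts of different samples.

    Coverage is the aligned length divided by each transcript's own spliced
    length; identity is the more conservative (minimum) of the two
    directions when both exist.
    """

    transcript_a: str
    transcript_b: str
    coverage_a: float
    coverage_b: float
    identity: float
    reciprocal: bool

    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.transcript_a, self.transcript_b)))


@dataclass(frozen=True)
class Orthogroup:
    """A cross-sample cluster of transcripts under one definition."""

    id: str
    definition: int
    members: tuple[tuple[str, str], ...]  # (sample, transcript_id)
    is_clique: bool = True

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("orthogroup must have members")

    @property
    def occupancy(self) -> int:
        return len({s for s, _ in self.members})


def _transcript_map(catalogs: Sequence[TranscriptCatalog]) -> dict[str, Transcript]:
    by_id: dict[str, Transcript] = {}
    for cat in catalogs:
        for t in cat:
            if t.id in by_id:
                raise ValueError(
                    f"transcript id {t.id!r} appears in more than one catalog; "
                    "ids must be unique across samples")
            by_id[t.id] = t
    return by_id


def similarity_from_hits(hits: Sequence[HomologyHit],
                         catalogs: Sequence[TranscriptCatalog]) -> list[SimilarityRecord]:
    """Condense all-vs-all cross-sample hits into per-pair similarity records.

    Keeps the best-E-value hit per direction of each unordered pair; a pair
    is reciprocal when hits exist in both directions.  Hits referencing
    unknown transcripts, or two transcripts of the same sample, are skipped.
    """
    by_id = _transcript_map(catalogs)
    best: dict[tuple[str, str], HomologyHit] = {}  # ordered (query, subject)
    skipped = 0
    for h in hits:
        if h.query_id not in by_id or h.subject_id not in by_id:
            skipped += 1
            continue
        if h.query_id == h.subject_id:
            continue
        if by_id[h.query_id].sample == by_id[h.subject_id].sample:
            continue
        key = (h.query_id, h.subject_id)
        if key not in best or h.evalue < best[key].evalue:
            best[key] = h
    if skipped:
        logger.warning("similarity_from_hits: %d hits referenced unknown "
                       "transcripts (skipped)", skipped)

    records: list[SimilarityRecord] = []
    for a, b in sorted({tuple(sorted(k)) for k in best}):
        ab = best.get((a, b))
        ba = best.get((b, a))
        reciprocal = ab is not None and ba is not None
        len_a = by_id[a].spliced_length
        len_b = by_id[b].spliced_length
        cov_a = (ab.alignment_length if ab else ba.alignment_length) / len_a
        cov_b = (ba.alignment_length if ba else ab.alignment_length) / len_b
        idents = [h.percent_identity for h in (ab, ba) if h is not None]
        records.append(SimilarityRecord(
            transcript_a=a, transcript_b=b,
            coverage_a=min(cov_a, 1.0), coverage_b=min(cov_b, 1.0),
            identity=min(idents), reciprocal=reciprocal,
        ))
    return records


def _sort_key(t: Transcript) -> tuple:
    return (t.chrom, t.start, t.sample, t.id)


def _components_to_orthogroups(graph: nx.Graph, by_id: dict[str, Transcript],
                               definition: int,
                               split_fn=None) -> list[Orthogroup]:
    """Connected components -> orthogroups with deterministic ids.

    ``split_fn``, when given, takes a sorted member list and yields sub-lists
    (greedy window splitting).  Components that are not cliques are flagged.
    """
    groups: list[list[str]] = []
    for comp in nx.connected_components(graph):
        members = sorted(comp, key=lambda tid: _sort_key(by_id[tid]))
        if split_fn is None:
            groups.append(members)
        else:
            groups.extend(split_fn(members))
    groups.sort(key=lambda ms: _sort_key(by_id[ms[0]]))

    out = []
    for i, members in enumerate(groups):
        clique = all(
            graph.has_edge(a, b)
            for j, a in enumerate(members) for b in members[j + 1:]
        )
        if not clique:
            logger.info("orthogroup OG%07d (def %d) is not a clique", i + 1, definition)
        out.append(Orthogroup(
            id=f"OG{i + 1:07d}", definition=definition,
            members=tuple((by_id[m].sample, m) for m in members),
            is_clique=clique,
        ))
    return out


def _similarity_graph(transcripts: Sequence[Transcript],
                      sims: Sequence[SimilarityRecord],
                      min_coverage: float, min_identity: float) -> tuple[nx.Graph, dict]:
    by_id = {t.id: t for t in sorted(transcripts, key=_sort_key)}
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for rec in sims:
        if rec.transcript_a not in by_id or rec.transcript_b not in by_id:
            continue
        if (rec.reciprocal
                and rec.coverage_a >= min_coverage
                and rec.coverage_b >= min_coverage
                and rec.identity >= min_identity):
            graph.add_edge(rec.transcript_a, rec.transcript_b)
    return graph, by_id


def cluster_definition1(transcripts: Sequence[Transcript],
                        sims: Sequence[SimilarityRecord],
                        min_coverage: float = 0.70,
                        min_identity: float = 75.0) -> list[Orthogroup]:
    """Orthogroups by reciprocal sequence similarity of spliced transcripts."""
    graph, by_id = _similarity_graph(transcripts, sims, min_coverage, min_identity)
    return _components_to_orthogroups(graph, by_id, definition=1)


def _greedy_window_split(members: list[str], keys, window: float):
    """Split a sorted member list so every emitted group spans <= window.

    ``keys`` maps a transcript id to one or more coordinates; a new group is
    opened as soon as adding the next member would stretch any coordinate's
    span (max - min) beyond the window.
    """
    if not members:
        return
    group = [members[0]]
    lo = list(keys(members[0]))
    hi = list(lo)
    for tid in members[1:]:
        ks = keys(tid)
        new_lo = [min(a, k) for a, k in zip(lo, ks)]
        new_hi = [max(a, k) for a, k in zip(hi, ks)]
        if any(h - l > window for l, h in zip(new_lo, new_hi)):
            yield group
            group, lo, hi = [tid], list(ks), list(ks)
        else:
            group.append(tid)
            lo, hi = new_lo, new_hi
    yield group


def cluster_definition2(transcripts: Sequence[Transcript],
                        sims: Sequence[SimilarityRecord],
                        min_coverage: float = 0.70,
                        min_identity: float = 75.0,
                        tss_window: float = 500.0) -> list[Orthogroup]:
    """Definition 1 edges restricted to co-located transcription start sites.

    Edges additionally require the same chromosome and strand-aware TSSs at
    most ``tss_window`` apart; components whose total TSS span still exceeds
    the window are split greedily by ascending TSS.
    """
    graph, by_id = _similarity_graph(transcripts, sims, min_coverage, min_identity)
    for a, b in list(graph.edges):
        ta, tb = by_id[a], by_id[b]
        if ta.chrom != tb.chrom or abs(ta.tss - tb.tss) > tss_window:
            graph.remove_edge(a, b)

    def split(members: list[str]):
        members = sorted(members, key=lambda tid: (by_id[tid].tss, _sort_key(by_id[tid])))
        yield from _greedy_window_split(members, lambda tid: (by_id[tid].tss,), tss_window)

    return _components_to_orthogroups(graph, by_id, definition=2, split_fn=split)


def cluster_definition3(transcripts: Sequence[Transcript],
                        window: float = 500.0,
                        require_same_strand: bool = True) -> list[Orthogroup]:
    """Positional orthogroups of unspliced transcripts.

    Edges join transcripts of different samples on the same chromosome (and
    strand, by default) whose genomic starts differ by at most ``window`` and
    whose ends differ by at most ``window``; no sequence similarity is used.
    Components whose start-span or end-span exceeds the window are split
    greedily by ascending (start, end).
    """
    by_id = {t.id: t for t in sorted(transcripts, key=_sort_key)}
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    # bucket by (chrom[, strand]) to avoid the full quadratic sweep
    buckets: dict[tuple, list[Transcript]] = {}
    for t in by_id.values():
        key = (t.chrom, t.strand) if require_same_strand else (t.chrom,)
        buckets.setdefault(key, []).append(t)
    for bucket in buckets.values():
        bucket.sort(key=lambda t: t.start)
        for i, ta in enumerate(bucket):
            for tb in bucket[i + 1:]:
                if tb.start - ta.start > window:
                    break
                if ta.sample != tb.sample and abs(ta.end - tb.end) <= window:
                    graph.add_edge(ta.id, tb.id)

    def split(members: list[str]):
        members = sorted(members,
                         key=lambda tid: (by_id[tid].start, by_id[tid].end, _sort_key(by_id[tid])))
        yield from _greedy_window_split(
            members, lambda tid: (by_id[tid].start, by_id[tid].end), window)

    return _components_to_orthogroups(graph, by_id, definition=3, split_fn=split)


def nucleotide_sharing(catalogs: Sequence[TranscriptCatalog]) -> np.ndarray:
    """Count transcribed positions by the number of samples sharing them.

    Strand-aware: for every genomic position (chrom, strand) covered by at
    least one sample's unspliced transcripts, count the covering samples;
    entry ``k-1`` of the result is the number of positions covered by exactly
    ``k`` samples.  Two 200 nt transcripts overlapping by 50 nt in two
    samples therefore contribute 50 to N2 and 2*150 to N1.
    """
    n = len(catalogs)
    counts = np.zeros(n, dtype=np.int64)
    events: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for cat in catalogs:
        per_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for t in cat:
            per_key.setdefault((t.chrom, t.strand), []).append((t.start, t.end))
        # union per sample so duplicated coverage within a sample counts once
        for key, ivs in per_key.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            evs = events.setdefault(key, [])
            for s, e in merged:
                evs.append((s, +1))
                evs.append((e, -1))
    for evs in events.values():
        evs.sort()
        depth = 0
        prev = None
        for pos, delta in evs:
            if depth > 0 and pos > prev:
                counts[depth - 1] += pos - prev
            depth += delta
            prev = pos
    return counts


def spectrum_from_orthogroups(orthogroups: Sequence[Orthogroup],
                              sample_list: Sequence[str]) -> FrequencySpectrum:
    """Frequency spectrum of orthogroup occupancy over ``sample_list``.

    Occupancy counts only samples in ``sample_list`` (e.g. excluding an
    outgroup sample); orthogroups with no member in the list are dropped.
    """
    samples = set(sample_list)
    if not samples:
        raise ValueError("sample_list must be non-empty")
    occupancies = []
    for og in orthogroups:
        k = len({s for s, _ in og.members if s in samples})
        if k > 0:
            occupancies.append(k)
    return FrequencySpectrum.from_counts(occupancies, n=len(samples))


def orthogroups_to_frame(orthogroups: Sequence[Orthogroup]) -> pd.DataFrame:
    """Tidy membership table (og_id, definition, sample, transcript_id)."""
    rows = [
        {"og_id": og.id, "definition": og.definition, "sample": s, "transcript_id": tid}
        for og in orthogroups for s, tid in og.members
    ]
    return pd.DataFrame(rows, columns=["og_id", "definition", "sample", "transcript_id"])
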