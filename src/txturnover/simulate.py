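"""Synthetic data generation: coalescent gain/loss simulator and toy catalogs.

Two generators cover the two halves of the pipeline:

- :func:`simulate_coalescent_presence` realises the infinitely-many-genes
  process on a Kingman genealogy and returns a transcripts-by-samples 0/1
  presence matrix.  The default "exact" mode simulates individual gain
  events with uniform arrival times and exponential lifetimes along each
  branch, so it doubles as an independent oracle for the analytic spectrum;
  a distributionally equivalent Poisson-thinning mode is faster.
- :func:`generate_toy_dataset` emits small multi-sample transcript catalogs
  with a matching reference annotation, planted orthogroups (with
  configurable coordinate jitter and sequence divergence) and ground-truth
  tables, exercising the filtering/classification/clustering front-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import HomologyHit, Transcript, TranscriptCatalog, write_transcript_gtf
from .model import Scale, TurnoverParams, expected_spectrum
from .orthogroups import SimilarityRecord
from .spectra import FrequencySpectrum

__all__ = [
    "PresenceMatrix",
    "simulate_coalescent_presence",
    "simulate_presence",
    "simulate_poisson_spectrum",
    "ToyConfig",
    "PlantedGroup",
    "ToyDataset",
    "generate_toy_dataset",
]


@dataclass
class PresenceMatrix:
    """Simulated transcripts-by-samples 0/1 matrix with per-row truth tags."""

    matrix: np.ndarray                 # shape (n_transcripts, n_samples)
    truth: tuple[str, ...]             # "class<i>" or "fixed" per row
    params: dict
    seed: int | None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("presence matrix must be 2-D")
        if len(self.truth) != self.matrix.shape[0]:
            raise ValueError("one truth tag per row required")
        rs = self.matrix.sum(axis=1)
        if self.matrix.shape[0] and rs.min() < 1:
            raise ValueError("all-zero rows must be dropped")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def spectrum(self) -> FrequencySpectrum:
        n = self.n_samples
        d = np.bincount(self.matrix.sum(axis=1), minlength=n + 1)[1:]
        return FrequencySpectrum(n=n, d=tuple(int(x) for x in d))


def _kingman_tree(n: int, rng: np.random.Generator):
    """Random Kingman genealogy for ``n`` leaves.

    Returns (children, root) where ``children[node]`` is a list of
    (child, branch_length) pairs; leaves are nodes ``0..n-1``.
    """
    heights = [0.0] * n
    children: list[list] = [[] for _ in range(n)]
    active = list(range(n))
    t = 0.0
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(2.0 / (j * (j - 1)))
        i1, i2 = sorted(rng.choice(j, size=2, replace=False))
        b = active.pop(i2)
        a = active.pop(i1)
        children.append([(a, t - heights[a]), (b, t - heights[b])])
        heights.append(t)
        active.append(len(children) - 1)
    return children, active[0]


def simulate_coalescent_presence(theta: float, rho: float, c_fixed: int,
                                 n: int, seed=None, mode: str = "exact",
                                 rng: np.random.Generator | None = None,
                                 ) -> PresenceMatrix:
    """One realisation of the gain/loss process on a random genealogy.

    Gains arrive at rate ``theta/2`` per lineage and each transcript is
    lost at rate ``rho/2`` per lineage, in coalescent time; the root carries
    the stationary Poisson(theta/rho) complement.  ``c_fixed`` all-ones rows
    are appended.  ``mode="exact"`` simulates gain times uniformly on each
    branch with exponential lifetimes; ``mode="thinning"`` draws the
    (equivalent) Poisson number of surviving gains directly.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    if rho <= 0:
        raise ValueError("rho must be positive")
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if mode not in ("exact", "thinning"):
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(seed)

    children, root = _kingman_tree(n, rng)
    n_root = rng.poisson(theta / rho) if theta > 0 else 0
    next_id = n_root
    genes: dict[int, np.ndarray] = {root: np.arange(n_root)}
    leaf_genes: dict[int, np.ndarray] = {}

    stack = [root]
    while stack:
        node = stack.pop()
        parent_genes = genes.pop(node)
        if not children[node]:
            leaf_genes[node] = parent_genes
            continue
        for child, length in children[node]:
            surv = parent_genes[
                rng.random(parent_genes.size) < math.exp(-rho * length / 2.0)]
            if theta > 0:
                if mode == "exact":
                    m = rng.poisson(theta * length / 2.0)
                    arrival = rng.uniform(0.0, length, size=m)
                    lifetime = rng.exponential(2.0 / rho, size=m)
                    m_surv = int((lifetime > length - arrival).sum())
                else:
                    m_surv = rng.poisson(
                        theta / rho * -math.expm1(-rho * length / 2.0))
                new = np.arange(next_id, next_id + m_surv)
                next_id += m_surv
            else:
                new = np.empty(0, dtype=int)
            genes[child] = np.concatenate([surv, new])
            stack.append(child)

    present = sorted(set().union(*[set(g.tolist()) for g in leaf_genes.values()]))
    idx = {g: i for i, g in enumerate(present)}
    matrix = np.zeros((len(present) + c_fixed, n), dtype=np.int8)
    for leaf in range(n):
        for g in leaf_genes[leaf]:
            matrix[idx[g], leaf] = 1
    matrix[len(present):, :] = 1
    truth = ("class1",) * len(present) + ("fixed",) * c_fixed
    return PresenceMatrix(
        matrix=matrix, truth=truth,
        params={"theta": theta, "rho": rho, "c_fixed": c_fixed, "n": n, "mode": mode},
        seed=seed if isinstance(seed, int) else None,
    )


def simulate_presence(params: TurnoverParams, n: int, seed=None,
                      mode: str = "exact") -> PresenceMatrix:
    """Multi-class wrapper: one presence matrix per class, stacked."""
    rng = np.random.default_rng(seed)
    blocks, truth = [], []
    for i, cl in enumerate(params.classes, start=1):
        pm = simulate_coalescent_presence(cl.theta, cl.rho, 0, n, rng=rng, mode=mode)
        blocks.append(pm.matrix)
        truth.extend([f"class{i}"] * pm.matrix.shape[0])
    fixed = int(round(params.c_fixed))
    blocks.append(np.ones((fixed, n), dtype=np.int8))
    truth.extend(["fixed"] * fixed)
    return PresenceMatrix(
        matrix=np.vstack(blocks), truth=tuple(truth),
        params={"classes": [tuple(c) for c in params.classes],
                "c_fixed": fixed, "n": n, "mode": mode},
        seed=seed if isinstance(seed, int) else None,
    )


def simulate_poisson_spectrum(params: TurnoverParams, n: int,
                              seed=None) -> FrequencySpectrum:
    """Fast spectrum generator: independent Poisson draws around the
    analytic expectation (distributionally matching the coalescent
    simulator's marginal means)."""
    rng = np.random.default_rng(seed)
    t = expected_spectrum(params, n).as_array()
    d = rng.poisson(t)
    return FrequencySpectrum(n=n, d=tuple(int(x) for x in d))


# --------------------------------------------------------------------------
# toy transcript catalogs with planted ground truth
# --------------------------------------------------------------------------

CATEGORY_CHOICES = ("intergenic", "antisense", "intronic",
                    "exon_longer", "ncRNA", "pseudogenic")


@dataclass(frozen=True)
class PlantedGroup:
    """Specification of one planted orthogroup."""

    og_id: str
    category: str
    samples: tuple[str, ...]
    tss_offsets: tuple[float, ...] | None = None   # per sample; overrides jitter
    end_offsets: tuple[float, ...] | None = None
    divergence: float | None = None                # overrides config divergence


@dataclass(frozen=True)
class ToyConfig:
    """Conditions of a toy dataset.

    Defaults plant one orthogroup per category in every sample, with no
    coordinate jitter and no sequence divergence, on a single synthetic
    chromosome; ``groups`` overrides the automatic layout entirely.
    """

    n_samples: int = 3
    counts: Mapping[str, int] = field(
        default_factory=lambda: {c: 1 for c in CATEGORY_CHOICES})
    tss_jitter_sd: float = 0.0
    end_jitter_sd: float = 0.0
    divergence: float = 0.0            # fraction; identity = 100*(1-divergence)
    splice_variant_prob: float = 0.0
    transcript_length: int = 1000
    locus_spacing: int = 12_000
    chrom: str = "sim_chr1"
    n_conserved_decoys: int = 0        # transcripts with an outgroup homology hit
    n_low_tpm_decoys: int = 0          # transcripts below the 0.5 TPM threshold
    groups: tuple[PlantedGroup, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.tss_jitter_sd < 0 or self.end_jitter_sd < 0:
            raise ValueError("jitter standard deviations must be non-negative")
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must be in [0, 1]")
        bad = set(self.counts) - set(CATEGORY_CHOICES)
        if bad:
            raise ValueError(f"unknown categories in counts: {bad}")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.n_samples))


@dataclass
class ToyDataset:
    """In-memory toy dataset; ``write`` emits the standard text files."""

    config: ToyConfig
    seed: int | None
    catalogs: dict[str, TranscriptCatalog]
    annotation_lines: tuple[str, ...]
    sims: list[SimilarityRecord]
    outgroup_hits: list[HomologyHit]
    truth: pd.DataFrame                # transcript_id, sample, og_id, category

    def write(self, directory) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sample, cat in self.catalogs.items():
            p = directory / f"{sample}.gtf"
            write_transcript_gtf(cat, p)
            paths[f"gtf:{sample}"] = p
        p = directory / "annotation.gtf"
        p.write_text("".join(self.annotation_lines))
        paths["annotation"] = p
        sim_df = pd.DataFrame([
            {"transcript_a": s.transcript_a, "transcript_b": s.transcript_b,
             "coverage_a": s.coverage_a, "coverage_b": s.coverage_b,
             "identity": s.identity, "reciprocal": s.reciprocal}
            for s in self.sims])
        p = directory / "similarity.tsv"
        sim_df.to_csv(p, sep="\t", index=False)
        paths["similarity"] = p
        p = directory / "truth.tsv"
        self.truth.to_csv(p, sep="\t", index=False)
        paths["truth"] = p
        return paths


def _gtf_line(chrom, feature, start, end, strand, attrs) -> str:
    return "\t".join([chrom, "toy", feature, str(start + 1), str(end),
                      ".", strand, ".", attrs]) + "\n"


def _plan_groups(config: ToyConfig) -> tuple[PlantedGroup, ...]:
    groups = []
    i = 0
    for category in CATEGORY_CHOICES:
        for _ in range(int(config.counts.get(category, 0))):
            i += 1
            groups.append(PlantedGroup(
                og_id=f"TRUE_OG{i:04d}", category=category,
                samples=config.samples))
    return tuple(groups)


def generate_toy_dataset(config: ToyConfig | None = None, seed=None) -> ToyDataset:
    """Build catalogs, annotation, similarity and truth tables from a config.

    Every planted orthogroup occupies one locus, ``locus_spacing`` apart on
    one chromosome; the reference annotation is laid out so each group's
    transcripts fall in their planted genomic-position category.  Similarity
    records are emitted for all cross-sample pairs within a group (identity
    ``100*(1-divergence)``, coverage from the actual interval overlap);
    transcripts of different groups share no similarity record, mimicking a
    BLAST search with no cross-locus hits.
    """
    config = config or ToyConfig()
    rng = np.random.default_rng(seed)
    groups = config.groups if config.groups is not None else _plan_groups(config)

    ann_lines: list[str] = []
    per_sample: dict[str, list[Transcript]] = {s: [] for s in config.samples}
    truth_rows: list[dict] = []
    sims: list[SimilarityRecord] = []
    hits: list[HomologyHit] = []
    length = config.transcript_length

    def annotate(category: str, base: int, gid: str) -> None:
        chrom = config.chrom
        if category == "antisense":
            gs, ge = base + length // 2, base + length * 3
            attrs = f'gene_id "{gid}";'
            ann_lines.append(_gtf_line(chrom, "gene", gs, ge, "-", attrs))
            ann_lines.append(_gtf_line(chrom, "exon", gs, ge, "-", attrs))
        elif category == "exon_longer":
            gs, ge = base + length // 2, base + length * 3
            attrs = f'gene_id "{gid}";'
            ann_lines.append(_gtf_line(chrom, "gene", gs, ge, "+", attrs))
            ann_lines.append(_gtf_line(chrom, "exon", gs, ge, "+", attrs))
        elif category == "intronic":
            gs, ge = base - 3000, base + length + 3000
            attrs = f'gene_id "{gid}";'
            ann_lines.append(_gtf_line(chrom, "gene", gs, ge, "+", attrs))
            ann_lines.append(_gtf_line(chrom, "exon", gs, gs + 500, "+", attrs))
            ann_lines.append(_gtf_line(chrom, "exon", ge - 500, ge, "+", attrs))
        elif category == "ncRNA":
            ann_lines.append(_gtf_line(chrom, "ncRNA", base + 200, base + length - 200,
                                       "+", f'gene_id "{gid}";'))
        elif category == "pseudogenic":
            ann_lines.append(_gtf_line(chrom, "pseudogene", base + 200,
                                       base + length - 200, "+", f'gene_id "{gid}";'))
        # intergenic: nothing annotated at the locus

    def emit_group(gi: int, group: PlantedGroup) -> None:
        base = 20_000 + gi * config.locus_spacing
        annotate(group.category, base, f"ann_{group.og_id}")
        divergence = (group.divergence if group.divergence is not None
                      else config.divergence)
        members: list[Transcript] = []
        for si, sample in enumerate(group.samples):
            if group.tss_offsets is not None:
                dstart = group.tss_offsets[si]
            else:
                dstart = rng.normal(0, config.tss_jitter_sd) if config.tss_jitter_sd else 0.0
            if group.end_offsets is not None:
                dend = group.end_offsets[si]
            else:
                dend = rng.normal(0, config.end_jitter_sd) if config.end_jitter_sd else 0.0
            start = int(round(base + dstart))
            end = int(round(base + length + dend))
            tid = f"{sample}.{group.og_id}"
            tx = Transcript(
                id=tid, sample=sample, chrom=config.chrom,
                start=start, end=end, strand="+",
                exons=((start, end),), precursor_id=f"{sample}.g.{group.og_id}",
                tpm=float(np.round(rng.uniform(1.0, 50.0), 2)))
            per_sample[sample].append(tx)
            members.append(tx)
            truth_rows.append({"transcript_id": tid, "sample": sample,
                               "og_id": group.og_id, "category": group.category})
            if rng.random() < config.splice_variant_prob:
                vstart = start
                vend = start + max(length // 2, 10)
                vid = f"{tid}.v2"
                per_sample[sample].append(Transcript(
                    id=vid, sample=sample, chrom=config.chrom,
                    start=vstart, end=vend, strand="+",
                    exons=((vstart, vstart + length // 4),
                           (vend - length // 4, vend)),
                    precursor_id=f"{sample}.g.{group.og_id}",
                    tpm=float(np.round(rng.uniform(1.0, 50.0), 2))))
                truth_rows.append({"transcript_id": vid, "sample": sample,
                                   "og_id": group.og_id, "category": group.category})
        identity = 100.0 * (1.0 - divergence)
        for i, ta in enumerate(members):
            for tb in members[i + 1:]:
                overlap = min(ta.end, tb.end) - max(ta.start, tb.start)
                if overlap <= 0:
                    continue
                sims.append(SimilarityRecord(
                    transcript_a=ta.id, transcript_b=tb.id,
                    coverage_a=min(overlap / ta.spliced_length, 1.0),
                    coverage_b=min(overlap / tb.spliced_length, 1.0),
                    identity=identity, reciprocal=True))

    for gi, group in enumerate(groups):
        emit_group(gi, group)

    # decoys live on intergenic loci beyond the planted groups
    decoy_base = 20_000 + len(groups) * config.locus_spacing
    decoy_i = 0
    for kind, count in (("conserved", config.n_conserved_decoys),
                        ("low_tpm", config.n_low_tpm_decoys)):
        for _ in range(count):
            decoy_i += 1
            base = decoy_base + decoy_i * config.locus_spacing
            for sample in config.samples:
                tid = f"{sample}.DECOY_{kind.upper()}{decoy_i:03d}"
                tpm = 0.1 if kind == "low_tpm" else float(np.round(rng.uniform(1, 20), 2))
                per_sample[sample].append(Transcript(
                    id=tid, sample=sample, chrom=config.chrom,
                    start=base, end=base + length, strand="+",
                    exons=((base, base + length),),
                    precursor_id=f"{sample}.g.decoy{decoy_i}", tpm=tpm))
                truth_rows.append({"transcript_id": tid, "sample": sample,
                                   "og_id": f"DECOY_{kind}{decoy_i:03d}",
                                   "category": "decoy_" + kind})
                if kind == "conserved":
                    hits.append(HomologyHit(
                        query_id=tid, subject_id=f"outgroup_gene{decoy_i}",
                        percent_identity=95.0, alignment_length=length,
                        query_start=1, query_end=length,
                        subject_start=1, subject_end=length, evalue=1e-30))

    catalogs = {
        s: TranscriptCatalog(sample=s, transcripts=tuple(txs),
                             provenance=(f"generate_toy_dataset(seed={seed})",))
        for s, txs in per_sample.items()
    }
    truth = pd.DataFrame(truth_rows,
                         columns=["transcript_id", "sample", "og_id", "category"])
    return ToyDataset(
        config=config, seed=seed if isinstance(seed, int) else None,
        catalogs=catalogs, annotation_lines=tuple(ann_lines),
        sims=sims, outgroup_hits=hits, truth=truth,
    )
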