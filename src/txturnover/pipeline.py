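"""End-to-end orchestration: filters -> classification -> orthogroups ->
frequency spectra -> gain/loss rate fits.

`run_pipeline` is a pure function of (input files, config, seed): it reads
per-sample transcript GTFs, applies the de novo filters, classifies
transcripts against a reference annotation, clusters them into orthogroups
under the requested definitions, builds frequency spectra (overall and per
genomic region) and fits the turnover model, writing everything as
TSV/JSON into one results directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .catalog import (TranscriptCatalog, filter_by_homology, filter_by_tpm,
                      merge_splice_variants, read_blast_tabular,
                      read_transcript_gtf)
from .fitting import fit_per_region, fit_spectrum
from .model import PopulationScaling
from .orthogroups import (SimilarityRecord, cluster_definition1,
                          cluster_definition2, cluster_definition3,
                          orthogroups_to_frame, similarity_from_hits,
                          spectrum_from_orthogroups)
from .positions import build_annotation_index, classify_catalog
from .spectra import FrequencySpectrum

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_similarity_tsv"]

DEFAULT_COVERAGE_FRACTIONS = {"intergenic": 0.68, "ncRNA": 0.09}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    gtf_paths: Mapping[str, str]                 # sample -> transcript GTF
    annotation_path: str | None = None
    outgroup_hit_paths: Sequence[str] = ()       # staged homology screens
    similarity_path: str | None = None           # precomputed similarity TSV
    cross_sample_hit_path: str | None = None     # or all-vs-all BLAST tabular
    out_dir: str = "txturnover_results"

    tpm_threshold: float = 0.5
    evalue_cutoff: float = 1e-2
    min_coverage: float = 0.70
    min_identity: float = 75.0
    window: float = 500.0
    definitions: Sequence[int] = (1, 2, 3)
    n_classes: Sequence[int] = (1, 2)

    effective_population_size: float = 900_000.0
    generations_per_year: float = 26.0

    outgroup_samples: Sequence[str] = ()         # excluded from the spectrum
    coverage_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVERAGE_FRACTIONS))
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.gtf_paths:
            raise ValueError("gtf_paths must name at least one sample")
        bad = set(self.definitions) - {1, 2, 3}
        if bad:
            raise ValueError(f"unknown orthogroup definitions: {bad}")

    @property
    def scaling(self) -> PopulationScaling:
        return PopulationScaling(self.effective_population_size,
                                 self.generations_per_year)

    @property
    def spectrum_samples(self) -> list[str]:
        return [s for s in self.gtf_paths if s not in set(self.outgroup_samples)]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def load_similarity_tsv(path) -> list[SimilarityRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SimilarityRecord(
            transcript_a=str(r.transcript_a), transcript_b=str(r.transcript_b),
            coverage_a=float(r.coverage_a), coverage_b=float(r.coverage_b),
            identity=float(r.identity), reciprocal=bool(r.reciprocal))
        for r in df.itertuples(index=False)
    ]


def _stage(name: str):
    logger.info("pipeline stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle also written
    to ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": {k: (dict(v) if isinstance(v, Mapping) else
                                   list(v) if isinstance(v, (list, tuple)) else v)
                               for k, v in asdict(config).items()},
                    "version": __version__}

    _stage("read + filter transcript catalogs")
    hits_stages = [read_blast_tabular(p) for p in config.outgroup_hit_paths]
    catalogs: dict[str, TranscriptCatalog] = {}
    for sample, path in config.gtf_paths.items():
        cat = read_transcript_gtf(path, sample)
        cat = filter_by_tpm(cat, config.tpm_threshold)
        for hits in hits_stages:
            cat = filter_by_homology(cat, hits, config.evalue_cutoff)
        catalogs[sample] = cat
    bundle["catalog_sizes"] = {s: len(c) for s, c in catalogs.items()}

    merged = {s: merge_splice_variants(c) for s, c in catalogs.items()}
    bundle["merged_sizes"] = {s: len(c) for s, c in merged.items()}

    categories = None
    if config.annotation_path:
        _stage("classify genomic positions")
        index = build_annotation_index(config.annotation_path)
        frames = [classify_catalog(merged[s], index) for s in merged]
        categories = pd.concat(frames, ignore_index=True)
        categories.to_csv(out_dir / "categories.tsv", sep="\t", index=False)
        bundle["category_counts"] = (
            categories.groupby("category")["transcript_id"].count().to_dict())

    sims: list[SimilarityRecord] = []
    if config.similarity_path:
        sims = load_similarity_tsv(config.similarity_path)
    elif config.cross_sample_hit_path:
        sims = similarity_from_hits(
            read_blast_tabular(config.cross_sample_hit_path),
            list(catalogs.values()))

    _stage("cluster orthogroups + build spectra + fit")
    spliced = [t for c in catalogs.values() for t in c]
    unspliced = [t for c in merged.values() for t in c]
    samples = config.spectrum_samples
    bundle["fits"] = {}
    bundle["spectra"] = {}
    for definition in config.definitions:
        try:
            if definition == 1:
                ogs = cluster_definition1(spliced, sims, config.min_coverage,
                                          config.min_identity)
            elif definition == 2:
                ogs = cluster_definition2(spliced, sims, config.min_coverage,
                                          config.min_identity, config.window)
            else:
                ogs = cluster_definition3(unspliced, config.window)
        except Exception as exc:
            raise RuntimeError(f"clustering stage (definition {definition}) "
                               f"failed: {exc}") from exc
        orthogroups_to_frame(ogs).to_csv(
            out_dir / f"orthogroups_def{definition}.tsv", sep="\t", index=False)
        spectrum = spectrum_from_orthogroups(ogs, samples)
        spectrum.to_tsv(out_dir / f"spectrum_def{definition}.tsv")
        bundle["spectra"][f"def{definition}"] = list(spectrum.d)
        bundle["fits"][f"def{definition}"] = {}
        if spectrum.n < 2 or spectrum.total == 0:
            logger.warning("definition %d: spectrum not fittable", definition)
            continue
        for k in config.n_classes:
            res = fit_spectrum(spectrum, n_classes=k, scaling=config.scaling)
            bundle["fits"][f"def{definition}"][f"{k}_class"] = res.to_dict()

        if categories is not None and definition == max(config.definitions):
            _stage("per-region spectra + fits")
            cat_of = dict(zip(categories["transcript_id"], categories["category"]))
            by_region: dict[str, list] = {}
            for og in ogs:
                cats = {cat_of.get(tid) for _, tid in og.members} - {None}
                if len(cats) == 1:
                    by_region.setdefault(cats.pop(), []).append(og)
            region_spectra = {
                region: spectrum_from_orthogroups(o, samples)
                for region, o in sorted(by_region.items())
            }
            table = fit_per_region(region_spectra, config.coverage_fractions,
                                   config.scaling)
            table.to_csv(out_dir / "per_region_fits.tsv", sep="\t", index=False)
            bundle["per_region"] = table.to_dict(orient="records")

    with open(out_dir / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=str)
    return bundle
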