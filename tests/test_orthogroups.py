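"""Orthogroup clustering, nucleotide sharing, and frequency spectra."""

import random

import numpy as np
import pytest

from txturnover import (FrequencySpectrum, HomologyHit, Orthogroup,
                        SimilarityRecord, Transcript, TranscriptCatalog,
                        cluster_definition1, cluster_definition2,
                        cluster_definition3, nucleotide_sharing,
                        similarity_from_hits, spectrum_from_orthogroups)


def _tx(tid, start, end, sample, strand="+", chrom="chr1"):
    return Transcript(id=tid, sample=sample, chrom=chrom, start=start, end=end,
                      strand=strand, exons=((start, end),), precursor_id=tid)


def _sim(a, b, cov_a=0.9, cov_b=0.9, identity=90.0, reciprocal=True):
    return SimilarityRecord(transcript_a=a, transcript_b=b, coverage_a=cov_a,
                            coverage_b=cov_b, identity=identity,
                            reciprocal=reciprocal)


def _memberships(ogs):
    return sorted((frozenset(tid for _, tid in og.members) for og in ogs),
                  key=sorted)


class TestSimilarityFromHits:
    @staticmethod
    def _hit(q, s, length, identity, evalue=1e-20):
        return HomologyHit(query_id=q, subject_id=s, percent_identity=identity,
                           alignment_length=length, query_start=1, query_end=length,
                           subject_start=1, subject_end=length, evalue=evalue)

    def test_coverage_and_identity(self):
        cats = [TranscriptCatalog("A", (_tx("a1", 0, 200, "A"),)),
                TranscriptCatalog("B", (_tx("b1", 0, 200, "B"),))]
        recs = similarity_from_hits(
            [self._hit("a1", "b1", 150, 80.0), self._hit("b1", "a1", 150, 80.0)],
            cats)
        (rec,) = recs
        assert rec.coverage_a == pytest.approx(0.75)
        assert rec.coverage_b == pytest.approx(0.75)
        assert rec.identity == pytest.approx(80.0)
        assert rec.reciprocal

    def test_one_directional_hit_not_reciprocal(self):
        cats = [TranscriptCatalog("A", (_tx("a1", 0, 200, "A"),)),
                TranscriptCatalog("B", (_tx("b1", 0, 200, "B"),))]
        (rec,) = similarity_from_hits([self._hit("a1", "b1", 150, 80.0)], cats)
        assert not rec.reciprocal

    def test_best_evalue_kept_per_direction(self):
        cats = [TranscriptCatalog("A", (_tx("a1", 0, 200, "A"),)),
                TranscriptCatalog("B", (_tx("b1", 0, 200, "B"),))]
        hits = [self._hit("a1", "b1", 100, 70.0, evalue=1e-5),
                self._hit("a1", "b1", 180, 95.0, evalue=1e-30),
                self._hit("b1", "a1", 160, 90.0, evalue=1e-10)]
        (rec,) = similarity_from_hits(hits, cats)
        assert rec.coverage_a == pytest.approx(0.9)   # 180/200 from the best hit
        assert rec.identity == pytest.approx(90.0)    # min over directions


class TestDefinition1:
    def test_pair_above_thresholds(self):
        txs = [_tx("a", 0, 100, "A"), _tx("b", 0, 100, "B")]
        ogs = cluster_definition1(txs, [_sim("a", "b", 0.75, 0.72, 80.0)])
        assert len(ogs) == 1 and ogs[0].occupancy == 2

    def test_coverage_below_threshold_on_one_side(self):
        txs = [_tx("a", 0, 100, "A"), _tx("b", 0, 100, "B")]
        ogs = cluster_definition1(txs, [_sim("a", "b", 0.69, 0.9, 80.0)])
        assert len(ogs) == 2

    def test_non_reciprocal_pair_not_linked(self):
        txs = [_tx("a", 0, 100, "A"), _tx("b", 0, 100, "B")]
        ogs = cluster_definition1(txs, [_sim("a", "b", reciprocal=False)])
        assert len(ogs) == 2

    def test_planted_group_recovered(self):
        samples = ["A", "B", "C", "D"]
        txs = [_tx(f"{s}.t", 1000, 2000, s) for s in samples]
        sims = [_sim(f"{a}.t", f"{b}.t", 0.9, 0.9, 90.0)
                for i, a in enumerate(samples) for b in samples[i + 1:]]
        ogs = cluster_definition1(txs, sims)
        assert len(ogs) == 1 and ogs[0].occupancy == 4 and ogs[0].is_clique


class TestDefinition2:
    def test_distant_tss_breaks_def1_edge(self):
        txs = [_tx("a", 0, 5000, "A"), _tx("b", 600, 5600, "B")]
        sims = [_sim("a", "b", 0.88, 0.88, 95.0)]
        assert len(cluster_definition1(txs, sims)) == 1
        assert len(cluster_definition2(txs, sims)) == 2

    def test_close_tss_kept(self):
        txs = [_tx("a", 0, 5000, "A"), _tx("b", 100, 5100, "B")]
        sims = [_sim("a", "b", 0.95, 0.95, 95.0)]
        assert len(cluster_definition2(txs, sims)) == 1

    def test_count_never_below_def1(self):
        rng = random.Random(0)
        samples = ["A", "B", "C"]
        txs, sims = [], []
        for g in range(8):
            base = 10_000 * g
            group = [_tx(f"{s}.g{g}", base + rng.randrange(0, 1200),
                         base + 6000, s) for s in samples]
            txs.extend(group)
            sims.extend(_sim(a.id, b.id, 0.8, 0.8, 90.0)
                        for i, a in enumerate(group) for b in group[i + 1:])
        assert len(cluster_definition1(txs, sims)) <= len(cluster_definition2(txs, sims))


class TestDefinition3:
    def test_window_on_both_ends(self):
        txs = [_tx("a", 100, 900, "A"), _tx("b", 300, 1000, "B"),
               _tx("c", 550, 1100, "C")]
        ogs = cluster_definition3(txs)
        assert len(ogs) == 1 and ogs[0].occupancy == 3

    def test_start_window_exceeded(self):
        txs = [_tx("a", 0, 900, "A"), _tx("b", 501, 1000, "B")]
        assert len(cluster_definition3(txs)) == 2

    def test_identical_coordinates_seven_samples(self):
        txs = [_tx(f"s{i}.t", 100, 1100, f"s{i}") for i in range(7)]
        (og,) = cluster_definition3(txs)
        assert og.occupancy == 7

    def test_opposite_strands_not_linked_by_default(self):
        txs = [_tx("a", 100, 900, "A"), _tx("b", 100, 900, "B", strand="-")]
        assert len(cluster_definition3(txs)) == 2
        assert len(cluster_definition3(txs, require_same_strand=False)) == 1


class TestClusteringProperties:
    def _random_inputs(self, seed):
        rng = random.Random(seed)
        samples = ["A", "B", "C", "D"]
        txs, sims = [], []
        for g in range(6):
            base = 20_000 * g
            members = [s for s in samples if rng.random() < 0.8] or ["A"]
            group = [_tx(f"{s}.g{g}", base + rng.randrange(0, 800),
                         base + 3000 + rng.randrange(0, 800), s) for s in members]
            txs.extend(group)
            for i, a in enumerate(group):
                for b in group[i + 1:]:
                    if rng.random() < 0.9:
                        sims.append(_sim(a.id, b.id, 0.85, 0.85, 88.0))
        return txs, sims

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_partition_property(self, seed):
        txs, sims = self._random_inputs(seed)
        for ogs in (cluster_definition1(txs, sims),
                    cluster_definition2(txs, sims),
                    cluster_definition3(txs)):
            members = [tid for og in ogs for _, tid in og.members]
            assert sorted(members) == sorted(t.id for t in txs)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_input_order_invariance(self, seed):
        txs, sims = self._random_inputs(seed)
        shuffled_txs = list(txs)
        shuffled_sims = list(sims)
        random.Random(99).shuffle(shuffled_txs)
        random.Random(98).shuffle(shuffled_sims)
        assert _memberships(cluster_definition2(txs, sims)) == \
            _memberships(cluster_definition2(shuffled_txs, shuffled_sims))
        assert _memberships(cluster_definition3(txs)) == \
            _memberships(cluster_definition3(shuffled_txs))


class TestNucleotideSharing:
    def test_worked_overlap_example(self):
        # two 200 nt transcripts overlapping by 50 nt in two samples
        a = TranscriptCatalog("A", (_tx("a", 0, 200, "A"),))
        b = TranscriptCatalog("B", (_tx("b", 150, 350, "B"),))
        n = nucleotide_sharing([a, b])
        assert n.tolist() == [300, 50]

    def test_identical_in_three_samples(self):
        cats = [TranscriptCatalog(s, (_tx(f"{s}.t", 100, 400, s),))
                for s in ("A", "B", "C")]
        assert nucleotide_sharing(cats).tolist() == [0, 0, 300]

    def test_disjoint_transcripts(self):
        a = TranscriptCatalog("A", (_tx("a", 0, 200, "A"),))
        b = TranscriptCatalog("B", (_tx("b", 1000, 1300, "B"),))
        assert nucleotide_sharing([a, b]).tolist() == [500, 0]

    def test_opposite_strands_do_not_share(self):
        a = TranscriptCatalog("A", (_tx("a", 0, 200, "A"),))
        b = TranscriptCatalog("B", (_tx("b", 0, 200, "B", strand="-"),))
        assert nucleotide_sharing([a, b]).tolist() == [400, 0]


class TestSpectrum:
    @staticmethod
    def _og(i, samples):
        return Orthogroup(id=f"OG{i}", definition=1,
                          members=tuple((s, f"{s}.t{i}") for s in samples))

    def test_occupancy_binning(self):
        ogs = [self._og(1, ["A"]), self._og(2, ["A", "B"]),
               self._og(3, ["A", "B", "C"])]
        spec = spectrum_from_orthogroups(ogs, ["A", "B", "C"])
        assert spec.d == (1, 1, 1)

    def test_restriction_rebins_occupancies(self):
        rng = random.Random(5)
        samples = [f"s{i}" for i in range(7)]
        ogs = [self._og(i, rng.sample(samples, rng.randint(1, 7)))
               for i in range(40)]
        subset = samples[:6]
        spec = spectrum_from_orthogroups(ogs, subset)
        # brute-force recount
        expected = [0] * 6
        for og in ogs:
            k = len({s for s, _ in og.members} & set(subset))
            if k:
                expected[k - 1] += 1
        assert list(spec.d) == expected
        assert spec.total <= len(ogs)

    def test_empty_input(self):
        spec = spectrum_from_orthogroups([], ["A", "B"])
        assert spec.d == (0, 0)
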