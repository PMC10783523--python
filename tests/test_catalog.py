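"""Transcript catalog I/O and de novo filters."""

import pytest

from txturnover import (HomologyHit, Transcript, TranscriptCatalog,
                        filter_by_homology, filter_by_tpm,
                        merge_splice_variants, read_blast_tabular,
                        read_transcript_gtf, write_transcript_gtf)
from txturnover.catalog import GtfParseError

from conftest import write_gtf


def _tx(tid, start, end, sample="S1", strand="+", tpm=1.0, precursor="", exons=None):
    return Transcript(id=tid, sample=sample, chrom="chr1", start=start, end=end,
                      strand=strand, exons=exons or ((start, end),),
                      precursor_id=precursor or tid, tpm=tpm)


def _catalog(*txs, sample="S1"):
    return TranscriptCatalog(sample=sample, transcripts=tuple(txs))


class TestReadGtf:
    def test_coordinates_and_lengths(self, tmp_path):
        attrs = 'gene_id "g1"; transcript_id "t1"; TPM "3.2";'
        p = write_gtf(tmp_path / "a.gtf", [
            ("chr1", "transcript", 101, 500, "+", attrs),
            ("chr1", "exon", 101, 200, "+", attrs),
            ("chr1", "exon", 401, 500, "+", attrs),
        ])
        cat = read_transcript_gtf(p, "S1")
        assert len(cat) == 1
        t = cat.transcripts[0]
        assert (t.start, t.end) == (100, 500)
        assert t.spliced_length == 200
        assert t.unspliced_length == 400
        assert t.tpm == pytest.approx(3.2)
        assert t.precursor_id == "g1"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        assert len(read_transcript_gtf(p, "S1")) == 0

    def test_five_transcripts_two_loci(self, tmp_path):
        rows = []
        for i in range(5):
            gene = "gA" if i < 3 else "gB"
            attrs = f'gene_id "{gene}"; transcript_id "t{i}"; TPM "1";'
            rows.append(("chr1", "transcript", 1 + 1000 * i, 500 + 1000 * i, "+", attrs))
            rows.append(("chr1", "exon", 1 + 1000 * i, 500 + 1000 * i, "+", attrs))
        cat = read_transcript_gtf(write_gtf(tmp_path / "b.gtf", rows), "S1")
        assert len(cat) == 5
        assert len({t.precursor_id for t in cat}) == 2

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\ttest\ttranscript\t1\t100\t.\t+\t.\ttranscript_id "t";\n'
                     "not a gtf line\n")
        with pytest.raises(GtfParseError, match="line 2"):
            read_transcript_gtf(p, "S1")

    def test_exon_outside_span_rejected(self, tmp_path):
        attrs = 'gene_id "g"; transcript_id "t";'
        p = write_gtf(tmp_path / "c.gtf", [
            ("chr1", "transcript", 101, 200, "+", attrs),
            ("chr1", "exon", 101, 300, "+", attrs),
        ])
        with pytest.raises(ValueError, match="outside transcript span"):
            read_transcript_gtf(p, "S1")

    def test_gtf_round_trip(self, tmp_path):
        cat = _catalog(_tx("t1", 100, 500, tpm=3.2,
                           exons=((100, 200), (400, 500))))
        p = tmp_path / "rt.gtf"
        write_transcript_gtf(cat, p)
        back = read_transcript_gtf(p, "S1")
        assert back.transcripts[0] == cat.transcripts[0]


class TestTpmFilter:
    @pytest.mark.parametrize("threshold, kept", [(0.5, 2), (5, 0), (0, 3), (1, 1)])
    def test_threshold_keeps_at_least_equal(self, threshold, kept):
        # a transcript at exactly the threshold is kept
        cat = _catalog(_tx("a", 0, 10, tpm=0.4), _tx("b", 20, 30, tpm=0.5),
                       _tx("c", 40, 50, tpm=3.0))
        assert len(filter_by_tpm(cat, threshold)) == kept

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_by_tpm(_catalog(), -1)


class TestHomologyFilter:
    @staticmethod
    def _hit(qid, evalue, forward=True):
        s, e = (1, 100) if forward else (100, 1)
        return HomologyHit(query_id=qid, subject_id="o1", percent_identity=90,
                           alignment_length=100, query_start=1, query_end=100,
                           subject_start=s, subject_end=e, evalue=evalue)

    def test_evalue_cutoff(self):
        cat = _catalog(_tx("a", 0, 10), _tx("b", 20, 30))
        out = filter_by_homology(cat, [self._hit("a", 1e-3), self._hit("b", 0.5)])
        assert out.ids() == {"b"}

    def test_reverse_hit_ignored_when_forward_only(self):
        cat = _catalog(_tx("a", 0, 10))
        assert len(filter_by_homology(cat, [self._hit("a", 1e-6, forward=False)])) == 1
        assert len(filter_by_homology(cat, [self._hit("a", 1e-6, forward=False)],
                                      forward_only=False)) == 0

    def test_two_stage_filter_matches_brute_force(self):
        txs = [_tx(f"t{i}", 100 * i, 100 * i + 50, tpm=i / 4) for i in range(1, 9)]
        cat = _catalog(*txs)
        stage1 = [self._hit("t1", 1e-5), self._hit("t3", 1e-3)]
        stage2 = [self._hit("t3", 1e-9), self._hit("t5", 1e-4), self._hit("t9", 1e-9)]
        out = filter_by_homology(filter_by_homology(cat, stage1), stage2)
        flagged = {h.query_id for h in stage1 + stage2 if h.evalue <= 1e-2}
        assert out.ids() == {t.id for t in txs if t.id not in flagged}

    def test_commutes_with_tpm_filter(self):
        txs = [_tx(f"t{i}", 100 * i, 100 * i + 50, tpm=i / 4) for i in range(1, 9)]
        cat = _catalog(*txs)
        hits = [self._hit("t2", 1e-4), self._hit("t6", 1e-3), self._hit("t7", 0.9)]
        a = filter_by_homology(filter_by_tpm(cat, 0.5), hits)
        b = filter_by_tpm(filter_by_homology(cat, hits), 0.5)
        assert a.ids() == b.ids()


class TestMergeSpliceVariants:
    def test_span_and_tpm(self):
        cat = _catalog(_tx("v1", 100, 500, precursor="g", tpm=2.0),
                       _tx("v2", 100, 250, precursor="g", tpm=7.0))
        out = merge_splice_variants(cat)
        assert len(out) == 1
        m = out.transcripts[0]
        assert (m.start, m.end) == (100, 500)
        assert m.spliced_length == m.unspliced_length == 400
        assert m.tpm == 7.0

    def test_distinct_precursors_unchanged(self):
        cat = _catalog(_tx("a", 0, 10), _tx("b", 20, 30))
        assert len(merge_splice_variants(cat)) == 2

    def test_idempotent(self):
        cat = _catalog(_tx("v1", 100, 500, precursor="g"),
                       _tx("v2", 100, 250, precursor="g"),
                       _tx("w", 1000, 1200))
        once = merge_splice_variants(cat)
        twice = merge_splice_variants(once)
        assert [t.id for t in once] == [t.id for t in twice]
        assert [(t.start, t.end) for t in once] == [(t.start, t.end) for t in twice]

    def test_strand_conflict_rejected(self):
        cat = _catalog(_tx("v1", 100, 500, precursor="g", strand="+"),
                       _tx("v2", 100, 250, precursor="g", strand="-"))
        with pytest.raises(ValueError, match="strand"):
            merge_splice_variants(cat)


class TestBlastTabular:
    def test_forward_orientation_inferred(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "t1\ts1\t98.0\t100\t2\t0\t1\t100\t1\t100\t1e-30\t180\n"
            "t2\ts1\t95.0\t100\t5\t0\t1\t100\t200\t101\t1e-10\t120\n")
        hits = read_blast_tabular(p)
        assert [h.forward for h in hits] == [True, False]
        assert hits[0].evalue == pytest.approx(1e-30)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "none.tsv"
        p.write_text("")
        assert read_blast_tabular(p) == []

    def test_non_numeric_evalue_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("t1\ts1\t98.0\t100\t2\t0\t1\t100\t1\t100\tno\t180\n")
        with pytest.raises(ValueError):
            read_blast_tabular(p)
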