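"""Homology scanning, coding-sequence filtering, dereplication."""

import random

import pytest

from acepamir.homology import (
    HomologyHit,
    ReferenceMature,
    dereplicate,
    orf_coding_filter,
    scan_candidates,
)
from acepamir.seqio import SequenceError, SequenceRecord, reverse_complement

from _oracles import brute_force_scan, six_frame_orf_lengths


def _random_rna(rng, n):
    return "".join(rng.choice("AUGC") for _ in range(n))


class TestScan:
    def test_reported_mature_found_in_own_precursor(self, reported_by_name):
        """The ace-miR162 mature matches its precursor once, 3' half, 0 mismatches."""
        m = reported_by_name["ace-miR162"]
        ref = ReferenceMature(id=m.name, sequence=m.mature)
        subject = SequenceRecord(id=m.subject_id, sequence=m.precursor, source="EST")
        hits = [h for h in scan_candidates([ref], [subject], max_mismatch=0)
                if h.strand == "+"]
        assert len(hits) == 1
        hit = hits[0]
        assert hit.mismatches == 0
        assert hit.matched_length == 21
        # mature midpoint in the 3' half of the 111-nt precursor
        assert (hit.start + hit.end) / 2 > len(m.precursor) / 2

    def test_poly_a_subject_has_no_hits(self):
        ref = ReferenceMature(id="r", sequence="UCGAUAAGCCUCUGCAUCCAG")
        subject = SequenceRecord(id="s", sequence="A" * 28, source="EST")
        assert scan_candidates([ref], [subject], max_mismatch=0) == []

    def test_matches_brute_force_oracle(self):
        rng = random.Random(42)
        refs = [
            ReferenceMature(id=f"ref{i}", sequence=_random_rna(rng, 21))
            for i in range(5)
        ]
        subjects = [
            SequenceRecord(id=f"s{i}", sequence=_random_rna(rng, 200), source="EST")
            for i in range(50)
        ]
        hits = scan_candidates(refs, subjects, max_mismatch=2)
        got = {
            (h.subject_id, h.reference_id, h.start, h.end, h.strand, h.mismatches)
            for h in hits
        }
        expected = brute_force_scan(refs, subjects, max_mismatch=2)
        assert got == expected
        assert len(hits) == len(got)  # each window reported exactly once

    def test_ambiguous_windows_skipped(self):
        ref = ReferenceMature(id="r", sequence="GGGGGGGGGGGGGGGGGGGG")
        subject = SequenceRecord(id="s", sequence="G" * 10 + "N" + "G" * 10, source="EST")
        hits = scan_candidates([ref], [subject], max_mismatch=3)
        assert hits == []

    def test_strand_symmetry(self):
        rng = random.Random(7)
        ref = ReferenceMature(id="r", sequence=_random_rna(rng, 20))
        seq = _random_rna(rng, 50) + ref.sequence + _random_rna(rng, 50)
        fwd = SequenceRecord(id="s", sequence=seq, source="EST")
        rev = SequenceRecord(id="s", sequence=reverse_complement(seq), source="EST")
        fwd_hits = scan_candidates([ref], [fwd], max_mismatch=1)
        rev_hits = scan_candidates([ref], [rev], max_mismatch=1)
        L = len(seq)
        mapped = {
            (L - h.end + 1, L - h.start + 1, "-" if h.strand == "+" else "+", h.mismatches)
            for h in rev_hits
        }
        assert {(h.start, h.end, h.strand, h.mismatches) for h in fwd_hits} == mapped

    def test_subject_order_invariance(self):
        rng = random.Random(3)
        refs = [ReferenceMature(id="r", sequence=_random_rna(rng, 20))]
        subjects = [
            SequenceRecord(id=f"s{i}", sequence=_random_rna(rng, 120), source="EST")
            for i in range(6)
        ]
        a = scan_candidates(refs, subjects, max_mismatch=3)
        b = scan_candidates(refs, list(reversed(subjects)), max_mismatch=3)
        assert a == b

    def test_short_reference_rejected(self):
        with pytest.raises(SequenceError):
            ReferenceMature(id="tiny", sequence="AUGCAUGCAUGC")


class TestOrfFilter:
    def test_constructed_long_orf_detected(self):
        rng = random.Random(1)
        body = ""
        while len(body) < 90 * 3:
            codon = _random_rna(rng, 3)
            if codon not in ("UAA", "UAG", "UGA"):
                body += codon
        seq = "AUG" + body + "UAA"
        rec = SequenceRecord(id="orf", sequence=seq, source="EST")
        assert orf_coding_filter(rec, min_orf_codons=80)
        assert six_frame_orf_lengths(seq) >= 80

    def test_periodic_stops_pass_filter(self):
        """Stops every <=30 codons in every frame leave no long ORF."""
        rng = random.Random(2)
        chunks = []
        for _ in range(12):
            chunks.append(_random_rna(rng, 24) + "UAAUAAUAA")  # stops in all frames
        seq = "".join(chunks)
        rec = SequenceRecord(id="stops", sequence=seq, source="EST")
        assert six_frame_orf_lengths(seq) < 80
        assert not orf_coding_filter(rec, min_orf_codons=80)

    def test_short_precursor_cannot_be_coding(self, reported_by_name):
        m = reported_by_name["ace-miR1223"]
        rec = SequenceRecord(id=m.name, sequence=m.precursor, source="EST")
        assert len(m.precursor) < 80 * 3
        assert not orf_coding_filter(rec, min_orf_codons=80)

    def test_agreement_with_six_frame_oracle(self):
        rng = random.Random(5)
        for _ in range(20):
            seq = _random_rna(rng, rng.randint(150, 400))
            rec = SequenceRecord(id="x", sequence=seq, source="EST")
            assert orf_coding_filter(rec, min_orf_codons=30) == (
                six_frame_orf_lengths(seq) >= 30
            )


def _hit(subject="s", ref="r", start=1, end=21, mm=0, strand="+"):
    return HomologyHit(
        subject_id=subject, reference_id=ref, start=start, end=end,
        strand=strand, matched_length=end - start + 1, mismatches=mm,
    )


class TestDereplicate:
    def test_identical_interval_tie_break(self):
        a = _hit(ref="osa-miR162")
        b = _hit(ref="zma-miR162")
        assert dereplicate([b, a]) == [a]  # smallest reference id wins the tie

    def test_fewest_mismatches_wins(self):
        worse = _hit(ref="a", mm=2)
        better = _hit(ref="z", mm=0)
        assert dereplicate([worse, better]) == [better]

    def test_non_overlapping_all_kept(self):
        a = _hit(start=1, end=21)
        b = _hit(start=100, end=120)
        assert dereplicate([a, b]) == [a, b]

    def test_random_clusters_match_greedy_oracle(self):
        rng = random.Random(11)
        for _ in range(20):
            hits = [
                _hit(start=s, end=s + 20, mm=rng.randint(0, 3), ref=f"r{k}")
                for k, s in enumerate(rng.sample(range(1, 300), rng.randint(3, 12)))
            ]
            kept = dereplicate(hits)
            # oracle: greedy selection over the 50%-overlap graph, best first
            def quality(h):
                return (h.mismatches, -h.matched_length, h.reference_id, h.start)

            def overlaps(a, b):
                ov = min(a.end, b.end) - max(a.start, b.start) + 1
                return ov > 0 and 2 * ov >= min(a.matched_length, b.matched_length)

            expected = []
            for h in sorted(hits, key=quality):
                if not any(overlaps(h, k) for k in expected):
                    expected.append(h)
            assert set(kept) == set(expected)
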