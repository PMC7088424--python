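"""Homology scanning of EST/GSS sequences against known mature miRNAs.

Candidate mature-miRNA loci are found by exhaustive ungapped scanning:
every window of every subject (both strands) whose length equals a
reference mature sequence is compared by Hamming distance.  This is a
superset of any seeded heuristic search at mature-miRNA lengths, so no
E-value statistics are needed.  Likely protein-coding subjects are
removed with a six-frame ORF-length heuristic, and redundant
overlapping hits are collapsed to the best-supported one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .seqio import RNA_BASES, SequenceError, SequenceRecord, normalize_to_rna

MIN_MATURE_LEN = 18
MAX_MATURE_LEN = 26

_FAMILY_RE = re.compile(r"(mir|miR|MIR)[-]?(\d+)", re.IGNORECASE)


@dataclass
class ReferenceMature:
    """A known mature miRNA used as a homology query.

    ``family`` is the numbered miRNA family (e.g. ``miR162``), derived
    from the id when not given explicitly.
    """

    id: str
    sequence: str
    family: str = ""

    def __post_init__(self) -> None:
        self.sequence = normalize_to_rna(self.sequence)
        if not set(self.sequence) <= RNA_BASES:
            raise SequenceError(f"reference {self.id} contains ambiguity codes")
        if not (MIN_MATURE_LEN <= len(self.sequence) <= MAX_MATURE_LEN):
            raise SequenceError(
                f"reference {self.id} length {len(self.sequence)} outside "
                f"[{MIN_MATURE_LEN}, {MAX_MATURE_LEN}]"
            )
        if not self.family:
            m = _FAMILY_RE.search(self.id)
            self.family = f"miR{m.group(2)}" if m else self.id

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HomologyHit:
    """An ungapped mature-miRNA match on a subject sequence.

    The interval is 1-based inclusive on the forward strand of the
    subject regardless of hit strand; for '-' hits the reference matched
    the reverse complement of that interval.
    """

    subject_id: str
    reference_id: str
    start: int
    end: int
    strand: str
    matched_length: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end - self.start + 1 != self.matched_length:
            raise ValueError("interval length disagrees with matched_length")
        if self.matched_length < MIN_MATURE_LEN:
            raise ValueError(f"match shorter than {MIN_MATURE_LEN} nt")


_ENC = {b: i for i, b in enumerate("ACGU")}


def _encode(seq: str) -> np.ndarray:
    """Encode RNA to int8; ambiguity codes map to -1 (never match)."""
    return np.array([_ENC.get(c, -1) for c in seq], dtype=np.int8)


def scan_candidates(
    references: list[ReferenceMature],
    subjects: list[SequenceRecord],
    max_mismatch: int = 3,
    min_match: int = MIN_MATURE_LEN,
) -> list[HomologyHit]:
    """Exhaustive both-strand Hamming scan of subjects against references.

    Every (subject window, reference, strand) triple with window length
    equal to the reference length and at most *max_mismatch*
    substitutions is reported exactly once.  Windows containing
    ambiguity codes are skipped.  Hits are sorted by
    (subject_id, start, reference_id, strand).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    for ref in references:
        if len(ref) < min_match:
            raise SequenceError(
                f"reference {ref.id} shorter than the {min_match}-nt minimum match"
            )
    hits: list[HomologyHit] = []
    for subj in subjects:
        L = len(subj.sequence)
        for strand in "+-":
            seq = subj.sequence if strand == "+" else _safe_revcomp(subj.sequence)
            enc = _encode(seq)
            ok = enc >= 0
            for ref in references:
                m = len(ref)
                if L < m:
                    continue
                renc = _encode(ref.sequence)
                windows = np.lib.stride_tricks.sliding_window_view(enc, m)
                valid = np.lib.stride_tricks.sliding_window_view(ok, m).all(axis=1)
                mism = (windows != renc).sum(axis=1)
                for s0 in np.nonzero(valid & (mism <= max_mismatch))[0]:
                    if strand == "+":
                        start, end = int(s0) + 1, int(s0) + m
                    else:
                        start, end = L - int(s0) - m + 1, L - int(s0)
                    hits.append(
                        HomologyHit(
                            subject_id=subj.id,
                            reference_id=ref.id,
                            start=start,
                            end=end,
                            strand=strand,
                            matched_length=m,
                            mismatches=int(mism[s0]),
                        )
                    )
    hits.sort(key=lambda h: (h.subject_id, h.start, h.reference_id, h.strand))
    return hits


def _safe_revcomp(seq: str) -> str:
    """Reverse complement that carries ambiguity codes through as N."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp.get(c, "N") for c in reversed(seq))


_STOPS = {"UAA", "UAG", "UGA"}


def orf_coding_filter(subject: SequenceRecord, min_orf_codons: int = 80) -> bool:
    """True if the subject is likely protein-coding and should be dropped.

    Scans all six reading frames (both strands) for an uninterrupted
    open reading frame of at least *min_orf_codons* codons, counted from
    an AUG start up to (excluding) an in-frame stop or the sequence end.
    """
    for seq in (subject.sequence, _safe_revcomp(subject.sequence)):
        for frame in range(3):
            codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
            run = 0
            in_orf = False
            for codon in codons:
                if codon in _STOPS:
                    in_orf = False
                    run = 0
                    continue
                if in_orf:
                    run += 1
                elif codon == "AUG":
                    in_orf = True
                    run = 1
                if run >= min_orf_codons:
                    return True
    return False


def _overlap(a: HomologyHit, b: HomologyHit) -> bool:
    """Intervals overlap by >= 50% of the shorter interval."""
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return False
    shorter = min(a.matched_length, b.matched_length)
    return ov * 2 >= shorter


def dereplicate(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Collapse redundant hits to one representative per locus.

    Hits on the same subject whose intervals overlap by at least half of
    the shorter interval are considered the same locus; the hit with the
    fewest mismatches survives (ties: longest match, then smallest
    reference id).
    """
    by_quality = sorted(
        hits, key=lambda h: (h.subject_id, h.mismatches, -h.matched_length,
                             h.reference_id, h.start, h.strand)
    )
    kept: list[HomologyHit] = []
    for hit in by_quality:
        if not any(k.subject_id == hit.subject_id and _overlap(k, hit) for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: (h.subject_id, h.start, h.reference_id, h.strand))
    return kept
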