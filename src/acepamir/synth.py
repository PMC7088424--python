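"""Seeded synthetic EST/GSS collections with ground-truth manifests.

Generates the structured inputs the discovery pipeline assumes, so that
every stage is testable without downloads: stem-loop precursors built
as mature + loop + (mutated) reverse-complement star arms, embedded in
random flanks to emulate EST/GSS reads; protein-coding decoys carrying
long open reading frames; unstructured compositional decoys; and
transcripts carrying target sites with prescribed mismatch/wobble
positions.  Flank composition is A/U-rich (~57% A+U), matching the
average composition of reported plant pre-miRNA sequence space.

All randomness flows from a single integer seed per call; there is no
global random state.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict

from .homology import ReferenceMature, orf_coding_filter
from .seqio import SequenceRecord, reverse_complement

#: flank base frequencies (A, U, G, C): A/U-rich like plant pre-miRNAs
FLANK_WEIGHTS = (0.285, 0.285, 0.215, 0.215)

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class EmbeddedPrecursor:
    """Manifest entry for one planted stem-loop."""

    subject_id: str
    reference_id: str
    mature_sequence: str
    mature_interval: tuple[int, int]      # on the subject, 1-based
    precursor_interval: tuple[int, int]   # on the subject, 1-based
    planned_mismatches: int
    planned_bulges: int
    arm: str


@dataclass
class PlantedSite:
    """Manifest entry for one planted target site."""

    transcript_id: str
    mirna_id: str
    site_interval: tuple[int, int]
    mismatch_positions: tuple[int, ...]
    wobble_positions: tuple[int, ...]


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for end-to-end verification."""

    records: list[SequenceRecord] = field(default_factory=list)
    embedded: list[EmbeddedPrecursor] = field(default_factory=list)
    decoy_ids: list[str] = field(default_factory=list)
    target_sites: list[PlantedSite] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "embedded": [asdict(e) for e in self.embedded],
            "decoy_ids": self.decoy_ids,
            "target_sites": [asdict(t) for t in self.target_sites],
        }
        return json.dumps(payload, indent=1)


def _random_rna(rng: random.Random, n: int,
                weights: tuple[float, float, float, float] = FLANK_WEIGHTS) -> str:
    return "".join(rng.choices("AUGC", weights=weights, k=n))


def _mutate_breaking_pair(rng: random.Random, star: list[str], pos: int, mature_base: str) -> None:
    """Substitute star[pos] so it neither pairs nor wobbles with mature_base."""
    forbidden = {_COMP[mature_base]}
    if mature_base == "G":
        forbidden.add("U")
    elif mature_base == "U":
        forbidden.add("G")
    choices = [b for b in "AUGC" if b not in forbidden and b != star[pos]]
    star[pos] = rng.choice(choices)


def make_precursor(
    mature: str,
    loop_len: int = 8,
    star_mismatches: int = 0,
    bulges: tuple[tuple[int, int], ...] = (),
    arm: str = "5p",
    seed: int = 0,
) -> tuple[str, tuple[int, int]]:
    """Build a synthetic stem-loop precursor around a mature sequence.

    The star arm is the reverse complement of the mature with
    *star_mismatches* pair-breaking substitutions at random positions
    and, for each (position, size) in *bulges*, *size* random bases
    inserted (creating star-side bulges).  ``arm`` places the mature on
    the 5' or 3' side of the loop.  Returns the precursor and the
    1-based mature interval within it.  Deterministic given *seed*.
    """
    if not (18 <= len(mature) <= 26):
        raise ValueError(f"mature length {len(mature)} outside [18, 26]")
    if loop_len < 3:
        raise ValueError("hairpin loop must be at least 3 nt")
    if arm not in ("5p", "3p"):
        raise ValueError(f"arm must be 5p or 3p, got {arm!r}")
    rng = random.Random(seed)
    star = list(reverse_complement(mature))
    if star_mismatches:
        n = len(star)
        positions = rng.sample(range(2, n - 2), star_mismatches)
        for p in positions:
            # star position p faces mature position n-1-p
            _mutate_breaking_pair(rng, star, p, mature[n - 1 - p])
    for pos, size in sorted(bulges, reverse=True):
        if not (0 <= pos <= len(star)):
            raise ValueError(f"bulge position {pos} outside the star arm")
        star[pos:pos] = list(_random_rna(rng, size))
    star_seq = "".join(star)
    # loop drawn from A/C so it cannot extend the stem
    loop = "".join(rng.choices("AC", weights=(0.7, 0.3), k=loop_len))
    if arm == "5p":
        pre = mature + loop + star_seq
        interval = (1, len(mature))
    else:
        pre = star_seq + loop + mature
        interval = (len(star_seq) + loop_len + 1, len(star_seq) + loop_len + len(mature))
    return pre, interval


def _coding_sequence(rng: random.Random, n_codons: int) -> str:
    """AUG + (n_codons - 1) random non-stop codons + UAA."""
    stops = {"UAA", "UAG", "UGA"}
    codons = ["AUG"]
    while len(codons) < n_codons:
        c = _random_rna(rng, 3, (0.25, 0.25, 0.25, 0.25))
        if c not in stops:
            codons.append(c)
    return "".join(codons) + "UAA"


def make_est_collection(
    n_true: int,
    n_coding_decoys: int,
    n_random_decoys: int,
    references: list[ReferenceMature],
    seed: int = 0,
    planned_mismatch_range: tuple[int, int] = (0, 3),
    total_length_range: tuple[int, int] = (300, 1000),
    loop_len_range: tuple[int, int] = (6, 20),
) -> SyntheticTruth:
    """Generate a synthetic EST/GSS collection with its truth manifest.

    True records embed a :func:`make_precursor` stem-loop (mature drawn
    from *references*, with the planned number of substitutions applied
    to the embedded mature copy) inside random A/U-rich flanks.  Coding
    decoys carry an ORF of at least 100 codons; random decoys are
    unstructured sequences of flank composition.  Byte-identical output
    for a fixed seed.
    """
    if not references:
        raise ValueError("need at least one reference mature miRNA")
    rng = random.Random(seed)
    truth = SyntheticTruth()
    for k in range(n_true):
        ref = references[rng.randrange(len(references))]
        n_mm = rng.randint(*planned_mismatch_range)
        mature = list(ref.sequence)
        for p in rng.sample(range(len(mature)), n_mm):
            mature[p] = rng.choice([b for b in "AUGC" if b != mature[p]])
        mature = "".join(mature)
        arm = rng.choice(("5p", "3p"))
        pre, (m_s, m_e) = make_precursor(
            mature,
            loop_len=rng.randint(*loop_len_range),
            star_mismatches=0,
            arm=arm,
            seed=rng.randrange(2**31),
        )
        total = rng.randint(*total_length_range)
        pad = max(total - len(pre), 20)
        left = rng.randint(10, pad - 10)
        right = pad - left
        sid = f"syn_true_{k:03d}"
        # regenerate flanks until no spurious long ORF spans the record,
        # so true records are non-coding by construction
        while True:
            seq = _random_rna(rng, left) + pre + _random_rna(rng, right)
            rec = SequenceRecord(id=sid, sequence=seq, source="synthetic")
            if not orf_coding_filter(rec):
                break
        truth.records.append(rec)
        truth.embedded.append(
            EmbeddedPrecursor(
                subject_id=sid,
                reference_id=ref.id,
                mature_sequence=mature,
                mature_interval=(left + m_s, left + m_e),
                precursor_interval=(left + 1, left + len(pre)),
                planned_mismatches=n_mm,
                planned_bulges=0,
                arm=arm,
            )
        )
    for k in range(n_coding_decoys):
        n_codons = rng.randint(100, 160)
        core = _coding_sequence(rng, n_codons)
        seq = _random_rna(rng, rng.randint(10, 40)) + core + _random_rna(rng, rng.randint(10, 40))
        sid = f"syn_coding_{k:03d}"
        truth.records.append(SequenceRecord(id=sid, sequence=seq, source="synthetic"))
        truth.decoy_ids.append(sid)
    for k in range(n_random_decoys):
        sid = f"syn_random_{k:03d}"
        n = rng.randint(*total_length_range)
        while True:
            rec = SequenceRecord(id=sid, sequence=_random_rna(rng, n), source="synthetic")
            if not orf_coding_filter(rec):
                break
        truth.records.append(rec)
        truth.decoy_ids.append(sid)
    return truth


def make_target_transcript(
    mirna: str,
    mismatch_positions: tuple[int, ...] = (),
    wobble_positions: tuple[int, ...] = (),
    pad: int = 50,
    seed: int = 0,
    mirna_id: str = "query",
    transcript_id: str = "syn_transcript",
) -> tuple[SequenceRecord, PlantedSite]:
    """Plant a target site with prescribed duplex states in a transcript.

    The site starts as the exact reverse complement of the miRNA; at
    each listed miRNA position (1-based, 5'->3') the facing site base
    is changed to create a mismatch or a G:U wobble.  Wobbles require
    the miRNA base to be G or U.  Position lists must be disjoint.
    """
    n = len(mirna)
    overlap = set(mismatch_positions) & set(wobble_positions)
    if overlap:
        raise ValueError(f"positions listed as both mismatch and wobble: {sorted(overlap)}")
    for p in (*mismatch_positions, *wobble_positions):
        if not (1 <= p <= n):
            raise ValueError(f"position {p} outside the miRNA")
    rng = random.Random(seed)
    site = list(reverse_complement(mirna))
    # miRNA position i (1-based) faces site index n - i
    for p in wobble_positions:
        base = mirna[p - 1]
        if base == "G":
            site[n - p] = "U"
        elif base == "U":
            site[n - p] = "G"
        else:
            raise ValueError(f"miRNA position {p} is {base}; G:U wobble needs G or U")
    for p in mismatch_positions:
        _mutate_breaking_pair(rng, site, n - p, mirna[p - 1])
    left = _random_rna(rng, pad)
    right = _random_rna(rng, pad)
    seq = left + "".join(site) + right
    record = SequenceRecord(id=transcript_id, sequence=seq, source="transcript")
    planted = PlantedSite(
        transcript_id=transcript_id,
        mirna_id=mirna_id,
        site_interval=(pad + 1, pad + n),
        mismatch_positions=tuple(sorted(mismatch_positions)),
        wobble_positions=tuple(sorted(wobble_positions)),
    )
    return record, planted
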