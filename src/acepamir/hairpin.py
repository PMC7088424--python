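"""Hairpin qualification criteria and per-precursor statistics.

Implements the conventional plant pre-miRNA screen: the mature miRNA
must sit in one arm of the stem-loop with at least half of its bases
paired, bulges in the miRNA/miRNA* duplex must stay under 4 nt with at
most one asymmetric bulge, precursor A+U content must lie in 30-70%,
the fold must have negative MFE, and the minimal folding free energy
index must clear the |MFEI| >= 0.85 cutoff that separates miRNA
precursors from tRNA/rRNA/mRNA folds.

Derived statistics:

    AMFE = MFE / LP * 100          (kcal/mol per 100 nt, LP = precursor length)
    MFEI = AMFE / (G+C)%           (dimensionless, negative)
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from .fold import PrecursorCandidate
from .seqio import PairTable


class Composition(NamedTuple):
    """Mononucleotide percentages of a sequence (unrounded)."""

    pct_a: float
    pct_u: float
    pct_g: float
    pct_c: float
    pct_gc: float
    pct_au: float

    def rounded(self, ndigits: int = 2) -> "Composition":
        return Composition(*(round(v, ndigits) for v in self))


def composition(seq: str) -> Composition:
    """Percent A/U/G/C and combined GC/AU content of an RNA string."""
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    a, u, g, c = (100.0 * seq.count(b) / n for b in "AUGC")
    return Composition(a, u, g, c, g + c, a + u)


def amfe(mfe: float, lp: int) -> float:
    """Adjusted MFE: free energy normalized per 100 nt of precursor."""
    if lp <= 0:
        raise ValueError(f"precursor length must be positive, got {lp}")
    return mfe / lp * 100.0


def mfei(amfe_value: float, pct_gc: float) -> float:
    """Minimal folding free energy index: AMFE / (G+C)%.

    Stored signed (negative for stable folds); the conventional miRNA
    cutoff applies to its magnitude (|MFEI| >= 0.85).
    """
    if pct_gc <= 0:
        raise ValueError("MFEI is undefined for zero G+C content")
    return amfe_value / pct_gc


@dataclass
class HairpinThresholds:
    """Tunable criteria for qualifying a candidate hairpin."""

    min_mature_arm_nt: int = 18
    min_paired_fraction: float = 0.5
    max_duplex_bulge: int = 4         # duplex bulges must be < this many nt
    max_asymmetric_bulges: int = 1
    min_pct_au: float = 30.0
    max_pct_au: float = 70.0
    mfei_min: float = 0.85            # applied to |MFEI|


@dataclass
class HairpinEvaluation:
    """All per-precursor statistics plus per-criterion pass flags."""

    candidate: PrecursorCandidate
    arm: str
    mature_paired_fraction: float
    max_duplex_bulge: int
    n_asymmetric_bulges: int
    comp: Composition
    mfe: float
    amfe: float
    mfei: float
    five_prime_nt: str
    criteria_flags: dict = field(default_factory=dict)
    passes: bool = False
    hit: object | None = None  # originating HomologyHit, attached by the pipeline

    @property
    def mature_sequence(self) -> str:
        return self.candidate.mature_sequence

    @property
    def lp(self) -> int:
        return self.candidate.lp


def _duplex_bulges(pt: PairTable, m_s: int, m_e: int) -> tuple[int, int]:
    """(largest bulge nt, asymmetric bulge count) within the miRNA/miRNA* duplex.

    Walks consecutive paired mature positions; an internal loop between
    pairs (i1, j1) and (i2, j2) has a = i2-i1-1 unpaired nt on the
    mature strand and b = j1-j2-1 on the star strand.  Its bulge size is
    max(a, b); it is asymmetric when a != b (counted once per loop).
    """
    paired = [i for i in range(m_s, m_e + 1) if pt[i]]
    max_bulge = 0
    n_asym = 0
    for i1, i2 in zip(paired, paired[1:]):
        j1, j2 = pt[i1], pt[i2]
        a = i2 - i1 - 1
        b = (j1 - j2 - 1) if j1 > j2 else 0
        if a > 0 or b > 0:
            max_bulge = max(max_bulge, max(a, b))
            if a != b:
                n_asym += 1
    return max_bulge, n_asym


def evaluate_hairpin(
    candidate: PrecursorCandidate,
    thresholds: HairpinThresholds | None = None,
) -> HairpinEvaluation:
    """Apply the hairpin qualification criteria to a folded candidate."""
    th = thresholds or HairpinThresholds()
    pre = candidate.precursor_sequence
    m_s, m_e = candidate.mature_interval
    if not (1 <= m_s <= m_e <= candidate.lp):
        raise ValueError("mature interval lies outside the precursor")
    pt = candidate.fold.pair_table()
    mature_len = m_e - m_s + 1

    paired = [i for i in range(m_s, m_e + 1) if pt[i]]
    paired_fraction = len(paired) / mature_len
    self_pairing = any(m_s <= pt[i] <= m_e for i in paired)

    mm = (m_s + m_e) / 2.0
    if paired:
        pm = sum(pt[i] for i in paired) / len(paired)
    else:
        pm = candidate.lp + 1 - mm  # mirror position; arm from sequence midpoint
    arm = "5p" if mm < pm else "3p"
    loop_mid = (mm + pm) / 2.0
    on_five = sum(1 for i in range(m_s, m_e + 1) if i < loop_mid)
    on_three = sum(1 for i in range(m_s, m_e + 1) if i > loop_mid)
    arm_nt = max(on_five, on_three)

    max_bulge, n_asym = _duplex_bulges(pt, m_s, m_e)
    comp = composition(pre)
    mfe_val = candidate.fold.mfe
    amfe_val = amfe(mfe_val, candidate.lp)
    mfei_val = mfei(amfe_val, comp.pct_gc) if comp.pct_gc > 0 else 0.0

    flags = {
        "mature_in_one_arm": (not self_pairing)
        and arm_nt >= min(th.min_mature_arm_nt, mature_len),
        "paired_fraction": paired_fraction >= th.min_paired_fraction,
        "max_duplex_bulge": max_bulge < th.max_duplex_bulge,
        "asymmetric_bulges": n_asym <= th.max_asymmetric_bulges,
        "au_content": th.min_pct_au <= comp.pct_au <= th.max_pct_au,
        "negative_mfe": mfe_val < 0,
        "mfei": abs(mfei_val) >= th.mfei_min,
    }
    return HairpinEvaluation(
        candidate=candidate,
        arm=arm,
        mature_paired_fraction=paired_fraction,
        max_duplex_bulge=max_bulge,
        n_asymmetric_bulges=n_asym,
        comp=comp,
        mfe=mfe_val,
        amfe=amfe_val,
        mfei=mfei_val,
        five_prime_nt=pre[m_s - 1],
        criteria_flags=flags,
        passes=all(flags.values()),
    )


def five_prime_counts(items: Iterable) -> Mapping[str, int]:
    """Count mature 5'-terminal nucleotides.

    Accepts :class:`HairpinEvaluation` objects or plain mature RNA
    strings; order-invariant.
    """
    counts: Counter[str] = Counter()
    for item in items:
        seq = item if isinstance(item, str) else item.mature_sequence
        if not seq:
            raise ValueError("empty mature sequence")
        counts[seq[0]] += 1
    return dict(counts)
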