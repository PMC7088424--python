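"""miRNA target prediction by complementarity expectation scoring.

A miRNA is aligned antiparallel against candidate transcript sites and
scored with the classical plant-target penalty schema: each mismatch
costs 1.0, each G:U wobble 0.5 and each gap 2.0, with penalties doubled
inside the functionally critical miRNA positions 2-13 (5' end
numbering).  The total is the *expectation*; 0 means perfect
complementarity and lower is better.  Sites whose duplex carries a
mismatch or gap at miRNA positions 9-10 — the slicing site — are
classified as translational inhibition, all others as cleavage.

Target-site accessibility energies (UPE) are accepted as an optional
pass-through annotation but never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .homology import ReferenceMature
from .seqio import SequenceRecord

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}

#: miRNA positions (1-based, 5'->3') where penalties are doubled.
CORE_REGION = (2, 13)
#: miRNA positions whose mismatch/gap switches inhibition to translation.
CENTRAL_MISMATCH_RANGE = (9, 10)

PENALTY = {"match": 0.0, "wobble": 0.5, "mismatch": 1.0, "gap": 2.0}


def expectation_score(
    mirna: str, site: str, core: tuple[int, int] = CORE_REGION
) -> tuple[float, list[str]]:
    """Score an ungapped miRNA:site duplex.

    Both strings are 5'->3'; miRNA position i pairs site position
    n-i+1.  Returns the expectation penalty and per-position states
    over miRNA positions 1..n ('match', 'wobble' or 'mismatch').
    """
    if len(mirna) != len(site):
        raise ValueError(
            f"ungapped scoring requires equal lengths ({len(mirna)} vs {len(site)})"
        )
    n = len(mirna)
    states: list[str] = []
    total = 0.0
    for i in range(n):
        duplex = (mirna[i], site[n - 1 - i])
        if duplex in WC:
            state = "match"
        elif duplex in WOBBLE:
            state = "wobble"
        else:
            state = "mismatch"
        pen = PENALTY[state]
        if core[0] <= i + 1 <= core[1]:
            pen *= 2.0
        states.append(state)
        total += pen
    return total, states


def rescore_states(states: list[str], core: tuple[int, int] = CORE_REGION) -> float:
    """Recompute an expectation from per-position states alone."""
    total = 0.0
    for i, state in enumerate(states, start=1):
        pen = PENALTY[state]
        if core[0] <= i <= core[1]:
            pen *= 2.0
        total += pen
    return total


def classify_inhibition(
    states: list[str], central: tuple[int, int] = CENTRAL_MISMATCH_RANGE
) -> str:
    """'translation' if the central positions carry a mismatch/gap, else 'cleavage'."""
    if not states:
        raise ValueError("empty state list")
    lo, hi = central
    for pos in range(lo, hi + 1):
        if pos <= len(states) and states[pos - 1] in ("mismatch", "gap"):
            return "translation"
    return "cleavage"


@dataclass
class TargetAlignment:
    """A scored miRNA:site duplex on a transcript."""

    mirna_id: str
    transcript_id: str
    site_interval: tuple[int, int]
    site_sequence: str
    per_position_states: list[str]
    expectation: float
    inhibition: str
    upe: float | None = None


def scan_transcript(
    mirna: ReferenceMature,
    transcript: SequenceRecord,
    max_expectation: float = 3.0,
    max_targets: int = 10,
) -> list[TargetAlignment]:
    """Score every window of a transcript against a miRNA.

    Windows at or below *max_expectation* are reported best-first
    (ties: leftmost), overlapping sites are merged to the best-scoring
    one, and at most *max_targets* alignments are returned.
    """
    m = len(mirna.sequence)
    seq = transcript.sequence
    if len(seq) < m:
        return []
    scored: list[tuple[float, int, list[str]]] = []
    for s0 in range(len(seq) - m + 1):
        window = seq[s0 : s0 + m]
        if any(c not in "AUGC" for c in window):
            continue
        exp, states = expectation_score(mirna.sequence, window)
        if exp <= max_expectation:
            scored.append((exp, s0, states))
    scored.sort(key=lambda t: (t[0], t[1]))
    kept: list[tuple[float, int, list[str]]] = []
    for exp, s0, states in scored:
        if any(abs(s0 - k1) < m for _, k1, _ in kept):
            continue
        kept.append((exp, s0, states))
        if len(kept) >= max_targets:
            break
    return [
        TargetAlignment(
            mirna_id=mirna.id,
            transcript_id=transcript.id,
            site_interval=(s0 + 1, s0 + m),
            site_sequence=seq[s0 : s0 + m],
            per_position_states=states,
            expectation=exp,
            inhibition=classify_inhibition(states),
        )
        for exp, s0, states in kept
    ]
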