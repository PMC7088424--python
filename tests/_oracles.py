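"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes a quantity by direct enumeration or an
independent algorithm, deliberately avoiding the code paths it checks.
"""

from __future__ import annotations

import random

from acepamir.fold import default_model, score_structure
from acepamir.seqio import PairTable

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# Folding: exhaustive enumeration of nested structures
# ---------------------------------------------------------------------------


def enumerate_pairings(seq: str, min_loop: int = 3):
    """Yield every pseudoknot-free set of canonical pairs (0-based tuples)."""

    def gen(i: int, j: int):
        if j - i < min_loop + 1:
            yield []
            return
        for s in gen(i + 1, j):  # i unpaired
            yield s
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _CANONICAL:
                for inner in gen(i + 1, k - 1):
                    for rest in gen(k + 1, j):
                        yield [(i, k)] + inner + rest

    yield from gen(0, len(seq) - 1)


def oracle_mfe(seq: str) -> float:
    """Exhaustive-enumeration MFE under the pinned model (empty structure = 0)."""
    md = default_model()
    best = 0.0
    for pairs in enumerate_pairings(seq, md.min_hairpin):
        if not pairs:
            continue
        partner = [0] * (len(seq) + 1)
        for i, j in pairs:
            partner[i + 1] = j + 1
            partner[j + 1] = i + 1
        best = min(best, score_structure(seq, PairTable(partner), md))
    return best


# ---------------------------------------------------------------------------
# Homology: brute-force Hamming scan
# ---------------------------------------------------------------------------


def revcomp(seq: str) -> str:
    return "".join(_WC.get(c, "N") for c in reversed(seq))


def brute_force_scan(references, subjects, max_mismatch: int):
    """Every (window, reference, strand) triple by direct Hamming distance.

    Returns a set of (subject_id, reference_id, start, end, strand,
    mismatches) tuples with forward-strand 1-based coordinates.
    """
    found = set()
    for subj in subjects:
        L = len(subj.sequence)
        for ref in references:
            m = len(ref.sequence)
            for s0 in range(L - m + 1):
                window = subj.sequence[s0 : s0 + m]
                if any(c not in "AUGC" for c in window):
                    continue
                for strand in "+-":
                    target = window if strand == "+" else revcomp(window)
                    mm = sum(1 for a, b in zip(ref.sequence, target) if a != b)
                    if mm <= max_mismatch:
                        found.add(
                            (subj.id, ref.id, s0 + 1, s0 + m, strand, mm)
                        )
    return found


def six_frame_orf_lengths(seq: str):
    """Longest AUG-initiated stop-free ORF (in codons) over all six frames."""
    best = 0
    for s in (seq, revcomp(seq)):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            run = 0
            active = False
            for c in codons:
                if c in ("UAA", "UAG", "UGA"):
                    active = False
                    run = 0
                elif active:
                    run += 1
                    best = max(best, run)
                elif c == "AUG":
                    active = True
                    run = 1
                    best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# Phylogenetics: random additive trees and their path-length matrices
# ---------------------------------------------------------------------------


def random_additive_case(n_taxa: int, seed: int):
    """A random binary tree and its exact leaf path-length distance matrix.

    Returns (labels, matrix, bipartitions) where bipartitions is the set
    of non-trivial splits as smaller-side frozensets.
    """
    rng = random.Random(seed)
    labels = [f"t{i}" for i in range(n_taxa)]
    # build by random joins; edges keyed by frozenset of clade leaves
    clades = [frozenset([l]) for l in labels]
    edge_len: dict[frozenset, float] = {c: rng.uniform(0.5, 3.0) for c in clades}
    children: dict[frozenset, list[frozenset]] = {}
    while len(clades) > 3:
        rng.shuffle(clades)
        a, b = clades.pop(), clades.pop()
        parent = a | b
        children[parent] = [a, b]
        edge_len[parent] = rng.uniform(0.5, 3.0)
        clades.append(parent)
    root = frozenset(labels)
    children[root] = clades
    full = frozenset(labels)

    def leaf_depths(clade: frozenset, acc: float, out: dict):
        for ch in children.get(clade, []):
            leaf_depths(ch, acc + edge_len[ch], out)
        if len(clade) == 1:
            (leaf,) = clade
            out[leaf] = acc

    # distance via lowest common ancestor on the rooted representation
    depths: dict[str, float] = {}
    leaf_depths(root, 0.0, depths)

    def path(clade: frozenset, leaf: str, acc: float) -> float:
        if len(clade) == 1:
            return acc
        for ch in children[clade]:
            if leaf in ch:
                return path(ch, leaf, acc + edge_len[ch])
        raise AssertionError

    def dist(x: str, y: str) -> float:
        clade = root
        while True:
            nxt = None
            for ch in children.get(clade, []):
                if x in ch and y in ch:
                    nxt = ch
                    break
            if nxt is None:
                return path(clade, x, 0.0) + path(clade, y, 0.0)
            clade = nxt

    n = len(labels)
    matrix = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            matrix[i][j] = matrix[j][i] = dist(labels[i], labels[j])

    bips = set()
    for clade in children:
        if clade != root and 1 < len(clade) < n - 1:
            other = full - clade
            bips.add(min(clade, other, key=lambda s: (len(s), sorted(s))))
    return labels, matrix, bips


# ---------------------------------------------------------------------------
# Target scanning: exhaustive window rescoring
# ---------------------------------------------------------------------------


def brute_force_target_windows(mirna: str, transcript: str, core=(2, 13)):
    """Score every transcript window directly; returns {start0: expectation}."""
    m = len(mirna)
    out = {}
    for s0 in range(len(transcript) - m + 1):
        site = transcript[s0 : s0 + m]
        if any(c not in "AUGC" for c in site):
            continue
        total = 0.0
        for i in range(m):
            a, b = mirna[i], site[m - 1 - i]
            if _WC[a] == b:
                pen = 0.0
            elif (a, b) in (("G", "U"), ("U", "G")):
                pen = 0.5
            else:
                pen = 1.0
            if core[0] <= i + 1 <= core[1]:
                pen *= 2.0
            total += pen
        out[s0] = total
    return out
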