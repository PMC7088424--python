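"""Neighbor-joining phylogenetics of precursor sequences.

Distances come from deterministic pairwise global alignments (Gotoh
affine-gap dynamic programming: match +1, mismatch -1, gap open -2,
gap extend -1) summarized as p-distances.  Trees are built with the
Saitou-Nei neighbor-joining algorithm with a fully specified tie-break,
and branch support is estimated by resampling alignment columns of a
center-star multiple alignment with replacement and recording
bipartition frequencies.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -2.0, -1.0

_NEG = float("-inf")


def align_global(a: str, b: str) -> tuple[str, str, float]:
    """Deterministic affine-gap global alignment of two sequences.

    Gap of length L costs GAP_OPEN + (L-1)*GAP_EXTEND.  Ties are broken
    in a fixed order (diagonal, then gap in *b*, then gap in *a*) so the
    traceback is reproducible.  Returns the two gapped rows and score.
    """
    n, m = len(a), len(b)
    # M: a[i] aligned b[j]; X: gap in b (a consumed); Y: gap in a
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ai == b[j - 1] else MISMATCH
            Mi[j] = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]) + s
            Xi[j] = max(Mi1[j] + GAP_OPEN, Xi1[j] + GAP_EXTEND, Yi1[j] + GAP_OPEN)
            Yi[j] = max(Mi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND, Xi[j - 1] + GAP_OPEN)
    # traceback
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M[i][j], "X": X[i][j], "Y": Y[i][j]}[s])
    score = {"M": M[i][j], "X": X[i][j], "Y": Y[i][j]}[state]
    ra: list[str] = []
    rb: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            target = M[i][j] - s
            i, j = i - 1, j - 1
            for st, val in (("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j])):
                if abs(val - target) <= tol:
                    state = st
                    break
        elif state == "X":
            ra.append(a[i - 1])
            rb.append("-")
            cur = X[i][j]
            i -= 1
            if abs(M[i][j] + GAP_OPEN - cur) <= tol:
                state = "M"
            elif abs(X[i][j] + GAP_EXTEND - cur) <= tol:
                state = "X"
            else:
                state = "Y"
        else:
            ra.append("-")
            rb.append(b[j - 1])
            cur = Y[i][j]
            j -= 1
            if abs(M[i][j] + GAP_OPEN - cur) <= tol:
                state = "M"
            elif abs(Y[i][j] + GAP_EXTEND - cur) <= tol:
                state = "Y"
            else:
                state = "X"
        if i == 0 and j == 0:
            break
    return "".join(reversed(ra)), "".join(reversed(rb)), score


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of mismatched or gapped columns among aligned columns.

    Columns where both rows are gaps are ignored; identical residue
    columns count as matches.
    """
    n_cols = 0
    n_diff = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" and cb == "-":
            continue
        n_cols += 1
        if ca != cb or ca == "-":
            n_diff += 1
    return n_diff / n_cols if n_cols else 0.0


def pairwise_distance(a: str, b: str) -> float:
    """Align two sequences globally and return their p-distance."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ra, rb, _ = align_global(a, b)
    return p_distance(ra, rb)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered taxon labels."""

    labels: list[str]
    d: list[list[float]]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.d) != n or any(len(r) != n for r in self.d):
            raise ValueError("distance matrix shape does not match labels")
        for i in range(n):
            if abs(self.d[i][i]) > 1e-12:
                raise ValueError("nonzero diagonal")
            for j in range(i + 1, n):
                if self.d[i][j] < 0 or abs(self.d[i][j] - self.d[j][i]) > 1e-9:
                    raise ValueError(f"asymmetric or negative entry at ({i}, {j})")

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "DistanceMatrix":
        labels = list(seqs)
        n = len(labels)
        d = [[0.0] * n for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                d[i][j] = d[j][i] = pairwise_distance(seqs[labels[i]], seqs[labels[j]])
        return cls(labels, d)


@dataclass
class TreeNode:
    """Node of an unrooted (stored rooted at an arbitrary trifurcation) tree."""

    label: str = ""
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.label for l in self.leaves()]

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return f"{self.label}:{self.length:g}"
        inner = ",".join(c._newick() for c in self.children)
        sup = "" if self.support is None else str(self.support)
        return f"({inner}){sup}:{self.length:g}"


@dataclass
class PhyloTree:
    """An unrooted binary tree with branch lengths and optional supports."""

    root: TreeNode
    negative_lengths_clamped: bool = False

    def to_newick(self) -> str:
        return self.root.to_newick()

    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaf_names())

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, each as the smaller-side frozenset."""
        all_leaves = frozenset(self.root.leaf_names())
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self.root)
        return out


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with a deterministic tie-break.

    At each step the pair minimizing the Q-criterion is joined; exact
    ties go to the lexicographically smallest (label, label) pair.
    Negative branch-length estimates are clamped to zero and flagged.
    Two taxa yield a single edge by convention; fewer is an error.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: dict[str, TreeNode] = {lab: TreeNode(label=lab) for lab in dm.labels}
    d = {la: {lb: dm.d[i][j] for j, lb in enumerate(dm.labels)} for i, la in enumerate(dm.labels)}
    active = sorted(dm.labels)
    clamped = False
    join_counter = 0

    if n == 2:
        a, b = active
        na, nb = nodes[a], nodes[b]
        na.length = nb.length = d[a][b] / 2.0
        return PhyloTree(TreeNode(children=[na, nb]))

    while len(active) > 3:
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for ia, a in enumerate(active):
            for b in active[ia + 1 :]:
                q = (len(active) - 2) * d[a][b] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * d[a][b] + (r[a] - r[b]) / (2.0 * (len(active) - 2))
        lb = d[a][b] - la
        if la < 0 or lb < 0:
            clamped = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        new_label = f"\x00join{join_counter}"  # internal; never serialized
        join_counter += 1
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        nodes[new_label] = TreeNode(children=[na, nb])
        d[new_label] = {}
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[new_label][c] = d[c][new_label] = max(dc, 0.0)
        active = sorted(set(active) - {a, b} | {new_label})
        del d[a], d[b]
        for c in list(d):
            d[c].pop(a, None)
            d[c].pop(b, None)

    a, b, c = active
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    if min(la, lb, lc) < 0:
        clamped = True
    na, nb, nc = nodes[a], nodes[b], nodes[c]
    na.length, nb.length, nc.length = (max(x, 0.0) for x in (la, lb, lc))
    return PhyloTree(TreeNode(children=[na, nb, nc]), negative_lengths_clamped=clamped)


# ---------------------------------------------------------------------------
# Center-star multiple alignment and bootstrap
# ---------------------------------------------------------------------------


def center_star_msa(seqs: dict[str, str]) -> dict[str, str]:
    """Simple center-star multiple alignment.

    The center is the sequence minimizing its summed p-distance to all
    others (ties: smallest label); every other sequence is aligned to
    the center pairwise and gaps are merged with the once-a-gap,
    always-a-gap rule.
    """
    labels = sorted(seqs)
    if len(labels) == 1:
        return dict(seqs)
    sums = {
        a: sum(pairwise_distance(seqs[a], seqs[b]) for b in labels if b != a)
        for a in labels
    }
    center = min(labels, key=lambda a: (sums[a], a))
    rows: dict[str, str] = {center: seqs[center]}
    for lab in labels:
        if lab == center:
            continue
        rc, rl, _ = align_global(seqs[center], seqs[lab])
        # merge: walk the existing alignment (old gaps in the center row)
        # and the new pairwise alignment (new gaps) over center residues
        old_center = rows[center]
        merged: dict[str, list[str]] = {k: [] for k in rows}
        new_row: list[str] = []
        p = q = 0
        while p < len(old_center) or q < len(rc):
            if p < len(old_center) and old_center[p] == "-":
                for key in merged:
                    merged[key].append(rows[key][p])
                new_row.append("-")
                p += 1
            elif q < len(rc) and rc[q] == "-":
                for key in merged:
                    merged[key].append("-")
                new_row.append(rl[q])
                q += 1
            else:
                for key in merged:
                    merged[key].append(rows[key][p])
                new_row.append(rl[q])
                p += 1
                q += 1
        rows = {k: "".join(v) for k, v in merged.items()}
        rows[lab] = "".join(new_row)
    return rows


def distances_from_alignment(rows: dict[str, str],
                             columns: Sequence[int] | None = None) -> DistanceMatrix:
    """p-distance matrix from alignment rows, optionally on resampled columns."""
    labels = sorted(rows)
    if columns is not None:
        rows = {k: "".join(rows[k][c] for c in columns) for k in labels}
    n = len(labels)
    d = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d[i][j] = d[j][i] = p_distance(rows[labels[i]], rows[labels[j]])
    return DistanceMatrix(labels, d)


def bootstrap_support(
    seqs: dict[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with integer bootstrap supports on internal edges.

    Builds a center-star alignment, the reference NJ tree from its
    p-distances, then resamples alignment columns with replacement
    *n_replicates* times, rebuilding NJ each time, and annotates each
    internal edge of the reference tree with the percentage of
    replicates containing its bipartition.
    """
    rows = center_star_msa(seqs)
    ref = nj_tree(distances_from_alignment(rows))
    ncols = len(next(iter(rows.values())))
    if ncols < 1:
        raise ValueError("alignment has no columns")
    counts: dict[frozenset[str], int] = {bp: 0 for bp in ref.bipartitions()}
    rng = random.Random(seed)
    for _ in range(n_replicates):
        cols = [rng.randrange(ncols) for _ in range(ncols)]
        rep = nj_tree(distances_from_alignment(rows, cols))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(ref.root.leaf_names())

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.label])
        below = frozenset().union(*(annotate(c) for c in node.children))
        if node is not ref.root and 1 < len(below) < len(all_leaves) - 1:
            bp = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
            node.support = round(100.0 * counts[bp] / n_replicates)
        return below

    annotate(ref.root)
    return ref
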