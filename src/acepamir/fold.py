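"""Minimum-free-energy RNA secondary structure prediction.

A Zuker-style dynamic program over a deliberately small, pinned
nearest-neighbor model: stacking free energies for the six canonical
pair types (Watson-Crick plus G:U) at 37 C, logarithmic hairpin /
bulge / interior-loop penalties, an affine multiloop penalty, a 3-nt
minimum hairpin loop, no dangling ends and no coaxial stacking.  The
parameters ship as a versioned JSON data file and every reported MFE
can be re-derived by independently re-scoring the returned structure
(:func:`score_structure`), which is also how the exhaustive-enumeration
oracle in the test suite is built.

The model trades absolute agreement with full Turner-parameter engines
for a compact, fully reproducible energy function: downstream
precursor statistics (AMFE, MFEI) only require a consistent,
documented free energy.  Externally computed structures with their own
MFE values can be supplied through :mod:`acepamir.seqio` readers to
reproduce published MFOLD numbers exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from numba import njit

from .seqio import PairTable, SequenceError, SequenceRecord, parse_dotbracket, reverse_complement
from .homology import HomologyHit

INF = 1e9

# pair type indices; order matches the parameter file's pair_order
_PAIR_ORDER = ("AU", "CG", "GC", "UA", "GU", "UG")
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "U": 3}


class EnergyModel:
    """Pinned simplified nearest-neighbor energy model (37 C, kcal/mol)."""

    def __init__(self, params: dict):
        self.version = params["version"]
        order = params["pair_order"]
        assert tuple(order) == _PAIR_ORDER
        # pair index lookup: 4x4, -1 for non-pairing bases
        self.pair_idx = np.full((4, 4), -1, dtype=np.int8)
        for k, pq in enumerate(order):
            self.pair_idx[_BASE_IDX[pq[0]], _BASE_IDX[pq[1]]] = k
        self.stack = np.array(
            [[params["stack"][p][q] for q in order] for p in order], dtype=np.float64
        )
        self.hairpin_base = float(params["hairpin_base"])
        self.bulge_base = float(params["bulge_base"])
        self.internal_base = float(params["internal_base"])
        self.log_coeff = float(params["loop_log_coeff"])
        self.min_hairpin = int(params["min_hairpin_loop"])
        self.max_interior = int(params["max_interior_loop"])
        self.ml_close = float(params["multiloop_closing"])
        self.ml_branch = float(params["multiloop_branch"])
        self.ml_unpaired = float(params["multiloop_unpaired"])

    def hairpin(self, n: int) -> float:
        if n < self.min_hairpin:
            return INF
        return self.hairpin_base + self.log_coeff * math.log(n / self.min_hairpin)

    def bulge(self, n: int) -> float:
        return self.bulge_base + self.log_coeff * math.log(n)

    def internal(self, n: int) -> float:
        return self.internal_base + self.log_coeff * math.log(n / 2.0)

    def loop_tables(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Precomputed hairpin/bulge/internal penalties for sizes 0..n."""
        hp = np.full(n + 1, INF)
        bu = np.full(n + 1, INF)
        it = np.full(n + 1, INF)
        for k in range(self.min_hairpin, n + 1):
            hp[k] = self.hairpin(k)
        for k in range(1, n + 1):
            bu[k] = self.bulge(k)
        for k in range(2, n + 1):
            it[k] = self.internal(k)
        return hp, bu, it


def default_model() -> EnergyModel:
    """The packaged energy parameter set."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("acepamir.data").joinpath("energy_params.json").read_text()
        _DEFAULT = EnergyModel(json.loads(text))
    return _DEFAULT


_DEFAULT: EnergyModel | None = None


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_IDX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise SequenceError(f"cannot fold sequence with ambiguity code {exc.args[0]!r}") from None


@njit(cache=True)
def _fill(enc, pair_idx, stack, hp, bu, it, min_h, max_int, ml_a, ml_b, ml_c):
    n = enc.shape[0]
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)   # >=1 multiloop branch in segment
    M1 = np.full((n, n), INF)  # >=1 branch, last branch ends at j
    for span in range(min_h + 1, n):
        for i in range(0, n - span):
            j = i + span
            pij = pair_idx[enc[i], enc[j]]
            if pij >= 0:
                best = hp[j - i - 1]
                # stacked pair
                pin = pair_idx[enc[i + 1], enc[j - 1]]
                if pin >= 0 and V[i + 1, j - 1] < INF:
                    e = V[i + 1, j - 1] + stack[pij, pin]
                    if e < best:
                        best = e
                # bulge / interior loops (total unpaired >= 1)
                for l1 in range(0, max_int + 1):
                    k = i + 1 + l1
                    if k >= j:
                        break
                    for l2 in range(0, max_int + 1 - l1):
                        if l1 == 0 and l2 == 0:
                            continue
                        l = j - 1 - l2
                        if l <= k:
                            break
                        if pair_idx[enc[k], enc[l]] >= 0 and V[k, l] < INF:
                            if l1 == 0 or l2 == 0:
                                pen = bu[l1 + l2]
                            else:
                                pen = it[l1 + l2]
                            e = V[k, l] + pen
                            if e < best:
                                best = e
                # multiloop: >= 2 branches inside
                for k in range(i + 1, j - 1):
                    if M[i + 1, k] < INF and M1[k + 1, j - 1] < INF:
                        e = M[i + 1, k] + M1[k + 1, j - 1] + ml_a
                        if e < best:
                            best = e
                V[i, j] = best
            # M1: one branch starting at i (pair (i, l), l <= j), trailing
            # unpaired bases charged ml_c each
            bm1 = INF
            if V[i, j] < INF:
                bm1 = V[i, j] + ml_b
            if j > i and M1[i, j - 1] < INF:
                e = M1[i, j - 1] + ml_c
                if e < bm1:
                    bm1 = e
            M1[i, j] = bm1
            # M: >= 1 branch anywhere in the segment
            bm = bm1
            if M[i + 1, j] < INF:
                e = M[i + 1, j] + ml_c
                if e < bm:
                    bm = e
            for k in range(i, j):
                if M[i, k] < INF and M1[k + 1, j] < INF:
                    e = M[i, k] + M1[k + 1, j]
                    if e < bm:
                        bm = e
            M[i, j] = bm
    # external segment
    W = np.zeros(n)
    for j in range(n):
        w = W[j - 1] if j > 0 else 0.0
        for i in range(0, j):
            if V[i, j] < INF:
                prev = W[i - 1] if i > 0 else 0.0
                e = prev + V[i, j]
                if e < w:
                    w = e
        W[j] = w
    return V, M, M1, W


class _Tracer:
    """Deterministic traceback over the filled DP matrices.

    Preference order at energy ties (tolerance 1e-7): leave a base
    unpaired before pairing it, hairpin before stack before interior
    loop (smallest loop first) before multiloop (smallest split first).
    This favors structures with fewer pairs among co-optimal ones.
    """

    TOL = 1e-7

    def __init__(self, enc, model: EnergyModel, V, M, M1, W):
        self.enc = enc
        self.md = model
        self.V, self.M, self.M1, self.W = V, M, M1, W
        self.pairs: list[tuple[int, int]] = []

    def _p(self, i, j):
        return self.md.pair_idx[self.enc[i], self.enc[j]]

    def run(self):
        self._trace_w(len(self.enc) - 1)
        return self.pairs

    def _trace_w(self, j):
        while j >= 0:
            w = self.W[j]
            if w >= -self.TOL:
                return
            if j > 0 and abs(self.W[j - 1] - w) <= self.TOL:
                j -= 1
                continue
            for i in range(0, j):
                prev = self.W[i - 1] if i > 0 else 0.0
                if self.V[i, j] < INF and abs(prev + self.V[i, j] - w) <= self.TOL:
                    self._trace_v(i, j)
                    j = i - 1
                    break
            else:  # pragma: no cover - matrices are self-consistent
                raise AssertionError("external traceback failed")

    def _trace_v(self, i, j):
        md = self.md
        self.pairs.append((i, j))
        v = self.V[i, j]
        pij = self._p(i, j)
        if abs(md.hairpin(j - i - 1) - v) <= self.TOL:
            return
        pin = self._p(i + 1, j - 1)
        if pin >= 0 and self.V[i + 1, j - 1] < INF and \
                abs(self.V[i + 1, j - 1] + md.stack[pij, pin] - v) <= self.TOL:
            self._trace_v(i + 1, j - 1)
            return
        for tot in range(1, md.max_interior + 1):
            for l1 in range(0, tot + 1):
                l2 = tot - l1
                k, l = i + 1 + l1, j - 1 - l2
                if k >= l or self._p(k, l) < 0 or self.V[k, l] >= INF:
                    continue
                pen = md.bulge(tot) if (l1 == 0 or l2 == 0) else md.internal(tot)
                if abs(self.V[k, l] + pen - v) <= self.TOL:
                    self._trace_v(k, l)
                    return
        for k in range(i + 1, j - 1):
            if self.M[i + 1, k] < INF and self.M1[k + 1, j - 1] < INF and \
                    abs(self.M[i + 1, k] + self.M1[k + 1, j - 1] + md.ml_close - v) <= self.TOL:
                self._trace_m(i + 1, k)
                self._trace_m1(k + 1, j - 1)
                return
        raise AssertionError("V traceback failed")  # pragma: no cover

    def _trace_m(self, i, j):
        md = self.md
        while True:
            m = self.M[i, j]
            if i + 1 <= j and self.M[i + 1, j] < INF and \
                    abs(self.M[i + 1, j] + md.ml_unpaired - m) <= self.TOL:
                i += 1
                continue
            if abs(self.M1[i, j] - m) <= self.TOL:
                self._trace_m1(i, j)
                return
            for k in range(i, j):
                if self.M[i, k] < INF and self.M1[k + 1, j] < INF and \
                        abs(self.M[i, k] + self.M1[k + 1, j] - m) <= self.TOL:
                    self._trace_m(i, k)
                    self._trace_m1(k + 1, j)
                    return
            raise AssertionError("M traceback failed")  # pragma: no cover

    def _trace_m1(self, i, j):
        md = self.md
        while True:
            m = self.M1[i, j]
            if j > i and self.M1[i, j - 1] < INF and \
                    abs(self.M1[i, j - 1] + md.ml_unpaired - m) <= self.TOL:
                j -= 1
                continue
            if self.V[i, j] < INF and abs(self.V[i, j] + md.ml_branch - m) <= self.TOL:
                self._trace_v(i, j)
                return
            raise AssertionError("M1 traceback failed")  # pragma: no cover


@dataclass
class FoldResult:
    """A predicted structure with its free energy (kcal/mol, <= 0)."""

    sequence: str
    structure: str
    mfe: float

    def pair_table(self) -> PairTable:
        return parse_dotbracket(self.structure)


def fold_mfe(seq: str, model: EnergyModel | None = None) -> FoldResult:
    """Fold an unambiguous RNA to its minimum-free-energy structure.

    The empty structure always scores 0, so the reported MFE is <= 0.
    Deterministic: co-optimal structures are resolved by the pinned
    traceback preference order (fewer pairs first).
    """
    if not seq:
        raise SequenceError("cannot fold an empty sequence")
    md = model or default_model()
    enc = _encode(seq)
    n = len(seq)
    if n <= md.min_hairpin + 1:
        return FoldResult(seq, "." * n, 0.0)
    hp, bu, it = md.loop_tables(n)
    V, M, M1, W = _fill(
        enc, md.pair_idx, md.stack, hp, bu, it,
        md.min_hairpin, md.max_interior, md.ml_close, md.ml_branch, md.ml_unpaired,
    )
    if W[n - 1] >= 0.0:
        return FoldResult(seq, "." * n, 0.0)
    pairs = _Tracer(enc, md, V, M, M1, W).run()
    out = ["."] * n
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    structure = "".join(out)
    # report the independently re-scored energy so mfe is exactly the sum
    # of the pinned terms of the returned structure
    mfe = score_structure(seq, structure, md)
    return FoldResult(seq, structure, float(mfe))


def score_structure(seq: str, structure: str | PairTable,
                    model: EnergyModel | None = None) -> float:
    """Score a structure by direct loop decomposition (independent of the DP).

    Decomposes the structure into hairpin, stack, bulge, interior and
    multiloop terms under the pinned model and sums them.  Used both to
    report :func:`fold_mfe` energies and as the basis of the exhaustive
    test oracle.
    """
    md = model or default_model()
    pt = structure if isinstance(structure, PairTable) else parse_dotbracket(structure)
    enc = _encode(seq)
    n = len(seq)

    def pair_of(i1: int, j1: int) -> int:  # 1-based
        k = md.pair_idx[enc[i1 - 1], enc[j1 - 1]]
        if k < 0:
            raise SequenceError(f"non-canonical pair {seq[i1-1]}:{seq[j1-1]} at ({i1},{j1})")
        return k

    total = 0.0
    for (i, j) in pt.pairs():
        # direct children of (i, j)
        children = []
        k = i + 1
        while k < j:
            if pt[k] > k:
                children.append((k, pt[k]))
                k = pt[k] + 1
            elif pt[k] != 0 and pt[k] < k:
                raise SequenceError("crossing pairs are not nested")
            else:
                k += 1
        if not children:
            total += md.hairpin(j - i - 1)
        elif len(children) == 1:
            (k1, l1) = children[0]
            a, b = k1 - i - 1, j - l1 - 1
            if a == 0 and b == 0:
                total += md.stack[pair_of(i, j), pair_of(k1, l1)]
            elif a == 0 or b == 0:
                total += md.bulge(a + b)
            else:
                total += md.internal(a + b)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += md.ml_close + md.ml_branch * len(children) + md.ml_unpaired * unpaired
    return total


# ---------------------------------------------------------------------------
# Precursor window extraction
# ---------------------------------------------------------------------------

DEFAULT_FLANK_STEPS = tuple(range(0, 200, 20))  # 0, 20, ..., 180 nt


@dataclass
class PrecursorCandidate:
    """A folded candidate precursor window around a homology hit.

    ``window_interval`` is on the forward strand of the subject;
    ``mature_interval`` is within the precursor (sense orientation of
    the hit, so the precursor contains the matched mature as-is).
    """

    subject_id: str
    window_interval: tuple[int, int]
    precursor_sequence: str
    mature_interval: tuple[int, int]
    fold: FoldResult
    strand: str = "+"

    @property
    def lp(self) -> int:
        return len(self.precursor_sequence)

    @property
    def mature_sequence(self) -> str:
        s, e = self.mature_interval
        return self.precursor_sequence[s - 1 : e]


def _gc_percent(seq: str) -> float:
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def extract_precursor_windows(
    subject: SequenceRecord,
    hit: HomologyHit,
    flank_steps: tuple[int, ...] = DEFAULT_FLANK_STEPS,
    min_lp: int = 0,
    max_lp: int = 400,
    model: EnergyModel | None = None,
) -> list[PrecursorCandidate]:
    """Fold candidate precursor windows spanning a homology hit.

    Every (upstream, downstream) extension from *flank_steps* is applied
    around the matched interval (clipped at the subject's ends); windows
    with length outside [min_lp, max_lp] are skipped.  Duplicate windows
    after clipping collapse to one candidate.  Candidates are sorted by
    |MFEI| descending (ties: shorter window, then 5' first).

    The published analyses never state how precursor boundaries were
    chosen from each EST/GSS; this grid search over symmetric and
    asymmetric extensions is this package's stand-in for that step.
    """
    if not (1 <= hit.start <= hit.end <= len(subject.sequence)):
        raise ValueError("hit does not lie on the subject")
    md = model or default_model()
    seen: set[tuple[int, int]] = set()
    cands: list[PrecursorCandidate] = []
    for up in flank_steps:
        for down in flank_steps:
            s = max(1, hit.start - up)
            e = min(len(subject.sequence), hit.end + down)
            if (s, e) in seen:
                continue
            seen.add((s, e))
            lp = e - s + 1
            if lp < min_lp or lp > max_lp:
                continue
            window = subject.sequence[s - 1 : e]
            if hit.strand == "+":
                pre = window
                m_s, m_e = hit.start - s + 1, hit.end - s + 1
            else:
                pre = reverse_complement(window)
                m_s, m_e = e - hit.end + 1, e - hit.start + 1
            try:
                fold = fold_mfe(pre, md)
            except SequenceError:
                continue  # ambiguity codes in the window
            cands.append(
                PrecursorCandidate(
                    subject_id=subject.id,
                    window_interval=(s, e),
                    precursor_sequence=pre,
                    mature_interval=(m_s, m_e),
                    fold=fold,
                    strand=hit.strand,
                )
            )

    def mfei_mag(c: PrecursorCandidate) -> float:
        gc = _gc_percent(c.precursor_sequence)
        if gc == 0.0 or c.fold.mfe == 0.0:
            return 0.0
        return abs((c.fold.mfe / c.lp * 100.0) / gc)

    cands.sort(key=lambda c: (-mfei_mag(c), c.lp, c.window_interval))
    return cands
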