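"""Sequence and structure I/O.

Reads and writes the plain-text formats the pipeline touches — FASTA,
Vienna dot-bracket, CT, TSV, Newick — and normalizes every nucleotide
sequence into a single internal RNA representation (uppercase, T→U).

Coordinates are 1-based inclusive throughout the package.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO

RNA_BASES = frozenset("AUGC")
#: IUPAC nucleotide ambiguity codes (everything legal beyond A/U/G/C).
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")

SOURCE_TAGS = ("EST", "GSS", "reference", "transcript", "synthetic")

_COMPLEMENT = str.maketrans("AUGC", "UACG")


class SequenceError(ValueError):
    """Malformed sequence input (bad characters, duplicate ids, empty files)."""


def normalize_to_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert DNA T to RNA U.

    Idempotent; ambiguity codes are preserved.  Raises
    :class:`SequenceError` for an empty string or characters outside the
    IUPAC nucleotide alphabet (1-based position reported).
    """
    if not seq:
        raise SequenceError("empty sequence")
    out = seq.upper().replace("T", "U")
    for pos, ch in enumerate(out, start=1):
        if ch not in RNA_BASES and ch not in AMBIGUITY_CODES:
            raise SequenceError(f"non-nucleotide character {ch!r} at position {pos}")
    return out


def has_ambiguity(seq: str) -> bool:
    """True if *seq* contains any IUPAC ambiguity code (N, R, Y, ...)."""
    return any(ch in AMBIGUITY_CODES for ch in seq)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an unambiguous RNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence normalized to the RNA alphabet.

    ``source`` tags where the sequence came from (EST, GSS, reference,
    transcript or synthetic); ``ambiguous`` flags the presence of IUPAC
    ambiguity codes, which excludes windows from scanning and folding.
    """

    id: str
    sequence: str
    source: str = "EST"
    description: str = ""
    ambiguous: bool = field(init=False)

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"invalid record id {self.id!r}")
        if self.source not in SOURCE_TAGS:
            raise SequenceError(f"unknown source tag {self.source!r}")
        self.sequence = normalize_to_rna(self.sequence)
        self.ambiguous = has_ambiguity(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | os.PathLike, source: str = "EST") -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Record order is preserved; duplicate ids and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=str(rec.seq),
                source=source,
                description=rec.description,
            )
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at *width* columns."""
    with open(path, "w") as fh:
        for r in records:
            desc = r.description or ""
            if desc and desc.split()[0] == r.id:
                desc = desc[len(r.id):].lstrip()
            header = f">{r.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Secondary-structure representation and interchange
# ---------------------------------------------------------------------------


class StructureError(ValueError):
    """Malformed secondary-structure input."""


@dataclass
class PairTable:
    """Base-pair partner table for a pseudoknot-free secondary structure.

    ``partner`` has length L+1 and is indexed 1..L; ``partner[i] == j``
    means i pairs j, 0 means unpaired.  Index 0 is unused.
    """

    partner: list[int]

    def __post_init__(self) -> None:
        p = self.partner
        if not p or p[0] != 0:
            raise StructureError("partner table must start with a sentinel 0")
        for i in range(1, len(p)):
            j = p[i]
            if j:
                if j == i:
                    raise StructureError(f"position {i} pairs with itself")
                if not (1 <= j < len(p)) or p[j] != i:
                    raise StructureError(f"asymmetric pair at position {i}")

    def __len__(self) -> int:
        return len(self.partner) - 1

    def __getitem__(self, i: int) -> int:
        return self.partner[i]

    def pairs(self) -> list[tuple[int, int]]:
        """All base pairs (i, j) with i < j, ascending in i."""
        return [(i, self.partner[i]) for i in range(1, len(self.partner)) if self.partner[i] > i]

    def to_dotbracket(self) -> str:
        out = ["."] * len(self)
        for i, j in self.pairs():
            out[i - 1] = "("
            out[j - 1] = ")"
        return "".join(out)


def parse_dotbracket(structure: str) -> PairTable:
    """Parse a dot-bracket string into a :class:`PairTable`.

    Only '.', '(' and ')' are accepted; unbalanced brackets raise
    :class:`StructureError` naming the first offending 1-based position.
    """
    partner = [0] * (len(structure) + 1)
    stack: list[int] = []
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {pos}")
            i = stack.pop()
            partner[i] = pos
            partner[pos] = i
        elif ch != ".":
            raise StructureError(f"illegal structure character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unclosed '(' at position {stack[0]}")
    return PairTable(partner)


def read_dotbracket(path: str | os.PathLike) -> list[tuple[str, str, str, float | None]]:
    """Read a Vienna dot-bracket (.dbn) file.

    Each record is a header line, a sequence line and a structure line;
    a trailing ``(-12.3)`` energy annotation on the structure line is
    parsed as the MFE.  Returns (id, sequence, structure, mfe) tuples.
    """
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureError(f"expected FASTA-style header at line {i + 1} of {path}")
        if i + 2 >= len(lines):
            raise StructureError(f"truncated dot-bracket record at end of {path}")
        header = lines[i][1:].strip()
        seq = normalize_to_rna(lines[i + 1].strip())
        struct_line = lines[i + 2].strip()
        mfe: float | None = None
        if " " in struct_line:
            struct, _, tail = struct_line.partition(" ")
            tail = tail.strip()
            if tail.startswith("(") and tail.endswith(")"):
                mfe = float(tail[1:-1])
        else:
            struct = struct_line
        if len(struct) != len(seq):
            raise StructureError(f"structure/sequence length mismatch for {header!r}")
        parse_dotbracket(struct)  # validate
        out.append((header.split()[0], seq, struct, mfe))
        i += 3
    return out


def write_dotbracket(records: Iterable[tuple[str, str, str, float | None]],
                     path: str | os.PathLike) -> None:
    """Write (id, sequence, structure, mfe) tuples in Vienna .dbn layout."""
    with open(path, "w") as fh:
        for rid, seq, struct, mfe in records:
            fh.write(f">{rid}\n{seq}\n{struct}")
            if mfe is not None:
                fh.write(f" ({mfe:.2f})")
            fh.write("\n")


def read_ct(path: str | os.PathLike) -> tuple[str, PairTable]:
    """Read a CT (connectivity table) structure file.

    Columns per base line: index, base, previous, next, partner, index.
    Returns the sequence and its :class:`PairTable`.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise StructureError(f"empty CT file {path}")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError):
        raise StructureError(f"bad CT header in {path}") from None
    if len(lines) - 1 < n:
        raise StructureError(f"CT file {path} promises {n} bases, has {len(lines) - 1}")
    bases = []
    partner = [0] * (n + 1)
    for ln in lines[1 : n + 1]:
        cols = ln.split()
        if len(cols) < 6:
            raise StructureError(f"short CT line: {ln!r}")
        idx, base, partner_idx = int(cols[0]), cols[1], int(cols[4])
        bases.append(base)
        partner[idx] = partner_idx
    seq = normalize_to_rna("".join(bases))
    return seq, PairTable(partner)


# ---------------------------------------------------------------------------
# Tabular and tree output
# ---------------------------------------------------------------------------


def write_tsv(rows: Sequence[dict], path: str | os.PathLike,
              columns: Sequence[str] | None = None) -> None:
    """Write dict rows as a TSV with a header line.

    An empty row list still produces the header (columns required then).
    Floats are rendered with repr-style shortest form for determinism.
    """
    if columns is None:
        if not rows:
            raise ValueError("columns must be given for an empty report")
        columns = list(rows[0].keys())
    buf = io.StringIO()
    buf.write("\t".join(columns) + "\n")
    for row in rows:
        buf.write("\t".join(_cell(row.get(c, "")) for c in columns) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _cell(value) -> str:
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def read_tsv(path: str | os.PathLike) -> list[dict]:
    """Read a header-rowed TSV back into a list of string-valued dicts."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"empty TSV {path}")
    cols = lines[0].split("\t")
    return [dict(zip(cols, ln.split("\t"))) for ln in lines[1:]]


def write_newick(tree, path: str | os.PathLike | None = None) -> str:
    """Serialize a tree (anything with ``to_newick()``) to Newick text.

    Returns the Newick string; also writes it to *path* when given.
    """
    text = tree.to_newick() if hasattr(tree, "to_newick") else str(tree)
    if not text.endswith(";"):
        text += ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
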