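"""Sequence and alignment I/O.

Plain FASTA is handled through Bio.SeqIO.  On top of that this module
defines an *annotated FASTA* dialect that carries, for each record, the
per-position gap-opening penalties and the predicted indel-flanking-region
(IndelFR) intervals that drive the variable gap penalty of the aligner::

    >id description
    MKVLH...            (sequence lines, wrapped at 60)
    #GPO 4.1000 3.2000 ...   (one non-negative real per residue)
    #IFR 12-31 80-95         (1-based inclusive intervals; may be empty)

The two ``#`` lines follow each record's sequence lines, so files remain
readable by FASTA parsers that skip comment-style lines.  Intervals are
1-based inclusive on disk and 0-based half-open in memory.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from io import StringIO
from typing import Sequence

import numpy as np
from Bio import SeqIO

#: The 20 standard amino acids, in the classic PAM ordering used by the
#: packaged substitution-matrix file.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_AA_SET = frozenset(AMINO_ACIDS)

#: Letters that are legal in permissive mode only (ambiguity/rare codes).
NONSTANDARD = frozenset("BJOUXZ")

GAP = "-"

_WRAP = 60


class FastaFormatError(ValueError):
    """Raised for malformed FASTA / annotated-FASTA input."""


@dataclass(frozen=True)
class ProteinSequence:
    """An ungapped protein sequence over the 20 standard residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}")
        if not self.residues:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - _AA_SET - {"X"}
        if bad:
            raise FastaFormatError(
                f"record {self.id!r} contains illegal residue(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _clean_residues(raw: str, *, permissive: bool, record_id: str) -> str:
    s = raw.upper().replace(".", "").replace(GAP, "")
    if permissive:
        s = "".join("X" if c in NONSTANDARD else c for c in s)
    else:
        bad = sorted(set(s) & NONSTANDARD)
        if bad:
            raise FastaFormatError(
                f"record {record_id!r} contains non-standard residue(s) "
                f"{''.join(bad)!r} (strict mode)"
            )
    return s


@dataclass(frozen=True)
class AnnotatedSequence:
    """A sequence plus its variable-gap-penalty annotation.

    ``gpo`` holds one non-negative gap-opening penalty per residue;
    ``ifrs`` the predicted IndelFR intervals, sorted, disjoint, 0-based
    half-open within ``[0, n)``.
    """

    seq: ProteinSequence
    gpo: np.ndarray
    ifrs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        gpo = np.asarray(self.gpo, dtype=float)
        object.__setattr__(self, "gpo", gpo)
        object.__setattr__(self, "ifrs", tuple(tuple(map(int, iv)) for iv in self.ifrs))
        n = len(self.seq)
        if gpo.shape != (n,):
            raise ValueError(
                f"record {self.seq.id!r}: {gpo.size} gap-opening penalties "
                f"for {n} residues"
            )
        if np.any(gpo < 0) or not np.all(np.isfinite(gpo)):
            raise ValueError(f"record {self.seq.id!r}: gpo values must be finite and >= 0")
        prev_end = 0
        for a, b in self.ifrs:
            if not (0 <= a < b <= n):
                raise ValueError(f"record {self.seq.id!r}: interval [{a},{b}) out of range")
            if a < prev_end:
                raise ValueError(f"record {self.seq.id!r}: intervals overlap or unsorted")
            prev_end = b


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows; no column may be all gaps."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "rows", tuple(self.rows))
        if len(self.ids) != len(self.rows) or not self.rows:
            raise ValueError("ids and rows must be non-empty and of equal count")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows have unequal lengths")
        for j in range(width):
            if all(r[j] == GAP for r in self.rows):
                raise ValueError(f"alignment column {j} consists entirely of gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def degapped(self) -> list[ProteinSequence]:
        return [
            ProteinSequence(i, r.replace(GAP, "")) for i, r in zip(self.ids, self.rows)
        ]


class SubstitutionMatrix:
    """A symmetric residue-pair scoring matrix over a fixed alphabet."""

    def __init__(self, alphabet: str, scores: np.ndarray):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(alphabet), len(alphabet)):
            raise ValueError("score matrix shape does not match alphabet")
        if not np.allclose(scores, scores.T):
            raise ValueError("substitution matrix must be symmetric")
        self.alphabet = alphabet
        self.scores = scores
        self._index = {a: i for i, a in enumerate(alphabet)}
        # X (wildcard) scores as the row minimum: a conservative penalty
        # that invents no chemistry for ambiguous residues.
        if "X" not in self._index:
            mins = scores.min(axis=1)
            self._x_scores = mins
            self._x_vs_x = float(scores.min())

    def index(self, residue: str) -> int:
        return self._index[residue]

    def score(self, a: str, b: str) -> float:
        if a == "X" or b == "X":
            if a == b:
                return self._x_vs_x
            other = b if a == "X" else a
            return float(self._x_scores[self._index[other]])
        return float(self.scores[self._index[a], self._index[b]])


def load_gonnet250() -> SubstitutionMatrix:
    """Load the packaged GONNET250 (Gonnet PAM250) substitution matrix."""
    text = (
        importlib.resources.files("flankalign.data")
        .joinpath("gonnet250.txt")
        .read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    alphabet = "".join(lines[0].split())
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        rows.append([float(v) for v in parts[1:]])
    return SubstitutionMatrix(alphabet, np.array(rows))


# ---------------------------------------------------------------------------
# plain FASTA

def read_fasta(path, *, permissive: bool = False) -> list[ProteinSequence]:
    """Read standard (ungapped) FASTA into ProteinSequence records."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        residues = _clean_residues(str(rec.seq), permissive=permissive, record_id=rec.id)
        if not residues:
            raise FastaFormatError(f"record {rec.id!r} has an empty sequence")
        out.append(ProteinSequence(rec.id, residues, desc))
    return out


def write_fasta(seqs: Sequence[ProteinSequence], path) -> None:
    if not seqs:
        raise ValueError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for s in seqs:
            _write_record(fh, s.id, s.description, s.residues)


def _write_record(fh, rid: str, desc: str, body: str) -> None:
    header = f">{rid} {desc}".rstrip()
    fh.write(header + "\n")
    for i in range(0, len(body), _WRAP):
        fh.write(body[i : i + _WRAP] + "\n")


def read_alignment(path) -> MultipleAlignment:
    """Read aligned FASTA (rows may contain '-' or '.')."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    ids = tuple(r.id for r in records)
    rows = tuple(str(r.seq).upper().replace(".", GAP) for r in records)
    return MultipleAlignment(ids, rows)


def write_alignment(aln: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            _write_record(fh, rid, "", row)


# ---------------------------------------------------------------------------
# annotated FASTA dialect

def format_annotated(seqs: Sequence[AnnotatedSequence]) -> str:
    buf = StringIO()
    for ann in seqs:
        s = ann.seq
        header = f">{s.id} {s.description}".rstrip()
        buf.write(header + "\n")
        for i in range(0, len(s.residues), _WRAP):
            buf.write(s.residues[i : i + _WRAP] + "\n")
        buf.write("#GPO " + " ".join(f"{v:.4f}" for v in ann.gpo) + "\n")
        # 0-based half-open in memory -> 1-based inclusive on disk
        buf.write("#IFR" + "".join(f" {a + 1}-{b}" for a, b in ann.ifrs) + "\n")
    return buf.getvalue()


def write_annotated_fasta(seqs: Sequence[AnnotatedSequence], path) -> None:
    if not seqs:
        raise ValueError("refusing to write an empty annotated FASTA file")
    with open(path, "w") as fh:
        fh.write(format_annotated(seqs))


def parse_annotated(text: str, *, permissive: bool = False, strict_gpo: bool = True
                    ) -> list[AnnotatedSequence]:
    out: list[AnnotatedSequence] = []
    rid = desc = None
    seq_parts: list[str] = []
    gpo: list[float] | None = None
    ifrs_raw: list[tuple[int, int]] | None = None

    def flush():
        nonlocal rid, desc, seq_parts, gpo, ifrs_raw
        if rid is None:
            return
        residues = _clean_residues("".join(seq_parts), permissive=permissive, record_id=rid)
        if not residues:
            raise FastaFormatError(f"record {rid!r} has an empty sequence")
        seq = ProteinSequence(rid, residues, desc or "")
        n = len(residues)
        if gpo is None:
            if strict_gpo:
                raise FastaFormatError(f"record {rid!r} is missing its #GPO block")
            g = np.zeros(n)
        else:
            if len(gpo) != n:
                raise FastaFormatError(
                    f"record {rid!r}: {len(gpo)} #GPO values for {n} residues"
                )
            g = np.asarray(gpo)
        ivs: list[tuple[int, int]] = []
        for a, b in ifrs_raw or []:
            if not (1 <= a <= b <= n):
                raise FastaFormatError(
                    f"record {rid!r}: #IFR interval {a}-{b} outside [1, {n}]"
                )
            ivs.append((a - 1, b))  # 1-based inclusive -> 0-based half-open
        out.append(AnnotatedSequence(seq, g, tuple(sorted(ivs))))
        rid = desc = None
        seq_parts, gpo, ifrs_raw = [], None, None

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            head = line[1:].split(None, 1)
            rid = head[0] if head else ""
            desc = head[1] if len(head) > 1 else ""
            if not rid:
                raise FastaFormatError("FASTA header with empty id")
        elif line.startswith("#GPO"):
            if rid is None:
                raise FastaFormatError("#GPO line before any record header")
            gpo = [float(v) for v in line[4:].split()]
        elif line.startswith("#IFR"):
            if rid is None:
                raise FastaFormatError("#IFR line before any record header")
            ifrs_raw = []
            for token in line[4:].split():
                a, _, b = token.partition("-")
                try:
                    ifrs_raw.append((int(a), int(b)))
                except ValueError as exc:
                    raise FastaFormatError(
                        f"record {rid!r}: malformed #IFR token {token!r}"
                    ) from exc
        elif line.startswith("#"):
            continue  # unknown comment line: skip
        else:
            if rid is None:
                raise FastaFormatError("sequence data before any record header")
            seq_parts.append(line)
    flush()
    if not out:
        raise FastaFormatError("no annotated FASTA records found")
    return out


def read_annotated_fasta(path, *, permissive: bool = False, strict_gpo: bool = True
                         ) -> list[AnnotatedSequence]:
    with open(path) as fh:
        text = fh.read()
    try:
        return parse_annotated(text, permissive=permissive, strict_gpo=strict_gpo)
    except FastaFormatError as exc:
        raise FastaFormatError(f"{path}: {exc}") from exc
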