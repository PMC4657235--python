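"""Pairwise distance estimation by approximate word matching.

The aligner orders its progressive merges with distances derived from the
Muth–Manber one-error pattern-matching idea: every length-k word of the
shorter sequence is credited with the best agreement, (k - mismatches)/k,
it achieves against any word of the longer sequence, counting only word
pairs with at most one mismatch; the identity is the mean credit.  The
exact k-tuple identity (no mismatches allowed) is provided for contrast:
for the pair ABCABCABC / ABDABDABD it reports 0 shared words while the
one-error variant reports 67 % identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import ProteinSequence

DEFAULT_WORD = 3


def _residues(s) -> str:
    return s.residues if isinstance(s, ProteinSequence) else str(s)


def _words(s: str, k: int) -> list[str]:
    return [s[i : i + k] for i in range(len(s) - k + 1)]


def mm_identity(a, b, k: int = DEFAULT_WORD) -> float:
    """One-error word-matching identity in [0, 1] (symmetric).

    Accepts ProteinSequence or plain strings.
    """
    sa, sb = _residues(a), _residues(b)
    if len(sa) < k or len(sb) < k:
        raise ValueError(f"both sequences must be at least k={k} long")
    if len(sa) > len(sb):
        sa, sb = sb, sa
    short = _words(sa, k)
    longer = _words(sb, k)
    total = 0.0
    for w in short:
        best = 0.0
        for v in longer:
            mism = sum(1 for x, y in zip(w, v) if x != y)
            if mism <= 1:
                credit = (k - mism) / k
                if credit > best:
                    best = credit
                    if mism == 0:
                        break
        total += best
    return total / len(short)


def ktuple_identity(a, b, k: int = DEFAULT_WORD) -> float:
    """Fraction of the shorter sequence's k-words with an exact match."""
    sa, sb = _residues(a), _residues(b)
    if len(sa) < k or len(sb) < k:
        raise ValueError(f"both sequences must be at least k={k} long")
    if len(sa) > len(sb):
        sa, sb = sb, sa
    longer = set(_words(sb, k))
    short = _words(sa, k)
    return sum(1 for w in short if w in longer) / len(short)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match id count")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(("",) + self.ids) + "\n")
            for rid, row in zip(self.ids, self.values):
                fh.write(rid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def distance_matrix(seqs, k: int = DEFAULT_WORD) -> DistanceMatrix:
    """All-pairs distances d = 1 - mm_identity."""
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences for a distance matrix")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - mm_identity(seqs[i], seqs[j], k)
    ids = tuple(
        s.id if isinstance(s, ProteinSequence) else f"s{i}" for i, s in enumerate(seqs)
    )
    return DistanceMatrix(ids, d)
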