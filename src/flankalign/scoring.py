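"""Sum-of-pairs (SP) and total-column (TC) alignment accuracy.

Both metrics compare a test alignment against a reference whose reliably
aligned regions are marked by a *core-block* mask (absent mask: every
column is core).  SP is the fraction of core residue pairs of the
reference — (sequence pair, residue index pair) co-occurrences in a
column — that share a column in the test alignment; TC is the fraction of
core reference columns whose non-gap residues all co-occur in a single
test column.  For two-sequence alignments the metrics coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import GAP, MultipleAlignment


@dataclass(frozen=True)
class ReferenceAlignment:
    """A reference alignment with a per-column core-block mask."""

    alignment: MultipleAlignment
    core_mask: np.ndarray | None = None

    def __post_init__(self):
        width = self.alignment.n_columns
        mask = self.core_mask
        if mask is None:
            mask = np.ones(width, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (width,):
            raise ValueError("core mask length must equal reference column count")
        if not mask.any():
            raise ValueError("core mask marks no column; nothing to score")
        object.__setattr__(self, "core_mask", mask)


def read_core_mask(path, n_columns: int) -> np.ndarray:
    """Read a core-block mask file: 1-based inclusive column ranges."""
    mask = np.zeros(n_columns, dtype=bool)
    with open(path) as fh:
        for line in fh:
            for token in line.split():
                a, _, b = token.partition("-")
                lo = int(a)
                hi = int(b) if b else lo
                if not (1 <= lo <= hi <= n_columns):
                    raise ValueError(
                        f"core-block range {token!r} outside [1, {n_columns}]"
                    )
                mask[lo - 1 : hi] = True
    return mask


def _column_of_residue(aln: MultipleAlignment) -> dict[str, np.ndarray]:
    """Per row id: array mapping residue index -> alignment column."""
    out = {}
    for rid, row in zip(aln.ids, aln.rows):
        cols = np.fromiter(
            (j for j, c in enumerate(row) if c != GAP), dtype=np.int64
        )
        out[rid] = cols
    return out


def _check_compatible(test: MultipleAlignment, ref: MultipleAlignment) -> None:
    if set(test.ids) != set(ref.ids):
        raise ValueError("test and reference alignments have different sequence ids")
    if len(set(test.ids)) != len(test.ids):
        raise ValueError("duplicate sequence ids")
    by_id = dict(zip(test.ids, test.rows))
    for rid, ref_row in zip(ref.ids, ref.rows):
        if by_id[rid].replace(GAP, "") != ref_row.replace(GAP, ""):
            raise ValueError(f"sequence {rid!r} differs between test and reference")


def sp_score(test: MultipleAlignment, ref: ReferenceAlignment) -> float:
    """Fraction of core reference residue pairs recovered by the test."""
    _check_compatible(test, ref.alignment)
    raln = ref.alignment
    test_cols = _column_of_residue(test)
    ref_cols = _column_of_residue(raln)
    # residue index of each (row, ref column); -1 where gapped
    ridx = {}
    for rid, cols in ref_cols.items():
        arr = np.full(raln.n_columns, -1, dtype=np.int64)
        arr[cols] = np.arange(cols.size)
        ridx[rid] = arr
    ids = raln.ids
    total = correct = 0
    core = np.flatnonzero(ref.core_mask)
    for a in range(len(ids)):
        ra = ridx[ids[a]]
        ta = test_cols[ids[a]]
        for b in range(a + 1, len(ids)):
            rb = ridx[ids[b]]
            tb = test_cols[ids[b]]
            present = (ra[core] >= 0) & (rb[core] >= 0)
            ia = ra[core][present]
            ib = rb[core][present]
            total += ia.size
            correct += int(np.count_nonzero(ta[ia] == tb[ib]))
    if total == 0:
        raise ValueError("reference core blocks contain no residue pairs")
    return correct / total


def tc_score(test: MultipleAlignment, ref: ReferenceAlignment) -> float:
    """Fraction of core reference columns exactly recovered by the test."""
    _check_compatible(test, ref.alignment)
    raln = ref.alignment
    test_cols = _column_of_residue(test)
    ref_cols = _column_of_residue(raln)
    ridx = {}
    for rid, cols in ref_cols.items():
        arr = np.full(raln.n_columns, -1, dtype=np.int64)
        arr[cols] = np.arange(cols.size)
        ridx[rid] = arr
    core = np.flatnonzero(ref.core_mask)
    correct = 0
    for j in core:
        seen = set()
        ok = True
        for rid in raln.ids:
            k = ridx[rid][j]
            if k < 0:
                continue  # gapped rows do not constrain the column
            seen.add(int(test_cols[rid][k]))
            if len(seen) > 1:
                ok = False
                break
        if ok and seen:
            correct += 1
    return correct / core.size
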