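"""Profile–profile global alignment with the variable gap penalty.

Three-state affine dynamic programming (Gotoh-style) where the gap opening
and extension penalties are per position / per profile column rather than
constants.  States at prefix pair (i, j):

* ``M(i,j)``   — column i of A aligned with column j of B,
* ``I_A(i,j)`` — column i of A aligned against a gap,
* ``I_B(i,j)`` — column j of B aligned against a gap.

A gap run that consumes columns ``i0..i1`` of a profile is charged
``GPO[i0] + sum(GPE[i0..i1])`` from *that profile's* penalty arrays, so
gaps are cheap exactly where the indel-flank predictor assigns low
log-loss.  A gap state may open after either of the other two states (each
run pays its own opening), which makes the recursion attain the true
maximum over all global alignments.  Terminal gaps are charged like
internal ones.

Besides the full-matrix solver (quadratic memory, deterministic traceback
preferring M, then I_A, then I_B) a divide-and-conquer solver in linear
space is provided; both produce the same score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gap_model import GapPenalties, merge_gap_penalties
from .seqio import GAP, AnnotatedSequence, MultipleAlignment, ProteinSequence, SubstitutionMatrix

NEG = -np.inf

#: cell budget below which the linear-space solver falls back to the
#: full matrix (the asymptotics of the recursion are unaffected)
_BASE_CELLS = 4096


def _extended_scores(S: SubstitutionMatrix) -> tuple[str, np.ndarray]:
    """Alphabet and score table with an explicit X (wildcard) entry."""
    if "X" in S.alphabet:
        return S.alphabet, S.scores
    k = len(S.alphabet)
    ext = np.empty((k + 1, k + 1))
    ext[:k, :k] = S.scores
    ext[k, :k] = ext[:k, k] = S.scores.min(axis=1)
    ext[k, k] = S.scores.min()
    return S.alphabet + "X", ext


@dataclass(frozen=True)
class Profile:
    """An alignment treated as a single alignable object.

    ``counts[c]`` holds per-column residue counts (gaps excluded) over the
    extended alphabet; ``penalties`` carries the merged per-column gap
    penalties.
    """

    alignment: MultipleAlignment
    counts: np.ndarray
    penalties: GapPenalties
    alphabet: str

    def __post_init__(self):
        if self.counts.shape[0] != self.alignment.n_columns:
            raise ValueError("counts rows must match alignment columns")
        if len(self.penalties) != self.alignment.n_columns:
            raise ValueError("penalty length must match alignment columns")
        if np.any(self.counts.sum(axis=1) == 0):
            raise ValueError("profile contains an all-gap column")

    @property
    def ids(self) -> tuple[str, ...]:
        return self.alignment.ids

    @property
    def n_columns(self) -> int:
        return self.alignment.n_columns

    @property
    def n_rows(self) -> int:
        return len(self.alignment.rows)


def _count_columns(rows, alphabet: str) -> np.ndarray:
    index = {a: i for i, a in enumerate(alphabet)}
    width = len(rows[0])
    counts = np.zeros((width, len(alphabet)), dtype=float)
    for row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                counts[j, index[c]] += 1
    return counts


def profile_from_annotated(ann: AnnotatedSequence, S: SubstitutionMatrix,
                           gap_scale: float = 1.0) -> Profile:
    """Single-sequence profile carrying the sequence's own penalties.

    ``gap_scale`` converts the annotation's log-loss penalty units into
    substitution-score units before the DP (applied to GPO, and thereby to
    the derived GPE; zero extensions inside IndelFRs stay zero).
    """
    from .gap_model import penalties_for

    alphabet, _ = _extended_scores(S)
    aln = MultipleAlignment((ann.seq.id,), (ann.seq.residues,))
    return Profile(
        alignment=aln,
        counts=_count_columns(aln.rows, alphabet),
        penalties=penalties_for(np.asarray(ann.gpo) * gap_scale, ann.ifrs),
        alphabet=alphabet,
    )


def column_score(col_a: np.ndarray, col_b: np.ndarray, S: SubstitutionMatrix,
                 rows_a: int, rows_b: int) -> float:
    """Expected substitution score of two profile columns.

    ``col_a``/``col_b`` are residue-count vectors; frequencies are taken
    over all rows (so columns are implicitly down-weighted by their gap
    fraction).  Reduces to S(a, b) for two single-residue columns.
    """
    if col_a.sum() == 0 or col_b.sum() == 0:
        raise ValueError("cannot score an all-gap column")
    _, ext = _extended_scores(S)
    fa = col_a / rows_a
    fb = col_b / rows_b
    return float(fa @ ext[: fa.size, : fb.size] @ fb)


def _score_grid(pa: Profile, pb: Profile, ext: np.ndarray) -> np.ndarray:
    fa = pa.counts / pa.n_rows
    fb = pb.counts / pb.n_rows
    return fa @ ext @ fb.T


@dataclass(frozen=True)
class AlignmentResult:
    profile: Profile
    score: float
    trace: tuple[tuple[int | None, int | None], ...]


def dealign(result: AlignmentResult) -> list[ProteinSequence]:
    """Strip gaps from the merged rows, preserving order."""
    return result.profile.alignment.degapped()


# ---------------------------------------------------------------------------
# full-matrix solver

def _forward_tables(cs, gpoA, gpeA, gpoB, gpeB, start: str):
    """Full three-state DP tables; ``start`` is 'F' (free) or 'A' (a gap
    run in B is already open entering the block)."""
    nA, nB = cs.shape
    M = np.full((nA + 1, nB + 1), NEG)
    IA = np.full((nA + 1, nB + 1), NEG)
    IB = np.full((nA + 1, nB + 1), NEG)
    M[0, 0] = 0.0
    if start == "A":
        IA[0, 0] = 0.0
    # row 0: horizontal runs only
    C = np.concatenate(([0.0], np.cumsum(gpeB)))
    if nB:
        seed = np.maximum(M[0, :-1], IA[0, :-1]) - gpoB + C[:-1]
        IB[0, 1:] = np.maximum.accumulate(seed) - C[1:]
    for i in range(1, nA + 1):
        openA = gpoA[i - 1] + gpeA[i - 1]
        IA[i] = np.maximum(
            np.maximum(M[i - 1], IB[i - 1]) - openA, IA[i - 1] - gpeA[i - 1]
        )
        best_prev = np.maximum(np.maximum(M[i - 1], IA[i - 1]), IB[i - 1])
        M[i, 1:] = cs[i - 1] + best_prev[:-1]
        M[i, 0] = NEG
        if nB:
            seed = np.maximum(M[i, :-1], IA[i, :-1]) - gpoB + C[:-1]
            IB[i, 1:] = np.maximum.accumulate(seed) - C[1:]
            IB[i, 0] = NEG
    return M, IA, IB


def _traceback(M, IA, IB, cs, gpoA, gpeA, gpoB, gpeB, end: str):
    nA, nB = cs.shape
    i, j = nA, nB
    if end == "A":
        state = "IA"
    else:
        final = (M[i, j], IA[i, j], IB[i, j])
        state = ("M", "IA", "IB")[int(np.argmax(final))]
        # argmax returns the first maximum, matching the M > IA > IB preference
    trace: list[tuple[int | None, int | None]] = []
    while i > 0 or j > 0:
        if state == "M":
            trace.append((i - 1, j - 1))
            cand = (M[i - 1, j - 1], IA[i - 1, j - 1], IB[i - 1, j - 1])
            state = ("M", "IA", "IB")[int(np.argmax(cand))]
            i, j = i - 1, j - 1
        elif state == "IA":
            trace.append((i - 1, None))
            openA = gpoA[i - 1] + gpeA[i - 1]
            cand = (
                M[i - 1, j] - openA,
                IA[i - 1, j] - gpeA[i - 1],
                IB[i - 1, j] - openA,
            )
            state = ("M", "IA", "IB")[int(np.argmax(cand))]
            i -= 1
        else:
            trace.append((None, j - 1))
            openB = gpoB[j - 1] + gpeB[j - 1]
            cand = (
                M[i, j - 1] - openB,
                IA[i, j - 1] - openB,
                IB[i, j - 1] - gpeB[j - 1],
            )
            state = ("M", "IA", "IB")[int(np.argmax(cand))]
            j -= 1
        if i == 0 and j == 0:
            break
    trace.reverse()
    return trace


def _solve_full(cs, gpoA, gpeA, gpoB, gpeB, start: str = "F", end: str = "F"):
    M, IA, IB = _forward_tables(cs, gpoA, gpeA, gpoB, gpeB, start)
    nA, nB = cs.shape
    if end == "A":
        score = IA[nA, nB]
    else:
        score = max(M[nA, nB], IA[nA, nB], IB[nA, nB])
    trace = _traceback(M, IA, IB, cs, gpoA, gpeA, gpoB, gpeB, end)
    return float(score), trace


# ---------------------------------------------------------------------------
# linear-space solver (divide and conquer over the middle row)

def _forward_vectors(cs, gpoA, gpeA, gpoB, gpeB, start: str):
    """Last-row M/IA/IB vectors of the forward DP, O(nB) memory."""
    nA, nB = cs.shape
    C = np.concatenate(([0.0], np.cumsum(gpeB)))
    M = np.full(nB + 1, NEG)
    IA = np.full(nB + 1, NEG)
    IB = np.full(nB + 1, NEG)
    M[0] = 0.0
    if start == "A":
        IA[0] = 0.0
    if nB:
        seed = np.maximum(M[:-1], IA[:-1]) - gpoB + C[:-1]
        IB[1:] = np.maximum.accumulate(seed) - C[1:]
    for i in range(1, nA + 1):
        openA = gpoA[i - 1] + gpeA[i - 1]
        IA_new = np.maximum(np.maximum(M, IB) - openA, IA - gpeA[i - 1])
        best_prev = np.maximum(np.maximum(M, IA), IB)
        M_new = np.full(nB + 1, NEG)
        M_new[1:] = cs[i - 1] + best_prev[:-1]
        IB_new = np.full(nB + 1, NEG)
        if nB:
            seed = np.maximum(M_new[:-1], IA_new[:-1]) - gpoB + C[:-1]
            IB_new[1:] = np.maximum.accumulate(seed) - C[1:]
        M, IA, IB = M_new, IA_new, IB_new
    return M, IA, IB


def _solve_linear(cs, gpoA, gpeA, gpoB, gpeB, start: str, end: str, offA: int,
                  offB: int, out: list):
    nA, nB = cs.shape
    if nA <= 2 or (nA + 1) * (nB + 1) <= _BASE_CELLS:
        _, trace = _solve_full(cs, gpoA, gpeA, gpoB, gpeB, start, end)
        for j, k in trace:
            out.append((None if j is None else j + offA,
                        None if k is None else k + offB))
        return
    mid = nA // 2
    fM, fIA, fIB = _forward_vectors(cs[:mid], gpoA[:mid], gpeA[:mid], gpoB, gpeB, start)
    # backward over rows mid..nA; need bF at row mid and bA at row mid+1
    bF_mid, bA_next = _backward_rows(cs[mid:], gpoA[mid:], gpeA[mid:], gpoB, gpeB, end)
    best = NEG
    best_j = 0
    best_cross = False
    ext_next = gpeA[mid]  # extending the run into row mid+1
    for j in range(nB + 1):
        clean = max(fM[j], fIA[j], fIB[j]) + bF_mid[j]
        if clean > best:
            best, best_j, best_cross = clean, j, False
        cross = fIA[j] + (-ext_next + bA_next[j])
        if cross > best:
            best, best_j, best_cross = cross, j, True
    top_end = "A" if best_cross else "F"
    bot_start = "A" if best_cross else "F"
    _solve_linear(cs[:mid, :best_j], gpoA[:mid], gpeA[:mid], gpoB[:best_j],
                  gpeB[:best_j], start, top_end, offA, offB, out)
    _solve_linear(cs[mid:, best_j:], gpoA[mid:], gpeA[mid:], gpoB[best_j:],
                  gpeB[best_j:], bot_start, end, offA + mid, offB + best_j, out)


def _backward_rows(cs, gpoA, gpeA, gpoB, gpeB, end: str):
    """Suffix-score vectors for a block: bF at its first row (row 0) and
    bA at its second row (row 1).

    ``bF(i, j)`` is the best score of aligning column suffixes ``A[i:]``
    and ``B[j:]`` starting fresh; ``bA(i, j)`` the same given a vertical
    gap run is open covering column i-1 (extending into column i costs
    only its GPE); ``bB(i, j)`` likewise for a horizontal run covering
    column j-1.  With ``end == 'A'`` the final alignment column must be a
    vertical gap consuming the last column of A.
    """
    nA, nB = cs.shape
    if nA < 2:
        raise ValueError("backward pass needs at least two rows in the block")
    C = np.concatenate(([0.0], np.cumsum(gpeB)))
    # base row nA: only horizontal tails remain (or nothing, for end='A')
    bF = np.full(nB + 1, NEG)
    bB = np.full(nB + 1, NEG)
    bA = np.full(nB + 1, NEG)
    if end == "A":
        bA[nB] = 0.0
    else:
        bF[nB] = 0.0
        bF[:nB] = -(gpoB + (C[nB] - C[:nB]))
        bB[nB] = 0.0
        for j in range(nB - 1, -1, -1):
            bB[j] = max(bF[j], -gpeB[j] + bB[j + 1])
        bA = bF.copy()
    bA_row1 = bA
    for i in range(nA - 1, -1, -1):
        nFv = np.full(nB + 1, NEG)
        nBv = np.full(nB + 1, NEG)
        openA = gpoA[i] + gpeA[i]
        nFv[nB] = -openA + bA[nB]
        nBv[nB] = nFv[nB]
        for j in range(nB - 1, -1, -1):
            best = cs[i, j] + bF[j + 1]
            v = -openA + bA[j]
            if v > best:
                best = v
            h = -(gpoB[j] + gpeB[j]) + nBv[j + 1]
            if h > best:
                best = h
            nFv[j] = best
            ext = -gpeB[j] + nBv[j + 1]
            nBv[j] = ext if ext > best else best
        nAv = np.maximum(nFv, bA - gpeA[i])
        bF, bB = nFv, nBv
        bA_row1 = bA  # becomes row 1's bA once i reaches 0
        bA = nAv
    return bF, bA_row1


def score_trace(pa: Profile, pb: Profile, trace, S: SubstitutionMatrix) -> float:
    """Score an alignment trace under the variable-gap-penalty model."""
    _, ext = _extended_scores(S)
    cs = _score_grid(pa, pb, ext)
    gpoA, gpeA = pa.penalties.gpo, pa.penalties.gpe
    gpoB, gpeB = pb.penalties.gpo, pb.penalties.gpe
    score = 0.0
    prev = None  # 'M' | 'A' | 'B'
    for j, k in trace:
        if j is not None and k is not None:
            score += cs[j, k]
            prev = "M"
        elif j is not None:
            score -= gpeA[j] + (gpoA[j] if prev != "A" else 0.0)
            prev = "A"
        else:
            score -= gpeB[k] + (gpoB[k] if prev != "B" else 0.0)
            prev = "B"
    return float(score)


def _merge_rows(pa: Profile, pb: Profile, trace) -> MultipleAlignment:
    rows_a = pa.alignment.rows
    rows_b = pb.alignment.rows
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    for j, k in trace:
        for r, row in zip(out_a, rows_a):
            r.append(row[j] if j is not None else GAP)
        for r, row in zip(out_b, rows_b):
            r.append(row[k] if k is not None else GAP)
    return MultipleAlignment(
        pa.ids + pb.ids,
        tuple("".join(r) for r in out_a) + tuple("".join(r) for r in out_b),
    )


def align_pair(pa: Profile, pb: Profile, S: SubstitutionMatrix,
               linear_space: bool = False) -> AlignmentResult:
    """Optimal global alignment of two profiles under the VGP model.

    The merged profile's penalties follow the aligned-column sum /
    gap-column copy rule; its rows de-gap to the input rows exactly.
    """
    if pa.alphabet != pb.alphabet:
        raise ValueError("profiles were built over different alphabets")
    _, ext = _extended_scores(S)
    cs = _score_grid(pa, pb, ext)
    gpoA, gpeA = pa.penalties.gpo, pa.penalties.gpe
    gpoB, gpeB = pb.penalties.gpo, pb.penalties.gpe
    if linear_space:
        trace: list = []
        _solve_linear(cs, gpoA, gpeA, gpoB, gpeB, "F", "F", 0, 0, trace)
        score = score_trace(pa, pb, trace, S)
    else:
        score, trace = _solve_full(cs, gpoA, gpeA, gpoB, gpeB)
    merged_aln = _merge_rows(pa, pb, trace)
    merged_pen = merge_gap_penalties(pa.penalties, pb.penalties, trace)
    merged = Profile(
        alignment=merged_aln,
        counts=_count_columns(merged_aln.rows, pa.alphabet),
        penalties=merged_pen,
        alphabet=pa.alphabet,
    )
    return AlignmentResult(profile=merged, score=score, trace=tuple(trace))
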