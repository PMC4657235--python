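"""Independent scoring oracles for the alignment DP.

Both are deliberately written without reference to the package's solver:
``brute_force_score`` enumerates every global alignment recursively, and
``gotoh_constant`` is a plain dictionary-based affine-gap aligner with
constant penalties.
"""

from __future__ import annotations

import math


def brute_force_score(a, b, score, gpoA, gpeA, gpoB, gpeB):
    """Max score over all global alignments; gap runs pay GPO at their
    first consumed position plus GPE per consumed position."""
    na, nb = len(a), len(b)
    best = -math.inf

    def rec(i, j, prev, acc):
        nonlocal best
        if i == na and j == nb:
            if acc > best:
                best = acc
            return
        if i < na and j < nb:
            rec(i + 1, j + 1, "M", acc + score(a[i], b[j]))
        if i < na:
            pen = gpeA[i] + (gpoA[i] if prev != "A" else 0.0)
            rec(i + 1, j, "A", acc - pen)
        if j < nb:
            pen = gpeB[j] + (gpoB[j] if prev != "B" else 0.0)
            rec(i, j + 1, "B", acc - pen)

    rec(0, 0, None, 0.0)
    return best


def gotoh_constant(a, b, score, go, ge):
    """Classic three-state affine-gap global alignment score with constant
    gap opening ``go`` and extension ``ge`` (opening a run costs go + ge)."""
    NEG = -math.inf
    na, nb = len(a), len(b)
    M = {(0, 0): 0.0}
    IA = {(0, 0): NEG}
    IB = {(0, 0): NEG}
    for i in range(1, na + 1):
        M[i, 0] = NEG
        IA[i, 0] = max(M[i - 1, 0], IA[i - 1, 0] + go) - (go + ge)
        IB[i, 0] = NEG
    for j in range(1, nb + 1):
        M[0, j] = NEG
        IB[0, j] = max(M[0, j - 1], IB[0, j - 1] + go) - (go + ge)
        IA[0, j] = NEG
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            M[i, j] = score(a[i - 1], b[j - 1]) + max(
                M[i - 1, j - 1], IA[i - 1, j - 1], IB[i - 1, j - 1]
            )
            IA[i, j] = max(
                M[i - 1, j] - (go + ge),
                IA[i - 1, j] - ge,
                IB[i - 1, j] - (go + ge),
            )
            IB[i, j] = max(
                M[i, j - 1] - (go + ge),
                IB[i, j - 1] - ge,
                IA[i, j - 1] - (go + ge),
            )
    return max(M[na, nb], IA[na, nb], IB[na, nb])
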