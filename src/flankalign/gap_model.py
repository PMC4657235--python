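"""The variable gap penalty (VGP) function.

Three pieces:

* position-specific gap *opening* penalties: per position i the minimum of
  the left/right window log-loss curves, GPO_i = min(LPPM_i, RPPM_i) for
  1 <= i <= n-L+1 (1-based); the last L-1 positions, which have no window
  of their own, inherit GPO_{n-L+1};
* region-specific gap *extension* penalties: GPE_i = 0 inside a predicted
  IndelFR, GPE_i = GPO_i elsewhere — gaps extend for free exactly where
  indels are predicted to be plausible;
* profile merging: when two profiles A and B are aligned into C, the
  penalty of each merged column is the sum of the two contributing column
  penalties where both profiles place residues, and a verbatim copy of the
  non-gap side's penalty where one profile has a gap.  This makes gaps
  progressively more expensive at positions that have stayed aligned and
  keeps them cheap where gaps already exist.

Penalties are stored as non-negative magnitudes and subtracted inside the
dynamic programming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ppm import ScanResult


@dataclass(frozen=True)
class GapPenalties:
    """Per-position (or per-column) opening and extension penalties."""

    gpo: np.ndarray
    gpe: np.ndarray

    def __post_init__(self):
        gpo = np.asarray(self.gpo, dtype=float)
        gpe = np.asarray(self.gpe, dtype=float)
        object.__setattr__(self, "gpo", gpo)
        object.__setattr__(self, "gpe", gpe)
        if gpo.shape != gpe.shape or gpo.ndim != 1:
            raise ValueError("gpo and gpe must be 1-D arrays of equal length")
        if np.any(gpo < 0) or np.any(gpe < 0):
            raise ValueError("gap penalties must be non-negative")

    def __len__(self) -> int:
        return self.gpo.size


def opening_penalties(scan: ScanResult, n: int) -> np.ndarray:
    """Position-specific gap-opening penalties for a length-n sequence.

    ``result[i] = min(lppm[i], rppm[i])`` for windowed positions
    ``0..n-L`` (0-based); the tail ``n-L+1..n-1`` repeats ``result[n-L]``.
    """
    m = scan.lppm.size
    if n != m + scan.L - 1:
        raise ValueError(
            f"sequence length {n} inconsistent with {m} windows of length {scan.L}"
        )
    out = np.empty(n)
    out[:m] = np.minimum(scan.lppm, scan.rppm)
    out[m:] = out[m - 1]
    return out


def extension_penalties(gpo: np.ndarray, ifrs) -> np.ndarray:
    """Region-specific extension penalties: 0 inside IndelFRs, GPO outside."""
    gpo = np.asarray(gpo, dtype=float)
    out = gpo.copy()
    n = gpo.size
    for a, b in ifrs:
        if not (0 <= a < b <= n):
            raise ValueError(f"IndelFR interval [{a},{b}) outside [0,{n})")
        out[a:b] = 0.0
    return out


def penalties_for(gpo: np.ndarray, ifrs) -> GapPenalties:
    """Bundle a sequence's opening penalties with its derived extensions."""
    return GapPenalties(np.asarray(gpo, float), extension_penalties(gpo, ifrs))


def merge_gap_penalties(pa: GapPenalties, pb: GapPenalties, trace) -> GapPenalties:
    """Merge two profiles' penalties along an alignment trace.

    ``trace`` lists one entry per merged column: ``(j, k)`` when column j of
    A is aligned with column k of B, ``(j, None)`` for a gap in B, and
    ``(None, k)`` for a gap in A.  Aligned columns sum the two penalties;
    gap columns copy the non-gap side verbatim.  The trace must consume all
    columns of both inputs exactly once, in order.
    """
    gpo = np.empty(len(trace))
    gpe = np.empty(len(trace))
    next_a = next_b = 0
    for i, (j, k) in enumerate(trace):
        if j is not None:
            if j != next_a:
                raise ValueError(f"trace consumes column {j} of A out of order")
            next_a += 1
        if k is not None:
            if k != next_b:
                raise ValueError(f"trace consumes column {k} of B out of order")
            next_b += 1
        if j is not None and k is not None:
            gpo[i] = pa.gpo[j] + pb.gpo[k]
            gpe[i] = pa.gpe[j] + pb.gpe[k]
        elif j is not None:
            gpo[i] = pa.gpo[j]
            gpe[i] = pa.gpe[j]
        elif k is not None:
            gpo[i] = pb.gpo[k]
            gpe[i] = pb.gpe[k]
        else:
            raise ValueError(f"trace column {i} consumes neither input")
    if next_a != len(pa) or next_b != len(pb):
        raise ValueError("trace does not consume all columns of both inputs")
    return GapPenalties(gpo, gpe)
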