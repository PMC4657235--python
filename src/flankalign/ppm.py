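"""Prediction-by-partial-match (PPM) models and IndelFR prediction.

A PPM model is a variable-order Markov model: conditional probabilities of
the next residue are blended over context lengths 0..D through escape
probabilities (PPM-C scheme: the escape count of a context equals the
number of distinct symbols observed after it; no exclusions), falling back
to a uniform order-(-1) distribution over the alphabet.

An :class:`IndelPredictor` pairs two such models — one trained on the
segments immediately left of known indels, one on the segments immediately
right — and scans a query sequence with a sliding window of length L,
recording for each window start the average log-loss (base 2) under each
model.  Windows resembling trained flanking regions score a low log-loss;
local log-loss minima anchor the predicted indel flanking regions (IndelFRs)
and the per-position minima of the two curves become gap-opening penalties
(see :mod:`flankalign.gap_model`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import AMINO_ACIDS, AnnotatedSequence, ProteinSequence

DEFAULT_ORDER = 4   # PPM memory length D
DEFAULT_WINDOW = 10  # scan window length L


class PPMModel:
    """A PPM-C variable-order Markov model over a residue alphabet.

    ``counts`` maps context strings of length 0..D to dicts of next-symbol
    counts; every stored count is >= 1 by construction.
    """

    def __init__(self, order: int = DEFAULT_ORDER, alphabet: str = AMINO_ACIDS,
                 counts: dict[str, dict[str, int]] | None = None):
        if order < 0:
            raise ValueError("PPM order must be >= 0")
        self.order = order
        self.alphabet = alphabet
        self._alpha_set = frozenset(alphabet)
        self.counts: dict[str, dict[str, int]] = counts if counts is not None else {}
        self.escape = "C"

    def observe(self, sequence: str) -> None:
        """Accumulate (context, next-symbol) counts at all orders 0..D."""
        for i, sym in enumerate(sequence):
            for d in range(min(i, self.order) + 1):
                ctx = sequence[i - d : i]
                slot = self.counts.setdefault(ctx, {})
                slot[sym] = slot.get(sym, 0) + 1

    def symbol_prob(self, symbol: str, context: str = "") -> float:
        """Blended probability of ``symbol`` after ``context`` (PPM-C).

        Only the last ``min(len(context), D)`` context symbols are used.
        The recursion escapes through shorter contexts and terminates at a
        uniform distribution over the alphabet, so the result is always
        strictly positive.
        """
        if symbol not in self._alpha_set:
            raise ValueError(f"symbol {symbol!r} outside the model alphabet")
        ctx = context[len(context) - self.order :] if self.order else ""
        prob = 0.0
        weight = 1.0  # product of escape probabilities so far
        for d in range(len(ctx), -1, -1):
            slot = self.counts.get(ctx[len(ctx) - d :])
            if not slot:
                continue  # unseen context: escape with probability 1
            total = sum(slot.values())
            q = len(slot)  # PPM-C: escape count = number of distinct symbols
            denom = total + q
            prob += weight * slot.get(symbol, 0) / denom
            weight *= q / denom
        return prob + weight / len(self.alphabet)

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "alphabet": self.alphabet,
            "escape": self.escape,
            "counts": self.counts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PPMModel":
        model = cls(d["order"], d["alphabet"])
        model.counts = {
            ctx: {s: int(c) for s, c in slot.items()} for ctx, slot in d["counts"].items()
        }
        return model


def train_ppm(corpus, order: int = DEFAULT_ORDER,
              alphabet: str = AMINO_ACIDS) -> PPMModel:
    """Train a PPM-C model on a corpus of sequences (or plain strings)."""
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot train a PPM model on an empty corpus")
    model = PPMModel(order, alphabet)
    for item in corpus:
        model.observe(item.residues if isinstance(item, ProteinSequence) else str(item))
    return model


def symbol_prob(model: PPMModel, symbol: str, context: str = "") -> float:
    """Module-level convenience wrapper for :meth:`PPMModel.symbol_prob`."""
    return model.symbol_prob(symbol, context)


def window_logloss(model: PPMModel, window: str, L: int | None = None) -> float:
    """Average base-2 log-loss of a length-L window under ``model``.

    Term k (0-based) conditions on exactly ``min(k, D)`` preceding window
    symbols; windows never reach outside themselves.
    """
    if L is None:
        L = len(window)
    if len(window) != L:
        raise ValueError(f"window has length {len(window)}, expected L={L}")
    total = 0.0
    for k in range(L):
        ctx = window[max(0, k - model.order) : k]
        total += math.log2(model.symbol_prob(window[k], ctx))
    return -total / L


@dataclass
class ScanResult:
    """Sliding-window log-loss profiles of one sequence.

    ``lppm[i]``/``rppm[i]`` are the left/right-model average log-losses of
    the window starting at position i (0-based); both arrays have length
    n - L + 1.
    """

    lppm: np.ndarray
    rppm: np.ndarray
    L: int

    def __post_init__(self):
        self.lppm = np.asarray(self.lppm, dtype=float)
        self.rppm = np.asarray(self.rppm, dtype=float)
        if self.lppm.shape != self.rppm.shape:
            raise ValueError("lppm and rppm must have the same length")
        if np.any(self.lppm < 0) or np.any(self.rppm < 0):
            raise ValueError("log-loss values must be non-negative")


@dataclass
class ExtractionParams:
    """Parameters of the deterministic IndelFR extraction rule.

    A position is a left-flank anchor when its ``lppm`` value is a strict
    local minimum lying below ``mean - c*std`` of the whole curve (right
    anchors analogously on ``rppm``).  Each left anchor pairs with the
    nearest unused right anchor at most ``pair_window`` positions
    downstream; the pair spans ``[left, right + L)``.  Unpaired anchors
    yield an interval of length L.
    """

    threshold_sigma: float = 1.0
    pair_window: int = 30
    smooth: bool = False  # optional width-3 moving average before extraction


def _anchors(values: np.ndarray, c: float) -> list[int]:
    if values.size < 3:
        return []
    mean = float(values.mean())
    std = float(values.std())
    cut = mean - c * std
    out = []
    for i in range(1, values.size - 1):
        if values[i] < values[i - 1] and values[i] < values[i + 1] and values[i] < cut:
            out.append(i)
    return out


def _smooth3(values: np.ndarray) -> np.ndarray:
    if values.size < 3:
        return values
    out = values.copy()
    out[1:-1] = (values[:-2] + values[1:-1] + values[2:]) / 3.0
    return out


def merge_intervals(intervals) -> tuple[tuple[int, int], ...]:
    """Sort and coalesce overlapping/adjacent half-open intervals."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


def extract_indelfrs(scan: ScanResult,
                     params: ExtractionParams | None = None) -> tuple[tuple[int, int], ...]:
    """Extract predicted IndelFR intervals from a scan (pure, deterministic).

    Returns sorted disjoint 0-based half-open intervals within [0, n) where
    n = len(scan.lppm) + L - 1.
    """
    params = params or ExtractionParams()
    lppm, rppm = scan.lppm, scan.rppm
    if params.smooth:
        lppm, rppm = _smooth3(lppm), _smooth3(rppm)
    n = lppm.size + scan.L - 1
    left = _anchors(lppm, params.threshold_sigma)
    right = _anchors(rppm, params.threshold_sigma)
    used_right: set[int] = set()
    intervals: list[tuple[int, int]] = []
    for p in left:
        candidates = [r for r in right
                      if r not in used_right and p <= r <= p + params.pair_window]
        if candidates:
            r = min(candidates, key=lambda r: r - p)
            used_right.add(r)
            intervals.append((p, r + scan.L))
        else:
            intervals.append((p, p + scan.L))
    for r in right:
        if r not in used_right:
            intervals.append((r, r + scan.L))
    clipped = [(max(0, a), min(n, b)) for a, b in intervals if a < n]
    return merge_intervals(clipped)


@dataclass
class IndelPredictor:
    """Two PPM models predicting left and right indel flanking regions."""

    left: PPMModel
    right: PPMModel
    L: int = DEFAULT_WINDOW
    params: ExtractionParams = field(default_factory=ExtractionParams)
    reverse_right: bool = False  # score the right model on reversed windows

    def __post_init__(self):
        if self.left.order != self.right.order:
            raise ValueError("left and right models must share the same order D")
        if self.L < self.left.order + 1:
            raise ValueError("window length L must be >= D + 1")

    @property
    def order(self) -> int:
        return self.left.order

    def scan(self, seq: ProteinSequence | str) -> ScanResult:
        return scan_sequence(self, seq)

    def annotate(self, seq: ProteinSequence) -> AnnotatedSequence:
        return annotate(self, seq)

    # --- persistence -------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "L": self.L,
            "reverse_right": self.reverse_right,
            "extraction": {
                "threshold_sigma": self.params.threshold_sigma,
                "pair_window": self.params.pair_window,
                "smooth": self.params.smooth,
            },
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "IndelPredictor":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            left=PPMModel.from_dict(d["left"]),
            right=PPMModel.from_dict(d["right"]),
            L=d["L"],
            params=ExtractionParams(**d["extraction"]),
            reverse_right=d.get("reverse_right", False),
        )


def train_predictor(left_corpus, right_corpus, order: int = DEFAULT_ORDER,
                    L: int = DEFAULT_WINDOW,
                    params: ExtractionParams | None = None) -> IndelPredictor:
    """Train left/right PPM models from flanking-region corpora."""
    return IndelPredictor(
        left=train_ppm(left_corpus, order),
        right=train_ppm(right_corpus, order),
        L=L,
        params=params or ExtractionParams(),
    )


def scan_sequence(pred: IndelPredictor, seq: ProteinSequence | str) -> ScanResult:
    """Slide a length-L window along ``seq``, scoring both models.

    Raises ValueError for sequences shorter than L, which cannot be
    annotated by the sliding window.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else str(seq)
    n = len(residues)
    L = pred.L
    if n < L:
        raise ValueError(
            f"sequence of length {n} is shorter than the scan window L={L}; "
            "such sequences cannot be annotated"
        )
    m = n - L + 1
    lppm = np.empty(m)
    rppm = np.empty(m)
    for i in range(m):
        win = residues[i : i + L]
        lppm[i] = window_logloss(pred.left, win, L)
        rwin = win[::-1] if pred.reverse_right else win
        rppm[i] = window_logloss(pred.right, rwin, L)
    return ScanResult(lppm, rppm, L)


def annotate(pred: IndelPredictor, seq: ProteinSequence) -> AnnotatedSequence:
    """Scan a sequence and attach gap-opening penalties and IndelFRs."""
    from .gap_model import opening_penalties  # local import: avoid cycle

    scan = scan_sequence(pred, seq)
    gpo = opening_penalties(scan, len(seq))
    ifrs = extract_indelfrs(scan, pred.params)
    return AnnotatedSequence(seq, gpo, ifrs)
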