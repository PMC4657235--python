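"""Synthetic protein families with known alignments and indel flanks.

The generator evolves a family from a single random ancestor along a star
phylogeny: each descendant independently receives i.i.d. substitutions and
then indels.  Indels are placed inside a small number of *hotspot*
segments of the ancestor (with an optional low background rate
elsewhere), reflecting the observation that insertions and deletions
cluster in a few structurally tolerant regions of a fold; this is what
makes flanking-region statistics learnable across families that share an
ancestor.  Because every edit is recorded, the true multiple alignment
and the true indel-flank intervals of every descendant are known exactly,
so prediction, alignment and scoring can all be tested without external
reference data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ppm import merge_intervals
from .seqio import AMINO_ACIDS, GAP, MultipleAlignment, ProteinSequence

DEFAULT_FLANK = 10  # flank length F; indel influence is negligible beyond it


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated family."""

    ancestor_length: int = 240
    n_seqs: int = 5
    sub_prob: float = 0.3         # per-site substitution probability
    indel_prob: float = 0.7       # per-hotspot, per-descendant indel probability
    background_indel_prob: float = 0.0  # per-site rate outside hotspots
    mean_indel_length: float = 4.0      # geometric length distribution
    max_indel_length: int = 15
    n_hotspots: int = 3
    hotspot_width: int = 8
    flank: int = DEFAULT_FLANK
    seed: int = 0

    def __post_init__(self):
        for name in ("sub_prob", "indel_prob", "background_indel_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.ancestor_length < 2 * DEFAULT_FLANK:
            raise ValueError("ancestor must be at least twice the flank length")
        if self.mean_indel_length < 1 or self.max_indel_length < 1:
            raise ValueError("indel lengths must be >= 1")


@dataclass(frozen=True)
class IndelEvent:
    """One recorded indel: deletion of ancestor sites or insertion between them."""

    seq_index: int
    kind: str              # 'del' | 'ins'
    anc_pos: int           # first deleted ancestor site / insertion point
    length: int
    inserted: str = ""


@dataclass(frozen=True)
class SimFamily:
    params: SimParams
    ancestor: str
    true_alignment: MultipleAlignment
    sequences: tuple[ProteinSequence, ...]
    events: tuple[IndelEvent, ...]
    true_indel_positions: tuple[tuple[tuple[int, int], ...], ...]
    hotspots: tuple[tuple[int, int], ...]


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def _geometric_length(rng: np.random.Generator, mean: float, cap: int) -> int:
    if mean <= 1.0:
        return 1
    return int(min(rng.geometric(1.0 / mean), cap))


def _pick_hotspots(rng, params: SimParams) -> tuple[tuple[int, int], ...]:
    """Disjoint hotspot intervals, kept away from the ancestor's ends.

    Hotspots model the structurally tolerant loops between conserved core
    elements, so they are separated by at least two flank lengths of core:
    the flanking regions of distinct indel segments never overlap.
    """
    margin = params.flank
    sep = 2 * params.flank + params.hotspot_width
    usable = params.ancestor_length - 2 * margin - params.hotspot_width
    if params.n_hotspots == 0 or usable <= 0:
        return ()
    starts: list[int] = []
    for _ in range(500):
        s = int(rng.integers(margin, margin + usable + 1))
        if all(abs(s - t) >= sep + params.hotspot_width for t in starts):
            starts.append(s)
        if len(starts) == params.n_hotspots:
            break
    return tuple((s, s + params.hotspot_width) for s in sorted(starts))


def simulate_family(params: SimParams | None = None, *,
                    ancestor: str | None = None,
                    hotspots: tuple[tuple[int, int], ...] | None = None,
                    rng: np.random.Generator | None = None) -> SimFamily:
    """Evolve one family; fully determined by ``params.seed`` (or ``rng``).

    ``ancestor`` and ``hotspots`` may be supplied to share a fold across
    several families (train/test splits draw on the same fold, the way a
    fold-specific flank predictor is meant to be used).
    """
    params = params or SimParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if ancestor is None:
        ancestor = _random_protein(rng, params.ancestor_length)
    else:
        params = SimParams(**{**params.__dict__, "ancestor_length": len(ancestor)})
    if hotspots is None:
        hotspots = _pick_hotspots(rng, params)
    n_anc = len(ancestor)
    aa = list(AMINO_ACIDS)

    events: list[IndelEvent] = []
    # per descendant: survived[i] residue at ancestor site i ('' if deleted),
    # insertions[i] string inserted immediately after ancestor site i-1
    survived_all: list[list[str]] = []
    inserted_all: list[list[str]] = []
    for s in range(params.n_seqs):
        residues = list(ancestor)
        subs = rng.random(n_anc) < params.sub_prob
        for i in np.flatnonzero(subs):
            choices = [c for c in aa if c != residues[i]]
            residues[i] = choices[int(rng.integers(len(choices)))]
        survived = list(residues)
        insertions = [""] * (n_anc + 1)

        sites: list[int] = []
        for a, b in hotspots:
            if rng.random() < params.indel_prob:
                sites.append(int(rng.integers(a, b)))
        if params.background_indel_prob > 0:
            bg = rng.random(n_anc) < params.background_indel_prob
            sites.extend(int(i) for i in np.flatnonzero(bg))
        for pos in sorted(set(sites)):
            length = _geometric_length(rng, params.mean_indel_length,
                                       params.max_indel_length)
            if rng.random() < 0.5:
                end = min(pos + length, n_anc)
                if end == pos:
                    continue
                for i in range(pos, end):
                    survived[i] = ""
                events.append(IndelEvent(s, "del", pos, end - pos))
            else:
                ins = _random_protein(rng, length)
                insertions[pos] += ins
                events.append(IndelEvent(s, "ins", pos, length, ins))
        survived_all.append(survived)
        inserted_all.append(insertions)

    # assemble the true alignment: for each ancestor site, first the
    # insertion columns of each descendant (gaps elsewhere), then the
    # ancestor-site column itself
    rows: list[list[str]] = [[] for _ in range(params.n_seqs)]
    for i in range(n_anc + 1):
        for s in range(params.n_seqs):
            for c in inserted_all[s][i]:
                for t in range(params.n_seqs):
                    rows[t].append(c if t == s else GAP)
        if i < n_anc:
            for t in range(params.n_seqs):
                rows[t].append(survived_all[t][i] or GAP)
    ids = tuple(f"seq{s}" for s in range(params.n_seqs))
    # an ancestor site deleted in every descendant leaves an all-gap column
    keep = [j for j in range(len(rows[0])) if any(r[j] != GAP for r in rows)]
    aln = MultipleAlignment(
        ids, tuple("".join(r[j] for j in keep) for r in rows)
    )
    seqs = tuple(aln.degapped())

    # true IndelFR intervals, in each descendant's own coordinates:
    # the indel's residues present in that sequence (insertions) plus up
    # to F residues on either side
    F = params.flank
    per_seq: list[tuple[tuple[int, int], ...]] = []
    col_to_res = []
    for row in aln.rows:
        arr = np.full(aln.n_columns, -1, dtype=int)
        k = 0
        for j, c in enumerate(row):
            if c != GAP:
                arr[j] = k
                k += 1
        col_to_res.append(arr)
    runs: set[tuple[int, int]] = set()
    for row in aln.rows:
        j = 0
        while j < aln.n_columns:
            if row[j] == GAP:
                k = j
                while k < aln.n_columns and row[k] == GAP:
                    k += 1
                runs.add((j, k))
                j = k
            else:
                j += 1
    for s in range(params.n_seqs):
        n_s = len(seqs[s])
        ivs: list[tuple[int, int]] = []
        for (j, k) in sorted(runs):
            # sequence-s coordinates of the indel site: s's residues inside
            # the gap columns (if s carries the insertion) plus F on either side
            inside = col_to_res[s][j:k]
            inside = inside[inside >= 0]
            prev = col_to_res[s][:j]
            left_end = int(prev.max()) + 1 if (prev >= 0).any() else 0
            lo = int(inside.min()) if inside.size else left_end
            hi = int(inside.max()) + 1 if inside.size else left_end
            start = max(0, lo - F)
            end = min(n_s, hi + F)
            if start < end:
                ivs.append((start, end))
        per_seq.append(merge_intervals(ivs))
    return SimFamily(
        params=params,
        ancestor=ancestor,
        true_alignment=aln,
        sequences=seqs,
        events=tuple(events),
        true_indel_positions=tuple(per_seq),
        hotspots=hotspots,
    )


def simulate_fold(n_families: int, params: SimParams | None = None,
                  seed: int = 0) -> list[SimFamily]:
    """Simulate families sharing one ancestor and one hotspot layout."""
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    ancestor = _random_protein(rng, params.ancestor_length)
    hotspots = _pick_hotspots(rng, params)
    return [
        simulate_family(params, ancestor=ancestor, hotspots=hotspots, rng=rng)
        for _ in range(n_families)
    ]


def make_training_corpus(families, flank: int = DEFAULT_FLANK
                         ) -> tuple[list[str], list[str]]:
    """Left/right flank corpora from the recorded indels of families.

    For every gap run in a family's true alignment, extract up to
    ``flank`` residues immediately left of the gap into the left corpus
    and up to ``flank`` residues immediately right into the right corpus
    (truncated at sequence ends; empty extractions are dropped).
    """
    if hasattr(families, "true_alignment"):
        families = [families]
    left: list[str] = []
    right: list[str] = []
    n_indels = 0
    for fam in families:
        aln = fam.true_alignment
        for s, row in enumerate(aln.rows):
            seq = fam.sequences[s].residues
            arr = np.full(aln.n_columns, -1, dtype=int)
            k = 0
            for j, c in enumerate(row):
                if c != GAP:
                    arr[j] = k
                    k += 1
            j = 0
            while j < aln.n_columns:
                if row[j] == GAP:
                    kcol = j
                    while kcol < aln.n_columns and row[kcol] == GAP:
                        kcol += 1
                    n_indels += 1
                    prev = arr[:j]
                    left_end = int(prev.max()) + 1 if (prev >= 0).any() else 0
                    lf = seq[max(0, left_end - flank) : left_end]
                    rf = seq[left_end : left_end + flank]
                    if lf:
                        left.append(lf)
                    if rf:
                        right.append(rf)
                    j = kcol
                else:
                    j += 1
    if n_indels == 0:
        raise ValueError("families contain no indels; nothing to train on")
    return left, right
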