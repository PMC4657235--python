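"""The full progressive alignment pipeline.

Steps: annotate input sequences with gap-opening penalties and predicted
IndelFRs (unless already annotated), estimate pairwise distances by
one-error word matching, build a UPGMA guide tree, then align profiles
bottom-up along the tree with the variable-gap-penalty dynamic program.
The alignment held by the root profile is the final MSA; its rows are
returned in input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import distance, guidetree, vgp_align
from .ppm import DEFAULT_ORDER, DEFAULT_WINDOW, ExtractionParams, IndelPredictor
from .seqio import (
    AnnotatedSequence,
    MultipleAlignment,
    ProteinSequence,
    SubstitutionMatrix,
    load_gonnet250,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable constants of the pipeline (defaults are the standard ones)."""

    word_length: int = 3          # k, for pairwise distance words
    window: int = DEFAULT_WINDOW  # L, scan window length
    order: int = DEFAULT_ORDER    # D, PPM memory length
    matrix: SubstitutionMatrix | None = None   # defaults to GONNET250
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    linear_space: bool = False
    permissive: bool = False
    # conversion from average-log-loss units (bits) to substitution-score
    # units: one bit of log-loss counts as gap_scale score points, putting
    # a typical opening penalty at 2-3x the average diagonal score
    gap_scale: float = 3.0
    # permissive-mode fallback for sequences shorter than the window:
    # a constant penalty equal to the corpus-mean log-loss
    short_seq_gpo: float | None = None

    def __post_init__(self):
        if self.word_length < 1:
            raise ValueError("word length k must be >= 1")
        if self.order < 0:
            raise ValueError("PPM order D must be >= 0")
        if self.window < self.order + 1:
            raise ValueError("window L must be >= D + 1")
        if self.gap_scale <= 0:
            raise ValueError("gap_scale must be positive")

    def substitution_matrix(self) -> SubstitutionMatrix:
        return self.matrix if self.matrix is not None else load_gonnet250()


def annotate_inputs(seqs, pred: IndelPredictor | None = None,
                    cfg: PipelineConfig | None = None) -> list[AnnotatedSequence]:
    """Annotate plain sequences with a predictor; pass through annotated ones."""
    cfg = cfg or PipelineConfig()
    out: list[AnnotatedSequence] = []
    for s in seqs:
        if isinstance(s, AnnotatedSequence):
            out.append(s)
            continue
        if pred is None:
            raise ValueError(
                f"sequence {s.id!r} is unannotated and no predictor was given"
            )
        if len(s) < pred.L:
            if cfg.permissive and cfg.short_seq_gpo is not None:
                g = np.full(len(s), float(cfg.short_seq_gpo))
                out.append(AnnotatedSequence(s, g, ()))
                continue
            raise ValueError(
                f"sequence {s.id!r} (length {len(s)}) is shorter than the "
                f"scan window L={pred.L}"
            )
        out.append(pred.annotate(s))
    return out


def run_msa(seqs, cfg: PipelineConfig | None = None,
            pred: IndelPredictor | None = None) -> MultipleAlignment:
    """Align annotated sequences progressively; deterministic.

    ``seqs`` may mix AnnotatedSequence and plain ProteinSequence entries;
    plain entries require ``pred``.  A single sequence is returned as a
    one-row alignment.
    """
    cfg = cfg or PipelineConfig()
    annotated = annotate_inputs(seqs, pred, cfg)
    if not annotated:
        raise ValueError("no input sequences")
    ids = [a.seq.id for a in annotated]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in input")
    S = cfg.substitution_matrix()
    if len(annotated) == 1:
        a = annotated[0]
        return MultipleAlignment((a.seq.id,), (a.seq.residues,))

    d = distance.distance_matrix([a.seq for a in annotated], cfg.word_length)
    tree = guidetree.upgma(d)
    profiles: dict[int, vgp_align.Profile] = {}
    leaf_profiles = [
        vgp_align.profile_from_annotated(a, S, gap_scale=cfg.gap_scale)
        for a in annotated
    ]

    def resolve(node) -> vgp_align.Profile:
        if node.is_leaf:
            return leaf_profiles[node.leaf]
        key = id(node)
        return profiles[key]

    for node in tree.postorder():
        left, right = node.children
        result = vgp_align.align_pair(
            resolve(left), resolve(right), S, linear_space=cfg.linear_space
        )
        profiles[id(node)] = result.profile

    root = resolve(tree.root)
    aln = root.alignment
    # restore input row order
    order = [aln.ids.index(i) for i in ids]
    return MultipleAlignment(
        tuple(aln.ids[i] for i in order), tuple(aln.rows[i] for i in order)
    )


def constant_penalty_inputs(annotated, gpo: float | None = None
                            ) -> list[AnnotatedSequence]:
    """Rewrite annotations with one constant opening penalty and no IndelFRs.

    The affine-gap control for mechanism comparisons: gpo defaults to the
    mean of all variable opening penalties, and with no IndelFR intervals
    the extension penalty equals the opening penalty everywhere.
    """
    annotated = list(annotated)
    if gpo is None:
        gpo = float(np.mean(np.concatenate([a.gpo for a in annotated])))
    return [
        AnnotatedSequence(a.seq, np.full(len(a.seq), gpo), ()) for a in annotated
    ]
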