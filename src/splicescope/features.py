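"""Junction candidate aggregation and the nine classification features.

Every gapped alignment contributes one support record to each junction it
spans.  A unique candidate is the tuple (sequence, donor position, acceptor
end, strand).  Nine features characterize a candidate:

alignment-derived
    1. ``skew``          coverage-skew score, log2((1+C) / (1+max(u_d, u_a)))
                         where C is the junction depth and u_d, u_a are the
                         counts of *ungapped* reads crossing the donor and
                         acceptor boundaries — strongly negative skew marks
                         junctions weakly supported relative to the local
                         unspliced coverage;
    2. ``depth``         number of supporting gapped alignments (C);
    3. ``gap_loglik``    log2 likelihood of the intron length under the
                         intron length distribution;
    4. ``entropy``       depth-weighted Shannon entropy of the supports'
                         left-anchor offsets, -sum_i c_i * log2(c_i / C) —
                         stacks of identical alignments (PCR/repeat
                         artifacts) score 0, diverse offsets score high;
    5. ``min_overhang``  the junction's best evidence: the maximum over
                         supports of each support's shorter overhang;
sequence-derived
    6. ``donor_score``   donor PSFM log-odds (bits);
    7. ``acceptor_score`` acceptor PSFM log-odds (bits);
gene-prediction-derived
    8. ``frameshift``    1 if the junction sits between predicted coding
                         exons and splicing it shifts the predicted reading
                         frame of the downstream exon;
    9. ``strand_discord`` 1 if the junction lies in a predicted gene on the
                         opposite strand.

Features 1, 4 and 5 drive the self-labeling heuristics only; 2, 3, 6-9 form
the classifier's input vector.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .aligner import SplicedAlignment, UngappedHit
from .models import (
    SpliceModels,
    acceptor_window,
    donor_window,
    intron_length_loglik,
    score_splice_site,
)

FEATURE_NAMES = (
    "skew", "depth", "gap_loglik", "entropy", "min_overhang",
    "donor_score", "acceptor_score", "frameshift", "strand_discord",
)

# classifier input (selection features skew/entropy/min_overhang excluded)
CLASSIFIER_FEATURES = (
    "donor_score", "acceptor_score", "gap_loglik",
    "frameshift", "strand_discord", "depth",
)

SCORE_FLOOR = -50.0  # bits, for windows that run off the contig


@dataclass(frozen=True)
class Support:
    read_id: str
    left_overhang: int
    right_overhang: int
    left_offset: int  # left-anchor offset: exonic nt between read start side and the junction


@dataclass
class JunctionCandidate:
    seq_id: str
    donor_pos: int      # first intronic base (genomic interval start)
    acceptor_end: int   # one past the last intronic base
    strand: str
    cls: str
    supports: list[Support] = field(default_factory=list)

    @property
    def intron_length(self) -> int:
        return self.acceptor_end - self.donor_pos

    def key(self) -> tuple[str, int, int, str]:
        return (self.seq_id, self.donor_pos, self.acceptor_end, self.strand)


@dataclass
class JunctionFeatures:
    skew: float
    depth: int
    gap_loglik: float
    entropy: float
    min_overhang: int
    donor_score: float
    acceptor_score: float
    frameshift: int
    strand_discord: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CLASSIFIER_FEATURES], dtype=float)


# ---------------------------------------------------------------------------
# aggregation

def aggregate_junctions(
    alignments: Sequence[SplicedAlignment],
) -> list[JunctionCandidate]:
    """Group spliced alignments into unique junction candidates.  An
    alignment with k introns supports k candidates; the per-support
    overhangs are the exonic block lengths flanking that junction within
    the alignment."""
    table: dict[tuple, JunctionCandidate] = {}
    for aln in alignments:
        for i, intron in enumerate(aln.introns):
            key = (aln.seq_id, intron.start, intron.end, intron.strand)
            cand = table.get(key)
            if cand is None:
                cand = JunctionCandidate(
                    aln.seq_id, intron.start, intron.end, intron.strand, intron.cls
                )
                table[key] = cand
            left, right = aln.junction_overhangs(i)
            cand.supports.append(Support(aln.read_id, left, right, left))
    return sorted(table.values(), key=JunctionCandidate.key)


# ---------------------------------------------------------------------------
# ungapped boundary-crossing coverage

class BoundaryCoverage:
    """Per-sequence count of ungapped read placements crossing each
    inter-base boundary.  Boundary b separates positions b-1 and b; an
    ungapped placement [s, e) crosses it when s < b < e."""

    def __init__(self, seq_lengths: Mapping[str, int]):
        self._diff = {sid: np.zeros(n + 2, dtype=np.int64)
                      for sid, n in seq_lengths.items()}
        self._cum: dict[str, np.ndarray] | None = None

    def add(self, seq_id: str, start: int, end: int) -> None:
        if end - start < 2:
            return
        d = self._diff[seq_id]
        d[start + 1] += 1
        d[end] -= 1
        self._cum = None

    def add_hits(self, hits: Sequence[UngappedHit], read_len: int) -> None:
        for h in hits:
            self.add(h.seq_id, h.pos, h.pos + read_len)

    def crossing(self, seq_id: str, boundary: int) -> int:
        if self._cum is None:
            self._cum = {sid: np.cumsum(d) for sid, d in self._diff.items()}
        c = self._cum[seq_id]
        if not 0 <= boundary < c.size:
            return 0
        return int(c[boundary])


# ---------------------------------------------------------------------------
# feature computation

def compute_alignment_features(
    candidate: JunctionCandidate, coverage: BoundaryCoverage
) -> tuple[float, int, float, int]:
    """(skew, depth, entropy, min_overhang) for one candidate."""
    depth = len(candidate.supports)
    counts: dict[int, int] = {}
    for s in candidate.supports:
        counts[s.left_offset] = counts.get(s.left_offset, 0) + 1
    entropy = -sum(c * math.log2(c / depth) for c in counts.values())
    min_overhang = max(min(s.left_overhang, s.right_overhang)
                       for s in candidate.supports)
    u_d = coverage.crossing(candidate.seq_id, candidate.donor_pos)
    u_a = coverage.crossing(candidate.seq_id, candidate.acceptor_end)
    skew = math.log2((1 + depth) / (1 + max(u_d, u_a)))
    return skew, depth, entropy, min_overhang


def compute_sequence_features(
    candidate: JunctionCandidate,
    genome: Mapping[str, str],
    models: SpliceModels,
) -> tuple[float, float, float]:
    """(gap_loglik, donor_score, acceptor_score) for one candidate.  Windows
    that run off the contig score the floor value."""
    seq = genome[candidate.seq_id]
    s, e, strand = candidate.donor_pos, candidate.acceptor_end, candidate.strand
    dw = donor_window(seq, s, e, strand)
    aw = acceptor_window(seq, s, e, strand)
    donor_score = (score_splice_site(dw, "donor", models)
                   if dw is not None else SCORE_FLOOR)
    acceptor_score = (score_splice_site(aw, "acceptor", models)
                      if aw is not None else SCORE_FLOOR)
    gap_loglik = intron_length_loglik(candidate.intron_length, models.intron_lengths)
    return gap_loglik, donor_score, acceptor_score


# ---------------------------------------------------------------------------
# ab initio gene predictions and the two indicator features

@dataclass
class PredictedGene:
    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]  # CDS exons, ascending, non-overlapping

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def coding_bases_before(self, pos: int) -> int:
        """Number of predicted coding bases strictly left of ``pos``."""
        total = 0
        for s, e in self.exons:
            total += max(0, min(e, pos) - s)
        return total

    def contains_in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)


class GenePredictionSet:
    """Interval-indexed ab initio gene predictions."""

    def __init__(self, genes: Sequence[PredictedGene]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._trees.setdefault(g.seq_id, IntervalTree())
            tree[g.start : g.end] = g

    def overlapping(self, seq_id: str, start: int, end: int) -> list[PredictedGene]:
        tree = self._trees.get(seq_id)
        if tree is None:
            return []
        return [iv.data for iv in sorted(tree.overlap(start, end))]

    def predicted_introns(self) -> set[tuple[str, int, int, str]]:
        out = set()
        for g in self.genes:
            for s, e in g.introns():
                out.add((g.seq_id, s, e, g.strand))
        return out


def compute_indicators(
    candidate: JunctionCandidate, predictions: GenePredictionSet
) -> tuple[int, int]:
    """(frameshift, strand_discord) for one candidate.

    frameshift is 1 iff both splice sites fall inside predicted coding exons
    of one gene and the number of predicted coding bases the candidate
    intron removes is not a multiple of 3 (i.e. the reading frame carried
    across the junction disagrees with the ab initio frame of the
    downstream exon).  strand_discord is 1 iff the intron overlaps a
    predicted gene on the opposite strand.
    """
    s, e = candidate.donor_pos, candidate.acceptor_end
    genes = candidate_genes = predictions.overlapping(candidate.seq_id, s, e)
    frameshift = 0
    for g in candidate_genes:
        # the exonic bases adjacent to the intron must be coding in the
        # prediction: position s-1 (last exonic before) and e (first after)
        if g.contains_in_exon(s - 1) and g.contains_in_exon(e):
            removed = g.coding_bases_before(e) - g.coding_bases_before(s)
            if removed % 3 != 0:
                frameshift = 1
                break
    strand_discord = int(any(g.strand != candidate.strand for g in genes))
    return frameshift, strand_discord


def compute_features(
    candidate: JunctionCandidate,
    coverage: BoundaryCoverage,
    genome: Mapping[str, str],
    models: SpliceModels,
    predictions: GenePredictionSet,
) -> JunctionFeatures:
    """All nine features for one candidate (a pure function of its inputs)."""
    skew, depth, entropy, min_overhang = compute_alignment_features(
        candidate, coverage
    )
    gap_loglik, donor_score, acceptor_score = compute_sequence_features(
        candidate, genome, models
    )
    frameshift, strand_discord = compute_indicators(candidate, predictions)
    return JunctionFeatures(
        skew=skew, depth=depth, gap_loglik=gap_loglik, entropy=entropy,
        min_overhang=min_overhang, donor_score=donor_score,
        acceptor_score=acceptor_score, frameshift=frameshift,
        strand_discord=strand_discord,
    )
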