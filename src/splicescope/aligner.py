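"""Ungapped and anchor-and-extend spliced alignment of RNA-seq reads.

The workflow mirrors the first two steps of a spliced-mapping pipeline:

1. attempt ungapped alignment of the full read against a k-mer genome
   index (a hash-based stand-in for an FM-index aligner);
2. for reads that fail, cut the read into short non-overlapping segments
   (18-25 nt), align the segments ungapped, and use the aligned segments as
   *anchors* that delimit the genomic region where an intron must lie; the
   unaligned remainder is then explained by a gap whose boundaries must be
   canonical GT-AG or semi-canonical GC-AG / AT-AC dinucleotides (the
   orientation of the dinucleotides defines the transcript strand).

Constraints enforced on every emitted alignment: a minimum 8 nt overhang on
the shorter side of each junction, intron length within
``[min_intron, max_intron)`` (default 20 to 10 000 nt), and allowed splice
dinucleotide classes.  Coordinates are 0-based, half-open; an intron's
``start`` is its first base and ``end`` one past its last.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._seq import encode, revcomp
from .models import (
    SpliceModels,
    acceptor_window,
    donor_window,
    score_splice_site,
)

# (forward-genome start dinuc, end dinuc) -> (class name, transcript strand)
SPLICE_CLASSES = {
    ("GT", "AG"): ("GT-AG", "+"),
    ("GC", "AG"): ("GC-AG", "+"),
    ("AT", "AC"): ("AT-AC", "+"),
    ("CT", "AC"): ("GT-AG", "-"),
    ("CT", "GC"): ("GC-AG", "-"),
    ("GT", "AT"): ("AT-AC", "-"),
}


@dataclass
class AlignerConfig:
    k: int = 20
    seg_len: int = 25
    max_mismatch: int = 2
    min_overhang: int = 8
    min_intron: int = 20
    max_intron: int = 10_000
    max_hits: int = 10
    classes: tuple[str, ...] = ("GT-AG", "GC-AG", "AT-AC")

    def __post_init__(self) -> None:
        if not 18 <= self.seg_len <= 25:
            raise ValueError("seg_len must be in [18, 25]")
        if self.max_mismatch not in (0, 1, 2):
            raise ValueError("max_mismatch must be 0, 1 or 2")
        if self.seg_len < self.k:
            raise ValueError("seg_len must be >= index seed length k")

    def dinuc_pairs(self):
        return [
            (s, e, cls, strand)
            for (s, e), (cls, strand) in SPLICE_CLASSES.items()
            if cls in self.classes
        ]


@dataclass
class Read:
    id: str
    sequence: str
    quality: str | None = None
    mate: int = 0  # 0 = unpaired

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UngappedHit:
    seq_id: str
    pos: int
    strand: str  # '+' read as given matched forward genome, '-' its revcomp did
    mismatches: int


@dataclass(frozen=True)
class Intron:
    start: int   # first intronic base (genomic, forward)
    end: int     # one past the last intronic base
    cls: str     # "GT-AG" / "GC-AG" / "AT-AC"
    strand: str  # transcript strand implied by the dinucleotide orientation

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SplicedAlignment:
    """A read placed on the genome as ordered blocks separated by introns."""

    read_id: str
    seq_id: str
    strand: str
    blocks: list[tuple[int, int]]
    mismatches: int
    introns: list[Intron] = field(default_factory=list)
    mate: int = 0
    source: str = "genome"  # "genome" or "remap"
    site_score: float = 0.0  # donor+acceptor bits, used only for tie-breaks

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def splice_strand(self) -> str | None:
        return self.introns[0].strand if self.introns else None

    def key(self) -> tuple:
        return (self.seq_id, self.strand, tuple(self.blocks))

    def junction_overhangs(self, i: int) -> tuple[int, int]:
        """Exonic nt flanking the i-th junction within this alignment."""
        left = self.blocks[i][1] - self.blocks[i][0]
        right = self.blocks[i + 1][1] - self.blocks[i + 1][0]
        return left, right


class AlignmentInvariantError(ValueError):
    pass


def validate_alignment(aln: SplicedAlignment, read_len: int, config: AlignerConfig) -> None:
    """Assert the structural invariants of a spliced alignment; raise
    AlignmentInvariantError on any violation."""
    blocks = aln.blocks
    if sum(e - s for s, e in blocks) != read_len:
        raise AlignmentInvariantError("block lengths do not sum to read length")
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if not (s1 < e1 <= s2 < e2):
            raise AlignmentInvariantError("blocks not strictly increasing")
    if len(aln.introns) != len(blocks) - 1:
        raise AlignmentInvariantError("intron count does not match gaps")
    for i, intron in enumerate(aln.introns):
        if intron.start != blocks[i][1] or intron.end != blocks[i + 1][0]:
            raise AlignmentInvariantError("intron does not match block gap")
        if not config.min_intron <= intron.length < config.max_intron:
            raise AlignmentInvariantError(f"intron length {intron.length} out of range")
        if intron.cls not in config.classes:
            raise AlignmentInvariantError(f"disallowed dinucleotide class {intron.cls}")
        left, right = aln.junction_overhangs(i)
        if min(left, right) < config.min_overhang:
            raise AlignmentInvariantError("junction overhang below minimum")


# ---------------------------------------------------------------------------
# genome index

class GenomeIndex:
    """Exact k-mer hash index over the forward strand of every sequence;
    reverse-strand hits are found by looking up the reverse complement."""

    def __init__(self, genome: Mapping[str, str], k: int = 20):
        if k < 8:
            raise ValueError("k must be >= 8")
        for seq_id, seq in genome.items():
            if len(seq) < k:
                raise ValueError(f"sequence {seq_id} shorter than k={k}")
        self.k = k
        self.genome = {sid: seq.upper() for sid, seq in genome.items()}
        self.codes = {sid: encode(seq) for sid, seq in self.genome.items()}
        table: dict[str, list[tuple[str, int]]] = {}
        for sid, seq in self.genome.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                table.setdefault(kmer, []).append((sid, pos))
        self._table = table

    def lookup_fwd(self, kmer: str) -> list[tuple[str, int]]:
        return self._table.get(kmer, [])

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All occurrences of ``kmer`` on either strand.  A '-' hit at
        position p means the reverse complement of the k-mer occurs at
        forward position p."""
        hits = [(sid, pos, "+") for sid, pos in self.lookup_fwd(kmer)]
        rc = revcomp(kmer)
        hits += [(sid, pos, "-") for sid, pos in self.lookup_fwd(rc)]
        return hits


def build_index(genome: Mapping[str, str], k: int = 20) -> GenomeIndex:
    return GenomeIndex(genome, k)


# ---------------------------------------------------------------------------
# ungapped alignment

def _count_mm(codes: np.ndarray, pos: int, query: np.ndarray) -> int:
    seg = codes[pos : pos + query.size]
    if seg.size != query.size:
        return query.size + 1
    return int(np.count_nonzero(seg != query))


def _seed_offsets(length: int, k: int, parts: int) -> list[int]:
    """Start offsets of ``parts`` non-overlapping seeds (pigeonhole: with
    <= parts-1 mismatches at least one seed is error-free)."""
    if length < k:
        return []
    parts = min(parts, length // k) or 1
    bounds = np.linspace(0, length, parts + 1).astype(int)
    return [int(b) for b in bounds[:-1] if b + k <= length]


def _ungapped_oriented(
    oseq: str, ocodes: np.ndarray, index: GenomeIndex, max_mismatch: int
) -> list[tuple[str, int, int]]:
    """(seq_id, pos, mm) placements of one read orientation."""
    out: dict[tuple[str, int], int] = {}
    for off in _seed_offsets(len(oseq), index.k, max_mismatch + 1):
        kmer = oseq[off : off + index.k]
        if "N" in kmer:
            continue
        for sid, pos in index.lookup_fwd(kmer):
            start = pos - off
            if start < 0 or (sid, start) in out:
                continue
            mm = _count_mm(index.codes[sid], start, ocodes)
            if mm <= max_mismatch:
                out[(sid, start)] = mm
    return [(sid, pos, mm) for (sid, pos), mm in out.items()]


def align_ungapped(
    read: Read,
    index: GenomeIndex,
    max_mismatch: int = 2,
    max_hits: int = 10,
) -> list[UngappedHit]:
    """All full-length gapless placements of the read with at most
    ``max_mismatch`` substitutions, on either strand, best (fewest
    mismatches) first, capped at ``max_hits``."""
    if len(read) < index.k:
        raise ValueError(f"read {read.id} shorter than index k={index.k}")
    hits: list[UngappedHit] = []
    fwd = read.sequence
    for strand, oseq in (("+", fwd), ("-", revcomp(fwd))):
        ocodes = encode(oseq)
        for sid, pos, mm in _ungapped_oriented(oseq, ocodes, index, max_mismatch):
            hits.append(UngappedHit(sid, pos, strand, mm))
    hits.sort(key=lambda h: (h.mismatches, h.seq_id, h.pos, h.strand))
    return hits[:max_hits]


def segment_read(sequence: str, seg_len: int) -> list[tuple[int, str]]:
    """Cut a read into consecutive non-overlapping segments of ``seg_len``;
    any remainder shorter than ``seg_len`` is appended to the last segment.
    Returns (read offset, segment sequence) pairs."""
    if not 18 <= seg_len <= 25:
        raise ValueError("seg_len must be in [18, 25]")
    if len(sequence) < seg_len:
        return [(0, sequence)]
    n = len(sequence) // seg_len
    segments = []
    for i in range(n):
        start = i * seg_len
        end = (i + 1) * seg_len if i < n - 1 else len(sequence)
        segments.append((start, sequence[start:end]))
    return segments


# ---------------------------------------------------------------------------
# anchor-and-extend

@dataclass(frozen=True)
class SegmentPlacement:
    offset: int      # read offset of the segment
    length: int
    seq_id: str
    pos: int         # genomic start
    mismatches: int


def align_segments(
    sequence: str, index: GenomeIndex, config: AlignerConfig
) -> list[SegmentPlacement]:
    """Ungapped placements of each read segment (at most 1 mismatch per
    segment so anchors stay trustworthy)."""
    placements: list[SegmentPlacement] = []
    for off, seg in segment_read(sequence, config.seg_len):
        if len(seg) < index.k:
            continue
        ocodes = encode(seg)
        for sid, pos, mm in _ungapped_oriented(seg, ocodes, index, min(1, config.max_mismatch)):
            placements.append(SegmentPlacement(off, len(seg), sid, pos, mm))
    return placements


def _best_chain(
    placements: Sequence[SegmentPlacement], config: AlignerConfig
) -> list[list[SegmentPlacement]]:
    """Collinear chains of segment placements, one best chain per sequence.

    A chain picks at most one placement per segment, in read order, with
    genomic spacing >= read spacing (introns insert genomic bases) and
    total extra genomic span below ``2 * max_intron``.  Chains maximize the
    number of anchored read bases, then minimize mismatches.
    """
    by_seq: dict[str, list[SegmentPlacement]] = {}
    for p in placements:
        by_seq.setdefault(p.seq_id, []).append(p)
    chains = []
    for sid, plist in by_seq.items():
        plist = sorted(plist, key=lambda p: (p.offset, p.pos))
        best: dict[int, tuple[tuple[int, int], list[SegmentPlacement]]] = {}
        states: list[tuple[tuple[int, int], list[SegmentPlacement]]] = []
        for p in plist:
            cand = ((p.length, -p.mismatches), [p])
            for score, chain in states:
                q = chain[-1]
                if q.offset >= p.offset:
                    continue
                read_gap = p.offset - (q.offset + q.length)
                gen_gap = p.pos - (q.pos + q.length)
                if read_gap < 0 or gen_gap < read_gap:
                    continue
                if gen_gap - read_gap >= 2 * config.max_intron:
                    continue
                s = (score[0] + p.length, score[1] - p.mismatches)
                if s > cand[0]:
                    cand = (s, chain + [p])
            states.append(cand)
        if states:
            chains.append(max(states, key=lambda sc: sc[0])[1])
    return chains


def _intron_info(seq: str, s: int, e: int, config: AlignerConfig):
    """Class and strand of the putative intron [s, e), or None."""
    pair = (seq[s : s + 2], seq[e - 2 : e])
    info = SPLICE_CLASSES.get(pair)
    if info is None or info[0] not in config.classes:
        return None
    return info


def _site_score(
    seq: str, s: int, e: int, strand: str, models: SpliceModels | None
) -> float:
    if models is None:
        return 0.0
    dw = donor_window(seq, s, e, strand)
    aw = acceptor_window(seq, s, e, strand)
    score = 0.0
    if dw is not None and "N" not in dw:
        score += score_splice_site(dw, "donor", models)
    if aw is not None and "N" not in aw:
        score += score_splice_site(aw, "acceptor", models)
    return score


@dataclass
class _Resolution:
    """One way of explaining an unaligned read stretch."""

    mismatches: int
    blocks: list[tuple[int, int]]     # genomic blocks covering the stretch
    introns: list[Intron]
    site_score: float = 0.0

    def sort_key(self):
        # parsimony first: at equal mismatches prefer no intron at all, then
        # the higher splice-site score, then the shorter intron
        ilen = sum(i.length for i in self.introns)
        pos = self.introns[0].start if self.introns else 0
        return (self.mismatches, len(self.introns), -self.site_score, ilen, pos)


def _resolve_between(
    seq: str,
    codes: np.ndarray,
    piece: np.ndarray,
    g_left: int,
    g_right: int,
    config: AlignerConfig,
    models: SpliceModels | None,
) -> _Resolution | None:
    """Explain read bases ``piece`` lying between anchors ending at genomic
    ``g_left`` and starting at ``g_right``.  The intron length is fixed by
    the anchor spacing; only the split point varies."""
    m = piece.size
    ilen = (g_right - g_left) - m
    if ilen == 0:
        mm = _count_mm(codes, g_left, piece)
        if mm > config.max_mismatch:
            return None
        blocks = [(g_left, g_right)] if m else []
        return _Resolution(mm, blocks, [])
    if not config.min_intron <= ilen < config.max_intron:
        return None
    best: _Resolution | None = None
    for j in range(m + 1):
        s = g_left + j
        e = s + ilen
        info = _intron_info(seq, s, e, config)
        if info is None:
            continue
        cls, strand = info
        mm = _count_mm(codes, g_left, piece[:j]) + _count_mm(codes, e, piece[j:])
        if mm > config.max_mismatch:
            continue
        blocks = []
        if j:
            blocks.append((g_left, s))
        if m - j:
            blocks.append((e, g_right))
        res = _Resolution(mm, blocks, [Intron(s, e, cls, strand)],
                          _site_score(seq, s, e, strand, models))
        if best is None or res.sort_key() < best.sort_key():
            best = res
    return best


def _dinuc_positions(codes: np.ndarray, lo: int, hi: int, dinuc: str) -> np.ndarray:
    """Positions p in [lo, hi) where codes[p:p+2] equals ``dinuc``."""
    lo = max(lo, 0)
    hi = min(hi, codes.size - 1)
    if hi <= lo:
        return np.empty(0, dtype=int)
    window = codes[lo : hi + 1]
    d = encode(dinuc)
    return lo + np.nonzero((window[:-1] == d[0]) & (window[1:] == d[1]))[0]


def _mm_at(codes: np.ndarray, starts: np.ndarray, piece: np.ndarray) -> np.ndarray:
    """Mismatch counts of ``piece`` placed at each start (vectorized)."""
    if piece.size == 0:
        return np.zeros(starts.size, dtype=int)
    idx = starts[:, None] + np.arange(piece.size)[None, :]
    valid = (idx[:, -1] < codes.size) & (starts >= 0)
    out = np.full(starts.size, piece.size + 1, dtype=int)
    if valid.any():
        sub = codes[np.clip(idx[valid], 0, codes.size - 1)]
        out[valid] = np.count_nonzero(sub != piece[None, :], axis=1)
    return out


def _resolve_tail(
    seq: str,
    codes: np.ndarray,
    piece: np.ndarray,
    g_left: int,
    config: AlignerConfig,
    models: SpliceModels | None,
    budget: int,
) -> _Resolution | None:
    """Explain trailing read bases after an anchor ending at ``g_left``:
    either a plain extension or one intron with >= min_overhang bases
    beyond it."""
    m = piece.size
    candidates: list[_Resolution] = []
    mm = _count_mm(codes, g_left, piece)
    if mm <= budget:
        candidates.append(_Resolution(mm, [(g_left, g_left + m)] if m else [], []))
    for j in range(0, m - config.min_overhang + 1):
        mm_left = _count_mm(codes, g_left, piece[:j])
        if mm_left > budget:
            continue
        s = g_left + j
        right = piece[j:]
        for sd, ed, cls, strand in config.dinuc_pairs():
            if seq[s : s + 2] != sd:
                continue
            ends = _dinuc_positions(
                codes, s + config.min_intron - 2, s + config.max_intron - 2, ed
            ) + 2
            if ends.size == 0:
                continue
            mms = _mm_at(codes, ends, right)
            ok = np.nonzero(mms + mm_left <= budget)[0]
            for i in ok:
                e = int(ends[i])
                blocks = []
                if j:
                    blocks.append((g_left, s))
                blocks.append((e, e + right.size))
                candidates.append(
                    _Resolution(mm_left + int(mms[i]), blocks,
                                [Intron(s, e, cls, strand)],
                                _site_score(seq, s, e, strand, models))
                )
    if not candidates:
        return None
    return min(candidates, key=_Resolution.sort_key)


def _resolve_head(
    seq: str,
    codes: np.ndarray,
    piece: np.ndarray,
    g_right: int,
    config: AlignerConfig,
    models: SpliceModels | None,
    budget: int,
) -> _Resolution | None:
    """Mirror of :func:`_resolve_tail` for leading read bases before an
    anchor starting at ``g_right``."""
    m = piece.size
    candidates: list[_Resolution] = []
    if g_right - m >= 0:
        mm = _count_mm(codes, g_right - m, piece)
        if mm <= budget:
            candidates.append(
                _Resolution(mm, [(g_right - m, g_right)] if m else [], [])
            )
    for j in range(config.min_overhang, m + 1):
        # left piece length j ends at the intron start; right part sits
        # immediately left of the anchor.
        right = piece[j:]
        e = g_right - right.size
        mm_right = _count_mm(codes, e, right)
        if e - 2 < 0 or mm_right > budget:
            continue
        left = piece[:j]
        for sd, ed, cls, strand in config.dinuc_pairs():
            if seq[e - 2 : e] != ed:
                continue
            starts = _dinuc_positions(
                codes, e - config.max_intron + 1, e - config.min_intron + 1, sd
            )
            if starts.size == 0:
                continue
            mms = _mm_at(codes, starts - j, left)
            ok = np.nonzero((mms + mm_right <= budget) & (starts - j >= 0))[0]
            for i in ok:
                s = int(starts[i])
                blocks = [(s - j, s)]
                if right.size:
                    blocks.append((e, g_right))
                candidates.append(
                    _Resolution(int(mms[i]) + mm_right, blocks,
                                [Intron(s, e, cls, strand)],
                                _site_score(seq, s, e, strand, models))
                )
    if not candidates:
        return None
    return min(candidates, key=_Resolution.sort_key)


def anchor_extend(
    read: Read,
    placements: Sequence[SegmentPlacement],
    index: GenomeIndex,
    models: SpliceModels | None,
    config: AlignerConfig,
    strand: str = "+",
    oriented_seq: str | None = None,
) -> list[SplicedAlignment]:
    """Gapped alignments of one read orientation from its segment anchors.

    ``placements`` are ungapped placements of the oriented read's segments;
    unaligned stretches between, before, or after the anchors are explained
    by at most one intron each.  Among placements with equal mismatch count
    ties go to the higher donor+acceptor score, then the shorter intron.
    Returns zero alignments when no anchor chain explains the full read.
    """
    oseq = oriented_seq if oriented_seq is not None else (
        read.sequence if strand == "+" else revcomp(read.sequence)
    )
    ocodes = encode(oseq)
    L = len(oseq)
    alignments: list[SplicedAlignment] = []
    for chain in _best_chain(placements, config):
        sid = chain[0].seq_id
        seq = index.genome[sid]
        codes = index.codes[sid]
        # Trim every anchor back by min_overhang bases at each border with an
        # unresolved stretch: an ungapped anchor can greedily overhang a few
        # bases into the intron (absorbing a mismatch), and the boundary
        # region must stay the resolvers' decision.
        n = len(chain)
        backoff = config.min_overhang
        anchors: list[tuple[int, int, int]] = []  # (read start, read end, genome start)
        for i, p in enumerate(chain):
            tl = backoff if (i > 0 or p.offset > 0) else 0
            tr = backoff if (i < n - 1 or p.offset + p.length < L) else 0
            while p.length - tl - tr < config.min_overhang and (tl or tr):
                if tl >= tr:
                    tl -= 1
                else:
                    tr -= 1
            anchors.append((p.offset + tl, p.offset + p.length - tr, p.pos + tl))
        mm_total = sum(
            _count_mm(codes, gs, ocodes[rs:re]) for rs, re, gs in anchors
        )
        if mm_total > config.max_mismatch:
            continue
        blocks: list[tuple[int, int]] = []
        introns: list[Intron] = []
        site_score = 0.0
        ok = True

        def absorb(res: _Resolution | None) -> bool:
            nonlocal mm_total, site_score
            if res is None:
                return False
            mm_total += res.mismatches
            site_score += res.site_score
            blocks.extend(res.blocks)
            introns.extend(res.introns)
            return mm_total <= config.max_mismatch

        first_rs, first_re, first_gs = anchors[0]
        if first_rs > 0:
            budget = config.max_mismatch - mm_total
            ok = absorb(
                _resolve_head(seq, codes, ocodes[:first_rs], first_gs,
                              config, models, budget)
            )
        if ok:
            blocks.append((first_gs, first_gs + (first_re - first_rs)))
            for (rs1, re1, gs1), (rs2, re2, gs2) in zip(anchors, anchors[1:]):
                piece = ocodes[re1:rs2]
                ok = absorb(
                    _resolve_between(seq, codes, piece,
                                     gs1 + (re1 - rs1), gs2,
                                     config, models)
                )
                if not ok:
                    break
                blocks.append((gs2, gs2 + (re2 - rs2)))
        if ok:
            last_rs, last_re, last_gs = anchors[-1]
            if last_re < L:
                budget = config.max_mismatch - mm_total
                ok = absorb(
                    _resolve_tail(seq, codes, ocodes[last_re:],
                                  last_gs + (last_re - last_rs),
                                  config, models, budget)
                )
        if not ok:
            continue
        merged = _merge_blocks(sorted(blocks))
        aln = SplicedAlignment(
            read_id=read.id, seq_id=sid, strand=strand,
            blocks=merged, mismatches=mm_total,
            introns=sorted(introns, key=lambda i: i.start),
            mate=read.mate,
        )
        aln.site_score = site_score
        try:
            validate_alignment(aln, L, config)
        except AlignmentInvariantError:
            continue
        alignments.append(aln)
    alignments.sort(
        key=lambda a: (a.mismatches, len(a.introns), -a.site_score,
                       sum(i.length for i in a.introns), a.seq_id, a.start)
    )
    return alignments[: config.max_hits]


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def gapped_align(
    read: Read,
    index: GenomeIndex,
    models: SpliceModels | None,
    config: AlignerConfig,
) -> list[SplicedAlignment]:
    """Segment the read, anchor, and extend — both orientations.  Returns
    the best alignments across orientations (fewest mismatches first)."""
    out: list[SplicedAlignment] = []
    for strand in ("+", "-"):
        oseq = read.sequence if strand == "+" else revcomp(read.sequence)
        placements = align_segments(oseq, index, config)
        out.extend(
            anchor_extend(read, placements, index, models, config,
                          strand=strand, oriented_seq=oseq)
        )
    out.sort(key=lambda a: (a.mismatches, len(a.introns), -a.site_score,
                            sum(i.length for i in a.introns), a.seq_id, a.start))
    return out[: config.max_hits]
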