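"""Rescue of unmapped reads via pseudo-transcripts, and paired-end filters.

Reads that span two closely spaced junctions (a short internal exon) leave
no room for an anchor segment and stay unmapped after anchor-and-extend.
For every predicted junction a set of *pseudo-transcripts* is built: the
spliced sequence obtained by concatenating L nt upstream and L nt
downstream of the junction (L = read length).  When n other junctions lie
within L nt of the focal one, each of the 2^n subsets of neighbors is
spliced in or not, yielding 2^n alternative references.  Unmapped reads are
aligned gaplessly to these references and the placements are projected back
to genomic coordinates, recovering multi-junction alignments.

Paired-end consistency is enforced afterwards: a spliced alignment whose
mate aligns on the same strand is removed, and mates must be ordered with
the forward-strand mate to the left.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._seq import encode, revcomp
from .aligner import (
    AlignerConfig,
    AlignmentInvariantError,
    Intron,
    Read,
    SplicedAlignment,
    validate_alignment,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Junction:
    """A unique predicted splice junction (intron) on the genome."""

    seq_id: str
    start: int
    end: int
    cls: str
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def as_intron(self) -> Intron:
        return Intron(self.start, self.end, self.cls, self.strand)


@dataclass
class PseudoTranscript:
    """A 2L-bounded spliced reference around one junction.

    ``blocks`` are the ascending genomic intervals whose concatenation is
    ``sequence``; ``spliced`` lists every junction removed from the genomic
    walk (the focal junction plus the chosen neighbor subset).
    """

    seq_id: str
    blocks: list[tuple[int, int]]
    sequence: str
    spliced: tuple[Junction, ...]
    mask: int  # bit i set <=> neighbor i spliced in

    def project(self, t_start: int, t_end: int) -> list[tuple[int, int]]:
        """Map a transcript interval [t_start, t_end) to genomic blocks."""
        if not 0 <= t_start < t_end <= sum(e - s for s, e in self.blocks):
            raise ValueError("transcript interval out of range")
        out: list[tuple[int, int]] = []
        offset = 0
        for s, e in self.blocks:
            blen = e - s
            lo = max(t_start, offset)
            hi = min(t_end, offset + blen)
            if lo < hi:
                out.append((s + lo - offset, s + hi - offset))
            offset += blen
        return out

    def unproject(self, gpos: int) -> int:
        """Inverse of project for a single genomic position inside a block."""
        offset = 0
        for s, e in self.blocks:
            if s <= gpos < e:
                return offset + gpos - s
            offset += e - s
        raise ValueError(f"genomic position {gpos} not on transcript")


def find_neighbors(
    focal: Junction, junctions: Sequence[Junction], L: int, cap: int = 8
) -> list[Junction]:
    """Junctions (same sequence, any strand) whose boundary lies within L nt
    of the focal junction's boundaries, nearest first, at most ``cap``."""
    out = []
    for j in junctions:
        if j.seq_id != focal.seq_id or j == focal:
            continue
        d = min(
            abs(j.start - focal.start), abs(j.start - focal.end),
            abs(j.end - focal.start), abs(j.end - focal.end),
        )
        if d <= L:
            out.append((d, j))
    out.sort(key=lambda t: (t[0], t[1].start, t[1].end))
    return [j for _, j in out[:cap]]


def _walk_right(
    seq_len: int, start: int, needed: int, introns: list[Junction]
) -> list[tuple[int, int]]:
    """Collect up to ``needed`` exonic bases walking right from ``start``,
    skipping the given (non-overlapping) introns."""
    blocks: list[tuple[int, int]] = []
    pos = start
    intr = sorted((j for j in introns if j.start >= start), key=lambda j: j.start)
    i = 0
    while needed > 0 and pos < seq_len:
        while i < len(intr) and intr[i].start < pos:
            i += 1
        limit = min(intr[i].start if i < len(intr) else seq_len, seq_len)
        take = min(needed, limit - pos)
        if take > 0:
            blocks.append((pos, pos + take))
            needed -= take
            pos += take
        if needed > 0 and i < len(intr) and pos == intr[i].start:
            pos = intr[i].end
            i += 1
        elif take <= 0:
            break
    return blocks


def _walk_left(
    start: int, needed: int, introns: list[Junction]
) -> list[tuple[int, int]]:
    """Mirror of :func:`_walk_right`, walking left from ``start``."""
    blocks: list[tuple[int, int]] = []
    pos = start
    intr = sorted((j for j in introns if j.end <= start), key=lambda j: -j.end)
    i = 0
    while needed > 0 and pos > 0:
        while i < len(intr) and intr[i].end > pos:
            i += 1
        limit = intr[i].end if i < len(intr) else 0
        take = min(needed, pos - limit)
        if take > 0:
            blocks.append((pos - take, pos))
            needed -= take
            pos -= take
        if needed > 0 and i < len(intr) and pos == intr[i].end:
            pos = intr[i].start
            i += 1
        elif take <= 0:
            break
    return blocks


def build_pseudo_transcripts(
    junction: Junction,
    neighbors: Sequence[Junction],
    genome: Mapping[str, str],
    L: int,
) -> list[PseudoTranscript]:
    """The 2^n pseudo-transcripts around ``junction`` (n = len(neighbors)).

    Each transcript holds up to L exonic nt on either side of the spliced
    focal junction; transcripts are truncated at contig edges.  Neighbors
    overlapping the focal intron or each other are silently skipped during
    the genomic walk of the masks selecting them.
    """
    n = len(neighbors)
    if n > 16:
        raise ValueError("too many neighbors; cap them before calling")
    return [
        _build_one(junction, _usable_subset(junction, neighbors, mask),
                   genome, L, mask)
        for mask in range(2 ** n)
    ]


def _usable_subset(
    junction: Junction, neighbors: Sequence[Junction], mask: int
) -> tuple[Junction, ...]:
    """Neighbors selected by ``mask`` that clash neither with the focal
    intron nor with an earlier-starting selected neighbor."""
    chosen = [neighbors[i] for i in range(len(neighbors)) if mask >> i & 1]
    usable: list[Junction] = []
    taken = [(junction.start, junction.end)]
    for j in sorted(chosen, key=lambda j: j.start):
        if all(j.end <= s or j.start >= e for s, e in taken):
            usable.append(j)
            taken.append((j.start, j.end))
    return tuple(usable)


def _build_one(
    junction: Junction,
    usable: tuple[Junction, ...],
    genome: Mapping[str, str],
    L: int,
    mask: int,
) -> PseudoTranscript:
    seq = genome[junction.seq_id]
    left = _walk_left(junction.start, L, list(usable))
    right = _walk_right(len(seq), junction.end, L, list(usable))
    blocks = sorted(left + right)
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and merged[-1][1] >= s:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    sequence = "".join(seq[s:e] for s, e in merged)
    if len(sequence) < 2 * L:
        logger.debug(
            "pseudo-transcript at %s:%d-%d truncated to %d nt",
            junction.seq_id, junction.start, junction.end, len(sequence),
        )
    return PseudoTranscript(
        junction.seq_id, merged, sequence, tuple([junction, *usable]), mask
    )


def _project_hit(
    transcript: PseudoTranscript,
    t_start: int,
    read: Read,
    strand: str,
    mm: int,
    config: AlignerConfig,
) -> SplicedAlignment | None:
    L = len(read)
    blocks = transcript.project(t_start, t_start + L)
    junctions = {(j.start, j.end): j for j in transcript.spliced}
    introns: list[Intron] = []
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        j = junctions.get((e1, s2))
        if j is None:
            return None  # gap not explained by a spliced junction
        introns.append(j.as_intron())
    aln = SplicedAlignment(
        read_id=read.id, seq_id=transcript.seq_id, strand=strand,
        blocks=blocks, mismatches=mm, introns=introns,
        mate=read.mate, source="remap",
    )
    try:
        validate_alignment(aln, L, config)
    except AlignmentInvariantError:
        return None
    return aln


def remap_unmapped(
    reads: Sequence[Read],
    junctions: Sequence[Junction],
    genome: Mapping[str, str],
    L: int,
    config: AlignerConfig,
    neighbor_cap: int = 8,
) -> list[SplicedAlignment]:
    """Align unmapped reads gaplessly to pseudo-transcripts and project the
    placements back onto the genome.  Duplicate projections of the same read
    through different transcripts are collapsed.

    The unmapped reads (few) are k-mer indexed and the pseudo-transcripts
    (potentially very many: 2^n per junction) are streamed against them one
    junction at a time, so memory stays bounded by the read set; masks whose
    usable neighbor subsets coincide are built only once.
    """
    if not reads or not junctions:
        return []
    k = config.k
    # seed index over both orientations of every read
    oriented: list[tuple[Read, str, str, np.ndarray]] = []
    rindex: dict[str, list[tuple[int, int]]] = {}
    for read in reads:
        for strand in ("+", "-"):
            oseq = read.sequence if strand == "+" else revcomp(read.sequence)
            oi = len(oriented)
            oriented.append((read, strand, oseq, encode(oseq)))
            for off in range(0, max(1, len(oseq) - k + 1), k):
                rindex.setdefault(oseq[off : off + k], []).append((oi, off))

    jlist = list(junctions)
    found: dict[int, dict[tuple, SplicedAlignment]] = {}
    for j in jlist:
        neigh = find_neighbors(j, jlist, L, cap=neighbor_cap)
        seen_subsets: set[tuple] = set()
        for mask in range(2 ** len(neigh)):
            subset = _usable_subset(j, neigh, mask)
            if subset in seen_subsets:
                continue
            seen_subsets.add(subset)
            t = _build_one(j, subset, genome, L, mask)
            seq = t.sequence
            if len(seq) < k:
                continue
            codes = encode(seq)
            for pos in range(len(seq) - k + 1):
                hits = rindex.get(seq[pos : pos + k])
                if not hits:
                    continue
                for oi, off in hits:
                    start = pos - off
                    read, strand, oseq, ocodes = oriented[oi]
                    if start < 0 or start + len(oseq) > len(seq):
                        continue
                    mm = int((codes[start : start + len(oseq)] != ocodes).sum())
                    if mm > config.max_mismatch:
                        continue
                    aln = _project_hit(t, start, read, strand, mm, config)
                    if aln is None:
                        continue
                    bucket = found.setdefault(oi // 2, {})
                    bucket.setdefault(aln.key(), aln)
    out: list[SplicedAlignment] = []
    for ri in sorted(found):
        hits = sorted(found[ri].values(),
                      key=lambda a: (a.mismatches, a.seq_id, a.start, a.strand))
        out.extend(hits[: config.max_hits])
    return out


# ---------------------------------------------------------------------------
# paired-end consistency

def filter_pairs(
    alignments: Sequence[SplicedAlignment],
    max_inner_distance: int = 500_000,
) -> list[SplicedAlignment]:
    """Paired-end consistency filter.

    A *spliced* alignment is kept only if its mate is unmapped or has at
    least one alignment on the opposite strand, on the same sequence, in
    proper order (the forward-strand mate starts left of the reverse-strand
    mate's end) and within ``max_inner_distance``.  Unspliced alignments and
    singletons pass unchanged.  The filter is idempotent.
    """

    def base_id(a: SplicedAlignment) -> str:
        return a.read_id

    groups: dict[str, dict[int, list[SplicedAlignment]]] = {}
    for a in alignments:
        groups.setdefault(base_id(a), {}).setdefault(a.mate, []).append(a)

    def compatible(a: SplicedAlignment, b: SplicedAlignment) -> bool:
        if a.seq_id != b.seq_id or a.strand == b.strand:
            return False
        plus, minus = (a, b) if a.strand == "+" else (b, a)
        if plus.start > minus.end:
            return False
        if minus.start - plus.end > max_inner_distance:
            return False
        return True

    kept: list[SplicedAlignment] = []
    for _, mates in groups.items():
        for mate_no, alns in mates.items():
            other = mates.get(3 - mate_no, []) if mate_no in (1, 2) else []
            for a in alns:
                if not a.introns or not other:
                    kept.append(a)
                elif any(compatible(a, b) for b in other):
                    kept.append(a)
    return kept
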