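"""Independent oracles and tiny fixture builders for the test suite.

Everything here deliberately avoids the implementation paths it checks:
placements are found by whole-genome scans and exhaustive enumeration, not
by the k-mer index or the anchor chains.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from splicescope._seq import encode, revcomp
from splicescope.aligner import SPLICE_CLASSES, AlignerConfig


# ---------------------------------------------------------------------------
# brute-force ungapped placement (full Hamming scan)

def hamming_scan(read_seq: str, genome: dict[str, str], max_mismatch: int):
    """All (seq_id, pos, strand, mm) full-length ungapped placements found
    by scanning every genome position on both strands."""
    out = []
    for strand in "+-":
        oseq = read_seq if strand == "+" else revcomp(read_seq)
        rcodes = encode(oseq)
        for sid, seq in genome.items():
            codes = encode(seq)
            if codes.size < rcodes.size:
                continue
            windows = sliding_window_view(codes, rcodes.size)
            mm = (windows != rcodes[None, :]).sum(axis=1)
            for p in np.nonzero(mm <= max_mismatch)[0]:
                out.append((sid, int(p), strand, int(mm[p])))
    return out


# ---------------------------------------------------------------------------
# exhaustive single-gap spliced enumeration

def enumerate_spliced(
    read_seq: str, genome: dict[str, str], config: AlignerConfig
):
    """Every placement of the read as either a full ungapped match or an
    exon-gap-exon arrangement whose gap starts/ends with an allowed splice
    dinucleotide pair, has a length in [min_intron, max_intron), and leaves
    >= min_overhang read bases on both sides.  Pure enumeration over all
    split points and all genome positions.

    Returns a list of (seq_id, strand, blocks, mismatches).
    """
    results = []
    pairs = config.dinuc_pairs()
    for strand in "+-":
        oseq = read_seq if strand == "+" else revcomp(read_seq)
        rcodes = encode(oseq)
        L = rcodes.size
        for sid, seq in genome.items():
            codes = encode(seq)
            G = codes.size
            if G < L:
                continue
            windows = sliding_window_view(codes, L)
            mism = windows != rcodes[None, :]
            C = np.cumsum(mism, axis=1)
            n_starts = C.shape[0]
            total = C[:, -1]
            for p in np.nonzero(total <= config.max_mismatch)[0]:
                results.append(
                    (sid, strand, ((int(p), int(p) + L),), int(total[p]))
                )
            # positions of every end-dinucleotide, for binary search
            end_pos: dict[str, np.ndarray] = {}
            for _, ed, _, _ in pairs:
                if ed not in end_pos:
                    d = encode(ed)
                    end_pos[ed] = (
                        np.nonzero((codes[:-1] == d[0]) & (codes[1:] == d[1]))[0] + 2
                    )
            for j in range(config.min_overhang, L - config.min_overhang + 1):
                pre = C[:, j - 1]
                for p in np.nonzero(pre <= config.max_mismatch)[0]:
                    s = int(p) + j
                    if s + 2 > G:
                        continue
                    start_dinuc = seq[s : s + 2]
                    for sd, ed, cls, istrand in pairs:
                        if start_dinuc != sd:
                            continue
                        ends = end_pos[ed]
                        lo = np.searchsorted(ends, s + config.min_intron)
                        hi = np.searchsorted(ends, min(s + config.max_intron,
                                                       G - (L - j) + 1))
                        for e in ends[lo:hi]:
                            q = int(e) - j
                            if q < 0 or q >= n_starts:
                                continue
                            mm = int(pre[p]) + int(C[q, -1] - C[q, j - 1])
                            if mm <= config.max_mismatch:
                                results.append((
                                    sid, strand,
                                    ((int(p), s), (int(e), int(e) + L - j)),
                                    mm,
                                ))
    return results


def unique_best(results):
    """The single placement with strictly fewest mismatches, or None when
    the read has no placement or the optimum is tied."""
    if not results:
        return None
    best_mm = min(r[3] for r in results)
    best = [r for r in results if r[3] == best_mm]
    dedup = {(r[0], r[1], r[2]) for r in best}
    if len(dedup) != 1:
        return None
    return best[0]


# ---------------------------------------------------------------------------
# hand-built junction fixtures

def toy_junction_genome(
    exon1_len: int = 60,
    intron_len: int = 80,
    exon2_len: int = 60,
    pad: int = 120,
    seed: int = 0,
):
    """A single GT-AG intron between two exons inside random padding.

    Returns (genome dict, exon1 interval, intron interval, exon2 interval);
    the intron carries a strong donor (GTAAGT) and acceptor (...TTTCAG).
    """
    rng = np.random.default_rng(seed)
    nucs = "ACGT"

    def rand(n):
        return "".join(nucs[i] for i in rng.integers(0, 4, size=n))

    exon1 = rand(exon1_len)
    exon2 = rand(exon2_len)
    core = rand(intron_len - 12)
    intron = "GTAAGT" + core + "TTTCAG"
    assert len(intron) == intron_len
    left_pad, right_pad = rand(pad), rand(pad)
    seq = left_pad + exon1 + intron + exon2 + right_pad
    e1 = (pad, pad + exon1_len)
    iv = (e1[1], e1[1] + intron_len)
    e2 = (iv[1], iv[1] + exon2_len)
    return {"chrT": seq}, e1, iv, e2


def splice_by_hand(seq: str, left: int, right: int, introns) -> str:
    """Reference construction of a spliced sequence over [left, right)
    with the given (start, end) introns removed — independent of the
    pseudo-transcript walker."""
    keep = []
    pos = left
    for s, e in sorted(introns):
        if e <= left or s >= right:
            continue
        keep.append(seq[pos:s])
        pos = e
    keep.append(seq[pos:right])
    return "".join(keep)
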