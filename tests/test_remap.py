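"""Pseudo-transcript construction, unmapped-read rescue and pair filters."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import splice_by_hand, toy_junction_genome
from splicescope.aligner import AlignerConfig, Intron, Read, SplicedAlignment, build_index, gapped_align
from splicescope.remap import (
    Junction,
    build_pseudo_transcripts,
    filter_pairs,
    find_neighbors,
    remap_unmapped,
)


def _junction(seq_id, s, e, strand="+"):
    return Junction(seq_id, s, e, "GT-AG", strand)


def _toy_multi_intron(seed=0, n_introns=4, exon_len=40, intron_len=70, pad=150):
    """chrM with n alternating exons/introns; introns are GT..AG."""
    rng = np.random.default_rng(seed)

    def rand(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    parts = [rand(pad)]
    pos = pad
    introns = []
    for i in range(n_introns):
        parts.append(rand(exon_len))
        pos += exon_len
        intron = "GTAAGT" + rand(intron_len - 12) + "TTTCAG"
        parts.append(intron)
        introns.append((pos, pos + intron_len))
        pos += intron_len
    parts.append(rand(exon_len))
    parts.append(rand(pad))
    return {"chrM": "".join(parts)}, introns


class TestBuildPseudoTranscripts:
    @pytest.mark.parametrize("n", [0, 1, 2, 3])
    def test_power_of_two_transcripts(self, n):
        genome, introns = _toy_multi_intron(seed=n)
        focal = _junction("chrM", *introns[0])
        neighbors = [_junction("chrM", *iv) for iv in introns[1 : 1 + n]]
        out = build_pseudo_transcripts(focal, neighbors, genome, L=75)
        assert len(out) == 2 ** n
        assert len({t.mask for t in out}) == 2 ** n
        for t in out:
            assert len(t.sequence) <= 2 * 75

    def test_no_neighbors_gives_full_2l_sequence(self):
        genome, introns = _toy_multi_intron(seed=1)
        focal = _junction("chrM", *introns[1])
        (t,) = build_pseudo_transcripts(focal, [], genome, L=60)
        assert len(t.sequence) == 120

    def test_sequences_match_splice_by_hand(self):
        """All 8 masks over 3 neighbors equal independent manual splicing."""
        genome, introns = _toy_multi_intron(seed=2, exon_len=30, intron_len=60)
        seq = genome["chrM"]
        L = 100
        focal_iv = introns[1]
        focal = _junction("chrM", *focal_iv)
        neighbors = [_junction("chrM", *introns[i]) for i in (0, 2, 3)]
        out = build_pseudo_transcripts(focal, neighbors, genome, L)
        assert len(out) == 8
        for t in out:
            spliced = sorted((j.start, j.end) for j in t.spliced)
            # manual construction: take L exonic bases left/right of the gap
            chosen = [iv for iv in spliced if iv != focal_iv]
            left_introns = [iv for iv in chosen if iv[1] <= focal_iv[0]]
            right_introns = [iv for iv in chosen if iv[0] >= focal_iv[1]]
            # grow outward until L exonic bases collected on each side
            lo = focal_iv[0]
            need = L
            for s, e in sorted(left_introns, reverse=True):
                if lo - s >= need + (e - s):
                    break
                need -= lo - e
                lo = s
            lo = max(0, lo - need)
            hi = focal_iv[1]
            need = L
            for s, e in sorted(right_introns):
                if e - hi >= need + (e - s):
                    break
                need -= s - hi
                hi = e
            hi = min(len(seq), hi + need)
            expected = splice_by_hand(
                seq, lo, hi, [focal_iv] + left_introns + right_introns
            )
            assert t.sequence == expected

    def test_projection_roundtrip_identity(self):
        genome, introns = _toy_multi_intron(seed=3)
        focal = _junction("chrM", *introns[1])
        neighbors = [_junction("chrM", *introns[2])]
        for t in build_pseudo_transcripts(focal, neighbors, genome, L=75):
            tlen = sum(e - s for s, e in t.blocks)
            for tpos in range(tlen):
                blocks = t.project(tpos, tpos + 1)
                assert len(blocks) == 1
                gpos = blocks[0][0]
                assert t.unproject(gpos) == tpos

    def test_contig_edge_truncates(self):
        genome, introns = _toy_multi_intron(seed=4, pad=10)
        focal = _junction("chrM", *introns[0])
        (t,) = build_pseudo_transcripts(focal, [], genome, L=75)
        assert len(t.sequence) < 150


class TestFindNeighbors:
    def test_within_l_and_capped(self):
        focal = _junction("c", 1000, 1100)
        others = [_junction("c", 1100 + d, 1200 + d) for d in range(0, 400, 40)]
        got = find_neighbors(focal, [focal] + others, L=100, cap=3)
        assert len(got) == 3
        assert all(j.start - 1100 <= 100 for j in got)

    def test_other_sequence_excluded(self):
        focal = _junction("c", 1000, 1100)
        other = _junction("d", 1010, 1110)
        assert find_neighbors(focal, [focal, other], L=100) == []


class TestRemapUnmapped:
    def test_rescues_short_exon_read(self):
        """A read across two junctions separated by a 30 nt exon has no room
        for a 25 nt anchor, fails anchor-and-extend, and is recovered as a
        3-block alignment through the pseudo-transcripts."""
        genome, introns = _toy_multi_intron(seed=5, exon_len=30)
        seq = genome["chrM"]
        (s1, e1), (s2, e2) = introns[0], introns[1]
        cfg = AlignerConfig()
        # junctions at read positions 15 and 45: both straddle the first two
        # 25 nt segments, leaving a single anchor on the right
        read_seq = seq[s1 - 15 : s1] + seq[e1:s2] + seq[e2 : e2 + 30]
        assert len(read_seq) == 75
        index = build_index(genome)
        read = Read("r", read_seq)
        assert gapped_align(read, index, None, cfg) == []
        junctions = [_junction("chrM", s1, e1), _junction("chrM", s2, e2)]
        alns = remap_unmapped([read], junctions, genome, 75, cfg)
        assert len(alns) == 1
        assert alns[0].blocks == [(s1 - 15, s1), (e1, s2), (e2, e2 + 30)]
        assert len(alns[0].introns) == 2
        assert alns[0].source == "remap"

    def test_unspliced_mask_projection_has_no_intron(self):
        """A read matching the unspliced side of a pseudo-transcript projects
        to a single-block alignment."""
        genome, introns = _toy_multi_intron(seed=6)
        seq = genome["chrM"]
        s1, e1 = introns[0]
        # read entirely inside the region left of the junction
        read = Read("r", seq[s1 - 75 : s1])
        junctions = [_junction("chrM", s1, e1)]
        alns = remap_unmapped([read], junctions, genome, 75, AlignerConfig())
        assert alns
        assert all(not a.introns for a in alns)

    def test_recovers_simulated_short_exon_truth(self):
        """On a short-exon genome (25-45 nt exons), reads unmapped by
        anchor-and-extend that remap uniquely must land on their
        simulator-truth placement."""
        from splicescope.simulate import SimConfig, simulate_dataset

        cfg = SimConfig(genome_len=30_000, n_genes=60, n_pairs=1_000,
                        n_transcripts=2_000, error_rate=0.0,
                        exon_len_range=(25, 45), fragment_mean=120.0,
                        fragment_sd=15.0, seed=12)
        genome, truth, models, pool, r1, r2 = simulate_dataset(cfg)
        acfg = AlignerConfig()
        index = build_index(genome)
        truthmap = {(t.read_id, t.mate): t for t in truth.reads}
        from splicescope.aligner import align_ungapped
        from splicescope.pipeline import junctions_from_alignments

        unmapped, spliced = [], []
        for rid, seq, q in r1:
            read = Read(rid, seq, q, 1)
            if align_ungapped(read, index, acfg.max_mismatch, acfg.max_hits):
                continue
            alns = gapped_align(read, index, models, acfg)
            if alns:
                spliced.extend(alns)
            else:
                unmapped.append(read)
        junctions = junctions_from_alignments(spliced)
        rescued = remap_unmapped(unmapped, junctions, genome, cfg.read_len, acfg)
        by_read: dict[str, list] = {}
        for a in rescued:
            by_read.setdefault(a.read_id, []).append(a)
        exact = 0
        for rid, alns in by_read.items():
            if len(alns) != 1:
                continue
            tr = truthmap[(rid, 1)]
            if alns[0].blocks == [tuple(b) for b in tr.blocks]:
                exact += 1
        assert by_read, "expected some rescued reads"
        assert exact >= 0.9 * sum(1 for alns in by_read.values() if len(alns) == 1)


def _mk_aln(read_id, mate, strand, start, end, spliced=True, seq_id="c"):
    introns = [Intron(start + 20, end - 20, "GT-AG", "+")] if spliced else []
    blocks = ([(start, start + 20), (end - 20, end)] if spliced
              else [(start, end)])
    return SplicedAlignment(read_id, seq_id, strand, blocks, 0, introns, mate)


class TestFilterPairs:
    def test_same_strand_spliced_mate_removed(self):
        a = _mk_aln("p", 1, "+", 100, 300)
        b = _mk_aln("p", 2, "+", 400, 600)
        kept = filter_pairs([a, b])
        assert kept == []

    def test_proper_fr_pair_kept(self):
        a = _mk_aln("p", 1, "+", 100, 300)
        b = _mk_aln("p", 2, "-", 400, 600)
        assert len(filter_pairs([a, b])) == 2

    def test_singleton_passes(self):
        a = _mk_aln("p", 1, "+", 100, 300)
        assert filter_pairs([a]) == [a]

    def test_exactly_the_misstranded_are_removed(self):
        """500 simulated pairs, 50 deliberately mis-stranded: exactly those
        100 spliced records are removed."""
        rng = np.random.default_rng(8)
        alns = []
        bad = set()
        for i in range(500):
            rid = f"p{i:03d}"
            if i < 50:
                alns.append(_mk_aln(rid, 1, "+", 100, 300))
                alns.append(_mk_aln(rid, 2, "+", 400, 600))
                bad.add(rid)
            else:
                s = int(rng.integers(0, 5000))
                alns.append(_mk_aln(rid, 1, "+", s + 100, s + 300))
                alns.append(_mk_aln(rid, 2, "-", s + 400, s + 600))
        kept = filter_pairs(alns)
        assert {a.read_id for a in kept} == {a.read_id for a in alns} - bad
        assert len(kept) == 900

    def test_wrong_coordinate_order_removed(self):
        a = _mk_aln("p", 1, "+", 1000, 1200)   # forward mate right of mate 2
        b = _mk_aln("p", 2, "-", 100, 300)
        assert filter_pairs([a, b]) == []

    @given(st.lists(
        st.tuples(st.integers(0, 30), st.sampled_from("+-"),
                  st.booleans(), st.integers(0, 40)),
        max_size=25,
    ))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_idempotent(self, spec):
        alns = []
        for i, (pair_id, strand, spliced, offset) in enumerate(spec):
            mate = 1 + (i % 2)
            start = 100 + 50 * offset
            alns.append(_mk_aln(f"p{pair_id}", mate, strand, start, start + 200,
                                spliced))
        once = filter_pairs(alns)
        twice = filter_pairs(once)
        assert [a.key() + (a.read_id, a.mate) for a in once] == \
            [a.key() + (a.read_id, a.mate) for a in twice]
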