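"""Synthetic compact-genome RNA-seq benchmark generator.

The generator emulates the situation the junction classifier is built for:
a gene-dense eukaryotic genome (intergenic stretches are short, introns
< 10 kb) expressing multi-exon genes, where a fraction of splicing events
pick one splice site at random ("splicing noise") and therefore produce
low-abundance nonfunctional junctions.

The pieces, in order:

* :func:`simulate_genome` — a background sequence with non-overlapping
  multi-exon genes on both strands; every functional intron starts GT and
  ends AG, with the full donor (9 nt) and acceptor (21 nt) windows drawn
  from generating PSFMs, and intron lengths drawn from a truncated
  log-normal.  The generating models are returned so estimation can be
  validated against them.
* :func:`simulate_transcripts_with_noise` — a pool of transcript molecules:
  each molecule comes from a gene picked proportionally to a log-normal
  expression law, and with probability ``noise_fraction`` one of its
  introns has its donor, acceptor, or both replaced by a random in-gene
  GT / AG position (each noisy molecule draws its own random site, so noise
  junctions are many, distinct and weakly covered — the empirical signature
  of splicing noise).
* :func:`simulate_reads` — paired-end FR reads with i.i.d. substitution
  errors (default rate 0.02) and per-read genomic truth blocks.

All randomness flows from a single seed; outputs are byte-identical across
runs with equal configs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seq import NUCS, revcomp
from .models import (
    ACCEPTOR_INTRONIC,
    DONOR_EXONIC,
    IntronLengthDist,
    Psfm,
    SpliceModels,
    estimate_background,
)


@dataclass
class SimConfig:
    genome_len: int = 100_000
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (2, 4)      # inclusive range
    exon_len_range: tuple[int, int] = (40, 90)
    intron_len_log_mean: float = math.log(95.0)   # log-normal, nt
    intron_len_log_sd: float = 0.35
    intron_len_range: tuple[int, int] = (55, 400)
    min_intergenic: int = 30
    noise_fraction: float = 0.2    # share of transcript molecules with a random splice site
    read_len: int = 75             # one of 50 / 75 / 100 in the reference experiments
    n_pairs: int = 50_000
    n_transcripts: int = 20_000    # molecules in the sampled pool
    fragment_mean: float = 180.0
    fragment_sd: float = 25.0
    error_rate: float = 0.02
    expression_log_sd: float = 1.0  # log-normal expression law
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in [0, 1)")
        if not 0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must be in [0, 0.2]")
        if self.fragment_mean < self.read_len:
            raise ValueError("fragment mean must be >= read length")


@dataclass
class SimGene:
    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]   # genomic, ascending

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]


@dataclass
class SimTranscript:
    """One transcript molecule of the pool."""

    transcript_id: str
    gene_id: str
    seq_id: str
    strand: str
    blocks: list[tuple[int, int]]     # genomic exon blocks, ascending
    label: str                        # "functional" or "noise"
    sequence: str = ""                # sense-strand cDNA

    def junctions(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])]


@dataclass
class ReadTruth:
    read_id: str
    mate: int
    seq_id: str
    strand: str                       # genomic strand the read matches forward
    blocks: list[tuple[int, int]]
    junctions: list[tuple[int, int]]  # genomic introns the read spans
    transcript_id: str
    n_errors: int


@dataclass
class TruthSet:
    genes: list[SimGene]
    introns: dict[tuple[str, int, int, str], str]  # key -> functional / noise
    reads: list[ReadTruth] = field(default_factory=list)


# ---------------------------------------------------------------------------
# generating splice-site models

def _psfm_from_weights(site_type: str, rows: list[dict[str, float]]) -> Psfm:
    probs = np.zeros((len(rows), 4, 4))
    for i, row in enumerate(rows):
        vec = np.array([row.get(c, 0.0) for c in NUCS], dtype=float)
        vec = vec / vec.sum()
        probs[i, :, :] = vec[None, :]
    return Psfm(site_type, 0, probs)


def default_generating_psfms() -> tuple[Psfm, Psfm]:
    """Zero-order generating PSFMs with a plant/fungus-like consensus:
    donor (M A G | G T A A G T), acceptor (polypyrimidine ... A G | G).
    The GT / AG core positions are (near-)deterministic."""
    eps = 1e-3
    donor_rows = [
        {"A": 0.34, "C": 0.34, "G": 0.16, "T": 0.16},       # exon -3
        {"A": 0.60, "C": 0.12, "G": 0.16, "T": 0.12},       # exon -2
        {"A": 0.10, "C": 0.06, "G": 0.78, "T": 0.06},       # exon -1
        {"G": 1 - 3 * eps, "A": eps, "C": eps, "T": eps},   # +1 (G)
        {"T": 1 - 3 * eps, "A": eps, "C": eps, "G": eps},   # +2 (T)
        {"A": 0.58, "C": 0.06, "G": 0.12, "T": 0.24},       # +3
        {"A": 0.64, "C": 0.08, "G": 0.12, "T": 0.16},       # +4
        {"A": 0.10, "C": 0.06, "G": 0.76, "T": 0.08},       # +5
        {"A": 0.18, "C": 0.14, "G": 0.18, "T": 0.50},       # +6
    ]
    pyr = {"A": 0.12, "C": 0.28, "G": 0.08, "T": 0.52}
    acceptor_rows = [dict(pyr) for _ in range(ACCEPTOR_INTRONIC - 2)]
    acceptor_rows[5] = {"A": 0.30, "C": 0.22, "G": 0.14, "T": 0.34}  # branch-ish
    acceptor_rows += [
        {"A": 1 - 3 * eps, "C": eps, "G": eps, "T": eps},   # -2 (A)
        {"G": 1 - 3 * eps, "A": eps, "C": eps, "T": eps},   # -1 (G)
        {"A": 0.24, "C": 0.14, "G": 0.48, "T": 0.14},       # exon +1
    ]
    return (
        _psfm_from_weights("donor", donor_rows),
        _psfm_from_weights("acceptor", acceptor_rows),
    )


# ---------------------------------------------------------------------------
# genome

_BACKGROUND_P = np.array([0.29, 0.21, 0.21, 0.29])


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [NUCS[i] for i in rng.choice(4, size=n, p=_BACKGROUND_P)]


def _sample_intron_len(rng: np.random.Generator, cfg: SimConfig) -> int:
    lo, hi = cfg.intron_len_range
    for _ in range(1000):
        l = int(round(rng.lognormal(cfg.intron_len_log_mean, cfg.intron_len_log_sd)))
        if lo <= l <= hi:
            return l
    return lo


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], TruthSet, SpliceModels]:
    """Generate the genome, its truth annotation, and the generating models.

    Genes are laid down left to right in *sense* orientation and written
    forward or reverse-complemented according to a random strand; splice
    site windows sampled from the generating PSFMs overwrite the sequence
    around every intron boundary.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    donor_psfm, acceptor_psfm = default_generating_psfms()

    structures: list[tuple[str, list[tuple[int, int]], int]] = []  # strand, sense exons, length
    total = 0
    for gi in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_len_range[0],
                                 config.exon_len_range[1] + 1, size=n_exons)
        intron_lens = [_sample_intron_len(rng, config) for _ in range(n_exons - 1)]
        exons = []
        pos = 0
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_exons - 1:
                pos += intron_lens[i]
        strand = "+" if rng.random() < 0.5 else "-"
        structures.append((strand, exons, pos))
        total += pos + config.min_intergenic
    if total + config.min_intergenic > config.genome_len:
        raise ValueError(
            f"cannot pack {config.n_genes} genes ({total} nt with spacing) "
            f"into {config.genome_len} nt; lower n_genes or gene sizes"
        )

    slack = config.genome_len - total - config.min_intergenic
    gaps = rng.multinomial(slack, np.full(config.n_genes + 1, 1.0 / (config.n_genes + 1)))

    chars = _random_seq(rng, config.genome_len)
    genes: list[SimGene] = []
    cursor = config.min_intergenic + int(gaps[0])
    intron_lengths: list[int] = []
    for gi, (strand, sense_exons, glen) in enumerate(structures):
        gstart = cursor
        cursor += glen + config.min_intergenic + int(gaps[gi + 1])
        # sense-coordinate gene sequence with PSFM windows at each boundary
        gene_chars = _random_seq(rng, glen)
        for (s1, e1), (s2, e2) in zip(sense_exons, sense_exons[1:]):
            # force the canonical core (the PSFM keeps epsilon mass off
            # GT/AG only so that its rows stay valid distributions)
            dwin = donor_psfm.sample(rng)
            dwin = dwin[:DONOR_EXONIC] + "GT" + dwin[DONOR_EXONIC + 2:]
            awin = acceptor_psfm.sample(rng)
            awin = awin[:ACCEPTOR_INTRONIC - 2] + "AG" + awin[ACCEPTOR_INTRONIC:]
            for k, ch in enumerate(dwin):
                gene_chars[e1 - DONOR_EXONIC + k] = ch
            for k, ch in enumerate(awin):
                gene_chars[s2 - ACCEPTOR_INTRONIC + k] = ch
            intron_lengths.append(s2 - e1)
        if strand == "+":
            genomic_exons = [(gstart + s, gstart + e) for s, e in sense_exons]
            chars[gstart : gstart + glen] = gene_chars
        else:
            genomic_exons = [(gstart + glen - e, gstart + glen - s)
                             for s, e in reversed(sense_exons)]
            chars[gstart : gstart + glen] = list(revcomp("".join(gene_chars)))
        genes.append(SimGene(f"gene{gi:04d}", "chr1", strand, genomic_exons))

    genome = {"chr1": "".join(chars)}
    introns = {
        ("chr1", s, e, g.strand): "functional"
        for g in genes for s, e in g.introns()
    }
    truth = TruthSet(genes=genes, introns=introns)
    models = SpliceModels(
        donor=donor_psfm,
        acceptor=acceptor_psfm,
        background=estimate_background(genome, order=0),
        intron_lengths=IntronLengthDist.from_lengths(intron_lengths)
        if intron_lengths else IntronLengthDist(55, 400, 10, np.full(35, 1 / 35)),
    )
    return genome, truth, models


# ---------------------------------------------------------------------------
# transcript pool with splicing noise

def _spliced_sequence(genome: dict[str, str], t: SimTranscript) -> str:
    s = "".join(genome[t.seq_id][a:b] for a, b in t.blocks)
    return s if t.strand == "+" else revcomp(s)


def _dinuc_sites(seq: str, lo: int, hi: int, dinuc: str) -> list[int]:
    out = []
    pos = seq.find(dinuc, lo)
    while 0 <= pos < hi:
        out.append(pos)
        pos = seq.find(dinuc, pos + 1)
    return out


def _noisy_blocks(
    gene: SimGene, genome_seq: str, rng: np.random.Generator, min_intron: int = 25
) -> list[tuple[int, int]] | None:
    """Replace the donor, acceptor, or both of one random intron with a
    random GT / AG position inside the gene span (forward-genome GT..AG for
    '+' genes, CT..AC for '-'); None if no valid site exists."""
    introns = gene.introns()
    if not introns:
        return None
    idx = int(rng.integers(len(introns)))
    s0, e0 = introns[idx]
    mode = ("donor", "acceptor", "both")[int(rng.integers(3))]
    d5, d3 = ("GT", "AG") if gene.strand == "+" else ("CT", "AC")
    # biological donor is the 5' end: genomic left for '+', right for '-'
    move_left = mode in ("donor", "both") if gene.strand == "+" else mode in ("acceptor", "both")
    move_right = mode in ("acceptor", "both") if gene.strand == "+" else mode in ("donor", "both")
    others = [iv for i, iv in enumerate(introns) if i != idx]

    def valid(s: int, e: int) -> bool:
        if e - s < min_intron or s <= gene.start or e >= gene.end:
            return False
        if (s, e) == (s0, e0):
            return False
        return not any(s < oe and e > os for os, oe in others)

    s_opts = ([p for p in _dinuc_sites(genome_seq, gene.start + 1, gene.end, d5)]
              if move_left else [s0])
    e_opts = ([p + 2 for p in _dinuc_sites(genome_seq, gene.start, gene.end - 1, d3)]
              if move_right else [e0])
    pairs = [(s, e) for s in s_opts for e in e_opts if valid(s, e)]
    if not pairs:
        return None
    new_s, new_e = pairs[int(rng.integers(len(pairs)))]
    # exon blocks = gene span minus the molecule's introns
    all_introns = sorted(others + [(new_s, new_e)])
    blocks: list[tuple[int, int]] = []
    pos = gene.start
    for s, e in all_introns:
        if s <= pos:
            return None
        blocks.append((pos, s))
        pos = e
    if pos >= gene.end:
        return None
    blocks.append((pos, gene.end))
    return blocks


def simulate_transcripts_with_noise(
    truth: TruthSet,
    genome: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SimTranscript]:
    """Sample the transcript-molecule pool.

    Genes are drawn proportionally to log-normal expression weights; each
    molecule is independently noisy with probability ``noise_fraction``.
    Noisy molecules that fail to find a random site after bounded retries
    fall back to the functional isoform.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if not truth.genes:
        raise ValueError("no genes to transcribe")
    weights = rng.lognormal(0.0, config.expression_log_sd, size=len(truth.genes))
    weights /= weights.sum()
    pool: list[SimTranscript] = []
    gene_idx = rng.choice(len(truth.genes), size=config.n_transcripts, p=weights)
    noisy = rng.random(config.n_transcripts) < config.noise_fraction
    for ti in range(config.n_transcripts):
        gene = truth.genes[int(gene_idx[ti])]
        label = "functional"
        blocks = list(gene.exons)
        if noisy[ti] and len(gene.exons) > 1:
            for _ in range(8):
                nb = _noisy_blocks(gene, genome[gene.seq_id], rng)
                if nb is not None:
                    blocks = nb
                    label = "noise"
                    break
        t = SimTranscript(
            transcript_id=f"t{ti:06d}", gene_id=gene.gene_id,
            seq_id=gene.seq_id, strand=gene.strand,
            blocks=blocks, label=label,
        )
        t.sequence = _spliced_sequence(genome, t)
        pool.append(t)
        if label == "noise":
            for s, e in t.junctions():
                truth.introns.setdefault((t.seq_id, s, e, t.strand), "noise")
    return pool


# ---------------------------------------------------------------------------
# reads

def _transcript_to_genomic(
    t: SimTranscript, t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Map a sense-transcript interval to ascending genomic blocks."""
    tlen = sum(e - s for s, e in t.blocks)
    if t.strand == "-":
        t_start, t_end = tlen - t_end, tlen - t_start
    out = []
    offset = 0
    for s, e in t.blocks:
        lo = max(t_start, offset)
        hi = min(t_end, offset + (e - s))
        if lo < hi:
            out.append((s + lo - offset, s + hi - offset))
        offset += e - s
    return out


def _apply_errors(
    seq: str, error_rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    if error_rate <= 0:
        return seq, 0
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        alt = [c for c in NUCS if c != arr[i]]
        arr[i] = alt[int(rng.integers(3))]
    return "".join(arr), len(hits)


def simulate_reads(
    pool: Sequence[SimTranscript],
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Paired-end FR reads from the transcript pool.

    Returns two FASTQ record lists ``(id, sequence, quality)`` (mate 1 and
    mate 2) and appends per-read truth to ``truth.reads``.  Fragments are
    drawn from molecules chosen uniformly from the pool (expression is
    encoded in the pool's composition); molecules shorter than the fragment
    are resampled.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    L = config.read_len
    reads1: list[tuple[str, str, str]] = []
    reads2: list[tuple[str, str, str]] = []
    qual = "I" * L
    n = 0
    attempts = 0
    while n < config.n_pairs and attempts < 50 * config.n_pairs:
        attempts += 1
        t = pool[int(rng.integers(len(pool)))]
        tlen = len(t.sequence)
        if tlen < L:
            continue
        flen = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
        flen = max(L, min(flen, tlen))
        start = int(rng.integers(0, tlen - flen + 1))
        frag = t.sequence[start : start + flen]
        rid = f"r{n:07d}"
        m1_seq, m1_err = _apply_errors(frag[:L], config.error_rate, rng)
        m2_seq, m2_err = _apply_errors(revcomp(frag[-L:]), config.error_rate, rng)
        reads1.append((rid, m1_seq, qual))
        reads2.append((rid, m2_seq, qual))
        for mate, t_lo, sense in ((1, start, True), (2, start + flen - L, False)):
            blocks = _transcript_to_genomic(t, t_lo, t_lo + L)
            juncs = [(e1, s2) for (_, e1), (s2, _) in zip(blocks, blocks[1:])]
            # genomic strand the read sequence matches forward:
            # mate1 carries the sense strand, mate2 the antisense
            if mate == 1:
                strand = t.strand
            else:
                strand = "-" if t.strand == "+" else "+"
            truth.reads.append(
                ReadTruth(rid, mate, t.seq_id, strand, blocks, juncs,
                          t.transcript_id, m1_err if mate == 1 else m2_err)
            )
        n += 1
    if n < config.n_pairs:
        raise RuntimeError("could not draw the requested number of pairs")
    return reads1, reads2


def simulate_dataset(config: SimConfig):
    """One-call convenience: genome, truth, generating models, transcript
    pool, and reads, all deterministically derived from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genome, truth, models = simulate_genome(config, rng)
    pool = simulate_transcripts_with_noise(truth, genome, config, rng)
    reads1, reads2 = simulate_reads(pool, truth, config, rng)
    return genome, truth, models, pool, reads1, reads2
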