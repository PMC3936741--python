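"""Standard-format I/O and evaluation against a reference annotation.

Coordinate conventions: everything in memory is 0-based, half-open.  GFF3
is written/read 1-based closed, SAM 1-based, BED 0-based half-open; the
conversions live here and nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .aligner import Read, SplicedAlignment
from .classify import ScoredJunction
from .features import FEATURE_NAMES, GenePredictionSet, PredictedGene


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def write_genome_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")

def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path, mate: int = 0) -> list[Read]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        rid = rec.id
        for suffix in ("/1", "/2"):
            if rid.endswith(suffix):
                rid = rid[:-2]
                if mate == 0:
                    mate = int(suffix[1])
        out.append(Read(rid, str(rec.seq), qual, mate))
    return out


# ---------------------------------------------------------------------------
# GFF3 annotation

@dataclass
class AnnotatedTranscript:
    transcript_id: str
    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]              # 0-based half-open, ascending
    cds: list[tuple[int, int]] = field(default_factory=list)

    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]


@dataclass
class Annotation:
    transcripts: list[AnnotatedTranscript]

    def intron_set(self) -> set[tuple[str, int, int, str]]:
        out = set()
        for t in self.transcripts:
            for s, e in t.introns():
                out.add((t.seq_id, s, e, t.strand))
        return out

    def to_predictions(self) -> GenePredictionSet:
        genes = [
            PredictedGene(t.transcript_id, t.seq_id, t.strand,
                          list(t.cds or t.exons))
            for t in self.transcripts
        ]
        return GenePredictionSet(genes)


def write_annotation_gff3(transcripts: Sequence[AnnotatedTranscript], path) -> None:
    """GFF3 writer (1-based closed coordinates); one gene + mRNA per
    transcript with exon and CDS children."""
    lines = ["##gff-version 3"]
    for t in transcripts:
        start = t.exons[0][0] + 1
        end = t.exons[-1][1]
        lines.append("\t".join([
            t.seq_id, "splicescope", "gene", str(start), str(end), ".",
            t.strand, ".", f"ID={t.gene_id}",
        ]))
        lines.append("\t".join([
            t.seq_id, "splicescope", "mRNA", str(start), str(end), ".",
            t.strand, ".", f"ID={t.transcript_id};Parent={t.gene_id}",
        ]))
        for s, e in t.exons:
            lines.append("\t".join([
                t.seq_id, "splicescope", "exon", str(s + 1), str(e), ".",
                t.strand, ".", f"Parent={t.transcript_id}",
            ]))
        for s, e in t.cds:
            lines.append("\t".join([
                t.seq_id, "splicescope", "CDS", str(s + 1), str(e), ".",
                t.strand, "0", f"Parent={t.transcript_id}",
            ]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


class AnnotationParseError(ValueError):
    pass


def parse_annotation(path) -> Annotation:
    """Parse a GFF3 into transcripts with exons (and CDS when present);
    introns are derived as the gaps between consecutive exons.

    Parsing proper is delegated to :mod:`gffutils` (in-memory database);
    exon/CDS features are grouped under their Parent transcript, and
    features without an mRNA record still form an implicit transcript.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted internal errors
        raise AnnotationParseError(f"cannot parse GFF3 {path}: {exc}") from exc

    table: dict[str, AnnotatedTranscript] = {}
    for feat in db.features_of_type(("mRNA", "transcript")):
        parent = feat.attributes.get("Parent", [feat.id])[0]
        table[feat.id] = AnnotatedTranscript(
            feat.id, parent, feat.seqid, feat.strand, [], []
        )
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent")
            if not parents:
                raise AnnotationParseError(
                    f"{ftype} feature at {feat.seqid}:{feat.start} has no Parent"
                )
            iv = (feat.start - 1, feat.end)
            for tid in parents:
                t = table.get(tid)
                if t is None:
                    t = AnnotatedTranscript(tid, tid, feat.seqid, feat.strand, [], [])
                    table[tid] = t
                (t.exons if ftype == "exon" else t.cds).append(iv)
    transcripts = []
    for t in table.values():
        if not t.exons and t.cds:
            t.exons = sorted(t.cds)
        if not t.exons:
            continue
        t.exons = sorted(t.exons)
        t.cds = sorted(t.cds)
        for (_, e1), (s2, _) in zip(t.exons, t.exons[1:]):
            if e1 > s2:
                raise AnnotationParseError(
                    f"transcript {t.transcript_id}: overlapping or unsorted exons"
                )
        transcripts.append(t)
    return Annotation(sorted(transcripts, key=lambda t: (t.seq_id, t.exons[0][0])))


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvalReport:
    """Confirmed (annotated) vs novel counts as the score threshold varies.

    ``points`` columns: threshold S, tp (confirmed with s > S), fp (novel
    with s > S).  Raising S can only shrink both counts (nesting).
    """

    points: pd.DataFrame
    n_candidates: int

    def __post_init__(self) -> None:
        tp = self.points["tp"].to_numpy()
        fp = self.points["fp"].to_numpy()
        s = self.points["S"].to_numpy()
        order = s.argsort()
        if (tp[order][1:] - tp[order][:-1] > 0).any() or \
           (fp[order][1:] - fp[order][:-1] > 0).any():
            raise ValueError("threshold nesting violated: counts must be "
                             "non-increasing in S")


def evaluate_vs_annotation(
    scored: Sequence[ScoredJunction],
    annotated_introns: set[tuple[str, int, int, str]],
    thresholds: Sequence[float] | None = None,
) -> EvalReport:
    """Per-threshold confirmed/novel counts; 'confirmed' is an exact match
    of sequence, both boundaries and strand to an annotated intron."""
    if thresholds is None:
        thresholds = [i / 20 for i in range(20)]
    rows = []
    for S in sorted(thresholds):
        tp = fp = 0
        for sj in scored:
            if sj.score > S:
                if sj.candidate.key() in annotated_introns:
                    tp += 1
                else:
                    fp += 1
        rows.append({"S": S, "tp": tp, "fp": fp})
    return EvalReport(pd.DataFrame(rows), n_candidates=len(scored))


def ranked_curve(
    keys_scores: Sequence[tuple[tuple, float]],
    annotated_introns: set[tuple[str, int, int, str]],
) -> pd.DataFrame:
    """Non-normalized ROC-type curve: walk candidates from the highest
    score down and accumulate confirmed (tp) vs novel (fp) counts.  Works
    for any scoring (posterior, or raw depth as a surrogate)."""
    ordered = sorted(keys_scores, key=lambda ks: -ks[1])
    tp = fp = 0
    rows = []
    for key, score in ordered:
        if key in annotated_introns:
            tp += 1
        else:
            fp += 1
        rows.append({"score": score, "tp": tp, "fp": fp})
    return pd.DataFrame(rows)


def label_coding_status(
    junction_key: tuple[str, int, int, str], annotation: Annotation
) -> str:
    """'noncoding' only when the exonic bases adjacent to the intron are
    outside the CDS in every overlapping isoform; junctions outside all
    transcripts are noncoding."""
    seq_id, s, e, _strand = junction_key
    for t in annotation.transcripts:
        if t.seq_id != seq_id or not t.cds:
            continue
        if e <= t.exons[0][0] or s >= t.exons[-1][1]:
            continue
        left_flank, right_flank = s - 1, e
        in_cds = lambda p: any(cs <= p < ce for cs, ce in t.cds)
        if in_cds(left_flank) or in_cds(right_flank):
            return "coding"
    return "noncoding"


# ---------------------------------------------------------------------------
# SAM / BED / TSV output

def write_sam(
    alignments: Sequence[SplicedAlignment],
    genome: Mapping[str, str],
    path,
    read_seqs: Mapping[str, str] | None = None,
) -> None:
    """SAM output with N CIGAR operations for introns and an XS:A tag
    giving the transcript strand of spliced alignments.  Remapped records
    carry a PG:Z:remap tag."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": sid, "LN": len(seq)} for sid, seq in genome.items()],
    }
    ref_ids = {sid: i for i, sid in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment()
            seg.query_name = aln.read_id
            seg.reference_id = ref_ids[aln.seq_id]
            seg.reference_start = aln.start
            flag = 0
            if aln.strand == "-":
                flag |= 16
            if aln.mate in (1, 2):
                flag |= 1 | (64 if aln.mate == 1 else 128)
            seg.flag = flag
            cigar = []
            for i, (s, e) in enumerate(aln.blocks):
                cigar.append((0, e - s))  # M
                if i + 1 < len(aln.blocks):
                    cigar.append((3, aln.blocks[i + 1][0] - e))  # N
            seg.cigartuples = cigar
            if read_seqs and aln.read_id in read_seqs:
                seg.query_sequence = read_seqs[aln.read_id]
            tags = [("NM", aln.mismatches)]
            if aln.splice_strand:
                tags.append(("XS", aln.splice_strand))
            if aln.source == "remap":
                tags.append(("PG", "remap"))
            seg.set_tags(tags)
            out.write(seg)


def write_junction_bed(scored: Sequence[ScoredJunction], path) -> None:
    """BED12-like junction file: one record per junction; the two blocks
    are the maximal observed overhangs, the score column is round(1000 s)."""
    lines = []
    for i, sj in enumerate(sorted(scored, key=lambda s: s.candidate.key())):
        c = sj.candidate
        left = max(s.left_overhang for s in c.supports)
        right = max(s.right_overhang for s in c.supports)
        chrom_start = c.donor_pos - left
        chrom_end = c.acceptor_end + right
        lines.append("\t".join(map(str, [
            c.seq_id, chrom_start, chrom_end, f"JUNC{i:05d}",
            round(1000 * sj.score), c.strand, chrom_start, chrom_end,
            "255,0,0", 2, f"{left},{right}",
            f"0,{c.acceptor_end - chrom_start}",
        ])))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_junction_bed(path) -> list[tuple[str, int, int, str, float]]:
    """Recover (seq, donor, acceptor_end, strand, score) from a junction
    BED12 written by :func:`write_junction_bed`."""
    out = []
    with open(path) as fh:
        for line in fh:
            p = line.rstrip("\n").split("\t")
            if len(p) < 12:
                continue
            chrom_start = int(p[1])
            sizes = [int(x) for x in p[10].split(",")]
            starts = [int(x) for x in p[11].split(",")]
            donor = chrom_start + starts[0] + sizes[0]
            acceptor_end = chrom_start + starts[1]
            out.append((p[0], donor, acceptor_end, p[5], int(p[4]) / 1000))
    return out


def feature_table(scored: Sequence[ScoredJunction]) -> pd.DataFrame:
    """Full per-candidate table: coordinates (1-based closed for human
    reading), the nine features, decision value and posterior score."""
    rows = []
    for sj in scored:
        c = sj.candidate
        row = {
            "seq": c.seq_id, "donor": c.donor_pos + 1, "acceptor": c.acceptor_end,
            "strand": c.strand, "class": c.cls,
        }
        row.update(sj.features.as_dict())
        row["decision_value"] = sj.decision_value
        row["score"] = sj.score
        rows.append(row)
    cols = ["seq", "donor", "acceptor", "strand", "class",
            *FEATURE_NAMES, "decision_value", "score"]
    return pd.DataFrame(rows, columns=cols)


def write_feature_table(scored: Sequence[ScoredJunction], path) -> None:
    feature_table(scored).to_csv(path, sep="\t", index=False)


def write_eval_report(report: EvalReport, path) -> None:
    df = report.points.copy()
    df["n_candidates"] = report.n_candidates
    df.to_csv(path, sep="\t", index=False)


def read_eval_report(path) -> EvalReport:
    df = pd.read_csv(path, sep="\t")
    n = int(df["n_candidates"].iloc[0]) if len(df) else 0
    return EvalReport(df[["S", "tp", "fp"]], n_candidates=n)
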