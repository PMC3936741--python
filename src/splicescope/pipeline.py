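"""End-to-end pipeline: align -> remap -> classify -> evaluate.

The stages follow the four-step design: (1) ungapped alignment of whole
reads, (2) anchor-and-extend gapped alignment of the reads that failed,
(3) remapping of still-unmapped reads against pseudo-transcripts built
around the predicted junctions, followed by paired-end consistency
filtering, and (4) SVM classification of the aggregated junction
candidates with posterior scoring and thresholding.  Remapping runs before
classification so the refined alignment depth feeds the classifier.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .aligner import (
    AlignerConfig,
    GenomeIndex,
    Read,
    SplicedAlignment,
    align_ungapped,
    gapped_align,
)
from .classify import (
    DEFAULT_LATTICE,
    ClassifierModel,
    LabeledExample,
    ScoredJunction,
    SvmConfig,
    fit_posterior,
    grid_search_svm,
    negative_rule,
    positive_rule,
    score_and_threshold,
    score_candidates,
    select_development_set,
    select_training_set,
)
from .features import (
    BoundaryCoverage,
    GenePredictionSet,
    JunctionCandidate,
    JunctionFeatures,
    aggregate_junctions,
    compute_features,
)
from .io_eval import EvalReport, evaluate_vs_annotation
from .models import SpliceModels
from .remap import Junction, filter_pairs, remap_unmapped

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    aligner: AlignerConfig = field(default_factory=AlignerConfig)
    train_size: int = 10_000
    dev_per_class: int = 5_000
    train_class_cap_fraction: float = 0.5  # leave the rest for the dev set
    lattice: tuple[int, ...] = DEFAULT_LATTICE
    threshold: float = 0.5
    neighbor_cap: int = 8
    seed: int = 0


@dataclass
class PipelineResult:
    alignments: list[SplicedAlignment]
    unmapped: list[Read]
    coverage: BoundaryCoverage
    candidates: list[tuple[JunctionCandidate, JunctionFeatures]]
    train: list[LabeledExample]
    dev: list[LabeledExample]
    svm_config: SvmConfig
    w_map: np.ndarray
    model: ClassifierModel
    scored: list[ScoredJunction]
    final: list[ScoredJunction]
    n_remapped: int


def align_all(
    reads: Sequence[Read],
    index: GenomeIndex,
    models: SpliceModels | None,
    config: AlignerConfig,
) -> tuple[list[SplicedAlignment], list[Read], BoundaryCoverage]:
    """Steps 1-2 for a batch of reads.

    Reads that align ungapped keep their best-tier placements as
    single-block alignments (and feed the boundary-crossing coverage);
    reads that do not are sent to anchor-and-extend.  Returns (alignments,
    unmapped reads, coverage).
    """
    coverage = BoundaryCoverage({sid: len(s) for sid, s in index.genome.items()})
    alignments: list[SplicedAlignment] = []
    unmapped: list[Read] = []
    for read in reads:
        hits = align_ungapped(read, index, config.max_mismatch, config.max_hits)
        if hits:
            best_mm = hits[0].mismatches
            for h in hits:
                if h.mismatches > best_mm:
                    break
                alignments.append(
                    SplicedAlignment(
                        read_id=read.id, seq_id=h.seq_id, strand=h.strand,
                        blocks=[(h.pos, h.pos + len(read))],
                        mismatches=h.mismatches, introns=[], mate=read.mate,
                    )
                )
                coverage.add(h.seq_id, h.pos, h.pos + len(read))
            continue
        gapped = gapped_align(read, index, models, config)
        if gapped:
            best_mm = gapped[0].mismatches
            alignments.extend(a for a in gapped if a.mismatches == best_mm)
        else:
            unmapped.append(read)
    return alignments, unmapped, coverage


def junctions_from_alignments(
    alignments: Sequence[SplicedAlignment],
) -> list[Junction]:
    seen: dict[tuple, Junction] = {}
    for aln in alignments:
        for intron in aln.introns:
            key = (aln.seq_id, intron.start, intron.end, intron.strand)
            if key not in seen:
                seen[key] = Junction(aln.seq_id, intron.start, intron.end,
                                     intron.cls, intron.strand)
    return sorted(seen.values(), key=lambda j: (j.seq_id, j.start, j.end))


def run_pipeline(
    genome: Mapping[str, str],
    reads: Sequence[Read],
    models: SpliceModels,
    predictions: GenePredictionSet,
    config: PipelineConfig,
) -> PipelineResult:
    """The full pipeline on in-memory inputs."""
    acfg = config.aligner
    index = GenomeIndex(genome, acfg.k)

    alignments, unmapped, coverage = align_all(reads, index, models, acfg)
    n_spliced = sum(1 for a in alignments if a.introns)
    logger.info("aligned %d records (%d spliced); %d reads unmapped",
                len(alignments), n_spliced, len(unmapped))

    read_len = max((len(r) for r in reads), default=0)
    junctions = junctions_from_alignments(alignments)
    remapped = remap_unmapped(unmapped, junctions, genome, read_len, acfg,
                              neighbor_cap=config.neighbor_cap)
    logger.info("remap rescued %d alignments from %d unmapped reads",
                len(remapped), len(unmapped))
    alignments = filter_pairs(alignments + remapped)

    spliced = [a for a in alignments if a.introns]
    candidates_raw = aggregate_junctions(spliced)
    candidates = [
        (cand, compute_features(cand, coverage, genome, models, predictions))
        for cand in candidates_raw
    ]

    n_pos = sum(1 for _, f in candidates if positive_rule(f))
    n_neg = sum(1 for _, f in candidates if negative_rule(f))
    cap = config.train_class_cap_fraction
    train_size = min(
        config.train_size,
        2 * max(1, int(min(n_pos, n_neg) * cap)) if cap else config.train_size,
    )
    train = select_training_set(candidates, size=train_size, seed=config.seed)
    dev = select_development_set(
        candidates, predictions.predicted_introns(), train,
        size_per_class=config.dev_per_class, seed=config.seed + 1,
    )
    svm_config, w_map = grid_search_svm(train, dev, config.lattice)
    logger.info("grid search optimum: c=%.4g gamma=%.4g (W=%d)",
                svm_config.c, svm_config.gamma, int(w_map.max()))
    model, _ = fit_posterior(train, svm_config, seed=config.seed)
    scored = score_candidates(candidates, model)
    final = score_and_threshold(scored, config.threshold)
    return PipelineResult(
        alignments=alignments, unmapped=unmapped, coverage=coverage,
        candidates=candidates, train=train, dev=dev, svm_config=svm_config,
        w_map=w_map, model=model, scored=scored, final=final,
        n_remapped=len(remapped),
    )


def evaluate_result(
    result: PipelineResult,
    annotated_introns: set[tuple[str, int, int, str]],
    thresholds: Sequence[float] | None = None,
) -> EvalReport:
    return evaluate_vs_annotation(result.scored, annotated_introns, thresholds)
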