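"""Simulated benchmark: wire the simulator into the pipeline and measure
junction-calling accuracy against the simulator's truth.

The ab initio gene predictions the classifier depends on are stood in for
by the truth gene structures with a fraction of genes randomly withheld
(an ab initio finder on a compact genome recovers most but not all genes);
sequence-model parameters are estimated from the predicted introns, not
read from the generator, so the whole parameter path is exercised.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .aligner import Read
from .features import GenePredictionSet, PredictedGene
from .models import SpliceModels, estimate_models
from .pipeline import PipelineConfig, PipelineResult, run_pipeline
from .simulate import SimConfig, TruthSet, simulate_dataset


@dataclass
class BenchmarkRun:
    sim_config: SimConfig
    genome: dict[str, str]
    truth: TruthSet
    generating_models: SpliceModels
    estimated_models: SpliceModels
    predictions: GenePredictionSet
    reads: list[Read]
    result: PipelineResult
    metrics: dict[str, float] = field(default_factory=dict)


def predictions_from_truth(
    truth: TruthSet, dropout: float, rng: np.random.Generator
) -> GenePredictionSet:
    """Truth gene structures minus a random ``dropout`` fraction, standing
    in for an imperfect ab initio prediction."""
    keep = rng.random(len(truth.genes)) >= dropout
    genes = [
        PredictedGene(g.gene_id, g.seq_id, g.strand, list(g.exons))
        for g, k in zip(truth.genes, keep) if k
    ]
    if not genes:
        genes = [PredictedGene(g.gene_id, g.seq_id, g.strand, list(g.exons))
                 for g in truth.genes]
    return GenePredictionSet(genes)


def truth_functional_introns(truth: TruthSet) -> set[tuple[str, int, int, str]]:
    return {k for k, label in truth.introns.items() if label == "functional"}


def _precision(
    scored_keys: Sequence[tuple], functional: set[tuple]
) -> float:
    if not scored_keys:
        return float("nan")
    return sum(1 for k in scored_keys if k in functional) / len(scored_keys)


def benchmark_metrics(run_result: PipelineResult, truth: TruthSet) -> dict[str, float]:
    functional = truth_functional_introns(truth)
    all_keys = [c.key() for c, _ in run_result.candidates]
    final_keys = [sj.candidate.key() for sj in run_result.final]
    train_pos = [ex for ex in run_result.train if ex.y == 1]
    train_neg = [ex for ex in run_result.train if ex.y == 0]
    metrics = {
        "n_candidates": float(len(all_keys)),
        "n_final": float(len(final_keys)),
        "precision_unfiltered": _precision(all_keys, functional),
        "precision_final": _precision(final_keys, functional),
        "recall_final": (
            sum(1 for k in final_keys if k in functional) / len(functional)
            if functional else float("nan")
        ),
        "train_positive_purity": _precision([e.key for e in train_pos], functional),
        "train_negative_true_fraction": _precision(
            [e.key for e in train_neg], functional
        ),
    }
    return metrics


def run_benchmark(
    sim_config: SimConfig,
    pipe_config: PipelineConfig | None = None,
    prediction_dropout: float = 0.1,
) -> BenchmarkRun:
    if pipe_config is None:
        pipe_config = PipelineConfig(seed=sim_config.seed)
    genome, truth, gen_models, pool, reads1, reads2 = simulate_dataset(sim_config)
    reads = [Read(rid, seq, q, 1) for rid, seq, q in reads1]
    reads += [Read(rid, seq, q, 2) for rid, seq, q in reads2]

    rng = np.random.default_rng(sim_config.seed + 17)
    predictions = predictions_from_truth(truth, prediction_dropout, rng)
    pred_introns = sorted(predictions.predicted_introns())
    estimated = estimate_models(
        [(sid, s, e, strand) for sid, s, e, strand in pred_introns], genome
    )
    result = run_pipeline(genome, reads, estimated, predictions, pipe_config)
    run = BenchmarkRun(
        sim_config=sim_config, genome=genome, truth=truth,
        generating_models=gen_models, estimated_models=estimated,
        predictions=predictions, reads=reads, result=result,
    )
    run.metrics = benchmark_metrics(result, truth)
    return run
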