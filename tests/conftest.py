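import numpy as np
import pytest

from splicescope.aligner import AlignerConfig, Read, build_index
from splicescope.benchmark import predictions_from_truth, run_benchmark
from splicescope.features import aggregate_junctions, compute_features
from splicescope.pipeline import align_all, junctions_from_alignments
from splicescope.remap import filter_pairs, remap_unmapped
from splicescope.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 30 kb genome with 50 genes, 3 000 read pairs, 2% errors, 20% noise
    molecules — the workhorse fixture for module-level checks."""
    cfg = SimConfig(genome_len=30_000, n_genes=50, n_pairs=3_000,
                    n_transcripts=4_000, seed=3)
    genome, truth, models, pool, r1, r2 = simulate_dataset(cfg)
    return cfg, genome, truth, models, pool, r1, r2


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free variant used wherever exact sequence identities matter."""
    cfg = SimConfig(genome_len=30_000, n_genes=50, n_pairs=1_000,
                    n_transcripts=2_000, error_rate=0.0, seed=4)
    genome, truth, models, pool, r1, r2 = simulate_dataset(cfg)
    return cfg, genome, truth, models, pool, r1, r2


def _reads_of(r1, r2):
    return ([Read(rid, seq, q, 1) for rid, seq, q in r1]
            + [Read(rid, seq, q, 2) for rid, seq, q in r2])


@pytest.fixture(scope="session")
def small_aligned(small_dataset):
    """Alignments + candidates + features for the small data set (align ->
    remap -> pair filter -> aggregate -> featurize, no classifier)."""
    cfg, genome, truth, models, pool, r1, r2 = small_dataset
    acfg = AlignerConfig()
    index = build_index(genome, acfg.k)
    reads = _reads_of(r1, r2)
    alignments, unmapped, coverage = align_all(reads, index, models, acfg)
    junctions = junctions_from_alignments(alignments)
    remapped = remap_unmapped(unmapped, junctions, genome, cfg.read_len, acfg)
    alignments = filter_pairs(alignments + remapped)
    spliced = [a for a in alignments if a.introns]
    rng = np.random.default_rng(99)
    predictions = predictions_from_truth(truth, 0.1, rng)
    candidates = [
        (c, compute_features(c, coverage, genome, models, predictions))
        for c in aggregate_junctions(spliced)
    ]
    return {
        "config": cfg, "aligner_config": acfg, "genome": genome,
        "truth": truth, "models": models, "reads": reads,
        "alignments": alignments, "unmapped": unmapped,
        "coverage": coverage, "predictions": predictions,
        "candidates": candidates,
    }


@pytest.fixture(scope="session")
def benchmark_run():
    """The standard synthetic benchmark: 100 kb genome, 200 genes, 50 k
    pairs, 20% noise molecules, seed 1 — one full pipeline run shared by
    the acceptance checks."""
    return run_benchmark(SimConfig(seed=1))
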