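# Methods

`splicescope` maps spliced RNA-seq reads to a compact eukaryotic genome and
denoises the resulting splice-junction calls. It targets genomes (< 500 Mb,
largely homogeneous GC) where functional alternative splicing is rare enough
that most novel junctions are either alignment artifacts or *splicing
noise* — transcripts spliced at one randomly selected site. The pipeline
runs in four steps: ungapped alignment, anchor-and-extend gapped alignment,
pseudo-transcript remapping, and SVM classification of junction candidates
with a posterior score. Remapping precedes classification so that the
refined alignment depth feeds the classifier.

## Alignment model

**Index.** A hash table of k-mers (default k = 20) over the forward strand;
reverse-strand hits are found by looking up a k-mer's reverse complement.
This reproduces the contract of an FM-index read aligner (find all gapless
placements with at most 2 substitutions) without the engine: reads are
seeded with `max_mismatch + 1` non-overlapping k-mers (pigeonhole: one seed
must be error-free) and verified by direct comparison.

**Anchor-and-extend.** A read that fails ungapped alignment is cut into
non-overlapping 18–25 nt segments (default 25; a trailing remainder is
appended to the last segment). Segments are aligned ungapped (≤ 1 mismatch)
and chained collinearly per sequence; the chain's anchored segments delimit
the genomic region where each intron must lie. Every unaligned stretch —
between two anchors, or at either read end — is explained by at most one
intron whose boundaries must be GT–AG, GC–AG or AT–AC (forward or
reverse-complemented; the orientation fixes the transcript strand reported
as the SAM `XS` tag). Between two anchors the intron length is fixed by the
anchor spacing and only the split point varies; at read ends the acceptor
(or donor) is searched within `max_intron` (default 10 000 nt, the length
cap appropriate for compact genomes) by a vectorized dinucleotide-gated
scan. Anchors are trimmed back by 8 nt wherever they border an unresolved
stretch, because a fully matching anchor can overhang a junction into the
intron while absorbing a mismatch; the resolvers re-decide that boundary
region. Hard constraints on every emitted alignment: block lengths sum to
the read length, each junction keeps ≥ 8 nt of exonic sequence on its
shorter side, intron length lies in `[min_intron, max_intron)` (defaults
20 and 10 000 nt), and only the three dinucleotide classes above occur.

Tie-breaking at equal mismatch count: fewer introns first (parsimony), then
the higher donor+acceptor log-odds score, then the shorter intron, then the
leftmost placement. Multi-mapping reads keep up to `max_hits` (default 10)
placements with no per-hit penalty.

**Remapping.** Reads spanning two junctions closer than a segment length
cannot anchor and stay unmapped. For every predicted junction a
pseudo-transcript is built by concatenating L exonic nt upstream and
downstream of the spliced junction (L = read length); when n other
junctions lie within L nt, all 2^n neighbor subsets are built (n capped at
8 nearest to bound the blow-up). Unmapped reads are aligned gaplessly to
these references and projected back through the block coordinate map;
projections must still satisfy every alignment constraint, and duplicate
projections of one read are collapsed.

**Paired-end filter.** A spliced alignment is removed unless its mate is
unmapped or has an alignment on the opposite strand of the same sequence
with the forward-strand mate on the left (inner distance ≤ 500 kb,
effectively off). Unspliced alignments and singletons pass. The filter is
idempotent.

## Sequence models

Splice sites are scored by position-specific frequency matrices: the donor
window spans 3 exonic + 6 intronic nt (width 9), the acceptor window 20
intronic + 1 exonic nt (width 21). Matrices are zero- or first-order
non-uniform Markov chains (first order is the default for estimation, as
used for real compact genomes); scores are log2 likelihood ratios against a
background model, by default order-0 whole-genome composition. A window
position holding N contributes the background probability to both numerator
and denominator and cancels, so N-bearing windows are scorable but never
advantaged. Intron lengths are scored as log2 of a binned empirical pmf
(bin width 10 nt) with a pseudo-mass of 1e-6 outside the support; nothing
scores above the cap of 10 000 nt.

Parameters are estimated from labeled introns — derived from an annotation,
supplied as a file, or taken from the simulator truth — with an additive
pseudocount of 0.5 per (position, context, letter); at least 50 introns are
required. The full parameter set round-trips losslessly through a sectioned
plain-text file (`[donor]`, `[acceptor]`, `[background]`,
`[intron_lengths]`; tab-separated rows at 17 significant digits). This
estimation path stands in for an ab initio gene finder's unsupervised
training, which is out of scope; in the benchmark the "ab initio
predictions" are the simulator's truth genes with 10% randomly withheld, so
the prediction-dependent features and the development-set labels see an
imperfect gene finder, as they would in practice.

## Junction features

Each unique candidate (sequence, donor position, acceptor end, strand)
aggregates its supporting gapped alignments. Nine features:

| feature | definition | default role |
|---|---|---|
| skew | log2((1+C)/(1+max(u_d, u_a))), C = junction depth, u = ungapped reads crossing the donor/acceptor boundary | selection only |
| depth | number of supporting gapped alignments | classifier |
| gap_loglik | log2 pmf of the intron length | classifier |
| entropy | −Σᵢ cᵢ·log2(cᵢ/C) over distinct left-anchor offsets | selection only |
| min_overhang | max over supports of each support's shorter overhang | selection only |
| donor_score | donor PSFM log-odds (bits) | classifier |
| acceptor_score | acceptor PSFM log-odds (bits) | classifier |
| frameshift | 1 iff both sites sit in predicted coding exons of one gene and the removed predicted-coding length is not a multiple of 3 | classifier |
| strand_discord | 1 iff the intron overlaps a predicted gene on the opposite strand | classifier |

The entropy is *depth-weighted* (not normalized) Shannon entropy: a stack
of identical alignments scores 0 regardless of depth, while diverse anchor
offsets score high — this makes the selection threshold of 20 attainable at
realistic depths, which a log2(L)-bounded normalized entropy could never
reach. The skew compares junction support against local *unspliced*
coverage; strongly negative values flag junctions that compete with a
well-covered contiguous genome. Both formulas are this package's definitions; the self-labeling thresholds
(20, −1, 2 nt) are calibrated to them, and tools defining skew or entropy
differently would need those thresholds revisited. Windows that would run off a contig score a −50-bit
floor. The feature vector is a pure function of its inputs; recomputation
is bit-identical.

## Self-labeled classification

No reference annotation is used to train. Positives: candidates with
min_overhang > 20 **and** entropy > 20. Negatives: skew < −1 **or**
min_overhang ≤ 2. Up to 10 000 examples, equally divided, are sampled
without replacement (candidates matching both rules are excluded). The
development set labels candidates by exact match — sequence, both
boundaries, strand — to the ab initio predicted introns, 5 000 per class,
disjoint from the training set by junction key. The three selection
features never enter the classifier input, which is the six-vector
(donor_score, acceptor_score, gap_loglik, frameshift, strand_discord,
depth).

At desk scale the candidate pool holds hundreds of true junctions rather
than the millions of a real run, and taking every eligible positive into
the training set would leave the development set without positives. The
pipeline therefore caps each training class at half its eligible pool
(`train_class_cap_fraction = 0.5`); the selection function itself keeps the
take-all-when-short contract for library users.

An RBF-kernel SVM is fitted at every point of the (ln c, ln γ) lattice
{−9, …, 3}² on the z-scored training features (standardization uses
training statistics; without it no shared γ lattice is sane) and scored by
W = TP − FP on the development set; ties break toward smaller γ (smoother
boundary), then smaller c. Decision values from a stratified 5-fold CV on
the training set calibrate a Platt sigmoid s = k/(1 + exp(A·f + B)), fitted
by Newton iterations with backtracking on Platt's smoothed maximum-
likelihood targets; k = 1 (standard Platt scaling). The posterior is
monotone in the decision value by construction, so raising the threshold S
can only shrink the reported junction set — the mechanism behind the
non-normalized ROC curves the evaluation writes. The default operating
point is S = 0.5 with a strict inequality (s > S).

## Synthetic data generator

The generator is first-class, tested code and defines the study
conditions. A background i.i.d. sequence (A/T 0.29, C/G 0.21) carries
non-overlapping genes on both strands: 2–4 exons of 40–90 nt, intron
lengths log-normal (median ≈ 95 nt) truncated to [55, 400] nt, ≥ 30 nt
intergenic spacing — a gene-dense, short-intron architecture typical of
fungal and plant genomes. Every functional intron is GT..AG with the full
donor/acceptor windows sampled from order-0 generating PSFMs (plant-like
consensus, GT/AG core forced); the generating matrices, background and the
empirical intron-length pmf are returned so estimation can be validated
against them.

Transcription samples a pool of molecules (default 20 000): genes are drawn
proportionally to log-normal expression weights (σ = 1), and each molecule
independently carries one noisy junction with probability `noise_fraction`
(default 0.2) — its donor, acceptor, or both replaced by a random in-gene
GT/AG position. Because each noisy molecule draws its own site, noise
junctions are numerous, distinct and weakly covered, reproducing the
empirical signature of splicing noise (novel junctions concentrated at
coverage ~1–5) rather than a few deep artifacts; noise junctions are
deliberately canonical GT–AG so the classifier cannot filter them by
dinucleotide class alone. Reads are FR-oriented pairs (default 50 000 pairs
of 75 nt, fragment length 180 ± 25) with i.i.d. substitution errors at
0.02 per base. Everything derives from one seed; outputs are byte-identical
across runs.

What the simulator does *not* emulate: indels and quality-profile errors,
PCR duplicates, repeat families and paralogy, expression-dependent 3' bias,
GC-inhomogeneous composition, and annotated alternative isoforms. Passing
tests therefore demonstrate the machinery's correctness and the separation
of noise from signal under this model, not performance on real libraries —
in particular real repeat structure would stress the multi-mapping path far
harder than a random background does.

## Numerical and scale choices

- Benchmark problem sizes: the standard run uses a 100 kb genome, 200
  genes, 50 000 pairs (≈ 75× coverage), 20 000 pool molecules, seed 1. The
  aligner-oracle comparison uses five 12 kb genomes with error-free reads
  and `max_intron` 2 000 (the oracle's one-sided scan is exhaustive in that
  window); reproducibility runs use a 20 kb genome with 4 000 pairs.
- The exhaustive-enumeration oracle covers single-gap placements; reads
  whose optimum uses two gaps are checked for dominance (the aligner's
  result must be at least as good) rather than equality.
- Platt fit: Newton with 1e-12 Hessian ridge, backtracking halving up to 30
  steps, convergence at step norm < 1e-10; falls back to the standard
  initialization A = 0, B = log((n−+1)/(n++1)) if a step fails.
- Probabilities in parameter files are written with 17 significant digits
  (`%.17g`), making save→load exact for IEEE doubles.
- Degenerate inputs: single-class training sets, empty label pools and
  empty prediction sets abort with diagnostic counts; junction windows off
  a contig edge score the −50-bit floor; pseudo-transcripts at contig edges
  truncate with a warning.

## Known limitations

- No indels within alignment blocks and no quality-aware scoring.
- One intron per unaligned stretch in anchor-and-extend; denser junction
  clusters are only recovered via remapping, so a junction closer than
  8 nt to a read end is invisible by design (overhang rule).
- Exact-match junction confirmation (boundary + strand); no tolerance
  window.
- The self-labeling thresholds are tied to this package's skew/entropy
  definitions (above).
- Genes are single-isoform in the simulator; dev-set negatives therefore
  never contain unannotated-but-functional splice forms.
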