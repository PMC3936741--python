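"""Sequence models for splice-site and intron-length scoring.

The models mirror what an ab initio gene finder would deliver for a compact
genome: position-specific frequency matrices (PSFMs) for the donor and
acceptor sites, a background nucleotide model, and an empirical intron
length distribution.  The donor PSFM spans 3 exonic nt upstream of the
intron plus the first 6 intronic nt (width 9); the acceptor PSFM spans the
last 20 intronic nt plus 1 exonic nt downstream (width 21).  PSFMs may be
zero- or first-order non-uniform Markov chains; splice-site scores are log2
likelihood ratios against the background model.

Parameters can be estimated from labeled introns (e.g. derived from an
annotation, or from simulator truth) and round-tripped through a sectioned
plain-text parameter file.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import NUCS, NUC_TO_CODE, encode, revcomp

logger = logging.getLogger(__name__)

DONOR_EXONIC = 3
DONOR_INTRONIC = 6
DONOR_WIDTH = DONOR_EXONIC + DONOR_INTRONIC          # 9
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 1
ACCEPTOR_WIDTH = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC  # 21
MAX_INTRON_LEN = 10_000

SITE_WIDTHS = {"donor": DONOR_WIDTH, "acceptor": ACCEPTOR_WIDTH}

_PROB_TOL = 1e-9


class ParamFileError(ValueError):
    """Raised when a parameter file is malformed."""


@dataclass
class Psfm:
    """Position-specific frequency matrix around a splice site.

    ``probs`` has shape ``(width, 4, 4)``: ``probs[i, prev, cur]`` is the
    probability of nucleotide ``cur`` at position ``i`` given nucleotide
    ``prev`` at position ``i - 1``.  For position 0, and everywhere in a
    zero-order matrix, rows are constant across ``prev`` so the same array
    shape serves both orders.
    """

    site_type: str
    order: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.site_type not in SITE_WIDTHS:
            raise ValueError(f"unknown site_type {self.site_type!r}")
        if self.order not in (0, 1):
            raise ValueError("PSFM order must be 0 or 1")
        self.probs = np.asarray(self.probs, dtype=float)
        expected = SITE_WIDTHS[self.site_type]
        if self.probs.shape != (expected, 4, 4):
            raise ValueError(
                f"{self.site_type} PSFM must have shape ({expected}, 4, 4), "
                f"got {self.probs.shape}"
            )
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=_PROB_TOL):
            raise ValueError(f"{self.site_type} PSFM rows do not sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError(f"{self.site_type} PSFM contains non-positive entries")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def marginal(self) -> np.ndarray:
        """Per-position marginal nucleotide probabilities, shape (width, 4).

        Computed by propagating the chain from position 0.
        """
        out = np.empty((self.width, 4))
        out[0] = self.probs[0, 0]
        for i in range(1, self.width):
            out[i] = out[i - 1] @ self.probs[i]
        return out

    def log_prob(self, window: str) -> float:
        """log2 probability of a window under the chain; positions holding N
        contribute nothing (they are cancelled against the background by the
        caller)."""
        codes = [NUC_TO_CODE[c] for c in window]
        total = 0.0
        marg = None
        for i, cur in enumerate(codes):
            if cur == 4:
                continue
            if i == 0:
                p = self.probs[0, 0, cur]
            else:
                prev = codes[i - 1]
                if prev == 4:
                    if marg is None:
                        marg = self.marginal()
                    p = marg[i, cur]
                else:
                    p = self.probs[i, prev, cur]
            total += math.log2(p)
        return total

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one window from the chain."""
        out = []
        prev = 0
        for i in range(self.width):
            row = self.probs[i, 0] if i == 0 else self.probs[i, prev]
            cur = rng.choice(4, p=row / row.sum())
            out.append(NUCS[cur])
            prev = cur
        return "".join(out)


@dataclass
class BackgroundModel:
    """Stationary nucleotide composition used as the likelihood-ratio
    denominator (order 0 by default; order 1 keeps per-context rows)."""

    order: int = 0
    probs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.order == 0:
            if self.probs.shape != (4,):
                raise ValueError("order-0 background needs shape (4,)")
        elif self.order == 1:
            if self.probs.shape != (4, 4):
                raise ValueError("order-1 background needs shape (4, 4)")
        else:
            raise ValueError("background order must be 0 or 1")
        if not np.allclose(self.probs.sum(axis=-1), 1.0, atol=_PROB_TOL):
            raise ValueError("background distributions do not sum to 1")

    def stationary(self) -> np.ndarray:
        if self.order == 0:
            return self.probs
        vals, vecs = np.linalg.eig(self.probs.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        return pi / pi.sum()

    def log_prob(self, window: str) -> float:
        """log2 probability of a window; N positions contribute nothing."""
        codes = [NUC_TO_CODE[c] for c in window]
        pi = self.stationary()
        total = 0.0
        for i, cur in enumerate(codes):
            if cur == 4:
                continue
            if self.order == 1 and i > 0 and codes[i - 1] != 4:
                p = self.probs[codes[i - 1], cur]
            else:
                p = pi[cur]
            total += math.log2(p)
        return total


@dataclass
class IntronLengthDist:
    """Binned empirical pmf over intron lengths (nt).

    Bins of ``bin_width`` cover ``[min_len, max_len)``; lengths outside the
    support score ``pseudo_mass``.
    """

    min_len: int
    max_len: int
    bin_width: int
    pmf: np.ndarray
    pseudo_mass: float = 1e-6

    def __post_init__(self) -> None:
        if self.max_len > MAX_INTRON_LEN:
            raise ValueError(f"max_len must be <= {MAX_INTRON_LEN}")
        if self.min_len < 1 or self.min_len >= self.max_len:
            raise ValueError("need 1 <= min_len < max_len")
        self.pmf = np.asarray(self.pmf, dtype=float)
        n_bins = -(-(self.max_len - self.min_len) // self.bin_width)
        if self.pmf.shape != (n_bins,):
            raise ValueError(f"pmf must have {n_bins} bins, got {self.pmf.shape}")
        if abs(self.pmf.sum() - 1.0) > 1e-6:
            raise ValueError("intron length pmf does not sum to 1")

    def bin_index(self, length: int) -> int:
        return (length - self.min_len) // self.bin_width

    @classmethod
    def from_lengths(
        cls,
        lengths: Sequence[int],
        bin_width: int = 10,
        pseudo_mass: float = 1e-6,
    ) -> "IntronLengthDist":
        lengths = np.asarray(lengths, dtype=int)
        if lengths.size == 0:
            raise ValueError("no intron lengths supplied")
        lo = int(lengths.min())
        hi = int(lengths.max()) + 1
        hi = min(hi, MAX_INTRON_LEN)
        n_bins = -(-(hi - lo) // bin_width)
        counts = np.zeros(n_bins)
        for l in lengths:
            counts[min((l - lo) // bin_width, n_bins - 1)] += 1
        return cls(lo, hi, bin_width, counts / counts.sum(), pseudo_mass)


@dataclass
class SpliceModels:
    """Bundle of all sequence models the pipeline scores with."""

    donor: Psfm
    acceptor: Psfm
    background: BackgroundModel
    intron_lengths: IntronLengthDist


# ---------------------------------------------------------------------------
# window extraction

def donor_window(seq: str, start: int, end: int, strand: str) -> str | None:
    """Donor-site window (3 exonic + 6 intronic nt) of the intron occupying
    the genomic interval [start, end) on ``strand``; None if it would run off
    the contig."""
    if strand == "+":
        lo, hi = start - DONOR_EXONIC, start + DONOR_INTRONIC
        if lo < 0 or hi > len(seq):
            return None
        return seq[lo:hi]
    lo, hi = end - DONOR_INTRONIC, end + DONOR_EXONIC
    if lo < 0 or hi > len(seq):
        return None
    return revcomp(seq[lo:hi])


def acceptor_window(seq: str, start: int, end: int, strand: str) -> str | None:
    """Acceptor-site window (20 intronic + 1 exonic nt)."""
    if strand == "+":
        lo, hi = end - ACCEPTOR_INTRONIC, end + ACCEPTOR_EXONIC
        if lo < 0 or hi > len(seq):
            return None
        return seq[lo:hi]
    lo, hi = start - ACCEPTOR_EXONIC, start + ACCEPTOR_INTRONIC
    if lo < 0 or hi > len(seq):
        return None
    return revcomp(seq[lo:hi])


# ---------------------------------------------------------------------------
# estimation

def _estimate_psfm(
    windows: Iterable[str], site_type: str, order: int, pseudocount: float
) -> Psfm:
    width = SITE_WIDTHS[site_type]
    counts = np.full((width, 4, 4), pseudocount, dtype=float)
    n = 0
    for w in windows:
        codes = [NUC_TO_CODE.get(c, 4) for c in w]
        if any(c == 4 for c in codes):
            continue
        n += 1
        counts[0, :, codes[0]] += 1.0
        for i in range(1, width):
            if order == 0:
                counts[i, :, codes[i]] += 1.0
            else:
                counts[i, codes[i - 1], codes[i]] += 1.0
    if n == 0:
        raise ValueError(f"no usable {site_type} windows")
    probs = counts / counts.sum(axis=2, keepdims=True)
    return Psfm(site_type, order, probs)


def estimate_models(
    introns: Sequence[tuple[str, int, int, str]],
    genome: Mapping[str, str],
    pseudocount: float = 0.5,
    order: int = 1,
    background_order: int = 0,
    bin_width: int = 10,
    pseudo_mass: float = 1e-6,
    min_introns: int = 50,
) -> SpliceModels:
    """Estimate all sequence models from labeled introns.

    ``introns`` are ``(seq_id, start, end, strand)`` with 0-based, half-open
    genomic intervals; ``start`` is the first intronic base on the forward
    strand and ``end`` one past the last.  Records whose site windows fall
    outside their contig are skipped with a warning.
    """
    if len(introns) < min_introns:
        raise ValueError(
            f"too few introns for model estimation: got {len(introns)}, "
            f"need >= {min_introns}"
        )
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    donors: list[str] = []
    acceptors: list[str] = []
    lengths: list[int] = []
    skipped = 0
    for seq_id, start, end, strand in introns:
        seq = genome[seq_id]
        dw = donor_window(seq, start, end, strand)
        aw = acceptor_window(seq, start, end, strand)
        if dw is None or aw is None:
            skipped += 1
            continue
        donors.append(dw)
        acceptors.append(aw)
        lengths.append(end - start)
    if skipped:
        logger.warning("skipped %d introns with out-of-bounds windows", skipped)
    donor = _estimate_psfm(donors, "donor", order, pseudocount)
    acceptor = _estimate_psfm(acceptors, "acceptor", order, pseudocount)
    background = estimate_background(genome, order=background_order)
    dist = IntronLengthDist.from_lengths(lengths, bin_width, pseudo_mass)
    return SpliceModels(donor, acceptor, background, dist)


def estimate_background(genome: Mapping[str, str], order: int = 0) -> BackgroundModel:
    """Background nucleotide model from whole-genome composition."""
    if order == 0:
        counts = np.full(4, 1.0)
        for seq in genome.values():
            codes = encode(seq)
            counts += np.bincount(codes[codes < 4], minlength=4)
        return BackgroundModel(0, counts / counts.sum())
    counts = np.full((4, 4), 1.0)
    for seq in genome.values():
        codes = encode(seq)
        prev, cur = codes[:-1], codes[1:]
        ok = (prev < 4) & (cur < 4)
        np.add.at(counts, (prev[ok], cur[ok]), 1.0)
    return BackgroundModel(1, counts / counts.sum(axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# scoring

def score_splice_site(window: str, site_type: str, models: SpliceModels) -> float:
    """log2 likelihood ratio (bits) of a site window: PSFM vs background.

    Positions holding N contribute the background probability in both the
    numerator and the denominator and therefore cancel.
    """
    psfm = models.donor if site_type == "donor" else models.acceptor
    width = SITE_WIDTHS[site_type]
    if len(window) != width:
        raise ValueError(
            f"{site_type} window must be {width} nt, got {len(window)}"
        )
    window = window.upper()
    return psfm.log_prob(window) - models.background.log_prob(window)


def intron_length_loglik(length: int, dist: IntronLengthDist) -> float:
    """log2 probability mass of the length's bin; out-of-support lengths get
    log2(pseudo_mass)."""
    if length <= 0:
        raise ValueError("intron length must be >= 1")
    if length < dist.min_len or length >= dist.max_len:
        return math.log2(dist.pseudo_mass)
    mass = dist.pmf[dist.bin_index(length)]
    if mass <= 0:
        return math.log2(dist.pseudo_mass)
    return math.log2(mass)


# ---------------------------------------------------------------------------
# parameter file I/O
#
# Sectioned plain text: [donor] / [acceptor] hold "order" and one
# tab-separated row per (position, previous-nucleotide context);
# [background] one row per context; [intron_lengths] holds the support line
# followed by one probability per bin.  Probabilities are written with 17
# significant digits so that save -> load is an exact round trip.

_FMT = "%.17g"


def save_params(models: SpliceModels, path) -> None:
    lines: list[str] = []
    for name, psfm in (("donor", models.donor), ("acceptor", models.acceptor)):
        lines.append(f"[{name}]")
        lines.append(f"order\t{psfm.order}")
        lines.append(f"width\t{psfm.width}")
        for i in range(psfm.width):
            for prev in range(4):
                row = "\t".join(_FMT % p for p in psfm.probs[i, prev])
                lines.append(f"{i}\t{NUCS[prev]}\t{row}")
    lines.append("[background]")
    lines.append(f"order\t{models.background.order}")
    if models.background.order == 0:
        lines.append("\t".join(_FMT % p for p in models.background.probs))
    else:
        for prev in range(4):
            lines.append(
                NUCS[prev] + "\t"
                + "\t".join(_FMT % p for p in models.background.probs[prev])
            )
    d = models.intron_lengths
    lines.append("[intron_lengths]")
    lines.append(
        f"support\t{d.min_len}\t{d.max_len}\t{d.bin_width}\t" + _FMT % d.pseudo_mass
    )
    for p in d.pmf:
        lines.append(_FMT % p)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _split_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = []
        elif current is None:
            raise ParamFileError(f"content before first section: {line!r}")
        else:
            sections[current].append(line)
    return sections


def _parse_psfm(name: str, body: list[str]) -> Psfm:
    header = dict(l.split("\t", 1) for l in body[:2])
    try:
        order = int(header["order"])
        width = int(header["width"])
    except (KeyError, ValueError) as exc:
        raise ParamFileError(f"bad {name} header") from exc
    rows = body[2:]
    if len(rows) != width * 4:
        raise ParamFileError(
            f"{name} section has {len(rows)} rows, expected {width * 4}"
        )
    probs = np.empty((width, 4, 4))
    for line in rows:
        parts = line.split("\t")
        if len(parts) != 6:
            raise ParamFileError(f"malformed {name} row: {line!r}")
        i = int(parts[0])
        prev = NUC_TO_CODE[parts[1]]
        vals = np.array([float(x) for x in parts[2:]])
        if abs(vals.sum() - 1.0) > 1e-6:
            raise ParamFileError(
                f"{name} row at position {i} (context {parts[1]}) sums to "
                f"{vals.sum():.6f}, not 1"
            )
        probs[i, prev] = vals
    return Psfm(name, order, probs)


def load_params(path) -> SpliceModels:
    with open(path) as fh:
        sections = _split_sections(fh.read())
    for required in ("donor", "acceptor", "background", "intron_lengths"):
        if required not in sections:
            raise ParamFileError(f"missing section: {required}")
    donor = _parse_psfm("donor", sections["donor"])
    acceptor = _parse_psfm("acceptor", sections["acceptor"])

    bg_body = sections["background"]
    bg_order = int(bg_body[0].split("\t")[1])
    if bg_order == 0:
        probs = np.array([float(x) for x in bg_body[1].split("\t")])
        background = BackgroundModel(0, probs)
    else:
        probs = np.empty((4, 4))
        for line in bg_body[1:]:
            parts = line.split("\t")
            probs[NUC_TO_CODE[parts[0]]] = [float(x) for x in parts[1:]]
        background = BackgroundModel(1, probs)

    il_body = sections["intron_lengths"]
    sup = il_body[0].split("\t")
    if sup[0] != "support":
        raise ParamFileError("intron_lengths section missing support line")
    min_len, max_len, bin_width = int(sup[1]), int(sup[2]), int(sup[3])
    pseudo_mass = float(sup[4])
    pmf = np.array([float(l) for l in il_body[1:]])
    dist = IntronLengthDist(min_len, max_len, bin_width, pmf, pseudo_mass)
    return SpliceModels(donor, acceptor, background, dist)
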