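"""Sequence-model estimation, scoring and serialization."""
import math

import numpy as np
import pytest

from splicescope._seq import revcomp
from splicescope.models import (
    ACCEPTOR_WIDTH,
    DONOR_WIDTH,
    BackgroundModel,
    IntronLengthDist,
    ParamFileError,
    Psfm,
    SpliceModels,
    estimate_models,
    intron_length_loglik,
    load_params,
    save_params,
    score_splice_site,
)
from splicescope.simulate import default_generating_psfms


def _uniform_background():
    return BackgroundModel(0, np.full(4, 0.25))


def _uniform_dist():
    # uniform over [60, 160) in 10 nt bins
    return IntronLengthDist(60, 160, 10, np.full(10, 0.1))


def _cassette_genome(windows_donor, windows_acceptor, intron_len=80, seed=0):
    """Concatenate one cassette per intron: pad + 3 exonic | intron | 1
    exonic + pad, with the supplied site windows written in."""
    rng = np.random.default_rng(seed)
    nucs = "ACGT"
    parts, introns = [], []
    pos = 0
    for dw, aw in zip(windows_donor, windows_acceptor):
        pad = "".join(nucs[i] for i in rng.integers(0, 4, size=12))
        filler = "".join(
            nucs[i] for i in rng.integers(0, 4, size=intron_len - 6 - 20)
        )
        cassette = pad + dw + filler + aw + pad
        start = pos + len(pad) + 3          # first intronic base
        end = start + intron_len
        parts.append(cassette)
        introns.append(("chr1", start, end, "+"))
        pos += len(cassette)
    return {"chr1": "".join(parts)}, introns


class TestEstimation:
    def test_degenerate_input_concentrates_mass(self):
        """Identical donor windows with a vanishing pseudocount put all the
        probability on the observed letters."""
        dw = "ACGGTAAGT"
        aw = "T" * 18 + "AGG"
        genome, introns = _cassette_genome([dw] * 1000, [aw] * 1000)
        models = estimate_models(introns, genome, pseudocount=1e-9, order=0)
        marg = models.donor.marginal()
        for i, ch in enumerate(dw):
            assert marg[i, "ACGT".index(ch)] == pytest.approx(1.0, abs=1e-5)

    def test_recovers_generating_matrix(self):
        """PSFMs re-estimated from windows drawn from a known generating
        matrix agree with it within +-0.05 per (position, letter)."""
        donor_psfm, acceptor_psfm = default_generating_psfms()
        rng = np.random.default_rng(11)
        n = 5_000
        dws = [donor_psfm.sample(rng) for _ in range(n)]
        aws = [acceptor_psfm.sample(rng) for _ in range(n)]
        genome, introns = _cassette_genome(dws, aws, seed=1)
        models = estimate_models(introns, genome, order=0)
        for est, gen in ((models.donor, donor_psfm),
                         (models.acceptor, acceptor_psfm)):
            err = np.abs(est.marginal() - gen.marginal()).max()
            assert err <= 0.05

    def test_estimation_error_shrinks_with_sample_size(self):
        """Max-abs estimation error at 20k introns is no larger than at 1k
        (consistency under a fixed seed schedule)."""
        donor_psfm, _ = default_generating_psfms()
        errs = []
        for n, seed in ((1_000, 5), (20_000, 5)):
            rng = np.random.default_rng(seed)
            dws = [donor_psfm.sample(rng) for _ in range(n)]
            aws = ["T" * 18 + "AGG"] * n
            genome, introns = _cassette_genome(dws, aws, seed=2)
            models = estimate_models(introns, genome, order=0)
            errs.append(np.abs(models.donor.marginal() - donor_psfm.marginal()).max())
        assert errs[1] <= errs[0]

    def test_too_few_introns_refused_with_count(self):
        genome, introns = _cassette_genome(["ACGGTAAGT"] * 10,
                                           ["T" * 18 + "AGG"] * 10)
        with pytest.raises(ValueError, match="too few introns.*10"):
            estimate_models(introns, genome)


class TestScoring:
    def test_consensus_window_scores_width_times_two_bits(self):
        """A deterministic order-0 PSFM against a uniform background gives
        log2(4) bits per position: 18 bits over the 9 nt donor window."""
        eps = 1e-12
        probs = np.full((DONOR_WIDTH, 4, 4), eps)
        consensus = "ACGGTAAGT"
        for i, ch in enumerate(consensus):
            probs[i, :, :] = eps
            probs[i, :, "ACGT".index(ch)] = 1 - 3 * eps
        psfm = Psfm("donor", 0, probs)
        models = SpliceModels(psfm, default_generating_psfms()[1],
                              _uniform_background(), _uniform_dist())
        score = score_splice_site(consensus, "donor", models)
        assert score == pytest.approx(9 * math.log2(4), abs=1e-9)

    def test_background_equal_psfm_scores_zero(self):
        probs = np.full((DONOR_WIDTH, 4, 4), 0.25)
        psfm = Psfm("donor", 0, probs)
        models = SpliceModels(psfm, default_generating_psfms()[1],
                              _uniform_background(), _uniform_dist())
        assert score_splice_site("ACGTACGTA", "donor", models) == pytest.approx(0.0)

    def test_matches_chained_probability_product(self):
        """Scores equal an independently computed log-ratio of chained
        conditional probabilities on 1 000 random first-order windows."""
        rng = np.random.default_rng(7)
        probs = rng.dirichlet(np.ones(4), size=(ACCEPTOR_WIDTH, 4))
        psfm = Psfm("acceptor", 1, probs)
        bg = BackgroundModel(0, rng.dirichlet(np.ones(4)))
        models = SpliceModels(default_generating_psfms()[0], psfm, bg,
                              _uniform_dist())
        for _ in range(1000):
            codes = rng.integers(0, 4, size=ACCEPTOR_WIDTH)
            window = "".join("ACGT"[c] for c in codes)
            expected = math.log2(probs[0, 0, codes[0]])
            for i in range(1, ACCEPTOR_WIDTH):
                expected += math.log2(probs[i, codes[i - 1], codes[i]])
            expected -= sum(math.log2(bg.probs[c]) for c in codes)
            got = score_splice_site(window, "acceptor", models)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_window_with_n_cancels_against_background(self):
        donor_psfm, acceptor_psfm = default_generating_psfms()
        models = SpliceModels(donor_psfm, acceptor_psfm,
                              _uniform_background(), _uniform_dist())
        full = score_splice_site("ACGGTAAGT", "donor", models)
        with_n = score_splice_site("NCGGTAAGT", "donor", models)
        # dropping the first position removes exactly its contribution
        expected = full - (math.log2(donor_psfm.probs[0, 0, 0]) - math.log2(0.25))
        assert with_n == pytest.approx(expected, abs=1e-9)

    def test_wrong_width_names_expected_width(self):
        donor_psfm, acceptor_psfm = default_generating_psfms()
        models = SpliceModels(donor_psfm, acceptor_psfm,
                              _uniform_background(), _uniform_dist())
        with pytest.raises(ValueError, match="9"):
            score_splice_site("ACGT", "donor", models)

    def test_strand_symmetric_window_extraction(self):
        """A minus-strand intron scores identically to the same intron read
        on the plus strand of the reverse-complemented genome."""
        from splicescope.models import acceptor_window, donor_window

        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
        s, e = 100, 180
        rc = revcomp(seq)
        s2, e2 = len(seq) - e, len(seq) - s
        assert donor_window(seq, s, e, "-") == donor_window(rc, s2, e2, "+")
        assert acceptor_window(seq, s, e, "-") == acceptor_window(rc, s2, e2, "+")


class TestIntronLengthDist:
    def test_uniform_bins_score_log_point_one(self):
        dist = _uniform_dist()
        for length in (60, 75, 99, 159):
            assert intron_length_loglik(length, dist) == pytest.approx(math.log2(0.1))

    def test_out_of_support_gets_pseudo_mass(self):
        dist = IntronLengthDist(60, 10_000, 10, np.full(994, 1 / 994), 1e-6)
        assert intron_length_loglik(9_999, dist) != math.log2(1e-6)
        # beyond the support (including the 10 kb cap) -> pseudo mass
        assert intron_length_loglik(12_000, dist) == pytest.approx(math.log2(1e-6))
        assert intron_length_loglik(12, dist) == pytest.approx(math.log2(1e-6))

    def test_modal_bin_scores_highest(self):
        rng = np.random.default_rng(0)
        lengths = np.clip(rng.lognormal(math.log(90), 0.3, size=5000), 55, 400)
        dist = IntronLengthDist.from_lengths(lengths.astype(int))
        scores = {l: intron_length_loglik(l, dist)
                  for l in range(dist.min_len, dist.max_len)}
        modal_bin = int(np.argmax(dist.pmf))
        modal_len = dist.min_len + modal_bin * dist.bin_width
        assert scores[modal_len] >= max(scores.values()) - 1e-12

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            intron_length_loglik(0, _uniform_dist())


class TestParamFile:
    def _models(self):
        donor_psfm, acceptor_psfm = default_generating_psfms()
        return SpliceModels(donor_psfm, acceptor_psfm,
                            BackgroundModel(0, np.array([0.3, 0.2, 0.2, 0.3])),
                            _uniform_dist())

    def test_round_trip_is_lossless(self, tmp_path):
        models = self._models()
        path = tmp_path / "m.params"
        save_params(models, path)
        loaded = load_params(path)
        np.testing.assert_array_equal(loaded.donor.probs, models.donor.probs)
        np.testing.assert_array_equal(loaded.acceptor.probs, models.acceptor.probs)
        np.testing.assert_array_equal(loaded.background.probs,
                                      models.background.probs)
        np.testing.assert_array_equal(loaded.intron_lengths.pmf,
                                      models.intron_lengths.pmf)
        assert loaded.intron_lengths.min_len == models.intron_lengths.min_len
        assert loaded.donor.order == models.donor.order

    def test_missing_section_named(self, tmp_path):
        path = tmp_path / "m.params"
        save_params(self._models(), path)
        text = path.read_text()
        broken = text[: text.index("[acceptor]")] + text[text.index("[background]"):]
        path.write_text(broken)
        with pytest.raises(ParamFileError, match="acceptor"):
            load_params(path)

    def test_bad_row_sum_reports_position(self, tmp_path):
        path = tmp_path / "m.params"
        save_params(self._models(), path)
        lines = path.read_text().splitlines()
        # corrupt the first donor probability row (position 0, context A)
        idx = next(i for i, l in enumerate(lines) if l.startswith("0\tA\t"))
        parts = lines[idx].split("\t")
        parts[2] = "0.0001"
        lines[idx] = "\t".join(parts)
        path.write_text("\n".join(lines))
        with pytest.raises(ParamFileError, match="position 0"):
            load_params(path)
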