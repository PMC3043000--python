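"""Sequence models: scanning matrix, occupancies, autocorrelation, and the
tandem E1-E2 segment HMM."""

import itertools

import numpy as np
import pytest

from circabind import motif, synth
from circabind.motif import TandemHMM, TandemHMMConfig, WeightedSequence
from conftest import make_corpus, make_window


class TestScanPswm:
    def test_consensus_probabilities(self):
        pswm = motif.build_scan_pswm()
        col = pswm.probabilities[0]
        assert col[motif._BASE_INDEX["C"]] == pytest.approx(0.96875)
        # non-consensus bases share the remaining mass equally
        assert col[motif._BASE_INDEX["A"]] == pytest.approx((1 - 0.96875) / 3)
        assert col[motif._BASE_INDEX["A"]] == col[motif._BASE_INDEX["G"]]
        assert np.allclose(pswm.probabilities.sum(axis=1), 1.0)

    def test_consensus_dominates_one_mismatch_words(self):
        pswm = motif.build_scan_pswm()
        best = pswm.log_odds("CACGTG")[0]
        for i in range(6):
            for b in "ACGT":
                word = "CACGTG"[:i] + b + "CACGTG"[i + 1 :]
                if word == "CACGTG":
                    continue
                assert pswm.log_odds(word)[0] < best


class TestScanOccupancy:
    pswm = motif.build_scan_pswm()

    def test_consensus_above_half(self):
        occ = motif.scan_occupancy("CACGTG", self.pswm)
        assert occ[0] > 0.5

    def test_two_mismatches_below_half(self):
        occ = motif.scan_occupancy("CATGTA", self.pswm)
        assert occ[0] < 0.5

    def test_one_mismatch_at_midpoint(self):
        occ = motif.scan_occupancy("AACGTG", self.pswm)
        assert occ[0] == pytest.approx(0.5, abs=1e-9)

    def test_short_sequence_empty(self):
        assert motif.scan_occupancy("CAC", self.pswm).size == 0

    def test_values_in_unit_interval(self):
        occ = motif.scan_occupancy(synth.generate_genome(500, rng=1), self.pswm)
        assert ((occ > 0) & (occ < 1)).all()


class TestOccupancyAutocorrelation:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(2)
        profiles = [rng.random(80) for _ in range(5)]
        acf, lo, hi = motif.occupancy_autocorrelation(profiles, 20, n_perm=50, rng=rng)
        assert acf[0] == pytest.approx(1.0)

    def test_planted_tandem_lag_exceeds_null_band(self):
        # motif pairs start-to-start 13 apart (6-mer + 7-bp gap)
        rng = np.random.default_rng(3)
        pswm = motif.build_scan_pswm()
        profiles = []
        for _ in range(40):
            seq = list(synth.generate_genome(101, rng=rng))
            seq[30:36] = "CACGTG"
            seq[43:49] = "CACGTG"
            profiles.append(motif.scan_occupancy("".join(seq), pswm))
        acf, lo, hi = motif.occupancy_autocorrelation(profiles, 20, n_perm=300, rng=rng)
        assert acf[13] > hi[13]

    def test_null_band_pointwise_coverage(self):
        # the band is a pointwise 95% interval: on random sequences about 5%
        # of positive lags fall outside it
        rng = np.random.default_rng(4)
        pswm = motif.build_scan_pswm()
        outside = total = 0
        for _ in range(10):
            profiles = [
                motif.scan_occupancy(synth.generate_genome(101, rng=rng), pswm)
                for _ in range(30)
            ]
            acf, lo, hi = motif.occupancy_autocorrelation(
                profiles, 20, n_perm=300, rng=rng
            )
            outside += int(((acf[1:] < lo[1:]) | (acf[1:] > hi[1:])).sum())
            total += 20
        assert outside / total <= 0.12

    def test_max_lag_validation(self):
        with pytest.raises(ValueError):
            motif.occupancy_autocorrelation([np.ones(10)], 10)


def mini_config():
    """Miniature model for exhaustive path enumeration: 1+2 blocks,
    spacers 1-2, filter length 2."""
    return TandemHMMConfig(
        flank_len=1, core_len=2, filter_len=2, spacer_min=1, spacer_max=2
    )


def enumerate_loglik(hmm: TandemHMM, seq: str) -> float:
    """Independent oracle: sum over all segmentations by brute force."""
    cfg = hmm.config
    s = motif.encode(seq)
    lp = hmm._log_params()
    N = s.size
    BL, LM = cfg.block_len, cfg.filter_len

    def emit(log_em, start, L):
        return sum(log_em[k][s[start + k]] for k in range(L))

    total = []

    def recurse(i, acc):
        if i == N:
            total.append(acc)
            return
        recurse(i + 1, acc + lp["lpB"] + lp["lbg"][s[i]])
        if i + LM <= N:
            recurse(i + LM, acc + lp["lpM"] + emit(lp["lfl"], i, LM))
        if i + BL <= N:
            recurse(i + BL, acc + lp["lpS"] + emit(lp["le1"], i, BL))
        for di, d in enumerate(cfg.spacers):
            end = i + 2 * BL + d
            if end <= N:
                acc2 = (
                    acc
                    + lp["lpT"]
                    + lp["lpi"][di]
                    + emit(lp["le1"], i, BL)
                    + sum(lp["lbg"][s[i + BL + k]] for k in range(d))
                    + emit(lp["le2"], i + BL + d, BL)
                )
                recurse(end, acc2)

    recurse(0, 0.0)
    from scipy.special import logsumexp

    return float(logsumexp(np.array(total)))


class TestTandemHMMForward:
    def test_forward_matches_path_enumeration(self):
        hmm = TandemHMM(mini_config())
        rng = np.random.default_rng(5)
        for n in (4, 7, 10, 12):
            seq = "".join(rng.choice(list("ACGT"), n))
            assert hmm.forward_loglik(seq) == pytest.approx(
                enumerate_loglik(hmm, seq), rel=1e-10
            )

    def test_forward_matches_enumeration_after_training(self):
        rng = np.random.default_rng(6)
        seqs = [
            WeightedSequence("".join(rng.choice(list("ACGT"), 12)), 1.0)
            for _ in range(12)
        ]
        hmm = TandemHMM(mini_config())
        hmm.config.max_iter = 5
        hmm.fit(seqs)
        seq = "CAACGTGTGACA"
        assert hmm.forward_loglik(seq) == pytest.approx(
            enumerate_loglik(hmm, seq), rel=1e-10
        )


class TestTraining:
    def test_loglik_monotone(self, trained_hmm):
        hmm, _ = trained_hmm
        trace = np.array(hmm.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_equal_weights_match_unweighted_fixpoint(self):
        rng = np.random.default_rng(7)
        seqs = [make_window(rng, "E1E2") for _ in range(20)]
        cfg = TandemHMMConfig(max_iter=3)
        h1 = TandemHMM(cfg)
        h1.fit([WeightedSequence(s, 1.0) for s in seqs])
        h2 = TandemHMM(TandemHMMConfig(max_iter=3))
        h2.fit([WeightedSequence(s, 2.5) for s in seqs])
        # uniform rescaling of all weights leaves the EM trajectory unchanged
        assert np.allclose(h1.em_e1, h2.em_e1)
        assert np.allclose(h1.spacer_probs, h2.spacer_probs)

    def test_weights_matter(self):
        rng = np.random.default_rng(8)
        tandem = [make_window(rng, "E1E2", spacer=6) for _ in range(10)]
        none = [make_window(rng, "NONE") for _ in range(10)]
        up = [WeightedSequence(s, 10.0) for s in tandem] + [
            WeightedSequence(s, 0.1) for s in none
        ]
        down = [WeightedSequence(s, 0.1) for s in tandem] + [
            WeightedSequence(s, 10.0) for s in none
        ]
        cfg = TandemHMMConfig(max_iter=8)
        h_up = TandemHMM(cfg).fit(up)
        h_down = TandemHMM(TandemHMMConfig(max_iter=8)).fit(down)
        assert h_up.p_tandem > h_down.p_tandem

    def test_planted_spacer_mode_recovered(self, trained_hmm):
        hmm, corpus = trained_hmm
        spacers = [
            motif.classify_site(hmm, w.sequence).spacer
            for cls, w in corpus
            if cls == "E1E2"
        ]
        spacers = [s for s in spacers if s is not None]
        vals, counts = np.unique(spacers, return_counts=True)
        assert vals[np.argmax(counts)] == 7

    def test_spacer_mode_across_lengths(self):
        # modal decoded spacer equals the planted value for 6, 7 and 8 bp
        for planted in (6, 7, 8):
            rng = np.random.default_rng(100 + planted)
            corpus = make_corpus(rng, 70, frac_tandem=0.6, frac_single=0.2, spacer=planted)
            hmm = motif.train_tandem_hmm(
                [w for _, w in corpus], TandemHMMConfig(max_iter=15)
            )
            spacers = [
                motif.classify_site(hmm, w.sequence).spacer
                for cls, w in corpus
                if cls == "E1E2"
            ]
            spacers = [s for s in spacers if s is not None]
            vals, counts = np.unique(spacers, return_counts=True)
            assert vals[np.argmax(counts)] == planted

    def test_training_preconditions(self):
        with pytest.raises(ValueError):
            motif.train_tandem_hmm([WeightedSequence("ACGT" * 20, 1.0)] * 5)
        with pytest.raises(ValueError):
            motif.train_tandem_hmm([WeightedSequence("ACGT" * 20, 0.0)] * 12)


class TestClassification:
    def test_background_sequence_is_none(self, trained_hmm):
        hmm, _ = trained_hmm
        # poly-CT sequence: nothing within 3 mismatches of CACGTG
        seq = "CT" * 50 + "C"
        assert motif.classify_site(hmm, seq).site_class == "NONE"

    def test_sp7_probe_is_tandem_with_spacer_7(self, trained_hmm):
        hmm, _ = trained_hmm
        rng = np.random.default_rng(9)
        seq = make_window(rng, "E1E2", spacer=7)
        call = motif.classify_site(hmm, seq)
        assert call.site_class == "E1E2"
        assert call.spacer == 7
        assert abs(call.offset) <= 5

    def test_single_embedded_box_is_e1(self, trained_hmm):
        hmm, _ = trained_hmm
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(10):
            seq = make_window(rng, "E1")
            hits += motif.classify_site(hmm, seq).site_class == "E1"
        assert hits >= 8

    def test_strand_symmetry(self, trained_hmm):
        hmm, _ = trained_hmm
        rng = np.random.default_rng(11)
        for cls in ("NONE", "E1", "E1E2"):
            seq = make_window(rng, cls)
            rc = "".join("ACGTN"[b] for b in motif.revcomp(motif.encode(seq)))
            c1, c2 = motif.classify_site(hmm, seq), motif.classify_site(hmm, rc)
            assert c1.site_class == c2.site_class
            assert c1.score == pytest.approx(c2.score, abs=1e-9)
            assert c1.spacer == c2.spacer

    def test_untrained_model_rejected(self):
        with pytest.raises(ValueError):
            motif.classify_site(TandemHMM(), "ACGT" * 30)


class TestSpacedMatrices:
    def test_layout_and_normalization(self, trained_hmm):
        hmm, _ = trained_hmm
        mats = motif.extract_spaced_matrices(hmm, (6, 7))
        for s, m in mats.items():
            assert len(m) == 13 + s + 13
            assert np.allclose(m.probabilities.sum(axis=1), 1.0)

    def test_scan_locates_planted_element_at_center(self, trained_hmm):
        hmm, _ = trained_hmm
        rng = np.random.default_rng(12)
        mats = motif.extract_spaced_matrices(hmm, (7,))
        hits = 0
        for _ in range(10):
            seq = make_window(rng, "E1E2", spacer=7, length=501)
            scores, offsets = motif.scan_spaced_matrix(mats[7], seq)
            best = offsets[np.argmax(scores)]
            hits += abs(best) <= 5
        assert hits >= 9

    def test_unsupported_spacer_rejected(self, trained_hmm):
        hmm, _ = trained_hmm
        with pytest.raises(ValueError):
            motif.extract_spaced_matrices(hmm, (25,))


class TestEnrichmentVsControl:
    def test_motifs_only_at_sites(self, trained_hmm):
        hmm, _ = trained_hmm
        rng = np.random.default_rng(13)
        mats = motif.extract_spaced_matrices(hmm, (7,))
        sites = [make_window(rng, "E1E2", spacer=7) for _ in range(30)]
        controls = [make_window(rng, "NONE") for _ in range(30)]
        sc, cc, t, p = motif.e1e2_enrichment_vs_control(
            sites, controls, mats, threshold_bits=8.0
        )
        assert cc.sum() == 0
        assert t > 0 and p < 1e-4

    def test_identical_sequences_no_difference(self, trained_hmm):
        hmm, _ = trained_hmm
        rng = np.random.default_rng(14)
        mats = motif.extract_spaced_matrices(hmm, (7,))
        seqs = [make_window(rng, "E1E2") for _ in range(10)]
        sc, cc, t, p = motif.e1e2_enrichment_vs_control(seqs, seqs, mats)
        assert (sc == cc).all() and t == 0.0 and p == 1.0
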