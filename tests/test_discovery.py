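"""Region detection, strand-kernel estimation, deconvolution and site calls."""

import numpy as np
import pandas as pd
import pytest

from circabind import discovery, synth, tags
from circabind.discovery import CandidateRegion, StrandKernel


def make_track(rows):
    return tags.normalize_and_merge(pd.DataFrame(rows, columns=tags.TAG_COLUMNS))


def background_rows(rng, n, length=50_000, library="A", timepoint=2.0):
    return [
        ("c1", int(rng.integers(0, length)), rng.choice(["+", "-"]), library, timepoint)
        for _ in range(n)
    ]


class TestDetectRegions:
    def test_null_data_yields_no_regions(self):
        rng = np.random.default_rng(0)
        chip = make_track(background_rows(rng, 3000))
        inp = make_track(background_rows(rng, 3000))
        regions = discovery.detect_regions(chip, inp, alpha=0.01)
        assert len(regions) == 0

    def test_single_planted_site_yields_one_region(self, small_sim, small_regions):
        truth = small_sim["truth"]
        # every planted site is inside exactly one detected region
        for s in truth.sites:
            hits = [
                r for r in small_regions if r.start <= s.center < r.end
            ]
            assert len(hits) == 1

    def test_overlapping_windows_merged(self, small_regions):
        starts = sorted((r.start, r.end) for r in small_regions)
        for (s1, e1), (s2, e2) in zip(starts, starts[1:]):
            assert s2 >= e1  # merged output is non-overlapping

    def test_zero_input_falls_back(self):
        rng = np.random.default_rng(1)
        spec = synth.SiteSpec("E1", 25_000, 500.0, 6.0, 0.0)
        _, truth = synth.plant_sites("A" * 50_000, [spec], background_rate=1e-4)
        chip_df, _ = synth.simulate_chip_tags(truth, 5000, rng)
        chip = make_track(chip_df.values.tolist())
        empty_like = make_track(background_rows(rng, 1, length=10))
        # input with (essentially) no genome coverage still detects the site
        regions = discovery.detect_regions(chip, empty_like)
        assert any(r.start <= 25_003 <= r.end for r in regions)


class TestEstimateKernel:
    def test_recovers_mean_offset(self, small_sim, small_regions):
        kernel = discovery.estimate_kernel(small_sim["chip_track"], small_regions)
        assert 90.0 <= kernel.mean_offset <= 110.0
        assert kernel.density_plus.sum() == pytest.approx(1.0)
        # mirror symmetry
        assert np.allclose(kernel.density_minus, kernel.density_plus[::-1])

    def test_identical_strand_profiles_give_zero_offset(self):
        rows = []
        for strand in "+-":
            for p in (1000, 1010, 1020, 1030):
                rows += [("c1", p, strand, "A", 2.0)] * 5
        track = make_track(rows)
        region = CandidateRegion("c1", 900, 1100, 40.0, 0.0, 10.0)
        kernel = discovery.estimate_kernel(track, [region], min_strand_tags=1)
        assert abs(kernel.mean_offset) <= 2.0

    def test_single_strand_regions_error(self):
        rows = [("c1", 1000 + i, "+", "A", 2.0) for i in range(20)]
        track = make_track(rows)
        region = CandidateRegion("c1", 900, 1100, 20.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            discovery.estimate_kernel(track, [region], min_strand_tags=1)


def simulate_region(rng, centers, n_tags_each, mu=100.0, sd=25.0, length=2000):
    """Strand-kernel tags around the given source centers; returns track+region."""
    rows = []
    for c, n in zip(centers, n_tags_each):
        offs = np.abs(rng.normal(mu, sd, n))
        plus = rng.random(n) < 0.5
        pos = np.where(plus, c - offs, c + offs).round().astype(int)
        for p, pl in zip(pos, plus):
            rows.append(("c1", int(p), "+" if pl else "-", "A", 2.0))
    track = make_track(rows)
    region = CandidateRegion("c1", 0, length, float(len(rows)), 0.0, 10.0)
    return track, region


class TestDeconvolveRegion:
    kernel = StrandKernel.from_normal(100.0, 25.0)

    def test_single_source_localized_and_concentrated(self):
        rng = np.random.default_rng(2)
        track, region = simulate_region(rng, [977], [2000])
        prof = discovery.deconvolve_region(region, track, self.kernel, grid_step=10)
        total = prof.source_intensity.sum()
        near = np.abs(prof.positions - 977) <= 20
        assert prof.source_intensity[near].sum() >= 0.95 * total
        best = prof.positions[np.argmax(prof.source_intensity)]
        assert abs(best - 977) <= 10

    def test_total_signal_conserved_without_penalty(self):
        rng = np.random.default_rng(3)
        track, region = simulate_region(rng, [700, 1300], [500, 800])
        prof = discovery.deconvolve_region(
            region, track, self.kernel, grid_step=10, penalty=0.0, max_iter=2000
        )
        assert abs(prof.fitted_total - prof.observed_total) <= 0.01 * prof.observed_total

    def test_two_sources_separated(self):
        rng = np.random.default_rng(4)
        track, region = simulate_region(rng, [700, 1000], [1000, 1000])
        prof = discovery.deconvolve_region(region, track, self.kernel, grid_step=10)
        calls = discovery.call_sites(prof, min_separation=100,
                                     min_intensity=0.05 * prof.source_intensity.max())
        assert len(calls) == 2
        assert min(abs(c - 700) for c in calls) <= 25
        assert min(abs(c - 1000) for c in calls) <= 25

    def test_zero_tags_errors(self):
        rng = np.random.default_rng(5)
        track, _ = simulate_region(rng, [500], [100])
        empty = CandidateRegion("c1", 10_000, 10_500, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            discovery.deconvolve_region(empty, track, self.kernel)

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        offs = np.abs(rng.normal(100, 25, 800))
        plus = rng.random(800) < 0.5
        shift = 5000
        calls = {}
        for delta in (0, shift):
            c = 900 + delta
            pos = np.where(plus, c - offs, c + offs).round().astype(int)
            rows = [
                ("c1", int(p), "+" if pl else "-", "A", 2.0)
                for p, pl in zip(pos, plus)
            ]
            track = make_track(rows)
            region = CandidateRegion("c1", delta, delta + 1800, 800.0, 0.0, 10.0)
            prof = discovery.deconvolve_region(region, track, self.kernel)
            calls[delta] = discovery.call_sites(prof, 100, 0.05 * prof.source_intensity.max())
        assert [c + shift for c in calls[0]] == calls[shift]

    def test_matches_brute_force_source_search(self):
        """Penalized fit agrees with exhaustive 1-2 source placement on a
        tiny region (<=500 bp, 25-bp grid)."""
        rng = np.random.default_rng(7)
        track, region = simulate_region(rng, [250], [400], length=500)
        kernel = self.kernel
        prof = discovery.deconvolve_region(region, track, kernel, grid_step=25)
        rl_best = prof.positions[np.argmax(prof.source_intensity)]

        # independent oracle: exhaustive Poisson-likelihood placement
        pad = int(np.abs(kernel.grid).max())
        lo, hi = region.start - pad, region.end + pad
        obs = {
            s: discovery._dense_profile(track, "c1", s, lo, hi) for s in "+-"
        }
        x = np.arange(lo, hi)
        sources = np.arange(region.start, region.end, 25)
        dens = {"+": kernel.density_plus, "-": kernel.density_minus}
        total = obs["+"].sum() + obs["-"].sum()

        def loglik(srcs):
            best = -np.inf
            for frac in (np.linspace(0.1, 0.9, 9) if len(srcs) == 2 else [1.0]):
                lls = 0.0
                for s in "+-":
                    lam = np.full(x.size, 1e-6)
                    weights = [frac, 1 - frac][: len(srcs)]
                    for src, fw in zip(srcs, weights):
                        idx = x - src - kernel.grid[0]
                        ok = (idx >= 0) & (idx < kernel.grid.size)
                        lam[ok] += 0.5 * total * fw * dens[s][idx[ok]]
                    lls += float(np.sum(obs[s] * np.log(lam) - lam))
                best = max(best, lls)
            return best

        one_best = max(sources, key=lambda s0: loglik([s0]))
        assert abs(one_best - rl_best) <= 25


class TestRegionBedIO:
    def test_roundtrip(self, tmp_path):
        regions = [
            discovery.CandidateRegion("c1", 100, 400, 50.0, 5.0, 4.0),
            discovery.CandidateRegion("c2", 0, 300, 20.0, 2.0, 2.5),
        ]
        path = tmp_path / "regions.bed"
        discovery.write_regions_bed(regions, path)
        back = discovery.read_regions_bed(path)
        assert [(r.chrom, r.start, r.end) for r in back] == [
            ("c1", 100, 400),
            ("c2", 0, 300),
        ]


class TestCallSites:
    def make_profile(self, intensities, step=10):
        return discovery.DeconvolvedProfile(
            np.arange(0, len(intensities) * step, step),
            np.asarray(intensities, float),
            0.0,
            True,
            1,
            0.0,
            0.0,
        )

    def test_monotone_profile_single_call(self):
        prof = self.make_profile([1, 2, 3, 4, 5])
        assert len(discovery.call_sites(prof, 10, 0.0)) <= 1

    def test_equal_maxima_merge_to_leftmost(self):
        prof = self.make_profile([0, 5, 0, 0, 0, 5, 0])
        calls = discovery.call_sites(prof, min_separation=100, min_intensity=0.0)
        assert calls == [10]

    def test_below_threshold_empty(self):
        prof = self.make_profile([1, 2, 1])
        assert discovery.call_sites(prof, 10, min_intensity=5.0) == []

    def test_separated_maxima_kept(self):
        prof = self.make_profile([0, 5, 0, 0, 0, 0, 0, 0, 0, 0, 0, 4, 0])
        calls = discovery.call_sites(prof, min_separation=100, min_intensity=0.0)
        assert calls == [10, 110]


class TestRejectSpurious:
    def test_strand_imbalance_rejected(self):
        rows = [("c1", 1000 + i, "+", "A", 2.0) for i in range(50)]
        track = make_track(rows)
        kept, log = discovery.reject_spurious(
            [("c1", 1000)], track, None, min_strand_frac=0.2
        )
        assert kept.empty and any("strand" in entry for entry in log)

    def test_planted_sites_mostly_retained(self, small_sim, small_regions):
        truth = small_sim["truth"]
        kernel = discovery.estimate_kernel(small_sim["chip_track"], small_regions)
        called = []
        for reg in small_regions:
            prof = discovery.deconvolve_region(reg, small_sim["chip_track"], kernel)
            thr = 0.05 * prof.source_intensity.max()
            called += [(reg.chrom, p) for p in discovery.call_sites(prof, 100, thr)]
        kept, _ = discovery.reject_spurious(
            called, small_sim["chip_track"], small_sim["input_track"]
        )
        pos = kept["position"].to_numpy()
        recovered = sum(
            1 for s in truth.sites if np.min(np.abs(pos - s.center)) <= 50
        )
        assert recovered >= 0.95 * len(truth.sites)

    def test_empty_input_empty_output(self, small_sim):
        kept, log = discovery.reject_spurious(
            [], small_sim["chip_track"], small_sim["input_track"]
        )
        assert kept.empty and log == []
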