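"""Site annotation: nearest TSS, positional categories, conservation,
expressed-gene filtering, target assignment and control regions."""

import numpy as np
import pandas as pd
import pytest

from circabind import annotate


def transcripts(rows):
    return pd.DataFrame(rows, columns=annotate.TRANSCRIPT_COLUMNS)


@pytest.fixture
def random_annotation():
    rng = np.random.default_rng(20)
    rows = []
    for i in range(60):
        strand = rng.choice(["+", "-"])
        tss = int(rng.integers(0, 500_000))
        length = int(rng.integers(1000, 40_000))
        tes = tss + length if strand == "+" else max(tss - length, 0)
        rows.append(
            (f"T{i:03d}", "c1", strand, tss, tes,
             rng.choice(["coding", "miRNA", "other ncRNA"], p=[0.7, 0.1, 0.2]),
             float(rng.uniform(0, 100)))
        )
    return transcripts(rows)


class TestNearestTss:
    def test_site_at_tss(self):
        tr = transcripts([("t1", "c1", "+", 100, 5000, "coding", 1.0)])
        best, d = annotate.nearest_tss("c1", 100, tr)
        assert d == 0 and best["id"] == "t1"

    def test_upstream_sign_convention(self):
        tr = transcripts([("t1", "c1", "+", 1000, 5000, "coding", 1.0)])
        _, d = annotate.nearest_tss("c1", 900, tr)
        assert d == -100
        tr_m = transcripts([("t1", "c1", "-", 1000, 0, "coding", 1.0)])
        _, d_m = annotate.nearest_tss("c1", 1100, tr_m)
        assert d_m == -100  # 5' of a minus-strand TSS is at larger coordinates

    def test_matches_exhaustive_scan(self, random_annotation):
        rng = np.random.default_rng(21)
        for _ in range(50):
            pos = int(rng.integers(0, 500_000))
            best, d = annotate.nearest_tss("c1", pos, random_annotation)
            dists = (random_annotation["tss"] - pos).abs()
            assert abs(d) == dists.min()

    def test_tie_breaks_by_id(self):
        tr = transcripts(
            [
                ("tB", "c1", "+", 90, 500, "coding", 1.0),
                ("tA", "c1", "+", 110, 500, "coding", 1.0),
            ]
        )
        best, _ = annotate.nearest_tss("c1", 100, tr)
        assert best["id"] == "tA"

    def test_empty_annotation(self):
        with pytest.raises(ValueError):
            annotate.nearest_tss("c1", 0, transcripts([]))


class TestCategorizeSite:
    tr = pd.Series(
        {"id": "t", "chrom": "c1", "strand": "+", "tss": 100_000, "tes": 130_000}
    )

    @pytest.mark.parametrize(
        "distance,expected",
        [
            (-1500, "promoter"),
            (1999, "promoter"),
            (-5000, "upstream"),
            (-10_000, "upstream"),
            (15_000, "gene"),  # midpoint of the 30-kb gene body
            (30_500, "downstream"),
            (41_000, "other"),
            (-20_000, "other"),
        ],
    )
    def test_category_definitions(self, distance, expected):
        assert annotate.categorize_site(distance, self.tr) == expected

    def test_exactly_one_category(self, random_annotation):
        rng = np.random.default_rng(22)
        for _ in range(100):
            pos = int(rng.integers(0, 500_000))
            best, d = annotate.nearest_tss("c1", pos, random_annotation)
            cat = annotate.categorize_site(d, best)
            assert cat in annotate.CATEGORIES


class TestConservationScore:
    def test_uniform_track(self):
        track = {"c1": np.full(1000, 0.8)}
        assert annotate.conservation_score("c1", 500, track) == pytest.approx(0.8)

    def test_boundary_position_included(self):
        arr = np.zeros(1000)
        arr[550] = 1.0
        assert annotate.conservation_score("c1", 500, {"c1": arr}) == 1.0
        arr2 = np.zeros(1000)
        arr2[551] = 1.0
        assert annotate.conservation_score("c1", 500, {"c1": arr2}) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(23)
        arr = rng.random(2000)
        for pos in (0, 49, 1000, 1999):
            got = annotate.conservation_score("c1", pos, {"c1": arr})
            lo, hi = max(pos - 50, 0), min(pos + 51, 2000)
            assert got == pytest.approx(arr[lo:hi].max())

    def test_unknown_chromosome(self):
        with pytest.raises(KeyError):
            annotate.conservation_score("nope", 0, {"c1": np.zeros(10)})


class TestExpressedFilter:
    def test_all_equal_gives_empty_set(self):
        tr = transcripts([(f"t{i}", "c1", "+", 0, 10, "coding", 5.0) for i in range(4)])
        kept, thr = annotate.expressed_filter(tr)
        assert kept.empty and thr == 5.0

    def test_top_half_retained(self):
        tr = transcripts(
            [(f"t{i}", "c1", "+", 0, 10, "coding", float(i)) for i in range(1, 101)]
        )
        kept, thr = annotate.expressed_filter(tr, 50)
        assert len(kept) == 50
        assert thr == pytest.approx(np.percentile(np.arange(1, 101), 50))

    def test_threshold_matches_independent_percentile(self):
        rng = np.random.default_rng(24)
        vals = rng.lognormal(0, 1, 200)
        tr = transcripts(
            [(f"t{i}", "c1", "+", 0, 10, "coding", float(v)) for i, v in enumerate(vals)]
        )
        for pct in (25, 50, 90):
            _, thr = annotate.expressed_filter(tr, pct)
            assert thr == pytest.approx(np.percentile(vals, pct))

    def test_missing_expression(self):
        tr = transcripts([("t1", "c1", "+", 0, 10, "coding", np.nan)])
        with pytest.raises(ValueError):
            annotate.expressed_filter(tr)


class TestAssignTargets:
    sites = pd.DataFrame({"chrom": ["c1"], "position": [100_000]})

    def test_distant_tss_unassigned(self):
        tr = transcripts([("t1", "c1", "+", 115_000, 130_000, "coding", 1.0)])
        out = annotate.assign_targets(self.sites, tr)
        assert out["target_id"].iloc[0] is None

    def test_nearby_coding_assigned(self):
        tr = transcripts([("t1", "c1", "+", 103_000, 130_000, "coding", 1.0)])
        out = annotate.assign_targets(self.sites, tr)
        assert out["target_id"].iloc[0] == "t1"
        assert out["tss_distance"].iloc[0] == -3000

    def test_coding_only_skips_nearer_ncrna(self):
        tr = transcripts(
            [
                ("nc", "c1", "+", 100_500, 105_000, "other ncRNA", 1.0),
                ("cod", "c1", "+", 103_000, 130_000, "coding", 1.0),
            ]
        )
        out = annotate.assign_targets(self.sites, tr, coding_only=True)
        assert out["target_id"].iloc[0] == "cod"
        out2 = annotate.assign_targets(self.sites, tr, coding_only=False)
        assert out2["target_id"].iloc[0] == "nc"


class TestControlRegion:
    def test_plus_500_rule(self):
        assert annotate.control_region(10_000, 100, 1_000_000) == (10_450, 10_550)

    def test_near_chromosome_end_flagged(self):
        assert annotate.control_region(10_000, 100, 10_540) is None

    def test_never_overlaps_site_window(self):
        rng = np.random.default_rng(25)
        for _ in range(100):
            pos = int(rng.integers(1000, 900_000))
            width = int(rng.integers(20, 200))
            ctrl = annotate.control_region(pos, width, 1_000_000)
            assert ctrl is not None
            lo, hi = ctrl
            assert lo > pos + 50 or hi <= pos - 50


class TestReaders:
    def test_gtf_roundtrip_conventions(self, tmp_path):
        gtf = tmp_path / "t.gtf"
        gtf.write_text(
            'c1\tsrc\ttranscript\t101\t500\t.\t+\t.\ttranscript_id "tp"; transcript_biotype "protein_coding";\n'
            'c1\tsrc\ttranscript\t1001\t1500\t.\t-\t.\ttranscript_id "tm"; transcript_biotype "miRNA";\n'
        )
        tr = annotate.read_gtf_transcripts(gtf)
        plus = tr[tr["id"] == "tp"].iloc[0]
        minus = tr[tr["id"] == "tm"].iloc[0]
        assert plus["tss"] == 100 and plus["tes"] == 500  # 0-based conversion
        assert plus["biotype"] == "coding"
        assert minus["tss"] == 1499 and minus["tes"] == 1000
        assert minus["biotype"] == "miRNA"

    def test_bed12_reader(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text(
            "c1\t100\t500\ttx1\t0\t-\t100\t500\t0\t1\t400\t0\n"
        )
        tr = annotate.read_bed12_transcripts(bed)
        assert tr.iloc[0]["tss"] == 499 and tr.iloc[0]["tes"] == 100

    def test_bedgraph_reader(self, tmp_path):
        bg = tmp_path / "c.bedgraph"
        bg.write_text("c1\t10\t20\t0.7\nc1\t20\t30\t0.2\n")
        track = annotate.read_bedgraph_track(bg, {"c1": 50})
        assert track["c1"][15] == 0.7 and track["c1"][25] == 0.2 and track["c1"][40] == 0.0
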