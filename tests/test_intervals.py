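"""Interval statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methdyn.intervals import (
    annotate_features,
    bin_signal,
    correlate_over_intervals,
    gene_set_overlap_test,
    jaccard,
    merge_intervals,
    nearest_tss,
    reciprocal_overlap,
    subtract_intervals,
)
from .conftest import make_track


def iv(records):
    return pd.DataFrame(records, columns=["chrom", "start", "end"])


def random_intervals(rng, n, span=10_000, max_len=500, chrom="chr1"):
    starts = rng.integers(0, span, n)
    lengths = rng.integers(1, max_len, n)
    return iv([(chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)])


def base_level_jaccard(a, b, span=20_000):
    """Per-base brute force over a finite coordinate window."""
    cov_a = np.zeros(span, bool)
    cov_b = np.zeros(span, bool)
    for _, r in a.iterrows():
        cov_a[r["start"] : r["end"]] = True
    for _, r in b.iterrows():
        cov_b[r["start"] : r["end"]] = True
    inter = (cov_a & cov_b).sum()
    union = (cov_a | cov_b).sum()
    return inter / union


class TestMergeSubtract:
    def test_merge_collapses_overlaps(self):
        merged = merge_intervals(iv([("chr1", 0, 100), ("chr1", 50, 150), ("chr1", 200, 300)]))
        assert list(zip(merged["start"], merged["end"])) == [(0, 150), (200, 300)]

    def test_subtract_tracks_source(self):
        out = subtract_intervals(
            iv([("chr1", 0, 100)]), iv([("chr1", 40, 60)])
        )
        assert list(zip(out["start"], out["end"])) == [(0, 40), (60, 100)]
        assert (out["source_index"] == 0).all()

    def test_subtract_fully_covered_yields_nothing(self):
        out = subtract_intervals(iv([("chr1", 10, 20)]), iv([("chr1", 0, 100)]))
        assert len(out) == 0


class TestJaccard:
    def test_identical_sets(self):
        a = iv([("chr1", 0, 100), ("chr2", 50, 80)])
        assert jaccard(a, a.copy()) == 1.0

    def test_disjoint_sets(self):
        assert jaccard(iv([("chr1", 0, 100)]), iv([("chr1", 200, 300)])) == 0.0

    def test_half_overlap(self):
        got = jaccard(iv([("chr1", 0, 100)]), iv([("chr1", 50, 150)]))
        assert got == pytest.approx(50 / 150)

    def test_both_empty_raises(self):
        empty = iv([])
        with pytest.raises(ValueError):
            jaccard(empty, empty)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = random_intervals(rng, 10)
            b = random_intervals(rng, 10)
            j1, j2 = jaccard(a, b), jaccard(b, a)
            assert j1 == pytest.approx(j2)
            assert 0 <= j1 <= 1

    def test_matches_per_base_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a = random_intervals(rng, 8)
            b = random_intervals(rng, 8)
            assert jaccard(a, b) == pytest.approx(base_level_jaccard(a, b))


class TestReciprocalOverlap:
    def test_rule_application(self):
        # overlap 60 of 100/100 -> both fractions > 0.5
        res = reciprocal_overlap(iv([("chr1", 0, 100)]), iv([("chr1", 40, 140)]))
        assert len(res["pairs"]) == 1

    def test_small_overlap_excluded(self):
        res = reciprocal_overlap(iv([("chr1", 0, 100)]), iv([("chr1", 90, 300)]))
        assert len(res["pairs"]) == 0

    def test_either_side_flag(self):
        # overlap 50: >50% of the short interval only
        a, b = iv([("chr1", 0, 60)]), iv([("chr1", 10, 300)])
        assert len(reciprocal_overlap(a, b)["pairs"]) == 0
        assert len(reciprocal_overlap(a, b, either_side=True)["pairs"]) == 1

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError):
            reciprocal_overlap(iv([]), iv([]), min_frac=0)

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(2)
        a = random_intervals(rng, 200, span=50_000)
        b = random_intervals(rng, 200, span=50_000)
        res = reciprocal_overlap(a, b)
        got = set(zip(res["pairs"]["index_a"], res["pairs"]["index_b"]))
        expected = set()
        for i, ra in a.iterrows():
            for j, rb in b.iterrows():
                o = min(ra["end"], rb["end"]) - max(ra["start"], rb["start"])
                if o > 0.5 * (ra["end"] - ra["start"]) and o > 0.5 * (rb["end"] - rb["start"]):
                    expected.add((i, j))
        assert got == expected


class TestNearestTss:
    def tss(self, records):
        return pd.DataFrame(records, columns=["chrom", "pos", "strand", "gene"])

    def test_midpoint_at_tss_gives_zero(self):
        t = self.tss([("chr1", 100, "+", "g1")])
        out = nearest_tss(iv([("chr1", 50, 150)]), t)
        assert out["tss_distance"].iloc[0] == 0

    def test_downstream_of_plus_strand_is_positive(self):
        t = self.tss([("chr1", 1000, "+", "g1")])
        out = nearest_tss(iv([("chr1", 1400, 1600)]), t)  # midpoint 1500
        assert out["tss_distance"].iloc[0] == 500

    def test_strand_flips_sign(self):
        t = self.tss([("chr1", 1000, "-", "g1")])
        out = nearest_tss(iv([("chr1", 1400, 1600)]), t)
        assert out["tss_distance"].iloc[0] == -500

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        t = self.tss(
            [("chr1", int(p), rng.choice(["+", "-"]), f"g{i}")
             for i, p in enumerate(rng.integers(0, 100_000, 50))]
        )
        ivs = random_intervals(rng, 40, span=100_000)
        out = nearest_tss(ivs, t)
        for idx, rec in ivs.iterrows():
            mid = (rec["start"] + rec["end"]) // 2
            dists = np.abs(t["pos"].to_numpy() - mid)
            assert abs(out.loc[idx, "tss_distance"]) == dists.min()


class TestAnnotateFeatures:
    @pytest.fixture
    def gene_model(self):
        # one plus-strand transcript: tx 10000-20000, CDS 11000-19000,
        # exons (10000-12000, 15000-16000, 18500-20000)
        return pd.DataFrame(
            [
                {
                    "chrom": "chr1",
                    "strand": "+",
                    "tx_start": 10_000,
                    "tx_end": 20_000,
                    "cds_start": 11_000,
                    "cds_end": 19_000,
                    "exon_starts": "10000,15000,18500",
                    "exon_ends": "12000,16000,20000",
                }
            ]
        )

    def test_upstream_of_tss_is_promoter(self, gene_model):
        out = annotate_features(iv([("chr1", 9_850, 9_950)]), gene_model)
        assert out["feature"].iloc[0] == "promoter"

    def test_gene_desert_is_intergenic(self, gene_model):
        out = annotate_features(iv([("chr1", 500_000, 500_200)]), gene_model)
        assert out["feature"].iloc[0] == "intergenic"

    def test_promoter_precedence_over_intron(self, gene_model):
        # spans the promoter window AND intronic sequence? use TSS-adjacent
        out = annotate_features(iv([("chr1", 10_500, 13_000)]), gene_model)
        assert out["feature"].iloc[0] == "promoter"

    def test_intron_and_exon_labels(self, gene_model):
        out = annotate_features(
            iv([("chr1", 13_000, 13_200), ("chr1", 15_200, 15_400)]), gene_model
        )
        assert list(out["feature"]) == ["intron", "exon"]

    def test_utr_labels(self, gene_model):
        # shrink the promoter window so it does not shadow the 5'UTR
        out = annotate_features(
            iv([("chr1", 10_200, 10_400), ("chr1", 19_400, 19_600)]),
            gene_model,
            promoter_window=100,
        )
        assert list(out["feature"]) == ["5UTR", "3UTR"]

    def test_malformed_model_raises(self):
        bad = pd.DataFrame([{"chrom": "chr1", "strand": "+"}])
        with pytest.raises(ValueError):
            annotate_features(iv([("chr1", 0, 10)]), bad)


class TestGeneSetOverlap:
    def test_identical_sets_degenerate_table(self):
        bg = [f"g{i}" for i in range(50)]
        odds, p = gene_set_overlap_test(bg, bg, bg)
        assert p == 1.0

    def test_matches_hypergeometric_enumeration(self):
        # table (a=5, b=5, c=5, d=85)
        bg = [f"g{i}" for i in range(100)]
        set_a = bg[:10]
        set_b = bg[:5] + bg[10:15]
        _, p = gene_set_overlap_test(set_a, set_b, bg)
        # exhaustive two-sided hypergeometric: sum over all tables with
        # fixed margins whose probability <= observed
        M, n, N = 100, 10, 10  # population, successes, draws
        obs = sps.hypergeom.pmf(5, M, n, N)
        total = sum(
            sps.hypergeom.pmf(k, M, n, N)
            for k in range(0, 11)
            if sps.hypergeom.pmf(k, M, n, N) <= obs * (1 + 1e-9)
        )
        assert p == pytest.approx(total, abs=1e-9)

    def test_disjoint_small_sets_not_enriched(self):
        bg = [f"g{i}" for i in range(1000)]
        odds, p = gene_set_overlap_test(bg[:5], bg[5:10], bg)
        assert odds == 0.0
        assert p > 0.5

    def test_subset_violation_raises(self):
        with pytest.raises(ValueError):
            gene_set_overlap_test(["x"], ["a"], ["a", "b"])

    def test_symmetric_in_the_two_sets(self):
        rng = np.random.default_rng(4)
        bg = [f"g{i}" for i in range(200)]
        for _ in range(20):
            a = list(rng.choice(bg, 30, replace=False))
            b = list(rng.choice(bg, 40, replace=False))
            _, p1 = gene_set_overlap_test(a, b, bg)
            _, p2 = gene_set_overlap_test(b, a, bg)
            assert p1 == pytest.approx(p2, rel=1e-12)


class TestBinSignal:
    def make_uniform_track(self, level=0.6, span=30_000, spacing=50, coverage=10):
        n_sites = span // spacing
        k = int(round(level * coverage))
        return make_track(
            [("chr1", i * spacing, "+", "CpG", k, coverage) for i in range(n_sites)]
        )

    def test_center_mode_column_count(self):
        track = self.make_uniform_track()
        sm = bin_signal(track, iv([("chr1", 10_000, 11_000)]), "center", 2000, 100)
        assert sm.matrix.shape == (1, 40)

    def test_uniform_track_gives_flat_means(self):
        track = self.make_uniform_track(level=0.6)
        sm = bin_signal(
            track,
            iv([("chr1", 10_000, 11_000), ("chr1", 20_000, 20_600)]),
            "center",
            2000,
            100,
        )
        np.testing.assert_allclose(sm.column_means, 0.6, atol=1e-12)

    def test_scaled_mode_shape(self):
        track = self.make_uniform_track()
        sm = bin_signal(
            track, iv([("chr1", 10_000, 11_000)]), "scaled", 1000, 100, body_bins=20
        )
        assert sm.matrix.shape == (1, 10 + 20 + 10)

    def test_empty_bins_are_nan_not_zero(self):
        track = make_track([("chr1", 10_000, "+", "CpG", 5, 10)])
        sm = bin_signal(track, iv([("chr1", 10_000, 10_100)]), "center", 2000, 100)
        assert np.isnan(sm.matrix).sum() == 39

    def test_invalid_bin_raises(self):
        track = self.make_uniform_track()
        with pytest.raises(ValueError):
            bin_signal(track, iv([("chr1", 0, 10)]), "center", 2000, 0)

    def test_planted_dme_dip_matches_truth(self, small_study):
        """Meta-profile over DMEs dips in the condition where the planted
        pattern is hypomethylated but not where it is high."""
        from methdyn.simulate import simulate_wgbs

        arch, truth, config = small_study
        dmes = truth.intervals[truth.intervals["layer"] == "DME"]
        # restrict to DMEs with high proB level and low WT level in B1a
        sel = dmes[
            dmes["levels_B1a"].apply(lambda v: v[0] >= 0.8 and v[1] <= 0.2)
        ]
        assert len(sel) > 0
        body_cols = slice(10, 30)
        profiles = {}
        for cond in ("proB", "WT"):
            track = simulate_wgbs(arch, truth, "B1a", cond, config)
            sm = bin_signal(track, sel, "scaled", 1000, 100, body_bins=20)
            profiles[cond] = np.nanmean(sm.column_means[body_cols])
        assert profiles["WT"] < 0.35
        assert profiles["proB"] > 0.6


class TestCorrelation:
    def test_anti_monotone_pairs(self):
        x = np.arange(10, dtype=float)
        assert correlate_over_intervals(x, -x) == pytest.approx(-1.0)

    def test_identity(self):
        x = np.linspace(0, 1, 20)
        assert correlate_over_intervals(x, x) == pytest.approx(1.0)

    def test_constant_side_is_missing(self):
        x = np.ones(10)
        y = np.arange(10, dtype=float)
        assert np.isnan(correlate_over_intervals(x, y))

    def test_matches_brute_force_ranks_with_ties(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 10, 50).astype(float)  # plenty of ties
        y = rng.integers(0, 10, 50).astype(float)

        def avg_ranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v), float)
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j - 1) / 2 + 1
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert correlate_over_intervals(x, y) == pytest.approx(expected, abs=1e-12)
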