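"""HMM segmentation: decoding oracle, EM behaviour, HMR/canyon calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methdyn.segmentation import (
    BetaBinomialHMM,
    HmmParams,
    call_canyons,
    call_hmrs,
    default_init,
    enumerate_posteriors,
    fit_hmm,
    hmr_length_stats,
    ks_statistic,
    posterior_marginals,
)
from .conftest import make_track, uniform_track


def two_state_track(seed=0, n_blocks=6, block_cpgs=25, spacing=40, coverage=10,
                    hypo=0.05, hyper=0.85):
    """Alternating hyper/hypo blocks; returns (track, hypo_blocks)."""
    rng = np.random.default_rng(seed)
    rows, hypo_blocks = [], []
    pos = 100
    for b in range(n_blocks):
        level = hypo if b % 2 else hyper
        start = pos
        for _ in range(block_cpgs):
            n = rng.poisson(coverage) + 1
            k = rng.binomial(n, level)
            rows.append(("chr1", pos, "+", "CpG", int(k), int(n)))
            pos += spacing
        if b % 2:
            hypo_blocks.append((start, pos - spacing))
    return make_track(rows), hypo_blocks


class TestDecodingOracle:
    @given(
        seed=st.integers(0, 10_000),
        length=st.integers(2, 12),
    )
    @settings(max_examples=60, deadline=None)
    def test_posteriors_match_exhaustive_enumeration(self, seed, length):
        """Forward-backward equals the sum over all 2^n state paths."""
        rng = np.random.default_rng(seed)
        n = rng.poisson(5, length) + 1
        k = rng.binomial(n, rng.uniform(0, 1))
        params = default_init()
        fb = posterior_marginals(k, n, params)
        brute = enumerate_posteriors(k, n, params)
        np.testing.assert_allclose(fb, brute, atol=1e-9)

    def test_oracle_agreement_with_binomial_emissions(self):
        rng = np.random.default_rng(3)
        n = rng.poisson(8, 10) + 1
        k = rng.binomial(n, 0.4)
        params = HmmParams(
            trans=np.array([[0.9, 0.1], [0.2, 0.8]]),
            start=np.array([0.3, 0.7]),
            alpha=np.array([1.0, 8.0]),
            beta=np.array([9.0, 2.0]),
            emission="binom",
        )
        np.testing.assert_allclose(
            posterior_marginals(k, n, params),
            enumerate_posteriors(k, n, params),
            atol=1e-9,
        )


class TestFit:
    def test_recovers_state_means(self):
        track, _ = two_state_track(seed=1, n_blocks=20, block_cpgs=30)
        params, _ = fit_hmm(track, seed=0)
        assert params.means[0] == pytest.approx(0.05, abs=0.05)
        assert params.means[1] == pytest.approx(0.85, abs=0.05)

    def test_loglik_monotone(self):
        track, _ = two_state_track(seed=2)
        _, trace = fit_hmm(track, seed=0, tol=1e-8, max_iter=50)
        assert np.all(np.diff(trace) >= -1e-6)

    def test_infinite_tol_returns_init_after_one_estep(self):
        track, _ = two_state_track(seed=3, n_blocks=2)
        init = default_init()
        params, trace = fit_hmm(track, init=init, tol=np.inf)
        assert len(trace) == 1
        np.testing.assert_array_equal(params.alpha, init.alpha)
        np.testing.assert_array_equal(params.trans, init.trans)

    def test_too_few_covered_cpgs_raises(self):
        track = make_track([("chr1", 10, "+", "CpG", 0, 0), ("chr1", 50, "+", "CpG", 0, 0)])
        with pytest.raises(ValueError):
            BetaBinomialHMM(track)

    def test_results_summary_mentions_fit(self):
        track, _ = two_state_track(seed=4)
        res = BetaBinomialHMM(track).fit(seed=0)
        s = res.summary()
        assert "log-likelihood" in s and "hypo" in s


class TestParamsValidation:
    def test_rejects_non_stochastic_transition(self):
        with pytest.raises(ValueError):
            HmmParams(
                trans=np.array([[0.5, 0.4], [0.1, 0.9]]),
                start=np.array([0.5, 0.5]),
                alpha=np.array([1.0, 8.0]),
                beta=np.array([9.0, 2.0]),
            )

    def test_rejects_unordered_state_means(self):
        with pytest.raises(ValueError):
            HmmParams(
                trans=np.eye(2),
                start=np.array([0.5, 0.5]),
                alpha=np.array([8.0, 1.0]),
                beta=np.array([2.0, 9.0]),
            )


class TestCallHmrs:
    def test_uniform_hypermethylated_track_yields_no_hmrs(self):
        track = uniform_track(np.arange(300) * 40, 0.85, 10, seed=5)
        params, _ = fit_hmm(track, seed=0, max_iter=20)
        # a track with no hypo segment: decoding must not invent HMRs
        hmrs = call_hmrs(track, default_init())
        assert len(hmrs) == 0

    def test_planted_block_recovered_with_tight_boundaries(self):
        rng = np.random.default_rng(6)
        rows = []
        spacing = 100
        for i in range(120):
            pos = 1000 + i * spacing
            level = 0.05 if 50 <= i < 70 else 0.85  # 2 kb hypo block, 20 CpGs
            n = rng.poisson(10) + 1
            k = rng.binomial(n, level)
            rows.append(("chr1", pos, "+", "CpG", int(k), int(n)))
        track = make_track(rows)
        hmrs = call_hmrs(track, default_init())
        assert len(hmrs) == 1
        start_idx = (hmrs.iloc[0]["start"] - 1000) // spacing
        end_idx = (hmrs.iloc[0]["end"] - 2 - 1000) // spacing
        assert abs(start_idx - 50) <= 2
        assert abs(end_idx - 69) <= 2

    def test_runs_split_at_large_gaps(self):
        rows = []
        for i in range(10):
            rows.append(("chr1", 100 + 40 * i, "+", "CpG", 0, 10))
        for i in range(10):
            rows.append(("chr1", 10_000 + 40 * i, "+", "CpG", 0, 10))
        track = make_track(rows)
        hmrs = call_hmrs(track, default_init(), gap_limit=1000)
        assert len(hmrs) == 2

    def test_end_coordinate_covers_dyad(self):
        track = uniform_track(np.arange(20) * 40 + 100, 0.0, 10, seed=7)
        hmrs = call_hmrs(track, default_init())
        assert hmrs.iloc[0]["end"] == int(track.sites["pos"].max()) + 2


class TestCanyons:
    def test_cutoff_classification_exact(self):
        hmrs = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [0, 10_000, 20_000],
                "end": [3_400, 13_500, 23_600],
            }
        )
        canyons = call_canyons(hmrs, min_length=3500)
        lengths = set(canyons["end"] - canyons["start"])
        assert lengths == {3500, 3600}  # "3.5 kb or longer"

    def test_empty_input(self):
        assert len(call_canyons(pd.DataFrame(columns=["chrom", "start", "end"]))) == 0

    def test_zero_cutoff_returns_all(self):
        hmrs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        assert len(call_canyons(hmrs, min_length=0)) == 1

    def test_negative_cutoff_raises(self):
        with pytest.raises(ValueError):
            call_canyons(pd.DataFrame(columns=["chrom", "start", "end"]), -1)

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        hmrs = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(20) * 10_000,
                "end": np.arange(20) * 10_000 + rng.integers(100, 8000, 20),
            }
        )
        shuffled = hmrs.sample(frac=1, random_state=1)
        a = call_canyons(hmrs).sort_values("start").reset_index(drop=True)
        b = call_canyons(shuffled).sort_values("start").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestLengthStats:
    def test_median(self):
        hmrs = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 1000, 2000], "end": [100, 1200, 2300]}
        )
        assert hmr_length_stats(hmrs)["median_length"] == 200

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            hmr_length_stats(pd.DataFrame(columns=["chrom", "start", "end"]))

    def test_genome_fraction(self):
        hmrs = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [500]})
        assert hmr_length_stats(hmrs, genome_size=10_000)["genome_fraction"] == 0.05

    def test_identical_sets_ks_zero(self):
        lengths = [100, 300, 900]
        stat, _ = ks_statistic(lengths, lengths)
        assert stat == 0.0

    @given(
        a=st.lists(st.integers(50, 5000), min_size=2, max_size=100),
        b=st.lists(st.integers(50, 5000), min_size=2, max_size=100),
    )
    @settings(max_examples=50, deadline=None)
    def test_ks_matches_brute_force_ecdf(self, a, b):
        stat, _ = ks_statistic(a, b)
        a_arr, b_arr = np.asarray(a, float), np.asarray(b, float)
        grid = np.concatenate([a_arr, b_arr])
        ecdf_a = np.array([(a_arr <= x).mean() for x in grid])
        ecdf_b = np.array([(b_arr <= x).mean() for x in grid])
        assert stat == pytest.approx(np.abs(ecdf_a - ecdf_b).max(), abs=1e-12)


class TestRecoveryOnSyntheticGenome:
    """Planted-HMR recovery on a 200 kb genome at 10x coverage."""

    def test_planted_hmrs_recovered(self):
        from methdyn.simulate import (
            SimulationConfig,
            generate_genome,
            plant_architecture,
            simulate_wgbs,
        )

        config = SimulationConfig(
            seed=17, conversion_rate=1.0, background_level=0.85,
            foundational_level=0.05, non_cpg_per_chrom=0,
        )
        genome = generate_genome(1, 200_000, 100, seed=17)
        arch, truth = plant_architecture(
            genome, {"chr1": 200_000}, n_foundational=8, n_dme=0, n_canyons=0,
            seed=17, config=config,
        )
        track = simulate_wgbs(arch, truth, "B1a", "WT", config, coverage_mean=10)
        res = BetaBinomialHMM(track).fit(seed=0)
        hmrs = res.call_hmrs()
        pos = arch.cpg_positions["chr1"]
        recovered = 0
        for _, t in arch.foundational_hmrs.iterrows():
            inside = pos[(pos >= t["start"]) & (pos < t["end"])]
            first, last = inside[0], inside[-1]
            hits = hmrs[(hmrs["start"] < t["end"]) & (hmrs["end"] > t["start"])]
            if len(hits) != 1:
                continue
            h = hits.iloc[0]
            d_start = np.searchsorted(pos, h["start"]) - np.searchsorted(pos, first)
            d_end = np.searchsorted(pos, h["end"] - 2) - np.searchsorted(pos, last)
            if abs(d_start) <= 2 and abs(d_end) <= 2:
                recovered += 1
        assert recovered >= 0.9 * len(arch.foundational_hmrs)

    def test_no_hmrs_in_pure_background(self):
        track = uniform_track(np.arange(2000) * 100, 0.85, 10, seed=18)
        res = BetaBinomialHMM(track).fit(seed=0)
        assert len(res.call_hmrs()) == 0
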