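import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakshaper.candidate_detection import (
    CandidatePeak,
    EnrichmentMap,
    EnrichmentParams,
    build_enrichment_map,
    detect,
    extract_candidates,
    rolling_mean,
)
from peakshaper.coverage_io import CoverageTrack


def oracle_rolling_mean(signal, window):
    """Brute-force windowed mean: explicit summation per base."""
    n = len(signal)
    out = np.empty(n)
    for i in range(n):
        lo = max(i - window // 2, 0)
        hi = min(i + (window - window // 2), n)
        out[i] = sum(signal[lo:hi]) / (hi - lo)
    return out


def oracle_enrichment_map(signal, params: EnrichmentParams):
    """Naive per-base, per-definition counting, independent of the cumsum path."""
    n = len(signal)
    chrom_mean = np.mean(signal)
    counts = np.zeros(n, dtype=int)
    for window in params.window_sizes:
        for i in range(n):
            lo = max(i - window // 2, 0)
            hi = min(i + (window - window // 2), n)
            m = np.mean(signal[lo:hi])
            for fold in params.folds:
                counts[i] += m > fold * chrom_mean
    return counts


def track_of(arr) -> CoverageTrack:
    return CoverageTrack(["chr1"], {"chr1": np.asarray(arr, dtype=np.float64)})


class TestEnrichmentParams:
    def test_default_definition_count(self):
        assert EnrichmentParams().n_definitions == 25

    def test_default_grids(self):
        params = EnrichmentParams()
        assert params.window_sizes == (100, 200, 400, 800, 1600)
        assert params.folds == (2, 4, 8, 16, 32)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentParams(window_sizes=(0, 100))


class TestRollingMean:
    def test_constant_signal(self):
        for window in (1, 2, 7, 100):
            out = rolling_mean(np.full(50, 3.5), window)
            assert np.allclose(out, 3.5)

    def test_window_one_is_identity(self):
        sig = np.array([1.0, 5.0, 2.0, 0.0])
        assert np.array_equal(rolling_mean(sig, 1), sig)

    def test_small_example_against_oracle(self):
        sig = [0.0, 4.0, 0.0, 0.0]
        assert np.array_equal(rolling_mean(np.array(sig), 2), oracle_rolling_mean(sig, 2))

    def test_bad_window(self):
        with pytest.raises(ValueError):
            rolling_mean(np.ones(5), 0)

    def test_empty_signal(self):
        with pytest.raises(ValueError):
            rolling_mean(np.array([]), 5)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=60),
        st.integers(min_value=1, max_value=80),
    )
    def test_matches_oracle_on_random_input(self, values, window):
        sig = np.array(values, dtype=np.float64)
        assert np.array_equal(rolling_mean(sig, window), oracle_rolling_mean(values, window))

    def test_output_length_preserved(self):
        assert rolling_mean(np.arange(17.0), 4).size == 17


class TestBuildEnrichmentMap:
    def test_all_zero_chromosome(self):
        emap = build_enrichment_map(track_of(np.zeros(3000)))
        assert np.array_equal(emap.counts["chr1"], np.zeros(3000, dtype=int))

    def test_constant_positive_chromosome(self):
        emap = build_enrichment_map(track_of(np.full(3000, 7.0)))
        assert not emap.counts["chr1"].any()

    def test_plateau_against_oracle(self):
        sig = np.zeros(10_000)
        sig[5000:5300] = 10.0
        params = EnrichmentParams()
        emap = build_enrichment_map(track_of(sig))
        assert np.array_equal(emap.counts["chr1"], oracle_enrichment_map(sig, params))

    def test_random_tracks_against_oracle(self):
        params = EnrichmentParams()
        for seed in range(3):
            rng = np.random.default_rng(seed)
            sig = rng.poisson(1.0, 20_000).astype(np.float64)
            # plant a peak so the map is non-trivial
            sig[8000:8400] += rng.poisson(15.0, 400)
            emap = build_enrichment_map(track_of(sig))
            assert np.array_equal(emap.counts["chr1"], oracle_enrichment_map(sig, params))

    def test_values_bounded(self):
        rng = np.random.default_rng(11)
        sig = rng.poisson(1.0, 20_000).astype(np.float64)
        sig[4000:4200] += 60
        counts = build_enrichment_map(track_of(sig)).counts["chr1"]
        assert counts.min() >= 0 and counts.max() <= 25


class TestScaleInvariance:
    @pytest.mark.parametrize("c", [10, 1000])
    def test_map_invariant(self, c):
        rng = np.random.default_rng(3)
        sig = rng.poisson(1.0, 30_000).astype(np.float64)
        sig[10_000:10_500] += rng.poisson(10.0, 500)
        track = track_of(sig)
        a = build_enrichment_map(track).counts["chr1"]
        b = build_enrichment_map(track.scale(c)).counts["chr1"]
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("c", [10, 1000])
    def test_candidate_set_invariant(self, c):
        rng = np.random.default_rng(4)
        sig = rng.poisson(1.0, 30_000).astype(np.float64)
        for start in (5000, 15_000, 25_000):
            sig[start : start + 400] += rng.poisson(12.0, 400)
        track = track_of(sig)
        base = [(p.region, p.n_definitions, p.saturated) for p in detect(track)]
        scaled = [(p.region, p.n_definitions, p.saturated) for p in detect(track.scale(c))]
        assert base and base == scaled


class TestExtractCandidates:
    def _emap(self, counts):
        return EnrichmentMap(["chr1"], {"chr1": np.asarray(counts, dtype=np.int16)})

    def test_all_zero_map(self):
        emap = self._emap(np.zeros(1000))
        assert extract_candidates(emap, track_of(np.zeros(1000))) == []

    def test_single_300_base_run(self):
        counts = np.zeros(1000)
        counts[200:500] = 5
        sig = np.zeros(1000)
        sig[200:500] = 9.0
        peaks = extract_candidates(self._emap(counts), track_of(sig))
        assert len(peaks) == 1
        pk = peaks[0]
        assert (pk.region.start, pk.region.end) == (200, 500)
        assert pk.n_definitions == 5
        assert not pk.saturated
        assert pk.height == 9.0

    def test_run_below_min_width_discarded(self):
        counts = np.zeros(1000)
        counts[100:130] = 7
        peaks = extract_candidates(self._emap(counts), track_of(np.zeros(1000)))
        assert peaks == []

    def test_recursion_into_nested_run(self):
        # 5 kb run at 5 definitions, 1 kb core at 6: parent too wide, child emitted
        counts = np.zeros(10_000)
        counts[1000:6000] = 5
        counts[3000:4000] = 6
        peaks = extract_candidates(self._emap(counts), track_of(np.zeros(10_000)))
        assert [(p.region.start, p.region.end, p.n_definitions) for p in peaks] == [
            (3000, 4000, 6)
        ]

    def test_wide_run_with_no_core_dropped(self):
        counts = np.zeros(10_000)
        counts[1000:6000] = 5  # uniform: nothing survives requirement 6
        assert extract_candidates(self._emap(counts), track_of(np.zeros(10_000))) == []

    def test_saturated_run_exempt_from_upper_bound(self):
        counts = np.zeros(10_000)
        counts[1000:6000] = 25
        peaks = extract_candidates(self._emap(counts), track_of(np.ones(10_000)))
        assert len(peaks) == 1
        assert peaks[0].saturated
        assert peaks[0].region.width == 5000
        assert peaks[0].n_definitions == 25

    def test_chromosome_mismatch(self):
        emap = self._emap(np.zeros(10))
        track = CoverageTrack(["chr2"], {"chr2": np.zeros(10)})
        with pytest.raises(ValueError):
            extract_candidates(emap, track)


class TestEndToEndProperties:
    def test_saturated_detection_on_extreme_track(self):
        sig = np.zeros(200_000)
        sig[100_000:105_000] = 1000.0
        peaks = detect(track_of(sig))
        assert any(p.saturated and p.region.width > 2000 for p in peaks)

    def test_candidates_disjoint_sorted_and_within_bounds(self):
        rng = np.random.default_rng(9)
        sig = rng.poisson(1.0, 100_000).astype(np.float64)
        for start in range(5000, 95_000, 10_000):
            width = int(rng.integers(100, 900))
            sig[start : start + width] += rng.poisson(10.0, width)
        peaks = detect(track_of(sig))
        assert peaks
        prev_end = -1
        for pk in peaks:
            assert pk.region.start >= prev_end
            prev_end = pk.region.end
            assert pk.region.width >= 50
            if not pk.saturated:
                assert pk.region.width <= 2000
            assert 5 <= pk.n_definitions <= 25

    def test_flat_tracks_yield_no_candidates(self):
        assert detect(track_of(np.zeros(50_000))) == []
        assert detect(track_of(np.full(50_000, 4.0))) == []

    def test_monotone_nesting_of_thresholded_sets(self):
        rng = np.random.default_rng(13)
        sig = rng.poisson(1.0, 20_000).astype(np.float64)
        sig[9000:9500] += 30
        counts = build_enrichment_map(track_of(sig)).counts["chr1"]
        for t in range(5, 25):
            assert np.all((counts >= t + 1) <= (counts >= t))
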