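import numpy as np
import pytest

import crafdseq as cs
from crafdseq.errors import CrafdValidationError
from conftest import make_track, random_count_track
from oracles import brute_boundaries, brute_call_peaks, brute_pair


def as_tuples(candidates):
    return [(c.position, c.kind, c.fold) for c in candidates]


class TestScanBoundaries:
    def test_flat_track_has_no_candidates(self):
        t = make_track(np.full(100, 10.0))
        assert cs.scan_boundaries(t, cs.PeakCallParams()) == []

    def test_step_track_boundaries_span_elevated_region(self, step_track):
        cands = cs.scan_boundaries(step_track, cs.PeakCallParams())
        assert [(c.position, c.kind) for c in cands] == [(51, "start"), (120, "end")]
        assert cands[0].fold == pytest.approx((20 + 0.1) / (10 + 0.1))

    def test_subthreshold_step_rejected(self):
        v = np.concatenate([np.full(50, 10.0), np.full(70, 14.0), np.full(80, 10.0)])
        assert cs.scan_boundaries(make_track(v), cs.PeakCallParams()) == []

    def test_track_shorter_than_two_windows_plus_spacer_is_empty(self):
        t = make_track(np.full(19, 10.0))  # needs >= 2*5+10 = 20
        assert cs.scan_boundaries(t, cs.PeakCallParams()) == []

    def test_circular_wrap_detects_origin_spanning_step(self):
        # elevated region wraps the origin: positions 181..200 and 1..20
        v = np.full(200, 10.0)
        v[180:] = 30.0
        v[:20] = 30.0
        t = make_track(v)
        linear = cs.scan_boundaries(t, cs.PeakCallParams())
        circular = cs.scan_boundaries(t, cs.PeakCallParams(circular=True))
        kinds = {(c.position, c.kind) for c in circular}
        assert (181, "start") in kinds and (20, "end") in kinds
        # the linear scan sees the same transitions away from the ends
        assert {(c.position, c.kind) for c in linear} <= kinds


class TestPairBoundaries:
    P = cs.PeakCallParams()

    def cand(self, pos, kind):
        return cs.BoundaryCandidate(pos, kind, 2.0)

    def test_single_pair(self):
        cands = [self.cand(100, "start"), self.cand(200, "end")]
        assert cs.pair_boundaries(cands, 500, self.P) == [(100, 200)]

    def test_interior_start_ignored(self):
        cands = [self.cand(100, "start"), self.cand(150, "start"),
                 self.cand(200, "end")]
        assert cs.pair_boundaries(cands, 500, self.P) == [(100, 200)]

    def test_leading_end_ignored(self):
        cands = [self.cand(50, "end"), self.cand(100, "start"),
                 self.cand(200, "end")]
        assert cs.pair_boundaries(cands, 500, self.P) == [(100, 200)]

    def test_dangling_start_discarded_or_closed_at_track_end(self):
        cands = [self.cand(100, "start")]
        assert cs.pair_boundaries(cands, 500, self.P) == []
        closed = cs.pair_boundaries(
            cands, 500, cs.PeakCallParams(close_open_peaks=True)
        )
        assert closed == [(100, 500)]

    def test_min_peak_len_filters_short_intervals(self):
        cands = [self.cand(100, "start"), self.cand(104, "end")]
        kept = cs.pair_boundaries(cands, 500, cs.PeakCallParams(min_peak_len=5))
        dropped = cs.pair_boundaries(cands, 500, cs.PeakCallParams(min_peak_len=6))
        assert kept == [(100, 104)] and dropped == []


class TestDatasetMean:
    def test_grand_mean_over_strands(self):
        fwd = make_track([0, 10])
        rev = make_track([10, 20], strand="R")
        assert cs.dataset_mean_coverage([fwd, rev]) == 10.0

    def test_zero_track_and_permutation_invariance(self):
        z = make_track([0, 0, 0])
        assert cs.dataset_mean_coverage([z]) == 0.0
        a, b = make_track([1, 2, 3]), make_track([4, 5, 6], strand="R")
        assert cs.dataset_mean_coverage([a, b]) == cs.dataset_mean_coverage([b, a])

    def test_empty_list_is_domain_error(self):
        with pytest.raises(CrafdValidationError):
            cs.dataset_mean_coverage([])


class TestCallPeaks:
    def test_step_track_single_peak_survives_coverage_filter(self, step_track):
        peaks = cs.call_peaks(step_track, [], cs.PeakCallParams())
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.start, p.end) == (51, 120)
        assert p.mean_coverage == pytest.approx(20.0)
        assert p.peak_id == 1

    def test_global_coverage_filter_removes_locally_valid_peak(self):
        # small peak (2 on background 1) plus a distant huge plateau that
        # raises the dataset mean so the 20% filter removes the small peak
        v = np.full(1000, 1.0)
        v[100:160] = 2.0
        v[500:800] = 170.0
        t = make_track(v)
        peaks = cs.call_peaks(t, [], cs.PeakCallParams())
        ds_mean = cs.dataset_mean_coverage([t])
        assert 2.0 < 0.2 * ds_mean
        assert all(not (p.start >= 100 and p.end <= 200) for p in peaks)
        assert any(p.start >= 490 for p in peaks)  # the plateau itself is kept

    def test_scale_invariance_with_coscaled_pseudocount(self):
        rng = np.random.default_rng(7)
        t = random_count_track(rng, 1500)
        base = cs.call_peaks(t, [], cs.PeakCallParams(pseudocount_eps=0.1))
        for k in (0.01, 1000.0):
            scaled = make_track(t.values * k)
            params = cs.PeakCallParams(pseudocount_eps=0.1 * k)
            got = cs.call_peaks(scaled, [], params)
            assert [(p.start, p.end) for p in got] == [
                (p.start, p.end) for p in base
            ]

    def test_monotone_in_fold_and_coverage_thresholds(self):
        rng = np.random.default_rng(11)
        t = random_count_track(rng, 2000, n_steps=6)
        n_prev = None
        for f in (1.3, 1.5, 1.8, 2.5):
            n = len(cs.call_peaks(t, [], cs.PeakCallParams(boundary_fold_f=f)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n
        n_prev = None
        for c in (0.05, 0.2, 0.5, 1.0):
            n = len(cs.call_peaks(t, [], cs.PeakCallParams(min_cov_frac_c=c)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_peaks_disjoint_and_sorted(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            t = random_count_track(rng, 1000, n_steps=5)
            peaks = cs.call_peaks(t, [], cs.PeakCallParams())
            for a, b in zip(peaks, peaks[1:]):
                assert a.end < b.start

    def test_stranded_numbering_continues_across_strands(self, step_track):
        rev = make_track(step_track.values, strand="R")
        peaks = cs.call_peaks_stranded(step_track, rev)
        assert [p.peak_id for p in peaks] == [1, 2]
        assert [p.strand for p in peaks] == ["F", "R"]


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(202)
        params = cs.PeakCallParams()
        for _ in range(60):
            length = int(rng.integers(30, 1200))
            t = random_count_track(rng, length, n_steps=int(rng.integers(0, 5)),
                                   background=int(rng.integers(1, 40)))
            got = cs.scan_boundaries(t, params)
            exp = brute_boundaries(t.values, 5, 10, 1.5, 0.1)
            assert as_tuples(got) == exp
            got_peaks = cs.call_peaks(t, [], params)
            exp_peaks = brute_call_peaks(t.values, [])
            assert [(p.start, p.end, p.mean_coverage) for p in got_peaks] == exp_peaks

    def test_pairing_matches_brute_force_on_random_candidate_lists(self):
        rng = np.random.default_rng(303)
        for _ in range(200):
            n = int(rng.integers(0, 12))
            cands = sorted(
                (
                    cs.BoundaryCandidate(
                        int(rng.integers(1, 500)),
                        "start" if rng.integers(0, 2) == 0 else "end",
                        2.0,
                    )
                    for _ in range(n)
                ),
                key=lambda c: (c.position, 0 if c.kind == "start" else 1),
            )
            close = bool(rng.integers(0, 2))
            params = cs.PeakCallParams(close_open_peaks=close)
            got = cs.pair_boundaries(cands, 500, params)
            exp = brute_pair(
                [(c.position, c.kind, c.fold) for c in cands], 500,
                close_open=close,
            )
            assert got == exp


class TestSpikeInRecovery:
    def test_planted_peaks_recovered_with_tight_boundaries(self):
        """>=95% of 200 planted peaks (fold >= 2, width >= 30) recovered with
        each boundary within spacer+window nt of truth."""
        rng = np.random.default_rng(99)
        n_peaks, spacing = 200, 1000
        L = n_peaks * spacing
        lam = np.full(L, 50.0)
        truth = []
        for i in range(n_peaks):
            width = int(rng.integers(30, 151))
            start = i * spacing + int(rng.integers(100, spacing - width - 100))
            fold = float(rng.uniform(2.0, 6.0))
            lam[start : start + width] *= fold
            truth.append((start + 1, start + width))
        t = make_track(rng.poisson(lam).astype(float))
        peaks = cs.call_peaks(t, [], cs.PeakCallParams())
        tol = 10 + 5  # spacer_s + window_w
        recovered = 0
        for ts, te in truth:
            hit = any(
                abs(p.start - ts) <= tol and abs(p.end - te) <= tol
                for p in peaks
            )
            recovered += hit
        assert recovered / n_peaks >= 0.95
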