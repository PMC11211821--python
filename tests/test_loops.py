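"""Loop-statistic correctness against independent pixel-enumeration oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from mvhic.contacts import ContactMap
from mvhic.loops import (
    KernelSpec,
    LoopCallConfig,
    LoopSet,
    call_loops,
    call_loops_matrix,
    counts_for_statistics,
    default_kernels,
    expected_by_distance,
    kernel_lambda,
    loop_statistics,
)
from conftest import random_symmetric_counts

KINDS = ("donut", "lower_left", "horizontal", "vertical")


def oracle_footprint(kind, p, w):
    """Footprint offsets enumerated point by point, independent of KernelSpec."""
    out = []
    for di in range(-w, w + 1):
        for dj in range(-w, w + 1):
            cheb = max(abs(di), abs(dj))
            if kind == "donut":
                keep = cheb <= w and cheb > p and di != 0 and dj != 0
            elif kind == "lower_left":
                keep = 1 <= di <= w and -w <= dj <= -1 and not (di <= p and dj >= -p)
            elif kind == "horizontal":
                keep = abs(di) <= 1 and p < abs(dj) <= w
            else:
                keep = abs(dj) <= 1 and p < abs(di) <= w
            if keep:
                out.append((di, dj))
    return out


def oracle_lambda(counts, expected, i, j, kind, p, w):
    """Direct footprint-sum lambda, one pixel at a time."""
    obs_sum = 0.0
    exp_sum = 0.0
    for di, dj in oracle_footprint(kind, p, w):
        obs_sum += counts[i + di, j + dj]
        exp_sum += expected[abs((i + di) - (j + dj))]
    if exp_sum <= 0:
        return 0.0
    return expected[abs(i - j)] * obs_sum / exp_sum


class TestExpectedByDistance:
    def test_constant_diagonal(self):
        n = 30
        counts = np.fromfunction(lambda i, j: 7.0 + 0 * i, (n, n))
        exp = expected_by_distance(ContactMap("c", 10_000, counts))
        np.testing.assert_allclose(exp, 7.0)

    def test_toeplitz_distance_dependence(self, decay_map):
        exp = expected_by_distance(decay_map)
        d = np.arange(decay_map.n_bins)
        np.testing.assert_allclose(exp, 100.0 / (1.0 + d))

    def test_matches_brute_force_on_random_matrix(self, rng):
        counts = random_symmetric_counts(rng, 100)
        exp = expected_by_distance(ContactMap("c", 10_000, counts))
        for d in range(100):
            np.testing.assert_allclose(exp[d], np.diagonal(counts, d).mean())

    def test_zero_marginal_bins_excluded(self, rng):
        counts = random_symmetric_counts(rng, 40) + 1.0
        counts[5, :] = counts[:, 5] = 0.0
        exp = expected_by_distance(ContactMap("c", 10_000, counts))
        d = 3
        diag = [counts[i, i + d] for i in range(40 - d) if i != 5 and i + d != 5]
        np.testing.assert_allclose(exp[d], np.mean(diag))


class TestKernelLambda:
    def test_observed_equals_expected_gives_expected(self, decay_map):
        exp = expected_by_distance(decay_map)
        k = KernelSpec("donut")
        lam = kernel_lambda(decay_map, exp, 20, 40, k)
        assert lam == pytest.approx(exp[20])

    def test_matches_enumeration_oracle_on_random_instances(self, rng):
        """Exact agreement with the pixel-enumeration oracle, all kernels."""
        for _ in range(50):
            counts = random_symmetric_counts(rng, 50, lam=5.0)
            cmap = ContactMap("c", 10_000, counts)
            exp = expected_by_distance(cmap)
            kind = KINDS[rng.integers(0, 4)]
            p, w = 2, 5
            i = int(rng.integers(w, 50 - w))
            j = int(rng.integers(w, 50 - w))
            got = kernel_lambda(cmap, exp, i, j, KernelSpec(kind, p, w))
            want = oracle_lambda(counts, exp, i, j, kind, p, w)
            assert got == pytest.approx(want, rel=1e-12)

    def test_all_zero_neighborhood(self):
        cmap = ContactMap("c", 10_000, np.zeros((20, 20)))
        exp = expected_by_distance(cmap)
        assert kernel_lambda(cmap, exp, 8, 12, KernelSpec("donut")) == 0.0

    def test_footprint_outside_matrix_is_nan(self, decay_map):
        exp = expected_by_distance(decay_map)
        assert np.isnan(kernel_lambda(decay_map, exp, 2, 10, KernelSpec("donut")))

    def test_planted_bump_matches_oracle(self):
        n = 21
        counts = np.full((n, n), 4.0)
        counts[10, 10] += 10.0
        cmap = ContactMap("c", 10_000, counts)
        exp = expected_by_distance(cmap)
        k = KernelSpec("donut", 1, 2)
        got = kernel_lambda(cmap, exp, 10, 10, k)
        want = oracle_lambda(counts, exp, 10, 10, "donut", 1, 2)
        assert got == pytest.approx(want, rel=1e-12)


class TestLoopStatistics:
    def test_matrix_statistics_match_scalar_lambda(self, rng):
        """Convolution-based lambdas equal the per-pixel implementation."""
        counts = random_symmetric_counts(rng, 80, lam=6.0)
        cmap = ContactMap("c", 10_000, counts)
        stats_ = loop_statistics(cmap, band_bins=60)
        exp = stats_.expected
        ii, jj = np.nonzero(stats_.valid)
        sel = rng.choice(len(ii), size=40, replace=False)
        for k in default_kernels():
            for idx in sel:
                i, j = int(ii[idx]), int(jj[idx])
                want = kernel_lambda(cmap, exp, i, j, k)
                assert stats_.lam[k.kind][i, j] == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_poisson_tail_example(self):
        """observed = lambda = 4 gives ratio 1 and p = P(Poisson(4) >= 4)."""
        n = 40
        counts = np.full((n, n), 4.0)
        cmap = ContactMap("c", 10_000, counts)
        stats_ = loop_statistics(cmap, band_bins=30)
        i, j = 15, 25
        assert stats_.valid[i, j]
        assert stats_.ratio["donut"][i, j] == pytest.approx(1.0)
        assert stats_.pvalue["donut"][i, j] == pytest.approx(0.5665, abs=2e-4)
        # independent numeric tail: 1 - sum_{k<4} pmf(k; 4)
        want = 1.0 - sum(sps.poisson.pmf(k, 4.0) for k in range(4))
        assert stats_.pvalue["donut"][i, j] == pytest.approx(want, rel=1e-12)

    def test_zero_observed_has_pvalue_one_ratio_zero(self, rng):
        counts = random_symmetric_counts(rng, 60, lam=6.0)
        i, j = 20, 35
        counts[i, j] = counts[j, i] = 0.0
        stats_ = loop_statistics(ContactMap("c", 10_000, counts), band_bins=50)
        assert stats_.ratio["donut"][i, j] == 0.0
        assert stats_.pvalue["donut"][i, j] == pytest.approx(1.0)

    def test_pvalue_monotone_in_observed(self):
        """For fixed lambda the Poisson tail is non-increasing in observed."""
        lam = 6.3
        pv = sps.poisson.sf(np.arange(0, 30) - 1, lam)
        assert (np.diff(pv) <= 1e-15).all()

    def test_normalized_input_rejected(self, small_map):
        from mvhic.contacts import clamp_normalize

        with pytest.raises(ValueError, match="count-scale"):
            loop_statistics(clamp_normalize(small_map, 100.0))

    def test_counts_for_statistics_rescales(self, small_map):
        from mvhic.contacts import clamp_normalize

        norm = clamp_normalize(small_map, 255.0)
        back = counts_for_statistics(norm, cap=255.0)
        np.testing.assert_allclose(back.counts, np.rint(np.minimum(small_map.counts, 255.0)))


class TestCallLoops:
    def _stats_with(self, ratios, pvals, n=30, i=10, j=20):
        """Minimal LoopStatistics carrying one interesting pixel."""
        from mvhic.loops import LoopStatistics

        obs = np.full((n, n), 4.0)
        lam = {k: np.ones((n, n)) for k in KINDS}
        ratio = {k: np.zeros((n, n)) for k in KINDS}
        pvalue = {k: np.ones((n, n)) for k in KINDS}
        valid = np.zeros((n, n), dtype=bool)
        valid[i, j] = True
        for k, r, p in zip(KINDS, ratios, pvals):
            ratio[k][i, j] = r
            pvalue[k][i, j] = p
        return LoopStatistics("c", 10_000, obs, np.ones(n), lam, ratio, pvalue, valid)

    def test_all_thresholds_passed_is_called(self):
        stats_ = self._stats_with((2.0, 2.0, 1.6, 1.6), (0.01,) * 4)
        assert len(call_loops(stats_)) == 1

    def test_boundary_ratio_not_called(self):
        stats_ = self._stats_with((1.75, 2.0, 1.6, 1.6), (0.01,) * 4)
        assert len(call_loops(stats_)) == 0

    def test_raw_mode_uses_p_threshold(self):
        stats_ = self._stats_with((2.0, 2.0, 1.6, 1.6), (0.09, 0.09, 0.09, 0.11))
        cfg = LoopCallConfig(fdr_q=None)
        assert len(call_loops(stats_, cfg)) == 0
        stats_ok = self._stats_with((2.0, 2.0, 1.6, 1.6), (0.09,) * 4)
        assert len(call_loops(stats_ok, cfg)) == 1

    def test_combine_any(self):
        stats_ = self._stats_with((2.0, 0.0, 0.0, 0.0), (0.01, 1.0, 1.0, 1.0))
        assert len(call_loops(stats_, LoopCallConfig(combine="any"))) == 1
        assert len(call_loops(stats_, LoopCallConfig(combine="all"))) == 0

    def test_planted_loops_called_and_match_brute_force_thresholds(self, rng):
        """Raw-threshold calling equals exhaustive scan over valid pixels."""
        from mvhic.synthetic import SyntheticSpec, generate_pair

        _, high, truth = generate_pair(SyntheticSpec(n_bins=150, depth=8e5, n_loops=4,
                                                     loop_distance=(20, 80), seed=5))
        stats_ = loop_statistics(high, band_bins=100)
        cfg = LoopCallConfig(fdr_q=None)
        called = call_loops(stats_, cfg).pixels()
        thr = cfg.ratio_thresholds
        expect = set()
        for i, j in np.argwhere(stats_.valid):
            ok = all(stats_.pvalue[k][i, j] < 0.1 for k in KINDS)
            ok &= all(stats_.ratio[k][i, j] > thr[k] for k in KINDS)
            if ok:
                expect.add((int(i), int(j)))
        assert called == expect
        planted = set(zip(truth.bin_i, truth.bin_j))
        assert planted <= called

    def test_null_decay_matrix_calls_almost_nothing(self):
        """Deep pure-decay Poisson matrices yield < 1e-3 called fraction."""
        n, band = 300, 150
        idx = np.arange(n)
        d = np.abs(np.subtract.outer(idx, idx))
        lam = 3000.0 / (1.0 + d) + 30.0
        frac = []
        for s in range(10):
            rng = np.random.default_rng(s)
            upper = rng.poisson(np.triu(lam))
            counts = (upper + np.triu(upper, 1).T).astype(float)
            stats_ = loop_statistics(ContactMap("c", 10_000, counts), band_bins=band)
            called = call_loops(stats_)
            frac.append(len(called) / stats_.valid.sum())
        assert np.mean(frac) < 1e-3

    def test_ratio_calling_invariant_to_global_rescale(self, rng):
        """With p-value tests disabled, calls depend only on ratios."""
        from dataclasses import replace as dreplace

        from mvhic.synthetic import SyntheticSpec, generate_pair

        _, high, _ = generate_pair(SyntheticSpec(n_bins=120, depth=4e5, n_loops=3,
                                                 loop_distance=(20, 60), seed=2))
        cfg = LoopCallConfig(fdr_q=None, p_threshold=1.1)  # p test vacuous
        base = call_loops(loop_statistics(high, band_bins=100), cfg).pixels()
        scaled_counts = high.counts * 3.0
        scaled = ContactMap("c", 10_000, scaled_counts)
        got = call_loops(loop_statistics(scaled, band_bins=100), cfg).pixels()
        assert got == base

    def test_cluster_reduces_to_one_pixel_per_component(self):
        from mvhic.synthetic import SyntheticSpec, generate_pair

        _, high, truth = generate_pair(SyntheticSpec(n_bins=150, depth=8e5, n_loops=3,
                                                     loop_distance=(20, 80), seed=3))
        cfg = LoopCallConfig(cluster=True)
        called = call_loops_matrix(high, cfg)
        # clustered calls are pairwise non-adjacent (Chebyshev distance > 1)
        px = sorted(called.pixels())
        for a in px:
            for b in px:
                if a != b:
                    assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) > 1


class TestBedpe:
    def test_round_trip(self, tmp_path, rng):
        from mvhic.synthetic import SyntheticSpec, generate_pair

        _, high, _ = generate_pair(SyntheticSpec(n_bins=150, depth=8e5, n_loops=3,
                                                 loop_distance=(20, 80), seed=4))
        loops = call_loops_matrix(high, band_bins=100)
        path = tmp_path / "loops.bedpe"
        loops.to_bedpe(path)
        back = LoopSet.from_bedpe(path)
        assert back.pixels() == loops.pixels()
        assert back.resolution == loops.resolution
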