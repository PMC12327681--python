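import math

import numpy as np
import pytest

from msmce.ms_io import Run, Spectrum
from msmce.preprocess import (BinGrid, FeatureMatrix, aggregate_rt, bin_spectrum,
                              build_feature_matrix, filter_low_tic, tic,
                              tic_normalize)


def spec(mz, intensity, rt=0.0):
    return Spectrum(np.asarray(mz, float), np.asarray(intensity, float), rt)


class TestBinGrid:
    def test_n_bins(self):
        assert BinGrid(100.0, 1600.0, 0.1).n_bins == 15000

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            BinGrid(100.0, 100.0)

    def test_edges_length(self):
        g = BinGrid(0.0, 1.0, 0.25)
        assert np.allclose(g.edges, [0.0, 0.25, 0.5, 0.75])


class TestTic:
    def test_simple_sum(self):
        assert tic(spec([1.0, 2.0, 3.0], [1, 2, 3])) == 6.0

    def test_empty_spectrum(self):
        assert tic(spec([], [])) == 0.0

    def test_matches_sum_oracle(self, rng):
        mz = np.sort(rng.uniform(100, 500, size=1000))
        inten = rng.lognormal(5, 1, size=1000)
        s = Spectrum(mz, inten, 0.0)
        oracle = 0.0
        for v in inten:
            oracle += v
        assert tic(s) == pytest.approx(oracle, rel=1e-12)


class TestFilterLowTic:
    def test_threshold_boundary_retains_equal(self):
        # "below threshold" is strict: TIC == 1e4 is retained
        spectra = [spec([100.0], [9999.0], 0.0), spec([100.0], [10000.0], 1.0),
                   spec([100.0], [20000.0], 2.0)]
        run = Run(spectra, label="a", file_id="f")
        kept = filter_low_tic(run, threshold=1e4)
        assert len(kept.spectra) == 2
        assert [s.rt for s in kept.spectra] == [1.0, 2.0]

    def test_zero_threshold_keeps_all(self, make_run):
        run = make_run(n_spectra=5)
        assert len(filter_low_tic(run, threshold=0.0).spectra) == 5

    def test_matches_bruteforce_oracle(self, make_run):
        run = make_run(n_spectra=20)
        thr = float(np.median([tic(s) for s in run.spectra]))
        kept = filter_low_tic(run, threshold=thr)
        expected = []
        for s in run.spectra:  # independent loop-based filter
            if sum(s.intensity) >= thr:
                expected.append(s.rt)
        assert [s.rt for s in kept.spectra] == expected

    def test_idempotent(self, make_run):
        run = make_run(n_spectra=10)
        thr = float(np.median([tic(s) for s in run.spectra]))
        once = filter_low_tic(run, thr)
        twice = filter_low_tic(once, thr)
        assert once == twice

    def test_all_removed_raises_with_file_id(self, make_run):
        run = make_run(n_spectra=3, file_id="myfile")
        with pytest.raises(ValueError, match="myfile"):
            filter_low_tic(run, threshold=1e18)


class TestBinSpectrum:
    def test_two_peaks_same_bin(self):
        g = BinGrid(100.0, 1600.0, 0.1)
        v = bin_spectrum(spec([100.04, 100.07], [5.0, 7.0]), g)
        assert v[0] == 12.0
        assert v.sum() == 12.0

    def test_vector_length(self):
        g = BinGrid(100.0, 1600.0, 0.1)
        v = bin_spectrum(spec([200.0], [1.0]), g)
        assert v.shape == (15000,)

    def test_right_edge_excluded(self):
        g = BinGrid(100.0, 200.0, 0.1)
        v = bin_spectrum(spec([200.0], [5.0]), g)
        assert v.sum() == 0.0

    def test_intensity_conservation(self, rng):
        g = BinGrid(100.0, 500.0, 0.1)
        mz = np.sort(rng.uniform(50, 600, size=500))
        inten = rng.lognormal(3, 1, size=500)
        s = Spectrum(mz, inten, 0.0)
        in_range = inten[(mz >= 100.0) & (mz < 500.0)]
        assert bin_spectrum(s, g).sum() == pytest.approx(in_range.sum(), rel=1e-12)

    def test_matches_hand_binning_oracle(self, rng):
        g = BinGrid(100.0, 110.0, 0.1)
        mz = np.sort(rng.uniform(99, 111, size=200))
        inten = rng.random(200)
        s = Spectrum(mz, inten, 0.0)
        oracle = np.zeros(g.n_bins)
        for m, i in zip(s.mz, s.intensity):  # per-peak loop with half-open check
            b = math.floor((m - 100.0) / 0.1)
            if 0 <= b < g.n_bins and 100.0 <= m < 110.0:
                oracle[b] += i
        assert np.allclose(bin_spectrum(s, g), oracle, rtol=1e-12, atol=0)


class TestAggregateRt:
    def test_mean_of_two(self):
        out = aggregate_rt([(0.0, np.array([4.0])), (1.0, np.array([6.0]))], 10.0)
        assert len(out) == 1 and out[0][0] == 5.0

    def test_single_spectrum_unchanged(self):
        v = np.array([1.0, 2.0, 3.0])
        out = aggregate_rt([(3.0, v)], 10.0)
        assert np.array_equal(out[0], v)

    def test_half_open_window_assignment(self):
        vecs = [(0.0, np.array([1.0])), (3.0, np.array([2.0])),
                (10.0, np.array([3.0])), (19.9, np.array([4.0]))]
        out = aggregate_rt(vecs, 10.0)
        assert len(out) == 2
        assert out[0][0] == 1.5  # rt 0 and 3
        assert out[1][0] == 3.5  # rt 10.0 and 19.9

    def test_empty_input(self):
        assert aggregate_rt([], 10.0) == []

    def test_identical_vectors_mean_is_identity(self, rng):
        v = rng.random(50)
        out = aggregate_rt([(float(i), v.copy()) for i in range(5)], 10.0)
        assert len(out) == 1
        assert np.allclose(out[0], v)

    def test_windows_anchored_at_first_rt(self):
        # same data shifted in time yields identical output
        vecs = [(2.0, np.array([1.0])), (5.0, np.array([3.0]))]
        shifted = [(rt + 100.0, v) for rt, v in vecs]
        out1, out2 = aggregate_rt(vecs, 10.0), aggregate_rt(shifted, 10.0)
        assert all(np.array_equal(a, b) for a, b in zip(out1, out2))

    def test_matches_window_oracle(self, rng):
        rts = np.sort(rng.uniform(0, 100, size=40))
        vecs = [(float(t), rng.random(8)) for t in rts]
        out = aggregate_rt(vecs, 10.0)
        groups = {}
        for t, v in vecs:
            groups.setdefault(int((t - rts[0]) // 10.0), []).append(v)
        oracle = [np.mean(groups[k], axis=0) for k in sorted(groups)]
        assert len(out) == len(oracle)
        assert all(np.allclose(a, b) for a, b in zip(out, oracle))


class TestBuildFeatureMatrix:
    def test_lcms_row_bookkeeping(self, make_run):
        r1 = make_run(n_spectra=4, label="a", file_id="f1")
        r2 = make_run(n_spectra=4, label="b", file_id="f2")
        # rts 0..3 in one 10 s window each -> 1 row per run with window=2
        g = BinGrid(100.0, 500.0, 0.1)
        fm = build_feature_matrix([r1, r2], g, mode="lcms", window=2.0)
        assert fm.n_instances == 4
        assert fm.file_ids == ["f1", "f1", "f2", "f2"]
        assert fm.labels == ["a", "a", "b", "b"]

    def test_spidermass_row_count(self):
        spectra = [spec([100.0], [v], rt=float(i))
                   for i, v in enumerate([5e3, 2e4, 3e4, 9e3, 1e4])]
        run = Run(spectra, label="a", file_id="f")
        g = BinGrid(50.0, 200.0, 0.1)
        fm = build_feature_matrix([run], g, mode="spidermass", tic_threshold=1e4)
        assert fm.n_instances == 3

    def test_lcms_row_bounded_by_max_tic(self, make_run):
        run = make_run(n_spectra=10)
        g = BinGrid(100.0, 500.0, 0.1)
        fm = build_feature_matrix([run], g, mode="lcms", window=10.0)
        max_tic = max(tic(s) for s in run.spectra)
        assert fm.values.sum(axis=1).max() <= max_tic + 1e-9

    def test_unknown_mode(self, make_run):
        with pytest.raises(ValueError, match="mode"):
            build_feature_matrix([make_run()], BinGrid(100, 500), mode="foo")

    def test_csv_round_trip(self, make_run, tmp_path):
        g = BinGrid(100.0, 500.0, 0.5)
        fm = build_feature_matrix([make_run(n_spectra=4)], g, mode="lcms",
                                  window=2.0)
        fm.to_csv(tmp_path / "m.csv")
        back = FeatureMatrix.from_csv(tmp_path / "m.csv", grid=g)
        assert np.allclose(back.values, fm.values)
        assert back.labels == fm.labels
        assert back.file_ids == fm.file_ids


class TestTicNormalize:
    def test_simple_row(self):
        g = BinGrid(0.0, 0.2, 0.1)
        fm = FeatureMatrix(np.array([[2.0, 2.0]]), ["a"], ["f"], g)
        assert np.allclose(tic_normalize(fm).values, [[0.5, 0.5]])

    def test_zero_row_untouched_with_warning(self, caplog):
        g = BinGrid(0.0, 0.2, 0.1)
        fm = FeatureMatrix(np.array([[0.0, 0.0], [1.0, 3.0]]), ["a", "a"],
                           ["f", "f"], g)
        with caplog.at_level("WARNING"):
            out = tic_normalize(fm)
        assert np.array_equal(out.values[0], [0.0, 0.0])
        assert "all-zero" in caplog.text

    def test_rows_sum_to_one(self, rng):
        g = BinGrid(0.0, 5.0, 0.1)
        vals = rng.random((20, g.n_bins))
        fm = FeatureMatrix(vals, ["a"] * 20, ["f"] * 20, g)
        sums = tic_normalize(fm).values.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_idempotent_on_nonzero_rows(self, rng):
        g = BinGrid(0.0, 1.0, 0.1)
        vals = rng.random((5, g.n_bins)) + 0.1
        fm = FeatureMatrix(vals, ["a"] * 5, ["f"] * 5, g)
        once = tic_normalize(fm)
        twice = tic_normalize(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)
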