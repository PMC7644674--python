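"""Five-step preprocessing: transforms, SNIP, peaks, warping, alignment."""

import numpy as np
import pytest

from speclearn.binning import BinGrid, SpectraDataset
from speclearn.preprocess import (
    ConventionalPreprocessor,
    PeakList,
    PreprocessConfig,
    WarpModel,
    align_by_class,
    apply_warp,
    detect_peaks_mad,
    fit_cubic_warp,
    log_transform,
    match_reference_peaks,
    preprocess_pipeline,
    snip_baseline,
    tic_normalize,
)


class TestLogTransform:
    def test_zero_maps_to_zero(self):
        assert log_transform(np.zeros(4), offset=1.0).tolist() == [0, 0, 0, 0]

    def test_closed_form(self):
        out = log_transform(np.array([0.0, np.e - 1]), offset=1.0)
        assert np.allclose(out, [0.0, 1.0])

    def test_monotone(self, rng):
        x = np.sort(rng.uniform(0, 50, 30))
        out = log_transform(x)
        assert np.all(np.diff(out) >= 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(np.array([-0.1, 1.0]))


def _naive_snip(x, iterations, lls):
    """Independent scalar-loop SNIP oracle (same definition, no vectorising)."""
    if lls:
        y = [np.log(np.log(np.sqrt(v + 1) + 1) + 1) for v in x]
    else:
        y = list(x)
    n = len(y)
    for m in range(1, iterations + 1):
        z = list(y)
        for i in range(m, n - m):
            z[i] = min(y[i], (y[i - m] + y[i + m]) / 2)
        y = z
    if lls:
        y = [(np.exp(np.exp(v) - 1) - 1) ** 2 - 1 for v in y]
    return np.minimum(np.array(y), x)


class TestSnip:
    def test_constant_signal_is_its_own_baseline(self):
        x = np.full(50, 7.0)
        base = snip_baseline(x, 10)
        assert np.allclose(base, 7.0)

    def test_spike_on_flat_baseline(self):
        x = np.full(200, 10.0)
        x[100:103] += 100.0
        base = snip_baseline(x, 20)
        residual = x - base
        assert residual[101] >= 90.0  # spike survives
        away = np.r_[base[:80], base[130:]]
        assert np.all(np.abs(away - 10.0) <= 0.5)  # baseline flat off-spike

    @pytest.mark.parametrize("lls", [True, False])
    def test_matches_naive_oracle(self, rng, lls):
        x = rng.uniform(0, 5, 60) + 3
        x[20] += 30
        got = snip_baseline(x, 8, lls=lls)
        want = _naive_snip(x, 8, lls)
        assert np.allclose(got, want, atol=1e-10)

    def test_baseline_never_exceeds_signal(self, rng):
        x = rng.uniform(0, 100, 300)
        base = snip_baseline(x, 40)
        assert np.all(base <= x + 1e-12)

    def test_too_many_iterations_rejected(self):
        with pytest.raises(ValueError):
            snip_baseline(np.ones(10), 5)


class TestTic:
    def test_proportions(self):
        assert np.allclose(tic_normalize(np.array([2.0, 3.0, 5.0])), [0.2, 0.3, 0.5])

    def test_sums_to_one_and_scale_invariant(self, rng):
        x = rng.uniform(0, 9, 40)
        out = tic_normalize(x)
        assert abs(out.sum() - 1.0) < 1e-12
        assert np.allclose(tic_normalize(3.7 * x), out)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            tic_normalize(np.zeros(5))


class TestMadPeaks:
    def test_constant_spectrum_has_no_peaks(self):
        assert len(detect_peaks_mad(np.full(50, 3.0))) == 0

    def test_single_spike(self):
        x = np.zeros(300)
        x[100] = 1.0
        peaks = detect_peaks_mad(x, mad_k=3, halfwindow=5)
        assert peaks.apex_mz.tolist() == [100.0]

    def test_hand_computed_toy_vector(self):
        # median=1, MAD=0 -> noise 0; strict maxima of +-2 windows: 2 and 6
        x = np.array([1, 1, 9, 1, 1, 1, 7, 1], dtype=float)
        peaks = detect_peaks_mad(x, mad_k=3, halfwindow=2)
        assert peaks.apex_mz.tolist() == [2.0, 6.0]
        assert peaks.apex_intensity.tolist() == [9.0, 7.0]

    def test_threshold_suppresses_small_maxima(self, rng):
        x = rng.normal(5, 1, 500)
        x[250] = 50.0
        peaks = detect_peaks_mad(x, mad_k=10, halfwindow=10)
        assert 250.0 in peaks.apex_mz.tolist()
        assert len(peaks) <= 3

    def test_bad_halfwindow(self):
        with pytest.raises(ValueError):
            detect_peaks_mad(np.ones(5), halfwindow=10)


class TestMatching:
    def test_identical_lists_fully_matched(self):
        p = PeakList([1.0, 2.0, 3.0], [1, 1, 1], [5, 5, 5])
        pairs = match_reference_peaks(p, p, 0.5)
        assert pairs == [(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]

    def test_disjoint_beyond_tolerance_empty(self):
        a = PeakList([1.0], [1], [5])
        b = PeakList([10.0], [1], [5])
        assert match_reference_peaks(a, b, 0.5) == []

    def test_closer_candidate_wins(self):
        obs = PeakList([1.0, 1.3], [1, 1], [5, 5])
        ref = PeakList([1.1], [1], [5])
        assert match_reference_peaks(obs, ref, 0.5) == [(1.0, 1.1)]


class TestWarp:
    def test_identity_recovered(self):
        xs = np.linspace(100, 1000, 12)
        pairs = [(x, x) for x in xs]
        model = fit_cubic_warp(pairs)
        assert np.allclose(model.alpha, (0, 1, 0, 0), atol=1e-9)

    def test_generating_coefficients_recovered(self):
        """Closed-form weighted-LS oracle in extended precision."""
        alpha = np.array([5.0, 1.001, 1e-6, -1e-10])
        xs = np.linspace(100, 1900, 10)
        ys = alpha[0] + alpha[1] * xs + alpha[2] * xs**2 + alpha[3] * xs**3
        model = fit_cubic_warp(list(zip(xs, ys)))
        assert np.allclose(model.alpha, alpha, rtol=1e-6)
        # independent oracle: normal equations in long double
        V = np.vander(xs.astype(np.longdouble), 4, increasing=True)
        beta = np.linalg.solve((V.T @ V).astype(float), (V.T @ ys.astype(np.longdouble)).astype(float))
        assert np.allclose(model.alpha, beta, rtol=1e-5)

    def test_weights_respected(self):
        # heavily weighting a subset forces near-interpolation of it
        xs = np.linspace(0, 9, 10) + 100
        ys = xs.copy()
        ys[-1] += 5.0  # outlier
        w = np.ones(10)
        w[-1] = 1e-9
        model = fit_cubic_warp(list(zip(xs, ys)), weights=w)
        # the down-weighted outlier barely deflects the warp
        assert np.max(np.abs(model(xs[:-1]) - xs[:-1])) < 1e-3

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_cubic_warp([(1, 1), (2, 2), (3, 3)])

    def test_apply_identity_and_shift(self):
        mz = np.linspace(100, 110, 50)
        inten = np.random.default_rng(0).uniform(0, 1, 50)
        out_mz, out_i = apply_warp(mz, inten, WarpModel.identity())
        assert np.allclose(out_mz, mz) and np.allclose(out_i, inten)
        out_mz, _ = apply_warp(mz, inten, WarpModel((1.0, 1.0, 0.0, 0.0)))
        assert np.allclose(out_mz, mz + 1.0)

    def test_round_trip_with_inverse_fit(self):
        xs = np.linspace(100, 200, 20)
        warp = WarpModel((2.0, 0.98, 1e-5, 0.0))
        ys = warp(xs)
        inverse = fit_cubic_warp(list(zip(ys, xs)))
        assert np.allclose(inverse(ys), xs, atol=1e-6)


def _shifted_class_dataset(shift, n=6, seed=0):
    """One class whose members drift linearly over a ``shift``-Da range."""
    grid = BinGrid(100.0, 140.0, 0.1)
    rng = np.random.default_rng(seed)
    # peak apexes at bin centers so detection is not edge-ambiguous
    peaks = np.array([105.05, 112.05, 118.05, 126.05, 133.05])
    amps = np.array([3.0, 5.0, 2.0, 4.0, 3.5])
    deltas = np.linspace(-shift / 2, shift / 2, n) if shift else np.zeros(n)
    rows = []
    centers = grid.centers
    for i in range(n):
        row = np.zeros(grid.n_bins)
        for p, a in zip(peaks + deltas[i], amps):
            row += a * np.exp(-0.5 * ((centers - p) / 0.2) ** 2)
        # strictly positive noise: breaks exact bin ties a real trace never has
        row += rng.uniform(0.001, 0.02, grid.n_bins)
        rows.append(row)
    return SpectraDataset(np.stack(rows), np.zeros(n, dtype=int), ["c"], grid), peaks


class TestAlignment:
    def test_aligned_class_warps_stay_identity(self):
        ds, _ = _shifted_class_dataset(0.0)
        cfg = PreprocessConfig(halfwindow=10, match_tolerance=1.0)
        _, _, warps = align_by_class(ds, cfg)
        assert warps  # anchors were found
        for warp in warps.values():
            assert np.linalg.norm(np.array(warp.alpha) - (0, 1, 0, 0)) < 1e-3

    def test_simulated_shift_recovered(self):
        """Members drifting over a 0.5 Da range re-align to < 0.1 Da offset."""
        ds, peaks = _shifted_class_dataset(0.5)
        cfg = PreprocessConfig(halfwindow=10, match_tolerance=1.0)
        aligned, refs, warps = align_by_class(ds, cfg)
        assert len(warps) == ds.n_spectra
        centers = ds.grid.centers
        offsets = []
        for row in aligned.matrix:
            found = detect_peaks_mad(row, 3, 10, mz=centers)
            for p in peaks:  # offset of each true peak's nearest found apex
                offsets.append(np.min(np.abs(found.apex_mz - p)))
        before = []
        for row in ds.matrix:
            found = detect_peaks_mad(row, 3, 10, mz=centers)
            for p in peaks:
                before.append(np.min(np.abs(found.apex_mz - p)))
        assert np.mean(offsets) < 0.1
        assert np.mean(offsets) <= np.mean(before)

    def test_alignment_preserves_count_and_tic(self):
        ds, _ = _shifted_class_dataset(0.4)
        aligned, _, _ = align_by_class(ds, PreprocessConfig(halfwindow=10, match_tolerance=1.0))
        assert aligned.n_spectra == ds.n_spectra
        assert np.allclose(aligned.matrix.sum(axis=1), ds.matrix.sum(axis=1), rtol=1e-9)


class TestPipeline:
    def test_noise_free_single_class_features_at_template_peaks(self):
        ds, peaks = _shifted_class_dataset(0.0)
        cfg = PreprocessConfig(snip_iterations=20, halfwindow=10, match_tolerance=1.0)
        features, bins = preprocess_pipeline(ds, cfg)
        assert features.shape[0] == ds.n_spectra
        assert features.shape[1] >= len(peaks)
        assert np.all(features >= 0)
        centers = ds.grid.centers[bins]
        for p in peaks:
            assert np.min(np.abs(centers - p)) < 0.3

    def test_pipeline_deterministic(self):
        ds, _ = _shifted_class_dataset(0.3)
        cfg = PreprocessConfig(halfwindow=10, match_tolerance=1.0)
        f1, b1 = preprocess_pipeline(ds, cfg)
        f2, b2 = preprocess_pipeline(ds, cfg)
        assert np.array_equal(b1, b2) and np.array_equal(f1, f2)

    def test_estimator_transform_matches_feature_bins(self):
        ds, _ = _shifted_class_dataset(0.0)
        prep = ConventionalPreprocessor(snip_iterations=20, halfwindow=10,
                                        match_tolerance=1.0)
        feats = prep.fit_transform(ds, ds.labels)
        new = prep.transform(ds.matrix[:2])
        assert new.shape == (2, feats.shape[1])
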