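"""Extraction tests: PCA, scores, SAM, moving window, late-time, SSC."""

import warnings

import numpy as np
import pytest

from petss.containers import (
    Component,
    DegenerateInputError,
    FrequencyWindows,
    ParameterError,
    SinogramSeries,
    SurrogateSignal,
)
from petss.extract import (
    ConventionalPCAExtractor,
    FeatureScorer,
    LateTimeExtractor,
    NoCandidateError,
    ScoreSelectCombineExtractor,
    WindowSchedule,
    apply_component,
    combine,
    compute_psd,
    conventional_extract,
    conventional_score,
    estimate_resp_window,
    frequency_score,
    late_time_extract,
    moving_window_extract,
    pca_decompose,
    sam_signed_mask,
    score_select,
)

from conftest import rank1_series


def sinusoid(freq_hz, n=512, fs=2.0, amp=1.0, phase=0.0):
    t = np.arange(n) / fs
    return SurrogateSignal(amp * np.sin(2 * np.pi * freq_hz * t + phase), fs)


class TestPCADecompose:
    def test_rank1_recovery(self):
        series, w, pattern = rank1_series()
        comps = pca_decompose(series, 1)
        sig = apply_component(comps[0], series)
        assert abs(np.corrcoef(sig.values, w)[0, 1]) > 1 - 1e-10

    def test_components_orthonormal(self):
        series, *_ = rank1_series(noise=0.5)
        comps = pca_decompose(series, 5)
        W = np.stack([c.weights.ravel() for c in comps])
        assert np.allclose(W @ W.T, np.eye(5), atol=1e-10)

    def test_matches_bruteforce_eigendecomposition(self):
        # independent oracle: eigh of the 3x3 bin covariance
        rng = np.random.default_rng(5)
        X = rng.random((16, 3))
        series = SinogramSeries(
            X.T.reshape(3, 1, 1, 1, 16), transformed=True
        )
        comps = pca_decompose(series, 3)
        C = np.cov(X.T, bias=True)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        for comp, idx in zip(comps, order):
            v = evecs[:, idx]
            dot = abs(float(comp.weights.ravel() @ v))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_surplus_components_dropped_with_warning(self):
        series, *_ = rank1_series()
        with pytest.warns(UserWarning, match="rank"):
            comps = pca_decompose(series, 10)
        assert len(comps) == 1

    def test_constant_series_rejected(self):
        s = SinogramSeries(np.ones((4, 1, 1, 1, 10)), transformed=True)
        with pytest.raises(DegenerateInputError):
            pca_decompose(s)

    def test_one_frame_rejected(self):
        s = SinogramSeries(np.ones((4, 1, 1, 1, 1)), transformed=True)
        with pytest.raises(ParameterError):
            pca_decompose(s)


class TestApplyComponent:
    def test_hand_example(self):
        # 2 bins, frames (3,1) and (0,2); PC (1,-1) -> W = (2,-2)
        data = np.array([[3.0, 0.0], [1.0, 2.0]]).reshape(2, 1, 1, 1, 2)
        series = SinogramSeries(data, transformed=True)
        comp = Component(np.array([1.0, -1.0]).reshape(2, 1, 1, 1))
        assert np.allclose(apply_component(comp, series).values, [2.0, -2.0])

    def test_all_ones_gives_frame_sums(self):
        rng = np.random.default_rng(0)
        data = rng.random((3, 2, 2, 1, 6))
        series = SinogramSeries(data, transformed=True)
        comp = Component(np.ones((3, 2, 2, 1)))
        assert np.allclose(
            apply_component(comp, series).values, data.sum(axis=(0, 1, 2, 3))
        )

    def test_linearity(self):
        series, *_ = rank1_series(noise=0.3)
        shape = series.spatial_shape
        rng = np.random.default_rng(3)
        w1, w2 = rng.random(shape), rng.random(shape)
        a, b = 2.5, -1.25
        lhs = apply_component(Component(a * w1 + b * w2), series).values
        rhs = a * apply_component(Component(w1), series).values \
            + b * apply_component(Component(w2), series).values
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        series, *_ = rank1_series()
        with pytest.raises(ParameterError):
            apply_component(Component(np.ones((3, 1, 1, 1))), series)


class TestSpectra:
    def test_psd_peak_at_signal_frequency(self):
        psd = compute_psd(sinusoid(0.25))
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(0.25, abs=1e-9)

    def test_constant_signal_zero_spectrum(self):
        psd = compute_psd(SurrogateSignal(np.full(64, 2.0)))
        assert np.allclose(psd.power, 0.0)

    def test_two_tone_equal_peaks(self):
        t = np.arange(800) / 2.0
        x = np.sin(2 * np.pi * 0.05 * t) + np.sin(2 * np.pi * 0.25 * t)
        psd = compute_psd(SurrogateSignal(x))
        p1 = psd.power[np.argmin(np.abs(psd.freqs - 0.05))]
        p2 = psd.power[np.argmin(np.abs(psd.freqs - 0.25))]
        assert p1 == pytest.approx(p2, rel=0.05)

    def test_conventional_score_prefers_respiratory_band(self):
        in_band = conventional_score(sinusoid(0.25))
        out_band = conventional_score(sinusoid(0.02))
        assert in_band > out_band
        assert conventional_score(SurrogateSignal(np.zeros(64))) == 0.0

    def test_conventional_score_scales_linearly(self):
        s1 = conventional_score(sinusoid(0.25, amp=1.0))
        s3 = conventional_score(sinusoid(0.25, amp=3.0))
        assert s3 == pytest.approx(3 * s1, rel=1e-9)


class TestFrequencyScore:
    def test_flat_spectrum_scores_one(self):
        # an impulse has a flat magnitude spectrum
        x = np.zeros(512)
        x[200] = 1.0
        score = frequency_score(SurrogateSignal(x), FrequencyWindows())
        assert score == pytest.approx(1.0, rel=0.05)

    def test_respiratory_tone_beats_kinetic_tone(self):
        rng = np.random.default_rng(0)
        noise = 0.05 * rng.standard_normal(512)
        resp = sinusoid(0.25).values + noise
        kin = sinusoid(0.02).values + noise
        win = FrequencyWindows()
        s_resp = frequency_score(SurrogateSignal(resp), win)
        s_kin = frequency_score(SurrogateSignal(kin), win)
        assert s_resp > 1.0 > s_kin or s_resp > s_kin
        assert s_resp / s_kin > 10

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = sinusoid(0.25).values + 0.1 * rng.standard_normal(512)
        a = frequency_score(SurrogateSignal(x), FrequencyWindows())
        b = frequency_score(SurrogateSignal(10 * x), FrequencyWindows())
        assert a == pytest.approx(b, rel=1e-9)

    def test_feature_scorer_maps_to_unit_interval(self):
        win = FrequencyWindows()
        scorer = FeatureScorer(win)
        rng = np.random.default_rng(2)
        x = np.zeros(512)
        x[100] = 1.0
        assert scorer(SurrogateSignal(x)) == pytest.approx(0.5, abs=0.05)
        resp = sinusoid(0.25).values + 0.05 * rng.standard_normal(512)
        assert 0.5 < scorer(SurrogateSignal(resp)) <= 1.0


class TestEstimateRespWindow:
    def test_pure_tone_centred(self):
        win = estimate_resp_window(sinusoid(0.25, n=1024))
        lo, hi = win.respiratory
        assert (lo + hi) / 2 == pytest.approx(0.25, abs=2 / 512)

    def test_two_tone_centre_between_peaks(self):
        t = np.arange(2048) / 2.0
        x = np.sin(2 * np.pi * 0.2 * t) + np.sin(2 * np.pi * 0.3 * t)
        win = estimate_resp_window(SurrogateSignal(x))
        lo, hi = win.respiratory
        # centroid accuracy limited by leakage skirts of the two tones
        assert (lo + hi) / 2 == pytest.approx(0.25, abs=0.02)
        assert lo < 0.2 + 0.02 and hi > 0.3 - 0.02

    def test_white_noise_moments(self):
        # flat spectrum on [0,1]: centroid 0.5, std 1/sqrt(12)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2**14)
        win = estimate_resp_window(SurrogateSignal(x))
        lo, hi = win.respiratory
        assert (lo + hi) / 2 == pytest.approx(0.5, abs=0.02)
        assert (hi - lo) / 2 == pytest.approx(0.5 / np.sqrt(12), abs=0.02)

    def test_windows_partition_axis(self):
        win = estimate_resp_window(sinusoid(0.25, n=1024))
        assert win.kinetic[1] == win.respiratory[0]
        assert win.respiratory[1] == win.noise[0]


class TestSAM:
    def _two_population_series(self, flip_half=False, n=256, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / 2.0
        resp = np.sin(2 * np.pi * 0.25 * t)
        data = np.zeros((12, 1, 1, 1, n))
        signs = np.ones(8)
        if flip_half:
            signs[4:] = -1.0
        for b in range(8):  # oscillating bins
            data[b, 0, 0, 0] = 10 + signs[b] * resp + 0.05 * rng.standard_normal(n)
        for b in range(8, 12):  # static bins
            data[b, 0, 0, 0] = 10 + 0.05 * rng.standard_normal(n)
        return SinogramSeries(data, transformed=True), resp

    def test_oscillating_bins_included_static_excluded(self):
        series, _ = self._two_population_series()
        comp = sam_signed_mask(series)
        w = comp.weights.ravel()
        assert np.all(w[:8] == 1.0)
        assert np.all(w[8:] == 0.0)

    def test_phase_negated_bins_get_negative_weight(self):
        series, resp = self._two_population_series(flip_half=True)
        comp = sam_signed_mask(series)
        w = comp.weights.ravel()
        assert np.all(w[:4] == -w[4:8])
        sig = apply_component(comp, series)
        assert abs(np.corrcoef(sig.values, resp)[0, 1]) > 0.99

    def test_static_series_rejected(self):
        rng = np.random.default_rng(1)
        data = 10 + 0.05 * rng.standard_normal((6, 1, 1, 1, 128))
        with pytest.raises(DegenerateInputError):
            sam_signed_mask(SinogramSeries(data, transformed=True))


class TestMovingWindow:
    def test_common_trace_recovered(self):
        series, w, _ = rank1_series(n_frames=512, noise=0.02)
        sched = WindowSchedule(np.full(512, 64))
        sig = moving_window_extract(series, sched)
        r = np.corrcoef(sig.values, w)[0, 1]
        assert abs(r) > 0.99

    def test_single_full_window_equals_conventional_first_pc(self):
        series, *_ = rank1_series(n_frames=128, noise=0.05)
        sched = WindowSchedule(np.full(128, 128))
        mw = moving_window_extract(series, sched).values
        pc1 = apply_component(pca_decompose(series, 1)[0], series).values
        assert np.allclose(mw, pc1, atol=1e-9) or np.allclose(mw, -pc1, atol=1e-9)

    def test_alternate_sign_flips_are_corrected(self):
        series, w, _ = rank1_series(n_frames=512, noise=0.02)
        sched = WindowSchedule(np.full(512, 64))

        calls = {"n": 0}

        def flipping_engine(window):
            comp = pca_decompose(window, 1)[0]
            sign = -1.0 if calls["n"] % 2 else 1.0
            calls["n"] += 1
            return sign * apply_component(comp, window).values

        ref = moving_window_extract(series, sched, engine="pca")
        flipped = moving_window_extract(series, sched, engine=flipping_engine)
        agree = np.allclose(flipped.values, ref.values, atol=1e-9)
        agree_neg = np.allclose(flipped.values, -ref.values, atol=1e-9)
        assert agree or agree_neg

    def test_schedule_validates_window_floor(self):
        with pytest.raises(ParameterError):
            WindowSchedule(np.array([2, 2, 2]))


class TestLateTime:
    def test_cutoff_zero_equals_conventional(self, preprocessed_small_phantom):
        proc, _ = preprocessed_small_phantom
        late = late_time_extract(proc, cutoff_fraction=0.0)
        conv = conventional_extract(proc)
        r = np.corrcoef(late.values, conv.values)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_short_late_interval_rejected(self, preprocessed_small_phantom):
        proc, _ = preprocessed_small_phantom
        with pytest.raises(ParameterError):
            late_time_extract(proc, cutoff_fraction=0.95)

    def test_component_support_is_late_frames(self, preprocessed_small_phantom):
        proc, _ = preprocessed_small_phantom
        est = LateTimeExtractor(cutoff_fraction=0.62).fit(proc)
        start, stop = est.component_.time_support
        assert start == int(0.62 * proc.n_frames)
        assert stop == proc.n_frames


class TestScoreSelect:
    def _components(self, series, n=3):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return pca_decompose(series, n)

    def test_threshold_and_ordering(self):
        series, *_ = rank1_series(noise=0.5)
        comps = self._components(series, 3)
        fixed = iter([0.2, 0.9, 0.5])
        scores = {id(c): s for c, s in zip(comps, [0.2, 0.9, 0.5])}
        scorer_calls = []

        def scorer(sig):
            # deterministic scores keyed by call order
            scorer_calls.append(1)
            return [0.2, 0.9, 0.5][len(scorer_calls) - 1]

        out = score_select(comps, series, scorer, threshold=0.3)
        assert [c.score for c in out] == [0.9, 0.5]

    def test_all_below_threshold_rejected(self):
        series, *_ = rank1_series(noise=0.5)
        comps = self._components(series, 2)
        with pytest.raises(NoCandidateError):
            score_select(comps, series, lambda s: 0.0, threshold=0.5)

    def test_ties_keep_original_order(self):
        series, *_ = rank1_series(noise=0.5)
        comps = self._components(series, 3)
        out = score_select(comps, series, lambda s: 1.0, threshold=0.0)
        assert [id(c) for c in out] == [id(c) for c in comps]


class TestCombine:
    def test_duplicate_component_not_added(self):
        # scale-invariant scorer cannot strictly improve on a duplicate
        series, *_ = rank1_series(noise=0.1)
        win = FrequencyWindows()
        scorer = lambda sig: frequency_score(sig, win)
        comp = pca_decompose(series, 1)[0]
        dup = Component(comp.weights.copy())
        out = combine([comp, dup], series, scorer)
        assert np.allclose(out.weights, comp.weights)

    def test_noise_component_never_accepted_and_score_never_drops(self):
        rng = np.random.default_rng(4)
        series, w, pattern = rank1_series(n_frames=512, noise=0.05, seed=4)
        win = FrequencyWindows()
        scorer = lambda sig: frequency_score(sig, win)
        clean = pca_decompose(series, 1)[0]
        base_score = scorer(apply_component(clean, series))
        noise_comp = Component(rng.standard_normal(clean.weights.shape))
        out = combine([clean, noise_comp], series, scorer)
        assert out.score >= base_score
        sig_out = apply_component(out, series).values
        sig_clean = apply_component(clean, series).values
        r = np.corrcoef(sig_out, sig_clean)[0, 1]
        assert abs(r) > 0.999

    def test_sign_symmetric_in_inputs(self):
        series, *_ = rank1_series(n_frames=512, noise=0.3, seed=6)
        win = FrequencyWindows()
        scorer = lambda sig: frequency_score(sig, win)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comps = pca_decompose(series, 4)
        out_pos = combine([Component(c.weights.copy()) for c in comps],
                          series, scorer)
        out_neg = combine([Component(-c.weights.copy()) for c in comps],
                          series, scorer)
        same = np.allclose(out_pos.weights, out_neg.weights, atol=1e-9)
        opposite = np.allclose(out_pos.weights, -out_neg.weights, atol=1e-9)
        assert same or opposite


class TestExtractorsEndToEnd:
    def test_conventional_recovers_motion_without_kinetics(self):
        # phantom-free construction: stationary respiration only
        series, w, _ = rank1_series(n_frames=600, noise=0.05, seed=1)
        sig = conventional_extract(series)
        assert abs(np.corrcoef(sig.values, w)[0, 1]) > 0.95

    def test_ssc_runs_on_phantom_and_tracks_truth(self, preprocessed_small_phantom):
        proc, truth = preprocessed_small_phantom
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = ScoreSelectCombineExtractor(cutoff_fraction=0.5).fit(proc)
            sig = est.extract(proc)
        late = truth.resp_trace.values[200:]
        r = np.corrcoef(sig.values[200:], late)[0, 1]
        assert abs(r) > 0.7
        assert est.windows_.respiratory[0] < 0.3 < est.windows_.respiratory[1] \
            or est.windows_.respiratory[0] < 0.25

    def test_estimators_expose_sklearn_params(self):
        est = ScoreSelectCombineExtractor(n_components=7)
        params = est.get_params()
        assert params["n_components"] == 7
        est.set_params(n_components=5)
        assert est.n_components == 5

    def test_transform_accepts_plain_matrix(self):
        series, w, _ = rank1_series(n_frames=256, noise=0.05)
        X = series.as_matrix()
        vals = ConventionalPCAExtractor(n_components=2).fit_transform(X)
        assert vals.shape == (256,)
        assert abs(np.corrcoef(vals, w)[0, 1]) > 0.9
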