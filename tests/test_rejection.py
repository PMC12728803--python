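"""Grubbs window rejection, background averaging, PCA background."""
import numpy as np
import pytest
from scipy import optimize, special

import lfpclean as L
from lfpclean.exceptions import AllWindowsRejectedError, InvalidArgumentError

from conftest import make_spectrogram


def t_quantile_oracle(p, df):
    """Student-t upper quantile via incomplete-beta inversion (independent
    of the implementation's t.ppf path)."""

    def cdf(x):
        ib = special.betainc(df / 2.0, 0.5, df / (df + x * x)) / 2.0
        return 1.0 - ib if x >= 0 else ib

    return optimize.brentq(lambda x: cdf(x) - p, -500, 500, xtol=1e-12)


def grubbs_oracle(N, alpha):
    t = t_quantile_oracle(1.0 - alpha / (2.0 * N), N - 2)
    g = t * t
    return (N - 1) / np.sqrt(N) * np.sqrt(g / (N - 2 + g))


def background_db(rng, n_windows=30, n_freq=151, df=0.5):
    """Synthetic stationary spectrogram in dB: shared 1/f shape + noise."""
    f = np.arange(1, n_freq + 1) * df
    shape = 10.0 * (1.0 - np.log10(f))
    return shape + rng.normal(0.0, 1.0, size=(n_windows, n_freq))


class TestGrubbsThreshold:
    def test_matches_independent_oracle(self):
        for N in [3, 5, 10, 30, 59, 100, 200]:
            for alpha in (0.01, 0.05, 0.2):
                assert L.grubbs_threshold(N, alpha) == pytest.approx(
                    grubbs_oracle(N, alpha), abs=1e-6)

    def test_n10_alpha05_is_tabulated_value(self):
        # standard two-sided Grubbs critical value for N = 10
        assert L.grubbs_threshold(10, 0.05) == pytest.approx(2.290, abs=0.001)

    def test_increasing_in_n(self):
        vals = [L.grubbs_threshold(N, 0.05) for N in range(3, 201)]
        assert np.all(np.diff(vals) > 0)

    def test_decreasing_in_alpha(self):
        assert L.grubbs_threshold(20, 0.9) < L.grubbs_threshold(20, 0.01)

    def test_small_n_rejected(self):
        with pytest.raises(InvalidArgumentError):
            L.grubbs_threshold(2, 0.05)


class TestCorrelationFilter:
    def test_identical_windows_no_rejection(self):
        f = np.linspace(0.5, 80, 160)
        row = 5.0 - 10.0 * np.log10(f)
        sg = make_spectrogram(np.tile(row, (20, 1)))
        res = L.correlation_outliers(sg)
        assert len(res.rejected) == 0

    def test_distinct_shape_window_rejected(self):
        rng = np.random.default_rng(0)
        M = background_db(rng)
        freqs = np.arange(1, M.shape[1] + 1) * 0.5
        # one window gets an extra 15 dB narrowband peak at ~40 Hz
        M[7] += 15.0 * np.exp(-0.5 * ((freqs - 40.0) / 1.5) ** 2)
        res = L.correlation_outliers(make_spectrogram(M))
        assert list(res.rejected) == [7]

    def test_broadband_offset_not_rejected(self):
        """Pearson correlation is offset-invariant: a pure dB shift passes."""
        rng = np.random.default_rng(1)
        M = background_db(rng)
        M[3] += 12.0  # same shape, shifted up
        res = L.correlation_outliers(make_spectrogram(M))
        assert 3 not in res.rejected

    def test_zscores_standardized(self):
        rng = np.random.default_rng(2)
        res = L.correlation_outliers(make_spectrogram(background_db(rng)))
        z = res.statistic_per_window
        assert np.nanmean(z) == pytest.approx(0.0, abs=1e-9)
        assert np.nanstd(z, ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestLowFreqFilter:
    def test_transient_window_rejected(self, mt_params):
        spec = L.SimulationSpec(
            duration=31.0, seed=3, qrs=None,
            transients=(L.TransientSpec(15.1, 0.4, 200.0, "ied"),))
        rec, truth = L.assemble_recording(spec)
        sg = L.short_time_spectrogram(rec, mt_params, channel=0)
        res = L.lowfreq_power_outliers(sg)
        s0, s1 = truth.transient_windows[0]
        hit = [i for i in res.rejected
               if sg.start_samples[i] < s1 and sg.start_samples[i] + 500 > s0]
        assert len(hit) >= 1

    def test_equal_power_windows_no_rejection(self):
        sg = make_spectrogram(np.tile(np.linspace(20, -10, 160), (15, 1)))
        assert len(L.lowfreq_power_outliers(sg).rejected) == 0

    def test_false_rejection_rate_bounded(self):
        """On clean stationary windows the Grubbs family-wise rejection
        probability stays near its design level (<= 2*alpha per set)."""
        rng = np.random.default_rng(7)
        alpha = 0.05
        n_rejecting = 0
        reps = 500
        for _ in range(reps):
            sg = make_spectrogram(background_db(rng))
            if len(L.lowfreq_power_outliers(sg, alpha=alpha).rejected):
                n_rejecting += 1
        assert n_rejecting / reps <= 2 * alpha


class TestBackgroundPsd:
    def test_no_outliers_matches_plain_average_within_1db(self):
        rng = np.random.default_rng(4)
        sg = make_spectrogram(background_db(rng))
        bg = L.background_psd(sg)
        plain = sg.power_matrix().mean(axis=0)
        diff = np.abs(bg.psd.power_db - 10 * np.log10(plain))
        assert np.max(diff) < 1.0

    def test_rejection_restores_beta_peak(self, mt_params):
        """Removing stim-edge/transient windows must sharpen the beta peak
        (height above the local 1/f) relative to the raw average."""
        spec = L.SimulationSpec(
            duration=60.0, seed=5, qrs=None,
            oscillations=(L.OscillationSpec(20.0, 3.0, 2.0),),
            transients=(L.TransientSpec(20.2, 0.5, 150.0, "ied"),
                        L.TransientSpec(40.1, 1.0, 120.0, "stim_edge")))
        rec, _ = L.assemble_recording(spec)
        sg = L.short_time_spectrogram(rec, mt_params, channel=0)
        kept = L.background_psd(sg).psd
        raw = L.Psd(sg.frequencies, sg.power_matrix().mean(axis=0), mt_params)

        def peak_height(psd):
            db = psd.power_db
            f = psd.frequencies
            beta = (f >= 16) & (f <= 24)
            floor = ((f >= 12) & (f <= 15)) | ((f >= 26) & (f <= 30))
            return db[beta].max() - np.median(db[floor])

        assert peak_height(kept) > peak_height(raw)

    def test_single_window_with_filters_off(self):
        row = np.linspace(10, -20, 160)
        sg = make_spectrogram(row[np.newaxis, :])
        bg = L.background_psd(sg, use_correlation=False, use_lowfreq=False)
        np.testing.assert_allclose(bg.psd.power, sg.windows[0].power)

    def test_degenerate_windows_raise(self):
        # every window flat in dB: zero variance leaves nothing the
        # correlation test can work with
        M = np.tile(np.full(160, 3.0), (6, 1)) + np.arange(6)[:, None]
        with pytest.raises((AllWindowsRejectedError, InvalidArgumentError)):
            L.background_psd(make_spectrogram(M), use_lowfreq=False)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        M = background_db(rng)
        M[11] += 18.0 * np.exp(
            -0.5 * ((np.arange(1, 152) * 0.5 - 30) / 2.0) ** 2)
        perm = rng.permutation(M.shape[0])
        r1 = L.correlation_outliers(make_spectrogram(M)).rejected
        r2 = L.correlation_outliers(make_spectrogram(M[perm])).rejected
        # shuffling window order permutes the rejected indices identically
        assert sorted(perm[r2]) == sorted(r1)

    def test_duplicate_inlier_stable(self):
        rng = np.random.default_rng(10)
        M = background_db(rng)
        before = set(int(i) for i in
                     L.lowfreq_power_outliers(make_spectrogram(M)).rejected)
        M2 = np.vstack([M, M[4]])  # exact duplicate of an inlier
        after = set(int(i) for i in
                    L.lowfreq_power_outliers(make_spectrogram(M2)).rejected)
        # no previously-inlying window becomes rejected
        assert not (after & set(range(M.shape[0]))) - before


class TestPcaBackground:
    def test_rank1_recovery(self):
        f = np.arange(1, 152) * 0.5
        shape = 8.0 - 9.0 * np.log10(f)
        amps = np.linspace(0.5, 2.0, 12)
        M = np.outer(amps, shape)
        bg = L.pca_background(make_spectrogram(M))
        mask = (f >= 4) & (f <= 75)
        got = bg.psd.power_db[mask]
        want = M.mean(axis=0)[mask]
        cos = np.dot(got - got.mean(), want - want.mean()) / (
            np.linalg.norm(got - got.mean()) * np.linalg.norm(want - want.mean()))
        assert cos >= 0.999

    def test_beats_raw_mean_on_contaminated_spectrogram(self):
        rng = np.random.default_rng(12)
        f = np.arange(1, 152) * 0.5
        true_db = 10.0 * (1.0 - np.log10(f))
        wins = 0
        for rep in range(20):
            M = true_db + rng.normal(0, 1.0, size=(30, 151))
            for i in rng.choice(30, size=3, replace=False):
                M[i] += rng.uniform(10, 25) * np.exp(
                    -0.5 * ((f - rng.uniform(5, 60)) / 3.0) ** 2) + rng.uniform(5, 15)
            sg = make_spectrogram(M)
            band = (f >= 4) & (f <= 75)
            err_pca = np.mean(np.abs(
                L.pca_background(sg).psd.power_db[band] - true_db[band]))
            err_raw = np.mean(np.abs(M.mean(axis=0)[band] - true_db[band]))
            wins += err_pca < err_raw
        assert wins >= 16  # >= 80% of replicates

    def test_sign_oriented_positively(self):
        rng = np.random.default_rng(13)
        sg = make_spectrogram(background_db(rng))
        bg = L.pca_background(sg)
        mask = sg.windows[0].band_slice((4, 75))
        mean_db = sg.db_matrix().mean(axis=0)
        r = np.corrcoef(bg.psd.power_db[mask], mean_db[mask])[0, 1]
        assert r > 0

    def test_agrees_with_threshold_filter_on_clean_data(self, mt_params):
        """With no artifacts both background estimators see the same thing."""
        diffs = []
        for seed in (21, 22):
            spec = L.SimulationSpec(duration=60.0, seed=seed, qrs=None)
            rec, _ = L.assemble_recording(spec)
            sg = L.short_time_spectrogram(rec, mt_params, channel=0)
            mask = sg.windows[0].band_slice((4, 75))
            a = L.background_psd(sg).psd.power_db[mask]
            b = L.pca_background(sg).psd.power_db[mask]
            diffs.append(np.max(np.abs(a - b)))
        assert np.mean(diffs) < 2.0

    def test_needs_two_windows(self):
        row = np.linspace(10, -10, 160)
        with pytest.raises(InvalidArgumentError):
            L.pca_background(make_spectrogram(row[np.newaxis, :]))
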