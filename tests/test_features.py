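"""Feature catalog: registry integrity, hand-computed oracles, an
independent convolution-cascade oracle for the wavelet path, and the
declared amplitude-scale behavior of every registry entry."""

import numpy as np
import pytest
import pywt

from emgintent.features import frequency as fq
from emgintent.features import time_domain as td
from emgintent.features import wavelet as wv
from emgintent.features.matrix import (FeatureMatrix, extract_feature,
                                       extract_matrix, read_matrix_csv,
                                       write_matrix_csv)
from emgintent.features.registry import (REGISTRY, FeatureSpec, column_tags,
                                         get_spec, registry_json,
                                         specs_for_domain)


class TestRegistry:
    def test_domain_counts(self):
        assert len(specs_for_domain("time")) == 31
        assert len(specs_for_domain("frequency")) == 9
        assert len(specs_for_domain("timefreq")) == 9
        assert len(REGISTRY) == 49

    def test_indices_are_1_to_49_in_catalog_order(self):
        idx = [s.index for s in REGISTRY.values()]
        assert sorted(idx) == list(range(1, 50))
        doms = [s.domain for s in sorted(REGISTRY.values(),
                                         key=lambda s: s.index)]
        assert doms == ["time"] * 31 + ["frequency"] * 9 + ["timefreq"] * 9

    def test_column_counts(self):
        assert get_spec("tmabs").n_columns(7) == 7
        assert get_spec("thist").n_columns(7) == 63
        assert get_spec("fe").n_columns(7) == 7 * 43
        assert get_spec("tcr").n_columns(7) == 21   # C(7, 2) pairs
        assert get_spec("tmcer").n_columns(7) == 7

    def test_column_tags_shape_and_order(self):
        tags = column_tags(get_spec("tcr"), 3)
        assert tags == [("tcr", "ch1:ch2", 0), ("tcr", "ch1:ch3", 0),
                        ("tcr", "ch2:ch3", 0)]
        tags = column_tags(get_spec("thist"), 2)
        assert len(tags) == 18 and tags[0] == ("thist", "ch1", 0)

    def test_unknown_ids_rejected(self):
        with pytest.raises(KeyError):
            get_spec("nope")
        with pytest.raises(ValueError):
            specs_for_domain("spatial")

    def test_registry_json_is_valid(self):
        import json
        entries = json.loads(registry_json())
        assert len(entries) == 49 and entries[0]["id"] == "tmabs"


class TestTimeDomainOracles:
    def test_amplitude_features_on_alternating_signal(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        assert td.tmabs(x)[0] == 1.0
        assert td.trms(x)[0] == 1.0
        assert td.tiabs(x)[0] == 4.0
        assert td.tssi(x)[0] == 4.0
        assert td.twl(x)[0] == 6.0
        assert td.tzc(x)[0] == 3.0

    def test_rms_of_3_4(self):
        assert td.trms(np.array([3.0, 4.0]))[0] == pytest.approx(
            np.sqrt(12.5))

    def test_constant_signal_gives_zero_counts_and_variation(self):
        x = np.full(100, 2.5)
        for f in (td.tzc, td.tslpch, td.twl, td.tvar, td.tstd, td.tdam,
                  td.tdasdv, td.tHmob, td.tHcom, td.twam):
            assert f(x)[0] == 0.0

    def test_variance_and_std_agree(self):
        x = np.random.default_rng(0).standard_normal(200)
        assert td.tvar(x)[0] == pytest.approx(td.tstd(x)[0] ** 2)
        assert td.tpwr(x)[0] == pytest.approx(td.trms(x)[0] ** 2)

    def test_willison_amplitude_threshold(self):
        x = np.array([0.0, 0.005, 0.05, 0.05])
        assert td.twam(x)[0] == 1.0       # only the 0.045 step exceeds 0.01

    def test_histogram_counts_sum_to_n(self):
        x = np.random.default_rng(1).standard_normal(600)
        h = td.thist(x)
        assert h.shape == (1, 9) and h.sum() == 600

    def test_correlation_of_identical_and_negated_channels(self):
        x = np.random.default_rng(2).standard_normal(100)
        X = np.column_stack([x, x, -x])
        r = td.tcr(X)
        assert r == pytest.approx([1.0, -1.0, -1.0])

    def test_covariance_matches_numpy(self):
        X = np.random.default_rng(3).standard_normal((50, 3))
        C = np.cov(X.T, ddof=1)
        assert td.tcv(X) == pytest.approx([C[0, 1], C[0, 2], C[1, 2]])

    def test_energy_ratios_sum_to_one(self):
        X = np.random.default_rng(4).standard_normal((80, 4))
        assert td.tmcer(X).sum() == pytest.approx(1.0)

    def test_percentile_and_log_detector(self):
        x = np.arange(1.0, 101.0)
        assert td.tperc75(x)[0] == np.percentile(x, 75)
        # geometric mean of 2,8 is 4
        assert td.tlogd(np.array([2.0, 8.0]))[0] == pytest.approx(4.0)

    def test_peak_features_on_known_bumps(self):
        x = np.zeros(50)
        x[10], x[30] = 4.0, 2.0
        # RMS ~ sqrt(20/50) = 0.63; both spikes are local maxima above it
        assert td.tpks(x)[0] == 2.0
        assert td.tmpks(x)[0] == 3.0
        v = td.tmvel(x, fs=100.0)[0]
        assert v == pytest.approx((2.0 - 4.0) / (20 / 100.0))

    def test_skew_kurt_on_symmetric_data(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert td.tskw(x)[0] == pytest.approx(0.0)
        assert td.tkurt(x)[0] == pytest.approx(1.7)  # moment kurtosis of this set

    def test_entropy_concentrated_vs_uniform_energy(self):
        spike = np.zeros(64); spike[5] = 1.0
        flat = np.ones(64)
        assert td.tren(spike)[0] == pytest.approx(0.0)
        assert td.tren(flat)[0] == pytest.approx(np.log(64))


class TestFrequencyOracles:
    def test_mean_and_median_frequency_of_pure_tone(self):
        fs, n = 2000.0, 2000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 100.0 * t)
        assert fq.fmn(x, fs)[0] == pytest.approx(100.0, abs=0.5)
        assert fq.fmd(x, fs)[0] == pytest.approx(100.0, abs=1.0)
        f, P = fq.power_spectrum(x, fs)
        assert f[np.argmax(P[:, 0])] == pytest.approx(100.0)

    def test_parseval_total_power(self):
        x = np.random.default_rng(5).standard_normal(512)
        f, P = fq.power_spectrum(x, 1000.0)
        # one-sided periodogram: doubling interior bins recovers sum x^2
        total = P[0, 0] + P[-1, 0] + 2 * P[1:-1, 0].sum()
        assert total == pytest.approx(np.sum(x ** 2), rel=1e-9)

    def test_frequency_ratio_low_tone_dominates(self):
        fs, n = 2000.0, 4000
        t = np.arange(n) / fs
        low = np.sin(2 * np.pi * 60.0 * t)
        high = np.sin(2 * np.pi * 400.0 * t)
        assert fq.fr(low, fs)[0] > 100.0
        assert fq.fr(high, fs)[0] < 0.01

    def test_fe_has_43_bins_covering_band_energy(self):
        fs, n = 2000.0, 2000
        x = np.random.default_rng(6).standard_normal(n)
        out = fq.fe(x, fs)
        assert out.shape == (1, 43)
        f, P = fq.power_spectrum(x, fs)
        in_band = P[(f >= 20) & (f < 450), 0].sum()
        assert out.sum() == pytest.approx(in_band, rel=1e-6)

    def test_spectral_peak_statistics_consistent(self):
        x = np.random.default_rng(7).standard_normal(1024)
        mn, md, sd = (fq.fpmn(x, 1000.0)[0], fq.fpmd(x, 1000.0)[0],
                      fq.fpstd(x, 1000.0)[0])
        assert mn > 0 and md > 0 and sd >= 0
        assert fq.fmxp(x, 1000.0)[0] >= mn


def _dwt_step_reference(x: np.ndarray, dec_lo: np.ndarray) -> np.ndarray:
    """One symmetric-padded analysis low-pass step, written directly from
    the convolution definition (independent of pywt.wavedec)."""
    n, flen = x.size, dec_lo.size
    pad = flen - 1
    xp = np.concatenate([x[:pad][::-1], x, x[-pad:][::-1]])
    full = np.convolve(xp, dec_lo, mode="full")
    return full[flen::2][: (n + flen - 1) // 2]


class TestWaveletOracles:
    def test_cA4_matches_direct_convolution_cascade(self):
        x = np.random.default_rng(8).standard_normal(600)
        dec_lo = np.asarray(pywt.Wavelet(wv.WAVELET).dec_lo)
        ref = x
        for _ in range(4):
            ref = _dwt_step_reference(ref, dec_lo)
        cA4 = wv.decompose(x)[0]
        assert cA4.shape == ref.shape
        np.testing.assert_allclose(cA4, ref, atol=1e-9)

    def test_feature_values_follow_cA4(self):
        x = np.random.default_rng(9).standard_normal(600)
        cA4 = wv.decompose(x)[0]
        assert wv.tfstd(x)[0] == pytest.approx(np.std(cA4, ddof=1))
        assert wv.tfvar(x)[0] == pytest.approx(np.var(cA4, ddof=1))
        assert wv.tfwl(x)[0] == pytest.approx(np.sum(np.abs(np.diff(cA4))))
        assert wv.tfe(x)[0] == pytest.approx(np.sum(cA4 ** 2))
        assert wv.tfmxabs1(x)[0] == pytest.approx(np.max(np.abs(cA4)))
        assert wv.tfmn(x)[0] == pytest.approx(np.mean(cA4))
        assert wv.tfmabs(x)[0] == pytest.approx(np.mean(np.abs(cA4)))

    def test_max_over_all_levels_dominates_approximation_max(self):
        x = np.random.default_rng(10).standard_normal(600)
        assert wv.tfmxabs2(x)[0] >= wv.tfmxabs1(x)[0]

    def test_too_short_window_raises(self):
        with pytest.raises(ValueError):
            wv.decompose(np.zeros(16))


@pytest.mark.parametrize("spec", sorted(REGISTRY.values(),
                                        key=lambda s: s.index),
                         ids=lambda s: s.id)
def test_declared_scale_behavior(spec: FeatureSpec):
    """Scaling the window by c must change the feature exactly as its
    registry entry declares (linear: xc; quadratic: xc^2; invariant: =)."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((640, 2))
    c = 3.0
    fs = 2000.0
    base = np.asarray(spec.func(X, fs), dtype=float).ravel()
    scaled = np.asarray(spec.func(c * X, fs), dtype=float).ravel()
    assert np.all(np.isfinite(base)) and np.all(np.isfinite(scaled))
    if spec.scale == "linear":
        np.testing.assert_allclose(scaled, c * base, rtol=1e-7, atol=1e-12)
    elif spec.scale == "quadratic":
        np.testing.assert_allclose(scaled, c * c * base, rtol=1e-7, atol=1e-12)
    elif spec.scale == "invariant":
        np.testing.assert_allclose(scaled, base, rtol=1e-7, atol=1e-10)
    else:
        assert spec.scale == "other"


class TestMatrix:
    def test_cfs_matrix_shape_and_columns(self, cfs_matrix, small_windowset):
        # 4 classes x 3 reps x 13 windows rows; tcr 3 pairs + 4 features x 3 ch
        assert cfs_matrix.values.shape == (len(small_windowset.windows), 15)
        assert cfs_matrix.feature_ids == ["tcr", "tmcer", "tlogd", "tHmob",
                                          "tiabs"]
        assert np.all(np.isfinite(cfs_matrix.values))
        assert cfs_matrix.groups is not None

    def test_select_features_keeps_groups_and_order(self, cfs_matrix):
        sub = cfs_matrix.select_features(["tlogd", "tiabs"])
        assert sub.values.shape[1] == 6
        assert sub.feature_ids == ["tlogd", "tiabs"]
        assert np.array_equal(sub.groups, cfs_matrix.groups)

    def test_extract_feature_matches_direct_call(self, small_windowset):
        w = small_windowset.windows[0]
        out = extract_feature(w, get_spec("trms"), small_windowset.fs)
        np.testing.assert_allclose(out, td.trms(w))

    def test_nonfinite_feature_is_reported_with_its_id(self, small_windowset):
        bad = FeatureSpec(id="tbad", domain="time",
                          func=lambda X, fs=None: np.full(X.shape[1], np.nan),
                          index=99)
        with pytest.raises(ValueError, match="tbad"):
            extract_matrix(small_windowset, [bad])

    def test_csv_roundtrip(self, cfs_matrix, tmp_path):
        p = tmp_path / "fm.csv"
        write_matrix_csv(cfs_matrix, p)
        back = read_matrix_csv(p)
        np.testing.assert_allclose(back.values, cfs_matrix.values)
        assert back.columns == cfs_matrix.columns
        assert np.array_equal(back.labels, cfs_matrix.labels)
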