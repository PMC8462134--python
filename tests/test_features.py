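"""Time-domain and frequency-domain feature computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import accelbehave as ab
from accelbehave.errors import AlignmentError, NameCollisionError, ParameterError

import pandas as pd


def single_axis_dataset(samples, samp_freq=10.0):
    arr = np.asarray(samples, dtype=float)[None, :]
    return ab.SegmentDataset(
        arr, np.array(["X"], dtype=object), n_axes=1, samp_freq=samp_freq
    )


class TestTimeDomain:
    def test_hand_computed_statistics(self):
        ds = single_axis_dataset([1, 2, 3, 4])
        ft = ab.time_domain_features(ds, winlen_dba=2)
        row = ft.iloc[0]
        assert row["x_mean"] == pytest.approx(2.5)
        assert row["x_variance"] == pytest.approx(5.0 / 3.0)  # n-1 denominator
        assert row["x_sd"] == pytest.approx(np.sqrt(5.0 / 3.0))
        assert row["x_max"] == 4 and row["x_min"] == 1 and row["x_range"] == 3

    def test_constant_segment_yields_zero_spread(self):
        ds = ab.SegmentDataset(
            np.ones((1, 12)), np.array(["C"], dtype=object), n_axes=3
        )
        row = ab.time_domain_features(ds, winlen_dba=3).iloc[0]
        for ax in "xyz":
            assert row[f"{ax}_mean"] == 1.0
            assert row[f"{ax}_variance"] == 0.0
            assert row[f"{ax}_sd"] == 0.0
            assert row[f"{ax}_range"] == 0.0
        assert row["ODBA"] == 0.0

    def test_column_count_and_order(self, stork_like):
        ft = ab.time_domain_features(stork_like, winlen_dba=11)
        assert ft.shape == (1746, 19)  # 6 per axis + ODBA
        assert list(ft.columns[:6]) == [
            "x_mean", "x_variance", "x_sd", "x_max", "x_min", "x_range",
        ]
        assert ft.columns[-1] == "ODBA"

    def test_winlen_out_of_range(self, toy_dataset):
        with pytest.raises(ParameterError):
            ab.time_domain_features(toy_dataset, winlen_dba=0)
        with pytest.raises(ParameterError):
            ab.time_domain_features(toy_dataset, winlen_dba=3)

    def test_identities_hold_on_synthetic_data(self, stork_like, stork_features):
        """sd^2 = variance, range = max - min, min <= mean <= max, ODBA >= 0."""
        ft = stork_features
        for ax in "xyz":
            np.testing.assert_allclose(
                ft[f"{ax}_sd"] ** 2, ft[f"{ax}_variance"], rtol=1e-9
            )
            np.testing.assert_allclose(
                ft[f"{ax}_range"], ft[f"{ax}_max"] - ft[f"{ax}_min"], rtol=1e-12
            )
            assert (ft[f"{ax}_min"] <= ft[f"{ax}_mean"] + 1e-12).all()
            assert (ft[f"{ax}_mean"] <= ft[f"{ax}_max"] + 1e-12).all()
        assert (ft["ODBA"] >= 0).all()


class TestOdba:
    def test_hand_computed_square_wave(self):
        # static is the segment mean (window spans the whole segment)
        value = ab.odba([[0, 2, 0, 2], [0, 0, 0, 0], [0, 0, 0, 0]], winlen_dba=4)
        assert value == pytest.approx(1.0)

    def test_constant_axes_vanish(self):
        assert ab.odba(np.ones((3, 8)), winlen_dba=3) == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50), seed=st.integers(0, 100))
    def test_homogeneity(self, scale, seed):
        axes = np.random.default_rng(seed).normal(size=(3, 16))
        base = ab.odba(axes, winlen_dba=5)
        assert ab.odba(scale * axes, winlen_dba=5) == pytest.approx(
            scale * base, rel=1e-9
        )


class TestAmplitudeSpectrum:
    def test_exact_bin_sinusoid(self):
        t = np.arange(40) / 10.0
        spec = ab.amplitude_spectrum(2.0 * np.sin(2 * np.pi * 3.0 * t), 10.0)
        peak = np.argmax(spec.amplitudes)
        assert spec.freqs[peak] == pytest.approx(3.0)
        assert spec.amplitudes[peak] == pytest.approx(2.0, abs=1e-9)
        others = np.delete(spec.amplitudes, peak)
        assert np.all(others < 1e-9)

    def test_constant_signal_has_zero_spectrum(self):
        spec = ab.amplitude_spectrum(np.full(16, 3.7), 8.0)
        assert np.all(spec.amplitudes < 1e-12)

    def test_bin_geometry(self):
        spec = ab.amplitude_spectrum(np.random.default_rng(0).normal(size=40), 10.0)
        assert len(spec.freqs) == 20
        assert spec.freqs[0] == pytest.approx(0.25)
        assert spec.freqs[-1] == pytest.approx(5.0)  # Nyquist inclusive
        assert np.all(np.diff(spec.freqs) > 0)

    def test_parseval_relation(self):
        """One-sided amplitudes reproduce the population variance of a
        zero-mean signal: var = 0.5 * sum(a_k^2) + 0.5 * a_nyq^2 for even N."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        x -= x.mean()
        spec = ab.amplitude_spectrum(x, 10.0)
        a = spec.amplitudes
        total = 0.5 * np.sum(a[:-1] ** 2) + a[-1] ** 2
        assert total == pytest.approx(np.mean(x**2), rel=1e-9)

    def test_rejects_short_or_nonfinite(self):
        with pytest.raises(ParameterError):
            ab.amplitude_spectrum([1.0, 2.0], 10.0)
        with pytest.raises(ValueError):
            ab.amplitude_spectrum([1.0, np.nan, 2.0, 3.0], 10.0)


class TestFreqDomain:
    def test_planted_sinusoid_recovered_on_heave_axis(self):
        t = np.arange(40) / 10.0
        z = 2.0 * np.sin(2 * np.pi * 3.0 * t)
        row = np.zeros((40, 3))
        row[:, 2] = z
        ds = ab.SegmentDataset(
            row.reshape(1, -1), np.array(["F"], dtype=object), n_axes=3,
            samp_freq=10.0,
        )
        ft = ab.freq_domain_features(ds)
        assert ft.shape == (1, 9)
        assert ft.loc[0, "z_main_freq"] == pytest.approx(3.0)
        assert ft.loc[0, "z_main_amp"] == pytest.approx(2.0, abs=1e-9)
        assert ft.loc[0, "z_entropy"] == pytest.approx(0.0, abs=1e-6)
        # silent axes follow the zero-power convention
        assert ft.loc[0, "x_entropy"] == 0.0
        assert ft.loc[0, "x_main_amp"] == 0.0

    def test_constant_dataset_zero_entropy(self):
        ds = ab.SegmentDataset(
            np.ones((2, 12)), np.array(["C", "C"], dtype=object), n_axes=1,
            samp_freq=4.0,
        )
        ft = ab.freq_domain_features(ds)
        assert (ft["x_entropy"] == 0.0).all()

    def test_white_noise_entropy_near_theoretical_value(self):
        """Mean per-segment entropy of Gaussian noise equals
        ln(N/2) - (1 - gamma): the spectral weights of a single noise
        realization are exponentially distributed, which sits the expected
        entropy the constant 1 - gamma below the flat-spectrum bound."""
        rng = np.random.default_rng(11)
        values = rng.normal(size=(200, 40))
        ds = ab.SegmentDataset(
            values, np.array(["N"] * 200, dtype=object), n_axes=1, samp_freq=10.0
        )
        mean_entropy = ab.freq_domain_features(ds)["x_entropy"].mean()
        expected = np.log(20) - (1.0 - np.euler_gamma)
        assert mean_entropy == pytest.approx(expected, rel=0.05)
        assert mean_entropy <= np.log(20)

    def test_entropy_and_main_freq_bounds(self, stork_like, stork_features):
        ft = stork_features
        fs = stork_like.samp_freq
        top = np.log(stork_like.seg_len // 2)
        for ax in "xyz":
            assert (ft[f"{ax}_main_freq"] > 0).all()
            assert (ft[f"{ax}_main_freq"] <= fs / 2 + 1e-12).all()
            assert (ft[f"{ax}_entropy"] >= 0).all()
            assert (ft[f"{ax}_entropy"] <= top + 1e-9).all()

    def test_frequency_recovery_under_noise(self):
        """A planted tone with noise sd at 10% of its amplitude is recovered
        within one bin width in at least 99% of 500 segments."""
        rng = np.random.default_rng(21)
        fs, n, f, amp = 10.0, 40, 3.3, 1.0
        t = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, 500)
        sig = amp * np.sin(2 * np.pi * f * t[None, :] + phases[:, None])
        sig = sig + rng.normal(0, 0.1 * amp, sig.shape)
        ds = ab.SegmentDataset(
            sig, np.array(["T"] * 500, dtype=object), n_axes=1, samp_freq=fs
        )
        recovered = ab.freq_domain_features(ds)["x_main_freq"].to_numpy()
        hit = np.abs(recovered - f) <= fs / n
        assert hit.mean() >= 0.99

    def test_samp_freq_required(self):
        ds = ab.SegmentDataset(
            np.random.default_rng(0).normal(size=(2, 12)),
            np.array(["A", "B"], dtype=object),
            n_axes=3,
        )
        with pytest.raises(ParameterError):
            ab.freq_domain_features(ds)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(shift=st.floats(-10, 10), seed=st.integers(0, 50))
    def test_shift_invariance(self, shift, seed):
        """Adding a constant moves mean/max/min only; spread, ODBA and all
        spectral features are unchanged (the spectrum is mean-removed)."""
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(1, 20))
        labels = np.array(["S"], dtype=object)
        a = ab.SegmentDataset(base, labels, n_axes=1, samp_freq=10.0)
        b = ab.SegmentDataset(base + shift, labels, n_axes=1, samp_freq=10.0)
        ta = ab.time_domain_features(a, winlen_dba=5)
        tb = ab.time_domain_features(b, winlen_dba=5)
        for kept in ("x_variance", "x_sd", "x_range", "ODBA"):
            assert tb[kept].iloc[0] == pytest.approx(ta[kept].iloc[0], abs=1e-9)
        assert tb["x_mean"].iloc[0] == pytest.approx(
            ta["x_mean"].iloc[0] + shift, abs=1e-9
        )
        fa = ab.freq_domain_features(a)
        fb = ab.freq_domain_features(b)
        np.testing.assert_allclose(fa.to_numpy(), fb.to_numpy(), atol=1e-9)


class TestCombineFeatures:
    def test_time_plus_freq_geometry(self, stork_features):
        assert stork_features.shape[1] == 28  # 6*3+1 time plus 3*3 frequency

    def test_identity_with_empty(self, stork_features):
        empty = pd.DataFrame(index=range(len(stork_features)))
        out = ab.combine_features(stork_features, empty)
        assert list(out.columns) == list(stork_features.columns)

    def test_name_collision(self, stork_features):
        with pytest.raises(NameCollisionError):
            ab.combine_features(stork_features, stork_features[["ODBA"]])

    def test_row_mismatch(self, stork_features):
        with pytest.raises(AlignmentError):
            ab.combine_features(stork_features, stork_features.iloc[:5][["ODBA"]])


class TestFeatureIO:
    def test_csv_round_trip_with_labels(self, stork_features, stork_like, tmp_path):
        path = tmp_path / "features.csv"
        ab.write_features(stork_features.iloc[:10], path, labels=stork_like.labels[:10])
        table, labels = ab.read_features(path)
        assert list(table.columns) == list(stork_features.columns)
        assert list(labels) == list(stork_like.labels[:10])
        np.testing.assert_allclose(
            table.to_numpy(), stork_features.iloc[:10].to_numpy(), rtol=1e-9
        )
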