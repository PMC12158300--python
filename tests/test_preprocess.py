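import warnings

import numpy as np
import pytest
from scipy.signal import lfilter

from mesostate import preprocess as pp
from mesostate.types import (
    CANONICAL_CHANNELS,
    AlignedRun,
    Annotation,
    EEGRecording,
    InvalidConfigError,
    InvalidInputError,
)

FS = 250.0


def sine_recording(freq, duration=20.0, fs=FS, n_channels=2):
    t = np.arange(0, duration, 1 / fs)
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return EEGRecording(data, [f"ch{i}" for i in range(n_channels)], fs)


class TestResample:
    def test_same_rate_is_identity(self, rng):
        rec = EEGRecording(rng.standard_normal((3, 1000)), ["a", "b", "c"], FS)
        out = pp.resample_to(rec, FS)
        assert np.array_equal(out.data, rec.data)

    def test_sinusoid_preserved(self):
        t = np.arange(0, 10, 1 / 500.0)
        rec = EEGRecording(np.sin(2 * np.pi * 10 * t)[None, :], ["a"], 500.0)
        out = pp.resample_to(rec, FS)
        t2 = np.arange(out.n_samples) / FS
        expected = np.sin(2 * np.pi * 10 * t2)
        # compare away from the edges; amplitude error below 1 %
        err = np.abs(out.data[0, 200:-200] - expected[200:-200]).max()
        assert err < 0.01
        assert abs(out.duration - rec.duration) <= 1 / FS

    def test_annotations_keep_their_seconds(self):
        rec = sine_recording(5.0)
        rec.annotations.append(Annotation(onset=10.0, duration=2.0, label="NFT"))
        out = pp.resample_to(rec, 125.0)
        assert out.annotations[0].onset == 10.0

    def test_extreme_upsampling_warns(self):
        rec = sine_recording(5.0)
        with pytest.warns(UserWarning, match="upsampling"):
            pp.resample_to(rec, FS * 5)

    def test_invalid_rate(self):
        with pytest.raises(InvalidConfigError):
            pp.resample_to(sine_recording(5.0), -1.0)


class TestBandpass:
    def test_zero_in_zero_out(self):
        rec = EEGRecording(np.zeros((2, 1000)), ["a", "b"], FS)
        out = pp.bandpass_zero_phase(rec)
        assert np.allclose(out.data, 0.0)

    def test_passband_gain_at_10hz(self):
        out = pp.bandpass_zero_phase(sine_recording(10.0, duration=40.0))
        mid = out.data[0, 2000:-2000]
        amp = np.sqrt(2 * np.mean(mid**2))
        assert 0.99 <= amp <= 1.01
        assert 0.99 <= pp.bandpass_gain(10.0, 0.5, 38.0, 8, FS) <= 1.01

    def test_stopband_attenuation_at_60hz(self):
        out = pp.bandpass_zero_phase(sine_recording(60.0, duration=60.0))
        mid = out.data[0, 2000:-2000]
        amp = np.sqrt(2 * np.mean(mid**2))
        analytic = pp.bandpass_gain(60.0, 0.5, 38.0, 8, FS)
        assert amp < 0.01
        assert abs(amp - analytic) < 0.2 * analytic

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(InvalidConfigError, match="Nyquist"):
            pp.bandpass_zero_phase(sine_recording(10.0), low=0.5, high=130.0)

    def test_zero_phase_symmetric_pulse(self):
        pulse = np.zeros(5001)
        pulse[2500] = 1.0
        rec = EEGRecording(np.vstack([pulse, pulse]), ["a", "b"], FS)
        out = pp.bandpass_zero_phase(rec).data[0]
        asymmetry = np.abs(out - out[::-1]).max() / np.abs(out).max()
        assert asymmetry < 1e-6


class TestCAR:
    def test_forced_arithmetic(self):
        rec = EEGRecording(np.array([[1.0], [3.0]]), ["a", "b"], FS)
        out = pp.common_average_reference(rec)
        assert np.array_equal(out.data[:, 0], [-1.0, 1.0])

    def test_idempotent(self, rng):
        rec = EEGRecording(rng.standard_normal((5, 300)), list("abcde"), FS)
        once = pp.common_average_reference(rec)
        twice = pp.common_average_reference(once)
        assert np.allclose(once.data, twice.data, atol=1e-15)

    def test_channel_mean_is_zero(self, rng):
        rec = EEGRecording(rng.standard_normal((5, 300)), list("abcde"), FS)
        out = pp.common_average_reference(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12

    def test_single_channel_rejected(self):
        rec = EEGRecording(np.ones((1, 10)), ["a"], FS)
        with pytest.raises(InvalidInputError):
            pp.common_average_reference(rec)

    def test_retained_reference_preserves_rank(self, rng):
        data = rng.standard_normal((4, 500))
        rec = EEGRecording(data, list("abcd"), FS)
        out = pp.common_average_reference(rec, keep_original_reference=True)
        assert out.channel_names[-1] == pp.REFERENCE_LABEL
        assert np.linalg.matrix_rank(out.data) == 4
        # plain CAR loses one dimension
        plain = pp.common_average_reference(rec)
        assert np.linalg.matrix_rank(plain.data) == 3


class TestICA:
    def _mixture(self, rng, with_artifact=True, n=5000):
        clean = lfilter([1], [1, -0.5], rng.standard_normal((7, n)), axis=1)
        if not with_artifact:
            return clean, clean
        artifact = 20 * np.sin(2 * np.pi * 1.0 * np.arange(n) / FS)
        noisy = clean + np.outer(rng.uniform(0.5, 1.5, 7), artifact)
        return noisy, clean

    def test_disabled_criteria_identity(self, rng):
        noisy, _ = self._mixture(rng)
        rec = EEGRecording(noisy, list(CANONICAL_CHANNELS), FS)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, dec = pp.remove_artifacts_ica(rec, pp.ICACriteria(enabled=False))
        assert dec.rejected == {}
        rel = np.linalg.norm(out.data - rec.data) / np.linalg.norm(rec.data)
        assert rel < 1e-6

    def test_artifact_removed_and_rmse_improves(self, rng):
        noisy, clean = self._mixture(rng)
        rec = EEGRecording(noisy, list(CANONICAL_CHANNELS), FS)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, dec = pp.remove_artifacts_ica(rec)
        assert any(reason == "ocular" for reason in dec.rejected.values())
        rmse_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_after = np.sqrt(np.mean((out.data - clean) ** 2))
        assert rmse_after < rmse_before

    def test_rejecting_everything_warns_and_zeroes(self, rng):
        noisy, _ = self._mixture(rng, with_artifact=False)
        rec = EEGRecording(noisy, list(CANONICAL_CHANNELS), FS)
        # impossible thresholds flag every component
        criteria = pp.ICACriteria(low_fraction=-1.0)
        with pytest.warns(UserWarning, match="all independent components"):
            out, dec = pp.remove_artifacts_ica(rec, criteria)
        assert len(dec.rejected) == dec.sources.shape[0]
        assert np.allclose(out.data, out.data.mean(axis=1, keepdims=True))

    def test_rank_deficient_input_rejected(self):
        row = np.sin(np.arange(1000))
        rec = EEGRecording(np.vstack([row, row]), ["a", "b"], FS)
        with pytest.raises(InvalidInputError, match="rank"):
            pp.remove_artifacts_ica(rec)


class TestAlignChannels:
    def test_flex8_po3_mean_of_equal_signals(self, rng):
        s = rng.standard_normal(400)
        names = ["C3", "Cz", "C4", "P3", "O1", "P7", "Oz", "Pz"]
        data = rng.standard_normal((8, 400))
        data[3] = s
        data[4] = s
        rec = EEGRecording(data, names, FS, device="flex8")
        out = pp.align_channels(rec)
        po3 = out.data[list(CANONICAL_CHANNELS).index("PO3")]
        assert np.allclose(po3, s, atol=0)

    def test_flex8_po3_forced_arithmetic(self):
        names = ["C3", "Cz", "C4", "P3", "O1", "P7", "Oz", "Pz"]
        data = np.ones((8, 10))
        data[3] = 2.0
        data[4] = 4.0
        rec = EEGRecording(data, names, FS, device="flex8")
        out = pp.align_channels(rec)
        assert np.allclose(out.data[list(CANONICAL_CHANNELS).index("PO3")], 3.0)

    def test_gtec32_selects_canonical_order(self, rng):
        extra = [f"X{i}" for i in range(25)]
        names = list(CANONICAL_CHANNELS) + extra
        rec = EEGRecording(rng.standard_normal((32, 100)), names, FS, device="gtec32")
        out = pp.align_channels(rec)
        assert list(out.channel_names) == list(CANONICAL_CHANNELS)

    def test_missing_channel_named_in_error(self, rng):
        rec = EEGRecording(
            rng.standard_normal((6, 100)),
            ["C3", "Cz", "C4", "P7", "Pz", "Oz"],
            FS,
            device="gtec32",
        )
        with pytest.raises(InvalidInputError, match="PO3"):
            pp.align_channels(rec)


class TestSegmentation:
    def _recording(self, rng, annotations, duration=300.0):
        n = int(duration * FS)
        rec = EEGRecording(
            rng.standard_normal((7, n)), list(CANONICAL_CHANNELS), FS,
            annotations=annotations,
        )
        return rec

    def test_ten_full_runs(self, rng):
        anns = [Annotation(onset=i * 140.0, duration=134.0, label="NFT") for i in range(10)]
        rec = self._recording(rng, anns, duration=1500.0)
        runs = pp.segment_runs(rec)
        assert len(runs) == 10
        assert all(r.n_samples == 33_500 for r in runs)
        assert not any(r.partial for r in runs)

    def test_invalid_annotation_dropped(self, rng):
        anns = [
            Annotation(onset=0.0, duration=134.0, label="NFT"),
            Annotation(onset=140.0, duration=134.0, label="NFT", valid=False),
        ]
        runs = pp.segment_runs(self._recording(rng, anns))
        assert len(runs) == 1

    def test_empty_annotations_warn(self, rng):
        with pytest.warns(UserWarning, match="no valid annotations"):
            runs = pp.segment_runs(self._recording(rng, []))
        assert runs == []

    def test_overlap_rejected(self, rng):
        anns = [
            Annotation(onset=0.0, duration=134.0, label="NFT"),
            Annotation(onset=100.0, duration=134.0, label="resting"),
        ]
        with pytest.raises(InvalidInputError, match="overlap"):
            pp.segment_runs(self._recording(rng, anns))

    def test_short_run_flagged_partial(self, rng):
        anns = [Annotation(onset=0.0, duration=60.0, label="NFT")]
        runs = pp.segment_runs(self._recording(rng, anns, duration=100.0))
        assert runs[0].partial


class TestBaselineAndZscore:
    def test_constant_signal_zeroed(self):
        run = AlignedRun(np.full((7, 1000), 4.2), FS, "NFT")
        out = pp.baseline_correct(run)
        assert np.allclose(out.data, 0.0)

    def test_baseline_window_mean_is_zero(self, aligned_run):
        out = pp.baseline_correct(aligned_run, baseline=0.5)
        n = int(0.5 * FS)
        assert np.abs(out.data[:, :n].mean(axis=1)).max() < 1e-12

    def test_idempotent_on_centred_input(self, aligned_run):
        once = pp.baseline_correct(aligned_run)
        twice = pp.baseline_correct(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_nonpositive_baseline_rejected(self, aligned_run):
        with pytest.raises(InvalidConfigError):
            pp.baseline_correct(aligned_run, baseline=0.0)

    def test_zscore_defining_property(self, rng):
        runs = [
            AlignedRun(5 + 3 * rng.standard_normal((7, 800)), FS, "NFT")
            for _ in range(4)
        ]
        out = pp.zscore_session(runs)
        pooled = np.concatenate([r.data for r in out], axis=1)
        assert np.abs(pooled.mean(axis=1)).max() < 1e-9
        assert np.abs(pooled.std(axis=1) - 1).max() < 1e-9

    def test_zscore_scale_invariance(self, rng):
        data = rng.standard_normal((7, 500))
        a = pp.zscore_session([AlignedRun(data, FS, "NFT")])
        b = pp.zscore_session([AlignedRun(10 * data, FS, "NFT")])
        assert np.allclose(a[0].data, b[0].data, atol=1e-12)

    def test_zscore_idempotent(self, rng):
        runs = [AlignedRun(rng.standard_normal((7, 500)), FS, "NFT")]
        once = pp.zscore_session(runs)
        twice = pp.zscore_session(once)
        assert np.allclose(once[0].data, twice[0].data, atol=1e-9)

    def test_zero_variance_channel_named(self):
        data = np.random.default_rng(0).standard_normal((7, 100))
        data[2] = 1.0
        with pytest.raises(InvalidInputError, match="C4"):
            pp.zscore_session([AlignedRun(data, FS, "NFT")])


class TestFullPipeline:
    def test_determinism_and_provenance(self, rng):
        from mesostate import synth

        cfg = synth.SimConfig(run_duration=20.0, measurement_noise_sd=0.5)
        target = synth._random_correlation(np.random.default_rng(1), 7, 0.3)
        segments = [
            synth.simulate_eeg_run(cfg, cond, target, seed=i)
            for i, cond in enumerate(["NFT", "resting"])
        ]
        data = np.concatenate([s.data for s in segments], axis=1)
        rec = EEGRecording(
            data, list(CANONICAL_CHANNELS), FS, device="synthetic",
            annotations=[
                Annotation(0.0, 20.0, "NFT"),
                Annotation(20.0, 20.0, "resting"),
            ],
        )
        pcfg = pp.PreprocessConfig(run_length_s=20.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            runs1, prov1 = pp.preprocess_recording(rec.copy_with(), pcfg)
            runs2, prov2 = pp.preprocess_recording(rec.copy_with(), pcfg)
        assert prov1["order"] == list(pp.PIPELINE_ORDER)
        assert len(runs1) == 2
        for r1, r2 in zip(runs1, runs2):
            assert np.array_equal(r1.data, r2.data)
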