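"""Filtering, artifact rejection and ICA cleaning contracts."""

import numpy as np
import pytest

from micomm.montage import ChannelMontage
from micomm.preprocess import bandpass, ica_clean, reject_artifact_segments
from micomm.simulate import (
    BackgroundSpectrumModel,
    Recording,
    SessionPlan,
    Section,
    inject_artifacts,
    make_session_plan,
    synthesize_recording,
)

ONE = ChannelMontage(("Cz",))
RATE = 256.0


def _sine_recording(freq: float, seconds: float = 8.0, amplitude: float = 1.0) -> Recording:
    t = np.arange(int(seconds * RATE)) / RATE
    return Recording(RATE, amplitude * np.sin(2 * np.pi * freq * t)[None, :], ONE)


def _mid_power(rec: Recording) -> float:
    n = rec.n_samples
    return float(np.var(rec.data[0, n // 4 : -n // 4]))  # avoid filter edges


def test_bandpass_stopband_and_passband():
    low = _sine_recording(1.0)
    out = bandpass(low)
    att_db = 10 * np.log10(_mid_power(low) / _mid_power(out))
    assert att_db >= 40.0

    mid = _sine_recording(10.0)
    out = bandpass(mid)
    amp_ratio = np.sqrt(_mid_power(out) / _mid_power(mid))
    assert amp_ratio == pytest.approx(1.0, abs=0.05)

    zero = Recording(RATE, np.zeros((1, 2048)), ONE)
    assert np.allclose(bandpass(zero).data, 0.0)


def test_bandpass_rejects_bad_cutoffs():
    rec = _sine_recording(10.0)
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass(rec, low=3.0, high=130.0)
    with pytest.raises(ValueError):
        bandpass(rec, low=60.0, high=3.0)


def test_bandpass_linearity():
    rng = np.random.default_rng(0)
    x = Recording(RATE, rng.normal(size=(2, 2048)), ChannelMontage(("C3", "C4")))
    y = Recording(RATE, rng.normal(size=(2, 2048)), ChannelMontage(("C3", "C4")))
    lhs = bandpass(Recording(RATE, 2.0 * x.data + 3.0 * y.data, x.montage)).data
    rhs = 2.0 * bandpass(x).data + 3.0 * bandpass(y).data
    assert np.allclose(lhs, rhs, atol=1e-9)


def test_rejection_leaves_clean_data_untouched():
    plan = make_session_plan("patient", "imagery", seed=1, reps_per_task=2)
    rec = synthesize_recording(plan, BackgroundSpectrumModel.healthy(), seed=2, montage=ONE)
    out, report = reject_artifact_segments(rec, "amplitude", threshold=1e6)
    assert report.fraction_removed == 0.0
    assert np.array_equal(out.data, rec.data)


def test_rejection_finds_injected_transients():
    plan = make_session_plan("patient", "imagery", seed=3, reps_per_task=5)
    rec = synthesize_recording(plan, BackgroundSpectrumModel.healthy(), seed=4, montage=ONE)
    scale = np.abs(rec.data).max()
    noisy = inject_artifacts(rec, rate_per_minute=2.0, amplitude=10 * scale, seed=5)
    out, report = reject_artifact_segments(noisy, "amplitude", threshold=3 * scale)
    truth = [(a, b) for a, b, k in noisy.annotations if k == "artifact"]
    covered = sum(
        any(a < b2 and b > a2 for a2, b2 in report.rejected_intervals) for a, b in truth
    )
    assert covered / len(truth) >= 0.9
    # unmasked samples unchanged
    mask = np.zeros(noisy.n_samples, dtype=bool)
    for a, b in report.rejected_intervals:
        mask[int(a * RATE) : int(b * RATE)] = True
    assert np.array_equal(out.data[:, ~mask], noisy.data[:, ~mask])


def test_rejection_annotation_mode_is_identity_on_inputs():
    rec = Recording(RATE, np.zeros((1, 2560)), ONE,
                    annotations=[(1.0, 2.0, "artifact"), (5.0, 6.0, "artifact")])
    out, report = reject_artifact_segments(rec, "annotations")
    assert report.rejected_intervals == [(1.0, 2.0), (5.0, 6.0)]
    assert out.masked_intervals() == [(1.0, 2.0), (5.0, 6.0)]


def test_rejection_refuses_to_remove_everything():
    rec = Recording(RATE, 1e4 * np.ones((1, 2560)), ONE)
    with pytest.raises(ValueError, match="fraction"):
        reject_artifact_segments(rec, "amplitude", threshold=1.0)


def test_chain_preserves_band_power_of_clean_signal():
    """Filtering + rejection changes 4-40 Hz band powers by < 5%."""
    plan = SessionPlan("healthy", "imagery", (Section(0.0, 60.0, "hand"),))
    rec = synthesize_recording(plan, BackgroundSpectrumModel.healthy(), seed=6, montage=ONE)
    out = bandpass(rec)
    out, _ = reject_artifact_segments(out, "amplitude", threshold=1e6)
    from scipy import signal as sps

    for x, y in ((rec.data[0], out.data[0]),):
        f, pin = sps.welch(x, fs=RATE, nperseg=1024)
        f, pout = sps.welch(y, fs=RATE, nperseg=1024)
        sel = (f >= 4) & (f <= 40)
        assert np.trapezoid(pout[sel], f[sel]) == pytest.approx(
            np.trapezoid(pin[sel], f[sel]), rel=0.05
        )


def _mixed_artifact_recording(seed=7):
    """Background plus one spiky source mixed into all channels."""
    rng = np.random.default_rng(seed)
    n = int(60 * RATE)
    n_ch = 4
    background = rng.normal(size=(n_ch, n))
    spikes = np.zeros(n)
    intervals = []
    for k in range(6):
        i0 = int((5 + 9 * k) * RATE)
        spikes[i0 : i0 + 128] = 50.0 * np.hanning(128)
        intervals.append((i0 / RATE, (i0 + 128) / RATE))
    mixing = rng.uniform(0.5, 1.5, size=n_ch)
    data = background + mixing[:, None] * spikes[None, :]
    rec = Recording(RATE, data, ChannelMontage(("C3", "C4", "Cz", "Fz")),
                    annotations=[(a, b, "artifact") for a, b in intervals])
    return rec, intervals


def test_ica_identity_when_nothing_matches():
    rng = np.random.default_rng(8)
    rec = Recording(RATE, rng.normal(size=(3, 5120)), ChannelMontage(("C3", "C4", "Cz")))
    out, report = ica_clean(rec, kurtosis_bound=1e6)
    assert report.n_components_removed == 0
    assert np.allclose(out.data, rec.data, atol=1e-6)


def test_ica_removes_spiky_source():
    rec, intervals = _mixed_artifact_recording()
    out, report = ica_clean(rec, kurtosis_bound=10.0, seed=1)
    assert report.n_components_removed >= 1

    def artifact_power(data):
        return sum(
            float(np.sum(data[:, int(a * RATE) : int(b * RATE)] ** 2)) for a, b in intervals
        )

    assert artifact_power(out.data) <= 0.2 * artifact_power(rec.data)


def test_ica_requires_two_channels():
    rec = Recording(RATE, np.zeros((1, 512)), ONE)
    with pytest.raises(ValueError, match="2 channels"):
        ica_clean(rec)
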