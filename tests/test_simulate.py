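"""Session plans, spectral fidelity and effect calibration of the generator."""

import numpy as np
import pytest
from scipy import signal as sps

from micomm.bands import BANDS
from micomm.montage import ChannelMontage
from micomm.simulate import (
    BackgroundSpectrumModel,
    Effect,
    EffectSpec,
    Section,
    SessionPlan,
    inject_artifacts,
    make_session_plan,
    synthesize_recording,
)

TRI = ChannelMontage(("C3", "C4", "Cz"))


@pytest.mark.parametrize(
    "cohort,trial,n_sections,duration",
    [
        ("healthy", "imagery", 20, 60.0),
        ("healthy", "pre-communication", 30, 30.0),
        ("patient", "imagery", 14, 30.0),
        ("patient", "pre-communication", 12, 30.0),
    ],
)
def test_plan_structure(cohort, trial, n_sections, duration):
    plan = make_session_plan(cohort, trial, seed=1)
    assert plan.n_sections == n_sections
    assert all(s.duration == duration for s in plan.sections)
    # contiguous and non-overlapping
    for a, b in zip(plan.sections, plan.sections[1:]):
        assert b.start == pytest.approx(a.end)
    if trial == "imagery":
        tasks = [s.task for s in plan.sections]
        assert tasks.count("hand") == tasks.count("foot") == n_sections // 2
    else:
        assert all(s.answer in ("yes", "no") for s in plan.sections)
        # answers encode tasks: yes -> hand, no -> foot
        assert all((s.answer == "yes") == (s.task == "hand") for s in plan.sections)


def test_plan_determinism_and_randomization():
    p1 = make_session_plan("healthy", "imagery", seed=5)
    p2 = make_session_plan("healthy", "imagery", seed=5)
    p3 = make_session_plan("healthy", "imagery", seed=6)
    assert p1 == p2
    assert [s.task for s in p1.sections] != [s.task for s in p3.sections]


def test_plan_rejects_unknown_inputs():
    with pytest.raises(ValueError, match="cohort"):
        make_session_plan("rodent", "imagery", 0)
    with pytest.raises(ValueError, match="trial_type"):
        make_session_plan("healthy", "dreaming", 0)


def test_recording_determinism():
    plan = make_session_plan("patient", "imagery", seed=2, reps_per_task=2)
    model = BackgroundSpectrumModel.healthy()
    r1 = synthesize_recording(plan, model, seed=3, montage=TRI)
    r2 = synthesize_recording(plan, model, seed=3, montage=TRI)
    assert np.array_equal(r1.data, r2.data)


def test_effect_electrode_must_be_in_montage():
    plan = make_session_plan("patient", "imagery", seed=2, reps_per_task=2)
    eff = EffectSpec((Effect("Pz", "alpha", "hand", 2.0),))
    with pytest.raises(ValueError, match="Pz"):
        synthesize_recording(plan, BackgroundSpectrumModel.healthy(), eff, seed=0, montage=TRI)


def _quiescent_psd(model, seconds=120.0, seed=0):
    plan = SessionPlan("healthy", "imagery", (Section(0.0, seconds, "hand"),))
    rec = synthesize_recording(plan, model, seed=seed, montage=ChannelMontage(("Cz",)))
    freqs, psd = sps.welch(rec.data[0], fs=rec.rate, nperseg=2048)
    return freqs, psd


def test_background_psd_matches_model():
    """Welch PSD of 120 s of quiescent signal tracks the model over 4-40 Hz."""
    model = BackgroundSpectrumModel.healthy()
    freqs, psd = _quiescent_psd(model, seed=4)
    sel = (freqs >= 4) & (freqs <= 40)
    expected = model.psd(freqs[sel])
    ratio = psd[sel] / expected
    assert np.median(ratio) == pytest.approx(1.0, abs=0.2)


def test_healthy_alpha_peak_and_doc_monotone():
    freqs, psd = _quiescent_psd(BackgroundSpectrumModel.healthy(), seed=5)
    alpha = (freqs >= 8) & (freqs <= 13)
    flank = ((freqs >= 5) & (freqs < 8)) | ((freqs > 13) & (freqs <= 16))
    assert psd[alpha].max() > 1.5 * psd[flank].max()

    freqs, psd = _quiescent_psd(BackgroundSpectrumModel.doc_like(), seed=6)
    # smoothed trend decreases above 4 Hz: compare mean power in octave bands
    bands = [(4, 8), (8, 16), (16, 32), (32, 60)]
    means = [psd[(freqs >= lo) & (freqs < hi)].mean() for lo, hi in bands]
    assert all(a > b for a, b in zip(means, means[1:]))


def test_effect_calibration_power_ratio():
    """A factor-2 alpha effect doubles hand-vs-foot alpha power at C3.

    Oracle: the expected band power is the integral of the model PSD over
    the band, so the hand/foot ratio of empirical alpha-power means at the
    affected electrode converges to the factor.
    """
    factor = 2.0
    plan = make_session_plan("healthy", "imagery", seed=7, reps_per_task=60,
                             section_duration=10.0)
    eff = EffectSpec((Effect("C3", "alpha", "hand", factor),))
    rec = synthesize_recording(plan, BackgroundSpectrumModel.healthy(), eff, seed=8, montage=TRI)
    lo, hi = BANDS["alpha"]
    sos = sps.butter(6, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
    band_sig = sps.sosfiltfilt(sos, rec.data, axis=1)
    powers = {"hand": [], "foot": []}
    for s in plan.sections:
        i0, i1 = int(s.start * rec.rate), int(s.end * rec.rate)
        powers[s.task].append(np.var(band_sig[:, i0:i1], axis=1))
    ratio = np.mean([p[0] for p in powers["hand"]]) / np.mean([p[0] for p in powers["foot"]])
    assert ratio == pytest.approx(factor, rel=0.15)
    # unaffected electrode: no effect
    ratio_cz = np.mean([p[2] for p in powers["hand"]]) / np.mean([p[2] for p in powers["foot"]])
    assert ratio_cz == pytest.approx(1.0, rel=0.15)


def test_no_effect_null_balance():
    plan = make_session_plan("patient", "imagery", seed=9)
    rec = synthesize_recording(plan, BackgroundSpectrumModel.healthy(),
                               EffectSpec.none(), seed=10, montage=TRI)
    var = {"hand": [], "foot": []}
    for s in plan.sections:
        i0, i1 = int(s.start * rec.rate), int(s.end * rec.rate)
        var[s.task].append(np.var(rec.data[:, i0:i1]))
    assert np.mean(var["hand"]) == pytest.approx(np.mean(var["foot"]), rel=0.1)


def test_inject_artifacts():
    plan = make_session_plan("patient", "imagery", seed=2, reps_per_task=10)  # 10 min
    rec = synthesize_recording(plan, BackgroundSpectrumModel.healthy(), seed=3, montage=TRI)

    same = inject_artifacts(rec, rate_per_minute=0.0, seed=0)
    assert np.array_equal(same.data, rec.data) and not same.annotations

    noisy = inject_artifacts(rec, rate_per_minute=2.0, amplitude=500.0, seed=4)
    events = [a for a in noisy.annotations if a[2] == "artifact"]
    assert 10 <= len(events) <= 32  # ~Poisson(20)
    for a, b, _ in events:
        i0, i1 = int(a * rec.rate), int(b * rec.rate)
        assert np.abs(noisy.data[:, i0:i1]).max() > np.abs(rec.data[:, i0:i1]).max()
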