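"""Synthetic multichannel EEG with the study's session structure.

The study protocol alternates timed sections of kinaesthetic motor imagery
(right hand vs right foot).  Healthy participants perform an Imagery Trial
(one-minute repetitions of each task) and a pre-Communication Trial (six
yes/no questions, each answered for 30 s by imagining hand movement for
"yes" and foot movement for "no", repeated five times).  Patients perform
shorter versions (30-s imagery repetitions; questions repeated twice).

Because no recordings from the original study are available, this module
generates surrogate EEG with the same section structure, a realistic
1/f-like background spectrum (with or without an alpha peak), and known
class-dependent band-power effects at chosen electrodes, so that every
downstream stage of the pipeline can be validated against ground truth.

Synthesis is spectral: each section of each channel is drawn independently
in the frequency domain with coefficients scaled so the expected one-sided
periodogram equals the model PSD, then inverse-FFT'd.  Band-power effects
multiply the model PSD in the affected band during sections of the affected
task.  This is not a biophysical model — downstream features are band
powers, for which matching the PSD is sufficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bands import BANDS
from .montage import DEFAULT_CHANNELS, ChannelMontage

SAMPLE_RATE = 256.0  # samples per second, fixed by the acquisition protocol

TASKS = ("hand", "foot")
#: Task used to convey each answer: hand imagery = yes, foot imagery = no.
ANSWER_TASK = {"yes": "hand", "no": "foot"}

#: Default intended answer per question id (1..6), alternating yes/no so the
#: answer classes are balanced and ground truth is known to the tests.
DEFAULT_ANSWERS = {1: "yes", 2: "no", 3: "yes", 4: "no", 5: "yes", 6: "no"}


@dataclass(frozen=True)
class Section:
    """One timed block of the protocol."""

    start: float  # seconds from recording onset
    duration: float  # seconds
    task: str  # "hand" | "foot"
    question: int | None = None  # question id for answer sections
    answer: str | None = None  # "yes" | "no" for answer sections

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class SessionPlan:
    """Ordered, timed sections of one trial of one session."""

    cohort: str  # "healthy" | "patient"
    trial_type: str  # "imagery" | "pre-communication"
    sections: tuple[Section, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sections", tuple(self.sections))
        last_end = 0.0
        for s in self.sections:
            if s.start < last_end - 1e-9:
                raise ValueError("sections overlap")
            last_end = s.end
        for s in self.sections:
            if s.task not in TASKS:
                raise ValueError(f"unknown task {s.task!r}")

    @property
    def duration(self) -> float:
        return self.sections[-1].end if self.sections else 0.0

    @property
    def n_sections(self) -> int:
        return len(self.sections)


def make_session_plan(
    cohort: str,
    trial_type: str,
    seed: int,
    *,
    reps_per_task: int | None = None,
    question_reps: int | None = None,
    section_duration: float | None = None,
    answers: dict[int, str] | None = None,
) -> SessionPlan:
    """Build a session plan with the protocol's section structure.

    Defaults reproduce the study design: healthy imagery is 10 sections per
    task of 60 s each in randomized order; patient imagery is 7 per task of
    30 s; pre-communication is 6 questions x 5 repetitions (healthy) or
    x 2 (patients), 30-s answers, question order randomized within each
    repetition block.  ``seed`` fixes the randomized ordering.
    """
    if cohort not in ("healthy", "patient"):
        raise ValueError(f"unknown cohort {cohort!r}: expected 'healthy' or 'patient'")
    if trial_type not in ("imagery", "pre-communication"):
        raise ValueError(
            f"unknown trial_type {trial_type!r}: expected 'imagery' or 'pre-communication'"
        )
    rng = np.random.default_rng(seed)
    sections: list[Section] = []
    t = 0.0
    if trial_type == "imagery":
        reps = reps_per_task if reps_per_task is not None else (10 if cohort == "healthy" else 7)
        dur = section_duration if section_duration is not None else (60.0 if cohort == "healthy" else 30.0)
        tasks = ["hand"] * reps + ["foot"] * reps
        order = rng.permutation(len(tasks))
        for i in order:
            sections.append(Section(start=t, duration=dur, task=tasks[i]))
            t += dur
    else:
        reps = question_reps if question_reps is not None else (5 if cohort == "healthy" else 2)
        dur = section_duration if section_duration is not None else 30.0
        answer_map = dict(DEFAULT_ANSWERS if answers is None else answers)
        questions = sorted(answer_map)
        for _ in range(reps):
            block = rng.permutation(len(questions))
            for qi in block:
                q = questions[qi]
                ans = answer_map[q]
                if ans not in ANSWER_TASK:
                    raise ValueError(f"answer for question {q} must be 'yes' or 'no', got {ans!r}")
                sections.append(
                    Section(start=t, duration=dur, task=ANSWER_TASK[ans], question=q, answer=ans)
                )
                t += dur
    return SessionPlan(cohort=cohort, trial_type=trial_type, sections=tuple(sections))


@dataclass(frozen=True)
class BackgroundSpectrumModel:
    """Parametric resting EEG power spectrum.

    PSD(f) = scale / f**exponent + alpha_amplitude * G(f; alpha_freq,
    alpha_bandwidth) + noise_floor, in uV^2/Hz, where G is a unit-height
    Gaussian.  The healthy preset shows a clear alpha peak; the DoC preset
    (disorders of consciousness) has no alpha peak and relatively more
    low-frequency (delta/theta) power, as seen in resting spectra of
    vegetative / minimally conscious patients.
    """

    exponent: float = 1.2  # 1/f slope (dimensionless)
    scale: float = 20.0  # uV^2/Hz at 1 Hz
    alpha_amplitude: float = 15.0  # uV^2/Hz at the alpha peak
    alpha_freq: float = 10.0  # Hz
    alpha_bandwidth: float = 1.5  # Gaussian sigma, Hz
    noise_floor: float = 0.5  # uV^2/Hz

    def __post_init__(self) -> None:
        if min(self.scale, self.alpha_amplitude, self.noise_floor) < 0:
            raise ValueError("spectral scales must be non-negative")
        if self.alpha_amplitude > 0 and not (8.0 <= self.alpha_freq <= 13.0):
            raise ValueError("alpha peak frequency must lie in [8, 13] Hz")

    @classmethod
    def healthy(cls) -> "BackgroundSpectrumModel":
        return cls()

    @classmethod
    def doc_like(cls) -> "BackgroundSpectrumModel":
        """Attenuated alpha, dominant low frequencies (delta/theta)."""
        return cls(exponent=1.8, scale=60.0, alpha_amplitude=0.0, noise_floor=0.2)

    def psd(self, freqs: np.ndarray) -> np.ndarray:
        """Model PSD (uV^2/Hz) on a frequency grid; finite at f = 0."""
        f = np.maximum(np.asarray(freqs, dtype=float), 0.25)
        out = self.scale / f**self.exponent + self.noise_floor
        if self.alpha_amplitude > 0:
            out = out + self.alpha_amplitude * np.exp(
                -0.5 * ((f - self.alpha_freq) / self.alpha_bandwidth) ** 2
            )
        return out


@dataclass(frozen=True)
class Effect:
    """Multiplicative band-power effect at one electrode during one task."""

    electrode: str
    band: str
    task: str
    factor: float

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.factor < 0:
            raise ValueError("power factor must be >= 0")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth set of class-dependent band-power effects."""

    effects: tuple[Effect, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))

    @classmethod
    def none(cls) -> "EffectSpec":
        return cls(())

    @classmethod
    def from_tuples(cls, entries) -> "EffectSpec":
        return cls(tuple(Effect(*e) for e in entries))

    @property
    def electrodes(self) -> tuple[str, ...]:
        """Ground-truth discriminative electrode set (insertion order)."""
        seen: dict[str, None] = {}
        for e in self.effects:
            seen.setdefault(e.electrode, None)
        return tuple(seen)

    def factor(self, electrode: str, band: str, task: str) -> float:
        out = 1.0
        for e in self.effects:
            if e.electrode == electrode and e.band == band and e.task == task:
                out *= e.factor
        return out


@dataclass
class Recording:
    """Multichannel EEG: signal matrix in uV, montage, typed annotations.

    ``annotations`` is a list of ``(start_s, end_s, kind)`` intervals; kinds
    in use are ``"artifact"`` (ground-truth injected transients) and
    ``"masked"`` (intervals excluded from epoching by artifact rejection).
    """

    rate: float
    data: np.ndarray  # (n_channels, n_samples)
    montage: ChannelMontage
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("signal matrix must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"signal has {self.data.shape[0]} channels but montage has {len(self.montage)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy(self) -> "Recording":
        return Recording(self.rate, self.data.copy(), self.montage, list(self.annotations))

    def masked_intervals(self) -> list[tuple[float, float]]:
        return [(a, b) for a, b, kind in self.annotations if kind == "masked"]


def _section_psd(
    model: BackgroundSpectrumModel,
    freqs: np.ndarray,
    effects: EffectSpec,
    electrode: str,
    task: str,
) -> np.ndarray:
    psd = model.psd(freqs)
    for e in effects.effects:
        if e.electrode == electrode and e.task == task and e.factor != 1.0:
            lo, hi = BANDS[e.band]
            sel = (freqs >= lo) & (freqs < hi)
            psd = np.where(sel, psd * e.factor, psd)
    return psd


def synthesize_recording(
    plan: SessionPlan,
    model: BackgroundSpectrumModel,
    effects: EffectSpec = EffectSpec(),
    seed: int = 0,
    montage: ChannelMontage | None = None,
    rate: float = SAMPLE_RATE,
) -> Recording:
    """Draw a recording whose expected PSD follows *model* section by section.

    During a section of task T, the PSD of every (electrode, band) named by
    *effects* with task T is multiplied by its factor.  Bit-identical for
    identical inputs and seed.
    """
    montage = montage if montage is not None else ChannelMontage()
    for e in effects.effects:
        if e.electrode not in montage:
            raise ValueError(f"effect electrode {e.electrode!r} not in montage")
    rng = np.random.default_rng(seed)
    n_total = int(round(plan.duration * rate))
    data = np.zeros((len(montage), n_total))
    for section in plan.sections:
        i0 = int(round(section.start * rate))
        n = int(round(section.duration * rate))
        freqs = np.fft.rfftfreq(n, d=1.0 / rate)
        for ci, label in enumerate(montage):
            psd = _section_psd(model, freqs, effects, label, section.task)
            # One-sided density S relates to FFT coefficients by
            # S_k = 2 |X_k|^2 / (fs * n); draw X_k complex normal with
            # E|X_k|^2 = S_k * fs * n / 2 so the expected periodogram is S.
            amp = np.sqrt(psd * rate * n / 2.0)
            z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
            coeffs = amp * z / math.sqrt(2.0)
            coeffs[0] = 0.0  # no DC offset
            if n % 2 == 0:
                coeffs[-1] = coeffs[-1].real * math.sqrt(2.0)
            data[ci, i0 : i0 + n] = np.fft.irfft(coeffs, n=n)
    return Recording(rate=rate, data=data, montage=montage)


def inject_artifacts(
    recording: Recording,
    rate_per_minute: float,
    amplitude: float = 500.0,
    seed: int = 0,
    duration: float = 0.5,
) -> Recording:
    """Add high-amplitude transient bursts and annotate their intervals.

    The number of events is Poisson with mean ``rate_per_minute`` x minutes;
    each event is a Hann-windowed burst of the given peak amplitude (uV)
    added to every channel and logged as an ``"artifact"`` annotation.
    """
    if rate_per_minute < 0:
        raise ValueError("artifact rate must be >= 0")
    out = recording.copy()
    if rate_per_minute == 0:
        return out
    rng = np.random.default_rng(seed)
    minutes = recording.duration / 60.0
    n_events = rng.poisson(rate_per_minute * minutes)
    n_burst = int(round(duration * recording.rate))
    burst = np.hanning(n_burst) * amplitude
    for _ in range(n_events):
        start = rng.uniform(0.0, recording.duration - duration)
        i0 = int(round(start * recording.rate))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out.data[:, i0 : i0 + n_burst] += sign * burst
        out.annotations.append((i0 / recording.rate, (i0 + n_burst) / recording.rate, "artifact"))
    return out


def section_labels(plan: SessionPlan) -> list[str]:
    """Task label of each section, in order."""
    return [s.task for s in plan.sections]


__all__ = [
    "SAMPLE_RATE",
    "TASKS",
    "ANSWER_TASK",
    "DEFAULT_ANSWERS",
    "Section",
    "SessionPlan",
    "make_session_plan",
    "BackgroundSpectrumModel",
    "Effect",
    "EffectSpec",
    "Recording",
    "synthesize_recording",
    "inject_artifacts",
]
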