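"""Preprocessing: band-pass filtering, artifact rejection, optional ICA.

The analysis chain band-pass filters the raw EEG to 3–60 Hz, removes
artefactual segments, and can optionally clean the signal with independent
component analysis.  In the original protocol artifact segments were marked
by an expert; here rejection is annotation-driven or uses an automatic
absolute-amplitude threshold, both of which are reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .simulate import Recording

log = logging.getLogger(__name__)


@dataclass
class CleaningReport:
    """What a cleaning stage removed."""

    rejected_intervals: list[tuple[float, float]] = field(default_factory=list)
    fraction_removed: float = 0.0
    n_components_removed: int = 0


def bandpass(
    recording: Recording,
    low: float = 3.0,
    high: float = 60.0,
    order: int = 6,
) -> Recording:
    """Zero-phase Butterworth band-pass filter.

    Applied forward–backward (``sosfiltfilt``) so section boundaries stay
    aligned with the plan.  The default order 6 gives >= 40 dB two-pass
    attenuation both at low/2 and at high + 20 Hz for the 3–60 Hz defaults.
    """
    nyq = recording.rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"cutoffs must satisfy 0 < low < high < Nyquist ({nyq:g} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=recording.rate, output="sos")
    out = recording.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    return out


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    merged = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def reject_artifact_segments(
    recording: Recording,
    method: str = "amplitude",
    threshold: float = 100.0,
    segment: float = 0.5,
    pad: float = 0.25,
) -> tuple[Recording, CleaningReport]:
    """Mask artefactual intervals so downstream epoching skips them.

    ``method="annotations"`` masks exactly the recording's ``"artifact"``
    annotations.  ``method="amplitude"`` scans ``segment``-second windows and
    masks those where any channel exceeds ``threshold`` uV in absolute value,
    padded by ``pad`` seconds on each side.  Unmasked samples are untouched.
    """
    if method not in ("annotations", "amplitude"):
        raise ValueError(f"unknown rejection method {method!r}")
    if method == "amplitude" and threshold <= 0:
        raise ValueError("amplitude threshold must be > 0")
    out = recording.copy()
    if method == "annotations":
        intervals = [(a, b) for a, b, kind in recording.annotations if kind == "artifact"]
    else:
        n_seg = int(round(segment * recording.rate))
        intervals = []
        for i0 in range(0, recording.n_samples, n_seg):
            chunk = recording.data[:, i0 : i0 + n_seg]
            if np.abs(chunk).max() > threshold:
                t0 = i0 / recording.rate
                t1 = min((i0 + n_seg) / recording.rate, recording.duration)
                intervals.append((max(0.0, t0 - pad), min(recording.duration, t1 + pad)))
    intervals = _merge_intervals(intervals)
    removed = sum(b - a for a, b in intervals)
    fraction = min(1.0, removed / recording.duration) if recording.duration else 0.0
    if fraction >= 1.0:
        raise ValueError(
            f"artifact rejection removed all data (fraction={fraction:.2f}); "
            "threshold or annotations are implausible"
        )
    out.annotations.extend((a, b, "masked") for a, b in intervals)
    return out, CleaningReport(rejected_intervals=intervals, fraction_removed=fraction)


def ica_clean(
    recording: Recording,
    max_components: int | None = None,
    criterion: str = "kurtosis",
    kurtosis_bound: float = 10.0,
    correlation_bound: float = 0.5,
    seed: int = 0,
) -> tuple[Recording, CleaningReport]:
    """Remove high-kurtosis (or artifact-correlated) independent components.

    Decomposes the signal with FastICA, zeroes the components matching the
    criterion, and reconstructs.  ``criterion="kurtosis"`` removes components
    whose excess kurtosis exceeds ``kurtosis_bound`` — transient, spiky
    sources.  ``criterion="correlation"`` removes components whose
    squared-amplitude time course correlates above ``correlation_bound`` with
    the annotated artifact intervals.  On decomposition failure the recording
    is passed through unchanged with a logged warning.
    """
    from sklearn.decomposition import FastICA

    if recording.n_channels < 2:
        raise ValueError("ICA cleaning needs at least 2 channels")
    if criterion not in ("kurtosis", "correlation"):
        raise ValueError(f"unknown ICA rejection criterion {criterion!r}")
    n_comp = max_components if max_components is not None else recording.n_channels
    n_comp = min(n_comp, recording.n_channels)
    X = recording.data.T  # samples x channels
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(n_components=n_comp, random_state=seed, max_iter=500)
            sources = ica.fit_transform(X)  # samples x components
    except Exception as exc:  # pragma: no cover - defensive
        log.warning("ICA decomposition failed (%s); passing recording through", exc)
        return recording.copy(), CleaningReport()

    if criterion == "kurtosis":
        k = stats.kurtosis(sources, axis=0, fisher=True)
        remove = np.where(k > kurtosis_bound)[0]
    else:
        mask = np.zeros(recording.n_samples, dtype=bool)
        for a, b, kind in recording.annotations:
            if kind == "artifact":
                mask[int(a * recording.rate) : int(b * recording.rate)] = True
        if not mask.any():
            remove = np.array([], dtype=int)
        else:
            power = sources**2
            r = np.array(
                [np.corrcoef(power[:, i], mask.astype(float))[0, 1] for i in range(n_comp)]
            )
            remove = np.where(np.nan_to_num(r) > correlation_bound)[0]

    cleaned_sources = sources.copy()
    cleaned_sources[:, remove] = 0.0
    recon = ica.inverse_transform(cleaned_sources).T
    out = recording.copy()
    out.data = recon
    report = CleaningReport(n_components_removed=int(len(remove)))
    return out, report


__all__ = ["CleaningReport", "bandpass", "reject_artifact_segments", "ica_clean"]
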