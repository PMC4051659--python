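"""Band-power parameter extraction.

A *parameter* is the vector of theta/alpha/beta/gamma band powers for one
electrode over one averaged 16-s PSD window, labelled with the imagery task
(hand/foot) or the intended answer (yes/no).  The chain is:

1. cut each section into non-overlapping 2-s epochs, discarding the first
   5 s (task onset) and any epoch overlapping a masked interval;
2. estimate each epoch's PSD with a modified periodogram (Blackman–Harris
   taper, FFT, density normalisation so white noise of variance sigma^2
   integrates to sigma^2);
3. average 8 consecutive epoch PSDs (16 s of data) with a configurable hop;
4. integrate the averaged PSD over the four bands.

With 30-s answer sections the defaults yield floor((30-5)/2) = 12 epochs and
12-8+1 = 5 windows, i.e. five parameters per answer.  For imagery sections
the default produces a single parameter per section (the mean PSD over all
of its eligible epochs), so a healthy session yields 10 parameters per task
per electrode and a patient session 7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import BAND_ORDER, BANDS
from .simulate import Recording, SessionPlan

log = logging.getLogger(__name__)

EPOCH_SECONDS = 2.0
ONSET_DISCARD_SECONDS = 5.0
PSD_GROUP = 8  # epochs averaged per 16-s window

#: Tidy-table column order for parameter tables.
PARAMETER_COLUMNS = (
    "subject", "session", "trial", "section", "window", "electrode",
    "theta", "alpha", "beta", "gamma", "label", "question",
)


@dataclass(frozen=True)
class Epoch:
    """A 2-s multichannel span drawn from one section."""

    data: np.ndarray  # (n_channels, n_samples)
    section: int  # section index within the plan
    position: int  # epoch index within the section

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def segment_eligible_epochs(
    recording: Recording,
    plan: SessionPlan,
    discard: float = ONSET_DISCARD_SECONDS,
    epoch_seconds: float = EPOCH_SECONDS,
) -> list[Epoch]:
    """Non-overlapping 2-s epochs per section, starting ``discard`` s in.

    Epochs overlapping a masked interval are skipped; sections too short for
    a single epoch are dropped with a warning.
    """
    rate = recording.rate
    n_epoch = int(round(epoch_seconds * rate))
    masked = recording.masked_intervals()
    epochs: list[Epoch] = []
    for si, section in enumerate(plan.sections):
        usable = section.duration - discard
        n_fit = int(np.floor(usable / epoch_seconds)) if usable > 0 else 0
        if n_fit < 1:
            log.warning(
                "section %d (%.1f s) too short for epoching after %.1f s discard; dropped",
                si, section.duration, discard,
            )
            continue
        for k in range(n_fit):
            t0 = section.start + discard + k * epoch_seconds
            t1 = t0 + epoch_seconds
            if any(a < t1 and b > t0 for a, b in masked):
                continue
            i0 = int(round(t0 * rate))
            epochs.append(Epoch(data=recording.data[:, i0 : i0 + n_epoch], section=si, position=k))
    return epochs


def modified_periodogram(
    data: np.ndarray, rate: float = 256.0
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD of 2-s epochs via a Blackman–Harris-tapered periodogram.

    ``data`` has shape (..., n_samples); returns ``(freqs, psd)`` with psd in
    uV^2/Hz on a 1/epoch-length grid (0.5 Hz for 512 samples at 256/s).  The
    taper's power loss is compensated (scipy's ``density`` scaling), so the
    integrated PSD of white noise equals its variance in expectation.
    """
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("epoch contains non-finite samples")
    freqs, psd = sps.periodogram(
        data, fs=rate, window="blackmanharris", scaling="density", axis=-1
    )
    return freqs, psd


def average_psds(psds: np.ndarray, group: int = PSD_GROUP, hop: int = 1) -> np.ndarray:
    """Sliding mean of ``group`` consecutive epoch PSDs, advancing by ``hop``.

    ``psds`` has shape (n_epochs, ...); output (n_windows, ...) where
    n_windows = floor((n_epochs - group) / hop) + 1, or 0 when there are
    fewer epochs than ``group`` (logged).
    """
    psds = np.asarray(psds)
    n = psds.shape[0]
    if group < 1 or hop < 1:
        raise ValueError("group and hop must be >= 1")
    if n < group:
        log.warning("only %d epoch PSDs available for a group of %d; no windows", n, group)
        return psds[:0]
    starts = range(0, n - group + 1, hop)
    return np.stack([psds[s : s + group].mean(axis=0) for s in starts])


def band_power(psd: np.ndarray, band: str, freqs: np.ndarray) -> np.ndarray:
    """Integrated power (uV^2) in a half-open band [low, high)."""
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    lo, hi = BANDS[band]
    df = freqs[1] - freqs[0]
    sel = (freqs >= lo) & (freqs < hi)
    return np.asarray(psd)[..., sel].sum(axis=-1) * df


def build_parameter_table(
    recording: Recording,
    plan: SessionPlan,
    subject: str = "s1",
    session: int = 1,
    group: int = PSD_GROUP,
    hop: int = 1,
    imagery_per_section: bool = True,
    discard: float = ONSET_DISCARD_SECONDS,
) -> pd.DataFrame:
    """Extract the labelled parameter table for one trial of one session.

    Returns a tidy DataFrame with one row per (window, electrode) carrying
    the four band powers, the class label (task for imagery, answer for
    pre-communication) and the question id where applicable.
    """
    epochs = segment_eligible_epochs(recording, plan, discard=discard)
    if not epochs:
        log.warning("no eligible epochs; returning empty parameter table")
        return pd.DataFrame(columns=list(PARAMETER_COLUMNS))

    channels = list(recording.montage)
    rows: list[dict] = []
    by_section: dict[int, list[Epoch]] = {}
    for ep in epochs:
        by_section.setdefault(ep.section, []).append(ep)

    for si, eps in sorted(by_section.items()):
        section = plan.sections[si]
        if plan.trial_type == "pre-communication":
            label = section.answer
        else:
            label = section.task
        if label is None:
            log.warning("section %d has no label; dropped", si)
            continue
        stack = np.stack([ep.data for ep in eps])  # (n_ep, n_ch, n_samp)
        freqs, psds = modified_periodogram(stack, rate=recording.rate)
        if plan.trial_type == "imagery" and imagery_per_section:
            windows = psds.mean(axis=0, keepdims=True)
        else:
            windows = average_psds(psds, group=group, hop=hop)
        for wi in range(windows.shape[0]):
            powers = {b: band_power(windows[wi], b, freqs) for b in BAND_ORDER}
            for ci, electrode in enumerate(channels):
                rows.append(
                    {
                        "subject": subject,
                        "session": session,
                        "trial": plan.trial_type,
                        "section": si,
                        "window": wi,
                        "electrode": electrode,
                        **{b: powers[b][ci] for b in BAND_ORDER},
                        "label": label,
                        "question": section.question if section.question is not None else -1,
                    }
                )
    return pd.DataFrame(rows, columns=list(PARAMETER_COLUMNS))


__all__ = [
    "Epoch",
    "PARAMETER_COLUMNS",
    "segment_eligible_epochs",
    "modified_periodogram",
    "average_psds",
    "band_power",
    "build_parameter_table",
]
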