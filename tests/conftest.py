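"""Shared fixtures: small synthetic sessions with known ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from micomm.bands import BAND_ORDER
from micomm.montage import ChannelMontage
from micomm.preprocess import bandpass
from micomm.features import build_parameter_table
from micomm.simulate import (
    BackgroundSpectrumModel,
    Effect,
    EffectSpec,
    make_session_plan,
    synthesize_recording,
)

#: Compact montage for classification tests: the planted electrodes plus
#: five uninformative ones, so the whole montage doubles as the BE list.
SMALL_MONTAGE = ChannelMontage(("C3", "C4", "Cz", "Fz", "P3", "P4", "O1", "O2"))

PLANTED = ("C3", "C4", "Cz")


def planted_effects(factor: float = 4.0) -> EffectSpec:
    return EffectSpec(
        (
            Effect("C3", "alpha", "hand", factor),
            Effect("C4", "beta", "hand", factor),
            Effect("Cz", "beta", "foot", factor),
        )
    )


def make_imagery_table(seed: int, cohort: str = "healthy", factor: float = 4.0,
                       montage: ChannelMontage = SMALL_MONTAGE) -> pd.DataFrame:
    plan = make_session_plan(cohort, "imagery", seed)
    rec = synthesize_recording(plan, BackgroundSpectrumModel.healthy(),
                               planted_effects(factor), seed=seed + 1000, montage=montage)
    rec = bandpass(rec)
    return build_parameter_table(rec, plan, subject=cohort[0] + "1", session=1)


def make_precomm_table(seed: int, cohort: str = "patient", factor: float = 4.0,
                       montage: ChannelMontage = SMALL_MONTAGE) -> pd.DataFrame:
    plan = make_session_plan(cohort, "pre-communication", seed)
    rec = synthesize_recording(plan, BackgroundSpectrumModel.healthy(),
                               planted_effects(factor), seed=seed + 2000, montage=montage)
    rec = bandpass(rec)
    return build_parameter_table(rec, plan, subject=cohort[0] + "1", session=1)


@pytest.fixture(scope="session")
def imagery_table() -> pd.DataFrame:
    """Healthy imagery session, 8 channels, factor-4 effects at 3 of them."""
    return make_imagery_table(seed=11)


@pytest.fixture(scope="session")
def patient_precomm_table() -> pd.DataFrame:
    """Patient pre-communication session (12 answers, 5 parameters each)."""
    return make_precomm_table(seed=13)


def random_parameter_table(rng, subject: str, session: int, electrodes,
                           n_per_class: int = 10, labels=("hand", "foot")) -> pd.DataFrame:
    """Parameter table with i.i.d. lognormal powers — a pure null."""
    rows = []
    section = 0
    for label in labels:
        for _ in range(n_per_class):
            for e in electrodes:
                rows.append(
                    {
                        "subject": subject, "session": session, "trial": "imagery",
                        "section": section, "window": 0, "electrode": e,
                        **{b: float(np.exp(rng.normal())) for b in BAND_ORDER},
                        "label": label, "question": -1,
                    }
                )
            section += 1
    return pd.DataFrame(rows)
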