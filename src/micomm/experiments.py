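"""Self-contained validation experiments over the whole pipeline.

Each function builds its own synthetic inputs from a seed, runs the
relevant stage(s) end to end, and returns the measured quantities.  They
back both the acceptance checks and the reproducibility script, so every
reported number is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from .classify import (
    mueller_putz_threshold,
    nested_lfo_communication,
    nested_loo_imagery,
)
from .features import band_power, build_parameter_table, modified_periodogram
from .montage import ChannelMontage, DEFAULT_CHANNELS
from .preprocess import bandpass
from .selection import answer_anovas, anova_two_level, run_selection_anovas
from .simulate import (
    BackgroundSpectrumModel,
    Effect,
    EffectSpec,
    make_session_plan,
    synthesize_recording,
)

#: Compact 8-channel montage whose channels double as the BE list in the
#: planted-effect experiments; the first three carry the effects.
RECOVERY_MONTAGE = ChannelMontage(("C3", "C4", "Cz", "Fz", "P3", "P4", "O1", "O2"))
PLANTED_ELECTRODES = ("C3", "C4", "Cz")


def planted_effects(factor: float = 4.0) -> EffectSpec:
    return EffectSpec(
        (
            Effect("C3", "alpha", "hand", factor),
            Effect("C4", "beta", "hand", factor),
            Effect("Cz", "beta", "foot", factor),
        )
    )


def _session_table(cohort: str, trial: str, seed: int, montage: ChannelMontage,
                   factor: float = 4.0, subject: str = "s1", session: int = 1,
                   **plan_kw):
    plan = make_session_plan(cohort, trial, seed, **plan_kw)
    rec = synthesize_recording(plan, BackgroundSpectrumModel.healthy(),
                               planted_effects(factor), seed=seed + 1, montage=montage)
    rec = bandpass(rec)
    return build_parameter_table(rec, plan, subject=subject, session=session)


def anova_bookkeeping(seed: int = 0) -> dict:
    """Cell counts of the two ANOVA searches on a full-shape synthetic cohort.

    5 healthy subjects x 2 sessions x 31 electrodes x 4 bands for the
    imagery-task search, and 5 patients x 8 best electrodes x 4 bands for
    the answer-labelled search.  Imagery sessions use two repetitions per
    task here — the cell count depends only on the cohort shape.
    """
    montage = ChannelMontage(DEFAULT_CHANNELS)
    rng = np.random.default_rng(seed)
    tables = []
    for s in range(1, 6):
        for k in (1, 2):
            tables.append(
                _session_table("healthy", "imagery", int(rng.integers(2**31 - 1)),
                               montage, subject=f"h{s}", session=k,
                               reps_per_task=2, section_duration=20.0)
            )
    healthy_cells = run_selection_anovas(tables)

    be = list(RECOVERY_MONTAGE)
    patient_tables = [
        _session_table("patient", "pre-communication", int(rng.integers(2**31 - 1)),
                       montage, subject=f"p{p}", session=1)
        for p in range(1, 6)
    ]
    patient_cells = answer_anovas(patient_tables, be)
    return {"healthy_cells": len(healthy_cells), "patient_cells": len(patient_cells)}


def type_one_error(seed: int = 0, n_sim: int = 10_000, n_per_group: int = 10,
                   alpha: float = 0.05) -> float:
    """Null rejection rate of the two-level ANOVA."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sim):
        _, p = anova_two_level(rng.normal(size=n_per_group), rng.normal(size=n_per_group))
        rejections += p < alpha
    return rejections / n_sim


def imagery_recovery(seed: int = 0, n_seeds: int = 10, factor: float = 4.0) -> dict:
    """Nested-LOO recovery of planted factor-``factor`` effects.

    Healthy imagery sessions (20 parameters) over the 8-channel recovery
    montage; returns the seed-averaged ICA and the fraction of external
    folds whose selected subset intersects the planted electrode set.
    """
    rng = np.random.default_rng(seed)
    be = list(RECOVERY_MONTAGE)
    icas, hits = [], []
    for _ in range(n_seeds):
        table = _session_table("healthy", "imagery", int(rng.integers(2**31 - 1)),
                               RECOVERY_MONTAGE, factor=factor)
        report = nested_loo_imagery(table, be)
        icas.append(report.nested_accuracy)
        hits.append(
            np.mean([bool(set(s) & set(PLANTED_ELECTRODES)) for s in report.fold_subsets])
        )
    return {
        "mean_ica": float(np.mean(icas)),
        "planted_fold_fraction": float(np.mean(hits)),
        "n_seeds": n_seeds,
    }


def shuffle_calibration(seed: int = 0, n_shuffles: int = 100) -> dict:
    """How often label-shuffled data beats the chance threshold.

    A patient-sized imagery session with no planted effects; for each
    shuffle the labels are permuted and the full nested LOO is rerun.
    """
    rng = np.random.default_rng(seed)
    plan = make_session_plan("patient", "imagery", int(rng.integers(2**31 - 1)))
    rec = synthesize_recording(plan, BackgroundSpectrumModel.healthy(),
                               EffectSpec.none(), seed=int(rng.integers(2**31 - 1)),
                               montage=RECOVERY_MONTAGE)
    rec = bandpass(rec)
    table = build_parameter_table(rec, plan)
    be = list(RECOVERY_MONTAGE)
    labels = table.pivot_table(index="section", values="label", aggfunc="first")
    exceed = 0
    for _ in range(n_shuffles):
        shuffled = table.copy()
        perm = rng.permutation(labels["label"].to_numpy())
        remap = dict(zip(labels.index, perm))
        shuffled["label"] = shuffled["section"].map(remap)
        report = nested_loo_imagery(shuffled, be)
        exceed += report.nested_accuracy > report.chance_threshold
    return {"exceed_rate": exceed / n_shuffles, "n_shuffles": n_shuffles}


def communication_fold_counts(seed: int = 0) -> dict:
    """External fold counts of the leave-five-out answer decoding."""
    be = list(RECOVERY_MONTAGE)
    healthy = _session_table("healthy", "pre-communication", seed, RECOVERY_MONTAGE)
    patient = _session_table("patient", "pre-communication", seed + 7, RECOVERY_MONTAGE)
    r_h = nested_lfo_communication(healthy, be, cardinalities=(1,))
    r_p = nested_lfo_communication(patient, be, cardinalities=(1,))
    per_answer = healthy.groupby("section")["window"].nunique()
    return {
        "healthy_folds": r_h.n_external,
        "patient_folds": r_p.n_external,
        "parameters_per_answer": int(per_answer.iloc[0]),
        "per_answer_uniform": bool((per_answer == per_answer.iloc[0]).all()),
    }


def spectral_checks(seed: int = 0, n_epochs: int = 400) -> dict:
    """Parseval normalisation and sinusoid band power of the periodogram."""
    rng = np.random.default_rng(seed)
    white = rng.normal(size=(n_epochs, 512))
    freqs, psd = modified_periodogram(white, 256.0)
    parseval = float((psd.sum(axis=-1) * (freqs[1] - freqs[0])).mean())

    a = 2.0
    t = np.arange(512) / 256.0
    x = a * np.sin(2 * np.pi * 10.0 * t)
    freqs, psd = modified_periodogram(x, 256.0)
    alpha_ratio = float(band_power(psd, "alpha", freqs) / (a**2 / 2))
    return {"parseval_ratio": parseval, "sinusoid_alpha_ratio": alpha_ratio,
            "n_epochs": n_epochs}


__all__ = [
    "RECOVERY_MONTAGE",
    "PLANTED_ELECTRODES",
    "planted_effects",
    "anova_bookkeeping",
    "type_one_error",
    "imagery_recovery",
    "shuffle_calibration",
    "communication_fold_counts",
    "spectral_checks",
    "mueller_putz_threshold",
]
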