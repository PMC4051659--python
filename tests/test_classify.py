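"""Subset enumeration, nested CV, majority voting and the chance threshold."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from micomm.classify import (
    enumerate_subsets,
    features_for_subset,
    internal_select,
    majority_vote,
    mueller_putz_threshold,
    nested_lfo_communication,
    nested_loo_imagery,
)
from conftest import PLANTED, SMALL_MONTAGE, make_precomm_table

BE = list(SMALL_MONTAGE)


def test_subset_counts_per_cardinality():
    counts = [len(enumerate_subsets(BE, c)) for c in range(1, 9)]
    assert counts == [8, 28, 56, 70, 56, 28, 8, 1]
    assert sum(counts) == 255
    subsets = enumerate_subsets(BE, 4)
    assert len(set(subsets)) == 70 and all(len(s) == 4 for s in subsets)
    with pytest.raises(ValueError, match="cardinality"):
        enumerate_subsets(BE, 0)
    with pytest.raises(ValueError, match="cardinality"):
        enumerate_subsets(BE, 9)


def test_feature_matrix_shape_and_order(imagery_table):
    for k in (1, 5, 8):
        X, y, meta = features_for_subset(imagery_table, BE[:k])
        assert X.shape == (20, 4 * k)  # 10 parameters per task
        assert sorted(pd.unique(y)) == ["foot", "hand"]
    # column order: electrode blocks of the four bands
    X, _, _ = features_for_subset(imagery_table, ["C3", "C4"])
    Xr, _, _ = features_for_subset(imagery_table, ["C4", "C3"])
    assert np.array_equal(X[:, :4], Xr[:, 4:])
    with pytest.raises(ValueError, match="not present"):
        features_for_subset(imagery_table, ["Pz"])


def test_mueller_putz_threshold_against_binomial_oracle():
    """Exact-binomial oracle: tail sums with rational arithmetic."""

    def oracle(n, alpha):
        for k in range(n + 1):
            tail = sum(Fraction(comb(n, i), 2**n) for i in range(k, n + 1))
            if tail <= Fraction(alpha).limit_denominator(10**6):
                return k / n
        return 1.0

    for n in (5, 12, 20, 30):
        assert mueller_putz_threshold(n, 0.05) == pytest.approx(oracle(n, 0.05))
    assert mueller_putz_threshold(12, 0.05) == pytest.approx(10 / 12)
    assert mueller_putz_threshold(1, 0.05) == 1.0
    thr = mueller_putz_threshold(100, 0.5)
    assert 0.5 < thr <= 0.52  # permissive alpha: threshold just above chance
    with pytest.raises(ValueError, match="alpha"):
        mueller_putz_threshold(10, 1.5)


def test_majority_vote():
    assert majority_vote(["yes", "yes", "no", "yes", "no"]) == "yes"
    assert majority_vote(["no"] * 5) == "no"
    assert majority_vote(["yes", "no"]) is None  # even split -> no answer


def test_internal_select_finds_planted_singleton():
    """A perfectly discriminative electrode wins at cardinality 1."""
    rng = np.random.default_rng(0)
    n = 20
    X = rng.normal(size=(n, 4 * len(BE)))
    y = np.array(["hand", "foot"] * (n // 2))
    X[y == "hand", 0] += 10.0  # C3 theta column separates perfectly
    best, per_card, table = internal_select(X, y, BE)
    assert best == ("C3",)
    assert per_card[1] == ("C3",)
    assert len(table) == 255
    assert table.loc[table["subset"] == ("C3",), "internal_accuracy"].item() == 1.0


def test_internal_accuracy_is_chance_on_noise():
    """A fixed subset's internal LOO accuracy hovers at 0.5 on pure noise."""
    accs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 32))
        y = np.array(["hand", "foot"] * 10)
        _, _, table = internal_select(X, y, BE, cardinalities=(8,))
        accs.append(table["internal_accuracy"].item())
    assert np.mean(accs) == pytest.approx(0.5, abs=0.12)


def test_nested_loo_fold_count_and_recovery(imagery_table):
    report = nested_loo_imagery(imagery_table, BE)
    assert report.n_external == 20
    assert len(report.fold_subsets) == 20
    assert report.best_accuracy >= 0.9  # factor-4 planted effects
    hit = sum(bool(set(s) & set(PLANTED)) for s in report.fold_subsets)
    assert hit / len(report.fold_subsets) >= 0.8
    assert report.chance_threshold == pytest.approx(15 / 20)


def test_nested_lfo_fold_count_and_majority(patient_precomm_table):
    report = nested_lfo_communication(patient_precomm_table, BE)
    assert report.n_external == 12
    assert report.chance_threshold == pytest.approx(10 / 12)
    assert report.best_accuracy >= 0.9
    assert set(report.folds["truth"]) == {"yes", "no"}


def test_healthy_communication_has_thirty_folds():
    table = make_precomm_table(seed=21, cohort="healthy")
    # cardinality restricted to 1: the fold structure is unaffected
    report = nested_lfo_communication(table, BE, cardinalities=(1,))
    assert report.n_external == 30
    assert report.chance_threshold == pytest.approx(20 / 30)


def test_no_leak_canary(imagery_table):
    """Corrupting only the held-out unit leaves internal selection unchanged."""
    baseline = nested_loo_imagery(imagery_table, BE, cardinalities=(1, 2))
    corrupted = imagery_table.copy()
    # external units are ordered by (section, window); corrupt unit 0
    first_section = sorted(corrupted["section"].unique())[0]
    sel = corrupted["section"] == first_section
    corrupted.loc[sel, ["theta", "alpha", "beta", "gamma"]] *= 100.0
    report = nested_loo_imagery(corrupted, BE, cardinalities=(1, 2))
    assert report.fold_subsets[0] == baseline.fold_subsets[0]


def test_feature_scaling_invariance(imagery_table):
    base = nested_loo_imagery(imagery_table, BE, cardinalities=(1, 2))
    scaled = imagery_table.copy()
    scaled[["theta", "alpha", "beta", "gamma"]] *= 37.0
    other = nested_loo_imagery(scaled, BE, cardinalities=(1, 2))
    assert other.accuracy_by_cardinality == base.accuracy_by_cardinality
    assert other.fold_subsets == base.fold_subsets


def test_too_few_parameters_rejected():
    rows = []
    for i, label in enumerate(["hand", "foot", "hand"]):
        for e in BE:
            rows.append({"subject": "x", "session": 1, "trial": "imagery",
                         "section": i, "window": 0, "electrode": e,
                         "theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0,
                         "label": label, "question": -1})
    with pytest.raises(ValueError, match="parameters per class"):
        nested_loo_imagery(pd.DataFrame(rows), BE)
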