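"""Nested cross-validated SVM classification with electrode-subset search.

Given the parameter table of one session and the eight best electrodes
(BE), classification proceeds per trial type:

* Imagery Trial — external leave-one-out over parameters.  For each
  external fold, an internal leave-one-out on the training remainder
  evaluates every electrode subset of every cardinality (8, 28, 56, 70,
  56, 28, 8, 1 subsets for cardinalities 1..8 — 255 in all), the best
  subset is chosen on internal accuracy alone, the model is retrained on
  the full remainder and the held-out parameter is classified.  The
  fraction of correctly classified parameters is the imagery
  classification accuracy (ICA).

* pre-Communication Trial — external leave-five-out over question
  instances (each instance contributes its five parameters); the internal
  loop is likewise leave-five-out.  The held-out answer is decoded by
  majority vote over its five parameter predictions, and the fraction of
  correctly decoded answers is the communication classification accuracy
  (CCA).

The held-out external unit never participates in subset selection,
standardisation statistics, or training — the no-leak contract.  Both
accuracies are compared to the exact-binomial chance threshold
(Mueller-Putz) at significance 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .bands import BAND_ORDER
from .svm import _smo_solve, _smo_solve_warm, train_linear_svm

log = logging.getLogger(__name__)

CARDINALITIES = tuple(range(1, 9))


def enumerate_subsets(electrodes: list[str], cardinality: int) -> list[tuple[str, ...]]:
    """All electrode subsets of one cardinality, in canonical order.

    Canonical order is combination order over the BE ranking, so ties in
    the selection stage resolve deterministically.
    """
    if not 1 <= cardinality <= len(electrodes):
        raise ValueError(f"cardinality must be in 1..{len(electrodes)}, got {cardinality}")
    return list(combinations(electrodes, cardinality))


def features_for_subset(
    table: pd.DataFrame, subset: list[str] | tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Labelled feature matrix for an electrode subset.

    One row per parameter window; 4 x |subset| columns in fixed
    (electrode, band) order.  Returns ``(X, y, meta)`` where ``meta`` keeps
    the section and question of each row.
    """
    missing = [e for e in subset if e not in set(table["electrode"])]
    if missing:
        raise ValueError(f"electrodes {missing} not present in the parameter table")
    wide = table.pivot_table(
        index=["section", "window"],
        columns="electrode",
        values=list(BAND_ORDER),
        sort=True,
    )
    cols = [(band, e) for e in subset for band in BAND_ORDER]
    X = wide[cols].to_numpy(dtype=float)
    meta = (
        table[["section", "window", "label", "question"]]
        .drop_duplicates(["section", "window"])
        .sort_values(["section", "window"])
        .reset_index(drop=True)
    )
    y = meta["label"].to_numpy()
    return X, y, meta


@dataclass
class SubsetResult:
    subset: tuple[str, ...]
    cardinality: int
    internal_accuracy: float


@dataclass
class TrialReport:
    """Outcome of one session's nested cross-validation."""

    trial_type: str
    n_external: int
    accuracy_by_cardinality: dict[int, float]
    nested_accuracy: float  # external accuracy of the globally best subset per fold
    best_accuracy: float  # max over cardinalities (best-configuration accuracy)
    best_cardinality: int
    chance_threshold: float
    significant: bool
    fold_subsets: list[tuple[str, ...]] = field(default_factory=list)
    folds: pd.DataFrame | None = None


def mueller_putz_threshold(n: int, alpha: float = 0.05, n_classes: int = 2) -> float:
    """Exact-binomial chance-level accuracy threshold.

    The smallest k/n such that P(X >= k) <= alpha for X ~ Binomial(n,
    1/n_classes); accuracies strictly above it are unlikely under random
    classification.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    k = np.arange(n + 1)
    tail = stats.binom.sf(k - 1, n, 1.0 / n_classes)
    ok = np.nonzero(tail <= alpha)[0]
    return float(ok[0]) / n if len(ok) else 1.0


def _standardize(train: np.ndarray, *others: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, *(((o - mu) / sd) for o in others)


class _SubsetSearch:
    """Shared machinery: per-electrode Gram decomposition of the subset SVMs.

    The Gram matrix of a subset's feature block is the sum of per-electrode
    Gram matrices, so each of the 255 subset SVMs reuses eight precomputed
    blocks instead of re-slicing the feature matrix.
    """

    def __init__(self, electrodes: list[str], cardinalities=CARDINALITIES, C: float = 1.0,
                 tol: float = 1e-3):
        self.electrodes = list(electrodes)
        self.C = float(C)
        self.tol = float(tol)
        max_card = max(cardinalities)
        wanted = set(cardinalities)
        # depth-first (lexicographic) order so each subset extends the
        # subset one position earlier on the stack by a single electrode
        self.subsets: list[tuple[int, ...]] = []
        self.subset_labels: list[tuple[str, ...]] = []
        self._emit: list[bool] = []

        def rec(prefix: tuple[int, ...], start: int) -> None:
            for e in range(start, len(self.electrodes)):
                s = prefix + (e,)
                self.subsets.append(s)
                self.subset_labels.append(tuple(self.electrodes[i] for i in s))
                self._emit.append(len(s) in wanted)
                if len(s) < max_card:
                    rec(s, e + 1)

        rec((), 0)

    def evaluate_subsets(
        self, X: np.ndarray, yv: np.ndarray, fold_indices: list[tuple[np.ndarray, np.ndarray]]
    ) -> np.ndarray:
        """Internal-CV accuracy of every subset; rows pooled over folds.

        ``yv`` is the +/-1 label vector; ``fold_indices`` gives (train,
        test) row indices per internal fold.  Standardisation uses each
        fold's training rows only.  Subset Gram matrices are built
        incrementally along the depth-first subset order (the Gram of a
        feature block is the sum of its per-electrode Grams).
        """
        n_subsets = len(self.subsets)
        correct = np.zeros(n_subsets)
        total = 0
        n_el = len(self.electrodes)
        for tr, te in fold_indices:
            if len(np.unique(yv[tr])) < 2:
                continue  # degenerate internal split
            Xtr, Xte = _standardize(X[tr], X[te])
            gtr = [None] * n_el  # per-electrode train Gram
            gx = [None] * n_el  # per-electrode test-x-train Gram
            for e in range(n_el):
                B = Xtr[:, 4 * e : 4 * e + 4]
                gtr[e] = B @ B.T
                gx[e] = Xte[:, 4 * e : 4 * e + 4] @ B.T
            total += len(te)
            ytr = yv[tr]
            yte = yv[te]
            zeros = np.zeros(len(tr))
            stack_tr: list[np.ndarray] = []
            stack_x: list[np.ndarray] = []
            stack_a: list[np.ndarray | None] = []
            for si, s in enumerate(self.subsets):
                depth = len(s)
                e = s[-1]
                if depth == 1:
                    Ktr, Kx = gtr[e].copy(), gx[e].copy()
                else:
                    Ktr = stack_tr[depth - 2] + gtr[e]
                    Kx = stack_x[depth - 2] + gx[e]
                del stack_tr[depth - 1 :], stack_x[depth - 1 :], stack_a[depth - 1 :]
                stack_tr.append(Ktr)
                stack_x.append(Kx)
                if not self._emit[si]:
                    stack_a.append(None)
                    continue
                # warm start from the nearest solved ancestor subset
                a0 = zeros
                for a in reversed(stack_a):
                    if a is not None:
                        a0 = a
                        break
                alpha, b = _smo_solve_warm(Ktr, ytr, self.C, self.tol, 1_000_000, a0)
                stack_a.append(alpha)
                dec = Kx @ (alpha * ytr) + b
                correct[si] += np.sum((dec > 0) == (yte > 0))
        if total == 0:
            return np.full(n_subsets, np.nan)
        acc = correct / total
        acc[~np.array(self._emit)] = np.nan
        return acc

    def best_per_cardinality(self, accuracies: np.ndarray) -> dict[int, int]:
        """Index of the best subset at each cardinality (first wins ties)."""
        best: dict[int, int] = {}
        for si, s in enumerate(self.subsets):
            card = len(s)
            acc = accuracies[si]
            if np.isnan(acc):
                continue
            if card not in best or acc > accuracies[best[card]]:
                best[card] = si
        return best

    def best_overall(self, accuracies: np.ndarray) -> int:
        """Globally best subset: accuracy, then smaller cardinality, then order."""
        best = -1
        for si in range(len(self.subsets)):
            if np.isnan(accuracies[si]):
                continue
            if best == -1:
                best = si
                continue
            a, b_ = accuracies[si], accuracies[best]
            if a > b_ or (a == b_ and len(self.subsets[si]) < len(self.subsets[best])):
                best = si
        if best == -1:
            raise ValueError("no subset could be evaluated on the internal splits")
        return best

    def train_predict(self, X, yv, tr, te, subset_idx) -> np.ndarray:
        """Retrain one subset on rows ``tr`` and classify rows ``te``."""
        s = self.subsets[subset_idx]
        cols = np.concatenate([np.arange(4 * e, 4 * e + 4) for e in s])
        Xtr, Xte = _standardize(X[np.ix_(tr, cols)], X[np.ix_(te, cols)])
        K = Xtr @ Xtr.T
        alpha, b = _smo_solve(K, yv[tr], self.C, self.tol, 1_000_000)
        return (Xte @ Xtr.T) @ (alpha * yv[tr]) + b


def internal_select(
    X: np.ndarray,
    y: np.ndarray,
    electrodes: list[str],
    groups: np.ndarray | None = None,
    cardinalities=CARDINALITIES,
    C: float = 1.0,
    tol: float = 1e-3,
) -> tuple[tuple[str, ...], dict[int, tuple[str, ...]], pd.DataFrame]:
    """Exhaustive subset search by internal cross-validation.

    Leave-one-out over rows, or leave-one-group-out when ``groups`` is
    given.  Returns the globally best subset, the best subset per
    cardinality, and the full per-subset accuracy table.  Ties resolve to
    the higher accuracy, then the smaller cardinality, then the first
    subset in canonical order.
    """
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("internal selection needs both classes in the training set")
    yv = np.where(y == classes[1], 1.0, -1.0)
    search = _SubsetSearch(electrodes, cardinalities, C, tol)
    folds = _loo_folds(len(y)) if groups is None else _group_folds(np.asarray(groups))
    acc = search.evaluate_subsets(X, yv, folds)
    best = search.best_overall(acc)
    per_card = {
        card: search.subset_labels[si] for card, si in search.best_per_cardinality(acc).items()
    }
    table = pd.DataFrame(
        {
            "subset": search.subset_labels,
            "cardinality": [len(s) for s in search.subsets],
            "internal_accuracy": acc,
        }
    )
    table = table[search._emit].reset_index(drop=True)
    return search.subset_labels[best], per_card, table


def _loo_folds(n: int) -> list[tuple[np.ndarray, np.ndarray]]:
    idx = np.arange(n)
    return [(np.delete(idx, i), np.array([i])) for i in range(n)]


def _group_folds(groups: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    idx = np.arange(len(groups))
    out = []
    for g in pd.unique(groups):
        te = idx[groups == g]
        out.append((idx[groups != g], te))
    return out


def nested_loo_imagery(
    table: pd.DataFrame,
    electrodes: list[str],
    C: float = 1.0,
    alpha: float = 0.05,
    cardinalities=CARDINALITIES,
    tol: float = 1e-3,
) -> TrialReport:
    """Nested leave-one-out over parameters; reports the ICA."""
    X, y, meta = features_for_subset(table, electrodes)
    classes = np.unique(y)
    if len(classes) != 2 or min((y == c).sum() for c in classes) < 2:
        raise ValueError("imagery classification needs >= 2 parameters per class")
    yv = np.where(y == classes[1], 1.0, -1.0)
    n = len(y)
    search = _SubsetSearch(electrodes, cardinalities, C, tol)

    n_cards = list(cardinalities)
    correct_best = 0
    correct_card = {c: 0 for c in n_cards}
    fold_subsets: list[tuple[str, ...]] = []
    records = []
    for ext_tr, ext_te in _loo_folds(n):
        acc = search.evaluate_subsets(X[ext_tr], yv[ext_tr], _loo_folds(len(ext_tr)))
        best_si = search.best_overall(acc)
        per_card = search.best_per_cardinality(acc)
        fold_subsets.append(search.subset_labels[best_si])
        dec = search.train_predict(X, yv, ext_tr, ext_te, best_si)
        ok = bool((dec[0] > 0) == (yv[ext_te[0]] > 0))
        correct_best += ok
        for card, si in per_card.items():
            d = search.train_predict(X, yv, ext_tr, ext_te, si)
            correct_card[card] += bool((d[0] > 0) == (yv[ext_te[0]] > 0))
        records.append(
            {
                "fold": int(ext_te[0]),
                "truth": y[ext_te[0]],
                "prediction": classes[1] if dec[0] > 0 else classes[0],
                "subset": "+".join(search.subset_labels[best_si]),
                "correct": ok,
            }
        )
    acc_by_card = {c: correct_card[c] / n for c in n_cards}
    best_card = max(acc_by_card, key=lambda c: (acc_by_card[c], -c))
    threshold = mueller_putz_threshold(n, alpha=alpha)
    best_acc = acc_by_card[best_card]
    return TrialReport(
        trial_type="imagery",
        n_external=n,
        accuracy_by_cardinality=acc_by_card,
        nested_accuracy=correct_best / n,
        best_accuracy=best_acc,
        best_cardinality=best_card,
        chance_threshold=threshold,
        significant=best_acc > threshold,
        fold_subsets=fold_subsets,
        folds=pd.DataFrame(records),
    )


def majority_vote(predictions) -> str | None:
    """Majority label of a set of parameter predictions; ``None`` on a tie."""
    vals, counts = np.unique(np.asarray(predictions), return_counts=True)
    if len(vals) == 1:
        return vals[0]
    if counts[0] == counts[1]:
        return None
    return vals[np.argmax(counts)]


def nested_lfo_communication(
    table: pd.DataFrame,
    electrodes: list[str],
    C: float = 1.0,
    alpha: float = 0.05,
    cardinalities=CARDINALITIES,
    expected_parameters: int = 5,
    on_incomplete: str = "skip",
    tol: float = 1e-3,
) -> TrialReport:
    """Nested leave-five-out over question instances; reports the CCA.

    Each external fold holds out one question instance (its five
    parameters); the decoded answer is the majority vote over the five
    parameter predictions.  A question instance with a different parameter
    count is skipped with a warning (``on_incomplete="skip"``) or voted
    over the available count (``"vote"``).
    """
    if on_incomplete not in ("skip", "vote"):
        raise ValueError(f"unknown on_incomplete policy {on_incomplete!r}")
    X, y, meta = features_for_subset(table, electrodes)
    groups = meta["section"].to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("communication decoding needs both answer classes")
    yv = np.where(y == classes[1], 1.0, -1.0)
    search = _SubsetSearch(electrodes, cardinalities, C, tol)

    unique_groups = pd.unique(groups)
    group_label = {g: y[groups == g][0] for g in unique_groups}
    n_per_class = pd.Series([group_label[g] for g in unique_groups]).value_counts()
    if n_per_class.min() < 2:
        raise ValueError("communication decoding needs >= 2 question instances per class")

    folds_eval: list[int] = []
    correct_best = 0
    correct_card: dict[int, int] = {c: 0 for c in cardinalities}
    fold_subsets: list[tuple[str, ...]] = []
    records = []
    idx = np.arange(len(y))
    for g in unique_groups:
        te = idx[groups == g]
        if len(te) != expected_parameters:
            if on_incomplete == "skip":
                log.warning(
                    "question instance %s has %d parameters (expected %d); fold skipped",
                    g, len(te), expected_parameters,
                )
                continue
        tr = idx[groups != g]
        acc = search.evaluate_subsets(X[tr], yv[tr], _group_folds(groups[tr]))
        best_si = search.best_overall(acc)
        per_card = search.best_per_cardinality(acc)
        fold_subsets.append(search.subset_labels[best_si])
        folds_eval.append(g)

        dec = search.train_predict(X, yv, tr, te, best_si)
        preds = np.where(dec > 0, classes[1], classes[0])
        answer = majority_vote(preds)
        truth = group_label[g]
        ok = bool(answer == truth)
        correct_best += ok
        for card, si in per_card.items():
            d = search.train_predict(X, yv, tr, te, si)
            a = majority_vote(np.where(d > 0, classes[1], classes[0]))
            correct_card[card] += bool(a == truth)
        records.append(
            {
                "fold": int(g),
                "truth": truth,
                "prediction": answer if answer is not None else "tie",
                "subset": "+".join(search.subset_labels[best_si]),
                "correct": ok,
            }
        )
    n_ext = len(folds_eval)
    if n_ext == 0:
        raise ValueError("no complete question instances to evaluate")
    acc_by_card = {c: correct_card[c] / n_ext for c in cardinalities}
    best_card = max(acc_by_card, key=lambda c: (acc_by_card[c], -c))
    threshold = mueller_putz_threshold(n_ext, alpha=alpha)
    best_acc = acc_by_card[best_card]
    return TrialReport(
        trial_type="pre-communication",
        n_external=n_ext,
        accuracy_by_cardinality=acc_by_card,
        nested_accuracy=correct_best / n_ext,
        best_accuracy=best_acc,
        best_cardinality=best_card,
        chance_threshold=threshold,
        significant=best_acc > threshold,
        fold_subsets=fold_subsets,
        folds=pd.DataFrame(records),
    )


__all__ = [
    "CARDINALITIES",
    "SubsetResult",
    "TrialReport",
    "enumerate_subsets",
    "features_for_subset",
    "train_linear_svm",
    "internal_select",
    "nested_loo_imagery",
    "nested_lfo_communication",
    "majority_vote",
    "mueller_putz_threshold",
]
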