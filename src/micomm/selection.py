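"""Best-electrode search by per-band two-level ANOVA scoring.

For every subject, session, electrode and band, a one-way fixed-effects
ANOVA on two levels (hand vs foot) tests whether the band power differs
between the imagery tasks at p < 0.05.  An electrode earns one unit score
for each subject-session in which it is significant in at least one band;
electrodes are ranked by total score and the top k = 8 become the "best
electrodes" (BE) used by the classification stage.  With 5 subjects and 2
sessions the maximum score is 10 and the search runs 5 x 2 x 31 x 4 = 1240
ANOVAs.  No multiple-testing correction is applied by default, matching the
selection procedure this reimplements; Bonferroni is available as a flag
for sensitivity analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .bands import BAND_ORDER

ANOVA_COLUMNS = ("subject", "session", "electrode", "band", "F", "p", "n_a", "n_b", "valid")


def anova_two_level(values_a, values_b) -> tuple[float, float]:
    """One-way fixed-effects F-test between two groups.

    Returns ``(F, p)`` with degrees of freedom (1, n_a + n_b - 2).  With zero
    within-group variance the statistic is defined as 0 (p = 1) for equal
    means and +inf (p = 0) otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must be finite")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    grand = (a.sum() + b.sum()) / (na + nb)
    ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ssw = ((a - ma) ** 2).sum() + ((b - mb) ** 2).sum()
    df2 = na + nb - 2
    if ssw == 0.0:
        return (0.0, 1.0) if ssb == 0.0 else (float("inf"), 0.0)
    f = ssb / (ssw / df2)
    p = float(stats.f.sf(f, 1, df2))
    return float(f), p


def run_selection_anovas(tables: pd.DataFrame | list[pd.DataFrame]) -> pd.DataFrame:
    """Per subject-session-electrode-band ANOVA over a cohort's tables.

    ``tables`` is a parameter table (or list of them, concatenated) whose
    ``label`` column carries the two class levels.  Produces exactly
    S x K x E x 4 cells; cells whose table lacks one of the two classes are
    flagged invalid rather than fabricated.
    """
    if isinstance(tables, (list, tuple)):
        tables = pd.concat(tables, ignore_index=True)
    if tables.empty:
        return pd.DataFrame(columns=list(ANOVA_COLUMNS))
    cells = []
    for (subject, session), tab in tables.groupby(["subject", "session"], sort=True):
        levels = sorted(tab["label"].unique())
        for electrode, sub in tab.groupby("electrode", sort=False):
            for band in BAND_ORDER:
                if len(levels) == 2:
                    a = sub.loc[sub["label"] == levels[0], band].to_numpy()
                    b = sub.loc[sub["label"] == levels[1], band].to_numpy()
                else:
                    a = b = np.empty(0)
                if a.size >= 2 and b.size >= 2:
                    f, p = anova_two_level(a, b)
                    valid = True
                else:
                    f, p, valid = np.nan, np.nan, False
                cells.append(
                    {
                        "subject": subject, "session": session,
                        "electrode": electrode, "band": band,
                        "F": f, "p": p, "n_a": a.size, "n_b": b.size, "valid": valid,
                    }
                )
    return pd.DataFrame(cells, columns=list(ANOVA_COLUMNS))


def answer_anovas(tables: pd.DataFrame | list[pd.DataFrame], electrodes: list[str]) -> pd.DataFrame:
    """Per-subject BE-band ANOVA on answer-labelled (yes/no) parameters.

    Same bookkeeping as :func:`run_selection_anovas`, restricted to the
    given electrodes, with the sign of the yes-minus-no mean power
    difference reported alongside p.
    """
    if isinstance(tables, (list, tuple)):
        tables = pd.concat(tables, ignore_index=True)
    tables = tables[tables["electrode"].isin(electrodes)]
    cells = run_selection_anovas(tables)
    signs = []
    for _, row in cells.iterrows():
        tab = tables[
            (tables["subject"] == row["subject"])
            & (tables["session"] == row["session"])
            & (tables["electrode"] == row["electrode"])
        ]
        yes = tab.loc[tab["label"] == "yes", row["band"]]
        no = tab.loc[tab["label"] == "no", row["band"]]
        if len(yes) and len(no):
            signs.append(int(np.sign(yes.mean() - no.mean())))
        else:
            signs.append(0)
    cells = cells.copy()
    cells["yes_minus_no_sign"] = signs
    return cells


def score_electrodes(cells: pd.DataFrame, alpha: float = 0.05, bonferroni: bool = False) -> pd.DataFrame:
    """Unit score per electrode: +1 per subject-session with any band p < alpha.

    Returns a DataFrame indexed by electrode with columns ``score`` (the
    unit score) and ``n_significant_cells`` (count of significant
    electrode-band cells, used only for tie-breaking).
    """
    cells = cells[cells["valid"]].copy()
    if bonferroni:
        alpha = alpha / len(BAND_ORDER)
    sig = cells["p"] < alpha
    cells["sig"] = sig
    per_ss = (
        cells.groupby(["subject", "session", "electrode"])["sig"].any().reset_index()
    )
    score = per_ss.groupby("electrode")["sig"].sum().astype(int)
    n_cells = cells.groupby("electrode")["sig"].sum().astype(int)
    out = pd.DataFrame({"score": score, "n_significant_cells": n_cells}).fillna(0)
    return out.astype(int)


def select_best(
    scores: pd.DataFrame,
    k: int = 8,
    montage_order: list[str] | None = None,
) -> list[str]:
    """The k highest-scoring electrodes, deterministically tie-broken.

    Ties at rank k resolve by higher count of significant electrode-band
    cells, then by canonical montage order (or alphabetical order when no
    montage is given).
    """
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} scored electrodes")
    order = {e: i for i, e in enumerate(montage_order)} if montage_order else None

    def rank_key(e: str):
        pos = order.get(e, len(order)) if order is not None else e
        return (-int(scores.loc[e, "score"]), -int(scores.loc[e, "n_significant_cells"]), pos)

    ranked = sorted(scores.index, key=rank_key)
    return ranked[:k]


__all__ = [
    "ANOVA_COLUMNS",
    "anova_two_level",
    "run_selection_anovas",
    "answer_anovas",
    "score_electrodes",
    "select_best",
]
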