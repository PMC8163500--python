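"""Comprehension-question scoring and behavioral statistics.

Each trial ends with four 3-alternative questions about the attended
narrative (chance accuracy 1/3).  Per-participant accuracy is the mean
correct answer per condition; the group is tested against chance with a
one-sample t-test, between conditions with a paired t-test, and a
median split on the 1 Hz phrase-rate ITPC of the Structured condition
probes whether neural tracking of the task-irrelevant stream relates to
behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CHANCE_LEVEL",
    "MedianSplitResult",
    "score_accuracy",
    "test_vs_chance",
    "paired_condition_test",
    "median_split_by_neural",
]

#: 3-alternative questions; exact in computation, 0.33 only in display.
CHANCE_LEVEL = 1.0 / 3.0


@dataclass(frozen=True)
class MedianSplitResult:
    low_group: np.ndarray  # participant ids
    high_group: np.ndarray
    mean_low: float
    mean_high: float
    t_stat: float
    p: float
    t_stat_diff: float  # on Structured - NonStructured accuracy difference
    p_diff: float


def score_accuracy(tbl: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-condition mean accuracy.

    Expects columns participant_id, trial_id, condition, question_index,
    correct; every (participant, condition) cell must contain trials.
    """
    if len(tbl) == 0:
        raise ValueError("empty answer table")
    acc = (tbl.groupby(["participant_id", "condition"])["correct"]
           .mean().unstack("condition"))
    # every participant must contribute trials to both conditions
    acc = acc.reindex(columns=["Structured", "NonStructured"])
    if acc.isna().any().any():
        missing = acc[acc.isna().any(axis=1)].index.tolist()
        raise ValueError(f"participants with no trials in some condition: {missing}")
    return acc


def test_vs_chance(accuracies, chance: float = CHANCE_LEVEL) -> tuple:
    """One-sample t-test of accuracies against chance; returns (t, df, p)."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 participants")
    df = acc.size - 1
    if acc.std(ddof=1) == 0:
        if np.allclose(acc, chance):
            return 0.0, df, 1.0
        raise ValueError("zero variance in accuracies away from chance: "
                         "t statistic undefined")
    t, p = stats.ttest_1samp(acc, chance)
    return float(t), df, float(p)


def paired_condition_test(acc_a, acc_b) -> tuple:
    """Paired t-test of accuracy between conditions; returns (t, df, p)."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    t, p = stats.ttest_rel(a, b)
    return float(t), a.size - 1, float(p)


def median_split_by_neural(accuracies: pd.DataFrame,
                           itpc_1hz_per_participant: pd.Series,
                           structured: str = "Structured",
                           nonstructured: str = "NonStructured") -> MedianSplitResult:
    """Median-split participants on 1 Hz Structured ITPC; compare behavior.

    Splits at the median of the (channel-averaged) 1 Hz ITPC in the
    Structured condition; with an odd number of participants the median
    participant joins the lower group.  Two-sample two-tailed t-tests are
    run on Structured accuracy and on the Structured - NonStructured
    difference.
    """
    itpc = itpc_1hz_per_participant.reindex(accuracies.index)
    if itpc.isna().any():
        raise ValueError("ITPC values missing for some participants")
    order = np.argsort(itpc.to_numpy(), kind="stable")
    n = len(order)
    low_idx = order[: (n + 1) // 2]
    high_idx = order[(n + 1) // 2:]
    acc_s = accuracies[structured].to_numpy()
    acc_d = acc_s - accuracies[nonstructured].to_numpy()
    t, p = stats.ttest_ind(acc_s[high_idx], acc_s[low_idx])
    t_d, p_d = stats.ttest_ind(acc_d[high_idx], acc_d[low_idx])
    return MedianSplitResult(
        low_group=accuracies.index.to_numpy()[low_idx],
        high_group=accuracies.index.to_numpy()[high_idx],
        mean_low=float(acc_s[low_idx].mean()),
        mean_high=float(acc_s[high_idx].mean()),
        t_stat=float(t), p=float(p),
        t_stat_diff=float(t_d), p_diff=float(p_d))
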