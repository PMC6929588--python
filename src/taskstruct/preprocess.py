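"""Trial- and participant-level filtering, transition labels, and bins.

The switch-cost analysis rests on classifying each learning-phase trial by
how the candidate supraordinate dimension's level relates to the previous
trial: repeats ("supraordinate-repeat"), changes while the other dimension
repeats ("supraordinate-switch"), or changes together with the other
dimension (a double feature switch, excluded as unattributable to either
feature rule).  Reaction-time analyses keep only correct responses inside
the 200-1250 ms window; accuracy analyses keep all responded trials (errors
are the outcome).  The first trial is always excluded from switch-cost data.

Memory analyses keep responded trials with RT >= 200 ms, and participants
need at least 10 responded old trials in every learning-phase bin (three
bins of 30 plus a fourth of 38 for 128-trial designs; four bins of 30 for
120-trial designs) to enter the binned ANOVA.

Boundary conventions are strict readings of the printed inequalities:
"<200 ms" and ">1250 ms" exclude, so 200 and 1250 are retained; accuracy
"<65%" excludes, so exactly 65% is included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .designs import Category, DesignError

__all__ = [
    "FIRST",
    "SUPRA_REPEAT",
    "SUPRA_SWITCH",
    "DOUBLE_SWITCH",
    "RT_FAST_MS",
    "RT_SLOW_MS",
    "ACCURACY_GATE",
    "MIN_TRIALS_PER_BIN",
    "BinAssignment",
    "classify_transition",
    "add_transition_labels",
    "filter_rt_trials",
    "filter_accuracy_trials",
    "filter_memory_trials",
    "participant_gate",
    "assign_bins",
    "bin_occupancy_ok",
]

FIRST = "first"
SUPRA_REPEAT = "supra_repeat"
SUPRA_SWITCH = "supra_switch"
DOUBLE_SWITCH = "double_switch_excluded"

RT_FAST_MS = 200.0
RT_SLOW_MS = 1250.0
ACCURACY_GATE = 0.65
MIN_TRIALS_PER_BIN = 10


def classify_transition(
    prev: Optional[Category], curr: Category, supra_dim_index: int
) -> str:
    """Label one trial transition under a candidate supraordinate dimension.

    ``supra_dim_index`` selects which of the category's two level slots is
    treated as supraordinate (0 or 1).
    """
    if prev is None:
        return FIRST
    supra_changed = prev.level_on(supra_dim_index) != curr.level_on(supra_dim_index)
    sub_changed = prev.level_on(1 - supra_dim_index) != curr.level_on(1 - supra_dim_index)
    if supra_changed and sub_changed:
        return DOUBLE_SWITCH
    return SUPRA_SWITCH if supra_changed else SUPRA_REPEAT


def add_transition_labels(
    trials: pd.DataFrame, supra_col: str, sub_col: str, label_col: str = "transition"
) -> pd.DataFrame:
    """Vectorized transition labels for a (single participant's) trial frame.

    ``supra_col``/``sub_col`` name the level columns of the candidate
    supraordinate and the other dimension.  Rows must be in trial order.
    """
    supra = trials[supra_col].to_numpy()
    sub = trials[sub_col].to_numpy()
    n = len(trials)
    labels = np.empty(n, dtype=object)
    if n:
        labels[0] = FIRST
        supra_chg = supra[1:] != supra[:-1]
        sub_chg = sub[1:] != sub[:-1]
        rest = np.where(
            supra_chg & sub_chg,
            DOUBLE_SWITCH,
            np.where(supra_chg, SUPRA_SWITCH, SUPRA_REPEAT),
        )
        labels[1:] = rest
    out = trials.copy()
    out[label_col] = labels
    return out


def filter_rt_trials(records: pd.DataFrame) -> pd.DataFrame:
    """RT-analysis gate: correct, responded, 200 <= rt <= 1250 ms, not trial 1."""
    ok = (
        (records["trial"] != 1)
        & ~records["timeout"].astype(bool)
        & records["correct"].astype(bool)
        & (records["rt_ms"] >= RT_FAST_MS)
        & (records["rt_ms"] <= RT_SLOW_MS)
    )
    return records.loc[ok.fillna(False)]


def filter_accuracy_trials(records: pd.DataFrame) -> pd.DataFrame:
    """Accuracy-analysis gate: responded trials (errors kept), not trial 1."""
    ok = (records["trial"] != 1) & ~records["timeout"].astype(bool)
    return records.loc[ok]


def filter_memory_trials(records: pd.DataFrame) -> pd.DataFrame:
    """Memory gate: a registered response with rt >= 200 ms."""
    ok = records["rating"].notna() & (records["rt_ms"] >= RT_FAST_MS)
    return records.loc[ok]


def participant_gate(
    learning_accuracy: float,
    post_test_correct: bool = True,
    age: Optional[float] = None,
    max_age: Optional[float] = None,
) -> tuple[bool, str]:
    """Participant-level inclusion decision with a reason string.

    Excludes for learning accuracy strictly below 65%, a failed post-test of
    the category-response associations, or (where the policy applies) age
    above ``max_age``.  Returns ``(include, reason)``; included participants
    with accuracy above 90% are marked bonus-eligible in the reason.
    """
    if not 0.0 <= learning_accuracy <= 1.0:
        raise ValueError("learning_accuracy must lie in [0, 1]")
    if learning_accuracy < ACCURACY_GATE:
        return False, "accuracy"
    if not post_test_correct:
        return False, "post_test"
    if max_age is not None and age is not None and age > max_age:
        return False, "age"
    return True, "bonus" if learning_accuracy > 0.90 else "included"


@dataclass(frozen=True)
class BinAssignment:
    """Learning-phase position bins used for the memory analyses."""

    bin_sizes: tuple[int, ...]

    @property
    def edges(self) -> np.ndarray:
        return np.cumsum(self.bin_sizes)

    def bin_of(self, lp_trial: np.ndarray | int) -> np.ndarray | int:
        """1-based bin index of 1-based learning-phase trial positions."""
        idx = np.searchsorted(self.edges, lp_trial, side="left") + 1
        if np.any(np.asarray(idx) > len(self.bin_sizes)):
            raise DesignError("learning trial index beyond the binned range")
        return idx


def assign_bins(n_learning_trials: int) -> BinAssignment:
    """Bin layout for the supported learning-phase lengths.

    128 trials -> (30, 30, 30, 38); 120 trials -> (30, 30, 30, 30).  Other
    lengths raise rather than silently rebinning.
    """
    if n_learning_trials == 128:
        return BinAssignment((30, 30, 30, 38))
    if n_learning_trials == 120:
        return BinAssignment((30, 30, 30, 30))
    raise DesignError(f"no bin layout defined for {n_learning_trials} learning trials")


def bin_occupancy_ok(
    memory_records: pd.DataFrame, n_bins: int = 4, min_per_bin: int = MIN_TRIALS_PER_BIN
) -> bool:
    """True if every bin has at least ``min_per_bin`` responded old trials.

    Expects already memory-filtered records of one participant with an
    ``lp_bin`` column.
    """
    old = memory_records[memory_records["status"] == "old"]
    counts = old["lp_bin"].value_counts()
    return all(counts.get(float(b), 0) >= min_per_bin for b in range(1, n_bins + 1))
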