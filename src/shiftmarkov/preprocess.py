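"""Trial codification and phase windowing for set-shifting response sequences.

Raw card-sorting trials are coded into three response categories --
correct (``C``), non-perseverative error (``E``) and perseverative error
(``PE``) -- and each subject's coded sequence is partitioned into ``T``
contiguous, (near-)equally sized *windows* of trials.  Windows play the
role of longitudinal occasions ("task phases"): the latent Markov model
downstream treats the per-window category counts as its observations.

Subjects may differ in total trial count; windows within a subject differ
in length by at most one trial, with the remainder assigned to the
earliest windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Response categories in canonical column order.
CATEGORIES: tuple[str, str, str] = ("C", "E", "PE")

#: Card features a response or sorting rule can target.
FEATURES: frozenset[str] = frozenset({"color", "shape", "number"})

CATEGORY_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class CodedTrial:
    """One coded response: 1-based trial position and category."""

    index: int
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_INDEX:
            raise ValueError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )
        if self.index < 1:
            raise ValueError("trial index is 1-based and must be >= 1")


@dataclass(frozen=True)
class RawTrial:
    """A raw card-sorting trial before codification.

    ``previous_rule`` is the sorting rule reinforced in the preceding rule
    block; it is ``None`` during the first block, when no rule has been
    abandoned yet.  ``feedback`` must be consistent with the match between
    the chosen feature and the active rule.
    """

    chosen_feature: str
    active_rule: str
    previous_rule: Optional[str] = None
    feedback: bool = False

    def __post_init__(self) -> None:
        for name in ("chosen_feature", "active_rule"):
            value = getattr(self, name)
            if value not in FEATURES:
                raise ValueError(f"{name} must be one of {sorted(FEATURES)}, got {value!r}")
        if self.previous_rule is not None and self.previous_rule not in FEATURES:
            raise ValueError(f"previous_rule must be one of {sorted(FEATURES)} or None")
        if self.feedback != (self.chosen_feature == self.active_rule):
            raise ValueError("feedback must be positive iff chosen_feature == active_rule")


@dataclass
class SubjectSequence:
    """Ordered coded responses of one subject with a binary group label."""

    subject_id: str
    group: int
    trials: list[CodedTrial] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in (0, 1):
            raise ValueError("group must be 0 (control) or 1 (SDI)")

    @property
    def categories(self) -> list[str]:
        return [t.category for t in self.trials]

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class WindowedCounts:
    """Per-phase response-category counts for one subject.

    ``counts`` is a T x R integer table (rows = phases, columns follow
    :data:`CATEGORIES`); row ``t`` sums to ``sizes[t]``.
    """

    subject_id: str
    group: int
    sizes: list[int]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.sizes), len(CATEGORIES)):
            raise ValueError("counts must be a T x 3 table matching sizes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.array_equal(self.counts.sum(axis=1), np.asarray(self.sizes)):
            raise ValueError("each counts row must sum to the corresponding window size")

    @property
    def n_windows(self) -> int:
        return len(self.sizes)

    @property
    def n_trials(self) -> int:
        return int(sum(self.sizes))


def codify_trial(trial: RawTrial) -> str:
    """Code a raw trial as ``C``, ``E`` or ``PE``.

    Positive feedback codes ``C``.  A negative-feedback response that
    matches the immediately preceding reinforced rule is perseverative
    (``PE``); any other error, including all first-block errors where no
    previous rule exists, is non-perseverative (``E``).
    """
    if trial.feedback:
        return "C"
    if trial.previous_rule is not None and trial.chosen_feature == trial.previous_rule:
        return "PE"
    return "E"


def codify_log(
    chosen: Sequence[str], active: Sequence[str]
) -> list[str]:
    """Code an ordered trial log given chosen features and active rules.

    The previous rule for each trial is derived by tracking rule changes in
    ``active``: it is the rule of the preceding block, or ``None`` within
    the first block.
    """
    if len(chosen) != len(active):
        raise ValueError("chosen and active must have equal length")
    codes: list[str] = []
    previous_rule: Optional[str] = None
    for i, (ch, ac) in enumerate(zip(chosen, active)):
        if i > 0 and ac != active[i - 1]:
            previous_rule = active[i - 1]
        trial = RawTrial(
            chosen_feature=ch,
            active_rule=ac,
            previous_rule=previous_rule,
            feedback=(ch == ac),
        )
        codes.append(codify_trial(trial))
    return codes


def window_sizes(n_trials: int, T: int) -> list[int]:
    """Split ``n_trials`` into ``T`` near-equal window lengths.

    With ``n = q*T + r`` the first ``r`` windows get ``q + 1`` trials and
    the rest get ``q``; sizes therefore differ by at most one and the
    extra trials land in the earliest phases.
    """
    if T < 1:
        raise ValueError("T must be a positive integer")
    if n_trials < T:
        raise ValueError(f"need at least T={T} trials to form {T} non-empty windows, got {n_trials}")
    q, r = divmod(n_trials, T)
    return [q + 1] * r + [q] * (T - r)


def partition_windows(seq: SubjectSequence, T: int = 5) -> WindowedCounts:
    """Partition a subject's coded sequence into ``T`` phases of counts."""
    sizes = window_sizes(len(seq), T)
    counts = np.zeros((T, len(CATEGORIES)), dtype=np.int64)
    pos = 0
    for t, size in enumerate(sizes):
        for trial in seq.trials[pos : pos + size]:
            counts[t, CATEGORY_INDEX[trial.category]] += 1
        pos += size
    return WindowedCounts(seq.subject_id, seq.group, sizes, counts)


def aggregate_block(dataset: Sequence[WindowedCounts], t: int) -> pd.DataFrame:
    """Slice phase ``t`` (1-based) across subjects, keeping order and labels.

    Returns a frame with one row per subject: ``subject_id``, ``group``,
    the three category counts and the window size.
    """
    if dataset:
        T = dataset[0].n_windows
        if any(w.n_windows != T for w in dataset):
            raise ValueError("all subjects must share the same number of windows")
        if not 1 <= t <= T:
            raise ValueError(f"phase index t must be in 1..{T}, got {t}")
    elif t < 1:
        raise ValueError("phase index t must be >= 1")
    rows = [
        {
            "subject_id": w.subject_id,
            "group": w.group,
            "n_C": int(w.counts[t - 1, 0]),
            "n_E": int(w.counts[t - 1, 1]),
            "n_PE": int(w.counts[t - 1, 2]),
            "window_size": int(w.sizes[t - 1]),
        }
        for w in dataset
    ]
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "n_C", "n_E", "n_PE", "window_size"]
    )


# ---------------------------------------------------------------------------
# CSV interfaces (1-based positions in files)

def read_trials_csv(path) -> list[SubjectSequence]:
    """Read a trial-level CSV with columns subject_id, group, trial_index, category."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "group", "trial_index", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    sequences: list[SubjectSequence] = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("trial_index")
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"subject {sid} has inconsistent group labels")
        trials = [
            CodedTrial(int(i), str(c))
            for i, c in zip(sub["trial_index"], sub["category"])
        ]
        sequences.append(SubjectSequence(str(sid), int(groups[0]), trials))
    return sequences


def write_trials_csv(sequences: Iterable[SubjectSequence], path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "trial_index": t.index,
            "category": t.category,
        }
        for s in sequences
        for t in s.trials
    ]
    pd.DataFrame(rows, columns=["subject_id", "group", "trial_index", "category"]).to_csv(
        path, index=False
    )


def read_raw_csv(path, T: int | None = None) -> list[SubjectSequence]:
    """Read a raw-log CSV (chosen_feature, active_rule per trial) and codify it."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "group", "trial_index", "chosen_feature", "active_rule"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"raw-log CSV missing columns: {sorted(missing)}")
    sequences: list[SubjectSequence] = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("trial_index")
        codes = codify_log(list(sub["chosen_feature"]), list(sub["active_rule"]))
        trials = [CodedTrial(i + 1, c) for i, c in enumerate(codes)]
        sequences.append(SubjectSequence(str(sid), int(sub["group"].iloc[0]), trials))
    return sequences


def windowed_to_frame(dataset: Sequence[WindowedCounts]) -> pd.DataFrame:
    """Tidy frame of windowed counts: one row per subject-phase."""
    rows = []
    for w in dataset:
        for t in range(w.n_windows):
            rows.append(
                {
                    "subject_id": w.subject_id,
                    "group": w.group,
                    "phase": t + 1,
                    "n_C": int(w.counts[t, 0]),
                    "n_E": int(w.counts[t, 1]),
                    "n_PE": int(w.counts[t, 2]),
                    "window_size": int(w.sizes[t]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "group", "phase", "n_C", "n_E", "n_PE", "window_size"],
    )


def write_windowed_csv(dataset: Sequence[WindowedCounts], path) -> None:
    windowed_to_frame(dataset).to_csv(path, index=False)


def read_windowed_csv(path) -> list[WindowedCounts]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    dataset: list[WindowedCounts] = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("phase")
        counts = sub[["n_C", "n_E", "n_PE"]].to_numpy(dtype=np.int64)
        dataset.append(
            WindowedCounts(
                str(sid),
                int(sub["group"].iloc[0]),
                [int(s) for s in sub["window_size"]],
                counts,
            )
        )
    return dataset
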