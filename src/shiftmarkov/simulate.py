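"""Synthetic coded card-sorting datasets with known latent-Markov structure.

The generator performs ancestral sampling of the model the analysis
assumes: for each subject, a latent state chain over ``T`` task phases is
drawn from the subject's group initial vector and transition matrix, and
each phase emits its window of i.i.d. coded responses (C / E / PE) from
the state's emission row.  True states are recorded so emission and
initial distributions can be checked directly.

:func:`default_truth` returns the reference three-state parameter set used
throughout the test-bench: published point estimates for the emission
matrix and the two group initial vectors, together with stipulated
transition matrices engineered to show the qualitative group contrast of
interest -- controls funnel into the optimal-strategy state (state 1),
while the substance-dependent profile makes the sub-optimal state
(state 2) near-absorbing and the perseverative state (state 3) sticky.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .lmm import LMMParams
from .preprocess import (
    CATEGORIES,
    CodedTrial,
    SubjectSequence,
    WindowedCounts,
    partition_windows,
    window_sizes,
    write_trials_csv,
)

__all__ = ["GeneratorConfig", "SimulatedData", "default_truth", "generate", "generate_scores"]


def default_truth() -> LMMParams:
    """Reference three-state, two-group parameter set (generative truth)."""
    phi = np.array(
        [
            [0.93, 0.02, 0.05],  # state 1: optimal strategy
            [0.80, 0.10, 0.10],  # state 2: sub-optimal strategy
            [0.44, 0.38, 0.18],  # state 3: perseverative non-optimal strategy
        ]
    )
    pi_init = np.array(
        [
            [0.57, 0.14, 0.29],  # control
            [0.38, 0.21, 0.41],  # SDI
        ]
    )
    trans = np.array(
        [
            [  # control: mass flows to state 1; state 3 never self-repeats
                [0.97, 0.02, 0.01],
                [0.90, 0.08, 0.02],
                [0.95, 0.05, 0.00],
            ],
            [  # SDI: state 2 near-absorbing, state 3 sticky
                [0.25, 0.60, 0.15],
                [0.02, 0.96, 0.02],
                [0.05, 0.25, 0.70],
            ],
        ]
    )
    return LMMParams(phi=phi, pi_init=pi_init, trans=trans, homogeneous=True)


#: Either a fixed per-subject trial total or an inclusive (low, high) range.
TrialSpec = Union[int, tuple[int, int]]


@dataclass
class GeneratorConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults mirror the reference study design: 44 controls and 38
    substance-dependent individuals, five task phases, and per-subject
    trial totals varying between 80 and 128 cards (so window lengths are
    unequal across subjects, as in real administrations where subjects
    finish the deck at different rates).
    """

    n_control: int = 44
    n_sdi: int = 38
    T: int = 5
    trials_per_subject: TrialSpec = (80, 128)
    truth: Optional[LMMParams] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_control < 1 and self.n_sdi < 1:
            raise ValueError("at least one group must contain a subject")
        if self.T < 1:
            raise ValueError("T must be positive")
        if isinstance(self.trials_per_subject, tuple):
            lo, hi = self.trials_per_subject
            if lo > hi or lo < self.T:
                raise ValueError("trial range must satisfy T <= low <= high")
        elif self.trials_per_subject < self.T:
            raise ValueError("trials_per_subject must be >= T")

    def resolve_truth(self) -> LMMParams:
        return self.truth if self.truth is not None else default_truth()

    def to_dict(self) -> dict:
        return {
            "n_control": self.n_control,
            "n_sdi": self.n_sdi,
            "T": self.T,
            "trials_per_subject": list(self.trials_per_subject)
            if isinstance(self.trials_per_subject, tuple)
            else self.trials_per_subject,
            "seed": self.seed,
            "truth": self.resolve_truth().to_dict(),
        }


@dataclass
class SimulatedData:
    """Generated cohort: coded sequences, windowed counts, and the truth."""

    sequences: list[SubjectSequence]
    windowed: list[WindowedCounts]
    states: np.ndarray  # (J, T) true latent states, 0-based
    groups: np.ndarray  # (J,)
    config: GeneratorConfig

    def write(self, trials_path, manifest_path=None) -> None:
        """Write the trial-level CSV and, optionally, a JSON run manifest."""
        write_trials_csv(self.sequences, trials_path)
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                json.dump(
                    {
                        "generator": self.config.to_dict(),
                        "n_subjects": len(self.sequences),
                        "trials_csv": str(trials_path),
                    },
                    fh,
                    indent=2,
                )


def generate(config: GeneratorConfig) -> SimulatedData:
    """Ancestral-sample a cohort from the configured truth parameters."""
    truth = config.resolve_truth()
    if truth.G < 2 and config.n_sdi > 0:
        raise ValueError("truth parameters must cover both groups")
    rng = np.random.default_rng(config.seed)
    T, S = config.T, truth.S

    sequences: list[SubjectSequence] = []
    windowed: list[WindowedCounts] = []
    states = []
    groups = []
    subject_labels = [(f"ctrl{j + 1:03d}", 0) for j in range(config.n_control)] + [
        (f"sdi{j + 1:03d}", 1) for j in range(config.n_sdi)
    ]
    for sid, g in subject_labels:
        if isinstance(config.trials_per_subject, tuple):
            lo, hi = config.trials_per_subject
            n_trials = int(rng.integers(lo, hi + 1))
        else:
            n_trials = int(config.trials_per_subject)
        sizes = window_sizes(n_trials, T)

        chain = np.empty(T, dtype=int)
        chain[0] = rng.choice(S, p=truth.pi_init[g])
        for t in range(1, T):
            P = truth.trans[g] if truth.homogeneous else truth.trans[g, t - 1]
            chain[t] = rng.choice(S, p=P[chain[t - 1]])

        cats: list[str] = []
        for t in range(T):
            draws = rng.choice(len(CATEGORIES), size=sizes[t], p=truth.phi[chain[t]])
            cats.extend(CATEGORIES[k] for k in draws)
        trials = [CodedTrial(i + 1, c) for i, c in enumerate(cats)]
        seq = SubjectSequence(sid, g, trials)
        sequences.append(seq)
        windowed.append(partition_windows(seq, T))
        states.append(chain)
        groups.append(g)

    return SimulatedData(
        sequences=sequences,
        windowed=windowed,
        states=np.asarray(states),
        groups=np.asarray(groups),
        config=config,
    )


def generate_scores(config: GeneratorConfig) -> pd.DataFrame:
    """Per-subject total C / E / PE counts for a freshly generated cohort."""
    data = generate(config)
    return scores_table(data)


def scores_table(data: SimulatedData) -> pd.DataFrame:
    rows = []
    for seq in data.sequences:
        cats = seq.categories
        rows.append(
            {
                "subject_id": seq.subject_id,
                "group": seq.group,
                "n_C": cats.count("C"),
                "n_E": cats.count("E"),
                "n_PE": cats.count("PE"),
                "n_trials": len(cats),
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "group", "n_C", "n_E", "n_PE", "n_trials"])


def score_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Group means and standard errors (SD / sqrt(N)) of the scoring totals."""
    out = []
    for g, sub in scores.groupby("group"):
        n = len(sub)
        row: dict = {"group": g, "n": n}
        for col in ("n_C", "n_E", "n_PE"):
            row[f"{col}_mean"] = sub[col].mean()
            row[f"{col}_se"] = sub[col].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        out.append(row)
    return pd.DataFrame(out)
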