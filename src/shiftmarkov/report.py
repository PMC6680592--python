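"""Report helpers: parameter tables and summary-statistic group comparisons.

Includes a two-sample t-test that works from *published* summary
statistics (group mean, standard error and size) rather than raw data --
the standard situation when re-analysing a printed scoring table.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .lmm import FitResult, LMMParams
from .preprocess import CATEGORIES

__all__ = ["TTestResult", "summary_ttest", "score_ttests", "emission_table", "initials_table", "transition_frames"]


class TTestResult(NamedTuple):
    t: float
    df: int


def summary_ttest(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> TTestResult:
    """Pooled-variance two-sample t-test from summary statistics.

    Group standard deviations are reconstructed as ``sd = se * sqrt(n)``;
    the statistic is the Student pooled-variance t with ``df = n1+n2-2``,
    signed as group 1 minus group 2.
    """
    if min(se1, se2) <= 0 or min(n1, n2) < 2:
        raise ValueError("standard errors must be positive and group sizes >= 2")
    var1 = (se1 * np.sqrt(n1)) ** 2
    var2 = (se2 * np.sqrt(n2)) ** 2
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * var1 + (n2 - 1) * var2) / df
    t = (mean1 - mean2) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    return TTestResult(float(t), int(df))


def score_ttests(summary: pd.DataFrame) -> pd.DataFrame:
    """Group comparison of total C / E / PE scores from a score summary.

    ``summary`` is the output of :func:`shiftmarkov.simulate.score_summary`
    (one row per group with means, SEs and n).  Returns one row per
    scoring measure with the pooled t and df.
    """
    if len(summary) != 2:
        raise ValueError("score t-tests need exactly two groups")
    g0 = summary[summary["group"] == 0].iloc[0]
    g1 = summary[summary["group"] == 1].iloc[0]
    rows = []
    for col, label in zip(("n_C", "n_E", "n_PE"), CATEGORIES):
        res = summary_ttest(
            g0[f"{col}_mean"], g0[f"{col}_se"], int(g0["n"]),
            g1[f"{col}_mean"], g1[f"{col}_se"], int(g1["n"]),
        )
        rows.append({"measure": label, "t": res.t, "df": res.df})
    return pd.DataFrame(rows)


def emission_table(params: LMMParams) -> pd.DataFrame:
    """Conditional response probabilities, categories x states."""
    return pd.DataFrame(
        params.phi.T,
        index=list(CATEGORIES),
        columns=[f"state_{s + 1}" for s in range(params.S)],
    )


def initials_table(params: LMMParams) -> pd.DataFrame:
    """Group-specific initial state probabilities."""
    return pd.DataFrame(
        params.pi_init,
        index=[f"group_{g}" for g in range(params.G)],
        columns=[f"state_{s + 1}" for s in range(params.S)],
    )


def transition_frames(params: LMMParams) -> dict[int, pd.DataFrame]:
    """One transition-matrix frame per group (homogeneous chains)."""
    if not params.homogeneous:
        raise ValueError("transition_frames expects a homogeneous parameter set")
    labels = [f"state_{s + 1}" for s in range(params.S)]
    return {
        g: pd.DataFrame(params.trans[g], index=labels, columns=labels)
        for g in range(params.G)
    }


def fit_report(fit: FitResult) -> str:
    """Human-readable dump of a fitted model's parameter tables."""
    parts = [
        f"log-likelihood: {fit.loglik:.2f}  (AIC {fit.aic:.1f}, BIC {fit.bic:.1f}, "
        f"k={fit.n_params}, n={fit.n_subjects})",
        "",
        "Conditional response probabilities P(y | state):",
        emission_table(fit.params).round(3).to_string(),
        "",
        "Initial state probabilities per group:",
        initials_table(fit.params).round(3).to_string(),
    ]
    for g, frame in transition_frames(fit.params).items():
        parts += ["", f"Transition matrix, group {g}:", frame.round(3).to_string()]
    if fit.degenerate:
        parts += ["", "warning: at least one state has (near-)zero posterior occupancy"]
    return "\n".join(parts)
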