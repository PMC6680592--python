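"""Information-criterion model selection over state counts and covariate use.

Both criteria penalise the maximised log-likelihood: AIC = -2*ll + 2k and
BIC = -2*ll + k*log(n), with k from :func:`count_params` and n the number
of subjects (the conventional sample size for subject-level longitudinal
mixtures).  Smaller is better for both.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .lmm import EMConfig, FitResult, count_params, em_fit
from .preprocess import WindowedCounts

__all__ = ["count_params", "select_states", "compare_covariate", "format_selection"]

_COLUMNS = ["model", "S", "has_covariate", "loglik", "n_params", "aic", "bic", "error"]


def _row(label: str, S: int, has_covariate: bool, fit: FitResult) -> dict:
    return {
        "model": label,
        "S": S,
        "has_covariate": has_covariate,
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "aic": fit.aic,
        "bic": fit.bic,
        "error": "",
    }


def select_states(
    dataset: Sequence[WindowedCounts],
    candidates: Sequence[int],
    config: Optional[EMConfig] = None,
    n_groups: Optional[int] = None,
) -> pd.DataFrame:
    """Fit one model per candidate state count; rank rows by BIC ascending.

    A fit failure is recorded in the row's ``error`` column instead of
    aborting the whole table.  Returns the fitted models in the frame's
    ``attrs["fits"]`` keyed by S.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    rows = []
    fits: dict[int, FitResult] = {}
    for S in candidates:
        try:
            fit = em_fit(dataset, S, config=config, n_groups=n_groups)
        except Exception as exc:  # recorded, not fatal
            rows.append(
                {
                    "model": f"{S}-state",
                    "S": S,
                    "has_covariate": n_groups != 1,
                    "loglik": float("nan"),
                    "n_params": count_params(S) if S >= 1 else 0,
                    "aic": float("nan"),
                    "bic": float("nan"),
                    "error": str(exc),
                }
            )
            continue
        fits[S] = fit
        rows.append(_row(f"{S}-state", S, n_groups != 1, fit))
    table = pd.DataFrame(rows, columns=_COLUMNS).sort_values(
        "bic", na_position="last", kind="mergesort"
    )
    table = table.reset_index(drop=True)
    table.attrs["fits"] = fits
    return table


def compare_covariate(
    dataset: Sequence[WindowedCounts],
    S: int,
    config: Optional[EMConfig] = None,
) -> pd.DataFrame:
    """Fit the basic (group-blind) and covariate models at a fixed S.

    The models are nested -- the covariate model frees one initial vector
    and one transition matrix per group while sharing the emission matrix
    -- so its maximised likelihood can only be higher, and BIC arbitrates
    whether the extra latent-process parameters are warranted.
    """
    groups = {w.group for w in dataset}
    if len(groups) < 2:
        raise ValueError("both covariate levels must be present to compare models")
    rows = []
    fits: dict[str, FitResult] = {}
    for label, n_groups in (("basic", 1), ("covariate", 2)):
        fit = em_fit(dataset, S, config=config, n_groups=n_groups)
        fits[label] = fit
        rows.append(_row(label, S, n_groups == 2, fit))
    table = pd.DataFrame(rows, columns=_COLUMNS).sort_values("bic", kind="mergesort")
    table = table.reset_index(drop=True)
    table.attrs["fits"] = fits
    return table


def format_selection(table: pd.DataFrame) -> str:
    """Pretty-print a selection table (model, BIC, AIC layout)."""
    view = table[["model", "S", "has_covariate", "loglik", "n_params", "bic", "aic"]]
    return view.to_string(
        index=False,
        float_format=lambda v: f"{v:.1f}",
    )
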