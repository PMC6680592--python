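"""Post-fit Markov-chain analysis of the latent strategy process.

Given a fitted group profile (initial vector pi_1 and transition matrix
P), this module answers the forecasting questions the transition estimates
support: how the marginal state distribution pi_t = pi_1 P^(t-1) evolves
over task phases, whether any state is (near-)absorbing, and how long a
chain started in one state takes, on average, to first reach another
(expected hitting time), both analytically and by seeded Monte-Carlo
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lmm import LMMParams

__all__ = [
    "MarginalTrajectory",
    "HittingTimeResult",
    "ForecastResult",
    "propagate_marginals",
    "marginal_trajectories",
    "trajectories_to_frame",
    "detect_absorbing",
    "expected_hitting_time",
    "simulate_forecast",
]


@dataclass
class MarginalTrajectory:
    """Latent-state distribution at each task phase for one group."""

    group: Optional[int]
    probs: np.ndarray  # (T, S); row t = distribution of S_t

    @property
    def T(self) -> int:
        return self.probs.shape[0]

    @property
    def S(self) -> int:
        return self.probs.shape[1]


@dataclass
class HittingTimeResult:
    """Expected number of steps to first reach ``target`` from ``start``."""

    start: int
    target: int
    expected_steps: float
    by: str  # "analytic" | "simulation"


@dataclass
class ForecastResult:
    """Monte-Carlo rollout summary of a latent chain."""

    start_state: int
    frequencies: np.ndarray  # (horizon, S) empirical state frequencies per step
    first_passage: np.ndarray  # (n_chains, S); step of first visit, inf if never
    n_chains: int

    def mean_first_passage(self, target: int) -> float:
        """Mean first-passage time to ``target`` over chains that reached it."""
        fp = self.first_passage[:, target]
        hit = np.isfinite(fp)
        return float(fp[hit].mean()) if hit.any() else float("inf")


def _check_stochastic_rows(arr: np.ndarray, name: str, atol: float = 1e-8) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if (arr < -atol).any() or not np.allclose(arr.sum(axis=-1), 1.0, atol=atol):
        raise ValueError(f"{name} must be row-stochastic")
    return arr


def propagate_marginals(
    pi1: np.ndarray,
    P: np.ndarray,
    T: int,
    group: Optional[int] = None,
) -> MarginalTrajectory:
    """Exact marginal recursion pi_{t+1} = pi_t P for T phases.

    ``P`` may be a single S x S matrix (homogeneous chain) or a stack of
    T-1 step-specific matrices.
    """
    pi1 = _check_stochastic_rows(pi1, "pi1")
    P = np.asarray(P, dtype=float)
    time_varying = P.ndim == 3
    _check_stochastic_rows(P, "P")
    if T < 1:
        raise ValueError("T must be >= 1")
    if time_varying and P.shape[0] < T - 1:
        raise ValueError("need T-1 step matrices for a time-varying chain")
    probs = np.empty((T, pi1.shape[0]))
    probs[0] = pi1
    for t in range(1, T):
        Pt = P[t - 1] if time_varying else P
        probs[t] = probs[t - 1] @ Pt
    return MarginalTrajectory(group=group, probs=probs)


def marginal_trajectories(params: LMMParams, T: int) -> list[MarginalTrajectory]:
    """One marginal trajectory per group, from the fitted parameter set."""
    return [
        propagate_marginals(params.pi_init[g], params.trans[g], T, group=g)
        for g in range(params.G)
    ]


def trajectories_to_frame(trajectories: Sequence[MarginalTrajectory]) -> pd.DataFrame:
    """Tidy export: one row per (group, phase, state) with its probability."""
    rows = [
        {
            "group": traj.group,
            "phase": t + 1,
            "state": s + 1,
            "probability": float(traj.probs[t, s]),
        }
        for traj in trajectories
        for t in range(traj.T)
        for s in range(traj.S)
    ]
    return pd.DataFrame(rows, columns=["group", "phase", "state", "probability"])


def detect_absorbing(P: np.ndarray, tol: float = 0.01) -> list[int]:
    """States whose self-transition probability is within ``tol`` of 1."""
    P = _check_stochastic_rows(P, "P")
    return [s for s in range(P.shape[0]) if P[s, s] >= 1.0 - tol]


def expected_hitting_time(P: np.ndarray, start: int, target: int) -> HittingTimeResult:
    """Expected first-passage time from ``start`` to ``target``.

    Solves the linear system h[target] = 0, h[s] = 1 + sum_{s' != target}
    P[s, s'] h[s'] on the states actually involved.  The result is
    infinite when the target is unreachable from the start, or when the
    chain can wander (with positive probability) into a region from which
    the target is unreachable -- in either case the hitting probability is
    below one and the expectation diverges.
    """
    P = _check_stochastic_rows(P, "P")
    S = P.shape[0]
    if not (0 <= start < S and 0 <= target < S):
        raise ValueError("start and target must be valid state indices")
    if start == target:
        return HittingTimeResult(start, target, 0.0, "analytic")

    adj = P > 0.0
    # states from which the target is reachable (reverse BFS)
    can_reach = {target}
    frontier = [target]
    while frontier:
        node = frontier.pop()
        for s in range(S):
            if adj[s, node] and s not in can_reach:
                can_reach.add(s)
                frontier.append(s)
    if start not in can_reach:
        return HittingTimeResult(start, target, float("inf"), "analytic")

    # states visitable from start before hitting the target
    visitable = {start}
    frontier = [start]
    while frontier:
        node = frontier.pop()
        if node == target:
            continue
        for s in range(S):
            if adj[node, s] and s not in visitable:
                visitable.add(s)
                frontier.append(s)
    if any(s != target and s not in can_reach for s in visitable):
        return HittingTimeResult(start, target, float("inf"), "analytic")

    transient = sorted(s for s in visitable if s != target)
    idx = {s: i for i, s in enumerate(transient)}
    Q = P[np.ix_(transient, transient)]
    # hitting probability one implies spectral radius of Q strictly below 1
    if np.max(np.abs(np.linalg.eigvals(Q))) >= 1.0 - 1e-12:
        raise np.linalg.LinAlgError(
            "transient sub-matrix is not strictly sub-stochastic; "
            "hitting-time system is singular"
        )
    h = np.linalg.solve(np.eye(len(transient)) - Q, np.ones(len(transient)))
    return HittingTimeResult(start, target, float(h[idx[start]]), "analytic")


def simulate_forecast(
    params: LMMParams,
    group: int,
    start_state: int,
    n_chains: int = 10_000,
    horizon: int = 5,
    seed: Optional[int] = None,
) -> ForecastResult:
    """Seeded Monte-Carlo rollout of one group's latent chain.

    All chains start in ``start_state`` (step 0) and evolve ``horizon - 1``
    transitions under the group's (homogeneous) transition matrix.
    Returns per-step empirical state frequencies and, per chain, the step
    index of the first visit to every state (inf when not visited within
    the horizon).
    """
    if group >= params.G:
        raise ValueError("group out of range for the parameter set")
    if not params.homogeneous:
        raise ValueError("forecast simulation assumes a homogeneous chain")
    S = params.S
    if not 0 <= start_state < S:
        raise ValueError("start_state out of range")
    rng = np.random.default_rng(seed)
    P = params.trans[group]
    cum = np.cumsum(P, axis=1)

    current = np.full(n_chains, start_state, dtype=np.intp)
    frequencies = np.empty((horizon, S))
    first_passage = np.full((n_chains, S), np.inf)
    first_passage[:, start_state] = 0.0
    frequencies[0] = np.bincount(current, minlength=S) / n_chains
    for step in range(1, horizon):
        u = rng.random(n_chains)
        current = (u[:, None] > cum[current]).sum(axis=1).astype(np.intp)
        frequencies[step] = np.bincount(current, minlength=S) / n_chains
        newly = np.isinf(first_passage[np.arange(n_chains), current])
        first_passage[np.arange(n_chains)[newly], current[newly]] = step
    return ForecastResult(
        start_state=start_state,
        frequencies=frequencies,
        first_passage=first_passage,
        n_chains=n_chains,
    )
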