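"""Covariate-stratified latent Markov model for windowed categorical counts.

The model: each subject carries a binary group label ``x`` and a sequence
of ``T`` windows of coded responses.  A hidden first-order Markov chain
``S_1, ..., S_T`` over ``S`` discrete states governs the windows; given the
state, the trials inside a window are i.i.d. categorical draws with
state-specific probabilities ``phi[s, y]`` (the measurement model, shared
across groups).  The latent process is group-specific: initial vectors
``pi_init[x]`` and (by default time-homogeneous) transition matrices
``trans[x]``.

A window's emission likelihood is the product of its per-trial category
probabilities, i.e. the multinomial kernel *without* the combinatorial
coefficient.  The coefficient is constant in the parameters, so dropping
it changes neither the EM path nor any likelihood difference; reported
log-likelihoods omit it throughout, and exact oracles must do the same.

Estimation is by EM (Baum-Welch) with scaled forward-backward recursions,
multiple random restarts, and a post-hoc canonical state ordering (states
sorted by descending probability of a correct response) to resolve label
switching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import xlogy

from .preprocess import WindowedCounts

__all__ = [
    "LMMParams",
    "EMConfig",
    "FitResult",
    "NumericalError",
    "window_log_emission",
    "forward_backward",
    "loglik_dataset",
    "em_fit",
    "order_states",
    "count_params",
]

_ROW_TOL = 1e-10


class NumericalError(RuntimeError):
    """Raised when the likelihood degenerates (e.g. all state paths impossible)."""


def _check_stochastic(arr: np.ndarray, name: str) -> None:
    arr = np.asarray(arr)
    if (arr < -_ROW_TOL).any() or (arr > 1 + _ROW_TOL).any():
        raise ValueError(f"{name} entries must lie in [0, 1]")
    sums = arr.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError(f"{name} rows must sum to 1 (got sums {sums})")


@dataclass
class LMMParams:
    """Full parameter set of the covariate latent Markov model.

    Attributes
    ----------
    phi : (S, R) array
        Conditional response probabilities ``P(Y = y | state = s)``; shared
        across groups.
    pi_init : (G, S) array
        Group-specific initial state distributions.
    trans : (G, S, S) or (G, T-1, S, S) array
        Group-specific transition matrices; the 4-d form holds one matrix
        per transition step when ``homogeneous`` is False.
    """

    phi: np.ndarray
    pi_init: np.ndarray
    trans: np.ndarray
    homogeneous: bool = True

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.pi_init = np.asarray(self.pi_init, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        S = self.phi.shape[0]
        if self.pi_init.ndim != 2 or self.pi_init.shape[1] != S:
            raise ValueError("pi_init must have shape (G, S)")
        expected_ndim = 3 if self.homogeneous else 4
        if self.trans.ndim != expected_ndim or self.trans.shape[-2:] != (S, S):
            raise ValueError("trans has inconsistent shape for the homogeneity flag")
        if self.trans.shape[0] != self.pi_init.shape[0]:
            raise ValueError("trans and pi_init disagree on the number of groups")
        _check_stochastic(self.phi, "phi")
        _check_stochastic(self.pi_init, "pi_init")
        _check_stochastic(self.trans, "trans")

    @property
    def S(self) -> int:
        return self.phi.shape[0]

    @property
    def R(self) -> int:
        return self.phi.shape[1]

    @property
    def G(self) -> int:
        return self.pi_init.shape[0]

    def permuted(self, perm: Sequence[int]) -> "LMMParams":
        """Return a copy with latent states relabelled by ``perm``.

        ``perm[k]`` is the old index of the state placed at new position k.
        """
        perm = np.asarray(perm)
        trans = self.trans[..., perm, :][..., :, perm]
        return LMMParams(
            phi=self.phi[perm],
            pi_init=self.pi_init[:, perm],
            trans=trans,
            homogeneous=self.homogeneous,
        )

    def to_dict(self) -> dict:
        return {
            "S": self.S,
            "R": self.R,
            "G": self.G,
            "homogeneous": self.homogeneous,
            "phi": self.phi.tolist(),
            "pi_init": self.pi_init.tolist(),
            "trans": self.trans.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LMMParams":
        return cls(
            phi=np.asarray(d["phi"], dtype=float),
            pi_init=np.asarray(d["pi_init"], dtype=float),
            trans=np.asarray(d["trans"], dtype=float),
            homogeneous=bool(d.get("homogeneous", True)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LMMParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class EMConfig:
    """EM settings: convergence tolerance, restarts, seeding.

    ``tol`` is the relative log-likelihood change declaring convergence;
    ``floor`` is a smoothing floor applied to every probability row in the
    M-step before renormalisation, preventing -inf lock-in once a
    probability hits exactly zero.
    """

    tol: float = 1e-8
    max_iter: int = 1000
    n_starts: int = 20
    seed: Optional[int] = None
    homogeneous: bool = True
    floor: float = 1e-10

    @classmethod
    def from_dict(cls, d: dict) -> "EMConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class FitResult:
    """EM output: ordered estimates, likelihood trace, criteria, posteriors."""

    params: LMMParams
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    aic: float
    bic: float
    posteriors: np.ndarray  # (J, T, S) smoothed state probabilities
    n_params: int
    n_subjects: int
    degenerate: bool = False
    restart_logliks: list = field(default_factory=list)
    restart_traces: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "aic": self.aic,
            "bic": self.bic,
            "n_params": self.n_params,
            "n_subjects": self.n_subjects,
            "degenerate": self.degenerate,
            "restart_logliks": [float(v) for v in self.restart_logliks],
        }


def count_params(
    S: int, R: int = 3, G: int = 1, T: int = 5, homogeneous: bool = True
) -> int:
    """Number of free parameters: emission + initial + transition rows.

    ``S*(R-1)`` emission, ``G*(S-1)`` initial, ``G*S*(S-1)`` transition
    probabilities (times ``T-1`` if transitions vary over steps).
    """
    if min(S, R, G, T) < 1:
        raise ValueError("all dimensions must be positive")
    trans = G * S * (S - 1)
    if not homogeneous:
        trans *= T - 1
    return S * (R - 1) + G * (S - 1) + trans


def window_log_emission(counts_row: np.ndarray, phi_s: np.ndarray) -> float:
    """Log-probability of a window's category counts under one state.

    Returns ``sum_y counts[y] * log(phi_s[y])`` -- the log multinomial
    kernel.  A zero probability paired with a positive count yields -inf.
    """
    counts_row = np.asarray(counts_row, dtype=float)
    phi_s = np.asarray(phi_s, dtype=float)
    if counts_row.shape != phi_s.shape:
        raise ValueError("counts and probability vector must have equal length")
    if (counts_row < 0).any():
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore"):
        return float(xlogy(counts_row, phi_s).sum())


# ---------------------------------------------------------------------------
# Batched internals: all subjects share T, so the recursions vectorize over J.

def _pack(dataset: Sequence[WindowedCounts]) -> tuple[np.ndarray, np.ndarray]:
    if not dataset:
        raise ValueError("dataset must be non-empty")
    T = dataset[0].n_windows
    if any(w.n_windows != T for w in dataset):
        raise ValueError("all subjects must share the same number of windows")
    counts = np.stack([w.counts for w in dataset]).astype(float)
    groups = np.asarray([w.group for w in dataset], dtype=np.intp)
    return counts, groups


def _log_emissions(counts: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """(J, T, S) log emission table; safe for zero entries of phi."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return xlogy(counts[:, :, None, :], phi[None, None, :, :]).sum(axis=-1)


def _forward_backward_batch(
    logB: np.ndarray, pi: np.ndarray, P: np.ndarray, homogeneous: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward over a batch of subjects.

    Parameters are already expanded per subject: ``pi`` is (J, S) and ``P``
    is (J, S, S) (or (J, T-1, S, S) for step-varying transitions).  Scaling
    subtracts the per-window max log-emission and renormalises the forward
    vector at every step, so window sizes in the thousands do not
    underflow.  Returns per-subject log-likelihoods, smoothed state
    posteriors gamma (J, T, S) and pairwise posteriors xi (J, T-1, S, S).
    """
    J, T, S = logB.shape
    c = logB.max(axis=2)
    if not np.isfinite(c).all():
        raise NumericalError(
            "a window has zero emission probability under every state; "
            "check for zero rows in phi against observed categories"
        )
    B = np.exp(logB - c[:, :, None])

    alphas = np.empty((J, T, S))
    loglik = np.zeros(J)
    a = pi * B[:, 0]
    for t in range(T):
        if t > 0:
            Pt = P if homogeneous else P[:, t - 1]
            a = np.einsum("js,jsk->jk", a, Pt) * B[:, t]
        norm = a.sum(axis=1)
        if (norm <= 0).any() or not np.isfinite(norm).all():
            bad = int(np.flatnonzero(~(norm > 0))[0])
            raise NumericalError(
                f"zero total likelihood for subject index {bad} at window {t}: "
                "every state path is impossible under the given parameters"
            )
        a = a / norm[:, None]
        loglik += np.log(norm) + c[:, t]
        alphas[:, t] = a

    gamma = np.empty((J, T, S))
    xi = np.empty((J, T - 1, S, S)) if T > 1 else np.zeros((J, 0, S, S))
    gamma[:, T - 1] = alphas[:, T - 1]
    beta = np.ones((J, S))
    for t in range(T - 2, -1, -1):
        Pt = P if homogeneous else P[:, t]
        w = B[:, t + 1] * beta
        x = alphas[:, t, :, None] * Pt * w[:, None, :]
        x /= x.sum(axis=(1, 2))[:, None, None]
        xi[:, t] = x
        beta = np.einsum("jsk,jk->js", Pt, w)
        beta /= beta.sum(axis=1)[:, None]
        g = alphas[:, t] * beta
        gamma[:, t] = g / g.sum(axis=1)[:, None]
    return loglik, gamma, xi


def _expand(params: LMMParams, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return params.pi_init[groups], params.trans[groups]


def forward_backward(
    subject: WindowedCounts, params: LMMParams
) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact smoothed inference for one subject.

    Returns the log-likelihood (log of the sum over all ``S**T`` latent
    paths of path prior times emission likelihood), the T x S smoothed
    posteriors gamma and the (T-1) x S x S pairwise posteriors xi.
    """
    if subject.group >= params.G:
        raise ValueError(
            f"subject group {subject.group} out of range for G={params.G} parameter set"
        )
    counts = subject.counts[None].astype(float)
    groups = np.asarray([subject.group], dtype=np.intp)
    logB = _log_emissions(counts, params.phi)
    pi, P = _expand(params, groups)
    ll, gamma, xi = _forward_backward_batch(logB, pi, P, params.homogeneous)
    return float(ll[0]), gamma[0], xi[0]


def loglik_dataset(dataset: Sequence[WindowedCounts], params: LMMParams) -> float:
    """Total log-likelihood: sum of per-subject forward passes."""
    counts, groups = _pack(dataset)
    if groups.max() >= params.G:
        raise ValueError("dataset contains a group label outside the parameter set")
    logB = _log_emissions(counts, params.phi)
    pi, P = _expand(params, groups)
    ll, _, _ = _forward_backward_batch(logB, pi, P, params.homogeneous)
    return float(ll.sum())


def _m_step(
    counts: np.ndarray,
    groups: np.ndarray,
    gamma: np.ndarray,
    xi: np.ndarray,
    G: int,
    homogeneous: bool,
    floor: float,
) -> LMMParams:
    S = gamma.shape[2]
    pi_init = np.empty((G, S))
    if homogeneous:
        trans = np.empty((G, S, S))
    else:
        trans = np.empty((G, xi.shape[1], S, S))
    for g in range(G):
        mask = groups == g
        pi_init[g] = gamma[mask, 0].sum(axis=0)
        if homogeneous:
            trans[g] = xi[mask].sum(axis=(0, 1))
        else:
            trans[g] = xi[mask].sum(axis=0)
    phi = np.einsum("jts,jtr->sr", gamma, counts)

    def normalize(rows: np.ndarray) -> np.ndarray:
        rows = np.maximum(rows, floor)
        return rows / rows.sum(axis=-1, keepdims=True)

    return LMMParams(
        phi=normalize(phi),
        pi_init=normalize(pi_init),
        trans=normalize(trans),
        homogeneous=homogeneous,
    )


def _random_params(
    rng: np.random.Generator, S: int, R: int, G: int, T: int, homogeneous: bool
) -> LMMParams:
    # flat-Dirichlet rows for every stochastic block
    phi = rng.dirichlet(np.ones(R), size=S)
    pi_init = rng.dirichlet(np.ones(S), size=G)
    if homogeneous:
        trans = rng.dirichlet(np.ones(S), size=(G, S))
    else:
        trans = rng.dirichlet(np.ones(S), size=(G, T - 1, S))
    return LMMParams(phi=phi, pi_init=pi_init, trans=trans, homogeneous=homogeneous)


def _em_single(
    counts: np.ndarray,
    groups: np.ndarray,
    params: LMMParams,
    config: EMConfig,
    G: int,
) -> tuple[LMMParams, float, list[float], np.ndarray, int, bool]:
    ll_old: Optional[float] = None
    trace: list[float] = []
    converged = False
    gamma = xi = None
    for it in range(config.max_iter):
        logB = _log_emissions(counts, params.phi)
        pi, P = _expand(params, groups)
        ll_j, gamma, xi = _forward_backward_batch(logB, pi, P, params.homogeneous)
        ll = float(ll_j.sum())
        trace.append(ll)
        if ll_old is not None and abs(ll - ll_old) < config.tol * abs(ll_old):
            converged = True
            break
        params = _m_step(counts, groups, gamma, xi, G, params.homogeneous, config.floor)
        ll_old = ll
    return params, trace[-1], trace, gamma, len(trace), converged


def em_fit(
    dataset: Sequence[WindowedCounts],
    S: int,
    config: Optional[EMConfig] = None,
    n_groups: Optional[int] = None,
) -> FitResult:
    """Fit the S-state model by EM with random restarts.

    The M-step is in closed form: group initial vectors from expected
    first-window state counts, group transition matrices from expected
    transition counts, and the shared emission matrix from expected
    per-state category counts pooled over groups.  ``n_groups=1`` ignores
    the group label (basic, covariate-free model).  The best restart is
    returned with states canonically ordered; the ``degenerate`` flag is
    set when some state captures (almost) no posterior mass, i.e. S
    exceeds what the data identify.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    config = config or EMConfig()
    counts, groups = _pack(dataset)
    J, T, R = counts.shape
    if n_groups == 1:
        groups = np.zeros(J, dtype=np.intp)
        G = 1
    else:
        G = int(groups.max()) + 1 if n_groups is None else n_groups
    group_counts = np.bincount(groups, minlength=G)
    if (group_counts == 0).any():
        empty = int(np.flatnonzero(group_counts == 0)[0])
        raise ValueError(f"group {empty} has no subjects")

    rng = np.random.default_rng(config.seed)
    best: Optional[tuple] = None
    restart_logliks: list[float] = []
    restart_traces: list[list[float]] = []
    for _ in range(max(1, config.n_starts)):
        params0 = _random_params(rng, S, R, G, T, config.homogeneous)
        result = _em_single(counts, groups, params0, config, G)
        restart_logliks.append(result[1])
        restart_traces.append(result[2])
        if best is None or result[1] > best[1]:
            best = result
    params, loglik, trace, gamma, n_iter, converged = best

    perm = _canonical_order(params.phi)
    params = params.permuted(perm)
    posteriors = gamma[:, :, perm]

    # a state is degenerate when its expected occupancy is essentially empty
    occupancy = posteriors.sum(axis=(0, 1))
    degenerate = bool((occupancy < 1e-6 * occupancy.sum()).any())

    k = count_params(S, R, G, T, config.homogeneous)
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * np.log(J)
    return FitResult(
        params=params,
        loglik=loglik,
        loglik_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        aic=float(aic),
        bic=float(bic),
        posteriors=posteriors,
        n_params=k,
        n_subjects=J,
        degenerate=degenerate,
        restart_logliks=restart_logliks,
        restart_traces=restart_traces,
    )


def _canonical_order(phi: np.ndarray) -> np.ndarray:
    """States sorted by P(C|s) descending; ties broken by P(PE|s) ascending."""
    return np.lexsort((phi[:, 2], -phi[:, 0]))


def order_states(
    params: LMMParams, posteriors: Optional[np.ndarray] = None
):
    """Apply the canonical state ordering to a parameter set.

    When smoothed posteriors are supplied, their state axis is permuted
    consistently and the pair is returned.
    """
    perm = _canonical_order(params.phi)
    ordered = params.permuted(perm)
    if posteriors is None:
        return ordered
    return ordered, np.asarray(posteriors)[..., perm]
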