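"""Shared fixtures and independent oracles for the test suite.

The brute-force functions below enumerate every latent state path
explicitly with plain Python loops; they are deliberately independent of
the package's scaled forward-backward implementation and serve as its
exact oracle at small S and T.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from shiftmarkov.lmm import LMMParams
from shiftmarkov.preprocess import WindowedCounts


def path_log_prob(path, counts, group, params: LMMParams) -> float:
    """log P(path, windows) by direct per-trial multiplication."""
    lp = math.log(params.pi_init[group][path[0]]) if params.pi_init[group][path[0]] > 0 else -math.inf
    for t in range(1, len(path)):
        P = params.trans[group] if params.homogeneous else params.trans[group, t - 1]
        p = P[path[t - 1], path[t]]
        lp += math.log(p) if p > 0 else -math.inf
    for t, s in enumerate(path):
        for r in range(params.R):
            c = int(counts[t, r])
            if c:
                p = params.phi[s, r]
                lp += c * math.log(p) if p > 0 else -math.inf
    return lp


def brute_force_inference(counts, group, params: LMMParams):
    """Exact (loglik, gamma, xi) by enumerating all S**T state paths."""
    counts = np.asarray(counts)
    T, S = counts.shape[0], params.S
    paths = list(itertools.product(range(S), repeat=T))
    logps = np.array([path_log_prob(p, counts, group, params) for p in paths])
    m = logps.max()
    if m == -math.inf:
        raise ValueError("all paths impossible")
    w = np.exp(logps - m)
    total = w.sum()
    loglik = m + math.log(total)
    gamma = np.zeros((T, S))
    xi = np.zeros((T - 1, S, S))
    for p, weight in zip(paths, w):
        for t, s in enumerate(p):
            gamma[t, s] += weight
        for t in range(T - 1):
            xi[t, p[t], p[t + 1]] += weight
    return loglik, gamma / total, xi / total


def random_params(rng: np.random.Generator, S: int, G: int = 2, R: int = 3) -> LMMParams:
    return LMMParams(
        phi=rng.dirichlet(np.ones(R), size=S),
        pi_init=rng.dirichlet(np.ones(S), size=G),
        trans=rng.dirichlet(np.ones(S), size=(G, S)),
    )


def random_subject(rng: np.random.Generator, T: int = 5, group: int = 0,
                   max_per_window: int = 6) -> WindowedCounts:
    sizes = rng.integers(1, max_per_window + 1, size=T)
    counts = np.stack(
        [rng.multinomial(n, rng.dirichlet(np.ones(3))) for n in sizes]
    )
    return WindowedCounts(f"s{rng.integers(1e6)}", group, [int(n) for n in sizes], counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def truth():
    from shiftmarkov.simulate import default_truth

    return default_truth()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort reused by several structural tests."""
    from shiftmarkov.simulate import GeneratorConfig, generate

    return generate(
        GeneratorConfig(n_control=30, n_sdi=30, trials_per_subject=(80, 128), seed=515)
    )
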