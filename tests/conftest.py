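"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import gammaln

from dmrllda import TrainConfig, simulate


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def collapsed_log_joint(
    assignments: list[np.ndarray],
    tokens: list[np.ndarray],
    Lambda: np.ndarray,
    alpha: np.ndarray,
    lam: np.ndarray,
) -> float:
    """Log of the collapsed joint p(T, W | Lambda, alpha, lam) up to a constant.

    Direct term-by-term evaluation from the assignment lists: Dirichlet-
    multinomial evidence per document over its active labels times the
    topic-word evidence per topic. Returns -inf if any assignment violates
    the label mask. Independent of the sampler's count bookkeeping.
    """
    D, T = alpha.shape
    W = lam.size
    N_dt = np.zeros((D, T))
    N_tw = np.zeros((T, W))
    for d in range(D):
        for t, w in zip(assignments[d], tokens[d]):
            if Lambda[d, t] == 0:
                return -np.inf
            N_dt[d, t] += 1
            N_tw[t, w] += 1
    lp = 0.0
    for d in range(D):
        A = alpha[d] * Lambda[d]
        active = Lambda[d] > 0
        S = A[active].sum()
        Nd = N_dt[d].sum()
        lp += gammaln(S) - gammaln(S + Nd)
        lp += np.sum(gammaln(A[active] + N_dt[d, active]) - gammaln(A[active]))
    for t in range(T):
        lp += gammaln(lam.sum()) - gammaln(lam.sum() + N_tw[t].sum())
        lp += np.sum(gammaln(lam + N_tw[t]) - gammaln(lam))
    return float(lp)


def enumerate_posterior(
    tokens: list[np.ndarray],
    Lambda: np.ndarray,
    alpha: np.ndarray,
    lam: np.ndarray,
) -> dict[tuple, float]:
    """Exact collapsed posterior over all joint assignments, by enumeration."""
    supports = []
    for d in range(Lambda.shape[0]):
        active = np.nonzero(Lambda[d])[0]
        supports.extend([active] * len(tokens[d]))
    sizes = [len(t) for t in tokens]
    states, logps = [], []
    for flat in itertools.product(*supports):
        flat = np.asarray(flat)
        per_doc, pos = [], 0
        for n in sizes:
            per_doc.append(flat[pos : pos + n])
            pos += n
        states.append(tuple(flat))
        logps.append(collapsed_log_joint(per_doc, tokens, Lambda, alpha, lam))
    logps = np.array(logps)
    p = np.exp(logps - logps.max())
    p /= p.sum()
    return dict(zip(states, p))


def all_concepts(Y: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """All formal concepts (maximal all-ones rectangles) of a binary matrix."""
    D, L = Y.shape
    seen, out = set(), []
    for r in range(1, L + 1):
        for attrs in itertools.combinations(range(L), r):
            a = np.array(attrs)
            rows = Y[:, a].all(axis=1).nonzero()[0]
            if rows.size == 0:
                continue
            closed = tuple(Y[rows, :].all(axis=0).nonzero()[0])
            key = (tuple(rows), closed)
            if key not in seen:
                seen.add(key)
                out.append((rows, np.array(closed)))
    return out


def exhaustive_min_rank(Y: np.ndarray) -> int:
    """Minimum Boolean rank by exhaustive search over concept covers."""
    concepts = all_concepts(Y)
    ones = set(zip(*np.nonzero(Y)))
    if not ones:
        return 0
    for k in range(1, len(concepts) + 1):
        for combo in itertools.combinations(concepts, k):
            covered: set = set()
            for rows, attrs in combo:
                covered |= {(r, c) for r in rows for c in attrs}
            if covered >= ones:
                return k
    raise AssertionError("unreachable: concepts always cover")


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_corpus():
    """Small synthetic corpus for fast functional tests."""
    corpus, truth = simulate(T=4, W=20, F=2, D=30, Nd=40, seed=11)
    return corpus, truth


@pytest.fixture(scope="session")
def quick_train_config():
    """Short but real Gibbs schedule for functional tests."""
    return TrainConfig(
        iterations=120,
        burn_in=60,
        thin=10,
        records=6,
        beta_interval=20,
        beta_burnin=40,
        seed=3,
    )
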