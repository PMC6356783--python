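"""Collapsed Gibbs sampling (CGS) for the feature-conditioned labeled topic
model.

With the topic weights pi and word distributions theta integrated out, the
state of the Markov chain is the per-token topic assignment t_dn together
with the count tables N_dt (doc-topic), N_tw (topic-word) and N_t. A token's
full conditional, restricted to its gene's annotated labels, is

    p(t_dn = t | rest) ∝ (alpha_dt + N_dt^{\\dn}) Lam_dt
                         * (lam_w + N_tw^{\\dn}) / (sum_w lam_w + N_t^{\\dn}),

where alpha_dt = exp(y^_d beta^_t) is the gene's feature-conditioned prior.
The feature weights beta^ are re-optimized at intervals inside the chain, and
point estimates are posterior means over recorded states:

    pi^_dt    = (alpha_dt Lam_dt + E[N_dt]) / sum_t (alpha_dt Lam_dt + E[N_dt])
    theta^_tw = (lam_w + E[N_tw]) / sum_w (lam_w + E[N_tw]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._kernels import gibbs_sweep_kernel, seed_kernel
from .dmr_prior import FeatureWeights, augment_features, compute_alpha, update_beta
from .io_corpus import Corpus, Vocabulary

logger = logging.getLogger("dmrllda")


@dataclass
class SamplerState:
    """Topic assignments plus count tables for one corpus.

    Tokens are stored flattened with documents contiguous; ``doc_offsets``
    delimits each document's slice. Active labels per document are stored in
    CSR form (``label_offsets``/``label_ids``).
    """

    token_doc: np.ndarray
    token_word: np.ndarray
    doc_offsets: np.ndarray
    assignments: np.ndarray
    label_offsets: np.ndarray
    label_ids: np.ndarray
    N_dt: np.ndarray
    N_tw: np.ndarray
    N_t: np.ndarray
    alpha: np.ndarray
    Lambda: np.ndarray
    lam: np.ndarray
    rng: np.random.Generator
    _probs: np.ndarray = field(repr=False, default=None)

    @property
    def n_docs(self) -> int:
        return self.N_dt.shape[0]

    @property
    def n_topics(self) -> int:
        return self.N_dt.shape[1]

    def doc_lengths(self) -> np.ndarray:
        return np.diff(self.doc_offsets)

    def audit(self, atol: float = 1e-9) -> None:
        """Assert count tables are consistent with the assignments."""
        D, T = self.N_dt.shape
        W = self.N_tw.shape[1]
        N_dt = np.zeros((D, T))
        N_tw = np.zeros((T, W))
        np.add.at(N_dt, (self.token_doc, self.assignments), 1.0)
        np.add.at(N_tw, (self.assignments, self.token_word), 1.0)
        assert np.allclose(N_dt, self.N_dt, atol=atol), "N_dt inconsistent"
        assert np.allclose(N_tw, self.N_tw, atol=atol), "N_tw inconsistent"
        assert np.allclose(N_tw.sum(axis=1), self.N_t, atol=atol), "N_t inconsistent"
        if np.any(self.N_dt[self.Lambda == 0] != 0):
            raise AssertionError("tokens assigned to inactive labels")


def _label_csr(Lambda: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.zeros(Lambda.shape[0] + 1, dtype=np.int64)
    ids: list[int] = []
    for d in range(Lambda.shape[0]):
        active = np.nonzero(Lambda[d])[0]
        ids.extend(active.tolist())
        offsets[d + 1] = len(ids)
    return offsets, np.asarray(ids, dtype=np.int64)


def init_state(
    corpus_or_tokens,
    Lambda: np.ndarray,
    alpha: np.ndarray,
    lam: np.ndarray,
    rng: np.random.Generator,
) -> SamplerState:
    """Initialize assignments uniformly over each document's active labels.

    ``corpus_or_tokens`` is a :class:`Corpus` or a list of per-document token
    id arrays.
    """
    if isinstance(corpus_or_tokens, Corpus):
        token_lists = [doc.tokens for doc in corpus_or_tokens.documents]
        W = corpus_or_tokens.n_words
    else:
        token_lists = [np.asarray(t, dtype=np.int64) for t in corpus_or_tokens]
        W = lam.shape[0]
    Lambda = np.asarray(Lambda)
    if np.any(Lambda.sum(axis=1) == 0):
        bad = int(np.nonzero(Lambda.sum(axis=1) == 0)[0][0])
        raise ValueError(f"document {bad} has no active labels")
    D, T = Lambda.shape
    doc_offsets = np.zeros(D + 1, dtype=np.int64)
    for d, toks in enumerate(token_lists):
        doc_offsets[d + 1] = doc_offsets[d] + len(toks)
    token_doc = np.repeat(np.arange(D, dtype=np.int64), np.diff(doc_offsets))
    token_word = np.concatenate([t for t in token_lists]) if D else np.empty(0, dtype=np.int64)
    token_word = token_word.astype(np.int64)

    label_offsets, label_ids = _label_csr(Lambda)
    assignments = np.empty(token_word.shape[0], dtype=np.int64)
    for d in range(D):
        active = label_ids[label_offsets[d] : label_offsets[d + 1]]
        sl = slice(doc_offsets[d], doc_offsets[d + 1])
        assignments[sl] = active[rng.integers(0, active.size, size=doc_offsets[d + 1] - doc_offsets[d])]

    N_dt = np.zeros((D, T))
    N_tw = np.zeros((T, W))
    np.add.at(N_dt, (token_doc, assignments), 1.0)
    np.add.at(N_tw, (assignments, token_word), 1.0)
    state = SamplerState(
        token_doc=token_doc,
        token_word=token_word,
        doc_offsets=doc_offsets,
        assignments=assignments,
        label_offsets=label_offsets,
        label_ids=label_ids,
        N_dt=N_dt,
        N_tw=N_tw,
        N_t=N_tw.sum(axis=1),
        alpha=np.asarray(alpha, dtype=float),
        Lambda=Lambda,
        lam=np.asarray(lam, dtype=float),
        rng=rng,
        _probs=np.empty(int(np.diff(label_offsets).max(initial=1)), dtype=float),
    )
    return state


def topic_conditional(state: SamplerState, d: int, n: int) -> np.ndarray:
    """Full conditional of token n of document d, as a normalized T-vector.

    The token's current assignment is removed from the counts before
    evaluation and restored afterwards; entries off the document's label set
    are exactly zero.
    """
    i = state.doc_offsets[d] + n
    if not state.doc_offsets[d] <= i < state.doc_offsets[d + 1]:
        raise IndexError(f"token {n} out of range for document {d}")
    w = state.token_word[i]
    t_old = state.assignments[i]
    state.N_dt[d, t_old] -= 1
    state.N_tw[t_old, w] -= 1
    state.N_t[t_old] -= 1
    p = (
        (state.alpha[d] + state.N_dt[d])
        * state.Lambda[d]
        * (state.lam[w] + state.N_tw[:, w])
        / (state.lam.sum() + state.N_t)
    )
    state.N_dt[d, t_old] += 1
    state.N_tw[t_old, w] += 1
    state.N_t[t_old] += 1
    total = p.sum()
    if total <= 0:
        raise ZeroDivisionError(f"zero normalization mass at token ({d}, {n})")
    return p / total


def gibbs_sweep(state: SamplerState) -> SamplerState:
    """Resample every token once, in corpus order, updating counts in place."""
    seed_kernel(int(state.rng.integers(0, 2**31 - 1)))
    gibbs_sweep_kernel(
        state.token_doc,
        state.token_word,
        state.assignments,
        state.label_offsets,
        state.label_ids,
        state.N_dt,
        state.N_tw,
        state.N_t,
        state.alpha,
        state.lam,
        float(state.lam.sum()),
        state._probs,
    )
    return state


def estimate_parameters(
    alpha: np.ndarray,
    Lambda: np.ndarray,
    lam: np.ndarray,
    recorded_N_dt: list[np.ndarray],
    recorded_N_tw: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior point estimates from recorded states (plain means)."""
    if not recorded_N_dt:
        raise ValueError("no recorded states")
    E_Ndt = np.mean(recorded_N_dt, axis=0)
    E_Ntw = np.mean(recorded_N_tw, axis=0)
    num_pi = alpha * Lambda + E_Ndt * Lambda
    pi_hat = num_pi / num_pi.sum(axis=1, keepdims=True)
    num_theta = lam[None, :] + E_Ntw
    theta_hat = num_theta / num_theta.sum(axis=1, keepdims=True)
    return pi_hat, theta_hat


@dataclass
class FittedModel:
    """Trained model: topic-word distributions plus the feature-prior weights."""

    theta_hat: np.ndarray         # (T, W)
    beta_hat: FeatureWeights      # T x (F+1)
    lam: np.ndarray               # (W,) word smoothing
    vocabulary: Vocabulary
    label_names: list[str]
    feature_names: list[str]
    transform: tuple[np.ndarray, np.ndarray] | None
    config: dict[str, Any]
    pi_hat_train: np.ndarray | None = None
    converged: bool = True

    @property
    def n_topics(self) -> int:
        return self.theta_hat.shape[0]


def train_cgs(corpus: Corpus, config) -> FittedModel:
    """Run the collapsed Gibbs chain and return the fitted model.

    ``config`` is a :class:`~dmrllda.config.TrainConfig`. The chain runs
    ``iterations`` sweeps; after ``burn_in`` sweeps the count tables are
    recorded every ``thin`` sweeps up to ``records`` snapshots. The feature
    weights are re-optimized every ``beta_interval`` sweeps once the chain has
    had ``beta_burnin`` sweeps to mix, and the prior alpha is refreshed from
    them. With ``update_features=False`` the weights stay at their
    initialization (alpha = alpha_init everywhere): the plain label-masked
    LLDA reduction.
    """
    from .config import TrainConfig  # local import to avoid cycle

    cfg = config if isinstance(config, TrainConfig) else TrainConfig(**config)
    rng = np.random.default_rng(cfg.seed)
    T = corpus.n_labels
    W = corpus.n_words
    F = corpus.features.n_features
    lam = np.full(W, cfg.lambda_scale / W)
    alpha_init = cfg.alpha_init if cfg.alpha_init is not None else 50.0 / T
    beta = FeatureWeights.initial(T, F, alpha_init, mu=cfg.mu, sigma2=cfg.sigma2)
    Y_hat = augment_features(corpus.features.values, F)
    Lambda = corpus.labels.matrix.astype(float)
    alpha = compute_alpha(Y_hat, beta)
    state = init_state(corpus, corpus.labels.matrix, alpha, lam, rng)
    Nd = state.doc_lengths().astype(float)

    recorded_N_dt: list[np.ndarray] = []
    recorded_N_tw: list[np.ndarray] = []
    for sweep in range(1, cfg.iterations + 1):
        gibbs_sweep(state)
        if (
            cfg.update_features
            and sweep >= cfg.beta_burnin
            and sweep % cfg.beta_interval == 0
        ):
            beta = update_beta(beta, Nd, state.N_dt, Lambda, Y_hat, damping=cfg.beta_damping)
            state.alpha = compute_alpha(Y_hat, beta)
        if sweep > cfg.burn_in and (sweep - cfg.burn_in) % cfg.thin == 0:
            if len(recorded_N_dt) < cfg.records:
                recorded_N_dt.append(state.N_dt.copy())
                recorded_N_tw.append(state.N_tw.copy())
        if len(recorded_N_dt) >= cfg.records and sweep >= cfg.iterations:
            break
    if not recorded_N_dt:  # schedule left no room; record the final state
        logger.warning("train_cgs: schedule recorded no states; using final state")
        recorded_N_dt.append(state.N_dt.copy())
        recorded_N_tw.append(state.N_tw.copy())

    pi_hat, theta_hat = estimate_parameters(
        state.alpha, Lambda, lam, recorded_N_dt, recorded_N_tw
    )
    config_snapshot = {**cfg.to_dict(), "n_recorded": len(recorded_N_dt)}
    return FittedModel(
        theta_hat=theta_hat,
        beta_hat=beta,
        lam=lam,
        vocabulary=corpus.vocabulary,
        label_names=list(corpus.labels.label_names),
        feature_names=list(corpus.features.feature_names),
        transform=corpus.features.transform,
        config=config_snapshot,
        pi_hat_train=pi_hat,
    )
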