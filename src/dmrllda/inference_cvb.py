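"""Collapsed variational Bayes inference: moment-corrected CVB and CVB0.

Both variants keep, for every (gene d, word type w) with N_dw > 0, a
responsibility vector eta_dwt over the gene's active labels. The collapsed
count statistics are replaced by their variational moments, indexed by word
type with an (N_dw - 1) self-exclusion weight:

    gamma_dt = sum_w (N_dw - 1) eta_dwt            (doc-topic)
    mu_tw    = sum_d (N_dw - 1) eta_dwt            (topic-word)
    mu_t     = sum_{d,w} (N_dw - 1) eta_dwt        (topic total)

CVB0 updates

    eta_dwt ∝ (alpha_dt Lam_dt + gamma_dt) (lam_w + mu_tw) / (sum lam + mu_t);

CVB additionally carries variance accumulators for each statistic and applies
the second-order correction E[log(a + N)] ≈ log(a + mu) - var / (2 (a + mu)^2)
to each of the three log terms (the topic-total term enters with opposite
sign, as it divides).

The schedule is alternating: per global iteration, every document re-derives
its responsibilities by a local fixed point (stopping when
(1/N_d) sum_t |delta gamma_dt| < local_tol or after local_iters passes) against
the previous iteration's global statistics; then the global statistics and the
feature weights beta^ are refreshed. Point estimates use full expected counts
sum_w N_dw eta_dwt (the exclusion-weighted statistics vanish for singleton
words and are unusable as E[N]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dmr_prior import FeatureWeights, augment_features, compute_alpha, update_beta
from .inference_cgs import FittedModel, estimate_parameters
from .io_corpus import Corpus

logger = logging.getLogger("dmrllda")


@dataclass
class VariationalState:
    """Responsibilities and moment accumulators for a corpus.

    ``eta[d]`` is a (K_d, T_d) array over the doc's word types and active
    labels. Variance accumulators are maintained only when ``track_var`` (the
    CVB variant); CVB0 leaves them at zero.
    """

    word_ids: list[np.ndarray]      # per-doc unique word ids (K_d,)
    word_counts: list[np.ndarray]   # per-doc N_dw (K_d,)
    active: list[np.ndarray]        # per-doc active label ids (T_d,)
    eta: list[np.ndarray]           # per-doc (K_d, T_d)
    gamma: np.ndarray               # (D, T) exclusion-weighted doc-topic stats
    mu_tw: np.ndarray               # (T, W)
    mu_t: np.ndarray                # (T,)
    var_tw: np.ndarray              # (T, W), CVB only
    var_t: np.ndarray               # (T,), CVB only
    alpha: np.ndarray               # (D, T)
    Lambda: np.ndarray              # (D, T)
    lam: np.ndarray                 # (W,)
    track_var: bool = False
    # randomized global initialization lam_w + s lam_w / 10, used as the
    # global statistic in the first iteration only
    init_mu_tw: np.ndarray = field(default=None, repr=False)

    @property
    def n_docs(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_topics(self) -> int:
        return self.gamma.shape[1]

    def doc_contribution(self, d: int) -> tuple[np.ndarray, np.ndarray]:
        """(K_d, T) dense exclusion-weighted contribution and its variance part."""
        m = (self.word_counts[d] - 1.0)[:, None]
        contrib = np.zeros((self.word_ids[d].size, self.gamma.shape[1]))
        contrib[:, self.active[d]] = m * self.eta[d]
        if self.track_var:
            var = np.zeros_like(contrib)
            me = m * self.eta[d]
            var[:, self.active[d]] = me * (1.0 - me)
            return contrib, var
        return contrib, np.zeros_like(contrib)

    def refresh_from_scratch(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Recompute (gamma, mu_tw, mu_t) directly from the responsibilities.

        Independent of the incrementally maintained accumulators; used by the
        consistency audit.
        """
        D, T = self.gamma.shape
        W = self.mu_tw.shape[1]
        gamma = np.zeros((D, T))
        mu_tw = np.zeros((T, W))
        for d in range(D):
            contrib, _ = self.doc_contribution(d)
            gamma[d] = contrib.sum(axis=0)
            np.add.at(mu_tw.T, self.word_ids[d], contrib)
        return gamma, mu_tw, mu_tw.sum(axis=1)

    def audit(self, atol: float = 1e-9) -> None:
        gamma, mu_tw, mu_t = self.refresh_from_scratch()
        assert np.allclose(gamma, self.gamma, atol=atol), "gamma accumulator inconsistent"
        assert np.allclose(mu_tw, self.mu_tw, atol=atol), "mu_tw accumulator inconsistent"
        assert np.allclose(mu_t, self.mu_t, atol=atol), "mu_t accumulator inconsistent"
        for d in range(self.n_docs):
            s = self.eta[d].sum(axis=1)
            assert np.allclose(s, 1.0, atol=1e-9), f"eta rows of doc {d} not normalized"

    def expected_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Full expected counts E[N_dt] (D,T) and E[N_tw] (T,W)."""
        D, T = self.gamma.shape
        W = self.mu_tw.shape[1]
        E_dt = np.zeros((D, T))
        E_tw = np.zeros((T, W))
        for d in range(D):
            full = np.zeros((self.word_ids[d].size, T))
            full[:, self.active[d]] = self.word_counts[d][:, None] * self.eta[d]
            E_dt[d] = full.sum(axis=0)
            np.add.at(E_tw.T, self.word_ids[d], full)
        return E_dt, E_tw


def init_variational_state(
    corpus: Corpus,
    alpha: np.ndarray,
    lam: np.ndarray,
    rng: np.random.Generator,
    track_var: bool = False,
) -> VariationalState:
    """Initialize responsibilities uniform over active labels and global
    statistics as mu_tw = lam_w + s * lam_w / 10 with random s ~ U(0, 1)."""
    D = corpus.n_documents
    T = corpus.n_labels
    W = corpus.n_words
    Lambda = corpus.labels.matrix
    word_ids, word_counts, active, eta = [], [], [], []
    for d, doc in enumerate(corpus.documents):
        ids = np.fromiter(doc.counts.keys(), dtype=np.int64)
        order = np.argsort(ids)
        ids = ids[order]
        counts = np.fromiter(doc.counts.values(), dtype=float)[order]
        act = np.nonzero(Lambda[d])[0]
        if act.size == 0:
            raise ValueError(f"document {d} has no active labels")
        word_ids.append(ids)
        word_counts.append(counts)
        active.append(act)
        eta.append(np.full((ids.size, act.size), 1.0 / act.size))

    s = rng.uniform(0.0, 1.0, size=(T, W))
    init_mu_tw = lam[None, :] + s * lam[None, :] / 10.0
    state = VariationalState(
        word_ids=word_ids,
        word_counts=word_counts,
        active=active,
        eta=eta,
        gamma=np.zeros((D, T)),
        mu_tw=np.zeros((T, W)),
        mu_t=np.zeros(T),
        var_tw=np.zeros((T, W)),
        var_t=np.zeros(T),
        alpha=np.asarray(alpha, dtype=float),
        Lambda=np.asarray(Lambda, dtype=float),
        lam=np.asarray(lam, dtype=float),
        track_var=track_var,
        init_mu_tw=init_mu_tw,
    )
    # accumulate global stats from the uniform responsibilities
    mu_tw = np.zeros((T, W))
    var_tw = np.zeros((T, W))
    for d in range(D):
        contrib, var = state.doc_contribution(d)
        state.gamma[d] = contrib.sum(axis=0)
        np.add.at(mu_tw.T, word_ids[d], contrib)
        if track_var:
            np.add.at(var_tw.T, word_ids[d], var)
    state.mu_tw = mu_tw
    state.mu_t = mu_tw.sum(axis=1)
    if track_var:
        state.var_tw = var_tw
        state.var_t = var_tw.sum(axis=1)
    return state


def cvb0_local_update(
    state: VariationalState,
    d: int,
    mu_tw: np.ndarray,
    mu_t: np.ndarray,
    local_iters: int = 100,
    local_tol: float = 1e-5,
) -> int:
    """CVB0 local fixed point for document d against global stats (mu_tw, mu_t).

    eta_dwt ∝ (alpha_dt + gamma_dt) (lam_w + mu_tw) / (sum lam + mu_t) over the
    doc's active labels; gamma is the (N_dw - 1)-weighted sum refreshed each
    pass. Returns the number of local iterations run.
    """
    ids = state.word_ids[d]
    m = state.word_counts[d] - 1.0
    act = state.active[d]
    Nd = state.word_counts[d].sum()
    lam_sum = state.lam.sum()
    alpha_a = state.alpha[d, act]
    num_tw = state.lam[ids][:, None] + mu_tw[act][:, ids].T  # (K, Ta)
    den_t = lam_sum + mu_t[act]                              # (Ta,)
    eta = state.eta[d]
    gamma = m @ eta
    for it in range(1, local_iters + 1):
        eta = (alpha_a + gamma)[None, :] * num_tw / den_t[None, :]
        norm = eta.sum(axis=1, keepdims=True)
        if np.any(norm <= 0):
            raise ZeroDivisionError(f"zero responsibility mass in doc {d}")
        eta = eta / norm
        gamma_new = m @ eta
        delta = np.abs(gamma_new - gamma).sum() / Nd
        gamma = gamma_new
        if delta < local_tol:
            break
    state.eta[d] = eta
    state.gamma[d] = np.zeros(state.n_topics)
    state.gamma[d, act] = gamma
    return it


def cvb_local_update(
    state: VariationalState,
    d: int,
    mu_tw: np.ndarray,
    mu_t: np.ndarray,
    var_tw: np.ndarray,
    var_t: np.ndarray,
    local_iters: int = 100,
    local_tol: float = 1e-5,
) -> int:
    """Moment-corrected CVB local fixed point for document d.

    Each log-count term gets the second-order correction
    -var / (2 (a + mu)^2); the topic-total term divides, so its correction
    enters with a plus sign. Variances are per-term Bernoulli-style sums
    m eta (1 - m eta) clipped at zero.
    """
    ids = state.word_ids[d]
    m = state.word_counts[d] - 1.0
    act = state.active[d]
    Nd = state.word_counts[d].sum()
    lam_sum = state.lam.sum()
    alpha_a = state.alpha[d, act]

    a_tw = state.lam[ids][:, None] + mu_tw[act][:, ids].T      # (K, Ta)
    if np.any(a_tw <= 0):
        raise ValueError("non-positive lam + mu_tw in CVB expansion")
    log_tw = np.log(a_tw) - var_tw[act][:, ids].T / (2.0 * a_tw**2)
    a_t = lam_sum + mu_t[act]                                  # (Ta,)
    if np.any(a_t <= 0):
        raise ValueError("non-positive lam sum + mu_t in CVB expansion")
    log_t = np.log(a_t) - var_t[act] / (2.0 * a_t**2)

    eta = state.eta[d]
    me = m[:, None] * eta
    gamma = me.sum(axis=0)
    var_dt = np.clip(me * (1.0 - me), 0.0, None).sum(axis=0)
    for it in range(1, local_iters + 1):
        a_dt = alpha_a + gamma
        if np.any(a_dt <= 0):
            raise ValueError("non-positive alpha + gamma in CVB expansion")
        log_dt = np.log(a_dt) - var_dt / (2.0 * a_dt**2)
        log_eta = log_dt[None, :] + log_tw - log_t[None, :]
        log_eta -= log_eta.max(axis=1, keepdims=True)
        eta = np.exp(log_eta)
        eta /= eta.sum(axis=1, keepdims=True)
        me = m[:, None] * eta
        gamma_new = me.sum(axis=0)
        var_dt = np.clip(me * (1.0 - me), 0.0, None).sum(axis=0)
        delta = np.abs(gamma_new - gamma).sum() / Nd
        gamma = gamma_new
        if delta < local_tol:
            break
    state.eta[d] = eta
    state.gamma[d] = np.zeros(state.n_topics)
    state.gamma[d, act] = gamma
    return it


def train_variational(corpus: Corpus, config, variant: str = "cvb0") -> FittedModel:
    """Alternating local/global collapsed variational inference.

    Per global iteration: alpha refreshed from the current feature weights;
    every document re-initialized to uniform responsibilities and iterated to
    local convergence against the previous global statistics; global
    statistics rebuilt incrementally from per-document deltas; feature weights
    re-optimized on the full expected counts. Stops when the global topic-word
    statistics change by less than ``global_tol`` on average, or after
    ``global_iters`` iterations (then flagged unconverged in the metadata).
    """
    from .config import TrainConfig

    cfg = config if isinstance(config, TrainConfig) else TrainConfig(**config)
    if variant not in ("cvb", "cvb0"):
        raise ValueError(f"unknown variant {variant!r}")
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
    state = init_variational_state(corpus, alpha, lam, rng, track_var=(variant == "cvb"))
    Nd = np.array([doc.n_tokens for doc in corpus.documents], dtype=float)

    converged = False
    for it in range(1, cfg.global_iters + 1):
        state.alpha = compute_alpha(Y_hat, beta)
        if it == 1:
            mu_tw_prev = state.init_mu_tw.copy()
            mu_t_prev = mu_tw_prev.sum(axis=1)
        else:
            mu_tw_prev = state.mu_tw.copy()
            mu_t_prev = state.mu_t.copy()
        var_tw_prev = state.var_tw.copy()
        var_t_prev = state.var_t.copy()
        for d in range(state.n_docs):
            old_contrib, old_var = state.doc_contribution(d)
            # fresh constant start for the local fixed point
            state.eta[d] = np.full_like(state.eta[d], 1.0 / state.active[d].size)
            if variant == "cvb0":
                cvb0_local_update(
                    state, d, mu_tw_prev, mu_t_prev, cfg.local_iters, cfg.local_tol
                )
            else:
                cvb_local_update(
                    state, d, mu_tw_prev, mu_t_prev, var_tw_prev, var_t_prev,
                    cfg.local_iters, cfg.local_tol,
                )
            new_contrib, new_var = state.doc_contribution(d)
            np.add.at(state.mu_tw.T, state.word_ids[d], new_contrib - old_contrib)
            if state.track_var:
                np.add.at(state.var_tw.T, state.word_ids[d], new_var - old_var)
        state.mu_t = state.mu_tw.sum(axis=1)
        if state.track_var:
            state.var_t = state.var_tw.sum(axis=1)

        if cfg.update_features:
            E_dt, _ = state.expected_counts()
            beta = update_beta(beta, Nd, E_dt, Lambda, Y_hat, damping=cfg.beta_damping)
        drift = np.abs(state.mu_tw - mu_tw_prev).mean()
        if drift < cfg.global_tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "train_variational(%s): not converged after %d global iterations", variant, it
        )

    state.alpha = compute_alpha(Y_hat, beta)
    E_dt, E_tw = state.expected_counts()
    pi_hat, theta_hat = estimate_parameters(state.alpha, Lambda, lam, [E_dt], [E_tw])
    return FittedModel(
        theta_hat=theta_hat,
        beta_hat=beta,
        lam=lam,
        vocabulary=corpus.vocabulary,
        label_names=list(corpus.labels.label_names),
        feature_names=list(corpus.features.feature_names),
        transform=corpus.features.transform,
        config={**cfg.to_dict(), "inference": variant},
        pi_hat_train=pi_hat,
        converged=converged,
    )
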