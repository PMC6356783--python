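"""Feature-conditioned Dirichlet prior (Dirichlet-multinomial regression).

Each gene d carries a feature vector y_d (molecular weight, isoelectric
point, hydrophilicity, ...). The model makes the gene's Dirichlet prior over
its annotated function-topics log-linear in those features:

    alpha_dt = exp(y^_d · beta^_t),

where y^_d is y_d augmented with a constant 1 ("default feature") and beta^_t
is the topic's weight vector over F real features plus a default column. The
default column absorbs the per-gene scale delta_d^{-1}, so no separate scale
parameter exists. Each beta_tf has an independent Normal(mu, sigma2) prior.

beta^ is optimized by a damped fixed-point iteration on the stationarity
condition of the collapsed log-likelihood's beta-dependent part,

    beta_tf = mu + sigma2 * sum_d y_df alpha_dt Lam_dt
              [ psi(S_d) - psi(S_d + N_d) + psi(alpha_dt + N_dt) - psi(alpha_dt) ],

with S_d = sum_t alpha_dt Lam_dt, monitored so the objective never decreases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

#: default clip bound on log(alpha); guards digamma/exp against overflow
LOG_ALPHA_CLIP = 30.0

#: type alias for the D x T matrix of positive Dirichlet hyper-parameters
AlphaPrior = np.ndarray


@dataclass
class FeatureWeights:
    """T x (F+1) per-topic feature weights; the last column is the default.

    The default column plays the role of a per-topic intercept: with all real
    weights zero and default weight log(a), every alpha_dt equals a.
    """

    matrix: np.ndarray
    mu: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature weight matrix must be 2-D (T x F+1)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature weights must be finite")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")

    @property
    def n_topics(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        """Number of real features F (excluding the default column)."""
        return self.matrix.shape[1] - 1

    @classmethod
    def initial(cls, n_topics: int, n_features: int, alpha_init: float,
                mu: float = 0.0, sigma2: float = 1.0) -> "FeatureWeights":
        """Weights whose default column yields alpha_dt = alpha_init everywhere."""
        mat = np.zeros((n_topics, n_features + 1))
        mat[:, -1] = np.log(alpha_init)
        return cls(matrix=mat, mu=mu, sigma2=sigma2)


def augment_features(y: np.ndarray, n_features: int | None = None) -> np.ndarray:
    """Append the constant default feature 1 to a vector or row matrix.

    ``n_features`` guards against double augmentation: when given, the input's
    trailing dimension must equal it exactly.
    """
    y = np.asarray(y, dtype=float)
    if n_features is not None and y.shape[-1] != n_features:
        raise ValueError(f"expected {n_features} features, got {y.shape[-1]}")
    if y.ndim == 1:
        return np.concatenate([y, [1.0]])
    if y.ndim == 2:
        return np.hstack([y, np.ones((y.shape[0], 1))])
    raise ValueError("features must be 1-D or 2-D")


def compute_alpha(Y_hat: np.ndarray, beta: FeatureWeights,
                  clip: float = LOG_ALPHA_CLIP) -> AlphaPrior:
    """alpha_dt = exp(y^_d · beta^_t), computed in log space with clipping.

    ``Y_hat`` is the D x (F+1) augmented feature matrix. The log is clipped to
    ``[-clip, clip]`` before exponentiation so extreme (un-standardized)
    features cannot overflow the sampler.
    """
    Y_hat = np.atleast_2d(np.asarray(Y_hat, dtype=float))
    if Y_hat.shape[1] != beta.matrix.shape[1]:
        raise ValueError(
            f"augmented features have {Y_hat.shape[1]} columns, "
            f"weights expect {beta.matrix.shape[1]}"
        )
    log_alpha = np.clip(Y_hat @ beta.matrix.T, -clip, clip)
    alpha = np.exp(log_alpha)
    if not np.all(np.isfinite(alpha)):
        d, t = np.argwhere(~np.isfinite(alpha))[0]
        raise FloatingPointError(f"non-finite alpha at (doc {d}, topic {t})")
    return alpha


def beta_log_objective(
    beta: FeatureWeights,
    Nd: np.ndarray,
    Ndt: np.ndarray,
    Lambda: np.ndarray,
    Y_hat: np.ndarray,
) -> float:
    """Log of the beta-dependent part of the collapsed joint.

    Gaussian prior term plus, per document, the Dirichlet-multinomial evidence
    over its active labels:

        log G(S_d) - log G(S_d + N_d)
        + sum_{t active} [ log G(alpha_dt + N_dt) - log G(alpha_dt) ],

    S_d = sum_{t active} alpha_dt. Counts may be expected (real-valued) counts
    from a variational state. Inactive labels contribute exactly zero.
    """
    Lambda = np.asarray(Lambda, dtype=float)
    Ndt = np.asarray(Ndt, dtype=float)
    Nd = np.asarray(Nd, dtype=float)
    alpha = compute_alpha(Y_hat, beta)
    A = alpha * Lambda
    active = Lambda > 0
    if np.any((A + Ndt * Lambda)[active] <= 0):
        raise ValueError("alpha + Ndt <= 0 on an active label")
    S = A.sum(axis=1)
    prior = -np.sum((beta.matrix - beta.mu) ** 2) / (2.0 * beta.sigma2)
    doc_term = gammaln(S) - gammaln(S + Nd)
    topic_term = np.where(active, gammaln(A + Ndt * Lambda) - gammaln(np.where(active, A, 1.0)), 0.0)
    return float(prior + doc_term.sum() + topic_term.sum())


def _beta_fixed_point(
    beta_mat: np.ndarray,
    mu: float,
    sigma2: float,
    Nd: np.ndarray,
    Ndt: np.ndarray,
    Lambda: np.ndarray,
    Y_hat: np.ndarray,
) -> np.ndarray:
    """One full evaluation of the stationarity right-hand side."""
    alpha = np.exp(np.clip(Y_hat @ beta_mat.T, -LOG_ALPHA_CLIP, LOG_ALPHA_CLIP))
    A = alpha * Lambda
    S = A.sum(axis=1)
    active = Lambda > 0
    safe_A = np.where(active, A, 1.0)
    g = np.where(
        active,
        digamma(S)[:, None] - digamma(S + Nd)[:, None]
        + digamma(safe_A + Ndt * Lambda) - digamma(safe_A),
        0.0,
    )
    # sum_d y_df * alpha_dt * Lam_dt * g_dt  ->  (T, F+1)
    return mu + sigma2 * (A * g).T @ Y_hat


def update_beta(
    beta: FeatureWeights,
    Nd: np.ndarray,
    Ndt: np.ndarray,
    Lambda: np.ndarray,
    Y_hat: np.ndarray,
    damping: float = 0.5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> FeatureWeights:
    """Damped fixed-point optimization of the feature weights.

    Each pass proposes the stationarity right-hand side (with alpha recomputed
    from the current weights) and moves a damped step
    ``new = (1 - rho) old + rho proposed`` toward it. Because the proposal
    offset equals sigma2 times the objective gradient, the damped step is a
    gradient ascent step: it is accepted under an Armijo sufficient-increase
    test, backtracked (rho halved) when the objective would decrease, and the
    step size is grown again after clean acceptances. Stops when the gradient
    ``max |proposed - beta| / sigma2`` falls below ``tol`` or after
    ``max_iter`` accepted passes.
    """
    if not 0 < damping <= 1:
        raise ValueError("damping must be in (0, 1]")
    Nd = np.asarray(Nd, dtype=float)
    Ndt = np.asarray(Ndt, dtype=float)
    Lambda = np.asarray(Lambda, dtype=float)
    Y_hat = np.atleast_2d(np.asarray(Y_hat, dtype=float))
    mat = beta.matrix.copy()
    obj = beta_log_objective(FeatureWeights(mat, beta.mu, beta.sigma2), Nd, Ndt, Lambda, Y_hat)
    start_obj = obj
    rho = damping
    for _ in range(max_iter):
        proposed = _beta_fixed_point(mat, beta.mu, beta.sigma2, Nd, Ndt, Lambda, Y_hat)
        step = proposed - mat            # = sigma2 * gradient of the objective
        grad_sq = float(np.sum(step**2)) / beta.sigma2
        if np.max(np.abs(step)) / beta.sigma2 < tol:
            break
        accepted = False
        for _back in range(40):
            cand = mat + rho * step
            cand_obj = beta_log_objective(
                FeatureWeights(cand, beta.mu, beta.sigma2), Nd, Ndt, Lambda, Y_hat
            )
            if cand_obj >= obj + 1e-4 * rho * grad_sq - 1e-12:
                accepted = True
                break
            rho *= 0.5
        if not accepted:
            break  # stationary up to backtracking resolution
        mat, obj = cand, cand_obj
        rho = min(rho * 2.0, 1.0)
    if obj < start_obj - 1e-9:
        raise RuntimeError(
            "beta optimization diverged (objective decreased); try a smaller damping"
        )
    return FeatureWeights(matrix=mat, mu=beta.mu, sigma2=beta.sigma2)
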