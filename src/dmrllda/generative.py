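"""Forward sampling of the generative model, for recovery tests and demos.

The synthetic corpus generator draws from exactly the process the inference
algorithms invert: per-topic word distributions theta_t ~ Dirichlet(lambda),
per-topic feature weights beta^_t ~ Normal(mu, sigma2 I); then per gene a
label set Lam_d, features y_d, the feature-conditioned prior
alpha_dt = exp(y^_d beta^_t) masked by Lam_d, topic weights
pi_d ~ Dirichlet(alpha_d masked), and finally per token a topic
t_dn ~ Cat(pi_d) and word w_dn ~ Cat(theta_{t_dn}).

Because labels and topics are in one-to-one correspondence, recovered
parameters can be compared to the ground truth topic-by-topic with no
permutation matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .dmr_prior import FeatureWeights, augment_features, compute_alpha
from .io_corpus import Corpus, FeatureTable, GeneDocument, Vocabulary, full_vocabulary
from .label_space import LabelMatrix

#: small default scenario: rich enough to exercise the feature-driven prior,
#: small enough for minutes-scale test runs
DEFAULT_SCENARIO = dict(T=5, W=30, F=2, D=200, Nd=100)


@dataclass
class GroundTruth:
    """True parameters and assignments behind a synthetic corpus."""

    theta_true: np.ndarray        # (T, W)
    beta_true: FeatureWeights     # T x (F+1)
    pi_true: np.ndarray           # (D, T), zero off the active labels
    assignments_true: list[np.ndarray]  # per-doc token topic ids
    alpha_true: np.ndarray        # (D, T) unmasked prior


def synthetic_vocabulary(W: int) -> Vocabulary:
    """First W dimer words in lexicographic order (W <= 400)."""
    base = full_vocabulary({2})
    if W > len(base):
        raise ValueError(f"synthetic vocabulary supports at most {len(base)} words")
    return Vocabulary(words=base.words[:W], k_set=frozenset({2}))


def sample_model(
    T: int,
    W: int,
    F: int,
    mu: float,
    sigma2: float,
    lambda_vec: np.ndarray | float,
    rng: np.random.Generator,
) -> tuple[FeatureWeights, np.ndarray]:
    """Draw global parameters: beta^_t ~ N(mu, sigma2 I), theta_t ~ Dir(lambda)."""
    if T < 1 or W < 1 or F < 0:
        raise ValueError("T, W must be >= 1 and F >= 0")
    lam = np.broadcast_to(np.asarray(lambda_vec, dtype=float), (W,))
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive")
    beta_mat = mu + np.sqrt(sigma2) * rng.standard_normal((T, F + 1))
    beta = FeatureWeights(matrix=beta_mat, mu=mu, sigma2=sigma2)
    theta = rng.dirichlet(lam, size=T)
    return beta, theta


def binomial_label_sampler(n_labels: int, extra_n: int = 2, extra_p: float = 0.5) -> Callable:
    """Label sets of size 1 + Binomial(extra_n, extra_p), drawn uniformly.

    Independent of the gene's features: the features then shape only the
    topic proportions within the label set, not which labels are present.
    """

    def sample(rng: np.random.Generator, y: np.ndarray) -> np.ndarray:
        k = 1 + rng.binomial(extra_n, extra_p)
        k = min(k, n_labels)
        lam = np.zeros(n_labels, dtype=np.int8)
        lam[rng.choice(n_labels, size=k, replace=False)] = 1
        return lam

    return sample


def feature_logistic_label_sampler(
    weights: np.ndarray, gain: float = 2.0, bias: float = -1.0
) -> Callable:
    """Label sets whose presence depends on the gene's features.

    Label t is active with probability sigmoid(gain * y · w_t + bias), with
    ``weights`` a (T, F) matrix; a gene drawing no label gets its
    highest-scoring one. This emulates real gene data, where features such as
    molecular weight carry information about which functions a gene has — the
    regime in which a feature-conditioned prior can help prediction.
    """
    weights = np.asarray(weights, dtype=float)

    def sample(rng: np.random.Generator, y: np.ndarray) -> np.ndarray:
        score = gain * (weights @ y) + bias
        p = 1.0 / (1.0 + np.exp(-score))
        lam = (rng.random(weights.shape[0]) < p).astype(np.int8)
        if lam.sum() == 0:
            lam[int(np.argmax(score))] = 1
        return lam

    return sample


def normal_feature_sampler(n_features: int) -> Callable:
    """Standard-normal feature vectors (already on the standardized scale)."""

    def sample(rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(n_features)

    return sample


def sample_corpus(
    theta_true: np.ndarray,
    beta_true: FeatureWeights,
    label_sampler: Callable,
    feature_sampler: Callable,
    D: int,
    Nd: int | np.ndarray,
    rng: np.random.Generator,
) -> tuple[Corpus, GroundTruth]:
    """Sample D genes of Nd tokens each from the generative process."""
    theta_true = np.asarray(theta_true, dtype=float)
    T, W = theta_true.shape
    F = beta_true.n_features
    doc_lengths = np.broadcast_to(np.asarray(Nd, dtype=int), (D,))

    Lambda = np.zeros((D, T), dtype=np.int8)
    features = np.zeros((D, F))
    for d in range(D):
        features[d] = feature_sampler(rng)
        lam = np.asarray(label_sampler(rng, features[d]), dtype=np.int8)
        if lam.sum() == 0:
            raise ValueError(f"label sampler produced an all-zero label set for doc {d}")
        Lambda[d] = lam

    alpha = compute_alpha(augment_features(features, F), beta_true)
    pi = np.zeros((D, T))
    docs: list[GeneDocument] = []
    assignments: list[np.ndarray] = []
    for d in range(D):
        active = Lambda[d].nonzero()[0]
        pi[d, active] = rng.dirichlet(alpha[d, active])
        t_dn = active[rng.choice(active.size, size=doc_lengths[d], p=pi[d, active])] \
            if active.size > 1 else np.full(doc_lengths[d], active[0])
        w_dn = np.empty(doc_lengths[d], dtype=np.int64)
        for t in np.unique(t_dn):
            mask = t_dn == t
            w_dn[mask] = rng.choice(W, size=int(mask.sum()), p=theta_true[t])
        docs.append(GeneDocument(gene_id=f"g{d:05d}", tokens=w_dn))
        assignments.append(t_dn.astype(np.int64))

    vocab = synthetic_vocabulary(W)
    labels = LabelMatrix(matrix=Lambda, label_names=[f"L{t:03d}" for t in range(T)])
    feats = FeatureTable(
        values=features,
        feature_names=[f"f{f + 1}" for f in range(F)],
        transform=(np.zeros(F), np.ones(F)),
    )
    corpus = Corpus(documents=docs, vocabulary=vocab, labels=labels, features=feats)
    truth = GroundTruth(
        theta_true=theta_true,
        beta_true=beta_true,
        pi_true=pi,
        assignments_true=assignments,
        alpha_true=alpha,
    )
    return corpus, truth


def simulate(
    T: int = DEFAULT_SCENARIO["T"],
    W: int = DEFAULT_SCENARIO["W"],
    F: int = DEFAULT_SCENARIO["F"],
    D: int = DEFAULT_SCENARIO["D"],
    Nd: int = DEFAULT_SCENARIO["Nd"],
    mu: float = 0.0,
    sigma2: float = 1.0,
    lambda_scale: float = 200.0,
    seed: int | np.random.Generator = 0,
) -> tuple[Corpus, GroundTruth]:
    """One-call synthetic scenario with the package defaults.

    ``lambda_scale`` sets the symmetric word smoothing lambda_w =
    lambda_scale / W, matching the model-side default.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta_true, theta_true = sample_model(T, W, F, mu, sigma2, lambda_scale / W, rng)
    return sample_corpus(
        theta_true,
        beta_true,
        binomial_label_sampler(T),
        normal_feature_sampler(F),
        D,
        Nd,
        rng,
    )


def simulate_feature_coupled(
    T: int = DEFAULT_SCENARIO["T"],
    W: int = DEFAULT_SCENARIO["W"],
    F: int = DEFAULT_SCENARIO["F"],
    D: int = DEFAULT_SCENARIO["D"],
    Nd: int = DEFAULT_SCENARIO["Nd"],
    mu: float = 0.0,
    sigma2: float = 1.0,
    lambda_scale: float = 200.0,
    gain: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> tuple[Corpus, GroundTruth]:
    """Synthetic scenario in which features genuinely drive the prior.

    Label presence follows a logistic model on the same feature weights that
    shape the within-set proportions (the real columns of beta_true), so a
    gene's features are informative about which functions it has — the regime
    a feature-conditioned prior is designed for.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta_true, theta_true = sample_model(T, W, F, mu, sigma2, lambda_scale / W, rng)
    label_sampler = feature_logistic_label_sampler(beta_true.matrix[:, :F], gain=gain)
    return sample_corpus(
        theta_true,
        beta_true,
        label_sampler,
        normal_feature_sampler(F),
        D,
        Nd,
        rng,
    )
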