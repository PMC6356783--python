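"""Fold-in prediction for new genes and multi-label evaluation.

Prediction keeps the fitted global parameters (theta^, beta^) fixed. A test
gene gets its own prior alpha_d = exp(y^_d beta^_t) from its features; its
label support defaults to the full label space (every label is a candidate)
unless a candidate mask is supplied. The gene's topic weights pi^_d are then
inferred either by a Gibbs fold-in chain,

    p(t_dn = t) ∝ (alpha_dt + N_dt^{\\dn}) theta^_{t, w_dn},

or by the zero-order variational local fixed point against theta^.

Evaluation covers the standard multi-label criteria — Hamming loss, ranking
average precision, one-error, micro-/macro-averaged F1 — plus three areas
under precision-recall curves: macro-averaged over labels, pooled over all
gene-label pairs, and label-frequency-weighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.metrics import average_precision_score, f1_score

from ._kernels import foldin_sweep_kernel, seed_kernel
from .config import CVConfig, PredictConfig, TrainConfig
from .dmr_prior import augment_features, compute_alpha
from .inference_cgs import FittedModel, _label_csr, train_cgs
from .io_corpus import Corpus, FeatureTable, apply_transform
from .label_space import LabelMatrix, bmd_decompose, bmd_recover

logger = logging.getLogger("dmrllda")


@dataclass
class PredictionScores:
    """D_test x L score matrix (rows are topic-weight distributions)."""

    scores: np.ndarray
    method: str
    config: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(self.scores < 0):
            raise ValueError("prediction scores must be non-negative")


# ---------------------------------------------------------------------------
# fold-in prediction
# ---------------------------------------------------------------------------

def predict(
    model: FittedModel,
    test_corpus: Corpus | list[np.ndarray],
    features: np.ndarray | None = None,
    config: PredictConfig | None = None,
    candidate_mask: np.ndarray | None = None,
) -> PredictionScores:
    """Score every label for each test gene by fold-in inference.

    ``test_corpus`` may be a :class:`Corpus` (its features are used, passed
    through the model's stored standardization transform) or a bare list of
    token-id arrays with ``features`` given explicitly on the standardized
    scale.
    """
    cfg = config or PredictConfig()
    T = model.n_topics
    if isinstance(test_corpus, Corpus):
        token_lists = [doc.tokens for doc in test_corpus.documents]
        feats = test_corpus.features.values
        if model.transform is not None and test_corpus.features.transform is None:
            feats = apply_transform(feats, model.transform)
    else:
        token_lists = [np.asarray(t, dtype=np.int64) for t in test_corpus]
        if features is None:
            raise ValueError("features required when test_corpus is a token list")
        feats = np.asarray(features, dtype=float)
    D = len(token_lists)
    F = model.beta_hat.n_features
    if feats.shape[1] != F:
        raise ValueError(f"test features have {feats.shape[1]} columns, model expects {F}")
    Lambda = (
        np.ones((D, T), dtype=np.int8)
        if candidate_mask is None
        else np.asarray(candidate_mask, dtype=np.int8)
    )
    alpha = compute_alpha(augment_features(feats, F), model.beta_hat)

    if cfg.method == "cgs":
        E_dt = _foldin_gibbs(token_lists, Lambda, alpha, model.theta_hat, cfg)
    else:
        E_dt = _foldin_cvb0(token_lists, Lambda, alpha, model.theta_hat, cfg)

    num = (alpha + E_dt) * Lambda
    scores = num / num.sum(axis=1, keepdims=True)
    return PredictionScores(scores=scores, method=cfg.method, config=cfg.to_dict())


def _foldin_gibbs(token_lists, Lambda, alpha, theta, cfg: PredictConfig) -> np.ndarray:
    rng = np.random.default_rng(cfg.seed)
    D, T = Lambda.shape
    doc_offsets = np.zeros(D + 1, dtype=np.int64)
    for d, toks in enumerate(token_lists):
        doc_offsets[d + 1] = doc_offsets[d] + len(toks)
    token_doc = np.repeat(np.arange(D, dtype=np.int64), np.diff(doc_offsets))
    token_word = (
        np.concatenate(token_lists).astype(np.int64)
        if doc_offsets[-1]
        else np.empty(0, dtype=np.int64)
    )
    label_offsets, label_ids = _label_csr(Lambda)
    z = np.empty(token_word.shape[0], dtype=np.int64)
    for d in range(D):
        active = label_ids[label_offsets[d] : label_offsets[d + 1]]
        sl = slice(doc_offsets[d], doc_offsets[d + 1])
        z[sl] = active[rng.integers(0, active.size, size=doc_offsets[d + 1] - doc_offsets[d])]
    N_dt = np.zeros((D, T))
    np.add.at(N_dt, (token_doc, z), 1.0)
    probs = np.empty(int(np.diff(label_offsets).max(initial=1)), dtype=float)
    recorded: list[np.ndarray] = []
    for sweep in range(1, cfg.iterations + 1):
        seed_kernel(int(rng.integers(0, 2**31 - 1)))
        foldin_sweep_kernel(
            token_doc, token_word, z, label_offsets, label_ids,
            N_dt, alpha, theta, probs,
        )
        if sweep > cfg.burn_in and (sweep - cfg.burn_in) % cfg.thin == 0:
            recorded.append(N_dt.copy())
    if not recorded:
        recorded.append(N_dt.copy())
    return np.mean(recorded, axis=0)


def _foldin_cvb0(token_lists, Lambda, alpha, theta, cfg: PredictConfig) -> np.ndarray:
    D, T = Lambda.shape
    E_dt = np.zeros((D, T))
    for d, toks in enumerate(token_lists):
        act = np.nonzero(Lambda[d])[0]
        if toks.size == 0:
            continue
        ids, counts = np.unique(toks, return_counts=True)
        counts = counts.astype(float)
        Nd = counts.sum()
        m = counts - 1.0
        theta_a = theta[np.ix_(act, ids)].T       # (K, Ta)
        eta = np.full((ids.size, act.size), 1.0 / act.size)
        gamma = m @ eta
        for _ in range(cfg.local_iters):
            eta = (alpha[d, act] + gamma)[None, :] * theta_a
            norm = eta.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            eta = eta / norm
            gamma_new = m @ eta
            if np.abs(gamma_new - gamma).sum() / Nd < cfg.local_tol:
                gamma = gamma_new
                break
            gamma = gamma_new
        E_dt[d, act] = counts @ eta
    return E_dt


# ---------------------------------------------------------------------------
# binarization and metrics
# ---------------------------------------------------------------------------

def tune_threshold(scores: np.ndarray, truth: np.ndarray) -> float:
    """Single global cut maximizing micro-F1 on reference predictions.

    Candidates are the distinct score values; ties on F1 go to the lowest
    threshold.
    """
    best_thr, best_f1 = 0.0, -1.0
    for thr in np.unique(scores):
        f1 = f1_score(truth, (scores >= thr).astype(int), average="micro", zero_division=0)
        if f1 > best_f1 + 1e-12:
            best_f1, best_thr = f1, float(thr)
    return best_thr


def binarize(
    scores: np.ndarray,
    policy: str = "uniform",
    threshold: float | None = None,
) -> np.ndarray:
    """Turn label scores into hard predictions.

    ``uniform``: label on iff score >= 1/L (boundary inclusive). ``tuned``:
    apply the supplied global ``threshold`` (obtained from
    :func:`tune_threshold` on training-fold predictions).
    """
    scores = np.asarray(scores, dtype=float)
    if policy == "uniform":
        return (scores >= 1.0 / scores.shape[1]).astype(np.int8)
    if policy == "tuned":
        if threshold is None:
            raise ValueError("tuned policy requires a threshold")
        return (scores >= threshold).astype(np.int8)
    raise ValueError(f"unknown binarization policy {policy!r}")


@dataclass
class MetricsReport:
    """The eight multi-label criteria plus bookkeeping."""

    hamming_loss: float
    average_precision: float
    one_error: float
    micro_f1: float
    macro_f1: float
    aupr_macro: float
    aupr_pooled: float
    aupr_weighted: float
    n_excluded: int = 0      # genes with empty truth, excluded from ranking metrics
    threshold: float | None = None

    def to_dict(self) -> dict[str, float]:
        return {
            "hamming_loss": self.hamming_loss,
            "average_precision": self.average_precision,
            "one_error": self.one_error,
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            "aupr_macro": self.aupr_macro,
            "aupr_pooled": self.aupr_pooled,
            "aupr_weighted": self.aupr_weighted,
        }


def _ranks(scores_row: np.ndarray) -> np.ndarray:
    """1-based rank of each label by descending score, ties by label index."""
    order = np.lexsort((np.arange(scores_row.size), -scores_row))
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, scores_row.size + 1)
    return ranks


def compute_metrics(
    scores: np.ndarray,
    binary_pred: np.ndarray,
    truth: LabelMatrix | np.ndarray,
    threshold: float | None = None,
) -> MetricsReport:
    """Evaluate predictions against the binary truth.

    Ranking metrics (average precision, one-error, the AUPR family) use the
    raw scores; Hamming loss and the F1 scores use ``binary_pred``. Genes with
    no true label are excluded from the ranking metrics with a count; labels
    with no positive gene are excluded from the macro/weighted AUPR means.
    """
    Y = truth.matrix if isinstance(truth, LabelMatrix) else np.asarray(truth)
    Y = Y.astype(int)
    scores = np.asarray(scores, dtype=float)
    binary_pred = np.asarray(binary_pred, dtype=int)
    if scores.shape != Y.shape or binary_pred.shape != Y.shape:
        raise ValueError("shape mismatch between scores, predictions and truth")
    D, L = Y.shape

    hl = float(np.mean(binary_pred != Y))

    nonempty = Y.sum(axis=1) > 0
    n_excluded = int(D - nonempty.sum())
    ap_terms, one_err_terms = [], []
    for d in np.nonzero(nonempty)[0]:
        ranks = _ranks(scores[d])
        true_ranks = np.sort(ranks[Y[d] == 1])
        prec_at = np.arange(1, true_ranks.size + 1) / true_ranks
        ap_terms.append(prec_at.mean())
        top = int(np.argmax(scores[d]))  # ties -> lowest index, matching _ranks
        one_err_terms.append(0.0 if Y[d, top] == 1 else 1.0)
    ap = float(np.mean(ap_terms)) if ap_terms else 0.0
    one_error = float(np.mean(one_err_terms)) if one_err_terms else 0.0

    micro = float(f1_score(Y, binary_pred, average="micro", zero_division=0))
    macro = float(f1_score(Y, binary_pred, average="macro", zero_division=0))

    pos_labels = np.nonzero(Y.sum(axis=0) > 0)[0]
    per_label = np.array(
        [average_precision_score(Y[:, l], scores[:, l]) for l in pos_labels]
    )
    freqs = Y[:, pos_labels].sum(axis=0).astype(float)
    aupr_macro = float(per_label.mean()) if per_label.size else 0.0
    aupr_weighted = float((per_label * freqs).sum() / freqs.sum()) if per_label.size else 0.0
    aupr_pooled = float(average_precision_score(Y.ravel(), scores.ravel())) if Y.any() else 0.0

    return MetricsReport(
        hamming_loss=hl,
        average_precision=ap,
        one_error=one_error,
        micro_f1=micro,
        macro_f1=macro,
        aupr_macro=aupr_macro,
        aupr_pooled=aupr_pooled,
        aupr_weighted=aupr_weighted,
        n_excluded=n_excluded,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-(round, fold) metric reports and their mean."""

    folds: list[tuple[int, int, MetricsReport]]
    mean: MetricsReport
    config: dict[str, Any]
    fold_assignments: list[np.ndarray] = field(default_factory=list)  # per round


def _mean_report(reports: list[MetricsReport]) -> MetricsReport:
    keys = reports[0].to_dict().keys()
    avg = {k: float(np.mean([r.to_dict()[k] for r in reports])) for k in keys}
    return MetricsReport(**avg, n_excluded=sum(r.n_excluded for r in reports))


def _subset_corpus(corpus: Corpus, idx: np.ndarray, labels: LabelMatrix | None = None) -> Corpus:
    lab = labels if labels is not None else corpus.labels
    raw = FeatureTable(
        values=corpus.features.values[idx],
        feature_names=list(corpus.features.feature_names),
    )
    return Corpus(
        documents=[corpus.documents[i] for i in idx],
        vocabulary=corpus.vocabulary,
        labels=LabelMatrix(matrix=lab.matrix[idx], label_names=list(lab.label_names)),
        features=raw,
    )


def _train(corpus: Corpus, cfg: TrainConfig) -> FittedModel:
    if cfg.inference == "cgs":
        return train_cgs(corpus, cfg)
    from .inference_cvb import train_variational

    return train_variational(corpus, cfg, variant=cfg.inference)


def cross_validate(corpus: Corpus, config: CVConfig | None = None) -> CVResult:
    """K-fold cross-validation repeated over independent rounds.

    Each round draws a fresh random (unstratified) partition; per fold the
    model is trained on the remaining genes (features re-standardized on the
    training fold), test genes are scored by fold-in, binarized, and
    evaluated. With ``use_bmd`` the training labels are compressed by Boolean
    matrix decomposition, the model runs in the compressed label space, and
    test scores are recovered to the full space through B (max-product)
    before evaluation.
    """
    from .io_corpus import standardize_features

    cfg = config or CVConfig()
    D = corpus.n_documents
    if D < cfg.n_folds:
        raise ValueError(f"need at least {cfg.n_folds} genes, got {D}")
    rng = np.random.default_rng(cfg.seed)
    reports: list[tuple[int, int, MetricsReport]] = []
    fold_assignments: list[np.ndarray] = []
    for rnd in range(cfg.n_rounds):
        perm = rng.permutation(D)
        fold_of = np.empty(D, dtype=int)
        fold_of[perm] = np.arange(D) % cfg.n_folds
        fold_assignments.append(fold_of.copy())
        for fold in range(cfg.n_folds):
            test_idx = np.nonzero(fold_of == fold)[0]
            train_idx = np.nonzero(fold_of != fold)[0]
            train_c = _subset_corpus(corpus, train_idx)
            test_c = _subset_corpus(corpus, test_idx)
            train_c.features = standardize_features(train_c.features, fit=True)

            B = None
            if cfg.use_bmd:
                fac = bmd_decompose(train_c.labels, max_rank=cfg.bmd_max_rank)
                B = fac.B
                train_c = Corpus(
                    documents=train_c.documents,
                    vocabulary=train_c.vocabulary,
                    labels=LabelMatrix(
                        matrix=fac.C,
                        label_names=[f"bmd{k}" for k in range(fac.rank)],
                    ),
                    features=train_c.features,
                )

            tcfg = TrainConfig(**{**cfg.train.to_dict(),
                                  "seed": cfg.train.seed + 1000 * rnd + fold})
            model = _train(train_c, tcfg)
            pcfg = PredictConfig(**{**cfg.predict.to_dict(),
                                    "seed": cfg.predict.seed + 1000 * rnd + fold})
            pred = predict(model, test_c, config=pcfg)
            scores = pred.scores
            if B is not None:
                scores = bmd_recover(scores, B)

            thr = None
            if cfg.binarize_policy == "tuned":
                train_pred = predict(model, train_c, config=pcfg)
                train_scores = train_pred.scores
                train_truth = corpus.labels.matrix[train_idx]
                if B is not None:
                    train_scores = bmd_recover(train_scores, B)
                thr = tune_threshold(train_scores, train_truth)
            pred_bin = binarize(scores, cfg.binarize_policy, threshold=thr)
            report = compute_metrics(
                scores, pred_bin, corpus.labels.matrix[test_idx], threshold=thr
            )
            reports.append((rnd, fold, report))
    return CVResult(
        folds=reports,
        mean=_mean_report([r for _, _, r in reports]),
        config=cfg.to_dict(),
        fold_assignments=fold_assignments,
    )
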