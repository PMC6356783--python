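"""Versioned on-disk archives for corpora and fitted models.

Archives are single ``.npz`` containers holding the numeric arrays plus a
JSON metadata entry (schema version, catalogs, config snapshot). The schema
version is checked on load so stale archives fail loudly instead of
deserializing into garbage.
"""

from __future__ import annotations

import json

import numpy as np

from .dmr_prior import FeatureWeights
from .inference_cgs import FittedModel
from .io_corpus import Corpus, FeatureTable, GeneDocument, Vocabulary
from .label_space import LabelMatrix

SCHEMA_VERSION = 1


def _check_version(meta: dict, kind: str) -> None:
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"{kind} archive schema version {meta.get('schema_version')} "
            f"!= supported {SCHEMA_VERSION}"
        )


def save_corpus(path, corpus: Corpus) -> None:
    offsets = np.zeros(corpus.n_documents + 1, dtype=np.int64)
    for d, doc in enumerate(corpus.documents):
        offsets[d + 1] = offsets[d] + doc.n_tokens
    tokens = (
        np.concatenate([doc.tokens for doc in corpus.documents])
        if corpus.n_documents
        else np.empty(0, dtype=np.int64)
    )
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": "corpus",
        "gene_ids": [doc.gene_id for doc in corpus.documents],
        "words": corpus.vocabulary.words,
        "k_set": sorted(corpus.vocabulary.k_set),
        "label_names": corpus.labels.label_names,
        "feature_names": corpus.features.feature_names,
        "has_transform": corpus.features.transform is not None,
    }
    arrays = dict(
        tokens=tokens,
        offsets=offsets,
        label_matrix=corpus.labels.matrix,
        features=corpus.features.values,
        meta=np.array(json.dumps(meta)),
    )
    if corpus.features.transform is not None:
        arrays["transform_mean"], arrays["transform_sd"] = corpus.features.transform
    np.savez(path, **arrays)


def load_corpus(path) -> Corpus:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        _check_version(meta, "corpus")
        tokens = z["tokens"]
        offsets = z["offsets"]
        docs = [
            GeneDocument(gene_id=g, tokens=tokens[offsets[d] : offsets[d + 1]])
            for d, g in enumerate(meta["gene_ids"])
        ]
        transform = (
            (z["transform_mean"], z["transform_sd"]) if meta["has_transform"] else None
        )
        return Corpus(
            documents=docs,
            vocabulary=Vocabulary(words=meta["words"], k_set=frozenset(meta["k_set"])),
            labels=LabelMatrix(matrix=z["label_matrix"], label_names=meta["label_names"]),
            features=FeatureTable(
                values=z["features"],
                feature_names=meta["feature_names"],
                transform=transform,
            ),
        )


def save_model(path, model: FittedModel) -> None:
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": "model",
        "words": model.vocabulary.words,
        "k_set": sorted(model.vocabulary.k_set),
        "label_names": model.label_names,
        "feature_names": model.feature_names,
        "config": model.config,
        "mu": model.beta_hat.mu,
        "sigma2": model.beta_hat.sigma2,
        "converged": bool(model.converged),
        "has_transform": model.transform is not None,
        "has_pi": model.pi_hat_train is not None,
    }
    arrays = dict(
        theta_hat=model.theta_hat,
        beta_matrix=model.beta_hat.matrix,
        lam=model.lam,
        meta=np.array(json.dumps(meta)),
    )
    if model.transform is not None:
        arrays["transform_mean"], arrays["transform_sd"] = model.transform
    if model.pi_hat_train is not None:
        arrays["pi_hat_train"] = model.pi_hat_train
    np.savez(path, **arrays)


def load_model(path) -> FittedModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        _check_version(meta, "model")
        transform = (
            (z["transform_mean"], z["transform_sd"]) if meta["has_transform"] else None
        )
        return FittedModel(
            theta_hat=z["theta_hat"],
            beta_hat=FeatureWeights(
                matrix=z["beta_matrix"], mu=meta["mu"], sigma2=meta["sigma2"]
            ),
            lam=z["lam"],
            vocabulary=Vocabulary(words=meta["words"], k_set=frozenset(meta["k_set"])),
            label_names=meta["label_names"],
            feature_names=meta["feature_names"],
            transform=transform,
            config=meta["config"],
            pi_hat_train=z["pi_hat_train"] if meta["has_pi"] else None,
            converged=meta["converged"],
        )
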