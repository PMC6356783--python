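"""Corpus construction: sequences, k-mer tokenization, vocabulary, features.

A gene plays the role of a document. Its protein sequence is broken into
amino-acid-block "words" (k-mers over the 20-letter alphabet), counted into a
bag of words, and aligned row-for-row with the gene's binary function-label
vector and its numeric feature vector. The resulting :class:`Corpus` is the
single input object consumed by every inference algorithm in this package.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .label_space import LabelMatrix

logger = logging.getLogger("dmrllda")

#: the 20 standard amino-acid one-letter codes
AMINO_ACIDS = "GAVLIFPYSCMNQTDEKRHW"
_AA_SET = frozenset(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

@dataclass
class Vocabulary:
    """Ordered catalogue of amino-acid-block words.

    Word ids are dense integers in ``[0, W)`` assigned in lexicographic order,
    so the same token lists always produce the same vocabulary.
    """

    words: list[str]
    k_set: frozenset[int]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.words)) != len(self.words):
            raise ValueError("duplicate words in vocabulary")
        for w in self.words:
            if len(w) not in self.k_set:
                raise ValueError(f"word {w!r} has length outside k_set {set(self.k_set)}")
            if not set(w) <= _AA_SET:
                raise ValueError(f"word {w!r} contains non-amino-acid characters")
        self.index = {w: i for i, w in enumerate(self.words)}

    def __len__(self) -> int:
        return len(self.words)

    @property
    def size(self) -> int:
        return len(self.words)


def full_vocabulary(k_set: set[int] | frozenset[int]) -> Vocabulary:
    """All possible amino-acid blocks for the given lengths.

    The candidate word space has ``sum(20**k for k in k_set)`` entries
    (e.g. 400 for k={2}, 8400 for k={2,3}).
    """
    k_set = frozenset(int(k) for k in k_set)
    if not k_set or min(k_set) < 1:
        raise ValueError("k_set must contain positive integers")
    words: list[str] = []
    for k in sorted(k_set):
        words.extend("".join(p) for p in itertools.product(sorted(AMINO_ACIDS), repeat=k))
    words.sort()
    return Vocabulary(words=words, k_set=k_set)


# ---------------------------------------------------------------------------
# FASTA reading and tokenization
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{gene_id: sequence}`` mapping.

    Sequences are uppercased and multi-line records concatenated. Non-standard
    residues are kept here; the tokenizer skips windows containing them.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        logger.warning("read_fasta: no records found in %s", path)
    return sequences


def tokenize_sequence(
    seq: str, k_set: set[int] | frozenset[int], stride: int = 1
) -> tuple[list[str], int]:
    """Cut a protein sequence into amino-acid-block words.

    For each block length ``k`` the windows start at 0, stride, 2*stride, ...
    and only full-length windows are emitted. Windows containing characters
    outside the 20-letter alphabet (X, B, Z, U, ``*`` ...) are skipped and
    counted, never fatal.

    Returns ``(tokens, n_skipped)``.
    """
    if not k_set:
        raise ValueError("k_set must be non-empty")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    seq = seq.upper()
    tokens: list[str] = []
    skipped = 0
    for k in sorted(int(k) for k in k_set):
        for start in range(0, len(seq) - k + 1, stride):
            window = seq[start : start + k]
            if set(window) <= _AA_SET:
                tokens.append(window)
            else:
                skipped += 1
    return tokens, skipped


def build_vocabulary(
    token_lists: list[list[str]],
    k_set: set[int] | frozenset[int],
    max_doc_freq: float | None = None,
) -> Vocabulary:
    """Vocabulary of observed words, optionally dropping ubiquitous ones.

    ``max_doc_freq`` is a fraction of documents: words appearing in a larger
    fraction are filtered out (high-frequency word removal). ``None`` disables
    the filter. Ordering is lexicographic, hence deterministic.
    """
    n_docs = len(token_lists)
    doc_freq: Counter[str] = Counter()
    for toks in token_lists:
        doc_freq.update(set(toks))
    if max_doc_freq is None:
        kept = sorted(doc_freq)
    else:
        limit = max_doc_freq * n_docs
        kept = sorted(w for w, c in doc_freq.items() if c <= limit)
    return Vocabulary(words=kept, k_set=frozenset(int(k) for k in k_set))


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """D x F numeric gene features with an optional z-score transform.

    The transform is fit on training genes and re-applied unchanged to test
    genes, so a prediction-time gene is scaled exactly as the model saw its
    training data. Constant columns get sd treated as 1.
    """

    values: np.ndarray  # (D, F) float
    feature_names: list[str]
    transform: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def standardize_features(table: FeatureTable, fit: bool = True) -> FeatureTable:
    """Z-score the feature columns.

    With ``fit=True`` the per-column (mean, sd) is estimated from the table and
    stored; with ``fit=False`` the table's stored transform is applied (the
    prediction path). Raw feature scales span orders of magnitude (molecular
    weight ~5e4 vs hydrophilicity ~0.1) and would overflow exp(y·beta) without
    this.
    """
    if fit:
        mean = table.values.mean(axis=0)
        sd = table.values.std(axis=0, ddof=0)
        sd = np.where(sd == 0.0, 1.0, sd)
    else:
        if table.transform is None:
            raise ValueError("no stored transform to apply (fit the training table first)")
        mean, sd = table.transform
        if len(mean) != table.n_features:
            raise ValueError("stored transform dimension mismatch")
    return FeatureTable(
        values=(table.values - mean) / sd,
        feature_names=list(table.feature_names),
        transform=(np.asarray(mean, dtype=float), np.asarray(sd, dtype=float)),
    )


def apply_transform(values: np.ndarray, transform: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    mean, sd = transform
    return (np.asarray(values, dtype=float) - mean) / sd


def inverse_transform(values: np.ndarray, transform: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    mean, sd = transform
    return np.asarray(values, dtype=float) * sd + mean


def load_feature_table(path) -> tuple[list[str], FeatureTable]:
    """Read a TSV with header ``gene_id <feature> <feature> ...``.

    Returns the gene-id column and the numeric table. Any number of feature
    columns is accepted.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 1:
        raise ValueError("feature table must have a gene_id column")
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("feature table contains missing values")
    return gene_ids, FeatureTable(values=values, feature_names=list(df.columns[1:]))


# ---------------------------------------------------------------------------
# documents and corpus
# ---------------------------------------------------------------------------

@dataclass
class GeneDocument:
    """One gene's bag of words: token ids and their counts."""

    gene_id: str
    tokens: np.ndarray  # (Nd,) int word ids in order of occurrence
    counts: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        self.counts = dict(Counter(self.tokens.tolist()))

    @property
    def n_tokens(self) -> int:
        return int(self.tokens.size)


@dataclass
class Corpus:
    """Row-aligned documents, labels and features over one gene universe."""

    documents: list[GeneDocument]
    vocabulary: Vocabulary
    labels: LabelMatrix
    features: FeatureTable

    def __post_init__(self) -> None:
        d = len(self.documents)
        if self.labels.matrix.shape[0] != d or self.features.values.shape[0] != d:
            raise ValueError("labels/features not row-aligned with documents")

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)

    @property
    def n_labels(self) -> int:
        return self.labels.matrix.shape[1]

    def count_matrix(self) -> np.ndarray:
        """Dense D x W bag-of-words count matrix."""
        mat = np.zeros((self.n_documents, self.n_words), dtype=np.int64)
        for d, doc in enumerate(self.documents):
            for w, c in doc.counts.items():
                mat[d, w] = c
        return mat


def build_corpus(
    sequences: dict[str, str],
    vocabulary: Vocabulary,
    label_matrix: LabelMatrix,
    label_gene_ids: list[str],
    feature_gene_ids: list[str],
    feature_table: FeatureTable,
    k_set: set[int] | frozenset[int],
    stride: int = 1,
) -> Corpus:
    """Assemble a row-aligned corpus from the three input components.

    Genes missing a sequence, a label row, or a feature row are dropped with a
    logged report; out-of-vocabulary tokens are dropped and counted.
    """
    label_pos = {g: i for i, g in enumerate(label_gene_ids)}
    feat_pos = {g: i for i, g in enumerate(feature_gene_ids)}
    shared = [g for g in sequences if g in label_pos and g in feat_pos]
    if not shared:
        raise ValueError("no gene ids shared between sequences, labels and features")
    dropped = (set(sequences) | set(label_pos) | set(feat_pos)) - set(shared)
    if dropped:
        logger.info("build_corpus: dropped %d genes missing a component", len(dropped))

    docs: list[GeneDocument] = []
    oov = 0
    for g in shared:
        tokens, _ = tokenize_sequence(sequences[g], k_set, stride)
        ids = [vocabulary.index[t] for t in tokens if t in vocabulary.index]
        oov += len(tokens) - len(ids)
        docs.append(GeneDocument(gene_id=g, tokens=np.asarray(ids, dtype=np.int64)))
    if oov:
        logger.info("build_corpus: dropped %d out-of-vocabulary tokens", oov)

    lab_rows = [label_pos[g] for g in shared]
    feat_rows = [feat_pos[g] for g in shared]
    labels = LabelMatrix(
        matrix=label_matrix.matrix[lab_rows, :], label_names=list(label_matrix.label_names)
    )
    features = FeatureTable(
        values=feature_table.values[feat_rows, :],
        feature_names=list(feature_table.feature_names),
        transform=feature_table.transform,
    )
    return Corpus(documents=docs, vocabulary=vocabulary, labels=labels, features=features)
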