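"""Binary gene-label matrices and Boolean matrix decomposition (BMD).

Gene function datasets can carry thousands of GO-term labels. BMD factorizes
the binary label matrix Y (D x L) into a Boolean product C ∘ B with C
(D x L') and B (L' x L), L' <= L, so a model can be trained on the compressed
label space C and its predictions restored to the full space through B.

The factorization is a greedy formal-concept cover: each factor is an all-ones
rectangle (a set of genes sharing a set of labels), rectangles never cover a
zero, and greedily chosen rectangles cover every one-cell — so the greedy
result is always exact (possibly at a rank above the optimum). Rank-minimal
factorizations of tiny instances are recovered by the exhaustive oracle in the
test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("dmrllda")


@dataclass
class LabelMatrix:
    """D x L binary annotation matrix with label names."""

    matrix: np.ndarray
    label_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("label matrix must be 2-D")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("label matrix entries must be 0/1")
        if self.matrix.shape[1] != len(self.label_names):
            raise ValueError("label_names length mismatch")

    @property
    def n_labels(self) -> int:
        return self.matrix.shape[1]


def load_annotations(path, gene_universe: list[str]) -> LabelMatrix:
    """Read two-column (gene_id, label_id) pairs into a LabelMatrix.

    Rows follow ``gene_universe`` order; labels are sorted; duplicate pairs
    collapse to a single 1; pairs naming genes outside the universe are
    dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "label_id"], dtype=str)
    known = set(gene_universe)
    unknown = (~df["gene_id"].isin(known)).sum()
    if unknown:
        logger.info("load_annotations: dropped %d pairs with unknown gene ids", int(unknown))
    df = df[df["gene_id"].isin(known)]
    labels = sorted(df["label_id"].unique())
    lab_idx = {l: j for j, l in enumerate(labels)}
    gene_idx = {g: i for i, g in enumerate(gene_universe)}
    mat = np.zeros((len(gene_universe), len(labels)), dtype=np.int8)
    for g, l in zip(df["gene_id"], df["label_id"]):
        mat[gene_idx[g], lab_idx[l]] = 1
    return LabelMatrix(matrix=mat, label_names=labels)


# ---------------------------------------------------------------------------
# Boolean matrix decomposition
# ---------------------------------------------------------------------------

@dataclass
class BMDFactorization:
    """Boolean factorization Y ≈ C ∘ B.

    ``exact`` is True when the Boolean product reproduces Y cell-for-cell;
    otherwise ``residual`` counts the uncovered one-cells.
    """

    C: np.ndarray  # (D, rank) binary
    B: np.ndarray  # (rank, L) binary
    rank: int
    residual: int = 0

    @property
    def exact(self) -> bool:
        return self.residual == 0


def boolean_product(C: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Boolean matrix product: (C ∘ B)[d, l] = OR_k C[d,k] AND B[k,l]."""
    return (np.asarray(C, dtype=bool) @ np.asarray(B, dtype=bool)).astype(np.int8)


def _closure(Y: np.ndarray, attrs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Formal-concept closure: rows having all ``attrs``, then their common attrs."""
    rows = Y[:, attrs].all(axis=1).nonzero()[0]
    if rows.size == 0:
        return rows, attrs
    closed = Y[rows, :].all(axis=0).nonzero()[0]
    return rows, closed


def _enumerate_concepts(mat: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """All formal concepts (maximal all-ones rectangles) with nonempty extent.

    Intents are attribute-set closures of single rows' intents intersections;
    enumerating closures of all intents of row subsets is equivalent to
    enumerating closures of all attribute subsets, done here bottom-up from
    row intents (tractable for the small matrices this is used on).
    """
    D, L = mat.shape
    intents: set[frozenset[int]] = {frozenset(np.nonzero(mat[d])[0]) for d in range(D)}
    intents.discard(frozenset())
    # close under pairwise intersection
    frontier = list(intents)
    while frontier:
        new: list[frozenset[int]] = []
        for a in frontier:
            for b in list(intents):
                c = a & b
                if c and c not in intents:
                    intents.add(c)
                    new.append(c)
        frontier = new
    concepts = []
    for intent in sorted(intents, key=sorted):
        attrs = np.fromiter(sorted(intent), dtype=np.int64)
        rows = mat[:, attrs].all(axis=1).nonzero()[0]
        closed = mat[rows, :].all(axis=0).nonzero()[0]
        if set(closed) == intent:  # keep only closed intents (true concepts)
            concepts.append((rows, closed))
    return concepts


def _min_concept_cover(
    mat: np.ndarray, upper_bound: int
) -> list[tuple[np.ndarray, np.ndarray]] | None:
    """Branch-and-bound minimal cover of the one-cells by formal concepts.

    Returns a cover strictly smaller than ``upper_bound``, or None. Only used
    on small matrices; deterministic by construction.
    """
    concepts = _enumerate_concepts(mat)
    cell_sets = [
        frozenset((int(r), int(c)) for r in rows for c in attrs)
        for rows, attrs in concepts
    ]
    ones = frozenset((int(r), int(c)) for r, c in zip(*np.nonzero(mat)))
    best: list[int] | None = None
    best_k = upper_bound

    def search(uncovered: frozenset, chosen: list[int]) -> None:
        nonlocal best, best_k
        if not uncovered:
            best, best_k = list(chosen), len(chosen)
            return
        if len(chosen) + 1 >= best_k:
            return
        # branch on the uncovered cell with fewest covering concepts
        cell = min(uncovered, key=lambda c: (sum(c in s for s in cell_sets), c))
        cands = [i for i, s in enumerate(cell_sets) if cell in s]
        cands.sort(key=lambda i: (-len(cell_sets[i] & uncovered), i))
        for i in cands:
            chosen.append(i)
            search(uncovered - cell_sets[i], chosen)
            chosen.pop()

    search(ones, [])
    if best is None:
        return None
    return [concepts[i] for i in best]


#: size limit below which the exact minimal-rank search is attempted
_EXACT_BMD_CELLS = 400


def bmd_decompose(Y: LabelMatrix | np.ndarray, max_rank: int | None = None) -> BMDFactorization:
    """Exact Boolean factorization of smallest found rank.

    Factors (formal concepts) are grown one attribute at a time, always adding
    the attribute whose closed rectangle covers the most still-uncovered
    one-cells (ties broken by lowest attribute index, so the result is
    deterministic). On small matrices the greedy cover is then refined by an
    exact branch-and-bound search for the minimal concept cover. The loop
    stops when every one-cell is covered or ``max_rank`` factors have been
    emitted; in the latter case the factorization is approximate and
    ``residual`` counts what is left.
    """
    mat = Y.matrix if isinstance(Y, LabelMatrix) else np.asarray(Y)
    mat = (mat != 0).astype(np.int8)
    if max_rank is not None and max_rank < 1:
        raise ValueError("max_rank must be >= 1")
    D, L = mat.shape
    uncovered = mat.astype(bool).copy()
    C_cols: list[np.ndarray] = []
    B_rows: list[np.ndarray] = []
    while uncovered.any():
        if max_rank is not None and len(C_cols) >= max_rank:
            break
        attrs = np.empty(0, dtype=np.int64)
        best_rows = np.empty(0, dtype=np.int64)
        best_val = 0
        while True:
            cand_best = None
            for j in range(L):
                if j in attrs:
                    continue
                rows, closed = _closure(mat, np.append(attrs, j).astype(np.int64))
                if rows.size == 0:
                    continue
                val = int(uncovered[np.ix_(rows, closed)].sum())
                if cand_best is None or val > cand_best[0]:
                    cand_best = (val, rows, closed)
            if cand_best is None or cand_best[0] <= best_val:
                break
            best_val, best_rows, attrs = cand_best
        if best_val == 0:  # nothing coverable (cannot happen for consistent input)
            break
        c = np.zeros(D, dtype=np.int8)
        c[best_rows] = 1
        b = np.zeros(L, dtype=np.int8)
        b[attrs] = 1
        C_cols.append(c)
        B_rows.append(b)
        uncovered[np.ix_(best_rows, attrs)] = False
    residual = int(uncovered.sum())
    if residual == 0 and len(C_cols) > 1 and D * L <= _EXACT_BMD_CELLS:
        better = _min_concept_cover(mat, upper_bound=len(C_cols))
        if better is not None and (max_rank is None or len(better) <= max_rank):
            C_cols, B_rows = [], []
            for rows, attrs in better:
                c = np.zeros(D, dtype=np.int8)
                c[rows] = 1
                b = np.zeros(L, dtype=np.int8)
                b[attrs] = 1
                C_cols.append(c)
                B_rows.append(b)
    rank = len(C_cols)
    C = np.stack(C_cols, axis=1) if rank else np.zeros((D, 0), dtype=np.int8)
    B = np.stack(B_rows, axis=0) if rank else np.zeros((0, L), dtype=np.int8)
    return BMDFactorization(C=C, B=B, rank=rank, residual=residual)


def bmd_recover(C_pred: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Restore compressed predictions to the full label space via B.

    Binary input -> Boolean product. Real-valued scores -> max-product
    (score of label l = max over factors k of C_pred[d,k] * B[k,l]), which
    preserves score rankings through the recovery.
    """
    C_pred = np.asarray(C_pred)
    B = np.asarray(B)
    if C_pred.ndim != 2 or C_pred.shape[1] != B.shape[0]:
        raise ValueError(
            f"shape mismatch: C_pred has {C_pred.shape[1] if C_pred.ndim == 2 else '?'} "
            f"columns, B has {B.shape[0]} rows"
        )
    if np.isin(C_pred, (0, 1)).all():
        return boolean_product(C_pred, B)
    # max-product over factors: (D, K, 1) * (K, L) -> max over K
    return np.max(C_pred[:, :, None] * B[None, :, :], axis=1)
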