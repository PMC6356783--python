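"""Numba inner loops for the collapsed Gibbs sampler.

The token-level resampling loop is sequential by nature (each draw updates the
count tables the next draw reads), so it is compiled rather than vectorized.
All randomness inside the kernel comes from numba's own legacy global RNG,
seeded per sweep from the caller's Generator to keep runs reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def seed_kernel(seed: int) -> None:
    np.random.seed(seed)


@njit(cache=False)
def foldin_sweep_kernel(
    token_doc,
    token_word,
    z,
    label_offsets,
    label_ids,
    N_dt,            # (D, T) float64, in place
    alpha,           # (D, T)
    theta,           # (T, W) fixed topic-word distributions
    probs,
) -> None:
    """Fold-in sweep with the topic-word distributions held fixed.

    p(t) ∝ (alpha_dt + N_dt^{\\dn}) * theta_tw over the candidate labels.
    """
    n_tokens = token_doc.size
    for i in range(n_tokens):
        d = token_doc[i]
        w = token_word[i]
        t_old = z[i]
        N_dt[d, t_old] -= 1.0
        lo = label_offsets[d]
        hi = label_offsets[d + 1]
        total = 0.0
        for j in range(lo, hi):
            t = label_ids[j]
            p = (alpha[d, t] + N_dt[d, t]) * theta[t, w]
            probs[j - lo] = p
            total += p
        u = np.random.random() * total
        t_new = label_ids[hi - 1]
        acc = 0.0
        for j in range(lo, hi):
            acc += probs[j - lo]
            if u < acc:
                t_new = label_ids[j]
                break
        z[i] = t_new
        N_dt[d, t_new] += 1.0


@njit(cache=False)
def gibbs_sweep_kernel(
    token_doc,      # (N,) int64 document index per token
    token_word,     # (N,) int64 word id per token
    z,              # (N,) int64 current topic per token (updated in place)
    label_offsets,  # (D+1,) int64 CSR offsets into label_ids
    label_ids,      # (sum Td,) int64 active topic ids per doc
    N_dt,           # (D, T) float64 doc-topic counts (in place)
    N_tw,           # (T, W) float64 topic-word counts (in place)
    N_t,            # (T,) float64 topic totals (in place)
    alpha,          # (D, T) float64 prior
    lam,            # (W,) float64 word smoothing
    lam_sum,        # float64
    probs,          # (max active,) float64 scratch
) -> None:
    """One full sweep: every token resampled once from its full conditional.

    p(t) ∝ (alpha_dt + N_dt^{\\dn}) * (lam_w + N_tw^{\\dn}) / (lam_sum + N_t^{\\dn})
    restricted to the document's active labels.
    """
    n_tokens = token_doc.size
    for i in range(n_tokens):
        d = token_doc[i]
        w = token_word[i]
        t_old = z[i]
        N_dt[d, t_old] -= 1.0
        N_tw[t_old, w] -= 1.0
        N_t[t_old] -= 1.0
        lo = label_offsets[d]
        hi = label_offsets[d + 1]
        total = 0.0
        for j in range(lo, hi):
            t = label_ids[j]
            p = (alpha[d, t] + N_dt[d, t]) * (lam[w] + N_tw[t, w]) / (lam_sum + N_t[t])
            probs[j - lo] = p
            total += p
        u = np.random.random() * total
        t_new = label_ids[hi - 1]
        acc = 0.0
        for j in range(lo, hi):
            acc += probs[j - lo]
            if u < acc:
                t_new = label_ids[j]
                break
        z[i] = t_new
        N_dt[d, t_new] += 1.0
        N_tw[t_new, w] += 1.0
        N_t[t_new] += 1.0
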