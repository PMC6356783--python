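# Methods

## Model

Each gene `d` is a document: a bag of `N_d` amino-acid-block words over a
vocabulary of size `W` built from its protein sequence. Each function label
(GO term) is a topic; labels and topics correspond one-to-one, so `T = L`.
A gene's observed annotations give a binary vector `Λ_d`, and its topics are
restricted to the annotated set. Each gene additionally carries a numeric
feature vector `y_d` (molecular weight, isoelectric point, hydrophilicity,
codon adaptation, …).

Generative process:

- per topic: word distribution `θ_t ~ Dirichlet(λ)` and feature weights
  `β̂_t ~ Normal(μ, σ² I)` over `F + 1` coordinates (the last is a default
  column multiplying a constant feature 1 — it acts as an intercept and
  absorbs any per-gene scale, so no separate scale parameter exists);
- per gene: prior `α_dt = exp(ŷ_d · β̂_t)` masked by `Λ_d`; topic weights
  `π_d ~ Dirichlet(α_d ∘ Λ_d)`; per token a topic `t_dn ~ Cat(π_d)` and a
  word `w_dn ~ Cat(θ_{t_dn})`.

The only difference from plain labeled LDA is that `α` is a log-linear
function of the gene's features rather than a shared constant; with all real
feature weights zero the model reduces exactly to label-masked LLDA with a
learned per-topic scalar prior.

## Inference

**Collapsed Gibbs (CGS).** With `π` and `θ` integrated out, a token's full
conditional restricted to the gene's active labels is

```
p(t_dn = t) ∝ (α_dt + N_dt^{\dn}) Λ_dt (λ_w + N_tw^{\dn}) / (Σ_w λ_w + N_t^{\dn}).
```

Assignments are initialized uniformly over each gene's active labels. The
token loop is numba-compiled (it is inherently sequential); all randomness
flows through one seeded generator, with the kernel's RNG reseeded from it
each sweep, so runs are bit-reproducible. Point estimates average count
tables over recorded states:

```
π̂_dt ∝ α_dt Λ_dt + E[N_dt],     θ̂_tw ∝ λ_w + E[N_tw].
```

**Feature-weight optimization.** The β̂-dependent part of the collapsed
log-likelihood is a Gaussian prior term plus per-gene Dirichlet-multinomial
evidence. Its stationarity condition has the fixed-point form

```
β_tf = μ + σ² Σ_d y_df α_dt Λ_dt [ψ(S_d) − ψ(S_d + N_d) + ψ(α_dt + N_dt) − ψ(α_dt)]
```

with `S_d = Σ_t α_dt Λ_dt`. The raw iteration is not a contraction on
realistic counts (it oscillates), but the proposal offset equals `σ²` times
the objective gradient, so the damped step `β + ρ(proposal − β)` is a
gradient-ascent step. The optimizer takes that step under an Armijo
sufficient-increase test with backtracking (halving ρ) and step regrowth
after clean acceptances; the objective trace is monotone by construction and
the iteration stops when the gradient infinity-norm falls below tolerance
(default 1e-6). Inside a Gibbs chain, β̂ is re-optimized every 20 sweeps
starting after sweep 100 (warm-started, so each call is cheap); the chain
schedule itself does not pin down when β̂ should be updated, and this
interval balances prior adaptation against sampler mixing. `log α` is
clipped at ±30 to guard the digamma terms against un-standardized features.

**Collapsed variational Bayes (CVB / CVB0).** Responsibilities `η_dwt` are
kept per (gene, word type, active label). The collapsed count statistics are
replaced by moments with an `(N_dw − 1)` self-exclusion weight shared across
a gene's word types:

```
γ_dt = Σ_w (N_dw − 1) η_dwt,   μ_tw = Σ_d (N_dw − 1) η_dwt,   μ_t = Σ_{d,w} (N_dw − 1) η_dwt.
```

CVB0 updates `η_dwt ∝ (α_dt Λ_dt + γ_dt)(λ_w + μ_tw)/(Σλ + μ_t)`. CVB
additionally carries variance accumulators and applies the second-order
correction `E[log(a + N)] ≈ log(a + μ) − var/(2(a + μ)²)` to each log term;
the topic-total term divides, so its correction enters with opposite sign.
The per-term variances use the Bernoulli-style form `m η (1 − m η)` (with
`m = N_dw − 1`), clipped at zero; the zero-variance limit reproduces CVB0
exactly and is tested.

Schedule: per global iteration every gene restarts from uniform
responsibilities and iterates its local fixed point against the previous
iteration's global statistics until `(1/N_d) Σ_t |Δγ_dt| < 1e-5` or 100
passes; global statistics are then rebuilt from per-gene deltas
(incremental, audited against scratch recomputation at 1e-9) and β̂ is
re-optimized on the full expected counts. The global statistics are
initialized as `μ_tw = λ_w + s λ_w / 10` with `s ~ U(0,1)` per entry, used
in the first iteration only. Point estimates use full expected counts
`Σ_w N_dw η_dwt`: the exclusion-weighted statistics vanish identically for
singleton words and cannot serve as expected counts.

**Prediction (fold-in).** Global parameters `θ̂, β̂` stay fixed. A test
gene's prior comes from its own features through `β̂` (after the training
standardization transform); its label support defaults to all labels, since
an unannotated gene must be scored on every candidate function, with an
optional candidate mask. Fold-in runs either a Gibbs chain with
`p(t) ∝ (α_dt + N_dt^{\dn}) θ̂_{t,w}` (default 1000 sweeps, 500 burn-in,
recorded every 50) or the CVB0 local fixed point against `θ̂`.

## Label-space compression

The Boolean factorization `Y = C ∘ B` is computed as a cover of the one
cells of `Y` by formal concepts (maximal all-ones rectangles): greedily by
largest new coverage with deterministic tie-breaks, then — on matrices up to
400 cells — refined by an exact branch-and-bound search for the minimal
concept cover. Any concept cover is exact by construction; `max_rank`
truncates the greedy cover and reports the uncovered residual. Binary
predictions are recovered through the Boolean product; real-valued scores
through the max-product `max_k C[d,k]·B[k,l]`, which preserves rankings.
Compression is off by default — the model is fully functional on the raw
label space.

## Evaluation

Hamming loss and micro-/macro-F1 are computed from hard predictions (the
default binarization turns a label on iff its score ≥ 1/L; a tuned global
threshold maximizing micro-F1 on training-fold predictions is also
available — with topic weights summing to one across L labels, 1/L is the
natural exceedance point, but nothing in the model fixes an operating
point). Ranking metrics use raw scores: average precision is the mean over
genes of precision at the ranks of their true labels; one-error is the rate
of a false top label; the precision-recall areas come in macro (mean over
labels with at least one positive), pooled (all gene-label pairs together)
and label-frequency-weighted forms, each computed with the step-wise
(non-interpolated) estimator, ties broken by stable label index. Genes with
no true label are excluded from ranking metrics with a count.
Cross-validation is an unstratified random 5-fold partition repeated in 5
independent rounds, features re-standardized per training fold, all seeded.

## Synthetic data and what the tests show

The simulator samples the generative process exactly, so every inference
path can be checked against ground truth with anchored (no-permutation)
comparisons. The default scenario — `T=5, W=30, F=2, D=200, N_d=100`,
`μ=0, σ²=1, λ_w=200/W`, label sets of size 1 + Binomial(2, 0.5), standard
normal features — is small enough for minutes-scale runs yet exercises the
feature-conditioned prior.

Two label regimes matter. With label sets drawn independently of features,
features shape only the proportions *within* a gene's annotated set; at
prediction time (all labels candidates) they then carry no information about
which labels are active, and the feature prior cannot help ranking. The
feature-benefit experiment therefore uses the feature-coupled scenario:
label presence is logistic in `y · β_true`, emulating real data where
features such as molecular weight correlate with function. Under that regime
the full model beats its feature-frozen reduction on held-out average
precision for every tested seed.

The simulator does not attempt realistic protein sequences, GO-hierarchy
structure among labels, or heavy-tailed word distributions; passing recovery
tests demonstrates correctness of the inference machinery, not performance
on real annotation corpora.

## Numerical choices and problem sizes

- `λ_w = 200/W` symmetric; initial `α = 50/T` through the default weight
  column; `μ = 0, σ² = 1`.
- Default chain schedule: 2000 sweeps, 1000 burn-in, record every 50 sweeps
  for 20 snapshots (training); 1000/500/50 for prediction. Variational:
  up to 1000 global iterations, local tolerance 1e-5, local cap 100.
- Tests and the acceptance script run the same algorithms on shortened
  schedules chosen for single-CPU runs (CGS 600-800 sweeps with denser
  thinning, CVB0 60 global iterations, fold-in 400-1000 sweeps); recovery
  margins are wide at these lengths (θ̂ mean L1 ≈ 0.08-0.10 against a 0.15
  bound).
- Categorical draws use inverse-CDF on the normalized conditional; ties have
  probability zero. Degenerate inputs fail loudly: genes with no active
  label, zero conditional mass, non-finite α, shape mismatches.
- Constant feature columns standardize to zero (sd treated as 1); the
  transform is stored in the model and re-applied to test genes.

## Limitations

- CVB follows the printed moment forms of its source recipe; their variance
  expressions are heuristic (clipped at zero when `m η > 1`) and CVB is the
  least-validated path — CVB0 and CGS are the recommended ones.
- The exact BMD refinement is exponential in the worst case and is capped at
  small matrices; beyond that the greedy rank may exceed the optimum.
- One chain only; no convergence diagnostics beyond the recorded schedule
  and the variational drift criterion.
- GO-ontology structure (ancestor propagation, hierarchy-aware metrics) is
  out of scope.
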