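# Methods

## Generative model

The package models two coupled binary observations over the same `N`
proteins. A symmetric PPI adjacency matrix `A` and an `N×C` annotation
profile `F` are both explained by `K` latent complexes through nonnegative
factors `Θ` (protein–complex affinity, N×K) and `Ψ` (complex–function
preference, K×C):

```
θ_ik ~ Exponential(λ)          ψ_kc ~ Exponential(λ)
A_ij | Θ    ~ Bernoulli( σ(Σ_k θ_ik θ_jk) )     for i < j
F_ic | Θ, Ψ ~ Bernoulli( σ(Σ_k θ_ik ψ_kc) )     when S_i = 1
```

with `σ(x) = 1 − exp(−x)` mapping the nonnegative "total affinity" onto a
valid probability. The link makes edge probability increase with every
shared complex — the same mechanism by which link-community models produce
overlapping groups. `S_i` flags whether protein *i* has an observed
annotation profile; `S_i = 0` rows contribute only topological evidence, so
functionally uncharacterized proteins are handled without special casing,
and setting all `S_i = 0` gives a pure topology-based mode.

Assumptions worth keeping in mind: edges and annotations are conditionally
independent given the factors; the network is unweighted, undirected and
simple (weighted networks must be binarized first); annotation terms are
treated as flat labels (no GO-hierarchy semantics).

## Objective and optimization

Maximizing the joint posterior is equivalent to minimizing a six-term
penalized negative log-likelihood: log-loss of the observed and absent
edges (pair sums over `i ≠ j` only, matching the generative definition for
`i < j`; the diagonal is excluded), log-loss of the observed and absent
annotations masked by `S_i`, and `λ·(ΣΘ + ΣΨ)` from the exponential priors.

The nonnegatively constrained problem is solved by multiplicative updates:
each entry is rescaled by the ratio of the negative to the positive part of
its partial derivative,

```
θ_ik ← θ_ik · [ S_i Σ_c F_ic ψ_kc/σ(Σθψ) + Σ_j A_ij θ_jk/σ(Σθθ) ]
              / [ S_i Σ_c ψ_kc + Σ_{j≠i} θ_jk + λ ]
ψ_kc ← ψ_kc · [ Σ_i S_i F_ic θ_ik/σ(Σθψ) ] / [ Σ_i S_i θ_ik + λ ]
```

One iteration performs a full Θ update with the current Ψ, then a full Ψ
update with the new Θ (the equations' order; the scheme is alternating and
no other order is implied by the derivation). Updates preserve zeros
exactly, so a complex whose Θ column dies is pruned permanently — this is
what lets the sparsity prior select the effective number of complexes when
`K` is set generously (default 1000, λ = 4).

The objective is evaluated once per iteration after both updates; iteration
stops when the relative change against the previous value drops below
`tol = 1e-6` or after `max_iter = 400` iterations. The objective is not
convex, so the fit is restarted `n_restarts = 100` times (defaults; tests
and examples use fewer) from i.i.d. Uniform(0,1) initializations — strictly
positive so no complex is dead at the start, and scale-free with respect to
the multiplicative dynamics. Restart *r* uses seed `seed + r`, making every
restart independently reproducible. The restart with the lowest final
objective is returned; restarts ending at an infinite objective are never
selected.

### Numerical choices

- Every occurrence of `1 − exp(−x)` inside a logarithm or an update
  denominator is floored at `ε = 1e-10` (implementation constant, not a
  model parameter). `expm1` is used throughout for accuracy at small `x`.
- An observed edge or annotation with a zero linear predictor makes the
  objective `+inf` (a true zero-probability configuration); such states are
  reported as the sentinel and never win the restart selection.
- The expensive sums are evaluated only at observed edges and annotations
  via sparse matrices, so one iteration costs `O(K(N + C + E + R))` with
  `E` edges and `R` associations; a wall-clock test checks this scaling
  coarsely.

## Complex detection

Rows of the estimated `Θ̂` are normalized to sum to one (rows entirely below
`1e-16` are zeroed first — the protein is assigned to no complex), then
thresholded at `τ = 0.2` inclusively (`θ̂_ik ≥ τ`). Because rows sum to one,
a protein can pass the threshold in at most `⌊1/τ⌋ = 5` complexes; τ is kept
a free parameter with that default. Each candidate complex is split into the
connected components it induces in the network (a locally optimal column may
bundle disconnected groups), components with fewer than `min_size = 3`
proteins are discarded, and identical protein sets arising from different
columns are de-duplicated (first occurrence kept) so duplicate predictions
cannot inflate counts or double-match during evaluation. Proteins with
all-zero normalized rows are reported in a diagnostic `unassigned` list.

## Evaluation

With overlap score `ω(a,b) = |a∩b|²/(|a|·|b|)`:

- **FRAC**: fraction of reference complexes with some prediction at
  `ω > 0.25` (strict inequality; the threshold is a parameter).
- **MMR**: maximum-weight bipartite matching (weights ω) between references
  and predictions, divided by the number of references; solved with the
  Hungarian algorithm and cross-checked in tests against exhaustive
  enumeration.
- **ACC**: `√(Sn · PPV)` from the reference×prediction overlap table, with
  `Sn = Σ_r max_j T_rj / Σ_r |ref_r|` and
  `PPV = Σ_j max_r T_rj / Σ_rj T_rj`; defined as 0 for empty predictions.
- **PR**: geometric mean of match precision (fraction of predictions
  matching some reference at `ω > 0.25`) and FRAC. The exact composite used
  in the complex-detection literature is not recoverable from public
  sources, so this form is a documented stand-in and is labelled
  `PR(composite)` in output.

Functional homogeneity: for each predicted complex, the hypergeometric
upper tail `P(X ≥ k)` of its annotated members carrying each term, with the
population being the annotated proteins of the analyzed network; the
minimum over terms is kept and binned at `<1e-15`, `[1e-15,1e-10)`,
`[1e-10,1e-5)`, `[1e-5,1]`. Raw P-values are binned by default (a Bonferroni
flag is available); complexes with no annotated member are excluded from
the bins and counted separately.

## Synthetic data

The simulator samples `(A, F)` from exactly the generative process above,
in two modes. *Prior* mode draws Θ and Ψ from Exponential(λ). *Planted* mode
takes user-supplied factors; `planted_complex_scenario` builds the standard
recovery benchmark: each planted complex is one Θ column with affinity
`within_strength` (default 2.0) for its members, giving within-block edge
probability `σ(4) ≈ 0.98` — comfortably identifiable; background proteins
get uniform affinities below 0.05 in every column, keeping background
density under 0.05; each complex prefers two private functional terms; an
`overlap` parameter makes consecutive complexes share proteins, creating
genuinely multi-group ground truth. Parameter sampling uses
`default_rng(seed)` and data sampling `default_rng(seed + 1)`, so both
stages replay independently and all outputs are bit-for-bit reproducible.

What the simulator does *not* emulate: the heavy-tailed degree
distributions, assay-specific false-negative structure and annotation
incompleteness biases of real PPI data. Passing recovery tests therefore
demonstrates correctness of the estimator on data matching the model's own
assumptions, not performance on any real interactome.

## Problem sizes used in tests

The test suite and acceptance script run at desk scale: recovery experiments
use 60–75 proteins, 2–4 planted complexes, `K = 10–20` and 5–10 restarts;
the λ sweep uses a 50-protein prior-mode instance at `K = 15` with 2
restarts; metric oracles enumerate instances up to 6×6 complexes and
populations up to 25. These sizes make every check exhaustive or
statistically well-powered while keeping the whole suite in a few seconds.

## Known limitations

- Unweighted networks only; weights in input files are ignored with a
  logged notice.
- No GO-hierarchy exploitation; terms are independent labels.
- Multiplicative updates converge to local optima; restart count trades
  time for solution quality.
- The PR score is a composite stand-in (see above).
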