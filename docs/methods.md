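# Methods

## Model and assumptions

The package scores unobserved miRNA–disease pairs by low-rank nonnegative
factorization of the (imputed) association matrix, under three modeling
assumptions:

* **Low-rank structure.** True associations are driven by a small number of
  latent biological factors, so Y ≈ W Hᵀ with k ≪ min(n, m); the
  nonnegativity of W and H gives a parts-based, additive decomposition.
* **Similarity smoothness.** Functionally similar miRNAs (and semantically
  similar diseases) should have nearby latent representations. This enters
  as graph-Laplacian penalties Tr(Wᵀ L_m W) and Tr(Hᵀ L_d H) on the
  integrated similarity graphs.
* **Row sparsity of H.** The L2,1 penalty on H shrinks entire disease rows,
  suppressing diseases whose latent profile is not supported by the data
  and making the disease factor matrix sparse at the row level.

The observed zeros of Y are treated as unlabeled rather than negative: the
WKNKN preprocessing replaces them with similarity-weighted likelihood
scores before fitting, and all evaluation protocols rank held-out known
pairs against the unverified pairs only.

## Parameters

| parameter | default | role |
|---|---|---|
| Δ (semantic decay) | 0.5 | geometric decay of DAG ancestor contributions (dimensionless, in (0,1]) |
| α₁, α₂ | 0.5, 0.5 | convex weights averaging the two semantic similarities into SD1 |
| θ₁, θ₂ / γ₁, γ₂ | 1, 0 / 1, 0 | blend of functional/semantic vs GIP similarity on pairs where the former is defined; the defaults use the curated similarity where available and GIP elsewhere |
| β′_m, β′_d | 1.0 | raw GIP bandwidths, normalized by the mean squared profile norm, the standard convention for interaction-profile kernels |
| K | 5 | WKNKN neighbor count |
| α (decay) | 0.7 | geometric decay over neighbor rank in WKNKN |
| a₁, a₂ | 1, 1 | miRNA-side vs disease-side weight in the WKNKN average |
| k (rank) | 50 | latent dimension; around 10% of the smaller matrix dimension of the reference benchmark |
| λ_l | 1.0 | Tikhonov coefficient, shared by the L2,1 term unless `lambda_21` overrides it |
| λ_m, λ_d | 0.01 | graph-regularization strengths |
| max_iter, tol | 500, 1e-6 | iteration cap and relative-objective-change stopping rule |
| eps | 1e-12 | denominator guard and row-norm floor |

The similarity weights are the settings under which the reference results
for this method were obtained. The factorization hyperparameters are not
pinned by any published value; the defaults sit in the range used by
graph-regularized NMF predecessors of this method, and reproducing the
benchmark AUCs exactly may require a small sweep around them. Every
parameter is exposed in both the library API and the CLI, and each CLI run
writes a manifest from which it can be re-executed bit-identically.

## Numerical choices

* **Initialization.** W and H start from seeded uniform(0,1) draws; the
  seed is a mandatory part of every stochastic entry point, and a single
  master seed is split deterministically across pipeline stages.
* **Update order.** Each iteration recomputes the L2,1 reweighting diagonal
  A from the current H, then updates H, then W. The objective is recorded
  after every full iteration and the trace is non-increasing (property
  tested at 1e-8 relative slack).
* **L2,1 gradient convention.** The derivative of ‖H‖₂,₁ is A H with
  A_ss = 1/‖H_s‖₂ — there is no factor 2, unlike the squared-norm terms.
  The multiplicative split therefore carries (λ_l/2)·A·H in the H-step
  denominator. Formulations that write λ_l·A·H there implicitly optimize an
  objective whose L2,1 coefficient is doubled, and measurably increase the
  objective as written here; the halved term is the exact
  majorize–minimize step for the stated objective and is what makes the
  monotonicity guarantee hold.
* **Degenerate inputs.** eps floors the row norms in A (zero rows of H
  would otherwise blow up the reweighting) and pads update denominators.
  GIP bandwidths are undefined when every profile is zero and raise with a
  remediation hint; a single empty row or column is fine. Diseases whose
  entire ancestor set is shared by every disease have zero
  frequency-weighted semantic value; their similarity is defined as 0 (the
  quotient is 0/0) with a warning.
* **Tie-breaking.** WKNKN neighbor lists and ranked candidate lists break
  score ties by ascending index/identifier, so cross-validation results and
  output tables are bit-reproducible.
* **ROC construction.** Thresholds sweep the distinct score values with
  tied scores grouped into one step; the trapezoidal area then equals the
  Mann–Whitney statistic with ties counted ½ (verified against a
  brute-force pair-count oracle and scikit-learn's implementation).

## Open design choices

* **LOOCV candidate scores.** Each held-out pair is scored by its own
  leave-out refit, while the unverified candidate pairs are scored once by
  a full-data fit. Re-scoring the full candidate set per refit would
  require 5430 score matrices on the reference benchmark without changing
  what is measured — the rank of each test pair among the candidates.
* **Five-fold pooling.** Within a repeat, each fold's held-out positives
  and the unverified candidates (scored by that fold's fit) are pooled into
  one ROC; the reported value is the mean AUC over repeats.
* **Leakage policy.** GIP kernels, integrated similarities and WKNKN are
  recomputed inside every fold from the masked matrix, so nothing derived
  from held-out entries reaches training. A `refold=False` /
  `--no-refold` variant reuses the full-data kernels, for sensitivity
  analysis only.
* **"Has similarity" predicate.** A pair participates in the
  functional/semantic branch of the integration when its entry in the
  supplied matrix is positive (an explicit boolean mask can override this).
* **Logarithm base.** The frequency-weighted ancestor contribution uses the
  natural log; any base cancels in the similarity quotient when applied
  uniformly.
* **WKNKN self-exclusion.** The target's own profile never enters its
  imputed profile; neighbors are restricted to rows/columns with at least
  one known association in the *current* (possibly fold-masked) matrix.

## The synthetic generator

`generate_synthetic` plants a rank-k nonnegative signal: latent factors
U, V are uniform(0,1) draws, Y marks the top `density` fraction of
U Vᵀ + noise, and both similarity matrices are cosine similarities of the
latent rows (clipped to [0,1], unit diagonal), so the similarity graphs
genuinely reflect the structure that generated Y — the regime the method
assumes. A random rooted tree over the disease ids exercises the DAG
code paths. Defaults (n=100, m=80, rank=5, density=0.05, noise_sd=0.1)
keep the observed density and side-information strength in the regime of
the curated benchmark while staying desk-scale.

What the generator does **not** emulate: the heavy-tailed degree
distribution of real disease–miRNA networks (a few hub diseases with
hundreds of associations), block structure from disease families, biased
ascertainment of which associations get experimentally confirmed, and
similarity matrices that are noisy or inconsistent with the association
signal. Passing the synthetic recovery tests therefore shows the pipeline
is implemented correctly and recovers planted structure under its own
assumptions — not that the same AUC will transfer to curated data.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at the
generator defaults (100×80, 400 known pairs), with global LOOCV subsampled
to 100 leave-out refits and five-fold CV at 5–10 repeats. Full LOOCV on
the curated benchmark (5430 refits of the entire pipeline) and 100-repeat
five-fold CV are supported but are overnight jobs on one CPU; the
benchmark-dependent tests in `tests/test_acceptance.py` document the
expected values and tolerances and run whenever the benchmark matrices are
present under `data/`.

## Known limitations

* Hyperparameters (k, λ_l, λ_m, λ_d, K, decay) are defaults, not tuned
  values; benchmark-exact AUC reproduction may need a sweep.
* miRNA functional similarity is consumed as a precomputed matrix; the
  underlying functional-similarity algorithm is not reimplemented.
* The factorization is solved only by multiplicative updates; no ADMM or
  projected-gradient alternative is provided.
* Validation of top-ranked candidates against external databases is out of
  scope; `write_rankings` emits the lists for downstream checking.
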