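# Methods

## Model

`pmfmda` factorizes a binary miRNA–disease association matrix
Y ∈ {0,1}<sup>n×m</sup> as Y ≈ UᵀV with nonnegative latent factors
U (D×n), V (D×m). The probabilistic reading — Gaussian observation noise
on the observed entries, zero-mean isotropic Gaussian priors on the factor
columns — collapses under MAP estimation into the objective

E = ½ Σ I_ij (Y_ij − U_iᵀV_j)² + (λ_U/2)‖U‖²_F + (λ_V/2)‖V‖²_F
  + (λ₁/2)‖UᵀU − S_m‖²_F + (λ₂/2)‖VᵀV − S_d‖²_F,

where λ_U = α_U/α and λ_V = α_V/α absorb the prior precisions, and the two
Gram-anchoring terms pull the model's implied miRNA and disease similarity
(UᵀU and VᵀV) toward the externally constructed S_m and S_d. The
similarity terms are what give the model signal for cold-start prediction:
a disease with an empty training column has no data term, and only the
λ₂-term can place its latent vector.

### Observation mask

I is the observation indicator. The default is the all-ones mask: in this
prediction setting an unknown pair is an *observed zero*, not a missing
value — the evaluation protocols rank every unknown pair, which requires
those pairs to contribute (0 − U_iᵀV_j)² terms to the loss. The
`mask_unknown` option (CLI `--mask-unknown`) instead sets I to Y's support
for true missing-data semantics.

### Optimization

E is minimized by multiplicative updates obtained from the KKT conditions
of the nonnegativity-constrained problem. Splitting each partial
derivative into its positive and negative parts gives, elementwise,

U ← U ⊙ [V(I⊙Y)ᵀ + 2λ₁ U S_m] ⁄ [V(I⊙(UᵀV))ᵀ + λ_U U + 2λ₁ U(UᵀU) + ε]

and symmetrically for V with U, S_d, λ_V, λ₂. Two points deserve note:

* **Mask-aware products.** A compact notation like I·(−VYᵀ + VVᵀU) is
  dimensionally loose; the implementation uses the exact gradient of the
  masked loss — residual R = I ⊙ (UᵀV − Y), ∂E/∂U-data-term = VRᵀ,
  ∂E/∂V-data-term = UR — and splits R's two parts between numerator and
  denominator. With the all-ones mask this reduces to plain matrix
  products. A finite-difference test pins the analytic gradient to the
  objective at 1e-5 relative, which fixes every symbol's interpretation.
* **V-update symmetry.** The similarity term in the V-update numerator is
  2λ₂·V·S_d, by symmetry with the U-update and by dimensional necessity
  (a U·S_m term would be D×n where D×m is required).

Updates alternate Gauss–Seidel style (the V-update sees the fresh U); a
Jacobi variant is available via `Hyperparams(ordering="jacobi")`. Factors
are initialized i.i.d. uniform(0,1) from a seeded generator — strict
positivity keeps multiplicative updates alive — and the similarity inputs
are symmetrized ((S+Sᵀ)/2) on entry as a guard against asymmetric files.

Multiplicative updates for this objective carry no monotonicity proof, so
the objective is recorded every sweep and the test suite *measures*
monotonicity (non-increase within 1e-8 relative slack) and stationarity
(final complementary-slackness residual below 1e-4 of its initial value)
across 100 random instances; violations fail the build.

### Numerical choices

* ε = 1e-10 guards every update denominator; an entry whose numerator and
  denominator are both below ε is left unchanged rather than driven by
  round-off.
* Stopping: relative objective change < tol (default 1e-6) or `max_iter`
  (default 1000) sweeps, whichever first; non-finite objectives raise
  immediately with the iteration index.
* Similarity values are clamped to [0,1] with absolute tolerance 1e-12
  (tiny negative round-off is zeroed, not an error).
* Ranking ties break by miRNA name, then disease name, so outputs are
  deterministic; metric computations give tied scores half credit
  (mid-rank AUC, grouped PR thresholds).

## Hyperparameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| D (`latent_dim`) | latent factor dimension | 50 | small relative to typical m (hundreds of diseases); sweep via `grid_search` if in doubt |
| λ_U, λ_V | factor norm regularizers | 1.0 | tuned values for this model family on the reference corpus |
| λ₁, λ₂ | similarity-anchor weights | 0.005 | idem; the leave-disease-out experiment shows the benefit directionally |
| Δ (`delta`) | semantic decay per DAG edge | 0.5 | standard choice for MeSH-based semantic similarity |
| γ′ (`gamma_prime`) | GIP bandwidth numerator | 1.0 | kernel bandwidth then equals 1 / mean squared profile norm |
| tol / max_iter | stopping rule | 1e-6 / 1000 | relative objective change |
| seed | initialization RNG | 0 | always recorded in summaries and saved metadata |

## Similarity construction

**Semantic (diseases).** Each disease's DAG is the union over its tree
codes of all prefix chains; nodes are keyed by the opaque dotted code, so
diseases sharing a prefix share ancestor nodes, and a disease with several
tree numbers is one entity whose own codes all carry contribution 1.
Contribution decays as D_d(t) = max over t's children within the DAG of
Δ·D_d(t′); similarity is the shared-ancestor sum normalized by the two
semantic values. Children are restricted to the disease's own DAG — an
ancestor's children outside it cannot contribute under this recursion
anyway.

**Coverage and fallback.** "Has semantic similarity" means *both diseases
possess a DAG*, not "similarity > 0": a computed zero between covered
diseases is a legitimate value and is kept. A miRNA is functionally
covered when its training-set disease list is nonempty and all its
diseases are semantically covered. Uncovered pairs take the GIP kernel
value. The disease similarity fed into the functional measure is the
integrated S_d (semantic with kernel fallback), respecting the dependency
order of the constructions.

**Leakage control.** The GIP kernels and the functional similarity are
functions of Y, so during cross-validation they are recomputed from each
fold's *training* matrix; `run_protocol` asserts that held-out entries are
zero in the matrix the similarity builder receives. A
`static_similarity_fn` reproduces the laxer full-matrix variant
(CLI `--static-similarity`) for comparison only.

## Evaluation protocols

* **Global k-fold CV** (default k = 5): known associations shuffled with
  the split seed and partitioned into near-equal folds. A per-disease
  variant (`make_kfold_splits(..., per_disease=name)`) stratifies within
  one disease's column.
* **Global LOOCV**: each association removed in turn.
* **CV_d**: one disease's entire column deleted — the novel-disease test.
  Hit counts at ranking thresholds k ∈ {20, 40, 60, 80, 100} are reported
  for the held-out column.

Pooling: positives are the held-out pairs scored by their own fold's
model; negatives are the pairs that are 0 in the *full* matrix, scored by
every fold's model; training 1-entries are never candidates. Per-fold
AUC/AUPR are reported alongside (mean ± sd) since pooled and averaged
fold metrics answer slightly different questions. The split seed and the
model seed are independent and both recorded in every report.

## Synthetic data

The generator emulates the structure of the curated corpora the method
targets (the reference corpus is 495 miRNAs × 383 diseases with 5,430
associations, density ≈ 0.029): sparse nonnegative factors U*, V* drawn as
|N(0,1)| with 70 % of entries zeroed (block structure makes the Gram
matrices informative, exercising the λ₁/λ₂ terms nontrivially), Y set to 1
at the top density·n·m entries of U*ᵀV*, optional label-flip noise, and a
recorded fraction of 1s hidden for recovery experiments. Ground-truth
similarities are the unit-diagonal normalized Gram matrices of the planted
factors. The ontology generator emits a rooted code tree and assigns
diseases 1–2 tree numbers, leaving a configurable fraction uncovered to
exercise the kernel fallback.

What the synthetic data does *not* emulate: the long-tailed degree
distribution of real curation (some diseases dominate the literature),
name-level noise, correlated annotation errors, and a real MeSH topology.
Passing tests therefore demonstrate correctness of the algorithms and
recoverability under the model's own generative assumptions — not
clinical-grade accuracy on real corpora, for which real association data
must be supplied through the same TSV interfaces.

### Experiment sizes

Recovery and protocol experiments run at 30 × 20 with rank-3 factors,
density 0.15 and 10 % of positives hidden — at this matrix size the
reference-corpus density would leave only ~17 positives, too few for
stable AUCs, so a denser planting is the generator's default for these
experiments. LOOCV examples use 20 × 12. The reference-scale fixture
(495 × 383, 5,430 ones, D = 50, 200 sweeps) is a smoke test of the full
pipeline, not an accuracy claim.

## Known limitations

* Multiplicative updates stall on entries that reach exactly zero; they
  cannot leave the boundary. This is inherent to the update family.
* With λ₁ = λ₂ = 0 and an empty disease column, the column's latent vector
  collapses to zero and all its candidates tie at score 0 — the documented
  cold-start failure the similarity terms exist to fix.
* The objective is non-convex; different seeds can reach different local
  minima. Reported experiments average over seeds, and all randomness is
  reproducible from the recorded seeds.
* Alternative semantic-contribution models, information-content
  weighting and sequence-based miRNA similarity are out of scope.
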