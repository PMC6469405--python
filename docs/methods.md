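# Methods

## Model family

All solvers operate on the polynomial regression

    y_i = Σ_m a_m · monomial_m(M_i,·) + ε_i

where the monomials run over an explicit, ordered set: intercept,
degree-1 terms by locus, pairwise products (j, k) with j < k in
lexicographic order, then optional squares M_j² (the dominance device).
The solvers cap the total degree at 2; the translation machinery
(`translate_polynomial`) supports arbitrary degree by exact integer
binomial expansion, so the top-degree-preservation property can be
checked beyond what the solvers fit.

Fitting minimises SSR plus a per-coefficient penalty: `ridge_fit`
solves `(XᵗX + diag(λ)) b = Xᵗy` in one symmetric system — unpenalized
coefficients (intercept, or the whole additive block in the
interactions-only model) simply carry zeros on the penalty diagonal
rather than being absorbed into a separate fixed-effect projection.
This keeps "additive effects as fixed effects, interactions penalized"
literally one matrix.  A reciprocal-condition threshold of 1e−12 on the
(penalized) normal matrix triggers an explicit singularity error; there
is no silent pseudo-inverse, because a rank-deficient unpenalized block
would silently destroy the invariance guarantees the package is about.

`lasso_fit` is cyclic coordinate descent with soft-thresholding,
deterministic column order, default tolerance 1e−8 on the largest
per-sweep coefficient change, 10 000-sweep budget.  λ_c = 0 coordinates
get the exact unpenalized update, so the intercept is never shrunk
unless asked.

## Coding translations

A coding is a translation `M̃ = M − 1ₙ Pᵗ`.  `MarkerMatrix` carries the
accumulated shift so that (a) translations compose additively, and
(b) `predict` re-applies the *training* shift to any new genotypes —
mixing codings between training and prediction is the central failure
mode and is made structurally impossible rather than documented away.
The named codings are: `original` (P = 0), `centered` (P = column
means), `symmetric` (P = max_dosage/2 everywhere, i.e. ±0.5 for
presence/absence data).  The symmetric rule for general ploidy
(subtract half the maximum dosage) is this package's convention; for
0/1 data it reduces to the usual ±0.5 coding, for 0/1/2 data it gives
−1/0/+1.  When the experiment harness has to infer `max_dosage` it uses
the maximum raw dosage observed, rounded.

## Completeness and the translation transform

`translate_polynomial(f, P)` returns f̃ with f̃(m̃) = f(m̃ + P)
identically, expanding each monomial with binomial coefficients.  If the
expansion generates a monomial with a nonzero coefficient that has no
slot in the model, the model is incomplete and a `CompletenessError` is
raised — for complete models (checked by `is_complete`) this cannot
happen.  Consequences exercised by the tests: SSR and all fitted values
are preserved under (translate data, translate polynomial); top-degree
coefficients are preserved exactly (they are copied through the
expansion with binomial factor 1 and shift power 0, so the equality is
bitwise); a degree-1 locus appearing in no higher monomial also keeps
its coefficient.

## Kernels and REML

Additive kernel `G = MMᵗ` in the current coding (optionally scaled to
trace n); epistatic kernel `H = 0.5(MMᵗ∘MMᵗ) − 0.5(M∘M)(M∘M)ᵗ`, which
equals Σ_{k<l} (M·k∘M·l)(M·k∘M·l)ᵗ and is therefore PSD by
construction.  H is divided by its maximum entry by default.  Any
kernel rescaling rescales its variance component and hence the penalty
factor λ = σ²_ε/σ²; reported λ values are only comparable under a fixed
normalization, which is why the normalization is stored on the kernel.
PSD validation accepts eigenvalues down to −1e−8 relative to the
largest.

`reml` estimates one variance per kernel plus a residual by
average-information updates: score `−½(tr(PK_i) − yᵗPK_iPy)`, AI matrix
`½ yᵗPK_iPK_jPy`, with step-halving if a proposal leaves the
nonnegative orthant or decreases the restricted log-likelihood, and an
EM-style ratio fallback `σ² ← σ² · (yᵗPKPy)/tr(PK)` (nonnegative by
construction) when the AI step cannot be salvaged.  Convergence:
relative log-likelihood change < 1e−8, at most 200 iterations (error
with the trajectory beyond that).  Standard errors are the square roots
of the inverse AI diagonal at convergence.  Degenerate inputs:
zero-variance phenotypes return all-zero components (converged, at the
boundary); an empty kernel list uses the residual-only closed form
RSS/(n − rank X); kernel pairs (including the implicit identity) with
cosine similarity > 1 − 1e−6 are reported as unidentifiable in
`warnings` but still estimated.  Dense O(n³) linear algebra throughout
— intended for panels of hundreds to a few thousand lines, not biobank
scale.

## Synthetic data

`simulate_genotypes` draws per-marker allele frequencies uniformly from
`maf_range` (default 0.1–0.5) and dosages Binomial(ploidy, q_j); the
default configuration — 300 lines × 50 presence/absence markers,
(σ²_β, σ²_h, σ²_ε) = (0.5, 0.1, 0.25), all effects nonzero — mirrors a
marker-subset study on a diversity panel of inbred lines scored with
dominant markers.  Phenotypes are generated from the degree-2 model
with i.i.d. normal effects drawn **in the raw coding**; the generating
polynomial is stored so the truth can be re-expressed in any coding via
the translation transform.  What the generator does *not* emulate:
linkage disequilibrium between markers, population structure, pedigree
relatedness, multi-environment structure, and non-Gaussian effect
distributions.  Tests passing on this generator therefore certify the
algebraic and statistical machinery, not robustness to structured real
panels, where chance kernel similarity and confounding can be far
worse.

## Experiment harness

`coding_comparison` follows a freeze-the-penalties protocol: variance
components are estimated once, on the column-mean-centered coding of
the full data (additive + epistatic kernels, or epistatic only when the
additive effects will be fixed), and the implied λ₁, λ₂ are held fixed
across codings and repetitions.  Re-estimating per coding would
confound the direct coding effect on the estimates with the indirect
effect of changed penalty factors; a `reestimate_per_coding` flag
exposes that confounded variant deliberately.  Each repetition draws
markers (and optionally lines) uniformly without replacement from its
own RNG stream seeded by (seed, repetition), so runs are bit-reproducible
and individual repetitions can be re-run in isolation.  Monomorphic
marker columns are not filtered.  Ranking of interaction estimates is
by descending absolute value with ties broken by original index (stable
sort); note that in the invariant regime estimates agree only to
numerical precision, so raw-float ranks can still swap on effective
ties — rank-based invariance should be read at the same tolerance as
the estimates.  Aggregates are means with standard errors over
repetitions.  Repetitions with constant predictions or constant
held-out phenotypes (undefined correlation) are excluded and counted.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each property is cleanly
measurable: the worked 5×2 example for the solver table; p ≤ 8 random
instances (20 seeds) for the invariance/non-invariance suite; 300 × 50
(1225 interactions, 10 repetitions) for the experiment-scale invariance
check; n = 400 with 50 replicates for REML recovery; and a 260-line
panel with training sizes 60/120/200 for the training-size trend, which
mirrors the full design's 200/300/539-line reductions at a quarter of
the compute.

## Known limitations

Solvers are dense and unblocked: the practical ceiling is a few
thousand model terms (p ≈ 150 markers with all pairs).  Marker
*scaling* (as opposed to translation) is out of scope, as are
genotype-frequency-based codings, G×E interaction kernels, Gaussian
RKHS regression, and Bayesian effect priors.  VCF input handles
biallelic sites only, and `errblup` deliberately refuses multi-allelic
records rather than splitting them.
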