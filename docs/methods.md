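# Methods

## Model

`facdiff` models a genes × cells matrix of UMI counts from two conditions
with a Poisson latent-factor model. Conditionally on a cell's factor vector
λ<sub>i</sub> ∈ R<sup>F</sup> (standard normal a priori), counts are Poisson
with

log μ_gi = β_g + t_i δ_g + Σ_f λ_if α_{gf;t_i} − ½ Σ_f α²_{gf;t_i},

so β_g is the control log-mean, δ_g the log-fold change, and the
condition-specific loadings α_{gf;t} route factors to genes. The quadratic
adjustment keeps the marginal mean at exp(β_g + t_i δ_g) whatever the
loadings; marginally over λ the count is overdispersed with

Var[Y_gi] = m (1 + m (Π_f exp(α²_{gf;t}) − 1)),  m = exp(β_g + t_i δ_g),

strictly exceeding the mean whenever any loading is nonzero. Large negative
factor draws push μ toward zero, which is how the model absorbs the zero
inflation of real scRNA-seq data without an explicit zero component.

Two shrinkage variants are implemented. Both place a horseshoe on the
condition deviation: α_{gf;t} ~ N(α̃_gf, κ²_{gf;t} τ²_f) with standard
half-Cauchy local (κ) and per-factor global (τ) scales, so condition loadings
are pulled toward a shared center α̃ and only well-supported differences
survive. SHS gives the center a plain normal prior N(0, ζ²); DHS puts a
second horseshoe on it (ω_gf local, ζ global), additionally sparsifying the
shared base network. β and δ get N(0, σ²) priors with half-Cauchy scale
hyperpriors. All half-Cauchy distributions are the untruncated standard form
with density 2/(π(1+x²)).

The network quantities are functions of the loadings only: within condition
t, A_t = α_t α_tᵀ is the covariance of the log-means, its correlation
normalisation ρ_t the co-expression network, and θ = ρ_0 − ρ_1 the
differential network. ρ is invariant to rotations of the factor axes, which
makes it identifiable although individual loadings are not. Genes whose
factor variance Σ_f α² falls below `var_floor` (10⁻¹²) are reported as
unconnected (ρ = 0 off-diagonal) — the ratio is 0/0 there and "no
factor-driven variation" is the only reading that keeps the edge table total.

## Estimation

The joint posterior is maximized with L-BFGS-B over an unconstrained
parameterization:

* positive scales (κ, τ, ω, ζ, σ_β, σ_δ) are optimized as logarithms **with
  the log-transform volume adjustment added to the objective**. The raw
  density is unbounded along the horseshoe funnel (κ → 0 with α → α̃); the
  adjusted objective is bounded above and is the standard practice for
  mode-finding in funnel geometries.
* loadings are non-centered: α = α̃ + κ τ η and α̃ = ζ [ω] η̃ with η, η̃ free
  standard-normal parameters. This conditions the funnel; the state is
  converted back to the natural parameterization for reporting.

Gradients are derived analytically and implemented in numpy (they are checked
against central finite differences in the test suite at ~10⁻⁸ relative
error). Defaults: η, η̃, λ, β, δ initialized N(0, 0.1²) by seed, log-scales at
0; 3 random restarts for a standalone fit, best objective wins, ties to the
lowest restart index; convergence at relative objective change < 10⁻⁸ or
gradient max-norm < 10⁻⁶, capped at 2000 iterations. The iteration cap is
frequently what stops a fit on realistic data; capped fits are kept (their
edge estimates are stable well before the cap), and only replicates that
diverge to non-finite objectives count as failures.

The log-mean is clipped at 30 (natural log) before exponentiation; counts
beyond e³⁰ are unphysical for scRNA-seq and the clip prevents overflow in
pathological optimizer states.

One consequence of the adjusted objective is worth noting: for degenerate
all-zero count matrices the mode can explain the data through large loadings
(the −½Σα² term drives every predicted mean to zero exactly) rather than
through strongly negative β. Both explanations predict zero means; tests
assert the prediction, not the mechanism.

## Inference

Uncertainty comes from a nonparametric bootstrap (the recommended procedure;
full HMC is out of scope and variational approximations are deliberately not
offered):

1. resample cells with replacement independently within each condition,
   preserving both group sizes;
2. re-estimate the posterior mode on the replicate (cold start, single
   restart by default — replicate-to-replicate resampling supplies the
   variability the intervals measure, and one start per replicate keeps the
   cost linear in the number of replicates);
3. record the replicate's ρ_0, ρ_1 edge vectors and θ = ρ_0 − ρ_1.

Replicate b is seeded `base_seed + b`, so replicates are independent,
parallelizable (joblib) and individually reproducible. The default number of
replicates is M_b = 1000; the scaled benchmark below uses 200. If more than
20% of replicates fail, the run errors out.

Edge summaries use the classical order-statistic percentile bootstrap: the
interval at level 1−α* is the k-th smallest/largest draw with
k = ⌊(M+1)α*/2⌋. At small M this is slightly wider than interpolated
quantiles, which keeps edge calls honest at the resolution the draws support.
The approximate p-value is 2·min(#draws ≤ 0, #draws ≥ 0)/M, floored at the
empirical resolution 2/M (so a unanimous sign is reported as p = 2/M, never
0, and ranking stays stable) — it is the smallest level at which the interval
excludes zero, up to the 2/M grid. Significance at level α* is interval
exclusion of zero. Within-condition networks are summarized from the ρ draws
with the same machinery.

Choosing the factor count F: the proportion of significant differential edges
is computed over a grid of F values; the chosen F is the one with the maximal
proportion among F > 5 (ties to the smallest). The proportion typically rises
to a peak and then flattens, and results are fairly insensitive to F in the
plateau; F = 7–8 is a reasonable default for tens to ~130 genes. A
single-optimization mode is also provided: rank edges by |θ̂| and take the
top fraction (ties broken by lexicographic gene pair) — fast, but without
significance calls.

## Synthetic benchmark data

The simulator deliberately uses a *different* generative family from the
model. Per-gene marginals are zero-inflated negative binomial (ZINB: mean μ,
size r, structural-zero probability π), coupled by a Gaussian copula (NORTA):
draw Z ~ MVN(0, Σ_t) per cell, map each coordinate through Φ and the gene's
ZINB quantile. Default ZINB parameters are drawn per gene as
log μ ~ U(log 0.5, log 20), r ~ U(0.5, 3), π ~ U(0.2, 0.7) — typical
scRNA-seq ranges — and are seedable; users can supply their own table.

Designed correlation structure: genes are sorted into `n_groups` equal
contiguous groups (default 10). Within-group correlation is 0.8 in both
conditions; between-group blocks share a base of 0.1, except for
`n_diff_blocks` block pairs whose correlation differs between conditions.
The differing pairs form disjoint cliques of blocks, each clique carrying one
difference level d (cycled from `delta_levels`, default {0.3, 0.6, 0.9}):
structure A sets ρ₀ = 0.1 + 2d/3 and ρ₁ = 0.1 − d/3 (|Δρ| = d exactly);
structure B splits each clique into two camps and flips the treatment sign on
cross-camp pairs (ρ₁ = −(0.1 + d/3), |Δρ| = 0.2 + d, up to 1.1). Clique
placement is what keeps both targets valid correlation matrices — scattering
strong changes over arbitrary block pairs is massively non-positive-definite.
A nearest-correlation repair (eigenvalue clipping with unit-diagonal
restoration) runs as a safety net and errors out if it would move any entry
by more than 0.05. The truth set is every gene pair inside a differing block
pair, n_diff_blocks · (G/n_groups)² edges: 325 at G = 50 and 1,300 at
G = 100 with 13 differing blocks.

Truth is defined on the design (latent-Gaussian) scale. The induced
count-scale correlation is attenuated by the discrete, zero-inflated
marginals, so the benchmark asks the method to recover latent structure
through that attenuation — the same convention used when the designed
structures are treated as ground truth. What the simulator does *not*
emulate: library-size variation, batch effects, gene-length effects, empirical
ZINB parameters refit from real tissue, and dropout that depends on
expression level. Passing these benchmarks therefore demonstrates recovery of
copula-scale block structure under realistic sparsity, not performance on any
particular real dataset.

Four named schemes mirror common benchmark sizes (sim1–3: G = 50 with
N = 1000/500/2000; sim4: G = 100, N = 1000; cells split equally; 13 differing
blocks).

## Evaluation

Detections are scored against the design truth with TPR = TP/|truth|,
FDR = FP/#detected (defined 0 for an empty detection set so tables aggregate
cleanly), and rank-based (Mann–Whitney) AUROC of per-edge scores with
average-rank tie handling — scores are the inverse approximate p-values, and
any strictly monotone transform gives the same AUROC.

## Scaled benchmark and problem sizes

`scripts/acceptance.py` runs a scaled-down version of the simulation study as
the package's reproducible benchmark: G = 30 genes (10 groups of 3), N = 400
cells split equally, 5 differing blocks with |Δρ| ∈ {0.3, 0.6, 0.9},
SFM-SHS with F = 7 and M_b = 200 replicates. These sizes keep a full
bootstrap run at a few minutes on a single CPU while preserving the structure
of the full-size designs (which use G = 50–100, N = 500–2000 and
M_b = 1000). FDR control degrades gracefully with fewer detections — with
~40 detected edges one false positive moves the FDR by ~2.5 points — so
FDR at this scale is intrinsically jumpier than at full size.

## Known limitations

* Only two conditions are supported (the data model keeps the group coding
  extensible, but the T-group generalization is not implemented).
* Counts are modeled without size-factor normalization, matching the model's
  definition; normalization is the user's preprocessing concern.
* The conditional likelihood is Poisson only — no negative-binomial or
  explicit zero-inflated conditional variant.
* The bootstrap refits a multimodal objective per replicate; label-swap
  equivariance of θ holds only up to optimizer multimodality on finite
  restarts.
* Edge significance uses interval exclusion per edge; no multiplicity
  correction across the G(G−1)/2 edges is applied (the horseshoe shrinkage
  and the bootstrap's finite resolution do the tempering in practice).
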