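# Methods

## The low-rank summary-statistics model

The starting point is the standard multiple regression y = Xβ + e of a
standardized phenotype on m standardized genotypes, var(e) = σ²_e I. All
modelling happens per quasi-independent LD block. For a block with
correlation matrix R = X′X/n and eigendecomposition R = U diag(Λ) U′, the
projection K = Λ^(−1/2)U′X′/√n satisfies KK′ = I, so applying K to y yields
the rank-q working model

    w = Qβ + ε,   ε ~ N(0, σ²_e I_q),

with w = √n Λ^(−1/2)U′ b_std and Q = √n Λ^(1/2)U′ computable from summary
statistics alone: b_std is the marginal genotype–phenotype correlation,
recovered from the GWAS t/z statistic via b_std = z/√(z² + n − 2). Only the
leading eigenvectors covering a fraction (default 0.995) of the trace are
kept; the default follows common low-rank practice for summary-data models
and also discards the noise-amplifying near-null eigendirections of a
finite LD reference. Negative eigenvalues are clamped to zero before rank
selection, and per-SNP sample-size heterogeneity is absorbed by using the
block median n.

Two properties of this construction matter for interpretation:

* **σ²_e is a nuisance scale, not 1 − h².** Because blocks are modelled as
  mutually independent, each block's residual ε contains the genetic signal
  of all *other* blocks in addition to the true residual: in-sample LD makes
  the cross-block term contribute ≈ h²_other per projected element, so the
  fitted σ²_e tends to ≈ 1 on the standardized scale rather than 1 − h².
  This is the correct description of block-projected data, and it is why
  the per-draw heritability is computed as the genetic variance itself
  (h² = Σ_blocks ‖Qβ‖²/n, capped at 1) against the phenotypic variance of
  1 implied by the standardization — not as var_g/(var_g + σ²_e), which
  would double-count genetic variance.
* **The per-SNP conditional uses d_j = Q_j′Q_j** (the eigen-truncated
  diagonal of nR) where full-rank algebra would give n; the two coincide
  when no eigenvalue is discarded.

## Priors and the Gibbs sampler

Effects carry a K-component normal mixture β_j ~ Σ_k π_jk N(0, γ_k σ²_g)
with γ₁ = 0 (the null spike). The point-normal model ("SBayesC") is the
K = 2 case with γ = (0, 1), so σ²_g is the slab variance itself; the
multi-component model ("SBayesRC") uses γ = (0, 10⁻⁵, 10⁻⁴, 10⁻³, 10⁻²)
so that the component variances are tied to the single scale σ²_g.

Conditional updates per sweep:

* each SNP in genomic order (a random scan is available): the adjusted
  statistic r_j = Q_j′ε + d_j β_j gives component probabilities
  ∝ π_jk √(λ_k/C_k) exp{r_j²/(2 C_k σ²_e)} with λ_k = σ²_e/(γ_k σ²_g) and
  C_k = d_j + λ_k, evaluated in log space with max-subtraction; a non-null
  draw is β_j ~ N(r_j/C_k, σ²_e/C_k), and the residual is updated
  incrementally (the bookkeeping is exact to 1e-8, which the tests check);
* π ~ Dirichlet(counts + 1) in the no-annotation mode;
* σ²_g from its scaled-inverse-χ² conditional given Σ β_j²/γ_δj (ν = 4,
  scale fixed at the initialization value), likewise σ²_e given Σ ε′ε with
  a floor of 1e-6;
* with annotations, per-SNP membership priors come from a sequential
  (stick-breaking) probit: stage k models Pr(δ > k | δ ≥ k) = Φ(μ_k +
  A_j α_k), updated by Albert–Chib truncated-normal data augmentation. The
  coefficient update uses a 1e-6 ridge plus a weakly-informative
  N(0, 100) prior so stages with (near-)pure outcomes stay finite. Under
  this parameterization a positive α raises a SNP's non-null prior mass
  monotonically.

Initialization is uninformative (β = 0, all-null, σ²_e = 1, σ²_g from a
crude plug-in of the projected data); chains of the default length
(10,000 iterations, 2,000 burn-in, thinning 10 for stored draws) absorb
it. PIPs are computed from every post-burn-in iteration via running counts;
stored (thinned) effect draws feed the credible-set statistics. Identical
seed, configuration and inputs give bit-identical draws.

### Automatic component pruning

Components with γ_k σ²_g ≪ 1/n are nearly unidentifiable against the null:
their Bayes factors hover at 1, so their occupancy performs a random walk
driven by the prior, which inflates the apparent number of causal variants
and distorts PIPs. The pruning procedure addresses this: at checkpoints
every 500 iterations (while the chain is inside a burn-in phase), the
non-null component explaining the least genetic variance is removed if its
share is strictly less than half of the second smallest's; every removal
restarts the burn-in clock, and retention begins once a full burn-in passes
without a removal. Shares are averaged over the trailing 100 iterations
before the checkpoint, so a component the chain has effectively abandoned
shows a ~zero share and the strict rule fires; this schedule reliably
collapses single-normal simulations to K = 2 while leaving genuinely
multi-scale architectures intact (a real component would have to explain
under half the variance of the smallest other component to be touched).
Pruning is enabled by default for the multi-component model only.

## Credible sets and posterior power statistics

* **α-LCS.** SNPs are visited once as focal, in decreasing PIP order (ties
  by position). The candidate set is the focal SNP's free (not yet
  reported) neighbours with r² > 0.5 within its block, r² taken from the
  eigen-reconstructed LD; members are added by decreasing PIP until
  ΣPIP ≥ α. The set is reported only if its PEP — the fraction of stored
  draws in which the set's Σβ² strictly exceeds that of a fresh uniformly
  drawn random set of equal size — exceeds 0.7; otherwise all its SNPs stay
  free for later sets. Singleton sets are allowed. The strict-inequality
  tie rule means a set equal to the whole panel has PEP 0 by definition,
  and under a pure-noise posterior PEP ≈ 1/2.
* **α-GCS.** The smallest prefix of PIP-ranked SNPs with ΣPIP ≥ α·m̂_c,
  where m̂_c = round(M(1 − π̂₁)); if total PIP mass falls short, all
  positive-PIP SNPs are returned with the achieved coverage recorded.
* **PHE** of a set is the per-draw ratio of the set's Σβ² to the
  genome-wide total, averaged over draws (zero-total draws contribute 0);
  it is additive over disjoint sets and equals 1 for the full panel.
* **TPR at threshold α** is Σ{PIP_j : PIP_j ≥ α}/(M·π̂_nonnull), clipped to
  [0, 1].

## Power prediction for prospective studies

For a causal variant explaining variance v at sample size n, the PIP it
would receive follows PIP = 1 − 1/(1 + Σ_k A_k e^{B_k Z}) with
A_k = (π_k/π₁)√(λ_k/C_k), B_k = n/(2C_k), C_k = n + λ_k and
Z ~ χ²₁(nv/σ²_e), sampled as (G + √ncp)² and evaluated as
expit(logsumexp(·)) for numerical stability. Power at threshold α is the
Monte-Carlo mass above α. Genome-wide quantities integrate v out by drawing
effects from the fitted mixture and squaring (exactly equivalent to the
change of variables for a symmetric effect density): power is the mean
per-variant power, expected discoveries are M(1 − π₁)·power, and expected
PHE is M(1 − π₁)σ_g⁻²·E[power_v · v], clipped to [0, 1] (the clip matters
when the fitted M π σ²_β slightly overshoots the fitted h²). When a
point-normal fit feeds the predictor, the architecture is re-expressed so
σ²_g is the heritability and γ₂ the slab-to-h² ratio, which makes the PHE
normalization exact. Defaults: 10⁴ PIP draws per v for single-v queries,
10⁵ architecture draws with 8 PIP draws each for genome-wide predictions.
`required_sample_size` bisects the predicted curve on log n (common random
numbers per evaluation; metric tolerance 0.005) and reports an explicit
not-reachable result with the asymptote when the target exceeds it. The
law treats causal variants as LD-independent; LD splitting of PIPs in the
realized data is partially recovered by evaluating realized PHE on credible
sets rather than single SNPs.

## Liability-scale conversion

For a disease with population prevalence K studied with v·N₀₁ cases, the
threshold model gives an equivalent quantitative-trait sample size
N_eq = i²v(1 − v)N₀₁/(1 − K)², with i = φ(Φ⁻¹(1 − K))/K the mean liability
of cases (upper-tail truncation). Per-SNP liability-scale effects are
se = 1/√(2p(1 − p)(N_eq + z²)), b = z·se, which preserves z and p-values
exactly. `cases_required` inverts the relation at a given case proportion
(the equal-controls design v = 1/2 being the default), so the two functions
are exact inverses.

## The synthetic test-bed

`simulate_genotypes` draws, per block, two latent AR(1) Gaussian haplotype
vectors per individual, thresholds each at Φ⁻¹(MAF_j) and sums them to a
0/1/2 genotype. This gives exact block independence, Hardy–Weinberg
proportions, a controllable MAF spectrum (uniform on [0.01, 0.5] by
default) and AR(1)-decaying within-block LD (per-block latent correlation
drawn uniformly from [0.2, 0.95] by default); the realized genotype
correlation is the tetrachoric-attenuated value of the latent one, which
the tests verify against the bivariate-normal orthant probability. What it
does *not* emulate: realistic demography and LD beyond AR(1) decay,
imputation error, allele-frequency–effect-size coupling from selection, or
genome-scale SNP counts — so passing tests certify the statistical
machinery under the model's own assumptions at desk scale, not performance
on real cohort data.

Phenotypes follow y = X_c β + e with the residual variance set to
var(X_c β)(1/h² − 1), so the causal set explains h² (default 0.5) of the
phenotypic variance in expectation. Architectures: *sparse* (a fraction
0.01 of SNPs causal, β ~ N(0, h²/m_c)); *large-effects* (10 designated
SNPs drawing from N(0, 0.2h²/10) — i.e., 10% of phenotypic variance at the
default h² — on top of the remaining causals sharing the rest); *ldms*
(causals drawn only from the high-LD, high-MAF quartile defined by median
splits of the within-block LD score and MAF). `run_gwas` performs exact
per-SNP least squares with two-sided normal p-values and emits `.ma`
records; monomorphic SNPs survive with a variance-floor standard error.
Desk-scale defaults (5,000 SNPs in 50 blocks of 100, 10,000 individuals)
were chosen as the smallest configuration at which mixture-proportion and
heritability recovery are unambiguous.

## Numerical and design choices

* Allele alignment: records must match the LD panel directly or as a swap
  (swap negates the effect and flips the frequency); palindromic A/T and
  C/G SNPs are excluded rather than strand-guessed. Alignment is
  idempotent.
* Exact small-m posterior (`exact_posterior_small`, m ≤ 12): enumerates all
  causal configurations with the multivariate-normal marginal likelihood
  N(w; 0, σ²_e I + σ²_β Q_S Q_S′) on the projected system; rank-deficient R
  (perfect LD) is handled by dropping null-space directions. It serves as
  the independent oracle for the sampler in the tests.
* Degenerate inputs: σ²_e floored at 1e-6, σ²_g at 1e-12; zero retained
  eigenvalues are a hard error for pseudo-data construction; empty
  candidate credible sets release their members.
* The test-bed's problem sizes (e.g. five seeded 5,000-SNP fits; 20-seed
  perfect-LD replicates; 3-seed LDMS comparisons) are the package's chosen
  desk-scale study conditions; all simulations and chains are seeded and
  reproducible.

## Known limitations

* Cross-block LD is exactly zero by assumption; long-range LD spanning
  block boundaries is invisible to both the sampler and the credible sets.
* σ²_e absorbs cross-block genetic signal (see above), so it should not be
  interpreted as 1 − h².
* The annotation model's sequential-probit construction is one faithful
  ordering of the membership stages; other orderings would give slightly
  different priors.
* The power law ignores LD between causal variants; its predictions are
  calibrated against isolated-causal simulations and can be optimistic for
  heavily clustered causals.
* The pruning rule, while robust in the tested regimes, compares only the
  two smallest variance shares; architectures engineered to hold several
  equal near-null components can in principle keep surplus components
  through burn-in.
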