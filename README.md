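# gwfm — genome-wide fine-mapping from GWAS summary statistics

`gwfm` identifies likely causal variants for complex traits by fitting a
Bayesian mixture model to *all* genome-wide SNPs jointly, using only GWAS
summary statistics (COJO `.ma` format) and block-wise LD information.
Unlike region-by-region fine-mapping, the genome-wide fit learns the trait's
genetic architecture — polygenicity, effect-size distribution, SNP-based
heritability — from the data itself and uses it as the prior for every
locus. The package is aimed at statistical geneticists who want, from a
single summary-statistics fit: per-SNP posterior inclusion probabilities
(PIPs), LD-based local and global credible sets, heritability attribution
for those sets, and a forward prediction of how fine-mapping power grows
with GWAS sample size.

## Model

Within each quasi-independent LD block, the summary data are projected onto
the leading eigenvectors of the block LD correlation matrix
R = U diag(Λ) U′ (keeping the top *q* components covering 99.5% of the
trace by default):

    w = Q β + ε,    w = √n Λ^(−1/2) U′ b̂_std,    Q = √n Λ^(1/2) U′,

where b̂_std are marginal effects on the standardized scale and
ε ~ N(0, σ²_e I_q) with σ²_e a nuisance parameter. SNP effects get a
point–normal ("SBayesC") or multi-component ("SBayesRC") mixture prior,

    β_j ~ Σ_k π_jk N(0, γ_k σ²_g),   γ = (0, 10⁻⁵, 10⁻⁴, 10⁻³, 10⁻²),

optionally with SNP-specific membership priors π_jk driven by functional
annotations through a sequential probit model. A Gibbs sampler (numba
kernel) draws the joint posterior; PIP_j is the post-burn-in frequency with
which SNP j is assigned a nonzero effect. Surplus mixture components are
pruned automatically during burn-in when they explain negligible genetic
variance.

On top of the fit:

* **α-LCS** — local credible sets built greedily from the top-PIP "free"
  SNP over its r² > 0.5 neighbours until ΣPIP ≥ α, reported when their
  posterior heritability-enrichment probability (PEP) exceeds 0.7;
* **α-GCS** — the smallest prefix of PIP-ranked SNPs whose PIP sum reaches
  α × (estimated number of causal variants);
* **PHE** — the proportion of SNP-based heritability a set explains,
  averaged over posterior effect draws;
* **power prediction** — the sampling law of PIP for a causal variant
  explaining variance v is PIP = 1 − 1/(1 + Σ_k A_k e^{B_k Z}) with
  Z ~ χ²₁(nv/σ²_e); integrating over the fitted effect-size mixture predicts
  power, expected discoveries, and expected PHE at any prospective n, and a
  bisection inverts that curve into a required sample size;
* **liability conversion** — case-control studies are mapped to an
  equivalent quantitative-trait sample size N_eq = i²v(1−v)N₀₁/(1−K)² under
  the threshold model, and effects/SEs are re-expressed on the liability
  scale.

A fully synthetic test-bed (blockwise-LD genotypes from thresholded latent
AR(1) Gaussians; sparse, large-effects and LD/MAF-stratified architectures;
marginal GWAS) makes every component testable without external data.

## Worked example

```python
import numpy as np
from gwfm import SimConfig, McmcConfig, simulate_and_fit

cfg = SimConfig()          # 5,000 SNPs, 10,000 individuals, h2=0.5, 1% causal
res = simulate_and_fit(cfg, "sbayesc", McmcConfig(n_iter=10_000, burn_in=2_000, seed=100))
s = res.summary
print(f"pi_nonnull = {1 - s.pi_hat[0]:.4f}")
print(f"h2_hat     = {s.h2_hat:.3f}")
print(f"m_c_hat    = {s.m_c_hat}")
print(f"mean PIP of causal SNPs = {s.pip[res.truth.causal_indices].mean():.3f}")
```

prints (seed 0 genotypes, seed 100 chain):

```
pi_nonnull = 0.0085
h2_hat     = 0.471
m_c_hat    = 42
mean PIP of causal SNPs = 0.604
```

i.e. the fit recovers the generative 1% causal fraction and h² = 0.5 (the
realized h² of this replicate is 0.513), estimates ~42 of the 50 simulated
causal variants, and concentrates posterior inclusion mass on the true
causals. The same workflow is available from the shell:

```bash
gwfm sim --config sim.yaml --out toy
gwfm fit --ma toy.ma --ldm toy.ld.h5 --model sbayesc --seed 1 --out fit
gwfm cs  --fit fit --ldm toy.ld.h5 --out fit
gwfm power --arch fit.parRes.json --n 1e5,1e6 --alpha 0.9
gwfm liability --prevalence 0.01 --cases 53386 --controls 77258 --neq
```

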