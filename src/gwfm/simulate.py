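"""Synthetic genotype/phenotype/summary-statistic generator.

Genotypes are drawn per LD block from thresholded latent Gaussians: each
individual carries two independent AR(1) latent haplotype vectors per block,
each thresholded at Phi^-1(MAF_j) to a 0/1 allele and summed to a 0/1/2
genotype.  This gives exact control of the within-block LD decay and the MAF
spectrum, independence between blocks, and Hardy-Weinberg proportions, at
the cost of some tetrachoric attenuation of the latent correlation.

Phenotypes follow an additive model y = X_c beta + e on the raw allele
scale, with the residual variance chosen as var(X_c beta) * (1/h2 - 1) so
the causal variants explain h2 of the phenotypic variance in expectation.
Three architectures are supported:

* ``sparse``       -- a fraction ``prop_causal`` of SNPs is causal with
                      effects N(0, h2/m_c);
* ``large_effects``-- ``n_large`` SNPs carry N(0, var_large/n_large) effects
                      and the remaining causals N(0, (h2-var_large)/(m_c-n_large));
* ``ldms``         -- as sparse, but causal variants are drawn only from the
                      high-LD, high-MAF quartile (median splits of
                      within-block LD score and MAF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SummaryStatRecord

ARCHITECTURES = ("sparse", "large_effects", "ldms")

#: base-pair spacing between adjacent simulated SNPs
_SNP_SPACING_BP = 1_000


@dataclass
class SimConfig:
    """Configuration of one simulated dataset.

    Defaults are desk-scale: 5,000 SNPs in 50 blocks of 100, 10,000
    individuals, 50% heritability with 1% of SNPs causal.
    """

    m: int = 5_000
    n: int = 10_000
    block_size: int = 100
    ld_rho: float | tuple[float, float] = (0.2, 0.95)
    maf_range: tuple[float, float] = (0.01, 0.5)
    architecture: str = "sparse"
    h2: float = 0.5
    prop_causal: float = 0.01
    n_large: int = 10
    var_large: float | None = None  # default 0.2 * h2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.m % self.block_size != 0:
            raise ValueError("m must be a multiple of block_size")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5 + 1e-12):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.h2 > 0 and self.architecture != "large_effects":
            if int(round(self.prop_causal * self.m)) < 1:
                raise ValueError("prop_causal * m must be at least 1")
        if self.var_large is None:
            self.var_large = 0.2 * self.h2

    @property
    def n_blocks(self) -> int:
        return self.m // self.block_size

    @property
    def m_causal(self) -> int:
        if self.architecture == "large_effects":
            return max(int(round(self.prop_causal * self.m)), self.n_large)
        return int(round(self.prop_causal * self.m))


@dataclass
class SimTruth:
    """Ground truth of a simulated phenotype."""

    causal_indices: np.ndarray
    true_beta_std: np.ndarray  # standardized-scale effects, length m
    true_beta_allele: np.ndarray  # raw allele-scale effects, length m
    architecture: str
    realized_h2: float
    large_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw a genotype matrix (n x m, int8) and per-SNP metadata.

    Returns ``(genotypes, meta)`` where ``meta`` is a DataFrame with columns
    snp, chrom, pos, a1, a2, maf, block and one row per SNP in genome order.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.maf_range
    n, bs = config.n, config.block_size
    geno = np.empty((n, config.m), dtype=np.int8)
    maf = rng.uniform(lo, hi, size=config.m)
    rho_cfg = config.ld_rho
    block_rho = np.empty(config.n_blocks)
    for b in range(config.n_blocks):
        if isinstance(rho_cfg, tuple):
            rho = rng.uniform(*rho_cfg)
        else:
            rho = float(rho_cfg)
        block_rho[b] = rho
        sl = slice(b * bs, (b + 1) * bs)
        thresh = stats.norm.ppf(maf[sl])
        scale = np.sqrt(1.0 - rho * rho)
        block_geno = np.zeros((n, bs), dtype=np.int8)
        for _hap in range(2):
            z = rng.standard_normal((n, bs))
            for j in range(1, bs):
                z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
            block_geno += (z < thresh).astype(np.int8)
        geno[:, sl] = block_geno

    meta = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(config.m)],
            "chrom": "1",
            "pos": np.arange(1, config.m + 1, dtype=np.int64) * _SNP_SPACING_BP,
            "a1": "A",
            "a2": "G",
            "maf": maf,
            "block": np.repeat(np.arange(config.n_blocks), bs),
            "block_rho": np.repeat(block_rho, bs),
        }
    )
    return geno, meta


def _ld_scores_and_maf(genotypes: np.ndarray, block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-block LD score (sum of r^2 to block members) and empirical MAF."""
    m = genotypes.shape[1]
    ld = np.empty(m)
    freq = genotypes.mean(axis=0) / 2.0
    emp_maf = np.minimum(freq, 1.0 - freq)
    for b in np.unique(block):
        idx = np.flatnonzero(block == b)
        x = genotypes[:, idx].astype(np.float64)
        x -= x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        r = (x.T @ x) / (x.shape[0] * np.outer(sd, sd))
        ld[idx] = np.sum(r * r, axis=1)
    return ld, emp_maf


def make_ldms_annotations(genotypes: np.ndarray, block: np.ndarray) -> pd.DataFrame:
    """Binary indicators for the four LD-by-MAF groups (2x2 median splits).

    Returns a DataFrame with columns ldms_<ld>{lo,hi}_<maf>{lo,hi}; every SNP
    belongs to exactly one group.
    """
    ld, maf = _ld_scores_and_maf(genotypes, block)
    hi_ld = ld >= np.median(ld)
    hi_maf = maf >= np.median(maf)
    return pd.DataFrame(
        {
            "ldms_lolo": (~hi_ld & ~hi_maf).astype(float),
            "ldms_lohi": (~hi_ld & hi_maf).astype(float),
            "ldms_hilo": (hi_ld & ~hi_maf).astype(float),
            "ldms_hihi": (hi_ld & hi_maf).astype(float),
        }
    )


def simulate_phenotype(
    genotypes: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    block: np.ndarray | None = None,
) -> tuple[np.ndarray, SimTruth]:
    """Simulate a phenotype under the configured architecture.

    ``block`` (per-SNP block labels) is required for the ``ldms``
    architecture to compute within-block LD scores.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n, m = genotypes.shape
    beta = np.zeros(m)
    large = np.empty(0, dtype=np.int64)

    if config.h2 == 0:
        y = rng.standard_normal(n)
        truth = SimTruth(
            causal_indices=np.empty(0, dtype=np.int64),
            true_beta_std=np.zeros(m),
            true_beta_allele=beta,
            architecture=config.architecture,
            realized_h2=0.0,
        )
        return y, truth

    m_c = config.m_causal
    if config.architecture == "ldms":
        if block is None:
            raise ValueError("the ldms architecture needs per-SNP block labels")
        ld, maf = _ld_scores_and_maf(genotypes, block)
        eligible = np.flatnonzero((ld >= np.median(ld)) & (maf >= np.median(maf)))
    else:
        eligible = np.arange(m)
    if len(eligible) < m_c:
        raise ValueError(f"only {len(eligible)} SNPs eligible for {m_c} causal variants")
    causal = np.sort(rng.choice(eligible, size=m_c, replace=False))

    if config.architecture == "large_effects":
        if m_c <= config.n_large:
            raise ValueError("large_effects needs more causals than n_large")
        large = np.sort(rng.choice(causal, size=config.n_large, replace=False))
        small = np.setdiff1d(causal, large)
        beta[large] = rng.normal(0.0, np.sqrt(config.var_large / config.n_large), config.n_large)
        var_small = (config.h2 - config.var_large) / (m_c - config.n_large)
        beta[small] = rng.normal(0.0, np.sqrt(var_small), len(small))
    else:
        beta[causal] = rng.normal(0.0, np.sqrt(config.h2 / m_c), m_c)

    xc = genotypes[:, causal].astype(np.float64)
    xc -= xc.mean(axis=0)
    g = xc @ beta[causal]
    var_g = g.var()
    var_e = var_g * (1.0 / config.h2 - 1.0)
    y = g + rng.normal(0.0, np.sqrt(var_e), n)

    sd_x = genotypes.astype(np.float64).std(axis=0)
    sd_y = y.std()
    truth = SimTruth(
        causal_indices=causal,
        true_beta_std=beta * sd_x / sd_y,
        true_beta_allele=beta,
        architecture=config.architecture,
        realized_h2=float(var_g / y.var()),
        large_indices=large,
    )
    return y, truth


def run_gwas(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    meta: pd.DataFrame | None = None,
    chunk: int = 512,
) -> list[SummaryStatRecord]:
    """Marginal per-SNP least-squares regression of phenotype on genotype.

    Emits .ma-style records (b, se, two-sided normal p, N, freq).
    Monomorphic SNPs get b = 0 and an se computed from a genotype-variance
    floor so they survive the file format; they are effectively uninformative.
    """
    n, m = genotypes.shape
    y = np.asarray(phenotype, dtype=np.float64)
    yc = y - y.mean()
    syy = float(yc @ yc)
    b = np.empty(m)
    se = np.empty(m)
    freq = np.empty(m)
    var_floor = 1.0 / n
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        x = genotypes[:, sl].astype(np.float64)
        xm = x.mean(axis=0)
        x -= xm
        sxx = np.einsum("ij,ij->j", x, x)
        sxy = x.T @ yc
        mono = sxx <= 0
        sxx_safe = np.where(mono, n * var_floor, sxx)
        b_sl = np.where(mono, 0.0, sxy / sxx_safe)
        rss = np.maximum(syy - b_sl * sxy, 1e-12)
        se_sl = np.sqrt(rss / ((n - 2) * sxx_safe))
        b[sl] = b_sl
        se[sl] = se_sl
        freq[sl] = xm / 2.0
    z = b / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    if meta is None:
        snp_ids = [f"rs{i + 1}" for i in range(m)]
        a1 = ["A"] * m
        a2 = ["G"] * m
        chrom = ["1"] * m
        pos = ((np.arange(m) + 1) * _SNP_SPACING_BP).tolist()
    else:
        snp_ids = meta["snp"].tolist()
        a1 = meta["a1"].tolist()
        a2 = meta["a2"].tolist()
        chrom = meta["chrom"].astype(str).tolist()
        pos = meta["pos"].tolist()

    # freq is clipped into the open interval so records pass .ma validation
    freq = np.clip(freq, 0.5 / n, 1.0 - 0.5 / n)
    return [
        SummaryStatRecord(
            snp_id=snp_ids[j],
            a1=a1[j],
            a2=a2[j],
            freq=float(freq[j]),
            b=float(b[j]),
            se=float(se[j]),
            p=float(p[j]),
            n=float(n),
            chrom=chrom[j],
            pos_bp=int(pos[j]),
        )
        for j in range(m)
    ]
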