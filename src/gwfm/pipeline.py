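"""End-to-end helpers wiring simulation, LD construction and model fitting.

These convenience functions implement the standard flow: genotypes ->
marginal GWAS -> standardized effects -> per-block eigenbases and
pseudo-data -> Gibbs fit.  They are used by the command-line interface, the
test-suite fixtures and the acceptance computations alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ldmatrix import (
    DEFAULT_VARIANCE_FRACTION,
    EigenBasis,
    PseudoData,
    build_pseudo_data,
    eigendecompose_block,
    empirical_correlation,
)
from .sampler import (
    AnnotationSet,
    McmcConfig,
    McmcSamples,
    MixtureSpec,
    PosteriorSummary,
    run_mcmc,
)
from .simulate import SimConfig, SimTruth, make_ldms_annotations, run_gwas, simulate_genotypes, simulate_phenotype
from .sumstats import SummaryStatRecord, records_to_frame, standardize_effects


def blocks_from_genotypes(
    genotypes: np.ndarray,
    block_labels: np.ndarray,
    b_std: np.ndarray,
    n_block: float,
    variance_fraction: float = DEFAULT_VARIANCE_FRACTION,
) -> tuple[list[EigenBasis], list[PseudoData]]:
    """Eigendecompose each block's sample LD and project the summary data."""
    bases: list[EigenBasis] = []
    pdata: list[PseudoData] = []
    for b in np.unique(block_labels):
        idx = np.flatnonzero(block_labels == b)
        R = empirical_correlation(genotypes[:, idx].astype(np.float64))
        basis = eigendecompose_block(R, variance_fraction)
        bases.append(basis)
        pdata.append(build_pseudo_data(b_std[idx], n_block, basis))
    return bases, pdata


def standardized_effects_array(
    records: list[SummaryStatRecord], meta: pd.DataFrame
) -> np.ndarray:
    """Align records against the panel's alleles and return b_std in panel order."""
    ref = {row.snp: (row.a1, row.a2) for row in meta.itertuples()}
    aligned, _ = standardize_effects(records, ref)
    by_id = {r.snp_id: r.b_std for r in aligned}
    return np.array([by_id[s] for s in meta["snp"]])


@dataclass
class SimFitResult:
    """Everything produced by one simulate-and-fit round."""

    config: SimConfig
    truth: SimTruth
    meta: pd.DataFrame
    records: list[SummaryStatRecord]
    bases: list[EigenBasis]
    blocks: list[PseudoData]
    samples: McmcSamples
    summary: PosteriorSummary

    @property
    def causal_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.meta), dtype=bool)
        mask[self.truth.causal_indices] = True
        return mask


def simulate_and_fit(
    sim_config: SimConfig,
    model: str = "sbayesc",
    mcmc_config: McmcConfig | None = None,
    use_ldms_annotations: bool = False,
    variance_fraction: float = DEFAULT_VARIANCE_FRACTION,
    keep_genotypes: bool = False,
) -> SimFitResult:
    """Simulate a dataset under ``sim_config`` and fit the chosen model.

    ``model`` is ``"sbayesc"`` (point-normal) or ``"sbayesrc"``
    (multi-component; with ``use_ldms_annotations`` the generator's LD/MAF
    group indicators enter the prior).
    """
    geno, meta = simulate_genotypes(sim_config)
    y, truth = simulate_phenotype(
        geno, sim_config, block=meta["block"].to_numpy()
    )
    records = run_gwas(geno, y, meta)
    frame = records_to_frame(records)
    b_std = (frame["z"] / np.sqrt(frame["z"] ** 2 + frame["N"] - 2)).to_numpy()
    bases, blocks = blocks_from_genotypes(
        geno, meta["block"].to_numpy(), b_std, sim_config.n, variance_fraction
    )

    if model == "sbayesc":
        spec = MixtureSpec.sbayesc()
        annotations = None
    elif model == "sbayesrc":
        spec = MixtureSpec.sbayesrc()
        annotations = None
        if use_ldms_annotations:
            ann = make_ldms_annotations(geno, meta["block"].to_numpy())
            annotations = AnnotationSet.from_frame(ann, standardize=False)
    else:
        raise ValueError(f"unknown model {model!r}")

    cfg = mcmc_config if mcmc_config is not None else McmcConfig()
    samples, summary = run_mcmc(blocks, spec, cfg, annotations)
    result = SimFitResult(
        config=sim_config,
        truth=truth,
        meta=meta,
        records=records,
        bases=bases,
        blocks=blocks,
        samples=samples,
        summary=summary,
    )
    if keep_genotypes:
        result.genotypes = geno  # type: ignore[attr-defined]
        result.phenotype = y  # type: ignore[attr-defined]
    return result


def perfect_ld_pair_pips(
    seed: int,
    n: int = 10_000,
    v: float = 0.005,
    m_background: int = 300,
    mcmc_config: McmcConfig | None = None,
) -> np.ndarray:
    """PIPs of a duplicated-SNP pair (r^2 = 1) with one well-powered causal member.

    The pair sits in its own LD block alongside ``m_background`` null SNPs in
    independent blocks; the causal member explains variance ``v`` of a
    standardized phenotype.  Returns the two members' PIPs.
    """
    rng = np.random.default_rng(seed)
    bg_cfg = SimConfig(m=m_background, n=n, block_size=50, h2=0.0, seed=seed)
    bg, meta = simulate_genotypes(bg_cfg)
    x = rng.binomial(2, 0.3, size=(n, 1)).astype(np.int8)
    geno = np.hstack([bg, x, x])
    xs = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std()
    y = xs * np.sqrt(v) + rng.normal(0.0, np.sqrt(1.0 - v), n)
    records = run_gwas(geno, y)
    frame = records_to_frame(records)
    b_std = (frame["z"] / np.sqrt(frame["z"] ** 2 + frame["N"] - 2)).to_numpy()
    labels = np.concatenate([meta["block"].to_numpy(), [bg_cfg.n_blocks, bg_cfg.n_blocks]])
    _, blocks = blocks_from_genotypes(geno, labels, b_std, n)
    cfg = mcmc_config if mcmc_config is not None else McmcConfig(seed=seed + 10_000)
    _, summary = run_mcmc(blocks, MixtureSpec.sbayesc(), cfg)
    return summary.pip[-2:]


def large_effect_variance_share(
    seed: int, m: int = 2_000, n: int = 2_000, prop_causal: float = 0.05
) -> float:
    """Phenotypic-variance share of the designated large-effect SNPs (one replicate).

    The default causal fraction keeps the small-effect pool polygenic (100
    causals backing the remaining variance), so the share estimator is not
    dominated by the sampling dispersion of a handful of small effects.
    """
    cfg = SimConfig(
        m=m, n=n, block_size=50, architecture="large_effects",
        prop_causal=prop_causal, seed=seed,
    )
    geno, _ = simulate_genotypes(cfg)
    y, truth = simulate_phenotype(geno, cfg)
    xl = geno[:, truth.large_indices].astype(np.float64)
    xl -= xl.mean(axis=0)
    g_large = xl @ truth.true_beta_allele[truth.large_indices]
    return float(g_large.var() / y.var())
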