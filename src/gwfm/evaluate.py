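"""Evaluation metrics for fine-mapping runs on simulated truth.

All metrics are pure functions of their inputs: PIP calibration against the
true discovery rate across 100 PIP bins, physical mapping precision
(distance of identified SNPs to the nearest causal variant), split-sample
replication rates, and out-of-sample polygenic-score prediction from
fine-mapped variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_BIN_COUNT = 10


@dataclass
class CalibrationCurve:
    """Binned PIP-vs-TDR calibration summary."""

    bin_edges: np.ndarray  # n_bins + 1 equal-width edges on [0, 1]
    mean_pip: np.ndarray  # per-bin mean PIP (NaN when empty)
    tdr: np.ndarray  # per-bin fraction of truly causal SNPs (NaN when empty)
    count: np.ndarray
    populated: np.ndarray  # bins with at least MIN_BIN_COUNT SNPs
    mean_abs_dev: float  # mean |TDR - mean PIP| over populated bins


def calibration_curve(pip: np.ndarray, truth: np.ndarray, n_bins: int = 100) -> CalibrationCurve:
    """Compare binned PIPs with the realized true discovery rate.

    ``truth`` is a boolean causal indicator aligned to ``pip``.  Bins with
    fewer than 10 SNPs are flagged as unpopulated and excluded from the
    mean absolute deviation.
    """
    pip = np.asarray(pip, dtype=np.float64)
    truth = np.asarray(truth, dtype=bool)
    if pip.size == 0:
        raise ValueError("empty input")
    if pip.shape != truth.shape:
        raise ValueError("pip and truth must be aligned")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(pip, edges[1:-1]), 0, n_bins - 1)
    count = np.bincount(idx, minlength=n_bins).astype(np.int64)
    with np.errstate(invalid="ignore"):
        mean_pip = np.bincount(idx, weights=pip, minlength=n_bins) / count
        tdr = np.bincount(idx, weights=truth.astype(float), minlength=n_bins) / count
    populated = count >= MIN_BIN_COUNT
    dev = np.abs(tdr[populated] - mean_pip[populated])
    mad = float(dev.mean()) if populated.any() else float("nan")
    return CalibrationCurve(edges, mean_pip, tdr, count, populated, mad)


@dataclass
class PrecisionSummary:
    distances: np.ndarray  # per identified SNP, bp to nearest causal
    frac_exact: float  # fraction at distance 0
    q99: float  # 99th percentile distance (bp)


def mapping_precision(
    identified_pos: np.ndarray, causal_pos: np.ndarray
) -> PrecisionSummary:
    """Distance of each identified SNP to the nearest causal variant (bp)."""
    identified_pos = np.sort(np.asarray(identified_pos, dtype=np.int64))
    causal_pos = np.sort(np.asarray(causal_pos, dtype=np.int64))
    if identified_pos.size == 0:
        return PrecisionSummary(np.empty(0, dtype=np.int64), float("nan"), float("nan"))
    if causal_pos.size == 0:
        raise ValueError("no causal positions supplied")
    right = np.searchsorted(causal_pos, identified_pos)
    left = np.clip(right - 1, 0, len(causal_pos) - 1)
    right = np.clip(right, 0, len(causal_pos) - 1)
    dist = np.minimum(
        np.abs(identified_pos - causal_pos[left]),
        np.abs(identified_pos - causal_pos[right]),
    )
    return PrecisionSummary(dist, float(np.mean(dist == 0)), float(np.percentile(dist, 99)))


def replication_rate(
    pip_discovery: np.ndarray,
    pip_replication: np.ndarray,
    discovery_alpha: float = 0.9,
    replication_thresholds: np.ndarray | None = None,
) -> dict[float, float]:
    """Fraction of discovery SNPs re-identified at each replication threshold.

    Discovery SNPs are those with discovery PIP >= ``discovery_alpha``.
    Returns NaN rates when there are no discoveries.
    """
    pip_discovery = np.asarray(pip_discovery, dtype=np.float64)
    pip_replication = np.asarray(pip_replication, dtype=np.float64)
    if pip_discovery.shape != pip_replication.shape:
        raise ValueError("discovery and replication fits must cover the same SNP set")
    if replication_thresholds is None:
        replication_thresholds = np.round(np.arange(0.1, 1.0, 0.1), 10)
    hits = pip_discovery >= discovery_alpha
    n_disc = int(hits.sum())
    out: dict[float, float] = {}
    for t in replication_thresholds:
        if n_disc == 0:
            out[float(t)] = float("nan")
        else:
            out[float(t)] = float(np.mean(pip_replication[hits] >= t))
    return out


@dataclass
class PgsResult:
    r2: float
    n_snps: int


def pgs_predict(
    beta_allele: np.ndarray,
    pip: np.ndarray,
    pip_threshold: float,
    genotypes_val: np.ndarray,
    phenotype_val: np.ndarray,
) -> PgsResult:
    """Polygenic-score prediction R^2 from fine-mapped variants.

    Scores validation individuals with allele-scale posterior-mean effects
    restricted to SNPs passing the PIP threshold, and reports the squared
    correlation with the validation phenotype.
    """
    beta_allele = np.asarray(beta_allele, dtype=np.float64)
    pip = np.asarray(pip, dtype=np.float64)
    use = pip >= pip_threshold
    n_used = int(use.sum())
    if n_used == 0:
        return PgsResult(0.0, 0)
    score = genotypes_val[:, use].astype(np.float64) @ beta_allele[use]
    if score.std() == 0 or np.std(phenotype_val) == 0:
        return PgsResult(0.0, n_used)
    r = np.corrcoef(score, phenotype_val)[0, 1]
    return PgsResult(float(r * r), n_used)
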