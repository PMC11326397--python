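"""Liability-scale conversion of case-control GWAS summary statistics.

Under the threshold model, a binary trait reflects an underlying standard
normal liability truncated at t = Phi^-1(1 - K) for population prevalence
K.  A case-control study of N01 = cases + controls with sample case
proportion v has the same power to detect a locus as a quantitative-trait
study of

    N_eq = i^2 v (1 - v) N01 / (1 - K)^2,     i = phi(t) / K

individuals (i is the mean liability of cases).  Given N_eq, per-SNP
liability-scale effects follow from the z-score and allele frequency:
se = 1 / sqrt(2 p (1-p) (N_eq + z^2)) and b = z * se, which leaves z and
p-values unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass
class LiabilityParams:
    """Threshold-model quantities for one disease study."""

    k_prev: float  # population prevalence
    v_prev: float  # sample case proportion
    n01: float  # total cases + controls
    t: float  # liability threshold Phi^-1(1 - K)
    h: float  # normal density at t
    i_mean: float  # mean liability of cases, h / K
    neq: float  # equivalent quantitative-trait sample size


def _check_prevalence(k_prev: float, v_prev: float) -> None:
    if not 0.0 < k_prev < 1.0:
        raise ValueError("population prevalence must lie strictly in (0, 1)")
    if not 0.0 < v_prev < 1.0:
        raise ValueError("sample case proportion must lie strictly in (0, 1)")


def liability_params(k_prev: float, v_prev: float, n01: float) -> LiabilityParams:
    _check_prevalence(k_prev, v_prev)
    t = norm.ppf(1.0 - k_prev)
    h = norm.pdf(t)
    i_mean = h / k_prev
    neq = i_mean**2 * v_prev * (1.0 - v_prev) * n01 / (1.0 - k_prev) ** 2
    return LiabilityParams(k_prev, v_prev, n01, float(t), float(h), float(i_mean), float(neq))


def equivalent_n(k_prev: float, v_prev: float, n01: float) -> float:
    """Equivalent quantitative-trait sample size of a case-control study."""
    return liability_params(k_prev, v_prev, n01).neq


def convert_to_liability(
    z: np.ndarray, freq: np.ndarray, neq: float
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal effect and standard error on the liability scale.

    Preserves z = b/se (hence p-values) exactly.
    """
    z = np.asarray(z, dtype=np.float64)
    freq = np.asarray(freq, dtype=np.float64)
    if np.any((freq <= 0) | (freq >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    se = 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * (neq + z**2))
    return z * se, se


def cases_required(neq: float, k_prev: float, v_prev: float = 0.5) -> float:
    """Number of cases needed to match an equivalent sample size.

    Inverse of :func:`equivalent_n`: the case count is v * N01 where N01
    solves the equivalent-sample-size relation at the given prevalence and
    case proportion.
    """
    _check_prevalence(k_prev, v_prev)
    t = norm.ppf(1.0 - k_prev)
    i_mean = norm.pdf(t) / k_prev
    n01 = (1.0 - k_prev) ** 2 * neq / (i_mean**2 * v_prev * (1.0 - v_prev))
    return v_prev * n01
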