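"""Analytic prediction of fine-mapping power at prospective sample sizes.

For a causal variant explaining variance v (standardized scale), the PIP it
would receive from the mixture model at sample size n follows

    PIP = 1 - 1 / (1 + sum_k A_k exp{B_k Z}),   Z ~ chi2_1(ncp = n v / sigma_e2)

with A_k = (pi_k / pi_1) sqrt(lam_k / C_k), B_k = n / (2 C_k),
lam_k = sigma_e2 / (gamma_k sigma_g2) and C_k = n + lam_k.  Monte Carlo
draws of Z turn this law into estimates of the power Pr(PIP > alpha | v);
integrating v over the fitted effect-size mixture (by sampling effects and
squaring) gives the genome-wide power, the expected number of identified
causal variants M (1 - pi_1) * power, and the expected proportion of
heritability they explain.  Inverting the predicted curve over n yields the
sample size required to reach a target power or PHE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp


@dataclass
class GeneticArchitecture:
    """Fitted mixture description sufficient for power prediction."""

    pi: np.ndarray  # K proportions, first = null
    gammas: np.ndarray  # K variance scalings, first = 0
    sigma_g2: float  # genetic variance scale
    h2: float  # SNP-based heritability
    M: int  # SNP panel size
    sigma_e2: float | None = None  # defaults to 1 - h2 (standardized scale)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=np.float64)
        self.gammas = np.asarray(self.gammas, dtype=np.float64)
        if len(self.pi) != len(self.gammas):
            raise ValueError("pi and gammas must have the same length")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-6):
            raise ValueError("mixture proportions must sum to 1")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.sigma_e2 is None:
            self.sigma_e2 = 1.0 - self.h2

    @property
    def pi_nonnull(self) -> float:
        return float(1.0 - self.pi[0])

    @classmethod
    def from_fit(cls, summary, M: int | None = None) -> "GeneticArchitecture":
        """Build an architecture from a :class:`~gwfm.sampler.PosteriorSummary`.

        For the point-normal model (gamma = (0, 1)) the slab variance is
        re-expressed relative to the heritability, so that sigma_g2 equals
        the total genetic variance as the power equations assume.
        """
        gammas = np.asarray(summary.gammas, dtype=np.float64)
        pi = np.asarray(summary.pi_hat, dtype=np.float64)
        h2 = float(summary.h2_hat)
        if len(gammas) == 2 and gammas[1] == 1.0 and h2 > 0:
            sigma_g2 = h2
            gammas = np.array([0.0, summary.sigma_g2_hat / h2])
        else:
            sigma_g2 = float(summary.sigma_g2_hat)
        return cls(
            pi=pi / pi.sum(),
            gammas=gammas,
            sigma_g2=sigma_g2,
            h2=h2,
            M=int(M if M is not None else len(summary.pip)),
        )


def _law_constants(arch: GeneticArchitecture, n: float):
    """(log A_k, B_k) over non-null components with positive mass."""
    if arch.sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    mask = arch.pi[1:] > 0
    gam = arch.gammas[1:][mask]
    pi_k = arch.pi[1:][mask]
    if arch.pi[0] <= 0 or len(gam) == 0 or arch.sigma_g2 <= 0:
        return None
    lam = arch.sigma_e2 / (gam * arch.sigma_g2)
    ck = n + lam
    log_a = np.log(pi_k / arch.pi[0]) + 0.5 * (np.log(lam) - np.log(ck))
    b = n / (2.0 * ck)
    return log_a, b


def sample_pip_law(
    v: float,
    n: float,
    arch: GeneticArchitecture,
    n_draws: int = 10_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draws from the sampling distribution of PIP for a causal variant.

    Z is drawn as (G + sqrt(ncp))^2 with G standard normal, and the PIP is
    evaluated stably as expit(logsumexp(log A_k + B_k Z)).
    """
    if v < 0:
        raise ValueError("v must be non-negative")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(0) if rng is None else rng
    consts = _law_constants(arch, n)
    if consts is None:
        return np.zeros(n_draws)
    log_a, b = consts
    ncp = n * v / arch.sigma_e2
    g = rng.standard_normal(n_draws)
    z = (g + np.sqrt(ncp)) ** 2
    s = logsumexp(log_a[None, :] + b[None, :] * z[:, None], axis=1)
    return expit(s)


def power_given_v(
    v: float,
    n: float,
    alpha: float,
    arch: GeneticArchitecture,
    n_draws: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo estimate of Pr(PIP > alpha) for a variant explaining v."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    pips = sample_pip_law(v, n, arch, n_draws=n_draws, rng=rng)
    return float(np.mean(pips > alpha))


@dataclass
class PowerPrediction:
    power: float
    expected_ncv: float
    expected_phe: float
    n: float


def predict_power_phe(
    arch: GeneticArchitecture,
    n: float,
    alpha: float = 0.9,
    n_mc: int = 100_000,
    rng: np.random.Generator | None = None,
    draws_per_v: int = 8,
) -> PowerPrediction:
    """Predict power, expected discoveries, and expected PHE at sample size n.

    Causal effects are sampled from the fitted mixture (component by the
    non-null proportions, then N(0, gamma_k sigma_g2)) and squared to give
    v; each v receives ``draws_per_v`` PIP-law draws.  The expected PHE is
    M (1 - pi_1) / sigma_g2 * E[1{PIP > alpha} v], clipped to [0, 1].
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if arch.pi_nonnull <= 0 or arch.sigma_g2 <= 0:
        return PowerPrediction(0.0, 0.0, 0.0, n)
    consts = _law_constants(arch, n)
    if consts is None:
        return PowerPrediction(0.0, 0.0, 0.0, n)
    log_a, b = consts

    p_comp = arch.pi[1:] / arch.pi_nonnull
    mask = p_comp > 0
    comp_sd = np.sqrt(arch.gammas[1:] * arch.sigma_g2)
    comp = rng.choice(np.flatnonzero(mask), size=n_mc, p=p_comp[mask])
    beta = rng.standard_normal(n_mc) * comp_sd[comp]
    v = beta**2

    ncp = n * v / arch.sigma_e2
    hits = np.zeros(n_mc)
    for _ in range(draws_per_v):
        g = rng.standard_normal(n_mc)
        z = (g + np.sqrt(ncp)) ** 2
        s = logsumexp(log_a[None, :] + b[None, :] * z[:, None], axis=1)
        hits += expit(s) > alpha
    power_v = hits / draws_per_v

    power = float(power_v.mean())
    n_causal = arch.M * arch.pi_nonnull
    expected_ncv = float(min(n_causal * power, n_causal))
    expected_phe = float(np.clip(n_causal / arch.sigma_g2 * np.mean(power_v * v), 0.0, 1.0))
    return PowerPrediction(power, expected_ncv, expected_phe, n)


@dataclass
class SampleSizeResult:
    n: float | None
    reachable: bool
    achieved: float
    asymptote: float
    target: str
    value: float


def required_sample_size(
    arch: GeneticArchitecture,
    target: str,
    value: float,
    alpha: float = 0.9,
    n_mc: int = 50_000,
    n_min: float = 1e3,
    n_max: float = 1e9,
    tol: float = 0.005,
    seed: int = 0,
) -> SampleSizeResult:
    """Smallest sample size at which a predicted metric reaches a target.

    ``target`` is ``"power"`` or ``"phe"``.  Bisection runs on log n with a
    common random seed per evaluation so the predicted curve is monotone up
    to Monte Carlo error; an unachievable target returns an explicit
    not-reachable result carrying the asymptote estimate.
    """
    if target not in ("power", "phe"):
        raise ValueError("target must be 'power' or 'phe'")

    def metric(n: float) -> float:
        pred = predict_power_phe(
            arch, n, alpha=alpha, n_mc=n_mc, rng=np.random.default_rng(seed)
        )
        return pred.power if target == "power" else pred.expected_phe

    hi_val = metric(n_max)
    if hi_val < value:
        return SampleSizeResult(None, False, hi_val, hi_val, target, value)
    lo_val = metric(n_min)
    if lo_val >= value:
        return SampleSizeResult(n_min, True, lo_val, hi_val, target, value)

    lo, hi = np.log(n_min), np.log(n_max)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        mv = metric(np.exp(mid))
        if mv >= value:
            hi = mid
        else:
            lo = mid
        if abs(mv - value) < tol and mv >= value:
            break
    n_star = float(np.exp(hi))
    return SampleSizeResult(n_star, True, metric(n_star), hi_val, target, value)
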