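"""MCMC Gibbs samplers for summary-statistics Bayesian mixture models.

Two priors on joint SNP effects are supported, both fitted to the low-rank
pseudo-data w = Q beta + eps of every LD block jointly:

* point-normal ("SBayesC"): beta_j ~ pi N(0, sigma_b^2) + (1 - pi) delta_0,
  with sigma_b^2 given a scaled-inverse-chi-square hyperprior and pi a
  uniform prior.  Internally this is the K = 2 case of the general mixture
  with gamma = (0, 1), so sigma_g2 coincides with the slab variance.
* multi-component annotation-aware mixture ("SBayesRC"):
  beta_j ~ sum_k pi_jk N(0, gamma_k sigma_g2) with fixed variance scalings
  gamma = (0, 1e-5, 1e-4, 1e-3, 1e-2) and, when annotations are supplied,
  SNP-specific membership priors pi_jk built from a sequential-probit
  (stick-breaking) generalized linear model on the annotation values.

Posterior inclusion probabilities are the post-burn-in frequencies of
non-null component membership.  The number of mixture components can be
pruned automatically early in the chain: at periodic checkpoints the
smallest-variance non-null component is dropped when the genetic variance
it explains falls below half of that in the second smallest component, and
burn-in restarts after each removal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri
from scipy.stats import multivariate_normal

from ._gibbs import sweep_block
from .ldmatrix import PseudoData

DEFAULT_GAMMAS_RC = (0.0, 1e-5, 1e-4, 1e-3, 1e-2)

_SIGMA_E2_FLOOR = 1e-6
_SIGMA_G2_FLOOR = 1e-12
_HYPER_NU = 4.0  # scaled-inverse-chi-square hyperprior degrees of freedom
_PROBIT_RIDGE = 1e-6
#: weakly-informative N(0, 100) prior on probit intercepts/annotation effects;
#: keeps stages with (near-)pure outcomes from drifting to +/- infinity
_PROBIT_PRIOR_PRECISION = 0.01


class ConfigError(ValueError):
    pass


@dataclass
class MixtureSpec:
    """Variance-scaling coefficients of the effect-size mixture."""

    gammas: np.ndarray

    def __post_init__(self) -> None:
        self.gammas = np.asarray(self.gammas, dtype=np.float64)
        if self.gammas[0] != 0.0:
            raise ConfigError("the first mixture coefficient must be 0 (null component)")
        if np.any(np.diff(self.gammas) <= 0):
            raise ConfigError("mixture coefficients must be strictly increasing")

    @property
    def K(self) -> int:
        return len(self.gammas)

    @classmethod
    def sbayesc(cls) -> "MixtureSpec":
        return cls(np.array([0.0, 1.0]))

    @classmethod
    def sbayesrc(cls) -> "MixtureSpec":
        return cls(np.array(DEFAULT_GAMMAS_RC))


@dataclass
class AnnotationSet:
    """Per-SNP annotation values (m x C); continuous columns standardized."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if np.any(~np.isfinite(self.matrix)):
            raise ConfigError("annotation matrix must be finite (no missing values)")

    @classmethod
    def from_frame(cls, df, standardize: bool = True) -> "AnnotationSet":
        mat = df.to_numpy(dtype=np.float64)
        if standardize:
            for c in range(mat.shape[1]):
                col = mat[:, c]
                if not set(np.unique(col)).issubset({0.0, 1.0}):
                    sd = col.std()
                    mat[:, c] = (col - col.mean()) / (sd if sd > 0 else 1.0)
        return cls(mat, list(df.columns))


@dataclass
class AnnotationEffects:
    """Sequential-probit coefficients: stage k models Pr(delta > k | delta >= k)."""

    mu: np.ndarray  # (K-1,)
    alpha: np.ndarray  # (C, K-1)


@dataclass
class McmcConfig:
    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 0
    prune_check_every: int = 500
    auto_prune: bool = False
    update_pi: bool = True
    update_sigma: bool = True
    random_scan: bool = False
    init_pi: np.ndarray | None = None
    init_sigma_g2: float | None = None
    init_sigma_e2: float = 1.0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ConfigError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be at least 1")


@dataclass
class SnpConditional:
    """Single-SNP conditional posterior quantities."""

    r: float
    lambda_k: np.ndarray  # per non-null component
    c_k: np.ndarray
    comp_prob: np.ndarray  # length K, sums to 1


def snp_component_probs(
    r: float,
    n: float,
    sigma_e2: float,
    sigma_g2: float,
    pi_j: np.ndarray,
    spec: MixtureSpec,
) -> SnpConditional:
    """Conditional component-membership probabilities for one SNP.

    ``r`` is the adjusted projected statistic Q_j'eps + n beta_j.  Computed
    in log space with max-subtraction; the non-null weight of component k is
    pi_jk sqrt(lam_k/C_k) exp{r^2/(2 C_k sigma_e2)}.
    """
    pi_j = np.asarray(pi_j, dtype=np.float64)
    if not np.isfinite(r):
        raise ValueError("r must be finite")
    if np.any(pi_j[1:] > 0) and sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive when non-null mass exists")
    gam = spec.gammas[1:]
    lam = sigma_e2 / (gam * max(sigma_g2, _SIGMA_G2_FLOOR))
    ck = n + lam
    with np.errstate(divide="ignore"):
        logw = np.concatenate(
            (
                [np.log(pi_j[0]) if pi_j[0] > 0 else -np.inf],
                np.where(
                    pi_j[1:] > 0,
                    np.log(np.where(pi_j[1:] > 0, pi_j[1:], 1.0))
                    + 0.5 * np.log(lam / ck)
                    + r * r / (2.0 * ck * sigma_e2),
                    -np.inf,
                ),
            )
        )
    logw -= logw.max()
    w = np.exp(logw)
    return SnpConditional(r=float(r), lambda_k=lam, c_k=ck, comp_prob=w / w.sum())


def auto_prune_components(
    shares: np.ndarray, spec: MixtureSpec
) -> tuple[MixtureSpec, int | None]:
    """Apply the component-pruning rule once.

    ``shares`` holds the genetic variance explained by each non-null
    component, ordered by ascending gamma.  Components are ranked by the
    variance they explain: the smallest is removed when its share is
    strictly less than half of the second smallest's.  (A component that
    explains essentially no variance is either a surplus small-effect
    component or one that merely absorbs null SNPs by chance; both distort
    PIPs and the causal-count estimate.)  Models cannot be pruned below
    K = 2.

    Returns the (possibly reduced) spec and the removed component's index
    (1-based among all components), or None if nothing was removed.
    """
    if spec.K <= 2:
        return spec, None
    shares = np.asarray(shares, dtype=np.float64)
    if shares.shape[0] != spec.K - 1:
        raise ValueError("one variance share per non-null component is required")
    order = np.argsort(shares, kind="stable")
    smallest, second = shares[order[0]], shares[order[1]]
    if smallest < 0.5 * second:
        k_rm = int(order[0]) + 1
        new = MixtureSpec(np.delete(spec.gammas, k_rm))
        return new, k_rm
    return spec, None


@dataclass
class ModelState:
    """Full sampler state (arrays are genome-wide, blocks hold residuals)."""

    beta: np.ndarray
    delta: np.ndarray  # 0-based labels, 0 = null
    sigma_e2: float
    sigma_g2: float
    pi: np.ndarray  # (K,) global proportions (no-annotation mode)
    log_pi_snp: np.ndarray  # (m, K) per-SNP log prior membership
    residuals: list[np.ndarray]  # per-block eps = w - Q beta
    spec: MixtureSpec
    annotation_effects: AnnotationEffects | None = None

    def recompute_residuals(self, blocks: list[PseudoData], offsets: np.ndarray) -> list[np.ndarray]:
        """Residuals recomputed from scratch (bookkeeping check)."""
        out = []
        for b, blk in enumerate(blocks):
            sl = slice(offsets[b], offsets[b] + blk.m_block)
            out.append(blk.w - blk.q_mat @ self.beta[sl])
        return out


@dataclass
class McmcSamples:
    """Thinned posterior draws retained after burn-in."""

    beta: np.ndarray  # (n_draws, m)
    nonnull: np.ndarray  # (n_draws, m) bool
    sigma_e2: np.ndarray
    sigma_g2: np.ndarray
    h2: np.ndarray
    pi: np.ndarray  # (n_draws, K_final)
    gammas: np.ndarray
    annot_mu: np.ndarray | None = None  # (n_draws, K_final - 1)
    annot_alpha: np.ndarray | None = None  # (n_draws, C, K_final - 1)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]


@dataclass
class PosteriorSummary:
    pip: np.ndarray
    beta_mean: np.ndarray
    pi_hat: np.ndarray
    h2_hat: float
    sigma_e2_hat: float
    sigma_g2_hat: float
    m_c_hat: int
    gammas: np.ndarray
    pruning_history: list[tuple[int, float]] = field(default_factory=list)


def _block_arrays(blocks: list[PseudoData]):
    qts = [blk.qt() for blk in blocks]
    diags = [blk.diag_qtq() for blk in blocks]
    offsets = np.concatenate(([0], np.cumsum([blk.m_block for blk in blocks])))[:-1]
    m = int(sum(blk.m_block for blk in blocks))
    return qts, diags, offsets, m


def _init_pi(K: int) -> np.ndarray:
    pi = np.empty(K)
    pi[0] = 0.95
    pi[1:] = 0.05 / (K - 1)
    return pi


def _plugin_h2(blocks: list[PseudoData]) -> float:
    """Crude heritability plug-in from the projected data: E[w'w] = q sigma_e2 + n varg."""
    sw2 = sum(float(blk.w @ blk.w) for blk in blocks)
    qtot = sum(blk.q for blk in blocks)
    n = np.median([blk.n_block for blk in blocks])
    return float(np.clip((sw2 - qtot) / (n * 1.0), 0.01, 0.9))


def _stick_break_log_pi(eta: np.ndarray) -> np.ndarray:
    """Per-SNP log membership probabilities from stage linear predictors.

    eta: (m, K-1); stage k gives Pr(delta > k | delta >= k) = Phi(eta_k).
    Returns (m, K) log probabilities summing to one per SNP.
    """
    m, n_stage = eta.shape
    K = n_stage + 1
    log_up = log_ndtr(eta)  # log Phi
    log_stop = log_ndtr(-eta)  # log (1 - Phi)
    out = np.empty((m, K))
    cum = np.zeros(m)
    for k in range(n_stage):
        out[:, k] = cum + log_stop[:, k]
        cum = cum + log_up[:, k]
    out[:, K - 1] = cum
    return out


def _sample_truncnorm(eta: np.ndarray, positive: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Latent probit residuals truncated to the sign implied by the outcome."""
    u = rng.random(eta.shape[0])
    phi_neg = ndtr(-eta)
    cdf = np.where(positive, phi_neg + u * (1.0 - phi_neg), u * phi_neg)
    cdf = np.clip(cdf, 1e-12, 1.0 - 1e-12)
    return eta + ndtri(cdf)


class GibbsModel:
    """Stateful Gibbs sampler over the concatenated block systems."""

    def __init__(
        self,
        blocks: list[PseudoData],
        spec: MixtureSpec,
        config: McmcConfig,
        annotations: AnnotationSet | None = None,
    ):
        if not blocks:
            raise ConfigError("at least one block is required")
        self.blocks = blocks
        self.config = config
        self.annotations = annotations
        self.rng = np.random.default_rng(config.seed)
        self.qts, self.diags, self.offsets, self.m = _block_arrays(blocks)
        if annotations is not None and annotations.matrix.shape[0] != self.m:
            raise ConfigError("annotation matrix is not aligned to the SNP set")
        self.state = self._init_state(spec)

    def _init_state(self, spec: MixtureSpec) -> ModelState:
        cfg = self.config
        K = spec.K
        pi = np.asarray(cfg.init_pi, dtype=np.float64) if cfg.init_pi is not None else _init_pi(K)
        if len(pi) != K:
            raise ConfigError("init_pi length must match the number of components")
        h2_plug = _plugin_h2(self.blocks)
        if cfg.init_sigma_g2 is not None:
            sigma_g2 = float(cfg.init_sigma_g2)
        elif K == 2 and spec.gammas[1] == 1.0:
            # point-normal: slab variance ~ h2 / expected causal count
            sigma_g2 = h2_plug / max(pi[1] * self.m, 1.0)
        else:
            sigma_g2 = h2_plug
        ann_eff = None
        if self.annotations is not None:
            C = self.annotations.matrix.shape[1]
            # intercepts matching the initial global proportions
            mu = np.empty(K - 1)
            rest = 1.0
            for k in range(K - 1):
                p_up = np.clip(1.0 - pi[k] / max(rest, 1e-12), 1e-6, 1 - 1e-6)
                mu[k] = ndtri(p_up)
                rest -= pi[k]
            ann_eff = AnnotationEffects(mu=mu, alpha=np.zeros((C, K - 1)))
            eta = mu[None, :] + self.annotations.matrix @ ann_eff.alpha
            log_pi_snp = _stick_break_log_pi(eta)
        else:
            log_pi_snp = np.tile(np.log(pi), (self.m, 1))
        state = ModelState(
            beta=np.zeros(self.m),
            delta=np.zeros(self.m, dtype=np.int64),
            sigma_e2=float(cfg.init_sigma_e2),
            sigma_g2=sigma_g2,
            pi=pi,
            log_pi_snp=np.ascontiguousarray(log_pi_snp),
            residuals=[blk.w.copy() for blk in self.blocks],
            spec=spec,
            annotation_effects=ann_eff,
        )
        self._hyper_scale_g = sigma_g2  # scaled-inv-chi2 scales fixed at initialization
        self._hyper_scale_e = float(cfg.init_sigma_e2)
        return state

    # ------------------------------------------------------------------ sweeps

    def sweep(self) -> ModelState:
        """One full Gibbs sweep: all SNPs, then hyperparameters."""
        st = self.state
        comp_var = st.spec.gammas * max(st.sigma_g2, _SIGMA_G2_FLOOR)
        comp_var[0] = 1.0  # unused slot; keeps the kernel division safe
        for b, blk in enumerate(self.blocks):
            sl = slice(self.offsets[b], self.offsets[b] + blk.m_block)
            if self.config.random_scan:
                order = self.rng.permutation(blk.m_block)
            else:
                order = np.arange(blk.m_block)
            sweep_block(
                self.qts[b],
                self.diags[b],
                st.residuals[b],
                st.beta[sl],
                st.delta[sl],
                st.log_pi_snp[sl],
                comp_var,
                st.sigma_e2,
                order,
                self.rng,
            )
        self._update_hyperparameters()
        return st

    def _update_hyperparameters(self) -> None:
        st = self.state
        cfg = self.config
        K = st.spec.K
        counts = np.bincount(st.delta, minlength=K).astype(np.float64)

        if cfg.update_pi:
            if self.annotations is None:
                st.pi = self.rng.dirichlet(counts + 1.0)
                np.copyto(st.log_pi_snp, np.log(np.clip(st.pi, 1e-300, None))[None, :])
            else:
                self._update_annotation_effects()
                pi_bar = np.exp(st.log_pi_snp).mean(axis=0)
                st.pi = pi_bar / pi_bar.sum()

        if cfg.update_sigma:
            nonnull = st.delta > 0
            m_nn = float(nonnull.sum())
            ssq = 0.0
            if m_nn:
                ssq = float(np.sum(st.beta[nonnull] ** 2 / st.spec.gammas[st.delta[nonnull]]))
            df = _HYPER_NU + m_nn
            st.sigma_g2 = max(
                (_HYPER_NU * self._hyper_scale_g + ssq) / self.rng.chisquare(df),
                _SIGMA_G2_FLOOR,
            )
            sse = sum(float(eps @ eps) for eps in st.residuals)
            q_tot = sum(blk.q for blk in self.blocks)
            df_e = _HYPER_NU + q_tot
            st.sigma_e2 = max(
                (_HYPER_NU * self._hyper_scale_e + sse) / self.rng.chisquare(df_e),
                _SIGMA_E2_FLOOR,
            )

    def _update_annotation_effects(self) -> None:
        """Albert-Chib update of the sequential-probit annotation model."""
        st = self.state
        A = self.annotations.matrix
        eff = st.annotation_effects
        K = st.spec.K
        for k in range(K - 1):
            in_stage = st.delta >= k
            if not np.any(in_stage):
                continue
            y_up = st.delta[in_stage] > k
            X = np.column_stack((np.ones(int(in_stage.sum())), A[in_stage]))
            theta = np.concatenate(([eff.mu[k]], eff.alpha[:, k]))
            eta = X @ theta
            z = _sample_truncnorm(eta, y_up, self.rng)
            xtx = X.T @ X + (_PROBIT_PRIOR_PRECISION + _PROBIT_RIDGE) * np.eye(X.shape[1])
            chol = np.linalg.cholesky(np.linalg.inv(xtx))
            mean = np.linalg.solve(xtx, X.T @ z)
            theta_new = mean + chol @ self.rng.standard_normal(X.shape[1])
            eff.mu[k] = theta_new[0]
            eff.alpha[:, k] = theta_new[1:]
        eta_all = eff.mu[None, :] + A @ eff.alpha
        np.copyto(st.log_pi_snp, _stick_break_log_pi(eta_all))

    # ------------------------------------------------------------------ pruning

    def prune(self, shares: np.ndarray) -> int | None:
        """Apply the pruning rule; on removal, null out the affected SNPs."""
        new_spec, k_rm = auto_prune_components(shares, self.state.spec)
        if k_rm is None:
            return None
        st = self.state
        gone = st.delta == k_rm
        for b, blk in enumerate(self.blocks):
            sl = slice(self.offsets[b], self.offsets[b] + blk.m_block)
            local = gone[sl]
            if np.any(local):
                st.residuals[b] += blk.q_mat[:, local] @ st.beta[sl][local]
        st.beta[gone] = 0.0
        st.delta[gone] = 0
        st.delta[st.delta > k_rm] -= 1
        st.spec = new_spec
        if self.annotations is None:
            pi = np.delete(st.pi, k_rm)
            pi[0] += st.pi[k_rm]
            st.pi = pi / pi.sum()
            st.log_pi_snp = np.ascontiguousarray(
                np.tile(np.log(np.clip(st.pi, 1e-300, None)), (self.m, 1))
            )
        else:
            # re-initialize the annotation model for the reduced component set
            pi = np.delete(st.pi, k_rm)
            pi[0] += st.pi[k_rm]
            pi = np.clip(pi / pi.sum(), 1e-6, 1.0)
            K = new_spec.K
            mu = np.empty(K - 1)
            rest = 1.0
            for k in range(K - 1):
                p_up = np.clip(1.0 - pi[k] / max(rest, 1e-12), 1e-6, 1 - 1e-6)
                mu[k] = ndtri(p_up)
                rest -= pi[k]
            C = self.annotations.matrix.shape[1]
            st.annotation_effects = AnnotationEffects(mu=mu, alpha=np.zeros((C, K - 1)))
            eta = mu[None, :] + self.annotations.matrix @ st.annotation_effects.alpha
            st.log_pi_snp = np.ascontiguousarray(_stick_break_log_pi(eta))
        st.pi = np.asarray(st.pi)
        return k_rm

    # ------------------------------------------------------------------ helpers

    def genetic_variance(self) -> float:
        """Current-draw genetic variance sum_b ||Q beta||^2 / n_b."""
        var_g = 0.0
        for b, blk in enumerate(self.blocks):
            qb = blk.w - self.state.residuals[b]
            var_g += float(qb @ qb) / blk.n_block
        return var_g

    def null_fraction(self) -> float:
        """Current prior null mass averaged over SNPs."""
        if self.annotations is None:
            return float(self.state.pi[0])
        return float(np.exp(self.state.log_pi_snp[:, 0]).mean())


def gibbs_sweep(model: GibbsModel) -> ModelState:
    """Advance the sampler by one full sweep and return the state."""
    return model.sweep()


def run_mcmc(
    blocks: list[PseudoData],
    spec: MixtureSpec,
    config: McmcConfig,
    annotations: AnnotationSet | None = None,
) -> tuple[McmcSamples, PosteriorSummary]:
    """Run the Gibbs sampler and summarize the posterior.

    PIPs use every post-burn-in iteration via running counts; effect draws
    are stored every ``thin`` iterations for credible-set statistics.  When
    ``config.auto_prune`` is set, component pruning checkpoints run every
    ``prune_check_every`` iterations until no component is removed, and each
    removal restarts the burn-in clock.
    """
    model = GibbsModel(blocks, spec, config, annotations)
    m = model.m
    cfg = config

    pip_counts = np.zeros(m)
    beta_sum = np.zeros(m)
    pi_sum = None
    h2_sum = 0.0
    sig_e_sum = 0.0
    sig_g_sum = 0.0
    null_frac_sum = 0.0
    n_kept = 0

    beta_draws: list[np.ndarray] = []
    nonnull_draws: list[np.ndarray] = []
    h2_draws: list[float] = []
    sig_e_draws: list[float] = []
    sig_g_draws: list[float] = []
    pi_draws: list[np.ndarray] = []
    mu_draws: list[np.ndarray] = []
    alpha_draws: list[np.ndarray] = []
    pruning_history: list[tuple[int, float]] = []

    # Pruning checkpoints run every prune_check_every iterations for as long
    # as the chain is inside a burn-in phase; each removal restarts burn-in,
    # and retention begins once a full burn-in passes without a removal.
    # Shares are averaged over a short trailing window before the checkpoint,
    # so a component the chain has effectively abandoned shows ~zero share.
    prune_on = cfg.auto_prune and spec.K > 2
    share_window = min(100, cfg.prune_check_every)
    share_acc = np.zeros(spec.K - 1)
    share_n = 0
    burn_start = 0  # iteration index at which the burn-in clock last started

    for it in range(cfg.n_iter):
        st = model.sweep()

        in_burnin = (it + 1 - burn_start) <= cfg.burn_in
        if prune_on and st.spec.K > 2 and in_burnin:
            phase = (it - burn_start) % cfg.prune_check_every
            if phase >= cfg.prune_check_every - share_window:
                for k in range(1, st.spec.K):
                    sel = st.delta == k
                    share_acc[k - 1] += float(np.sum(st.beta[sel] ** 2))
                share_n += 1
            if (it + 1 - burn_start) % cfg.prune_check_every == 0:
                shares = share_acc / max(share_n, 1)
                gammas_before = st.spec.gammas.copy()
                k_rm = model.prune(shares)
                if k_rm is not None:
                    pruning_history.append((it + 1, float(gammas_before[k_rm])))
                    burn_start = it + 1
                share_acc = np.zeros(model.state.spec.K - 1)
                share_n = 0

        kept_iter = it + 1 - burn_start - cfg.burn_in
        if kept_iter > 0:
            st = model.state
            pip_counts += st.delta > 0
            beta_sum += st.beta
            # On the standardized scale the phenotypic variance is 1 by
            # construction, so the heritability draw is the genetic variance
            # itself.  (The residual variance sigma_e2 of the block-projected
            # systems absorbs the genetic signal of all *other* blocks in
            # addition to the true residual, so varg/(varg + sigma_e2) would
            # double-count genetic variance and bias h2 downward.)
            var_g = model.genetic_variance()
            h2 = min(var_g, 1.0)
            h2_sum += h2
            sig_e_sum += st.sigma_e2
            sig_g_sum += st.sigma_g2
            null_frac_sum += model.null_fraction()
            if pi_sum is None or len(pi_sum) != st.spec.K:
                pi_sum = np.zeros(st.spec.K)
                # a pruning event after burn-in would invalidate earlier sums;
                # pruning checkpoints stop before then by construction
            pi_sum += st.pi
            n_kept += 1
            if kept_iter % cfg.thin == 0:
                beta_draws.append(st.beta.copy())
                nonnull_draws.append(st.delta > 0)
                h2_draws.append(h2)
                sig_e_draws.append(st.sigma_e2)
                sig_g_draws.append(st.sigma_g2)
                pi_draws.append(st.pi.copy())
                if st.annotation_effects is not None:
                    mu_draws.append(st.annotation_effects.mu.copy())
                    alpha_draws.append(st.annotation_effects.alpha.copy())

    if n_kept == 0:
        raise ConfigError(
            "no retained draws: chain too short for burn-in (possibly after pruning restarts)"
        )

    pip = pip_counts / n_kept
    null_hat = null_frac_sum / n_kept
    samples = McmcSamples(
        beta=np.array(beta_draws),
        nonnull=np.array(nonnull_draws, dtype=bool),
        sigma_e2=np.array(sig_e_draws),
        sigma_g2=np.array(sig_g_draws),
        h2=np.array(h2_draws),
        pi=np.array(pi_draws),
        gammas=model.state.spec.gammas.copy(),
        annot_mu=np.array(mu_draws) if mu_draws else None,
        annot_alpha=np.array(alpha_draws) if alpha_draws else None,
    )
    summary = PosteriorSummary(
        pip=pip,
        beta_mean=beta_sum / n_kept,
        pi_hat=pi_sum / n_kept,
        h2_hat=h2_sum / n_kept,
        sigma_e2_hat=sig_e_sum / n_kept,
        sigma_g2_hat=sig_g_sum / n_kept,
        m_c_hat=int(round(m * (1.0 - null_hat))),
        gammas=model.state.spec.gammas.copy(),
        pruning_history=pruning_history,
    )
    return samples, summary


def exact_posterior_small(
    b_std: np.ndarray,
    R: np.ndarray,
    n: float,
    pi: float,
    sigma_b2: float,
    sigma_e2: float,
    max_m: int = 12,
) -> np.ndarray:
    """Exact PIPs on a small system by enumerating causal configurations.

    Works on the projected system w = Q beta + eps (rank-deficient R is
    handled by dropping null-space directions), where the marginal likelihood
    of a configuration S is the multivariate normal
    N(w; 0, sigma_e2 I + sigma_b2 Q_S Q_S') and the prior of S is
    pi^|S| (1-pi)^(m-|S|).  Intended as an independent oracle for the MCMC.
    """
    b_std = np.asarray(b_std, dtype=np.float64)
    m = len(b_std)
    if m > max_m:
        raise ValueError(f"enumeration over 2^{m} configurations refused (m > {max_m})")
    vals, vecs = np.linalg.eigh(np.asarray(R, dtype=np.float64))
    keep = vals > 1e-8
    lam, U = vals[keep], vecs[:, keep]
    w = np.sqrt(n) * (U.T @ b_std) / np.sqrt(lam)
    Q = np.sqrt(n) * (np.sqrt(lam)[:, None] * U.T)
    q = len(w)

    log_post = np.empty(2**m)
    members = []
    for i, conf in enumerate(itertools.product([0, 1], repeat=m)):
        s = np.array(conf, dtype=bool)
        members.append(s)
        cov = sigma_e2 * np.eye(q)
        if s.any():
            qs = Q[:, s]
            cov = cov + sigma_b2 * (qs @ qs.T)
        ll = multivariate_normal.logpdf(w, mean=np.zeros(q), cov=cov)
        k = int(s.sum())
        log_post[i] = ll + k * np.log(pi) + (m - k) * np.log(1.0 - pi)
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    pip = np.zeros(m)
    for prob, s in zip(post, members):
        pip[s] += prob
    return pip
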