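"""Numba kernel for the per-block Gibbs sweep over SNP effects.

The kernel works on one block's pseudo-data system w = Q beta + eps.  For
SNP j it forms the adjusted projected statistic r_j = Q_j' eps + d_j beta_j
(d_j = Q_j'Q_j, which equals n at full rank), samples the mixture-component
label from the conditional posterior

    Pr(delta_j = k) propto pi_jk                                   (k null)
    Pr(delta_j = k) propto pi_jk sqrt(lam_k / C_k)
                            exp{r_j^2 / (2 C_k sigma_e2)}          (k > null)

with lam_k = sigma_e2 / (gamma_k sigma_g2) and C_k = d_j + lam_k, then draws
beta_j ~ N(r_j / C_k, sigma_e2 / C_k) for a non-null label (or sets it to
zero) and updates eps incrementally.  All probability arithmetic is done in
log space with max-subtraction.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_block(qt, diag, eps, beta, delta, log_pi, comp_var, sigma_e2, order, rng):
    """One Gibbs sweep over the SNPs of a single block (in-place).

    qt       : (m_b, q) rows Q_j per SNP
    diag     : (m_b,) diag(Q'Q)
    eps      : (q,) current residual w - Q beta
    beta     : (m_b,) joint effects (standardized scale)
    delta    : (m_b,) component labels, 0 = null
    log_pi   : (m_b, K) per-SNP log prior membership probabilities
    comp_var : (K,) component variances gamma_k * sigma_g2 (entry 0 unused)
    order    : (m_b,) SNP visitation order
    rng      : numpy Generator (numba-compatible)
    """
    m_b, q = qt.shape
    K = comp_var.shape[0]
    logw = np.empty(K)
    for jj in range(m_b):
        j = order[jj]
        d = diag[j]
        b_old = beta[j]
        r = d * b_old
        for t in range(q):
            r += qt[j, t] * eps[t]

        logw[0] = log_pi[j, 0]
        for k in range(1, K):
            lam = sigma_e2 / comp_var[k]
            ck = d + lam
            logw[k] = log_pi[j, k] + 0.5 * np.log(lam / ck) + r * r / (2.0 * ck * sigma_e2)

        mx = logw[0]
        for k in range(1, K):
            if logw[k] > mx:
                mx = logw[k]
        tot = 0.0
        for k in range(K):
            logw[k] = np.exp(logw[k] - mx)
            tot += logw[k]
        u = rng.random() * tot
        k_new = K - 1
        acc = 0.0
        for k in range(K):
            acc += logw[k]
            if u <= acc:
                k_new = k
                break

        if k_new == 0:
            b_new = 0.0
        else:
            lam = sigma_e2 / comp_var[k_new]
            ck = d + lam
            b_new = r / ck + rng.standard_normal() * np.sqrt(sigma_e2 / ck)

        if b_new != b_old:
            diff = b_old - b_new
            for t in range(q):
                eps[t] += qt[j, t] * diff
        beta[j] = b_new
        delta[j] = k_new
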