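"""Local and global credible sets, and posterior power/heritability statistics.

A local credible set (LCS) is a minimal group of mutually high-LD SNPs whose
PIPs sum to at least alpha, asserted to contain at least one causal variant
with probability alpha.  Sets are built greedily from the highest-PIP "free"
SNP outward, restricted to SNPs with r^2 > 0.5 to the focal SNP within its
LD block, and are only reported when their posterior heritability-enrichment
probability (PEP) exceeds a threshold: the probability, over posterior
draws, that the set explains more genetic variance than a random SNP set of
the same size.

A global credible set (GCS) is the smallest prefix of PIP-ranked genome-wide
SNPs whose PIP sum reaches alpha times the estimated number of causal
variants; it is expected to contain alpha of all causal variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ldmatrix import EigenBasis
from .sampler import McmcSamples

DEFAULT_R2_THRESHOLD = 0.5


@dataclass
class CredibleSet:
    kind: str  # "local" | "global"
    alpha: float
    members: np.ndarray  # SNP indices
    pip_sum: float
    pep: float | None = None  # local sets only
    phe: float | None = None
    block_id: str | None = None
    achieved_coverage: float | None = None  # global sets only

    @property
    def size(self) -> int:
        return len(self.members)


class BlockR2:
    """Within-block r^2 lookups from eigen-reconstructed LD; cross-block r^2 is 0."""

    def __init__(self, bases: list[EigenBasis], offsets: np.ndarray | None = None):
        self.bases = bases
        sizes = [b.m_block for b in bases]
        if offsets is None:
            offsets = np.concatenate(([0], np.cumsum(sizes)))[:-1]
        self.offsets = np.asarray(offsets)
        self.m = int(sum(sizes))
        self.block_of = np.empty(self.m, dtype=np.int64)
        for b, (off, size) in enumerate(zip(self.offsets, sizes)):
            self.block_of[off : off + size] = b
        self._cache: dict[int, np.ndarray] = {}

    def _r(self, b: int) -> np.ndarray:
        if b not in self._cache:
            self._cache[b] = self.bases[b].reconstruct_r()
        return self._cache[b]

    def r2_with(self, focal: int) -> tuple[np.ndarray, np.ndarray]:
        """Global indices in the focal SNP's block and their r^2 to it."""
        b = int(self.block_of[focal])
        off = int(self.offsets[b])
        r = self._r(b)
        local = focal - off
        row = r[local] ** 2
        return np.arange(off, off + len(row)), row


def build_lcs(
    pip: np.ndarray,
    r2: BlockR2,
    samples: McmcSamples,
    alpha: float = 0.9,
    pep_threshold: float = 0.7,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    positions: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> list[CredibleSet]:
    """Construct alpha-LCSs with heritability-enrichment filtering.

    SNPs are visited once as focal, in decreasing PIP order (ties broken by
    ascending position).  The candidate set of a focal SNP comprises the
    free SNPs with r^2 > ``r2_threshold`` to it within its block; members
    are added in decreasing PIP until the PIP sum reaches alpha.  A
    candidate set that reaches alpha and passes the PEP filter is reported
    and its members become unavailable; otherwise all its SNPs stay free.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    pip = np.asarray(pip, dtype=np.float64)
    m = len(pip)
    if positions is None:
        positions = np.arange(m)
    rng = np.random.default_rng(0) if rng is None else rng
    order = np.lexsort((positions, -pip))
    free = np.ones(m, dtype=bool)
    sets: list[CredibleSet] = []
    for focal in order:
        if not free[focal] or pip[focal] <= 0.0:
            continue
        idx, r2_row = r2.r2_with(int(focal))
        cand = idx[(r2_row > r2_threshold) & free[idx]]
        cand = cand[np.lexsort((positions[cand], -pip[cand]))]
        cum = np.cumsum(pip[cand])
        if cum[-1] < alpha:
            continue
        cut = int(np.searchsorted(cum, alpha - 1e-12) + 1)
        members = cand[:cut]
        pep = compute_pep(members, samples, rng)
        if pep > pep_threshold:
            sets.append(
                CredibleSet(
                    kind="local",
                    alpha=alpha,
                    members=members,
                    pip_sum=float(cum[cut - 1]),
                    pep=pep,
                    phe=estimate_phe(members, samples),
                    block_id=str(int(r2.block_of[focal])),
                )
            )
            free[members] = False
    return sets


def compute_pep(
    members: np.ndarray, samples: McmcSamples, rng: np.random.Generator
) -> float:
    """Posterior heritability-enrichment probability of a SNP set.

    For each retained draw, the summed squared effects of the set are
    compared (strictly) against a freshly drawn uniform random SNP set of
    the same size; ties therefore count against enrichment.
    """
    members = np.asarray(members)
    m = samples.beta.shape[1]
    if len(members) > m:
        raise ValueError("set is larger than the SNP panel")
    beta2 = samples.beta**2
    # both sides are 1-D sums over sorted indices, so the comparison is an
    # exact tie whenever the two sets coincide
    members_sorted = np.sort(members)
    wins = 0
    for r in range(samples.n_draws):
        rand = np.sort(rng.choice(m, size=len(members), replace=False))
        if beta2[r, members_sorted].sum() > beta2[r, rand].sum():
            wins += 1
    return wins / samples.n_draws


def estimate_phe(members: np.ndarray, samples: McmcSamples) -> float:
    """Proportion of SNP-based heritability explained by a SNP set.

    Per draw, the ratio of summed squared standardized effects in the set to
    the genome-wide total; averaged over draws.  Draws with zero total
    variance contribute zero.
    """
    members = np.asarray(members, dtype=np.int64)
    beta2 = samples.beta**2
    total = beta2.sum(axis=1)
    if members.size == 0:
        return 0.0
    num = beta2[:, members].sum(axis=1)
    ratio = np.divide(num, total, out=np.zeros_like(num), where=total > 0)
    return float(ratio.mean())


def build_gcs(pip: np.ndarray, m_c_hat: int, alpha: float) -> CredibleSet:
    """Smallest prefix of PIP-ranked SNPs whose PIP sum reaches alpha * m_c_hat.

    If the total PIP mass falls short, all SNPs with positive PIP are
    returned and the achieved coverage recorded.
    """
    if m_c_hat < 1:
        raise ValueError("m_c_hat must be at least 1")
    pip = np.asarray(pip, dtype=np.float64)
    order = np.argsort(-pip, kind="stable")
    spip = pip[order]
    target = alpha * m_c_hat
    cum = np.cumsum(spip)
    total = cum[-1] if len(cum) else 0.0
    if total < target:
        members = order[spip > 0]
        return CredibleSet(
            kind="global",
            alpha=alpha,
            members=members,
            pip_sum=float(total),
            achieved_coverage=float(total / m_c_hat),
        )
    cut = int(np.searchsorted(cum, target - 1e-12) + 1)
    members = order[:cut]
    return CredibleSet(
        kind="global",
        alpha=alpha,
        members=members,
        pip_sum=float(cum[cut - 1]),
        achieved_coverage=float(cum[cut - 1] / m_c_hat),
    )


def estimate_tpr_given_data(
    pip: np.ndarray, alpha: float, M: int, pi_nonnull: float
) -> float:
    """Estimated true-positive rate of fine-mapping at PIP threshold alpha.

    The sum of PIPs over SNPs reaching the threshold, divided by the
    expected number of causal variants M * pi_nonnull; clipped to [0, 1].
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    expected_causals = M * pi_nonnull
    if expected_causals <= 0:
        raise ValueError("M * pi_nonnull must be positive")
    pip = np.asarray(pip, dtype=np.float64)
    tpr = float(pip[pip >= alpha].sum() / expected_causals)
    return float(np.clip(tpr, 0.0, 1.0))
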