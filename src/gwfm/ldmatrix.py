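"""Low-rank LD representation: block definitions, eigenbases and pseudo-data.

Within each quasi-independent LD block with correlation matrix R = X'X/n
(standardized genotypes X), the model is rotated onto the leading
eigenvectors of R.  Writing R = U diag(L) U' and keeping the top q
eigenpairs, the projection K = L^{-1/2} U' X' / sqrt(n) satisfies KK' = I,
and applying it to the phenotype gives the working linear model

    w = Q beta + eps,     eps ~ N(0, sigma_e^2 I_q)

with w = sqrt(n) L^{-1/2} U' b_std computable from summary statistics alone
and Q = sqrt(n) L^{1/2} U'.  Blocks are mutually independent by assumption,
so the genome-wide model is the concatenation of the per-block systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

DEFAULT_VARIANCE_FRACTION = 0.995


class LdValidationError(ValueError):
    """Raised when an input correlation matrix fails validation."""


@dataclass
class LDBlockSpec:
    """A quasi-independent LD block: 1-based inclusive interval plus member SNPs."""

    block_id: str
    chrom: str
    start_bp: int
    end_bp: int
    snp_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def read_block_definitions(path: str | Path) -> list[LDBlockSpec]:
    """Read a plain-text block file with columns ``block_id chrom start end``."""
    blocks = []
    with open(path) as fh:
        header = fh.readline().split()
        if header[:4] != ["block_id", "chrom", "start", "end"]:
            raise LdValidationError(
                f"{path}: expected header 'block_id chrom start end', got {' '.join(header[:4])}"
            )
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            blocks.append(LDBlockSpec(parts[0], parts[1], int(parts[2]), int(parts[3])))
    return blocks


def assign_snps_to_blocks(
    blocks: Sequence[LDBlockSpec], chrom: np.ndarray, pos_bp: np.ndarray
) -> list[LDBlockSpec]:
    """Fill ``snp_indices`` by position membership (1-based inclusive intervals)."""
    chrom = np.asarray(chrom, dtype=object)
    pos_bp = np.asarray(pos_bp)
    seen = np.zeros(len(pos_bp), dtype=bool)
    for blk in blocks:
        in_blk = (chrom == blk.chrom) & (pos_bp >= blk.start_bp) & (pos_bp <= blk.end_bp)
        if np.any(in_blk & seen):
            raise LdValidationError(f"block {blk.block_id} overlaps a previous block")
        seen |= in_blk
        idx = np.flatnonzero(in_blk)
        blk.snp_indices = idx[np.argsort(pos_bp[idx], kind="stable")]
    return list(blocks)


@dataclass
class EigenBasis:
    """Retained eigenpairs of a block correlation matrix.

    ``eigenvalues`` are descending and non-negative (length q) and
    ``eigenvectors`` has orthonormal columns (m_block x q).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    variance_fraction_kept: float
    m_block: int
    q: int

    def reconstruct_r(self) -> np.ndarray:
        """Low-rank reconstruction U diag(L) U' of the correlation matrix."""
        return (self.eigenvectors * self.eigenvalues) @ self.eigenvectors.T


@dataclass
class PseudoData:
    """Projected data for one block: w (q) and Q (q x m_block)."""

    w: np.ndarray
    q_mat: np.ndarray
    n_block: float

    @property
    def q(self) -> int:
        return self.w.shape[0]

    @property
    def m_block(self) -> int:
        return self.q_mat.shape[1]

    def qt(self) -> np.ndarray:
        """Q transposed with contiguous per-SNP rows (m_block x q)."""
        return np.ascontiguousarray(self.q_mat.T)

    def diag_qtq(self) -> np.ndarray:
        """diag(Q'Q) = n * reconstructed R diagonal, per SNP."""
        return np.einsum("ij,ij->j", self.q_mat, self.q_mat)


def eigendecompose_block(
    R: np.ndarray, variance_fraction: float = DEFAULT_VARIANCE_FRACTION
) -> EigenBasis:
    """Eigendecompose a block LD correlation matrix and truncate.

    The retained rank q is the smallest rank whose cumulative eigenvalue sum
    reaches ``variance_fraction * m_block`` (the trace of R).  Negative
    eigenvalues arising from numerical noise are clamped to zero before
    selection.
    """
    R = np.asarray(R, dtype=np.float64)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise LdValidationError("R must be square")
    if not np.allclose(R, R.T, atol=1e-6):
        raise LdValidationError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise LdValidationError("R must have unit diagonal")
    if not 0.0 < variance_fraction <= 1.0:
        raise LdValidationError("variance_fraction must be in (0, 1]")

    m = R.shape[0]
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    cum = np.cumsum(vals)
    target = variance_fraction * m
    # smallest q whose cumulative sum reaches the target (floating slack)
    q = int(np.searchsorted(cum, target - 1e-9) + 1)
    q = min(q, m)
    return EigenBasis(
        eigenvalues=vals[:q].copy(),
        eigenvectors=np.ascontiguousarray(vecs[:, :q]),
        variance_fraction_kept=float(cum[q - 1] / m),
        m_block=m,
        q=q,
    )


def build_pseudo_data(b_std: np.ndarray, n_block: float, basis: EigenBasis) -> PseudoData:
    """Project standardized marginal effects onto the retained eigenbasis.

    w = sqrt(n) L^{-1/2} U' b_std and Q = sqrt(n) L^{1/2} U', so that
    Q'Q reconstructs n*R restricted to the retained basis.
    """
    b_std = np.asarray(b_std, dtype=np.float64)
    if b_std.shape[0] != basis.m_block:
        raise ValueError(
            f"b_std has length {b_std.shape[0]} but the basis covers {basis.m_block} SNPs"
        )
    if n_block <= 1:
        raise ValueError("n_block must exceed 1")
    lam = basis.eigenvalues
    if np.any(lam <= 0):
        raise ValueError("retained eigenvalues must be positive to build pseudo-data")
    sqrt_n = np.sqrt(n_block)
    ut_b = basis.eigenvectors.T @ b_std
    w = sqrt_n * ut_b / np.sqrt(lam)
    q_mat = sqrt_n * (np.sqrt(lam)[:, None] * basis.eigenvectors.T)
    return PseudoData(w=w, q_mat=np.ascontiguousarray(q_mat), n_block=float(n_block))


@dataclass
class BlockLd:
    """One block's worth of LD-store content."""

    block_id: str
    chrom: str
    start_bp: int
    end_bp: int
    snp_ids: list[str]
    pos_bp: np.ndarray
    a1: list[str]
    a2: list[str]
    basis: EigenBasis


def save_ld_store(path: str | Path, blocks: Sequence[BlockLd]) -> None:
    """Write per-block eigenbases and SNP metadata to an HDF5 container.

    Layout: ``/block_<id>/{values,vectors,snps,positions,a1,a2}`` with block
    interval and bookkeeping stored as group attributes.
    """
    with h5py.File(path, "w") as fh:
        fh.attrs["n_blocks"] = len(blocks)
        fh.attrs["block_ids"] = [b.block_id for b in blocks]
        for blk in blocks:
            grp = fh.create_group(f"block_{blk.block_id}")
            grp.create_dataset("values", data=blk.basis.eigenvalues)
            grp.create_dataset("vectors", data=blk.basis.eigenvectors)
            grp.create_dataset("snps", data=np.array(blk.snp_ids, dtype="S"))
            grp.create_dataset("positions", data=np.asarray(blk.pos_bp, dtype=np.int64))
            grp.create_dataset("a1", data=np.array(blk.a1, dtype="S"))
            grp.create_dataset("a2", data=np.array(blk.a2, dtype="S"))
            grp.attrs["chrom"] = blk.chrom
            grp.attrs["start_bp"] = blk.start_bp
            grp.attrs["end_bp"] = blk.end_bp
            grp.attrs["variance_fraction_kept"] = blk.basis.variance_fraction_kept
            grp.attrs["m_block"] = blk.basis.m_block


def load_ld_store(path: str | Path) -> list[BlockLd]:
    blocks: list[BlockLd] = []
    with h5py.File(path, "r") as fh:
        for block_id in fh.attrs["block_ids"]:
            grp = fh[f"block_{block_id}"]
            vals = grp["values"][:]
            vecs = grp["vectors"][:]
            basis = EigenBasis(
                eigenvalues=vals,
                eigenvectors=vecs,
                variance_fraction_kept=float(grp.attrs["variance_fraction_kept"]),
                m_block=int(grp.attrs["m_block"]),
                q=len(vals),
            )
            blocks.append(
                BlockLd(
                    block_id=str(block_id),
                    chrom=str(grp.attrs["chrom"]),
                    start_bp=int(grp.attrs["start_bp"]),
                    end_bp=int(grp.attrs["end_bp"]),
                    snp_ids=[s.decode() for s in grp["snps"][:]],
                    pos_bp=grp["positions"][:],
                    a1=[s.decode() for s in grp["a1"][:]],
                    a2=[s.decode() for s in grp["a2"][:]],
                    basis=basis,
                )
            )
    return blocks


def empirical_correlation(x_block: np.ndarray) -> np.ndarray:
    """Sample correlation matrix of a genotype block (n x m_block)."""
    xc = x_block - x_block.mean(axis=0)
    sd = xc.std(axis=0)
    sd[sd == 0] = 1.0
    r = (xc.T @ xc) / (x_block.shape[0] * np.outer(sd, sd))
    np.fill_diagonal(r, 1.0)
    return r
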