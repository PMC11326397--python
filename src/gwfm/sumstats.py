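"""Reading, validation and allele alignment of GWAS summary statistics.

The input dialect is the COJO ``.ma`` text format: a whitespace-delimited
table with header ``SNP A1 A2 freq b se p N`` where ``b`` is the marginal
per-allele effect of A1, ``se`` its standard error and ``N`` the per-SNP
sample size.  Downstream modelling works on the standardized scale
(standardized genotypes, standardized phenotype), where the marginal effect
of SNP j is the genotype-phenotype correlation; it is recovered from the
marginal t/z statistic via ``b_std = z / sqrt(z^2 + n - 2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MA_COLUMNS = ("SNP", "A1", "A2", "freq", "b", "se", "p", "N")

#: palindromic allele pairs whose strand cannot be resolved without frequency
#: heuristics; such SNPs are excluded during alignment.
_AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


class MaFormatError(ValueError):
    """Raised when a .ma file is empty or misses a required column."""


@dataclass
class SummaryStatRecord:
    """One SNP's marginal GWAS result.

    ``z`` is ``b/se``; ``b_std`` is the effect on the standardized scale and
    is NaN until :func:`standardize_effects` has been applied.  ``chrom`` and
    ``pos_bp`` are unknown to the .ma format and are filled in when the
    record is matched to an LD reference.
    """

    snp_id: str
    a1: str
    a2: str
    freq: float
    b: float
    se: float
    p: float
    n: float
    chrom: str = ""
    pos_bp: int = -1
    z: float = field(default=np.nan)
    b_std: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if np.isnan(self.z):
            self.z = self.b / self.se


def records_to_frame(records: Sequence[SummaryStatRecord]) -> pd.DataFrame:
    """Tabulate records in .ma column order (plus z/b_std)."""
    return pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "A1": [r.a1 for r in records],
            "A2": [r.a2 for r in records],
            "freq": [r.freq for r in records],
            "b": [r.b for r in records],
            "se": [r.se for r in records],
            "p": [r.p for r in records],
            "N": [r.n for r in records],
            "z": [r.z for r in records],
            "b_std": [r.b_std for r in records],
        }
    )


def read_ma(path: str | Path) -> list[SummaryStatRecord]:
    """Read a ``.ma`` summary-statistics file.

    Rows with non-positive ``se``, ``freq`` outside (0, 1) or any missing
    field are dropped; the number of dropped rows is logged.

    Raises
    ------
    MaFormatError
        If the file is empty or the header lacks a required column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except pd.errors.EmptyDataError as exc:
        raise MaFormatError(f"{path} is empty") from exc
    missing = [c for c in MA_COLUMNS if c not in df.columns]
    if missing:
        raise MaFormatError(f"{path} is missing required column(s): {', '.join(missing)}")
    df = df[list(MA_COLUMNS)]

    n_total = len(df)
    for col in ("freq", "b", "se", "p", "N"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df.notna().all(axis=1)
        & (df["se"] > 0)
        & (df["freq"] > 0)
        & (df["freq"] < 1)
    )
    dropped = n_total - int(ok.sum())
    if dropped:
        logger.warning("read_ma: dropped %d of %d rows failing validation", dropped, n_total)
    df = df[ok]
    if df.empty:
        raise MaFormatError(f"{path} contains no valid rows")

    return [
        SummaryStatRecord(
            snp_id=str(row.SNP),
            a1=str(row.A1),
            a2=str(row.A2),
            freq=float(row.freq),
            b=float(row.b),
            se=float(row.se),
            p=float(row.p),
            n=float(row.N),
        )
        for row in df.itertuples()
    ]


def write_ma(records: Sequence[SummaryStatRecord], path: str | Path) -> None:
    """Write records as a ``.ma`` file (the eight standard columns)."""
    df = records_to_frame(records)[list(MA_COLUMNS)]
    df.to_csv(path, sep="\t", index=False)


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    return (a1.upper(), a2.upper()) in _AMBIGUOUS_PAIRS


def standardize_effects(
    records: Iterable[SummaryStatRecord],
    ld_reference_alleles: Mapping[str, tuple[str, str]],
) -> tuple[list[SummaryStatRecord], int]:
    """Align records to an LD reference and compute standardized effects.

    Each record is matched to the reference by SNP id.  Alleles must match
    the reference either directly or as a swap; a swap negates the sign of
    the effect (and flips ``freq``).  Strand-ambiguous (A/T, C/G) SNPs and
    allele mismatches are excluded and counted.

    The standardized marginal effect uses the t-statistic-to-correlation
    identity ``b_std = z / sqrt(z^2 + n - 2)``.

    Returns
    -------
    (aligned, n_excluded)
        Aligned records carry ``b_std`` and the reference allele orientation,
        making the operation idempotent (aligning twice equals aligning once).
    """
    aligned: list[SummaryStatRecord] = []
    n_excluded = 0
    for rec in records:
        ref = ld_reference_alleles.get(rec.snp_id)
        if ref is None or is_strand_ambiguous(rec.a1, rec.a2):
            n_excluded += 1
            continue
        ref_a1, ref_a2 = ref
        if (rec.a1, rec.a2) == (ref_a1, ref_a2):
            sign = 1.0
            out = rec
        elif (rec.a1, rec.a2) == (ref_a2, ref_a1):
            sign = -1.0
            out = replace(
                rec,
                a1=ref_a1,
                a2=ref_a2,
                freq=1.0 - rec.freq,
                b=-rec.b,
                z=-rec.z,
            )
        else:
            n_excluded += 1
            continue
        z = out.z
        b_std = z / np.sqrt(z * z + out.n - 2.0)
        aligned.append(replace(out, b_std=float(b_std)))
    if n_excluded:
        logger.warning("standardize_effects: excluded %d unmatched/ambiguous SNPs", n_excluded)
    return aligned, n_excluded
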