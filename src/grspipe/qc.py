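"""Per-SNP quality statistics: MAF, Hardy-Weinberg equilibrium, and
cross-cohort allele-frequency comparison.

HWE is tested with a 1-df Pearson chi-square of the three genotype
counts against the n*(p^2, 2pq, q^2) expectations, without continuity
correction.  Cross-cohort comparison is the Pearson chi-square on the
2x2 allele-count table (alleles, not genotypes).  SNPs failing HWE are
reported, never removed: downstream analyses keep the full panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = [
    "HweResult",
    "SnpQcResult",
    "MafComparisonRow",
    "hwe_test",
    "compare_maf",
    "maf_to_counts",
    "qc_report",
    "qc_report_frame",
]

HWE_ALPHA = 0.05


@dataclass(frozen=True)
class HweResult:
    chi2: float
    p: float
    in_hwe: bool
    monomorphic: bool = False


@dataclass(frozen=True)
class SnpQcResult:
    rsid: str
    locus: str
    maf: float
    n_called: int
    genotype_counts: tuple[int, int, int]  # (n_major_hom, n_het, n_minor_hom)
    hwe_chi2: float
    hwe_p: float
    in_hwe: bool
    monomorphic: bool
    folded: bool


@dataclass(frozen=True)
class MafComparisonRow:
    rsid: str
    maf_cohort_a: float
    maf_cohort_b: float
    chi2: float
    p: float
    reconstructed: bool = False


def hwe_test(genotype_counts: tuple[int, int, int]) -> HweResult:
    """Pearson 1-df chi-square of genotype counts against HWE expectations.

    ``genotype_counts`` is (n_major_hom, n_het, n_minor_hom).  A
    monomorphic SNP has statistic 0 and is flagged.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one called genotype required")
    q = (n_ab + 2 * n_bb) / (2 * n)  # minor-allele frequency
    p = 1 - q
    if q == 0.0 or q == 1.0:
        return HweResult(chi2=0.0, p=1.0, in_hwe=True, monomorphic=True)
    expected = np.array([n * p * p, n * 2 * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    pval = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2=chi2, p=pval, in_hwe=pval >= HWE_ALPHA)


def maf_to_counts(maf: float, n_participants: int) -> tuple[int, int]:
    """Reconstruct (minor, major) allele counts from a printed MAF and n.

    Counts are recovered as the nearest integers on 2n alleles; exact
    counts are unrecoverable from a rounded frequency, so callers should
    flag results as reconstruction-approximate.
    """
    if n_participants <= 0:
        raise ValueError("cohort size must be positive")
    total = 2 * n_participants
    minor = int(round(maf * total))
    return minor, total - minor


def _allele_chi2(minor_a: int, major_a: int, minor_b: int, major_b: int) -> tuple[float, float]:
    table = np.array([[minor_a, major_a], [minor_b, major_b]], dtype=float)
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise ValueError("zero total alleles in a cohort")
    if table.sum(axis=0).min() == 0:  # one allele absent everywhere
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def compare_maf(
    counts_a: tuple[int, int] | tuple[float, int],
    counts_b: tuple[int, int] | tuple[float, int],
    rsid: str = "",
    from_maf: bool = False,
) -> MafComparisonRow:
    """Pearson chi-square comparing allele frequencies of two cohorts.

    Each cohort is given either as raw (minor, major) allele counts, or —
    with ``from_maf=True`` — as (MAF, n_participants), from which counts
    are reconstructed on 2n alleles and the row flagged approximate.
    """
    if from_maf:
        counts_a = maf_to_counts(*counts_a)
        counts_b = maf_to_counts(*counts_b)
    min_a, maj_a = counts_a
    min_b, maj_b = counts_b
    chi2, p = _allele_chi2(min_a, maj_a, min_b, maj_b)
    return MafComparisonRow(
        rsid=rsid,
        maf_cohort_a=min_a / (min_a + maj_a),
        maf_cohort_b=min_b / (min_b + maj_b),
        chi2=chi2,
        p=p,
        reconstructed=from_maf,
    )


def qc_report(matrix: GenotypeMatrix) -> list[SnpQcResult]:
    """Per-SNP MAF/HWE report.  SNPs failing HWE are flagged, not removed."""
    if not matrix.snps:
        raise ValueError("genotype matrix has no SNPs")
    out: list[SnpQcResult] = []
    for j, snp in enumerate(matrix.snps):
        col = matrix.dosage[:, j]
        called = col[~np.isnan(col)]
        n_called = int(called.size)
        if n_called == 0:
            out.append(
                SnpQcResult(snp.rsid, snp.locus, float("nan"), 0, (0, 0, 0),
                            0.0, 1.0, True, True, snp.rsid in matrix.folded_rsids)
            )
            continue
        counts = (
            int((called == 0).sum()),
            int((called == 1).sum()),
            int((called == 2).sum()),
        )
        maf = (counts[1] + 2 * counts[2]) / (2 * n_called)
        folded = snp.rsid in matrix.folded_rsids
        if maf > 0.5:  # residual fold (sub-matrix use); relabel for reporting
            counts = counts[::-1]
            maf = 1 - maf
            folded = True
        res = hwe_test(counts)
        out.append(
            SnpQcResult(snp.rsid, snp.locus, float(maf), n_called, counts,
                        res.chi2, res.p, res.in_hwe, res.monomorphic, folded)
        )
    return out


def qc_report_frame(matrix: GenotypeMatrix) -> pd.DataFrame:
    rows = qc_report(matrix)
    return pd.DataFrame(
        {
            "rsid": [r.rsid for r in rows],
            "locus": [r.locus for r in rows],
            "maf": [r.maf for r in rows],
            "n_called": [r.n_called for r in rows],
            "hwe_chi2": [r.hwe_chi2 for r in rows],
            "hwe_p": [r.hwe_p for r in rows],
            "in_hwe": [r.in_hwe for r in rows],
        }
    )


def write_qc_report(matrix: GenotypeMatrix, path: str | Path) -> None:
    qc_report_frame(matrix).to_csv(path, sep="\t", index=False)
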