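"""Genotype container and text-format I/O (VCF, PLINK .ped/.map).

Genotypes are held as minor-allele dosages (0, 1, 2; NaN = missing) in a
participants x SNPs matrix.  Coordinates carry no meaning here: the
files are treated purely as genotype containers for biallelic SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SnpMeta",
    "GenotypeMatrix",
    "GenotypeParseError",
    "read_genotypes",
    "read_vcf",
    "read_plink",
    "write_vcf",
    "write_plink",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file fails validation."""


@dataclass(frozen=True)
class SnpMeta:
    rsid: str
    locus: str = ""
    minor_allele: str = "A"
    major_allele: str = "G"


@dataclass
class GenotypeMatrix:
    """Participants x SNPs minor-allele dosage matrix.

    ``dosage`` is a float array with values in {0, 1, 2} and NaN for
    missing calls.  SNP order matches ``snps``; row order matches
    ``participant_ids``.
    """

    participant_ids: list[str]
    snps: list[SnpMeta]
    dosage: np.ndarray
    folded_rsids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.participant_ids) or m != len(self.snps):
            raise GenotypeParseError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.participant_ids)} participants x {len(self.snps)} SNPs"
            )
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise GenotypeParseError("dosage entries must be 0/1/2 or missing")
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise GenotypeParseError(f"duplicate rsids: {', '.join(dupes)}")

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    def column(self, rsid: str) -> np.ndarray:
        return self.dosage[:, self.rsids.index(rsid)]

    def fold_to_minor(self) -> None:
        """Relabel alleles so every column counts the minor allele.

        Columns whose counted-allele frequency exceeds 0.5 have dosages
        flipped (2 - d) and allele labels swapped; affected rsids are
        recorded in ``folded_rsids``.  Frequency exactly 0.5 is left as is.
        """
        for j, snp in enumerate(self.snps):
            col = self.dosage[:, j]
            called = col[~np.isnan(col)]
            if called.size == 0:
                continue
            if called.sum() / (2 * called.size) > 0.5:
                self.dosage[:, j] = 2.0 - col
                self.snps[j] = SnpMeta(
                    rsid=snp.rsid,
                    locus=snp.locus,
                    minor_allele=snp.major_allele,
                    major_allele=snp.minor_allele,
                )
                self.folded_rsids.add(snp.rsid)


def read_genotypes(path: str | Path, fmt: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf`` or ``plink_text`` (.ped/.map)."""
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "plink_text":
        return read_plink(path)
    raise ValueError(f"unknown genotype format: {fmt!r}")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into minor-allele dosages.

    ALT dosages are counted first and then folded so each column counts
    the allele that is minor in this file.  Multiallelic records are
    rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snps: list[SnpMeta] = []
    rows: list[np.ndarray] = []
    multiallelic: list[str] = []
    for var in vcf:
        rsid = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            multiallelic.append(rsid)
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        snps.append(SnpMeta(rsid=rsid, minor_allele=var.ALT[0], major_allele=var.REF))
        rows.append(dos)
    vcf.close()
    if multiallelic:
        raise GenotypeParseError(
            "multiallelic records not supported: " + ", ".join(multiallelic)
        )
    mat = GenotypeMatrix(sample_ids, snps, np.column_stack(rows) if rows else
                         np.empty((len(sample_ids), 0)))
    mat.fold_to_minor()
    return mat


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 text file (GT only)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.participant_ids),
    ]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, snp in enumerate(matrix.snps):
        col = matrix.dosage[:, j]
        gts = "\t".join("./." if np.isnan(d) else gt_map[d] for d in col)
        lines.append(
            f"1\t{j + 1}\t{snp.rsid}\t{snp.major_allele}\t{snp.minor_allele}"
            f"\t.\t.\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_plink(matrix: GenotypeMatrix, prefix: str | Path) -> None:
    """Write PLINK-style text files ``<prefix>.ped`` and ``<prefix>.map``."""
    prefix = Path(prefix)
    map_lines = [f"1\t{s.rsid}\t0\t{j + 1}" for j, s in enumerate(matrix.snps)]
    prefix.with_suffix(".map").write_text("\n".join(map_lines) + "\n")
    ped_lines = []
    for i, pid in enumerate(matrix.participant_ids):
        fields = [pid, pid, "0", "0", "0", "-9"]
        for j, snp in enumerate(matrix.snps):
            d = matrix.dosage[i, j]
            if np.isnan(d):
                fields += ["0", "0"]
            elif d == 0:
                fields += [snp.major_allele, snp.major_allele]
            elif d == 1:
                fields += [snp.minor_allele, snp.major_allele]
            else:
                fields += [snp.minor_allele, snp.minor_allele]
        ped_lines.append(" ".join(fields))
    prefix.with_suffix(".ped").write_text("\n".join(ped_lines) + "\n")


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK-style ``.ped``/``.map`` text into minor-allele dosages.

    The minor allele of each SNP is the rarer of the two alleles observed
    in the file (alphabetically first on an exact tie).
    """
    prefix = Path(prefix)
    if prefix.suffix in {".ped", ".map"}:
        prefix = prefix.with_suffix("")
    map_path, ped_path = prefix.with_suffix(".map"), prefix.with_suffix(".ped")
    rsids: list[str] = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), 1):
        parts = line.split()
        if len(parts) < 4:
            raise GenotypeParseError(f"{map_path}:{lineno}: expected 4 columns")
        rsids.append(parts[1])
    m = len(rsids)
    ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), 1):
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise GenotypeParseError(
                f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
            )
        ids.append(parts[1])
        allele_rows.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
        )
    dosage = np.full((len(ids), m), np.nan)
    snps: list[SnpMeta] = []
    for j, rsid in enumerate(rsids):
        counts: dict[str, int] = {}
        for row in allele_rows:
            for a in row[j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise GenotypeParseError(f"SNP {rsid} has >2 alleles")
        alleles = sorted(counts, key=lambda a: (counts[a], a))
        if not alleles:
            snps.append(SnpMeta(rsid=rsid, minor_allele="?", major_allele="?"))
            continue
        minor = alleles[0]
        major = alleles[-1] if len(alleles) == 2 else alleles[0]
        if len(alleles) == 1:
            minor, major = "?", alleles[0]  # monomorphic: all dosages 0
        snps.append(SnpMeta(rsid=rsid, minor_allele=minor, major_allele=major))
        for i, row in enumerate(allele_rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 == minor) + (a2 == minor)
    mat = GenotypeMatrix(ids, snps, dosage)
    mat.fold_to_minor()
    return mat
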