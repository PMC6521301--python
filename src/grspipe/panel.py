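"""Reference SNP panel for the omega-3 triglyceride-response GRS.

The panel covers the GWAS loci implicated in the plasma triglyceride
response to omega-3 fatty acid supplementation (IQCJ-SCHIP1, NXPH1,
PHF17, MYB, NELL1, SLIT2) plus candidate TG genes.  For each SNP the
published minor allele frequency is recorded in two cohorts: French
Canadian Caucasians (the discovery cohort) and Mexicans (the
replication cohort).  Frequencies are as printed in the source report;
a labeled "minor" allele may exceed 0.5 in one cohort when it is minor
only in the other.

``REPLICATION_PANEL`` lists the seven SNPs retained for the replication
GRS (GWAS-hit SNPs that were designable and not in strong LD in the
replication cohort).
"""

from __future__ import annotations

# (gene/locus, rsid, MAF Caucasian, MAF Mexican)
REFERENCE_PANEL: list[tuple[str, str, float, float]] = [
    ("IQCJ-SCHIP1", "rs12497650", 0.32, 0.27),
    ("IQCJ-SCHIP1", "rs4501157", 0.35, 0.24),
    ("IQCJ-SCHIP1", "rs13091349", 0.17, 0.09),
    ("IQCJ-SCHIP1", "rs2044704", 0.26, 0.41),
    ("IQCJ-SCHIP1", "rs1962071", 0.27, 0.38),
    ("IQCJ-SCHIP1", "rs7634829", 0.44, 0.28),
    ("IQCJ-SCHIP1", "rs2621294", 0.38, 0.23),
    ("IQCJ-SCHIP1", "rs6800211", 0.29, 0.14),
    ("IQCJ-SCHIP1", "rs17782879", 0.30, 0.39),
    ("IQCJ-SCHIP1", "rs1868414", 0.33, 0.17),
    ("IQCJ-SCHIP1", "rs2595260", 0.25, 0.52),
    ("IQCJ-SCHIP1", "rs6763890", 0.34, 0.20),
    ("NXPH1", "rs6956210", 0.24, 0.13),
    ("NXPH1", "rs2107779", 0.55, 0.41),
    ("NXPH1", "rs10273195", 0.20, 0.24),
    ("NXPH1", "rs12216689", 0.28, 0.32),
    ("NXPH1", "rs6963644", 0.08, 0.04),
    ("NXPH1", "rs17150341", 0.30, 0.16),
    ("NXPH1", "rs1013868", 0.33, 0.45),
    ("NXPH1", "rs4318981", 0.36, 0.36),
    ("NXPH1", "rs17153997", 0.43, 0.30),
    ("NXPH1", "rs7801099", 0.45, 0.53),
    ("NXPH1", "rs4725120", 0.46, 0.47),
    ("NXPH1", "rs10238726", 0.31, 0.38),
    ("NXPH1", "rs1012960", 0.50, 0.46),
    ("NXPH1", "rs11767429", 0.30, 0.34),
    ("NXPH1", "rs4333500", 0.40, 0.45),
    ("NXPH1", "rs7793115", 0.10, 0.05),
    ("NXPH1", "rs7799856", 0.43, 0.39),
    ("NXPH1", "rs7806226", 0.16, 0.41),
    ("NXPH1", "rs13221144", 0.23, 0.11),
    ("NXPH1", "rs17406479", 0.19, 0.31),
    ("NXPH1", "rs10486228", 0.18, 0.44),
    ("NXPH1", "rs17154569", 0.18, 0.08),
    ("NXPH1", "rs4141002", 0.12, 0.17),
    ("NXPH1", "rs7805772", 0.19, 0.40),
    ("NXPH1", "rs2349780", 0.38, 0.49),
    ("NXPH1", "rs2107474", 0.42, 0.49),
    ("NXPH1", "rs11769942", 0.37, 0.43),
    ("NXPH1", "rs6952383", 0.10, 0.05),
    ("NXPH1", "rs6974252", 0.14, 0.23),
    ("NXPH1", "rs10265408", 0.28, 0.31),
    ("NXPH1", "rs2189904", 0.33, 0.18),
    ("NXPH1", "rs2057862", 0.41, 0.53),
    ("PHF17", "rs2217023", 0.19, 0.74),
    ("PHF17", "rs4975270", 0.43, 0.47),
    ("PHF17", "rs11722830", 0.21, 0.18),
    ("PHF17", "rs12505447", 0.19, 0.16),
    ("PHF17", "rs6534704", 0.08, 0.03),
    ("PHF17", "rs13148510", 0.04, 0.01),
    ("PHF17", "rs13143771", 0.28, 0.32),
    ("PHF17", "rs13142964", 0.07, 0.05),
    ("MYB", "rs9321493", 0.45, 0.45),
    ("MYB", "rs11154794", 0.13, 0.10),
    ("MYB", "rs210798", 0.42, 0.43),
    ("MYB", "rs210936", 0.48, 0.30),
    ("MYB", "rs7757388", 0.16, 0.05),
    ("MYB", "rs17639758", 0.03, 0.02),
    ("MYB", "rs1013891", 0.35, 0.23),
    ("MYB", "rs2179308", 0.51, 0.43),
    ("IQCJ-SCHIP1", "rs1449009", 0.29, 0.60),
    ("IQCJ-SCHIP1", "rs61332355", 0.18, 0.33),
    ("IQCJ-SCHIP1", "rs12485627", 0.40, 0.32),
    ("IQCJ-SCHIP1", "rs2595242", 0.52, 0.26),
    ("IQCJ-SCHIP1", "rs7639937", 0.25, 0.49),
    ("IQCJ-SCHIP1", "rs9820807", 0.16, 0.07),
    ("IQCJ-SCHIP1", "rs1375409", 0.29, 0.38),
    ("IQCJ-SCHIP1", "rs1967363", 0.22, 0.36),
    ("IQCJ-SCHIP1", "rs9824310", 0.40, 0.46),
    ("IQCJ-SCHIP1", "rs11915303", 0.27, 0.33),
    ("IQCJ-SCHIP1", "rs9835214", 0.46, 0.39),
    ("IQCJ-SCHIP1", "rs11921343", 0.19, 0.26),
    ("IQCJ-SCHIP1", "rs13066560", 0.16, 0.08),
    ("IQCJ-SCHIP1", "rs1675497", 0.29, 0.32),
    ("IQCJ-SCHIP1", "rs9839862", 0.11, 0.17),
    ("IQCJ-SCHIP1", "rs16829875", 0.22, 0.37),
    ("IQCJ-SCHIP1", "rs17795566", 0.36, 0.23),
    ("IQCJ-SCHIP1", "rs9860588", 0.23, 0.10),
    ("IQCJ-SCHIP1", "rs16830408", 0.27, 0.23),
    ("IQCJ-SCHIP1", "rs17798579", 0.17, 0.16),
    ("IQCJ-SCHIP1", "rs2364930", 0.40, 0.23),
    ("IQCJ-SCHIP1", "rs9865997", 0.14, 0.29),
    ("IQCJ-SCHIP1", "rs2595241", 0.26, 0.58),
    ("IQCJ-SCHIP1", "rs7632574", 0.19, 0.29),
    ("IQCJ-SCHIP1", "rs2621308", 0.2589, 0.5895),
    ("SLIT2", "rs2952724", 0.3511, 0.4789),
    ("PHF17", "rs1216352", 0.3475, 0.5921),
    ("PHF17", "rs1216365", 0.6196, 0.3421),
    ("MYB", "rs6920829", 0.1241, 0.1032),
    ("NXPH1", "rs6463808", 0.1773, 0.4),
    ("NELL1", "rs752088", 0.3841, 0.4579),
]

#: The 7-SNP panel used to replicate the discovery-cohort GRS.
REPLICATION_PANEL: tuple[str, ...] = (
    "rs1449009",
    "rs61332355",
    "rs1216352",
    "rs1216365",
    "rs6920829",
    "rs6463808",
    "rs752088",
)

#: The five SNPs the published stepwise refinement retained; used as the
#: default planted causal panel in the synthetic cohort generator.
REFINED_PANEL: tuple[str, ...] = (
    "rs10265408",
    "rs10486228",
    "rs17150341",
    "rs6974252",
    "rs2595241",
)


def fold_maf(freq: float) -> float:
    """Fold an allele frequency onto the minor-allele scale (<= 0.5)."""
    return freq if freq <= 0.5 else 1.0 - freq


def default_panel(n_snps: int = 103) -> list[tuple[str, str, float]]:
    """Default simulation panel: (locus, rsid, Mexican MAF folded to <=0.5).

    The published comparison table lists the 91 SNPs genotyped in both
    cohorts; the genotyped panel comprised 103 SNPs.  When more SNPs are
    requested than the table prints, the panel is padded deterministically
    by cycling the printed frequencies under synthetic rsids (rsSYN01...).
    """
    rows = [(locus, rsid, fold_maf(mex)) for locus, rsid, _, mex in REFERENCE_PANEL]
    i = 0
    while len(rows) < n_snps:
        locus, _, maf = rows[i % len(REFERENCE_PANEL)]
        rows.append((locus, f"rsSYN{i + 1:02d}", maf))
        i += 1
    return rows[:n_snps]
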