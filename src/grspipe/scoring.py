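"""Odds-ratio-directed genetic risk score construction.

Each SNP's risk direction comes from the allelic odds ratio of carrying
the minor allele among non-responders versus responders (2x2 table on
2n alleles, the PLINK-style allelic association table): OR > 1 means
the minor allele is enriched in non-responders and is "at risk"
(direction +1); OR < 1 marks it beneficial (direction -1); OR exactly 1
or undefined contributes nothing (0).  The GRS of a participant is the
sum over the panel of direction x minor-allele dosage, so a positive
score means more at-risk alleles.  Participants missing any panel
genotype are excluded from that panel's score vector rather than
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .panel import REPLICATION_PANEL

__all__ = [
    "RiskWeight",
    "GrsVector",
    "allele_odds_ratio",
    "compute_weights",
    "compute_grs",
    "grs_distribution",
    "replication_panel_grs",
    "REPLICATION_PANEL",
]


@dataclass(frozen=True)
class RiskWeight:
    rsid: str
    odds_ratio: float  # minor-allele odds, non-responders vs responders
    direction: int  # {-1, 0, +1}
    or_table: tuple[float, float, float, float]  # minor_NR, major_NR, minor_R, major_R
    haldane_corrected: bool = False
    uninformative: bool = False


@dataclass
class GrsVector:
    panel_name: str
    rsids: list[str]
    participant_ids: list[str]
    scores: np.ndarray  # int per scored participant
    excluded_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.participant_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"participant_id": self.participant_ids, "score": self.scores.astype(int)}
        )


def allele_odds_ratio(
    dosages: np.ndarray, responder_flags: np.ndarray, rsid: str = ""
) -> RiskWeight:
    """Allelic odds ratio of the minor allele, non-responders vs responders.

    ``dosages`` are minor-allele counts (NaN = missing).  Allele counts
    per group are sum(dosage) minor and 2*n_called - sum(dosage) major.
    Any zero cell triggers the Haldane-Anscombe +0.5 correction (flagged).
    """
    dosages = np.asarray(dosages, dtype=float)
    resp = np.asarray(responder_flags, dtype=bool)
    if resp.all() or (~resp).all():
        raise ValueError("both responder groups must be non-empty")
    called = ~np.isnan(dosages)
    counts = {}
    for label, grp in (("nr", ~resp), ("r", resp)):
        sel = called & grp
        n_called = int(sel.sum())
        minor = float(dosages[sel].sum()) if n_called else 0.0
        counts[label] = (minor, 2 * n_called - minor)
    (minor_nr, major_nr), (minor_r, major_r) = counts["nr"], counts["r"]
    if (minor_nr + major_nr) == 0 or (minor_r + major_r) == 0:
        return RiskWeight(rsid, float("nan"), 0,
                          (minor_nr, major_nr, minor_r, major_r),
                          uninformative=True)
    table = (minor_nr, major_nr, minor_r, major_r)
    corrected = 0.0 in table
    if corrected:
        minor_nr, major_nr, minor_r, major_r = (c + 0.5 for c in table)
    odds_ratio = (minor_nr / major_nr) / (minor_r / major_r)
    direction = 0 if odds_ratio == 1.0 else (1 if odds_ratio > 1.0 else -1)
    return RiskWeight(rsid, float(odds_ratio), direction, table, corrected)


def compute_weights(
    matrix: GenotypeMatrix, responder_flags: np.ndarray
) -> list[RiskWeight]:
    """In-cohort risk direction for every SNP in the matrix."""
    return [
        allele_odds_ratio(matrix.dosage[:, j], responder_flags, rsid=snp.rsid)
        for j, snp in enumerate(matrix.snps)
    ]


def compute_grs(
    matrix: GenotypeMatrix,
    weights: list[RiskWeight] | dict[str, int],
    panel: list[str] | None = None,
    panel_name: str = "panel",
    carrier_mode: bool = False,
) -> GrsVector:
    """Sum of direction-signed minor-allele dosages over a SNP panel.

    ``weights`` may be RiskWeight objects or an rsid->direction mapping.
    With ``carrier_mode`` a carrier contributes +/-1 regardless of
    dosage.  Participants missing any panel genotype are excluded and
    listed in ``excluded_ids``.
    """
    if isinstance(weights, dict):
        directions = dict(weights)
    else:
        directions = {w.rsid: w.direction for w in weights}
    panel = list(panel) if panel is not None else list(directions)
    missing_w = [r for r in panel if r not in directions]
    if missing_w:
        raise ValueError(f"panel rsids absent from weights: {', '.join(missing_w)}")
    missing_m = [r for r in panel if r not in matrix.rsids]
    if missing_m:
        raise ValueError(f"panel rsids absent from genotypes: {', '.join(missing_m)}")
    idx = [matrix.rsids.index(r) for r in panel]
    sub = matrix.dosage[:, idx] if idx else np.zeros((len(matrix.participant_ids), 0))
    dirs = np.array([directions[r] for r in panel], dtype=float)
    complete = ~np.isnan(sub).any(axis=1)
    contrib = np.sign(sub) * dirs if carrier_mode else sub * dirs
    scores = np.nansum(contrib, axis=1)[complete].astype(int)
    ids = np.asarray(matrix.participant_ids, dtype=object)
    return GrsVector(
        panel_name=panel_name,
        rsids=panel,
        participant_ids=list(ids[complete]),
        scores=scores,
        excluded_ids=list(ids[~complete]),
    )


def grs_distribution(grs: GrsVector) -> dict[int, int]:
    """Histogram of integer scores: {score: count}, keys sorted ascending."""
    if grs.n == 0:
        raise ValueError("empty GRS vector")
    vals, counts = np.unique(grs.scores, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}


def replication_panel_grs(
    matrix: GenotypeMatrix, weights: list[RiskWeight] | dict[str, int]
) -> GrsVector:
    """GRS on the fixed 7-SNP replication panel (in-cohort directions)."""
    missing = [r for r in REPLICATION_PANEL if r not in matrix.rsids]
    if missing:
        raise ValueError(
            "replication panel SNPs absent from genotypes: " + ", ".join(missing)
        )
    return compute_grs(matrix, weights, list(REPLICATION_PANEL),
                       panel_name="replication_7")


def write_weights(weights: list[RiskWeight], path: str | Path) -> None:
    pd.DataFrame(
        {
            "rsid": [w.rsid for w in weights],
            "odds_ratio": [w.odds_ratio for w in weights],
            "direction": [w.direction for w in weights],
            "correction_flag": [w.haldane_corrected for w in weights],
        }
    ).to_csv(path, sep="\t", index=False)


def read_weights(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["rsid"], df["direction"].astype(int)))
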