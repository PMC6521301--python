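"""Synthetic genotype/phenotype cohort generator.

Emulates the structure of a 6-week omega-3 fatty-acid supplementation
trial in young adults: biallelic genotypes drawn in Hardy-Weinberg
equilibrium at reference minor-allele frequencies, inclusion-range
covariates (age 18-40 y, BMI 18.5-<30 kg/m^2), a right-skewed
(log-normal) baseline plasma triglyceride level, and a triglyceride
change (delta TG, mg/dL) that is linear in a small set of causal SNP
dosages plus covariates plus Gaussian noise.

The residual noise variance is solved analytically so that the planted
genetic term accounts for a target fraction of the delta-TG variance
(the quantity the downstream covariate-adjusted model estimates), and
the intercept is calibrated so the expected non-responder proportion
(delta TG >= 0) matches the observed study value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, SnpMeta, write_plink, write_vcf
from .panel import REFINED_PANEL, default_panel

__all__ = [
    "CausalSnp",
    "SimulationConfig",
    "SyntheticCohort",
    "ConfigurationError",
    "simulate_cohort",
    "write_cohort",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class CausalSnp:
    """A planted causal SNP: effect in mg/dL delta TG per minor-allele copy."""

    index: int
    effect: float


def _default_causal(panel: Sequence[tuple[str, str, float]]) -> tuple[CausalSnp, ...]:
    """Five causal SNPs at the refined-panel rsids, +/-12 mg/dL per allele."""
    rsids = [rsid for _, rsid, _ in panel]
    signs = (+1, -1, +1, -1, +1)
    out = []
    for rsid, s in zip(REFINED_PANEL, signs):
        if rsid in rsids:
            out.append(CausalSnp(rsids.index(rsid), 12.0 * s))
    return tuple(out)


@dataclass
class SimulationConfig:
    n_participants: int = 191
    n_snps: int = 103
    #: explicit MAF list, or None to use the reference panel frequencies
    maf: Sequence[float] | None = None
    #: uniform sampling interval for MAFs, used only when ``maf`` is None
    maf_interval: tuple[float, float] | None = None
    #: None = default five-SNP planted panel; () = no causal SNPs
    causal_snps: Sequence[CausalSnp] | None = None
    target_grs_partial_r2: float = 0.11
    #: (age, male, BMI) coefficients on delta TG, mg/dL per unit
    covariate_effects: tuple[float, float, float] = (0.3, 5.0, 1.0)
    baseline_tg_mean: float = 97.9
    baseline_tg_sd: float = 53.6
    #: coefficient of (baseline TG - mean) on delta TG; mildly negative so
    #: high-baseline participants tend to respond (TG drop)
    baseline_coupling: float = -0.15
    prop_male: float = 0.37
    prop_nonresponder: float = 0.408
    age_mean: float = 26.5
    age_sd: float = 6.2
    age_range: tuple[float, float] = (18.0, 40.0)
    bmi_mean: float = 23.6
    bmi_sd: float = 2.7
    bmi_range: tuple[float, float] = (18.5, 30.0)
    #: residual SD (mg/dL) used when no genetic variance is planted
    null_noise_sd: float = 45.0
    missing_rate: float = 0.0
    seed: int = 0

    # populated in __post_init__
    panel: list[tuple[str, str, float]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.maf is not None:
            mafs = [float(f) for f in self.maf]
            self.panel = [("SIM", f"sim{j + 1:04d}", f) for j, f in enumerate(mafs)]
            self.n_snps = len(mafs)
        elif self.maf_interval is not None:
            lo, hi = self.maf_interval
            if not (0 < lo <= hi <= 0.5):
                raise ConfigurationError("maf_interval must lie within (0, 0.5]")
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7]))
            mafs = rng.uniform(lo, hi, self.n_snps)
            self.panel = [("SIM", f"sim{j + 1:04d}", float(f)) for j, f in enumerate(mafs)]
        else:
            self.panel = default_panel(self.n_snps)
        for _, rsid, f in self.panel:
            if not (0 < f <= 0.5):
                raise ConfigurationError(f"MAF for {rsid} outside (0, 0.5]: {f}")
        if self.causal_snps is None:
            self.causal_snps = _default_causal(self.panel)
        self.causal_snps = tuple(
            c if isinstance(c, CausalSnp) else CausalSnp(int(c[0]), float(c[1]))
            for c in self.causal_snps
        )
        for c in self.causal_snps:
            if not (0 <= c.index < self.n_snps):
                raise ConfigurationError(f"causal SNP index {c.index} out of range")
            if not np.isfinite(c.effect):
                raise ConfigurationError("causal effect sizes must be finite")
        if not (0 <= self.target_grs_partial_r2 < 1):
            raise ConfigurationError("target_grs_partial_r2 must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")

    # --- analytic moments used for calibration -------------------------
    @property
    def genetic_variance(self) -> float:
        """Variance of the planted genetic term under HWE independence."""
        return sum(
            c.effect**2 * 2 * self.panel[c.index][2] * (1 - self.panel[c.index][2])
            for c in self.causal_snps
        )

    def _trunc(self, mean: float, sd: float, lo: float, hi: float):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm(a, b, loc=mean, scale=sd)

    def solve_noise_sd(self) -> float:
        """Residual SD giving the target planted genetic variance fraction."""
        v_g = self.genetic_variance
        a_age, a_sex, a_bmi = self.covariate_effects
        v_cov = (
            a_age**2 * self._trunc(self.age_mean, self.age_sd, *self.age_range).var()
            + a_sex**2 * self.prop_male * (1 - self.prop_male)
            + a_bmi**2 * self._trunc(self.bmi_mean, self.bmi_sd, *self.bmi_range).var()
        )
        v_base = self.baseline_coupling**2 * self.baseline_tg_sd**2
        if v_g == 0 or self.target_grs_partial_r2 == 0:
            if v_g > 0 and self.target_grs_partial_r2 == 0:
                raise ConfigurationError(
                    "target_grs_partial_r2=0 is unsatisfiable with nonzero "
                    "causal effects"
                )
            return self.null_noise_sd
        v_noise = v_g / self.target_grs_partial_r2 - v_g - v_cov - v_base
        if v_noise <= 0:
            raise ConfigurationError(
                "unsatisfiable target_grs_partial_r2="
                f"{self.target_grs_partial_r2}: planted genetic variance "
                f"{v_g:.1f} plus covariate/baseline variance "
                f"{v_cov + v_base:.1f} exceeds the implied total variance "
                f"{v_g / self.target_grs_partial_r2:.1f}"
            )
        return float(np.sqrt(v_noise))

    def total_delta_sd(self) -> float:
        v_g = self.genetic_variance
        if v_g > 0 and self.target_grs_partial_r2 > 0:
            return float(np.sqrt(v_g / self.target_grs_partial_r2))
        a_age, a_sex, a_bmi = self.covariate_effects
        v_cov = (
            a_age**2 * self._trunc(self.age_mean, self.age_sd, *self.age_range).var()
            + a_sex**2 * self.prop_male * (1 - self.prop_male)
            + a_bmi**2 * self._trunc(self.bmi_mean, self.bmi_sd, *self.bmi_range).var()
        )
        v_base = self.baseline_coupling**2 * self.baseline_tg_sd**2
        return float(np.sqrt(self.null_noise_sd**2 + v_cov + v_base))


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: dict

    @property
    def participant_ids(self) -> list[str]:
        return self.genotypes.participant_ids


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) moment-matched to an arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort; identical config + seed gives a bit-identical cohort."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, m = config.n_participants, config.n_snps
    mafs = np.array([f for _, _, f in config.panel])

    dosage = rng.binomial(2, mafs, size=(n, m)).astype(float)
    sex_male = (rng.random(n) < config.prop_male).astype(int)
    age = config._trunc(config.age_mean, config.age_sd, *config.age_range).rvs(
        n, random_state=rng
    )
    bmi = config._trunc(config.bmi_mean, config.bmi_sd, *config.bmi_range).rvs(
        n, random_state=rng
    )
    mu, sigma = _lognormal_params(config.baseline_tg_mean, config.baseline_tg_sd)
    tg_pre = rng.lognormal(mu, sigma, n)

    genetic = np.zeros(n)
    for c in config.causal_snps:
        genetic += c.effect * dosage[:, c.index]
    genetic_centered = genetic - sum(
        c.effect * 2 * config.panel[c.index][2] for c in config.causal_snps
    )

    noise_sd = config.solve_noise_sd()
    total_sd = config.total_delta_sd()
    intercept = total_sd * stats.norm.ppf(config.prop_nonresponder)

    a_age, a_sex, a_bmi = config.covariate_effects
    age_mean = config._trunc(config.age_mean, config.age_sd, *config.age_range).mean()
    bmi_mean = config._trunc(config.bmi_mean, config.bmi_sd, *config.bmi_range).mean()
    delta = (
        intercept
        + genetic_centered
        + a_age * (age - age_mean)
        + a_sex * (sex_male - config.prop_male)
        + a_bmi * (bmi - bmi_mean)
        + config.baseline_coupling * (tg_pre - config.baseline_tg_mean)
        + rng.normal(0, noise_sd, n)
    )
    tg_post = np.maximum(tg_pre + delta, 1.0)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosage[mask] = np.nan

    ids = [f"P{i + 1:03d}" for i in range(n)]
    snps = [SnpMeta(rsid=rsid, locus=locus) for locus, rsid, _ in config.panel]
    genotypes = GenotypeMatrix(ids, snps, dosage)
    phenotypes = pd.DataFrame(
        {
            "participant_id": ids,
            "age": np.round(age, 4),
            "sex": np.where(sex_male == 1, "male", "female"),
            "bmi": np.round(bmi, 4),
            "tg_pre": np.round(tg_pre, 4),
            "tg_post": np.round(tg_post, 4),
        }
    )

    realized_delta = phenotypes["tg_post"].to_numpy() - phenotypes["tg_pre"].to_numpy()
    var_delta = float(np.var(realized_delta))
    truth = {
        "causal_snps": [
            {
                "rsid": config.panel[c.index][1],
                "index": c.index,
                "effect": c.effect,
                "risk_direction": int(np.sign(c.effect)),
            }
            for c in config.causal_snps
        ],
        "target_grs_partial_r2": config.target_grs_partial_r2,
        "noise_sd": noise_sd,
        "intercept": intercept,
        "realized_genetic_variance_fraction": (
            float(np.var(genetic_centered) / var_delta) if var_delta > 0 else 0.0
        ),
        "seed": config.seed,
    }
    return SyntheticCohort(genotypes, phenotypes, truth)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, str]:
    """Write VCF + PLINK genotypes, phenotype CSV and truth JSON; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(out / "genotypes.vcf"),
        "ped": str(out / "genotypes.ped"),
        "map": str(out / "genotypes.map"),
        "phenotypes": str(out / "phenotypes.csv"),
        "truth": str(out / "truth.json"),
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    write_plink(cohort.genotypes, out / "genotypes")
    cohort.phenotypes.to_csv(paths["phenotypes"], index=False)
    Path(paths["truth"]).write_text(json.dumps(cohort.truth, indent=2, sort_keys=True))
    return paths
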