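"""Covariate-adjusted association models for the triglyceride response.

The contribution of a genetic risk score to delta TG is quantified by
ordinary least squares of delta TG on GRS + age + sex + BMI.  The "% of
TG variance explained by the GRS" is the incremental R^2: the full
model's R^2 minus that of the covariate-only model (equivalently the
squared semi-partial correlation of GRS with delta TG given the
covariates).  Partial eta^2 (t^2 / (t^2 + df_resid)) is reported
alongside as the other common reading of the same phrase.

SNP refinement uses classic bidirectional stepwise regression on
individual SNP dosages with age, sex and BMI forced into every model:
at each iteration the candidate with the smallest p-value below the
entry threshold is added, then any included SNP whose p-value rises
above the stay threshold is removed; thresholds default to 0.15 (the
conventional stepwise defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotypes import GenotypeMatrix
from .scoring import GrsVector, RiskWeight, compute_grs

__all__ = [
    "VarianceExplainedFit",
    "StepwiseResult",
    "fit_grs_model",
    "stepwise_select",
    "refit_refined_grs",
]

COVARIATES = ("age", "sex_male", "bmi")


@dataclass
class VarianceExplainedFit:
    n: int
    params: dict[str, float]
    bse: dict[str, float]
    grs_percent_variance: float
    grs_p: float
    r2_full: float
    r2_covariates_only: float
    partial_eta2_percent: float
    grs_inestimable: bool = False

    def summary_frame(self) -> pd.DataFrame:
        terms = list(self.params)
        return pd.DataFrame(
            {
                "term": terms,
                "estimate": [self.params[t] for t in terms],
                "se": [self.bse[t] for t in terms],
            }
        )


def _design(df: pd.DataFrame, extra: list[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    cols += [df[c].to_numpy(dtype=float) for c in extra]
    return np.column_stack(cols)


def _prepare(phenotypes: pd.DataFrame) -> pd.DataFrame:
    df = phenotypes.copy()
    if "delta_tg" not in df.columns:
        df["delta_tg"] = df["tg_post"] - df["tg_pre"]
    if "sex_male" not in df.columns:
        df["sex_male"] = (
            df["sex"].astype(str).str.lower().isin(["male", "m", "1"]).astype(float)
        )
    return df


def fit_grs_model(phenotypes: pd.DataFrame, grs: GrsVector) -> VarianceExplainedFit:
    """OLS of delta TG on GRS + age + sex + BMI, with incremental R^2.

    Complete-case over phenotype columns and the scored participants of
    ``grs``.  A constant GRS is flagged inestimable (zero variance
    attributed, p undefined).
    """
    df = _prepare(phenotypes)
    df = df.merge(grs.to_frame(), on="participant_id", how="inner")
    df = df.dropna(subset=["delta_tg", "age", "sex_male", "bmi", "score"])
    n = len(df)
    if n < 6:
        raise ValueError(f"too few complete rows for the model: {n}")
    y = df["delta_tg"].to_numpy(dtype=float)

    x_cov = _design(df, ["age", "sex_male", "bmi"])
    fit_cov = sm.OLS(y, x_cov).fit()

    if np.ptp(df["score"].to_numpy()) == 0:
        return VarianceExplainedFit(
            n=n,
            params={"intercept": float(fit_cov.params[0]),
                    "age": float(fit_cov.params[1]),
                    "sex_male": float(fit_cov.params[2]),
                    "bmi": float(fit_cov.params[3])},
            bse={}, grs_percent_variance=0.0, grs_p=float("nan"),
            r2_full=float(fit_cov.rsquared),
            r2_covariates_only=float(fit_cov.rsquared),
            partial_eta2_percent=0.0, grs_inestimable=True,
        )

    x_full = _design(df, ["score", "age", "sex_male", "bmi"])
    fit_full = sm.OLS(y, x_full).fit()
    names = ["intercept", "grs", "age", "sex_male", "bmi"]
    t_grs = float(fit_full.tvalues[1])
    df_resid = float(fit_full.df_resid)
    return VarianceExplainedFit(
        n=n,
        params=dict(zip(names, map(float, fit_full.params))),
        bse=dict(zip(names, map(float, fit_full.bse))),
        grs_percent_variance=100 * float(fit_full.rsquared - fit_cov.rsquared),
        grs_p=float(fit_full.pvalues[1]),
        r2_full=float(fit_full.rsquared),
        r2_covariates_only=float(fit_cov.rsquared),
        partial_eta2_percent=100 * t_grs**2 / (t_grs**2 + df_resid),
    )


def _ols_pvalues(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values per column of a full-rank design."""
    n, k = x.shape
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n - rank
    if dof <= 0:
        return np.full(k, np.nan)
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.pinv(x.T @ x)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    return 2 * stats.t.sf(np.abs(t), dof)


@dataclass
class StepwiseResult:
    selected: list[str]  # in entry order
    entry_p: float
    stay_p: float
    log: list[tuple[str, str, float]] = field(default_factory=list)  # (rsid, action, p)
    n_used: int = 0


def stepwise_select(
    phenotypes: pd.DataFrame,
    matrix: GenotypeMatrix,
    candidates: list[str] | None = None,
    entry_p: float = 0.15,
    stay_p: float = 0.15,
) -> StepwiseResult:
    """Bidirectional stepwise selection of SNP dosage terms.

    Covariates (age, sex, BMI) are forced and never removed.  Each
    iteration adds the candidate with the smallest p-value under the
    current model if it is below ``entry_p`` (ties by smaller p then
    lexicographic rsid), then repeatedly removes the included SNP with
    the largest p-value above ``stay_p``.  Deterministic given inputs.
    """
    if not (0 < entry_p < 1) or not (0 < stay_p < 1):
        raise ValueError("entry_p and stay_p must lie in (0, 1)")
    candidates = list(candidates) if candidates is not None else list(matrix.rsids)
    if not candidates:
        raise ValueError("at least one candidate SNP required")
    df = _prepare(phenotypes)
    order = [matrix.rsids.index(r) for r in candidates]
    geno = pd.DataFrame(
        matrix.dosage[:, order], columns=candidates
    ).assign(participant_id=matrix.participant_ids)
    df = df.merge(geno, on="participant_id", how="inner")
    df = df.dropna(subset=["delta_tg", "age", "sex_male", "bmi", *candidates])
    y = df["delta_tg"].to_numpy(dtype=float)
    n = len(df)

    included: list[str] = []
    log: list[tuple[str, str, float]] = []
    seen_states: set[tuple[str, ...]] = set()
    while True:
        state = tuple(included)
        if state in seen_states:
            break
        seen_states.add(state)
        changed = False
        # entry step: best candidate under the current model
        pool = [c for c in candidates if c not in included]
        best: tuple[float, str] | None = None
        for c in sorted(pool):
            x = _design(df, list(included) + [c] + list(COVARIATES))
            p = _ols_pvalues(y, x)[len(included) + 1]
            if np.isnan(p):
                continue
            if best is None or (p, c) < best:
                best = (p, c)
        if best is not None and best[0] < entry_p:
            included.append(best[1])
            log.append((best[1], "enter", best[0]))
            changed = True
        # removal step: drop worst included SNPs above the stay threshold
        while included:
            x = _design(df, list(included) + list(COVARIATES))
            pvals = _ols_pvalues(y, x)[1 : 1 + len(included)]
            worst = int(np.argmax(pvals))
            if pvals[worst] > stay_p:
                rsid = included.pop(worst)
                log.append((rsid, "remove", float(pvals[worst])))
                changed = True
            else:
                break
        if not changed:
            break
    return StepwiseResult(selected=included, entry_p=entry_p, stay_p=stay_p,
                          log=log, n_used=n)


def refit_refined_grs(
    matrix: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    selected: list[str],
    weights: list[RiskWeight] | dict[str, int],
) -> VarianceExplainedFit:
    """GRS over the selected panel (frozen weights), refit against delta TG."""
    if not selected:
        raise ValueError("selected SNP panel must be non-empty")
    grs = compute_grs(matrix, weights, list(selected), panel_name="refined")
    return fit_grs_model(phenotypes, grs)
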