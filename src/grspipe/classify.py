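"""Triglyceride-response classification and descriptive statistics.

Delta TG is post-intervention minus baseline (mg/dL).  A participant
whose plasma TG fell (delta TG < 0) is a responder to the omega-3
supplementation; delta TG >= 0 is a non-responder (the boundary case
counts as non-response).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClassificationResult",
    "DescriptiveRow",
    "classify_responders",
    "descriptive_table",
    "read_phenotypes",
]

PHENOTYPE_COLUMNS = ["participant_id", "age", "sex", "bmi", "tg_pre", "tg_post"]


@dataclass
class ClassificationResult:
    table: pd.DataFrame  # with delta_tg and responder columns
    rejected_ids: list[str]

    @property
    def n_responders(self) -> int:
        return int(self.table["responder"].sum())

    @property
    def n_non_responders(self) -> int:
        return int((~self.table["responder"]).sum())

    @property
    def percent_non_responders(self) -> float:
        """Share of non-responders among classified participants, 1 decimal."""
        return round(100 * self.n_non_responders / len(self.table), 1)

    @property
    def percent_responders(self) -> float:
        return round(100 * self.n_responders / len(self.table), 1)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {', '.join(missing)}")
    return df


def classify_responders(table: pd.DataFrame) -> ClassificationResult:
    """Attach delta_tg and responder flags; reject rows with missing TG.

    A row with a missing pre- or post-intervention TG cannot be
    classified and is dropped, with its id reported.
    """
    df = table.copy()
    bad = df["tg_pre"].isna() | df["tg_post"].isna()
    rejected = df.loc[bad, "participant_id"].astype(str).tolist()
    df = df.loc[~bad].copy()
    if df.empty:
        raise ValueError("no classifiable rows (all TG values missing)")
    df["delta_tg"] = df["tg_post"] - df["tg_pre"]
    df["responder"] = df["delta_tg"] < 0
    return ClassificationResult(table=df.reset_index(drop=True), rejected_ids=rejected)


@dataclass(frozen=True)
class DescriptiveRow:
    variable: str
    responder_pre: tuple[float, float]  # (mean, sd)
    responder_post: tuple[float, float] | None
    responder_p_within: float | None
    non_responder_pre: tuple[float, float]
    non_responder_post: tuple[float, float] | None
    non_responder_p_within: float | None
    p_between_pre: float | None
    p_between_post: float | None
    degenerate: bool = False


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")


def _paired_p(pre: np.ndarray, post: np.ndarray) -> tuple[float | None, bool]:
    """Two-sided paired t-test p; zero-variance difference gives p=1, flagged."""
    if len(pre) < 2:
        return None, True
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0.0):
        return 1.0, True
    return float(stats.ttest_rel(pre, post).pvalue), False


def _between_p(a: np.ndarray, b: np.ndarray, welch: bool = False) -> tuple[float | None, bool]:
    """Two-sided two-sample t-test p (pooled variance unless ``welch``)."""
    if len(a) < 2 or len(b) < 2:
        return None, True
    if np.allclose(np.concatenate([a, b]).std(ddof=1), 0.0):
        return 1.0, True
    return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue), False


def descriptive_table(
    classified: pd.DataFrame, welch: bool = False
) -> list[DescriptiveRow]:
    """Group descriptive statistics with within- and between-group t-tests.

    Pre-vs-post variables (TG) get a paired two-sided t-test within each
    group; baseline variables (age, BMI, TG pre, TG post) are compared
    between groups with a two-sample Student t-test (pooled variance by
    default, Welch behind the flag).
    """
    resp = classified[classified["responder"]]
    nonr = classified[~classified["responder"]]
    rows: list[DescriptiveRow] = []
    for var in ("age", "bmi"):
        pb, deg = _between_p(resp[var].to_numpy(), nonr[var].to_numpy(), welch)
        rows.append(
            DescriptiveRow(
                variable=var,
                responder_pre=_mean_sd(resp[var].to_numpy()),
                responder_post=None,
                responder_p_within=None,
                non_responder_pre=_mean_sd(nonr[var].to_numpy()),
                non_responder_post=None,
                non_responder_p_within=None,
                p_between_pre=pb,
                p_between_post=None,
                degenerate=deg,
            )
        )
    r_pre, r_post = resp["tg_pre"].to_numpy(), resp["tg_post"].to_numpy()
    n_pre, n_post = nonr["tg_pre"].to_numpy(), nonr["tg_post"].to_numpy()
    p_r, deg_r = _paired_p(r_pre, r_post)
    p_n, deg_n = _paired_p(n_pre, n_post)
    pb_pre, deg_bp = _between_p(r_pre, n_pre, welch)
    pb_post, deg_bq = _between_p(r_post, n_post, welch)
    rows.append(
        DescriptiveRow(
            variable="triglycerides",
            responder_pre=_mean_sd(r_pre),
            responder_post=_mean_sd(r_post),
            responder_p_within=p_r,
            non_responder_pre=_mean_sd(n_pre),
            non_responder_post=_mean_sd(n_post),
            non_responder_p_within=p_n,
            p_between_pre=pb_pre,
            p_between_post=pb_post,
            degenerate=deg_r or deg_n or deg_bp or deg_bq,
        )
    )
    return rows


def descriptive_frame(classified: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    rows = descriptive_table(classified, welch=welch)
    rec = []
    for r in rows:
        rec.append(
            {
                "variable": r.variable,
                "responder_pre_mean": r.responder_pre[0],
                "responder_pre_sd": r.responder_pre[1],
                "responder_post_mean": r.responder_post[0] if r.responder_post else np.nan,
                "responder_post_sd": r.responder_post[1] if r.responder_post else np.nan,
                "responder_p_within": r.responder_p_within,
                "non_responder_pre_mean": r.non_responder_pre[0],
                "non_responder_pre_sd": r.non_responder_pre[1],
                "non_responder_post_mean": (
                    r.non_responder_post[0] if r.non_responder_post else np.nan
                ),
                "non_responder_post_sd": (
                    r.non_responder_post[1] if r.non_responder_post else np.nan
                ),
                "non_responder_p_within": r.non_responder_p_within,
                "p_between_pre": r.p_between_pre,
                "p_between_post": r.p_between_post,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rec)
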