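"""Extreme-response retrenchment sweep.

Progressively removes the participants with the weakest triglyceride
response — responders closest to zero from below and non-responders
closest to zero from above — first to reach a 50:50
responder:non-responder ratio, then in equal steps from both groups,
refitting the covariate-adjusted GRS model on each retained subset with
the GRS weights frozen from the full cohort.  This probes whether the
score explains more of the response variance among participants with
extreme responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import VarianceExplainedFit, fit_grs_model
from .scoring import GrsVector

__all__ = [
    "RetrenchmentRow",
    "default_schedule",
    "retrench_and_refit",
]


@dataclass(frozen=True)
class RetrenchmentRow:
    n_responders_excluded: int
    n_non_responders_excluded: int
    n_included: int
    grs_percent_variance: float
    grs_p: float


def default_schedule(
    n_responders: int,
    n_non_responders: int,
    step: int = 10,
    min_n: int = 30,
) -> list[tuple[int, int]]:
    """Cumulative (responders, non-responders) exclusion schedule.

    Starts at (0, 0); the first real step removes the group-size
    difference from the larger group to reach 50:50; each later step
    removes ``step`` more from each group, stopping before fewer than
    ``min_n`` participants would remain.  If non-responders outnumber
    responders the schedule is mirrored.
    """
    if n_responders < 0 or n_non_responders < 0:
        raise ValueError("group sizes must be non-negative")
    mirrored = n_non_responders > n_responders
    big, small = (
        (n_non_responders, n_responders) if mirrored
        else (n_responders, n_non_responders)
    )
    sched: list[tuple[int, int]] = [(0, 0)]
    excl_big, excl_small = big - small, 0
    while small - excl_small > 0 and (big - excl_big) + (small - excl_small) >= min_n:
        if (excl_big, excl_small) != (0, 0):
            sched.append((excl_big, excl_small))
        excl_big += step
        excl_small += step
    if mirrored:
        sched = [(s, b) for b, s in sched]
    return sched


def _ranked_exclusions(
    classified: pd.DataFrame, non_responder_order: str = "magnitude"
) -> tuple[list[str], list[str]]:
    """Participant ids of each group ranked weakest-response-first.

    Responders (delta < 0) are ranked by least-negative delta first.
    Non-responders are ranked by smallest delta first ("magnitude",
    default) or largest first ("largest").  Ties break on participant id.
    """
    resp = classified[classified["responder"]]
    nonr = classified[~classified["responder"]]
    r_order = resp.sort_values(
        ["delta_tg", "participant_id"], ascending=[False, True]
    )["participant_id"].tolist()
    ascending = non_responder_order == "magnitude"
    if non_responder_order not in ("magnitude", "largest"):
        raise ValueError("non_responder_order must be 'magnitude' or 'largest'")
    n_order = nonr.sort_values(
        ["delta_tg", "participant_id"], ascending=[ascending, True]
    )["participant_id"].tolist()
    return r_order, n_order


def retrench_and_refit(
    classified: pd.DataFrame,
    grs: GrsVector,
    schedule: list[tuple[int, int]] | None = None,
    step: int = 10,
    min_n: int = 30,
    non_responder_order: str = "magnitude",
) -> list[RetrenchmentRow]:
    """Refit the GRS model on nested extreme-response subsets.

    Operates on the participants who have a GRS (scored).  Each schedule
    entry is a cumulative exclusion count per group; the corresponding
    weakest-response participants are removed and the model refit.  A
    step that would empty a group truncates the sweep.
    """
    scored = classified[classified["participant_id"].isin(grs.participant_ids)]
    n_r = int(scored["responder"].sum())
    n_n = int((~scored["responder"]).sum())
    if schedule is None:
        schedule = default_schedule(n_r, n_n, step=step, min_n=min_n)
    r_rank, n_rank = _ranked_exclusions(scored, non_responder_order)
    rows: list[RetrenchmentRow] = []
    for excl_r, excl_n in schedule:
        if excl_r >= n_r or excl_n >= n_n:
            break  # would empty a group
        drop = set(r_rank[:excl_r]) | set(n_rank[:excl_n])
        subset = scored[~scored["participant_id"].isin(drop)]
        fit = fit_grs_model(subset, grs)
        rows.append(
            RetrenchmentRow(
                n_responders_excluded=excl_r,
                n_non_responders_excluded=excl_n,
                n_included=fit.n,
                grs_percent_variance=fit.grs_percent_variance,
                grs_p=fit.grs_p,
            )
        )
    return rows


def retrenchment_frame(rows: list[RetrenchmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "excluded_responders": [r.n_responders_excluded for r in rows],
            "excluded_non_responders": [r.n_non_responders_excluded for r in rows],
            "n_included": [r.n_included for r in rows],
            "pct_variance": [r.grs_percent_variance for r in rows],
            "grs_p": [r.grs_p for r in rows],
        }
    )
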