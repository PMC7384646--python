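"""Time-stratified referent selection and matched-set construction.

In a time-stratified case-crossover design each decedent's exposure on the
case day (date of death) is compared with their own exposure on referent
days: every 3rd day before and after the case day, restricted to the same
calendar month and year. The strata are therefore fixed calendar sets — all
days of a month sharing a day-of-month residue mod 3 — which makes referent
selection symmetric within the stratum and avoids the overlap bias of
unidirectional schemes.

Matched sets are person-events: two deaths on the same day in the same block
group yield two distinct (identical-covariate) sets, which the conditional
likelihood handles without aggregation.
"""

from __future__ import annotations

import datetime as dt
import logging
from functools import lru_cache

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["select_referents", "build_matched_sets", "BuildLog"]


@lru_cache(maxsize=4096)
def _referent_cache(year: int, month: int, day: int) -> tuple[dt.date, ...]:
    case = dt.date(year, month, day)
    days_in_month = (pd.Timestamp(case) + pd.offsets.MonthEnd(0)).day
    out = []
    for dom in range(1, days_in_month + 1):
        if dom != day and (dom - day) % 3 == 0:
            out.append(dt.date(year, month, dom))
    return tuple(out)


def select_referents(case_day) -> list:
    """Referent days for one case day: ``case_day ± 3k`` within the month.

    Returns ascending ``datetime.date`` objects; the case day itself is
    excluded. Every calendar day yields between 8 and 10 referents.
    """
    d = pd.Timestamp(case_day)
    return list(_referent_cache(d.year, d.month, d.day))


def stratum_days(case_day) -> list:
    """All days of the case day's stratum (referents plus the case day), ascending."""
    d = pd.Timestamp(case_day).date()
    return sorted(select_referents(d) + [d])


class BuildLog(dict):
    """Counts of records retained/dropped (with reasons) during set building."""

    def __str__(self):  # pragma: no cover - cosmetic
        return ", ".join(f"{k}={v}" for k, v in self.items())


def build_matched_sets(
    records: pd.DataFrame,
    covariates: pd.DataFrame,
    modifiers: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, BuildLog]:
    """Long-format case-crossover design: one row per (record, stratum day).

    Parameters
    ----------
    records
        One row per event with at least ``record_id, date`` plus any
        per-record columns to carry along (``block_group_id, race, ...``).
    covariates
        Daily windowed covariates per record's exposure cell: either a frame
        with ``record_id``-level lookup columns ``cell_id`` plus wide
        matrices, or — the form produced by the exposure module — a frame
        ``cell_id x date`` lookup. Here we accept the practical long form:
        columns ``cell_id, date, pm25_window, temp_window`` together with a
        ``cell_id`` column on ``records``.
    modifiers
        Optional per-block-group modifier columns keyed by
        ``block_group_id``; merged onto every row of the design.

    Returns
    -------
    (design, log)
        ``design`` columns: ``record_id, date, is_case, pm25_window,
        temp_window, dow`` plus carried record columns and merged modifier
        columns. Days with a missing (NaN) window are omitted; a record whose
        *case day* window is missing is dropped entirely, with counts in
        ``log``.
    """
    log = BuildLog(n_records=len(records), dropped_missing_case_day=0, referent_days_dropped=0)
    if len(records) == 0:
        return (
            pd.DataFrame(
                columns=["record_id", "date", "is_case", "pm25_window", "temp_window", "dow"]
            ),
            log,
        )
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])

    # expand each record into its stratum days (vectorized ragged take over
    # the distinct case dates)
    codes, uniq_dates = pd.factorize(rec["date"])
    day_arrays = [np.asarray(stratum_days(d), dtype="datetime64[D]") for d in uniq_dates]
    flat = np.concatenate(day_arrays)
    sizes_u = np.array([len(a) for a in day_arrays])
    starts_u = np.r_[0, np.cumsum(sizes_u)[:-1]]
    counts = sizes_u[codes]
    within = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    long = rec.loc[rec.index.repeat(counts)].reset_index(drop=True)
    case_date = long["date"].copy()
    long["date"] = pd.to_datetime(flat[np.repeat(starts_u[codes], counts) + within])
    long["is_case"] = (long["date"] == case_date).astype(int)

    cov = covariates.copy()
    cov["date"] = pd.to_datetime(cov["date"])
    long = long.merge(cov, on=["cell_id", "date"], how="left", validate="many_to_one")

    # drop days with missing windows; drop whole sets whose case day is missing
    missing = long["pm25_window"].isna() | long["temp_window"].isna()
    bad_records = set(long.loc[missing & (long["is_case"] == 1), "record_id"])
    log["dropped_missing_case_day"] = len(bad_records)
    log["referent_days_dropped"] = int((missing & (long["is_case"] == 0)).sum())
    keep = ~missing & ~long["record_id"].isin(bad_records)
    long = long.loc[keep].reset_index(drop=True)

    # a set must retain at least one referent
    sizes = long.groupby("record_id")["is_case"].agg(["size", "sum"])
    lonely = set(sizes.index[sizes["size"] < 2])
    if lonely:
        log["dropped_no_referents"] = len(lonely)
        long = long.loc[~long["record_id"].isin(lonely)].reset_index(drop=True)

    # weekday via datetime64 day arithmetic (the epoch was a Thursday)
    wd = (long["date"].to_numpy().astype("datetime64[D]").view("int64") + 3) % 7
    long["dow"] = np.array(
        ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday"]
    )[wd]
    if modifiers is not None:
        long = long.merge(modifiers, on="block_group_id", how="left", validate="many_to_one")
    log["n_sets"] = int(long["record_id"].nunique())
    logger.info("matched sets built: %s", log)
    return long, log
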