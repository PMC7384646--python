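"""End-to-end assembly: inputs -> matched-set design -> fitted model.

The stages mirror the study's workflow:

1. score the census table (composition percentages, segregation indices);
2. assign each decedent the exposure series of the grid cell nearest their
   residence, and build two-day-window covariates;
3. expand each death into its time-stratified matched set;
4. maximize the conditional logistic likelihood, optionally with an
   exposure x modifier interaction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .exposure import assign_nearest_cells, build_cell_series, rolling_window
from .model import CaseCrossoverModel, CaseCrossoverResults, ModelSpec
from .referents import build_matched_sets
from .segregation import score_census_table

__all__ = ["cell_covariates", "prepare_design", "fit_study", "simulate_and_fit", "MODIFIERS"]

#: modifier name -> (design column, kind, extra spec kwargs)
MODIFIERS = {
    "race": dict(modifier="race", modifier_kind="binary", modifier_level="black"),
    "pct_black": dict(modifier="pct_black", modifier_kind="continuous"),
    "pct_white": dict(modifier="pct_white", modifier_kind="continuous"),
    "ird": dict(modifier="ird", modifier_kind="continuous"),
    "rrs_category": dict(
        modifier="rrs_category", modifier_kind="categorical", modifier_reference="G1"
    ),
}


def cell_covariates(exposure: pd.DataFrame, lags=(0, 1)) -> pd.DataFrame:
    """Per-(cell, date) windowed covariates.

    Columns: ``cell_id, date, pm25_window, temp_window, pm25_day`` —
    ``pm25_day`` is the lag-0 daily value kept for the below-NAAQS
    restriction, which applies to the 24-hour average.
    """
    series = build_cell_series(exposure)
    pm_w = rolling_window(series["pm25"], lags)
    t_w = rolling_window(series["temperature"], lags)
    nd, nc = pm_w.shape
    return pd.DataFrame(
        {
            "cell_id": np.tile(pm_w.columns.to_numpy(), nd),
            "date": np.repeat(pm_w.index.to_numpy(), nc),
            "pm25_window": pm_w.to_numpy().ravel(),
            "temp_window": t_w.to_numpy().ravel(),
            "pm25_day": series["pm25"].to_numpy().ravel(),
        }
    )


def prepare_design(
    events: pd.DataFrame,
    exposure: pd.DataFrame,
    census: pd.DataFrame | None = None,
    lags=(0, 1),
) -> tuple[pd.DataFrame, dict]:
    """Long-format matched-set design from raw study inputs.

    ``events`` columns: ``record_id, date, block_group_id, race, lon, lat``.
    When ``census`` is given, block-group composition and segregation
    columns (``pct_black, pct_white, rrs, rrs_category, ird``) are merged on;
    block groups with undefined scores are excluded (their records dropped,
    counted in the log).
    """
    cells = exposure[["cell_id", "lon", "lat"]].drop_duplicates("cell_id")
    rec = events.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    # nearest cell per unique residential coordinate
    uniq = rec[["lon", "lat"]].drop_duplicates().reset_index(drop=True)
    uniq["cell_id"] = assign_nearest_cells(uniq, cells)
    rec = rec.merge(uniq, on=["lon", "lat"], how="left")

    cov = cell_covariates(exposure, lags=lags)
    modifiers = None
    dropped_flagged = 0
    if census is not None:
        scores = score_census_table(census)
        ok = scores["flag"] == ""
        dropped_flagged = int(
            rec["block_group_id"].isin(set(scores.loc[~ok, "block_group_id"])).sum()
        )
        rec = rec[~rec["block_group_id"].isin(set(scores.loc[~ok, "block_group_id"]))]
        modifiers = scores.loc[ok, ["block_group_id", "pct_white", "pct_black", "rrs", "rrs_category", "ird"]]

    keep_cols = [c for c in ("record_id", "date", "block_group_id", "race", "cell_id") if c in rec.columns]
    design, log = build_matched_sets(rec[keep_cols], cov, modifiers=modifiers)
    log["dropped_flagged_block_group"] = dropped_flagged
    return design, dict(log)


def fit_study(design: pd.DataFrame, modifier: str | None = None, **fit_kw) -> CaseCrossoverResults:
    """Fit the study model, optionally with one of the racial modifiers.

    ``modifier`` is one of ``race, pct_black, pct_white, ird, rrs_category``
    or None for the unmodified main model.
    """
    if modifier is None:
        spec = ModelSpec()
    elif modifier in MODIFIERS:
        spec = ModelSpec(**MODIFIERS[modifier])
    else:
        raise ValidationError(
            f"unknown modifier {modifier!r}; choose from {sorted(MODIFIERS)} or None"
        )
    return CaseCrossoverModel(design, spec).fit(**fit_kw)


def simulate_and_fit(cfg=None, seed: int = 0, modifier: str | None = None,
                     census: pd.DataFrame | None = None, **fit_kw):
    """One simulation replicate: generate a study and run the full pipeline.

    A pre-simulated ``census`` may be passed to hold the geography fixed
    across replicates (exposure and events are still freshly drawn); child
    seeds are spawned from ``seed`` exactly as in
    :func:`casecross.simulate.simulate_study`, so with ``census=None`` the
    replicate analyses that function's dataset.

    Returns ``(results, truth)``.
    """
    from .simulate import DEFAULT_CONFIG, simulate_census, simulate_events, simulate_exposure

    cfg = cfg or DEFAULT_CONFIG
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    if census is None:
        census = simulate_census(cfg, seed=s1)
    expo = simulate_exposure(cfg, census, seed=s2)
    events, truth = simulate_events(cfg, census, expo, seed=s3)
    design, _ = prepare_design(events, expo, census=census, lags=cfg.lags)
    return fit_study(design, modifier=modifier, **fit_kw), truth
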