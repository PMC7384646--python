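"""Exposure assignment and lag-window construction.

Each event record is assigned, once, the daily PM2.5/temperature series of
the grid cell nearest (great-circle distance) to its residential coordinates
— a static-residence assumption. Time-varying covariates are then moving
averages over a configurable set of non-negative lags; the main analysis
window is the two-day mean (lags {0, 1}).

A window mean is defined only when *all* constituent daily values are
present; otherwise it is NaN and the affected day is excluded downstream
rather than imputed, which preserves the validity of the matched-set
conditional likelihood.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "haversine_km",
    "assign_nearest_cell",
    "assign_nearest_cells",
    "window_mean",
    "rolling_window",
    "build_cell_series",
    "daily_covariates",
]

_EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Broadcasts over array inputs.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def assign_nearest_cell(record_lonlat, cells: pd.DataFrame) -> str:
    """Grid cell nearest to a residential coordinate.

    Parameters
    ----------
    record_lonlat
        ``(lon, lat)`` in decimal degrees.
    cells
        Frame with columns ``cell_id, lon, lat`` (one row per cell).

    Ties in distance are broken by the lexicographically smallest cell id so
    the assignment is deterministic and permutation-invariant.
    """
    if len(cells) == 0:
        raise ConfigurationError("empty grid-cell list")
    lon, lat = record_lonlat
    if not (np.isfinite(lon) and np.isfinite(lat)):
        raise ValidationError(f"non-finite record coordinates ({lon!r}, {lat!r})")
    d = haversine_km(lon, lat, cells["lon"].to_numpy(), cells["lat"].to_numpy())
    ids = cells["cell_id"].astype(str).to_numpy()
    best = d.min()
    return str(min(ids[d == best]))


def _unit_xyz(lon, lat):
    lon, lat = np.radians(np.asarray(lon, dtype=float)), np.radians(np.asarray(lat, dtype=float))
    return np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def assign_nearest_cells(points: pd.DataFrame, cells: pd.DataFrame) -> pd.Series:
    """Vectorized nearest-cell assignment for many points.

    ``points`` has columns ``lon, lat``; returns a Series of cell ids aligned
    with ``points``'s index. Same metric and tie-break as
    :func:`assign_nearest_cell`: chord distance on the unit sphere is
    monotone in great-circle distance, so a KD-tree query is exact; near-ties
    are re-checked among the closest candidates and broken by smallest id.
    """
    if len(cells) == 0:
        raise ConfigurationError("empty grid-cell list")
    from scipy.spatial import cKDTree

    cs = cells.sort_values("cell_id", key=lambda s: s.astype(str)).reset_index(drop=True)
    tree = cKDTree(_unit_xyz(cs["lon"], cs["lat"]))
    k = min(4, len(cs))
    dist, idx = tree.query(_unit_xyz(points["lon"], points["lat"]), k=k)
    if k == 1:
        best = np.atleast_1d(idx)
    else:
        # among candidates within rounding of the minimum, take smallest id
        tied = dist <= dist[:, [0]] * (1 + 1e-12) + 1e-12
        masked = np.where(tied, idx, len(cs))
        best = masked.min(axis=1)
    return pd.Series(cs["cell_id"].astype(str).to_numpy()[best], index=points.index)


def window_mean(series: pd.Series, date, lags, on_missing: str = "nan") -> float:
    """Arithmetic mean of daily values at ``date - lag`` for each lag.

    ``series`` is indexed by date. When any requested lag date is absent or
    NaN the window is undefined: with ``on_missing="nan"`` (default) NaN is
    returned as the missing-covariate marker and downstream code drops the
    day; with ``on_missing="raise"`` a
    :class:`~casecross.exceptions.MissingCovariateError` is raised.
    """
    from .exceptions import MissingCovariateError

    lags = sorted(set(int(l) for l in lags))
    if not lags or min(lags) < 0:
        raise ValidationError(f"lags must be non-negative and non-empty, got {lags}")
    date = pd.Timestamp(date)
    vals = []
    for lag in lags:
        day = date - pd.Timedelta(days=lag)
        vals.append(series.loc[day] if day in series.index else np.nan)
    vals = np.asarray(vals, dtype=float)
    if np.isnan(vals).any():
        if on_missing == "raise":
            raise MissingCovariateError(
                f"window at {date.date()} over lags {lags} has missing daily values"
            )
        return float("nan")
    return float(vals.mean())


def build_cell_series(exposure: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pivot a long exposure table into per-variable (date x cell) frames.

    ``exposure`` has columns ``cell_id, lon, lat, date, pm25, temperature``.
    Validates the daily calendar is contiguous per cell and pm25 >= 0.
    Returns ``{"pm25": frame, "temperature": frame}`` with a DatetimeIndex
    and one column per cell id.
    """
    df = exposure.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["cell_id"] = df["cell_id"].astype(str)
    if (df["pm25"].dropna() < 0).any():
        raise ValidationError("negative PM2.5 value in exposure table")
    if df.duplicated(["cell_id", "date"]).any():
        raise ValidationError("duplicate (cell, date) rows in exposure table")
    out = {}
    for var in ("pm25", "temperature"):
        wide = df.pivot(index="date", columns="cell_id", values=var).sort_index()
        full = pd.date_range(wide.index.min(), wide.index.max(), freq="D")
        if len(full) != len(wide.index):
            raise ValidationError("exposure dates do not form a contiguous daily calendar")
        out[var] = wide
    return out


def rolling_window(wide: pd.DataFrame, lags) -> pd.DataFrame:
    """Moving average over ``lags`` of a (date x cell) frame.

    Row ``d`` holds the mean of rows ``d - lag`` for each lag; NaN where any
    constituent day is unavailable (incl. the first ``max(lags)`` days).
    """
    lags = sorted(set(int(l) for l in lags))
    if not lags or min(lags) < 0:
        raise ValidationError(f"lags must be non-negative and non-empty, got {lags}")
    acc = sum(wide.shift(l) for l in lags)
    return acc / len(lags)


def daily_covariates(
    records: pd.DataFrame,
    exposure: pd.DataFrame,
    lags=(0, 1),
) -> pd.DataFrame:
    """Per-record windowed exposure covariates at the record's own date.

    ``records`` has columns ``record_id, date, lon, lat``; the result has
    ``record_id, date, cell_id, pm25_window, temp_window, dow`` with dow as
    weekday name. Windows are NaN when any constituent day is missing.
    """
    cells = exposure[["cell_id", "lon", "lat"]].drop_duplicates("cell_id")
    series = build_cell_series(exposure)
    pm_w = rolling_window(series["pm25"], lags)
    t_w = rolling_window(series["temperature"], lags)

    out = records[["record_id", "date"]].copy()
    out["date"] = pd.to_datetime(out["date"])
    out["cell_id"] = assign_nearest_cells(records[["lon", "lat"]], cells).to_numpy()

    def look(wide, dates, cids):
        di = wide.index.get_indexer(dates)
        ci = wide.columns.get_indexer(cids)
        vals = np.full(len(dates), np.nan)
        ok = (di >= 0) & (ci >= 0)
        vals[ok] = wide.to_numpy()[di[ok], ci[ok]]
        return vals

    out["pm25_window"] = look(pm_w, out["date"], out["cell_id"])
    out["temp_window"] = look(t_w, out["date"], out["cell_id"])
    out["dow"] = out["date"].dt.day_name()
    return out
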