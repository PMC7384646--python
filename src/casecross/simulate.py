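"""Synthetic study generator with known ground truth.

Generates the three inputs of the case-crossover pipeline — a nested census
race-count table, a gridded daily PM2.5/temperature series, and individual
mortality records — under a Poisson log-linear daily death rate. Because
deaths are rare at the daily/block-group scale, conditioning a Poisson
log-linear rate on the matched-set totals yields exactly the conditional-
logistic softmax the pipeline estimates, so the implied case-crossover log
odds for the exposure window equals ``beta + delta * m`` by construction
and fitted estimates are directly comparable to the echoed truth.

What the generator emulates
---------------------------
* Block-group race composition: a right-skewed percent-black distribution
  (a point mass at zero, a low-mix bulk, a small high-black component and a
  small racially balanced component) whose p10/p90 anchors are
  configurable; the low-mix Beta shape is solved at run time from the
  anchors, and the high-black/balanced components guarantee all five
  segregation-score categories are populated.
* Daily PM2.5: annual cycle + shared AR(1) day-to-day variation + a
  time-constant cell offset that increases with the percent black of the
  cell's block group (an exposure-disparity gradient) + iid cell noise,
  truncated at zero.
* Daily temperature: annual cycle + AR(1) noise.
* Mortality: per (block group, race, day) Poisson counts with day-of-week
  multipliers, a U-shaped temperature-mortality term, the exposure effect
  ``beta_pm`` per ug/m^3 of the two-day window, and an optional
  exposure x modifier interaction ``delta`` (modifier: block-group percent
  black, decedent race, or any scored column).

Each death becomes a decedent record carrying date, block group, race,
residential coordinates (jittered block-group centroid) and descriptive
covariates (age, sex, education, place of death) that play no role in the
likelihood.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ValidationError
from .exposure import assign_nearest_cells, rolling_window
from .segregation import score_census_table

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticStudy",
    "simulate_census",
    "simulate_exposure",
    "simulate_events",
    "simulate_study",
    "config_for_modification",
    "DEFAULT_CONFIG",
    "FULL_SCALE_CONFIG",
]

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class SimulationConfig:
    """All generating parameters of the synthetic study.

    The default scale (500 block groups in 120 tracts, two years, roughly
    twenty thousand events) is small enough for repeated simulation studies
    on one CPU while keeping per-fit standard errors a few times the
    full-scale study's; ``FULL_SCALE_CONFIG`` mirrors the real study's
    dimensions (4,613 block groups, eleven years, ~130k events).
    """

    # geography
    n_block_groups: int = 500
    n_tracts: int = 120
    grid_nx: int = 25
    grid_ny: int = 20
    lon_min: float = -71.5
    lat_min: float = 42.0
    cell_deg: float = 0.012  # ~1 km in latitude
    centroid_jitter_deg: float = 0.002
    # study period
    start: str = "2001-01-01"
    end: str = "2002-12-31"
    # race composition (percent-black mixture, decedent-weighted anchors)
    p_zero_black: float = 0.25     # point mass of exactly-zero-black block groups
    p_high_black: float = 0.04     # high-black component (populates G1/G2)
    high_black_a: float = 8.0      # Beta(a, b) of the high component, on [0, 1]
    high_black_b: float = 2.0
    p_mixed_black: float = 0.03    # racially balanced component (populates G3)
    mixed_black_a: float = 25.0
    mixed_black_b: float = 27.0
    low_black_a: float = 0.9       # Beta a of the low-mix bulk; b solved from anchors
    pct_black_p10: float = 0.0     # target 10th percentile of percent black
    pct_black_p90: float = 16.0    # target 90th percentile of percent black
    pct_other_a: float = 2.0       # Beta for percent of other races
    pct_other_b: float = 30.0
    bg_pop_min: int = 600
    bg_pop_max: int = 3000
    majority_race: str = "white"   # "black" swaps the two race counts
    # PM2.5 process (ug/m^3)
    pm_base: float = 10.0
    pm_seasonal_amp: float = 2.5
    pm_ar: float = 0.6
    pm_daily_sd: float = 6.0       # stationary sd of the shared AR(1) term
    pm_cell_noise_sd: float = 1.0  # iid per (cell, day)
    pm_black_gradient: float = 0.03  # ug/m^3 per percent black (cross-sectional)
    pm_cell_offset_sd: float = 0.8
    # temperature process (deg C)
    temp_mean: float = 10.0
    temp_seasonal_amp: float = 12.0
    temp_ar: float = 0.7
    temp_daily_sd: float = 3.0
    temp_cell_noise_sd: float = 0.5
    # mortality model
    base_rate: float = 3.2e-5      # deaths per person-day at covariate zero
    beta_pm: float = float(np.log(1.02) / 10.0)  # per ug/m^3 of the window
    delta: float = 0.0             # interaction log odds per unit modifier
    interaction_modifier: str | None = None  # None|"pct_black"|"race"|scored column
    dow_log: tuple = (0.0, 0.02, 0.02, 0.01, 0.01, 0.0, -0.03)  # Mon..Sun
    temp_center: float = 15.0
    temp_lin: float = -0.005       # per deg C (cold excess)
    temp_quad: float = 0.0004      # per deg C^2 (heat excess)
    lags: tuple = (0, 1)
    max_events: int = 500_000

    def validate(self):
        if not (-1.0 < self.pm_ar < 1.0 and -1.0 < self.temp_ar < 1.0):
            raise ValidationError("AR(1) coefficients must lie in (-1, 1)")
        if self.base_rate <= 0 or self.pm_daily_sd < 0 or self.temp_daily_sd < 0:
            raise ValidationError("rates and noise scales must be positive")
        if self.n_tracts > self.n_block_groups:
            raise ValidationError("more tracts than block groups")
        if self.majority_race not in ("white", "black"):
            raise ValidationError("majority_race must be 'white' or 'black'")
        if pd.Timestamp(self.start) >= pd.Timestamp(self.end):
            raise ValidationError("empty study period")

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")

    def n_cells(self) -> int:
        return self.grid_nx * self.grid_ny


DEFAULT_CONFIG = SimulationConfig()

#: Mirrors the real study's dimensions; ~25x the default's run time.
FULL_SCALE_CONFIG = replace(
    DEFAULT_CONFIG,
    n_block_groups=4613,
    n_tracts=1100,
    grid_nx=80,
    grid_ny=60,
    start="2001-01-01",
    end="2011-12-31",
    base_rate=2.4e-5,
)


@dataclass
class GroundTruth:
    """Generating parameters echoed next to every simulated dataset."""

    beta_pm: float
    delta: float
    interaction_modifier: str | None
    percent_change_per10: float
    config: dict = field(default_factory=dict)

    def percent_change_at(self, m: float) -> float:
        """True percent change per 10 ug/m^3 at modifier value ``m``."""
        return 100.0 * float(np.expm1(10.0 * (self.beta_pm + self.delta * m)))

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def config_for_modification(
    pc_at_zero: float,
    pc_at_m: float,
    m: float,
    modifier: str = "pct_black",
    base: SimulationConfig = DEFAULT_CONFIG,
) -> SimulationConfig:
    """Config whose true per-10 ug/m^3 percent change is ``pc_at_zero`` at
    modifier value 0 and ``pc_at_m`` at modifier value ``m``.

    Solves ``beta_pm`` and the interaction ``delta`` from the two anchors of
    the exposure-response gradient.
    """
    if m == 0:
        raise ValidationError("anchor modifier value m must be nonzero")
    beta0 = float(np.log1p(pc_at_zero / 100.0) / 10.0)
    beta_m = float(np.log1p(pc_at_m / 100.0) / 10.0)
    return replace(
        base,
        beta_pm=beta0,
        delta=(beta_m - beta0) / m,
        interaction_modifier=modifier,
    )


def _solve_low_black_beta_b(cfg: SimulationConfig) -> float:
    """Beta ``b`` of the low-mix bulk such that the percent-black mixture
    hits the configured p90 anchor."""
    p0, ph = cfg.p_zero_black, cfg.p_high_black
    q = cfg.pct_black_p90 / 100.0
    if not (0.0 < q < 1.0):
        raise ValidationError("pct_black_p90 must be in (0, 100)")
    # a p10 anchor of 0 requires at least 10% exactly-zero block groups
    if cfg.pct_black_p10 == 0.0 and p0 < 0.10:
        raise ValidationError("p10 anchor of 0% needs p_zero_black >= 0.10")
    if p0 >= 0.9:
        # degenerate all-majority composition: the p90 anchor sits in the
        # zero point mass and the bulk shape is immaterial
        return 1e4
    pm_ = cfg.p_mixed_black
    high_mass_below = stats.beta.cdf(q, cfg.high_black_a, cfg.high_black_b)
    mixed_mass_below = stats.beta.cdf(q, cfg.mixed_black_a, cfg.mixed_black_b)
    target = (0.9 - p0 - ph * high_mass_below - pm_ * mixed_mass_below) / (
        1.0 - p0 - ph - pm_
    )
    if not (0.0 < target < 1.0):
        raise ValidationError("infeasible percent-black anchor configuration")

    def f(b):
        return stats.beta.cdf(q, cfg.low_black_a, b) - target

    try:
        return float(optimize.brentq(f, 1e-3, 1e4))
    except ValueError as exc:
        raise ValidationError("infeasible percent-black anchor configuration") from exc


def _grid(cfg: SimulationConfig) -> pd.DataFrame:
    ix = np.arange(cfg.n_cells())
    gx, gy = ix % cfg.grid_nx, ix // cfg.grid_nx
    return pd.DataFrame(
        {
            "cell_id": [f"C{i:04d}" for i in ix],
            "lon": cfg.lon_min + gx * cfg.cell_deg / np.cos(np.radians(cfg.lat_min)),
            "lat": cfg.lat_min + gy * cfg.cell_deg,
        }
    )


def simulate_census(cfg: SimulationConfig, seed: int = 0) -> pd.DataFrame:
    """Nested block-group/tract race counts plus block-group centroids.

    Returns columns ``block_group_id, tract_id, n_white, n_black, n_total,
    lon, lat``; the first five form the census table proper.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = cfg.n_block_groups
    b_low = _solve_low_black_beta_b(cfg)

    u = rng.random(n)
    pb = np.empty(n)
    c1 = cfg.p_zero_black
    c2 = c1 + cfg.p_high_black
    c3 = c2 + cfg.p_mixed_black
    zero, high, mixed = u < c1, (u >= c1) & (u < c2), (u >= c2) & (u < c3)
    mid = ~zero & ~high & ~mixed
    pb[zero] = 0.0
    pb[high] = rng.beta(cfg.high_black_a, cfg.high_black_b, high.sum())
    pb[mixed] = rng.beta(cfg.mixed_black_a, cfg.mixed_black_b, mixed.sum())
    pb[mid] = rng.beta(cfg.low_black_a, b_low, mid.sum())

    p_other = rng.beta(cfg.pct_other_a, cfg.pct_other_b, n)
    p_other = np.minimum(p_other, 1.0 - pb)
    pw = 1.0 - pb - p_other

    pop = rng.integers(cfg.bg_pop_min, cfg.bg_pop_max + 1, n)
    n_black = np.rint(pb * pop).astype(int)
    n_white = np.rint(pw * pop).astype(int)
    n_white = np.minimum(n_white, pop - n_black)
    if cfg.majority_race == "black":
        n_white, n_black = n_black, n_white

    tract = np.floor(np.arange(n) * cfg.n_tracts / n).astype(int)
    grid = _grid(cfg)
    cell_ix = np.arange(n) % cfg.n_cells()
    jit = rng.normal(0.0, cfg.centroid_jitter_deg, (n, 2))
    return pd.DataFrame(
        {
            "block_group_id": [f"BG{i:05d}" for i in range(n)],
            "tract_id": [f"T{t:04d}" for t in tract],
            "n_white": n_white,
            "n_black": n_black,
            "n_total": pop,
            "lon": grid["lon"].to_numpy()[cell_ix] + jit[:, 0],
            "lat": grid["lat"].to_numpy()[cell_ix] + jit[:, 1],
        }
    )


def _ar1(rng, n, rho, sd):
    """Stationary AR(1) path of length n with marginal sd ``sd``."""
    if sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t]
    return x


def simulate_exposure(cfg: SimulationConfig, census: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Long daily exposure table ``cell_id, lon, lat, date, pm25, temperature``.

    The time-constant cell offset rises with the percent black of the block
    group(s) the cell serves, producing the cross-sectional exposure
    disparity; day-to-day variation is shared across cells (a regional
    AR(1) + annual cycle) with small independent cell noise.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    dates = cfg.dates()
    nd, nc = len(dates), cfg.n_cells()
    grid = _grid(cfg)

    doy = dates.dayofyear.to_numpy()
    season_pm = cfg.pm_seasonal_amp * np.cos(2 * np.pi * (doy - 28) / _DAYS_PER_YEAR)
    season_t = -cfg.temp_seasonal_amp * np.cos(2 * np.pi * (doy - 28) / _DAYS_PER_YEAR)

    # percent black context of each cell = mean over its block groups
    pb = 100.0 * census["n_black"] / census["n_total"]
    cell_ix = np.arange(len(census)) % nc
    pb_cell = pd.Series(pb.to_numpy()).groupby(cell_ix).mean().reindex(range(nc)).fillna(pb.mean())
    offset = (
        cfg.pm_black_gradient * pb_cell.to_numpy()
        + rng.normal(0.0, cfg.pm_cell_offset_sd, nc)
    )

    pm_shared = cfg.pm_base + season_pm + _ar1(rng, nd, cfg.pm_ar, cfg.pm_daily_sd)
    t_shared = cfg.temp_mean + season_t + _ar1(rng, nd, cfg.temp_ar, cfg.temp_daily_sd)

    pm = pm_shared[:, None] + offset[None, :] + rng.normal(0.0, cfg.pm_cell_noise_sd, (nd, nc))
    np.maximum(pm, 0.0, out=pm)
    temp = t_shared[:, None] + rng.normal(0.0, cfg.temp_cell_noise_sd, (nd, nc))

    out = pd.DataFrame(
        {
            "cell_id": np.tile(grid["cell_id"].to_numpy(), nd),
            "lon": np.tile(grid["lon"].to_numpy(), nd),
            "lat": np.tile(grid["lat"].to_numpy(), nd),
            "date": np.repeat(dates.to_numpy(), nc),
            "pm25": pm.ravel(),
            "temperature": temp.ravel(),
        }
    )
    return out


def _modifier_values(cfg: SimulationConfig, scores: pd.DataFrame) -> np.ndarray:
    """Per-(block group) modifier value entering the generating interaction;
    race is handled separately (per decedent)."""
    if cfg.interaction_modifier in (None, "race"):
        return np.zeros(len(scores))
    if cfg.interaction_modifier not in scores.columns:
        raise ValidationError(f"unknown interaction modifier {cfg.interaction_modifier!r}")
    return scores[cfg.interaction_modifier].to_numpy(dtype=float)


def simulate_events(
    cfg: SimulationConfig,
    census: pd.DataFrame,
    exposure: pd.DataFrame,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Decedent records drawn from the Poisson log-linear daily rate.

    Returns ``(events, truth)``; events columns are ``record_id, date,
    block_group_id, race, lon, lat, age, sex, education, place_of_death``.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    dates = cfg.dates()
    nd = len(dates)

    scores = score_census_table(census)
    grid = _grid(cfg)
    cells = assign_nearest_cells(census[["lon", "lat"]], grid)
    cell_pos = {c: i for i, c in enumerate(grid["cell_id"])}
    cix = np.array([cell_pos[c] for c in cells])

    # windowed exposure per cell, then per block group
    pm_wide = exposure.pivot(index="date", columns="cell_id", values="pm25").sort_index()
    t_wide = exposure.pivot(index="date", columns="cell_id", values="temperature").sort_index()
    pm_w = rolling_window(pm_wide, cfg.lags).to_numpy()
    t_w = rolling_window(t_wide, cfg.lags).to_numpy()
    col_pos = {c: i for i, c in enumerate(pm_wide.columns)}
    cix_cols = np.array([col_pos[grid["cell_id"].iloc[i]] for i in cix])
    pm_bg = pm_w[:, cix_cols]  # (n_days, n_bg)
    t_bg = t_w[:, cix_cols]

    m_bg = _modifier_values(cfg, scores)
    dow = np.asarray(cfg.dow_log)[dates.dayofweek.to_numpy()]
    tc = t_bg - cfg.temp_center
    log_rate_shared = (
        dow[:, None] + cfg.beta_pm * pm_bg + cfg.temp_lin * tc + cfg.temp_quad * tc**2
    )

    nb = census["n_black"].to_numpy(dtype=float)
    nw = census["n_white"].to_numpy(dtype=float)
    valid = ~np.isnan(pm_bg)  # first max(lags) days have no window

    counts = {}
    for race, n_at_risk in (("white", nw), ("black", nb)):
        m = m_bg if cfg.interaction_modifier != "race" else np.full(len(census), float(race == "black"))
        lam = n_at_risk[None, :] * cfg.base_rate * np.exp(
            log_rate_shared + cfg.delta * pm_bg * m[None, :]
        )
        lam = np.where(valid, lam, 0.0)
        expected = lam.sum()
        if expected > cfg.max_events:
            raise ValidationError(
                f"expected event count {expected:.0f} exceeds cap {cfg.max_events}; reduce base_rate"
            )
        counts[race] = rng.poisson(lam)

    rows = []
    for race in ("white", "black"):
        ti, bi = np.nonzero(counts[race])
        k = counts[race][ti, bi]
        rows.append(
            pd.DataFrame(
                {
                    "date": np.repeat(dates.to_numpy()[ti], k),
                    "bg_index": np.repeat(bi, k),
                    "race": race,
                }
            )
        )
    ev = pd.concat(rows, ignore_index=True)
    ev = ev.sort_values(["date", "bg_index", "race"], kind="stable").reset_index(drop=True)
    ev["record_id"] = [f"R{i:07d}" for i in range(len(ev))]
    ev["block_group_id"] = census["block_group_id"].to_numpy()[ev["bg_index"]]
    ev["lon"] = census["lon"].to_numpy()[ev["bg_index"]] + rng.normal(0, cfg.centroid_jitter_deg / 2, len(ev))
    ev["lat"] = census["lat"].to_numpy()[ev["bg_index"]] + rng.normal(0, cfg.centroid_jitter_deg / 2, len(ev))

    # descriptive covariates only; they never enter the likelihood
    is_black = (ev["race"] == "black").to_numpy()
    age = rng.normal(np.where(is_black, 72.3, 80.5), np.where(is_black, 14.5, 12.3))
    ev["age"] = np.clip(np.rint(age), 40, 110).astype(int)
    ev["sex"] = np.where(rng.random(len(ev)) < 0.469, "M", "F")
    ev["education"] = rng.choice(
        ["elementary", "high_school", "some_college", "college_plus"],
        size=len(ev),
        p=[0.192, 0.537, 0.119, 0.152],
    )
    ev["place_of_death"] = np.where(rng.random(len(ev)) < 0.444, "hospital", "out_of_hospital")
    ev = ev.drop(columns="bg_index")[
        ["record_id", "date", "block_group_id", "race", "lon", "lat",
         "age", "sex", "education", "place_of_death"]
    ]

    truth = GroundTruth(
        beta_pm=float(cfg.beta_pm),
        delta=float(cfg.delta),
        interaction_modifier=cfg.interaction_modifier,
        percent_change_per10=100.0 * float(np.expm1(10.0 * cfg.beta_pm)),
        config=asdict(cfg),
    )
    return ev, truth


@dataclass
class SyntheticStudy:
    """A complete simulated study: inputs plus the generating truth."""

    config: SimulationConfig
    census: pd.DataFrame
    exposure: pd.DataFrame
    events: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir):
        """Write census.csv, exposure.csv, events.csv and truth.json."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.census.to_csv(out / "census.csv", index=False)
        self.exposure.to_csv(out / "exposure.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.truth.to_json(out / "truth.json")


def simulate_study(cfg: SimulationConfig = DEFAULT_CONFIG, seed: int = 0) -> SyntheticStudy:
    """Generate census, exposure and events under one master seed.

    The three stages draw from independent child seeds of ``seed`` so the
    whole study is reproducible bit-for-bit from ``(cfg, seed)``.
    """
    ss = np.random.SeedSequence(seed)
    s_census, s_expo, s_events = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    census = simulate_census(cfg, seed=s_census)
    exposure = simulate_exposure(cfg, census, seed=s_expo)
    events, truth = simulate_events(cfg, census, exposure, seed=s_events)
    return SyntheticStudy(cfg, census, exposure, events, truth)
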