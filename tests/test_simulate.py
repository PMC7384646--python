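"""Synthetic-study generator: determinism, composition, exposure process."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from casecross.exceptions import ValidationError
from casecross.segregation import score_census_table
from casecross.simulate import (
    DEFAULT_CONFIG,
    SimulationConfig,
    config_for_modification,
    simulate_census,
    simulate_events,
    simulate_exposure,
    simulate_study,
)

from conftest import SMALL_CONFIG


class TestDeterminism:
    def test_identical_seeds_identical_outputs(self):
        a = simulate_study(SMALL_CONFIG, seed=3)
        b = simulate_study(SMALL_CONFIG, seed=3)
        pd.testing.assert_frame_equal(a.census, b.census)
        pd.testing.assert_frame_equal(a.exposure, b.exposure)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_different_seeds_differ(self):
        a = simulate_census(SMALL_CONFIG, seed=3)
        b = simulate_census(SMALL_CONFIG, seed=4)
        assert not a.equals(b)


class TestCensus:
    def test_composition_anchors_and_category_coverage(self):
        census = simulate_census(DEFAULT_CONFIG, seed=11)
        scores = score_census_table(census.drop(columns=["lon", "lat"]))
        pb = scores["pct_black"].to_numpy()
        # decedent-weighted and block-group-weighted distributions coincide
        # in expectation (uniform per-capita rate)
        assert np.percentile(pb, 10) == pytest.approx(0.0, abs=1e-9)
        assert np.percentile(pb, 90) == pytest.approx(16.0, abs=5.0)
        assert set(scores["rrs_category"]) == {"G1", "G2", "G3", "G4", "G5"}
        # right-skewed: median far below mean of the nonzero tail
        assert np.median(pb) < pb.mean() * 1.5

    def test_counts_respect_population_invariants(self):
        census = simulate_census(DEFAULT_CONFIG, seed=5)
        assert (census["n_white"] + census["n_black"] <= census["n_total"]).all()
        assert census["n_total"].between(
            DEFAULT_CONFIG.bg_pop_min, DEFAULT_CONFIG.bg_pop_max
        ).all()
        assert census.groupby("block_group_id")["tract_id"].nunique().eq(1).all()

    def test_race_swap_mirrors_rrs(self):
        base = simulate_census(SMALL_CONFIG, seed=9)
        swap = simulate_census(
            dataclasses.replace(SMALL_CONFIG, majority_race="black"), seed=9
        )
        r1 = score_census_table(base.drop(columns=["lon", "lat"]))["rrs"]
        r2 = score_census_table(swap.drop(columns=["lon", "lat"]))["rrs"]
        np.testing.assert_allclose(r1.to_numpy(), -r2.to_numpy(), atol=1e-12)

    def test_all_white_limit(self):
        cfg = dataclasses.replace(
            SMALL_CONFIG, p_zero_black=0.999999, p_high_black=0.0,
            pct_black_p90=0.5, pct_other_a=1e-3,
        )
        census = simulate_census(cfg, seed=1)
        scores = score_census_table(census.drop(columns=["lon", "lat"]))
        assert (scores["rrs"] > 0.9).all()
        # IRD comparing an empty black distribution is flagged, not zeroed
        assert (scores["flag"] == "undefined_ird").all()

    def test_infeasible_anchor_rejected(self):
        with pytest.raises(ValidationError):
            simulate_census(
                dataclasses.replace(DEFAULT_CONFIG, p_zero_black=0.05), seed=0
            )  # p10 anchor of 0% unreachable with so few all-white block groups


class TestExposure:
    def test_zero_noise_zero_amplitude_is_constant(self):
        cfg = dataclasses.replace(
            SMALL_CONFIG,
            pm_seasonal_amp=0.0, pm_daily_sd=0.0, pm_cell_noise_sd=0.0,
            pm_cell_offset_sd=0.0, pm_black_gradient=0.0,
            temp_seasonal_amp=0.0, temp_daily_sd=0.0, temp_cell_noise_sd=0.0,
        )
        census = simulate_census(cfg, seed=2)
        expo = simulate_exposure(cfg, census, seed=2)
        assert expo["pm25"].nunique() == 1
        assert expo["temperature"].nunique() == 1

    def test_pm_nonnegative_and_calendar_contiguous(self, small_study):
        expo = small_study.exposure
        assert (expo["pm25"] >= 0).all()
        per_cell = expo.groupby("cell_id")["date"].count()
        assert per_cell.nunique() == 1

    def test_ar1_autocorrelation_recovered(self):
        census = simulate_census(DEFAULT_CONFIG, seed=21)
        expo = simulate_exposure(DEFAULT_CONFIG, census, seed=21)
        one = expo[expo["cell_id"] == "C0000"].sort_values("date")
        x = one["pm25"].to_numpy()
        doy = pd.to_datetime(one["date"]).dt.dayofyear.to_numpy()
        # remove the annual cycle by harmonic regression, then lag-1 autocorr
        H = np.column_stack(
            [np.ones_like(x), np.cos(2 * np.pi * doy / 365.25), np.sin(2 * np.pi * doy / 365.25)]
        )
        resid = x - H @ np.linalg.lstsq(H, x, rcond=None)[0]
        r1 = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert r1 == pytest.approx(DEFAULT_CONFIG.pm_ar, abs=0.1)

    def test_gradient_links_pm_to_percent_black(self):
        census = simulate_census(DEFAULT_CONFIG, seed=13)
        expo = simulate_exposure(DEFAULT_CONFIG, census, seed=13)
        pb = (100.0 * census["n_black"] / census["n_total"]).to_numpy()
        cell_mean = expo.groupby("cell_id", sort=True)["pm25"].mean()
        # default: block group i sits at cell i
        r = np.corrcoef(pb, cell_mean.to_numpy())[0, 1]
        assert r > 0.3

    def test_null_gradient_uncorrelated(self):
        cfg = dataclasses.replace(DEFAULT_CONFIG, pm_black_gradient=0.0)
        census = simulate_census(cfg, seed=13)
        expo = simulate_exposure(cfg, census, seed=13)
        pb = (100.0 * census["n_black"] / census["n_total"]).to_numpy()
        cell_mean = expo.groupby("cell_id", sort=True)["pm25"].mean()
        assert abs(np.corrcoef(pb, cell_mean.to_numpy())[0, 1]) < 0.1


class TestEvents:
    def test_race_mix_tracks_census_composition(self, small_study):
        census, events = small_study.census, small_study.events
        share_black_events = (events["race"] == "black").mean()
        share_black_pop = census["n_black"].sum() / (
            census["n_black"].sum() + census["n_white"].sum()
        )
        assert share_black_events == pytest.approx(share_black_pop, abs=0.03)

    def test_truth_echoes_generating_parameters(self, small_study):
        t = small_study.truth
        assert t.beta_pm == pytest.approx(np.log(1.02) / 10)
        assert t.percent_change_per10 == pytest.approx(2.0, abs=1e-9)
        assert t.config["n_block_groups"] == SMALL_CONFIG.n_block_groups

    def test_event_cap_enforced(self):
        cfg = dataclasses.replace(SMALL_CONFIG, max_events=100)
        census = simulate_census(cfg, seed=1)
        expo = simulate_exposure(cfg, census, seed=1)
        with pytest.raises(ValidationError):
            simulate_events(cfg, census, expo, seed=1)

    def test_events_pass_pipeline_validators(self, small_study, small_design):
        # every record flows through scoring, assignment and set-building
        assert small_design["record_id"].nunique() == len(small_study.events)
        assert small_design[["pm25_window", "temp_window", "pct_black", "ird"]].notna().all().all()


class TestConfig:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(pm_ar=1.5),
            dict(base_rate=0.0),
            dict(n_tracts=10_000),
            dict(majority_race="green"),
            dict(start="2002-01-01", end="2001-01-01"),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValidationError):
            dataclasses.replace(DEFAULT_CONFIG, **bad).validate()

    def test_config_for_modification_anchors(self):
        cfg = config_for_modification(1.6, 3.4, m=16.0)
        assert 100 * np.expm1(10 * cfg.beta_pm) == pytest.approx(1.6, rel=1e-12)
        assert 100 * np.expm1(10 * (cfg.beta_pm + 16 * cfg.delta)) == pytest.approx(3.4, rel=1e-12)
        assert cfg.interaction_modifier == "pct_black"


def test_simulate_cli_writes_all_outputs(tmp_path):
    from click.testing import CliRunner

    from casecross.cli import main

    cfg_yaml = tmp_path / "cfg.yaml"
    cfg_yaml.write_text(
        "n_block_groups: 30\nn_tracts: 6\ngrid_nx: 6\ngrid_ny: 5\n"
        "start: '2001-01-01'\nend: '2001-03-31'\n"
    )
    result = CliRunner().invoke(
        main,
        ["simulate", "--config", str(cfg_yaml), "--seed", "5", "--outdir", str(tmp_path / "out")],
    )
    assert result.exit_code == 0, result.output
    for name in ("census.csv", "exposure.csv", "events.csv", "truth.json"):
        assert (tmp_path / "out" / name).exists()
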