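"""Cohort generator: design invariants, determinism, threshold mechanics."""

import numpy as np
import pandas as pd
import pytest

from thermaldev.simulate import (
    SimulationConfig,
    build_sampling_schedule,
    generate_cohort,
    rate_attenuation,
)
from thermaldev.stages import DEAD, PREADULT_STAGES, STAGES


def test_same_config_same_seed_is_bit_identical(default_config, default_cohort):
    again = generate_cohort(default_config)
    pd.testing.assert_frame_equal(default_cohort, again)


def test_counts_plus_deaths_conserve_cup_size(default_cohort):
    total = default_cohort[list(STAGES)].sum(axis=1) + default_cohort[DEAD]
    assert (total == default_cohort["n_total"]).all()
    assert (default_cohort["n_total"] == 20).all()


def test_each_cup_sampled_once(default_cohort):
    keys = default_cohort[["temperature_c", "time_h", "replicate"]]
    assert not keys.duplicated().any()


def test_no_development_below_biological_minimum(default_cohort):
    """At 7.5 and 10.0 degC (below the 11 degC biological minimum) every
    individual stays an egg at every sampling time."""
    cold = default_cohort[default_cohort["temperature_c"].isin([7.5, 10.0])]
    assert len(cold) > 0
    assert (cold["E"] == cold["n_total"]).all()
    assert (cold[list(STAGES[1:])].to_numpy() == 0).all()


def test_mortality_produces_dead_and_conserves():
    cfg = SimulationConfig(mortality_per_stage=0.1, seed=3)
    obs = generate_cohort(cfg)
    assert obs[DEAD].sum() > 0
    total = obs[list(STAGES)].sum(axis=1) + obs[DEAD]
    assert (total == obs["n_total"]).all()


def test_cv_zero_counts_are_all_or_nothing_at_closed_form_crossings():
    """With cv = 0 every individual shares the same thresholds, so each cup
    is entirely in the stage given by comparing elapsed physiological time
    to the cumulative ADD thresholds: the stage flips at exactly
    t = 24 * cumulative_ADD / (T - dev_min) hours."""
    cfg = SimulationConfig(
        temperatures=(17.5, 25.0),
        transition_cv=0.0,
        curvature_strength=0.0,
        seed=5,
    )
    obs = generate_cohort(cfg)
    cum_add = np.cumsum(cfg.stage_add_array)
    for _, row in obs.iterrows():
        t_cross = 24.0 * cum_add / (row["temperature_c"] - cfg.true_dev_min)
        expected_stage = int((row["time_h"] >= t_cross).sum())
        counts = np.array([row[s] for s in STAGES])
        assert counts[expected_stage] == row["n_total"]
        assert counts.sum() == row["n_total"]


def test_stage_occupancy_monotone_in_time_at_fixed_temperature():
    cfg = SimulationConfig(transition_cv=0.0, seed=2)
    obs = generate_cohort(cfg)
    idx = {s: i for i, s in enumerate(STAGES)}
    for temp, grp in obs.groupby("temperature_c"):
        grp = grp.sort_values("time_h")
        mean_stage = (
            grp[list(STAGES)].to_numpy() * np.array([idx[s] for s in STAGES])
        ).sum(axis=1) / grp["n_total"].to_numpy()
        assert (np.diff(mean_stage) >= -1e-12).all()


def test_transition_time_scales_inversely_with_excess_temperature():
    """curvature 0, cv 0: observed hatch bracketing times obey
    t * (T - dev_min) = 24 * ADD_egg within one sampling interval."""
    cfg = SimulationConfig(
        temperatures=(15.0, 20.0, 30.0),
        transition_cv=0.0,
        curvature_strength=0.0,
        seed=0,
    )
    obs = generate_cohort(cfg)
    for temp, grp in obs.groupby("temperature_c"):
        grp = grp.sort_values("time_h")
        hatched = grp[grp["L1"] + grp[list(STAGES[2:])].sum(axis=1) > 0]
        t_true = 24.0 * cfg.true_stage_add["E"] / (temp - cfg.true_dev_min)
        first_hatch_obs = hatched["time_h"].min()
        before = grp[grp["time_h"] < first_hatch_obs]["time_h"]
        assert first_hatch_obs >= t_true - 1e-9
        if len(before):
            assert before.max() < t_true


# ----------------------------------------------------------------------
# Sampling schedule
# ----------------------------------------------------------------------
DUR = {s: d for s, d in zip(PREADULT_STAGES, (16.0, 44.0, 63.0, 111.0, 281.0, 441.0))}


def test_window_inversely_proportional_to_excess_temperature():
    sched = build_sampling_schedule(DUR, 25.0, 10.0, [17.5, 25.0])
    # 25 degC sits 15 degC above the minimum, twice as far as 17.5 degC:
    # every window at 17.5 degC is twice as long.
    for stage in PREADULT_STAGES:
        np.testing.assert_allclose(
            sched.times_for(17.5)[stage], 2.0 * sched.times_for(25.0)[stage]
        )


def test_windows_divided_into_equal_sample_times():
    sched = build_sampling_schedule({**DUR, "E": 10.0}, 25.0, 10.0, [25.0])
    np.testing.assert_allclose(
        sched.times_for(25.0)["E"], [2.0, 4.0, 6.0, 8.0, 10.0]
    )


def test_default_egg_interval_at_25C_matches_reference_magnitude():
    """The egg-hatch sampling interval at 25 degC is 2-3 h in the reference
    design; the default pilot schedule lands in that window."""
    cfg = SimulationConfig()
    sched = build_sampling_schedule(
        cfg.pilot_durations(), cfg.reference_temp, cfg.assumed_dev_min,
        cfg.temperatures, cfg.samples_per_stage,
    )
    times = sched.times_for(25.0)["E"]
    interval = float(np.diff(times).mean())
    assert 2.0 <= interval <= 3.0


def test_sub_minimum_temperatures_reuse_lowest_schedule():
    cfg = SimulationConfig()
    sched = build_sampling_schedule(
        cfg.pilot_durations(), 25.0, 10.0, cfg.temperatures
    )
    for stage in PREADULT_STAGES:
        np.testing.assert_array_equal(
            sched.times_for(7.5)[stage], sched.times_for(12.5)[stage]
        )
        np.testing.assert_array_equal(
            sched.times_for(10.0)[stage], sched.times_for(12.5)[stage]
        )


def test_schedule_input_validation():
    with pytest.raises(ValueError, match="non-empty"):
        build_sampling_schedule({}, 25.0, 10.0, [25.0])
    with pytest.raises(ValueError, match="positive"):
        build_sampling_schedule({**DUR, "E": -1.0}, 25.0, 10.0, [25.0])
    with pytest.raises(ValueError, match="reference_temp"):
        build_sampling_schedule(DUR, 10.0, 10.0, [25.0])


def test_config_invariants_enforced():
    with pytest.raises(ValueError, match="strictly increasing"):
        SimulationConfig(temperatures=(20.0, 15.0))
    with pytest.raises(ValueError, match="transition_cv"):
        SimulationConfig(transition_cv=1.2)
    with pytest.raises(ValueError, match="eggs_per_cup"):
        SimulationConfig(eggs_per_cup=0)
    with pytest.raises(ValueError, match="linear_range"):
        SimulationConfig(linear_range=(30.0, 15.0))


def test_attenuation_is_one_inside_linear_range_zero_below_biological_min():
    cfg = SimulationConfig()
    assert rate_attenuation(20.0, cfg) == 1.0
    assert rate_attenuation(32.5, cfg) == 1.0
    assert rate_attenuation(11.0, cfg) == 0.0
    assert 0.0 < rate_attenuation(12.5, cfg) < 1.0
    no_curve = SimulationConfig(curvature_strength=0.0)
    assert rate_attenuation(12.5, no_curve) == 1.0
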