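"""Simulator unit and property tests: dynamics, label arithmetic, treatment."""

import math

import numpy as np
import pandas as pd
import pytest

from lrckit import (
    SimConfig,
    TreatmentPlan,
    apply_treatment,
    measure_flow,
    retransplant,
    simulate_engraftment,
    simulate_expression,
    simulate_lda,
)
from lrckit.simulate import EmptyCohortError, PopulationCapError


def test_no_dynamics_keeps_population_fixed():
    cfg = SimConfig(
        n_injected=100, homing_prob=1.0, r=0.0, d=0.0, p_dormant_seed=0.0,
        K=1e6, n_days=5, lag_days=0, seed=0,
    )
    cohort, burden = simulate_engraftment(cfg)
    assert (burden["n_cells"] == 100).all()
    assert (cohort.cells["divisions"] == 0).all()


def test_deterministic_doubling_three_days():
    # daily division probability 1: 100 cells -> 800 after 3 days, all k=3
    cfg = SimConfig(
        n_injected=100, homing_prob=1.0, r=1.0, d=0.0, p_dormant_seed=0.0,
        K=math.inf, n_days=3, lag_days=0, seed=0,
    )
    cohort, burden = simulate_engraftment(cfg)
    assert burden["n_cells"].tolist() == [100, 200, 400, 800]
    assert (cohort.cells["divisions"] == 3).all()
    assert np.allclose(cohort.cells["true_mfi"], cfg.m0 / 8)


def test_mean_trajectory_matches_discretized_logistic():
    """Stochastic mean tracks the deterministic per-step logistic map."""
    cfg = SimConfig(
        n_injected=10_000, homing_prob=1.0, r=0.9, K=1e6, d=0.0,
        p_dormant_seed=0.0, n_days=21, lag_days=0,
    )
    reps = 8
    trajs = []
    for seed in range(reps):
        _, burden = simulate_engraftment(cfg.with_(seed=seed))
        trajs.append(burden["n_cells"].to_numpy(float))
    trajs = np.array(trajs)
    mean = trajs.mean(axis=0)
    se = trajs.std(axis=0, ddof=1) / math.sqrt(reps)

    det = [10_000.0]
    for _ in range(cfg.n_days):
        n = det[-1]
        det.append(n * (1.0 + max(cfg.r * (1.0 - n / cfg.K), 0.0)))
    det = np.array(det)
    # 3 Monte-Carlo SE band, skipping day 0 (both exactly n0)
    assert np.all(np.abs(mean[1:] - det[1:]) <= 3 * se[1:] + 1e-9)


def test_exponential_mean_growth_without_niche():
    """With K -> inf and d = 0 the mean follows N0*(1+p)^t."""
    cfg = SimConfig(
        n_injected=500, homing_prob=1.0, r=0.4, K=math.inf, d=0.0,
        p_dormant_seed=0.0, n_days=6, lag_days=0,
    )
    finals = np.array([
        simulate_engraftment(cfg.with_(seed=s))[1]["n_cells"].iloc[-1]
        for s in range(40)
    ], dtype=float)
    expected = 500 * 1.4**6
    se = finals.std(ddof=1) / math.sqrt(finals.size)
    assert abs(finals.mean() - expected) <= 3 * se


def test_label_conservation_noiseless(noiseless_cohort):
    """measured_mfi * 2**divisions == m0 exactly when noise is off."""
    cfg, cohort, _ = noiseless_cohort
    sample = measure_flow(cohort, cv_mfi=0.0)
    recovered = sample.data["measured_mfi"].to_numpy() * np.exp2(
        sample.data["divisions_truth"].to_numpy(float)
    )
    assert np.all(recovered == cfg.m0)


def test_divisions_never_decrease_along_burden():
    cfg = SimConfig(n_injected=2000, homing_prob=1.0, r=0.5, K=1e5, d=0.1,
                    p_dormant_seed=0.0, n_days=10, lag_days=0, seed=3)
    cohort, burden = simulate_engraftment(cfg)
    assert (cohort.cells["divisions"] >= 0).all()
    assert burden["day"].is_monotonic_increasing


def test_same_seed_reproducible_different_seed_not():
    cfg = SimConfig(n_injected=5000, homing_prob=0.5, K=1e5, n_days=8, seed=11)
    a, _ = simulate_engraftment(cfg)
    b, _ = simulate_engraftment(cfg)
    pd.testing.assert_frame_equal(a.cells, b.cells)
    c, _ = simulate_engraftment(cfg.with_(seed=12))
    assert len(c) != len(a) or not a.cells["divisions"].equals(c.cells["divisions"])


def test_hard_cap_aborts_with_message():
    cfg = SimConfig(n_injected=1000, homing_prob=1.0, r=1.0, K=math.inf,
                    d=0.0, n_days=10, lag_days=0, hard_cap=10_000, seed=0)
    with pytest.raises(PopulationCapError, match="hard cap"):
        simulate_engraftment(cfg)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"homing_prob": 0.0},
        {"homing_prob": 1.5},
        {"d": 1.0},
        {"r": -0.1},
        {"r": 1.2},  # r*dt > 1
        {"m0": 0.0},
        {"cv_mfi": -0.1},
        {"K": 10.0, "n_injected": 1000, "homing_prob": 1.0},
        {"dt": 0.3},
    ],
)
def test_config_validation_rejects(kwargs):
    with pytest.raises(ValueError):
        SimConfig(**kwargs)


def test_substep_dt_preserves_daily_burden_grid():
    cfg = SimConfig(n_injected=2000, homing_prob=1.0, r=0.8, K=1e5,
                    p_dormant_seed=0.0, n_days=6, lag_days=0, dt=0.5, seed=4)
    _, burden = simulate_engraftment(cfg)
    assert burden["day"].tolist() == list(range(7))


# ---- flow readout ----------------------------------------------------------

def test_measure_flow_exact_values():
    cfg = SimConfig(n_injected=4, homing_prob=1.0, r=1.0, d=0.0, K=math.inf,
                    p_dormant_seed=0.0, n_days=3, lag_days=0, m0=1000.0, seed=0)
    cohort, _ = simulate_engraftment(cfg)
    sample = measure_flow(cohort, cv_mfi=0.0)
    assert np.all(sample.data["measured_mfi"] == 125.0)  # 1000 / 2**3


def test_measure_flow_identity_at_zero_divisions():
    cfg = SimConfig(n_injected=10, homing_prob=1.0, r=0.0, d=0.0,
                    p_dormant_seed=0.0, K=1e3, n_days=2, lag_days=0, seed=0)
    cohort, _ = simulate_engraftment(cfg)
    assert np.all(measure_flow(cohort, 0.0).data["measured_mfi"] == cfg.m0)


def test_measure_flow_geometric_mean_preserved():
    cfg = SimConfig(n_injected=100_000, homing_prob=1.0, r=0.0, d=0.0,
                    p_dormant_seed=0.0, K=1e6, n_days=1, lag_days=0, seed=1)
    cohort, _ = simulate_engraftment(cfg)
    sample = measure_flow(cohort, cv_mfi=0.2, seed=2)
    geo = np.exp(np.log(sample.data["measured_mfi"]).mean())
    assert abs(geo - cfg.m0) / cfg.m0 < 0.01


def test_measure_flow_empty_cohort_is_explicit():
    cfg = SimConfig(n_injected=10, homing_prob=1.0, r=0.0, d=0.0,
                    p_dormant_seed=0.0, K=1e3, n_days=1, lag_days=0, seed=0)
    cohort, _ = simulate_engraftment(cfg)
    cohort.cells["alive"] = False
    with pytest.raises(EmptyCohortError):
        measure_flow(cohort, 0.0)
    assert len(measure_flow(cohort, 0.0, allow_empty=True)) == 0


# ---- treatment -------------------------------------------------------------

def _mixed_cohort(n_per_arm, seed=0):
    """Half the cells divided in the preceding day, half did not."""
    from lrckit.simulate import Cohort

    divisions = np.concatenate([np.ones(n_per_arm, int), np.zeros(n_per_arm, int)])
    divided = np.concatenate([np.ones(n_per_arm, bool), np.zeros(n_per_arm, bool)])
    return Cohort.from_arrays(divisions, np.zeros(2 * n_per_arm, bool),
                              divided, m0=1000.0, day=5)


def test_treatment_noop_and_total_kill():
    cohort = _mixed_cohort(100)
    noop = apply_treatment(cohort, TreatmentPlan(((5, 0.0, 0.0),)), seed=0)
    assert noop.n_alive == 200
    divided_only = _mixed_cohort(100)
    divided_only.cells["divided_last_day"] = True
    wiped = apply_treatment(divided_only, TreatmentPlan(((5, 1.0, 1.0),)), seed=0)
    assert wiped.n_alive == 0


def test_treatment_survivor_ratio_matches_programmed_kill():
    cohort = _mixed_cohort(100_000, seed=1)
    treated = apply_treatment(cohort, TreatmentPlan(((5, 0.99, 0.5),)), seed=2)
    alive = treated.cells[treated.cells["alive"]]
    n_und = int((~alive["divided_last_day"]).sum())
    n_div = int(alive["divided_last_day"].sum())
    # closed-form survival 0.5 vs 0.01 -> ratio 50; error dominated by n_div
    ratio = n_und / n_div
    assert abs(ratio - 50.0) < 4 * 50.0 / math.sqrt(n_div)


def test_treatment_plan_validation():
    with pytest.raises(ValueError, match="proliferation-dependent"):
        TreatmentPlan(((3, 0.1, 0.5),))
    with pytest.raises(ValueError):
        TreatmentPlan(((3, 1.5, 0.5),))
    with pytest.raises(ValueError, match="precedes"):
        apply_treatment(_mixed_cohort(10), TreatmentPlan(((1, 0.5, 0.1),)))


def test_in_simulation_treatment_day_beyond_horizon_rejected():
    cfg = SimConfig(n_injected=100, homing_prob=1.0, n_days=5, seed=0)
    with pytest.raises(ValueError, match="horizon"):
        simulate_engraftment(cfg, plan=TreatmentPlan(((9, 0.5, 0.1),)))


# ---- limiting dilution -----------------------------------------------------

def test_lda_certain_and_impossible_engraftment():
    all_on = simulate_lda(1.0, [1, 5], 10, seed=0)
    assert (all_on["n_engrafted"] == all_on["n_mice"]).all()
    all_off = simulate_lda(0.0, [10, 100], 10, seed=0)
    assert (all_off["n_engrafted"] == 0).all()


def test_lda_engraftment_rate_matches_single_hit_form():
    table = simulate_lda(0.02, [10], 100_000, seed=5)
    p = 1 - 0.98**10  # 0.1829
    frac = table["n_engrafted"].iloc[0] / table["n_mice"].iloc[0]
    se = math.sqrt(p * (1 - p) / 100_000)
    assert abs(frac - p) <= 3 * se


def test_lda_flux_readout_reproduces_calls():
    from lrckit import call_engraftment

    table, fluxes = simulate_lda(0.05, [5, 20], 50, seed=3, emit_flux=True)
    calls = call_engraftment(fluxes["flux"])
    recounted = (
        fluxes.assign(engrafted=calls)
        .groupby("dose")["engrafted"]
        .sum()
        .astype(int)
    )
    assert recounted.tolist() == table.set_index("dose")["n_engrafted"].tolist()


# ---- expression ------------------------------------------------------------

def test_expression_library_factor_scales_group_totals():
    m = simulate_expression(500, 100, seed=9, library_factor_a=0.5)
    totals = m.counts.sum(axis=0)
    ratio = totals[m.groups == "A"].mean() / totals[m.groups == "B"].mean()
    assert abs(ratio - 0.5) < 0.05


def test_expression_planted_truth_and_validation():
    planted = {"g0001": 2.0, "g0002": -1.5}
    m = simulate_expression(100, 20, planted=planted, seed=1)
    assert m.truth.loc["g0001", "planted_log2fc"] == 2.0
    assert set(m.truth.index[m.truth["planted"]]) == set(planted)
    with pytest.raises(ValueError, match="dispersion"):
        simulate_expression(10, 5, dispersion=0.0)
    with pytest.raises(ValueError, match="universe"):
        simulate_expression(10, 5, planted={"nope": 1.0})


def test_expression_planted_fold_change_realized():
    m = simulate_expression(200, 200, planted={"g0000": 3.0}, seed=2,
                            dispersion=0.2)
    mean_a = m.counts.loc["g0000", m.groups == "A"].mean()
    mean_b = m.counts.loc["g0000", m.groups == "B"].mean()
    assert abs(np.log2(mean_a / mean_b) - 3.0) < 0.3


# ---- re-transplantation ----------------------------------------------------

def test_retransplant_regenerates_dormant_fraction():
    """Re-transplanted fully-diluted cells regrow the same LRC compartment."""
    cfg = SimConfig(n_injected=2000, homing_prob=0.5, r=0.9, K=1e6, d=0.0,
                    p_dormant_seed=0.01, n_days=10, lag_days=0, seed=21)
    cohort, _ = simulate_engraftment(cfg)
    nonlrc = cohort.cells[cohort.cells["divisions"] >= 7]
    assert len(nonlrc) > 10_000

    re_cfg = cfg.with_(homing_prob=1.0, r=0.0, n_days=0, n_injected=1)
    bulk = cohort.alive().sample(len(nonlrc), random_state=0)
    sub_cohort, _ = retransplant(cohort, re_cfg, seed=1, subset=nonlrc)
    bulk_cohort, _ = retransplant(cohort, re_cfg, seed=2, subset=bulk)
    for re_run in (sub_cohort, bulk_cohort):
        frac = (re_run.cells["compartment"] == "dormant").mean()
        n = len(re_run)
        se = math.sqrt(0.01 * 0.99 / n)
        assert abs(frac - 0.01) <= 3.5 * se
        # label is fresh again
        assert (re_run.cells["divisions"] == 0).all()
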