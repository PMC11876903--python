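"""Sweeps, break-even bisection, scenario grids and PSA."""

import dataclasses

import numpy as np
import pytest

from hccsim.cea import compare_arms
from hccsim.engine import simulate_pair
from hccsim.parameters import (
    DistributionSpec,
    ModelParams,
    SimulationConfig,
    ValidationError,
)
from hccsim.sensitivity import (
    SweepSpec,
    apply_parameter,
    find_breakeven,
    one_way_sweep,
    run_psa,
    scenario_grid,
)


@pytest.fixture()
def config():
    return SimulationConfig(n_patients=4_000, seed=99)


def test_spec_rejects_unknown_parameter_and_non_monotone_grid():
    with pytest.raises(ValidationError):
        SweepSpec("no_such_knob", [1, 2]).validate()
    with pytest.raises(ValidationError):
        SweepSpec("adherence_outreach", [0.1, 0.3, 0.2]).validate()


def test_apply_parameter_composites(base_params, calib_unprinted):
    p, _ = apply_parameter(base_params, calib_unprinted, "outreach_cost_annual", 60.0)
    assert p.outreach_cost_y1 == p.outreach_cost_later == 60.0
    p, _ = apply_parameter(base_params, calib_unprinted, "adherence_gain", 0.05)
    assert p.adherence_outreach == pytest.approx(0.28)
    p, _ = apply_parameter(base_params, calib_unprinted,
                           "early_survival_gain_years", 5 / 12)
    assert p.surv_early_hcc == pytest.approx(2.0 + 5 / 12)
    _, u = apply_parameter(base_params, calib_unprinted, "cost_care_comp_annual", 99.0)
    assert u.cost_care_comp_annual == 99.0


def test_single_point_sweep_matches_base_case_comparison(base_params,
                                                         calib_unprinted, config):
    out, usual = simulate_pair(config, base_params, calib_unprinted)
    cmp = compare_arms(out, usual)
    df = one_way_sweep(SweepSpec("adherence_outreach", [0.35]),
                       base_params, calib_unprinted, config)
    assert len(df) == 1
    assert df.delta_cost.iloc[0] == pytest.approx(cmp.delta_cost)
    assert df.delta_qaly.iloc[0] == pytest.approx(cmp.delta_qaly)


def test_delta_cost_strictly_increasing_in_outreach_cost(base_params,
                                                         calib_unprinted, config):
    """Under common random numbers the program-cost response is exactly
    monotone (affine) in the annual outreach cost."""
    grid = [0.0, 20.0, 40.0, 60.0, 80.0]
    df = one_way_sweep(SweepSpec("outreach_cost_annual", grid),
                       base_params, calib_unprinted, config)
    deltas = df.delta_cost.to_numpy()
    assert (np.diff(deltas) > 0).all()
    # affine: second differences vanish
    assert np.abs(np.diff(deltas, 2)).max() < 1e-4 * abs(deltas).max()


def test_positive_adherence_gain_always_increases_qalys(base_params,
                                                        calib_unprinted, config):
    df = one_way_sweep(SweepSpec("adherence_gain", [0.02, 0.05, 0.09, 0.12]),
                       base_params, calib_unprinted, config)
    assert (df.delta_qaly > 0).all()


def test_breakeven_recovers_root_of_affine_response(base_params,
                                                    calib_unprinted, config):
    """The outreach-cost response is affine under CRN, so the bisection
    crossing must match the analytically interpolated root."""
    grid = [0.0, 120.0]
    df = one_way_sweep(SweepSpec("outreach_cost_annual", grid),
                       base_params, calib_unprinted, config)
    y0, y1 = df.delta_cost.to_numpy()
    root = grid[0] - y0 * (grid[1] - grid[0]) / (y1 - y0)
    be = find_breakeven("outreach_cost_annual", base_params, calib_unprinted,
                        config, bracket=(0.0, 120.0))
    assert be.value == pytest.approx(root, abs=0.2)
    assert be.mc_halfwidth > 0


def test_breakeven_requires_sign_change(calib_unprinted):
    config = SimulationConfig(n_patients=1_000, seed=1)
    with pytest.raises(ValidationError, match="sign"):
        find_breakeven("outreach_cost_annual", ModelParams(), calib_unprinted,
                       config, bracket=(500.0, 1000.0))


def test_scenario_grid_emits_one_row_per_scenario(base_params,
                                                  calib_unprinted, config):
    df = scenario_grid([5, 10], [2_000, 4_000], base_params, calib_unprinted, config)
    assert len(df) == 4
    assert set(df.horizon_years) == {5, 10}
    assert np.allclose(df.delta_cost_per_patient, df.delta_cost / df.n_patients)


def test_scenario_rejects_fractional_cycle_horizon(base_params,
                                                   calib_unprinted, config):
    with pytest.raises(ValidationError):
        scenario_grid([7.3], [1_000], base_params, calib_unprinted, config)


class TestPSA:
    def test_spread_zero_draws_equal_base_case(self, base_params,
                                               calib_unprinted, config):
        mp = ModelParams()
        mp.distributions = {name: DistributionSpec("fixed", spec.center)
                            for name, spec in mp.distributions.items()}
        df = run_psa(3, mp, calib_unprinted, config, seed=5)
        # all draws identical to each other (same parameters per draw)
        assert df.delta_qaly.nunique() == 3  # substrates differ per draw...
        mp_draws = df[["delta_cost", "delta_qaly"]]
        # ...but rerunning reproduces them exactly
        df2 = run_psa(3, mp, calib_unprinted, config, seed=5)
        assert (df2[["delta_cost", "delta_qaly"]].to_numpy()
                == mp_draws.to_numpy()).all()

    def test_quadrant_fractions_partition(self, base_params, calib_unprinted):
        config = SimulationConfig(n_patients=1_500, seed=7)
        df = run_psa(12, base_params, calib_unprinted, config, seed=7)
        q = ((df.delta_cost < 0) & (df.delta_qaly > 0)).mean() \
            + ((df.delta_cost < 0) & (df.delta_qaly <= 0)).mean() \
            + ((df.delta_cost >= 0) & (df.delta_qaly > 0)).mean() \
            + ((df.delta_cost >= 0) & (df.delta_qaly <= 0)).mean()
        assert q == pytest.approx(1.0)
        assert len(df) == 12

    def test_majority_of_draws_dominant_with_published_distributions(
            self, base_params, calib_unprinted):
        """Consistent with the robustness narrative: most PSA draws fall in
        the cost-saving, QALY-gaining quadrant (the exact fraction is an
        output, not an anchor)."""
        config = SimulationConfig(n_patients=4_000, seed=31)
        df = run_psa(40, base_params, calib_unprinted, config, seed=31)
        assert (df.verdict == "dominant").mean() > 0.5
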