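"""Scenario sweeps and break-even detection."""

import numpy as np
import pytest

from costmin import expressions as ex
from costmin.model import CostComponent, ModelDefinition, ModelError, Parameter, evaluate_point
from costmin.sensitivity import find_break_even, one_way_sweep, two_way_sweep
from costmin.synthetic import generate_monotone_breakeven_model


def test_linear_toy_sweep_and_root(linear_sweep_model):
    sweep = one_way_sweep(linear_sweep_model, "x", 0.0, 10.0, 11)
    # incremental = (10 + x) - 15 = x - 5: linear, crossing at x = 5
    assert np.allclose(sweep.incrementals, sweep.values - 5.0)
    roots = find_break_even(linear_sweep_model, "x", 0.0, 10.0, 1e-6)
    assert len(roots) == 1
    assert roots[0] == pytest.approx(5.0, abs=1e-6)
    assert sweep.break_even[0] == pytest.approx(5.0, abs=1e-3)


def test_no_sign_change_returns_empty(linear_sweep_model):
    # incremental = x - 5 is strictly positive on [6, 10]
    assert find_break_even(linear_sweep_model, "x", 6.0, 10.0, 1e-6) == []


def test_piecewise_linear_break_even():
    """Incremental 32.5 - 0.65 * (x - 7) on [7, 200] crosses zero at 57.0."""
    model = ModelDefinition(
        name="piecewise",
        parameters=(Parameter("x", "distance", 7.0),),
        components=(
            CostComponent(
                "t", "teledermatology", "gp",
                ex.sub(ex.const(32.5),
                       ex.mul(ex.const(0.65), ex.sub(ex.param("x"), ex.const(7.0)))),
            ),
            CostComponent("c", "conventional", "gp", ex.const(0.0)),
        ),
    )
    roots = find_break_even(model, "x", 7.0, 200.0, 1e-6)
    assert len(roots) == 1
    assert roots[0] == pytest.approx(7.0 + 32.5 / 0.65, abs=1e-5)


def test_sweep_argument_validation(linear_sweep_model):
    with pytest.raises(ModelError):
        one_way_sweep(linear_sweep_model, "nope", 0, 1, 5)
    with pytest.raises(ValueError):
        one_way_sweep(linear_sweep_model, "x", 1.0, 1.0, 5)
    with pytest.raises(ValueError):
        one_way_sweep(linear_sweep_model, "x", 0.0, 1.0, 1)
    with pytest.raises(ValueError):
        find_break_even(linear_sweep_model, "x", 0.0, 1.0, tolerance=0.0)


def test_single_point_sweep_matches_point_override(mechanistic_model):
    sweep = one_way_sweep(mechanistic_model, "prop_preventable", 0.3, 0.4, 2)
    bd = evaluate_point(mechanistic_model, {"prop_preventable": 0.3})
    assert sweep.tele_totals[0] == pytest.approx(
        bd.arm_totals["teledermatology"], rel=1e-12)
    assert sweep.incrementals[0] == pytest.approx(bd.incremental_total, rel=1e-12)


def test_conventional_arm_invariant_under_tele_only_sweeps(mechanistic_model):
    for pid, lo, hi in [("derm_tele_min", 4.5, 13.1),
                        ("gp_tele_activity_min", 4.6, 28.8),
                        ("camera_price_eur", 50, 300)]:
        sweep = one_way_sweep(mechanistic_model, pid, lo, hi, 9)
        assert np.ptp(sweep.conv_totals) == 0.0


@pytest.mark.parametrize("seed", range(100))
def test_bisection_agrees_with_grid_scan_on_monotone_models(seed):
    """Bisection root vs brute-force 10,001-point grid scan, and vs the
    generator's analytic root, on random monotone linear models."""
    model, pid, lo, hi, analytic_root = generate_monotone_breakeven_model(seed)
    roots = find_break_even(model, pid, lo, hi, tolerance=1e-6)
    assert len(roots) == 1
    # independent oracle: sign change location on a dense grid
    grid = np.linspace(lo, hi, 10_001)
    incr = np.array([])
    from costmin.sensitivity import _incremental_on_grid

    incr = _incremental_on_grid(model, pid, grid)["incr"]
    sign_change = np.nonzero(np.diff(np.sign(incr)) != 0)[0]
    assert len(sign_change) == 1
    cell = (hi - lo) / 10_000
    assert abs(roots[0] - grid[sign_change[0]]) <= cell
    assert roots[0] == pytest.approx(analytic_root, abs=1e-5)


def test_multiple_roots_all_returned():
    """Oscillating incremental: (x-2)(x-5)(x-8) has three roots on [0, 10]."""
    x = ex.param("x")
    prod = ex.mul(ex.sub(x, ex.const(2.0)), ex.sub(x, ex.const(5.0)),
                  ex.sub(x, ex.const(8.0)))
    model = ModelDefinition(
        name="cubic",
        parameters=(Parameter("x", "", 0.0),),
        components=(
            CostComponent("t", "teledermatology", "gp", prod),
            CostComponent("c", "conventional", "gp", ex.const(0.0)),
        ),
    )
    roots = find_break_even(model, "x", 0.0, 10.0, 1e-6)
    assert np.allclose(roots, [2.0, 5.0, 8.0], atol=1e-5)
    assert roots == sorted(roots)


class TestTwoWay:
    def test_identical_parameters_rejected(self, mechanistic_model):
        with pytest.raises(ValueError):
            two_way_sweep(mechanistic_model, "prop_preventable", [0.1, 0.2],
                          "prop_preventable", [0.1, 0.2])

    def test_constant_model_has_flat_surface_no_contour(self):
        model = ModelDefinition(
            name="const2",
            parameters=(Parameter("a", "", 1.0), Parameter("b", "", 1.0)),
            components=(
                CostComponent("t", "teledermatology", "gp", ex.const(3.0)),
                CostComponent("c", "conventional", "gp", ex.const(1.0)),
            ),
        )
        res = two_way_sweep(model, "a", [0.0, 1.0, 2.0], "b", [0.0, 1.0])
        assert np.all(res.incrementals == 2.0)
        assert all(row == () for row in res.row_break_even)

    def test_one_by_one_grid_equals_point_override(self, mechanistic_model):
        res = two_way_sweep(mechanistic_model, "prop_preventable", [0.3],
                            "derm_distance_km", [50.0])
        bd = evaluate_point(mechanistic_model,
                            {"prop_preventable": 0.3, "derm_distance_km": 50.0})
        assert res.incrementals[0, 0] == pytest.approx(bd.incremental_total, rel=1e-12)

    def test_break_even_distance_decreases_with_preventable_proportion(
            self, mechanistic_model):
        """More preventable consultations move the break-even hospital
        distance closer; verified against brute-force grid evaluation."""
        p_grid = [0.15, 0.2, 0.3, 0.4]
        d_grid = np.linspace(3.0, 200.0, 30)
        res = two_way_sweep(mechanistic_model, "prop_preventable", p_grid,
                            "derm_distance_km", d_grid)
        roots = [row[0] for row in res.row_break_even if row]
        assert len(roots) >= 3
        assert np.all(np.diff(roots) < 0)
        # brute force: incremental decreases along every row and in p
        assert np.all(np.diff(res.incrementals, axis=1) < 0)
        assert np.all(np.diff(res.incrementals, axis=0) < 0)
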