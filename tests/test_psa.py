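"""Probabilistic sensitivity analysis: determinism, summaries, calibration."""

import numpy as np
import pytest

from costmin import expressions as ex
from costmin.distributions import PointDistribution, TriangularDistribution
from costmin.model import CostComponent, ModelDefinition, Parameter, evaluate_point
from costmin.psa import PSAConfig, prob_positive_gaussian, run_psa
from costmin.reference import TABLE2_TOTALS


def _ua(pid, value, dist):
    return Parameter(pid, pid, value, "", dist, None,
                     frozenset({"uncertainty_analysis"}))


@pytest.fixture()
def point_mass_model():
    return ModelDefinition(
        name="point-mass",
        parameters=(
            _ua("a", 3.0, PointDistribution(3.0)),
            _ua("b", 4.0, PointDistribution(4.0)),
        ),
        components=(
            CostComponent("t", "teledermatology", "gp",
                          ex.mul(ex.param("a"), ex.param("b"))),
            CostComponent("c", "conventional", "gp", ex.param("b")),
        ),
    )


def test_point_mass_psa_reproduces_point_evaluation(point_mass_model):
    res = run_psa(point_mass_model, PSAConfig(n_draws=500, seed=0))
    point = evaluate_point(point_mass_model)
    incr = res.draws["incremental"].to_numpy()
    assert np.all(incr == point.incremental_total)
    assert incr.std() == 0.0


def test_config_validation():
    with pytest.raises(ValueError):
        PSAConfig(n_draws=1).validate()
    with pytest.raises(ValueError):
        PSAConfig(ci_level=1.0).validate()


def test_seeded_determinism_and_stream_stability(calibrated_model):
    short = run_psa(calibrated_model, PSAConfig(n_draws=400, seed=11))
    again = run_psa(calibrated_model, PSAConfig(n_draws=400, seed=11))
    assert short.draws.equals(again.draws)
    long = run_psa(calibrated_model, PSAConfig(n_draws=800, seed=11))
    # first half of a double-length run is unchanged (prefix-stable substreams)
    assert np.allclose(long.draws.iloc[:400].to_numpy(), short.draws.to_numpy())


def test_unflagged_parameters_stay_at_point_values():
    model = ModelDefinition(
        name="mixed-flags",
        parameters=(
            _ua("a", 1.0, TriangularDistribution(0, 1, 2)),
            Parameter("fixed", "not sampled", 5.0,
                      distribution=TriangularDistribution(0, 5, 10)),
        ),
        components=(
            CostComponent("t", "teledermatology", "gp",
                          ex.add(ex.param("a"), ex.param("fixed"))),
            CostComponent("c", "conventional", "gp", ex.param("fixed")),
        ),
    )
    res = run_psa(model, PSAConfig(n_draws=300, seed=2))
    assert res.parameter_ids == ("a",)
    # incremental = a + fixed - fixed = a: the unsampled parameter cancels
    assert np.allclose(res.draws["incremental"], res.draws["a"])


def test_monte_carlo_mean_matches_linearity_of_expectation():
    """Sum of a point mass and a triangular component: the Monte Carlo mean
    of the total lands within 3 standard errors of the analytic sum."""
    tri = TriangularDistribution(10, 20, 60)
    model = ModelDefinition(
        name="linearity",
        parameters=(_ua("t1", 20.0, tri), _ua("p1", 7.0, PointDistribution(7.0))),
        components=(
            CostComponent("t", "teledermatology", "gp",
                          ex.add(ex.param("t1"), ex.param("p1"))),
            CostComponent("c", "conventional", "gp", ex.const(0.0)),
        ),
    )
    n = 20_000
    res = run_psa(model, PSAConfig(n_draws=n, seed=5))
    se = np.sqrt(tri.variance() / n)
    assert res.draws["tele_total"].mean() == pytest.approx(tri.mean() + 7.0, abs=3 * se)


def test_histogram_counts_sum_and_edges(calibrated_model):
    res = run_psa(calibrated_model, PSAConfig(n_draws=2_000, seed=3))
    assert res.histogram_counts.sum() == 2_000
    assert np.all(np.diff(res.histogram_edges) > 0)
    assert res.prob_cost_saving + res.prob_conventional_cheaper + res.prob_tie == 1.0


@pytest.mark.parametrize(
    "mean, interval, level, expected, tol",
    [
        (0.0, (-1.0, 1.0), 0.95, 0.5, 1e-12),      # symmetric around zero
        (32.5, (-29.0, 74.7), 0.95, 0.890, 5e-4),  # published headline
        (10.0, (10 - 1.96, 10 + 1.96), 0.95, 1.0, 1e-9),
    ],
)
def test_prob_positive_gaussian(mean, interval, level, expected, tol):
    assert prob_positive_gaussian(mean, interval, level) == pytest.approx(expected, abs=tol)


def test_prob_positive_gaussian_rejects_degenerate_interval():
    with pytest.raises(ValueError):
        prob_positive_gaussian(1.0, (2.0, 2.0))


@pytest.fixture(scope="module")
def psa_result(calibrated_model):
    return run_psa(calibrated_model, PSAConfig(n_draws=10_000, seed=42))


class TestCalibrationFidelity:
    """The calibrated profile's simulated intervals track the published ones."""

    def test_prob_agrees_with_gaussian_oracle(self, psa_result):
        oracle = prob_positive_gaussian(32.5, (-29.0, 74.7), 0.95)
        mc_se = np.sqrt(oracle * (1 - oracle) / 10_000)
        assert psa_result.prob_conventional_cheaper == pytest.approx(oracle, abs=3 * mc_se)

    @pytest.mark.parametrize("arm", ["teledermatology", "conventional"])
    def test_arm_total_interval_covers_published_endpoints(self, psa_result, arm):
        row = psa_result.summary.set_index("quantity").loc[
            "tele_total" if arm == "teledermatology" else "conv_total"]
        _, lo, hi = TABLE2_TOTALS[arm]
        assert row.ci_lower == pytest.approx(lo, rel=0.10)
        assert row.ci_upper == pytest.approx(hi, rel=0.10)
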