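import pytest

from costmin import build_reference_model
from costmin import expressions as ex
from costmin.model import CostComponent, ModelDefinition, Parameter


@pytest.fixture(scope="session")
def calibrated_model():
    return build_reference_model("calibrated")


@pytest.fixture(scope="session")
def mechanistic_model():
    return build_reference_model("mechanistic")


@pytest.fixture()
def toy_model():
    """tele = 2 * 3, conv = 4: totals 6 and 4, incremental 2."""
    return ModelDefinition(
        name="toy",
        parameters=(Parameter("x", "unused", 1.0),),
        components=(
            CostComponent("tele_c", "teledermatology", "gp",
                          ex.mul(ex.const(2.0), ex.const(3.0))),
            CostComponent("conv_c", "conventional", "gp", ex.const(4.0)),
        ),
    )


@pytest.fixture()
def linear_sweep_model():
    """tele = 10 + x, conv = 15: incremental crosses zero at x = 5."""
    return ModelDefinition(
        name="linear-sweep",
        parameters=(Parameter("x", "sweep parameter", 0.0, sweep_range=(0.0, 10.0)),),
        components=(
            CostComponent("tele_c", "teledermatology", "gp",
                          ex.add(ex.const(10.0), ex.param("x"))),
            CostComponent("conv_c", "conventional", "gp", ex.const(15.0)),
        ),
    )
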