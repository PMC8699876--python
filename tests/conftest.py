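import numpy as np
import pytest

from plaqueprop.geometry import Contour, make_error_models
from plaqueprop.synthetic import StenosisSpec, VesselRecipe, generate_vessel


def regular_polygon(n: int = 72, radius: float = 1.0, center=(0.0, 0.0, 0.0)) -> Contour:
    theta = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack(
        [
            center[0] + radius * np.cos(theta),
            center[1] + radius * np.sin(theta),
            np.full(n, center[2]),
        ]
    )
    return Contour(pts)


@pytest.fixture
def unit_square() -> Contour:
    return Contour(np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float))


@pytest.fixture
def straight_vessel():
    """Constant-radius tube: r = 1.5 mm, 30 mm long, no stenosis."""
    return generate_vessel(VesselRecipe(length=30.0, base_radius=1.5, seed=1, case_id="straight"))


@pytest.fixture
def stenosed_vessel():
    """Single 50%-area stenosis at mid-vessel."""
    return generate_vessel(
        VesselRecipe(
            length=30.0,
            base_radius=1.5,
            stenoses=(StenosisSpec(center=15.0, length=10.0, severity=0.5),),
            seed=2,
            case_id="stenosed",
        )
    )


@pytest.fixture
def triplet(stenosed_vessel):
    """(original, overestimated, underestimated) at the 5% area error."""
    return make_error_models(stenosed_vessel, 0.05)
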