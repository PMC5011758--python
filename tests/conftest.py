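import numpy as np
import pytest

from subchondral import AwlSpec, LesionSpec, PhantomSpec


@pytest.fixture
def awl() -> AwlSpec:
    return AwlSpec()  # 1.2 mm diameter, 2.0 mm penetration


@pytest.fixture
def residual_hole_spec() -> PhantomSpec:
    """Single narrow hole: Hd1 = 2.0 < 2.4, Hd2 = 1.8 < 3.6."""
    return PhantomSpec(
        lesions=(LesionSpec(4.5, 2.0, 1.8, 2.0, "trapezoid"),),
        defect_extent_mm=(2.5, 6.5),
    )


@pytest.fixture
def cyst_spec() -> PhantomSpec:
    """Narrow-neck bulb: Hd1 = 1.0, Hd2 = 4.0 > 3.6."""
    return PhantomSpec(
        lesions=(LesionSpec(4.5, 1.0, 4.0, 2.2, "bulb"),),
        defect_extent_mm=(2.0, 7.0),
    )


@pytest.fixture
def two_hole_spec() -> PhantomSpec:
    """Persistent bridge (Vd2 = 0.6 < 0.5 * Vd1 = 1.0) separating a wide and
    a narrow hole."""
    return PhantomSpec(
        lesions=(
            LesionSpec(3.2, 2.5, 3.0, 2.0, "trapezoid"),
            LesionSpec(5.35, 1.5, 1.4, 2.0, "trapezoid"),
        ),
        bridge_vd2_mm=0.6,
        defect_extent_mm=(1.0, 7.5),
    )


@pytest.fixture
def intact_spec() -> PhantomSpec:
    """Completely reconstituted plate: no lesions, no overgrowth."""
    return PhantomSpec(defect_extent_mm=(2.5, 6.5))
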