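"""Bundled demonstration data.

``three_food_demo`` is a minimal fruit/vegetables/cereal world used to show
why a conditional PE matrix transplanted across settings breaks the
no-expenditure-change property.  The elasticities in the fruit-price column
(own -1.0; +0.3 onto vegetables; -0.05 onto cereal) drive the demo; the
consumption, price and energy values were constructed so that, in the home
setting, a conventional application of a 20% fruit subsidy leaves total
expenditure exactly unchanged while raising total energy by 0.51%, whereas
the same matrix moved to the transplanted consumption pattern shifts
expenditure and raises energy by 2.38%.
"""

from __future__ import annotations

import numpy as np

from .demand import FoodSystem, PEMatrix, PolicySpec

__all__ = ["three_food_demo", "three_food_transplanted", "fruit_subsidy_20"]

_FOODS = ["fruit", "vegetables", "cereal"]
_PRICES = [1.00, 0.50, 2.00]          # per 100 g
_ENERGY = [250.0, 170.0, 580.0]       # kJ per 100 g

# only the fruit-price column matters for the 20% fruit subsidy demo; the
# other columns are filled with plausible values
_EPSILON = np.array([
    [-1.00, 0.20, 0.10],
    [0.30, -0.90, 0.05],
    [-0.05, 0.10, -0.40],
])


def three_food_demo() -> tuple[FoodSystem, PEMatrix]:
    """Home setting: the consumption pattern the PE matrix 'belongs' to."""
    system = FoodSystem(
        food_id=list(_FOODS),
        q_b=[50.0, 400.0, 700.0],
        p_b=list(_PRICES),
        energy_density=list(_ENERGY),
        nutrient_content={"sugar": [10.0, 4.0, 8.0],
                          "satfat": [0.2, 0.3, 1.5]},
    )
    return system, PEMatrix(epsilon=_EPSILON.copy(), food_id=list(_FOODS))


def three_food_transplanted() -> FoodSystem:
    """Different setting: same foods, prices and energy densities, but a
    different starting consumption pattern."""
    return FoodSystem(
        food_id=list(_FOODS),
        q_b=[150.0, 245.0, 390.0],
        p_b=list(_PRICES),
        energy_density=list(_ENERGY),
        nutrient_content={"sugar": [10.0, 4.0, 8.0],
                          "satfat": [0.2, 0.3, 1.5]},
    )


def fruit_subsidy_20() -> PolicySpec:
    return PolicySpec(ad_valorem={"fruit": -0.20}, name="20% fruit subsidy")
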