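"""Canonical example designs.

``xor_design`` is the unbalanced four-triplet XOR used in the touch-screen
serial reaction time experiment; the restaurant designs are the didactic
worked examples that motivate the dissociation between frequency and
transitional probability.
"""

from __future__ import annotations

from .design import DesignSpec

__all__ = [
    "xor_design",
    "switched_xor_design",
    "menu_design",
    "customer_count_design",
    "customer_profile_design",
]

_PROFILES = (
    ("Salad", "Dish", "NoDessert"),
    ("NoSalad", "Dish", "Dessert"),
    ("Salad", "NoDish", "Dessert"),
    ("NoSalad", "NoDish", "NoDessert"),
)


def xor_design() -> DesignSpec:
    """The unbalanced XOR: {ABC: .40, AEF: .25, DBF: .25, DEC: .10}."""
    return DesignSpec.from_strings(["ABC", "AEF", "DBF", "DEC"], [0.40, 0.25, 0.25, 0.10])


def switched_xor_design() -> DesignSpec:
    """The switch-phase counterpart {ABF, AEC, DBC, DEF} with inherited frequencies."""
    return DesignSpec.from_strings(["ABF", "AEC", "DBC", "DEF"], [0.40, 0.25, 0.25, 0.10])


def menu_design() -> DesignSpec:
    """Restaurant menus: 1/5 Salad-Dish, 1/5 Salad-Dish-Dessert, 3/5 Dish-Dessert.

    Gives p(Dish|Salad) = 1 and p(Dessert|Dish) = .80 position-agnostically,
    and second-order p(Dessert|Salad, Dish) = .5.
    """
    return DesignSpec(
        (
            ("Salad", "Dish"),
            ("Salad", "Dish", "Dessert"),
            ("Dish", "Dessert"),
        ),
        (0.2, 0.2, 0.6),
    )


def customer_count_design() -> DesignSpec:
    """Twenty customers: 8 dieters, 5 big eaters, 5 small eaters, 2 coffee-only.

    An unbalanced XOR over customer profiles: p(Dish|NoSalad) = 5/7 = .71 is
    the highest first-order TP while Salad-Dish (8/20 = .4) is the most
    frequent pair.
    """
    return DesignSpec.from_counts(_PROFILES, (8, 5, 5, 2))


def customer_profile_design() -> DesignSpec:
    """The four customer profiles at equal frequency: a balanced XOR.

    Every first-order TP equals .5 and every second-order TP equals 1.
    """
    return DesignSpec(_PROFILES, (0.25, 0.25, 0.25, 0.25))
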