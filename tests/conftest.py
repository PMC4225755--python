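"""Shared fixtures: the beta* table and the phantom planning/adaptation
pipeline are expensive, so they are built once per session."""

import warnings

import pytest

from twostep_imrt import (PhantomSpec, build_beta_star_table,
                          generate_quasimodo)
from twostep_imrt.adaptation import adapt_plan, make_native_plan
from twostep_imrt.finetune import Objective

PHANTOM_D0 = 60.0  # Gy prescribed to the phantom target


def phantom_objectives(d0: float = PHANTOM_D0) -> list[Objective]:
    return [
        Objective("PTV", "min_dose", 0.98 * d0, weight=100.0),
        Objective("PTV", "max_dose", 1.03 * d0, weight=30.0),
        Objective("Rectum", "max_dose", 0.6 * d0, weight=10.0),
        Objective("Body", "max_dose", 1.05 * d0, weight=0.1),
    ]


@pytest.fixture(scope="session")
def beta_table():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_beta_star_table()


@pytest.fixture(scope="session")
def quasimodo_pair():
    """Planning geometry and geometry of the day with a 5% normalized OAR
    radius change at constant gap."""
    return generate_quasimodo(PhantomSpec(n_slices=8), 0.05)


@pytest.fixture(scope="session")
def quasimodo_native(quasimodo_pair, beta_table):
    ct1, _ = quasimodo_pair
    return make_native_plan(
        ct1, beta_table, {"PTV": PHANTOM_D0}, targets=("PTV",),
        objectives=phantom_objectives(), weight_iterations=25,
        leaf_iterations=1)


@pytest.fixture(scope="session")
def quasimodo_adaptation(quasimodo_pair, quasimodo_native, beta_table):
    _, ct2 = quasimodo_pair
    return adapt_plan(quasimodo_native, ct2, beta_table)
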