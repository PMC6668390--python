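import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from n15flux import constants as c
from n15flux.fluxes import ChamberGeometry
from n15flux.isotope import (
    delta_ratios,
    fractions_from_atom_fraction,
    mix_pools,
    natural_ratio_pair,
    ratio_pair_from_fractions,
)
from n15flux.simulate import SimulationConfig, TreatmentSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # fixtures used inside @given tests are pure value factories
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


@pytest.fixture
def geometry():
    return ChamberGeometry()


@pytest.fixture
def natural_bg():
    return natural_ratio_pair()


@pytest.fixture
def forward_deltas(natural_bg):
    """Noiseless diatomic deltas for a pool (a, d) over natural background."""

    def make(a, d):
        bg = fractions_from_atom_fraction(c.NAT_15N)
        pool = fractions_from_atom_fraction(a)
        return delta_ratios(
            ratio_pair_from_fractions(mix_pools(bg, pool, d)), natural_bg
        )

    return make


def single_chamber_config(
    n2_flux=980.0,
    n2o_flux=221.0,
    a_pool=0.48,
    n2o_pool_fraction=1.0,
    noise=None,
    n_days=1,
    refs_per_closure=2,
):
    """One chamber, one closure per day: the smallest processable campaign."""
    noise_sd = dict(c.NOISE_SD) if noise is None else dict(noise)
    return SimulationConfig(
        treatments=[
            TreatmentSpec(
                name="T",
                chambers=("CH1",),
                n2_flux=(float(n2_flux),) * n_days,
                n2o_flux=(float(n2o_flux),) * n_days,
                a_pool=(float(a_pool),) * n_days,
                n2o_pool_fraction=n2o_pool_fraction,
            )
        ],
        n_days=n_days,
        closures_per_day=1,
        refs_per_closure=refs_per_closure,
        noise_sd=noise_sd,
    )


ZERO_NOISE = {k: 0.0 for k in c.NOISE_SD}


@pytest.fixture
def tiny_config():
    return single_chamber_config


@pytest.fixture
def zero_noise():
    return dict(ZERO_NOISE)
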