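import numpy as np
import pytest

from nmrcsp.crystio import AtomSite, Crystal, UnitCell, perceive_bonds
from nmrcsp.synthetic import (
    CampaignConfig,
    base_crystal,
    build_campaign,
    default_forward_model,
)


@pytest.fixture(scope="session")
def base():
    return base_crystal()


@pytest.fixture(scope="session")
def base_topology(base):
    return perceive_bonds(base)


@pytest.fixture(scope="session")
def forward_model():
    return default_forward_model(seed=0)


@pytest.fixture(scope="session")
def small_campaign():
    """A compact campaign shared by pipeline-level tests (truth + 5 decoys)."""
    return build_campaign(
        CampaignConfig(n_candidates=6, n_torsion_flips=1), seed=11
    )


@pytest.fixture
def cubic_cell():
    return UnitCell(10.0, 10.0, 10.0)


def make_crystal(cell, atoms, **kwargs):
    sites = [AtomSite(label=l, element=e, frac=f) for l, e, f in atoms]
    return Crystal(cell=cell, sites=sites, **kwargs)


@pytest.fixture
def random_crystal_factory():
    """Small random P1 crystals with well-separated carbon sites."""

    def factory(seed, n_sites=6):
        rng = np.random.default_rng(seed)
        cell = UnitCell(
            *(8.0 + 4.0 * rng.random(3)), *(80.0 + 20.0 * rng.random(3))
        )
        atoms = [
            (f"C{i + 1}", "C", rng.random(3)) for i in range(n_sites)
        ]
        return make_crystal(cell, atoms, name=f"random_{seed}")

    return factory
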