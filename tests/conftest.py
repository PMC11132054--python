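from dataclasses import replace

import numpy as np
import pytest

import antheridyn as ad


@pytest.fixture(scope="session")
def scenario():
    return ad.BurstScenario()


@pytest.fixture(scope="session")
def quiet_scenario(scenario):
    """Default burst conditions without landmark noise."""
    return replace(scenario, noise_sigma_um=0.0)


@pytest.fixture(scope="session")
def template(scenario):
    return ad.make_antheridium_template(scenario)


@pytest.fixture(scope="session")
def small_dataset(scenario):
    """A small noisy before/after dataset shared across tests."""
    return ad.simulate_burst_dataset(scenario, n_specimens=6, seed=0)


def triangle_geometry(points=None, **kw):
    """Minimal 3-point geometry for normalization arithmetic tests."""
    pts = np.asarray(points if points is not None else [(0, 0), (1, 1), (1, 0)], float)
    kw.setdefault("specimen_id", "t")
    kw.setdefault("frame", 1)
    kw.setdefault("time_s", 0.0)
    kw.setdefault("structure", ["organ_outline"] * len(pts))
    kw.setdefault("anchor_left", 0)
    kw.setdefault("anchor_right", 1)
    return ad.LandmarkGeometry(points=pts, **kw)
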