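import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from disctraj.core import AtomTable, Frame
from disctraj.synthetic import (
    DynamicsSpec,
    PatchSpec,
    add_edge_polymers,
    build_patch,
    default_selection_config,
    simulate_dynamics,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sel():
    return default_selection_config()


@pytest.fixture(scope="session")
def small_patch():
    """Static 40 A patch, mixed composition."""
    spec = PatchSpec(radius=40.0, seed=1)
    atoms, frame0 = build_patch(spec)
    return spec, atoms, frame0


@pytest.fixture(scope="session")
def rim_patch():
    """Compact patch (~500 atoms) with rim polymers, for SASA/contact tests."""
    spec = PatchSpec(radius=22.0, n_tail_atoms=2, seed=41)
    atoms, frame0 = build_patch(spec)
    atoms, frame0 = add_edge_polymers(atoms, frame0, 12, 18, seed=42)
    return atoms, frame0


@pytest.fixture(scope="session")
def dense_rim_patch():
    """Compact patch with rim polymers covering the full 360 degrees."""
    spec = PatchSpec(radius=22.0, n_tail_atoms=2, seed=41)
    atoms, frame0 = build_patch(spec)
    atoms, frame0 = add_edge_polymers(atoms, frame0, 36, 40, seed=42)
    return atoms, frame0


def make_atoms(n, element="C", radius=1.7, species="UNK"):
    """Minimal one-atom-per-residue table for geometric unit tests."""
    df = pd.DataFrame(
        {
            "atom_id": np.arange(n),
            "atom_name": ["X"] * n,
            "element": [element] * n,
            "residue_name": [species] * n,
            "residue_id": np.arange(1, n + 1),
            "segment": ["A"] * n,
            "vdw_radius": [radius] * n,
        }
    )
    return AtomTable(df)


@pytest.fixture
def single_atom():
    return make_atoms(1, radius=1.9), Frame(np.zeros((1, 3)))
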