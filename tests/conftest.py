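"""Shared fixtures: small handcrafted PDB fixtures and the session-scoped
synthetic runs that several test modules analyse."""

from __future__ import annotations

import numpy as np
import pytest

import ectodyn as ed
from ectodyn.io import Structure
from ectodyn.synthetic import toy_domain_map

ALA5_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 25.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 25.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.923  1.00 25.00           C
ATOM      4  O   ALA A   1      13.831   7.064  -5.374  1.00 25.00           O
ATOM      5  CB  ALA A   1      12.217   4.682  -4.880  1.00 25.00           C
END
"""


@pytest.fixture(scope="session")
def ala5_path(tmp_path_factory):
    p = tmp_path_factory.mktemp("fixtures") / "ala5.pdb"
    p.write_text(ALA5_PDB)
    return p


def make_structure(coords, elements=None, names=None, res_ids=None,
                   masses=None, res_names=None, chain="A"):
    """Minimal Structure factory for geometric tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    elements = np.asarray(elements if elements is not None else ["C"] * n)
    names = np.asarray(names if names is not None else
                       [f"C{i + 1}" for i in range(n)])
    res_ids = np.asarray(res_ids if res_ids is not None else
                         np.arange(1, n + 1))
    res_names = np.asarray(res_names if res_names is not None else ["GLY"] * n)
    masses = np.asarray(masses if masses is not None else np.full(n, 12.011))
    return Structure(
        identifier="test",
        serial=np.arange(1, n + 1),
        name=names,
        element=elements,
        res_id=res_ids,
        res_name=res_names,
        chain_id=np.full(n, chain),
        ins_code=np.full(n, ""),
        coords=coords,
        bfactor=np.zeros(n),
        occupancy=np.ones(n),
        mass=masses.astype(float),
    )


@pytest.fixture(scope="session")
def toy_topology():
    return ed.build_toy_receptor(seed=0)


@pytest.fixture(scope="session")
def domain_map():
    return toy_domain_map()


@pytest.fixture(scope="session")
def two_state_run(toy_topology):
    """One replica of the default two-state (closed/open) trajectory."""
    return ed.generate_trajectory(
        toy_topology, ed.default_states(["closed", "open"], [0.5, 0.5]),
        n_frames=500, noise_sigma=0.3, seed=11, label="S1")


@pytest.fixture(scope="session")
def three_state_run(toy_topology):
    """Three-state run used for clustering ground-truth recovery."""
    return ed.generate_trajectory(
        toy_topology, ed.default_states(["closed", "open", "twisted"],
                                        [0.4, 0.35, 0.25]),
        n_frames=600, noise_sigma=0.3, seed=12, label="S3")


@pytest.fixture(scope="session")
def noise_only_run(toy_topology):
    """Single-state, frozen-linker control: only Gaussian noise moves atoms."""
    return ed.generate_trajectory(
        toy_topology, ed.default_states(["open"], [1.0]),
        n_frames=5000, noise_sigma=0.4, seed=13, freeze_linker=True,
        label="noise")
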