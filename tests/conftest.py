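import numpy as np
import pytest

from lcbsr.fixtures import (
    demo_fixture_specs,
    make_pose_ensemble,
    make_toy_receptor,
)
from lcbsr.interactions import InteractionParams, assign_radii
from lcbsr.structures import Atom, Pose, ResidueKey


@pytest.fixture
def params():
    return InteractionParams()


@pytest.fixture
def demo_specs():
    return demo_fixture_specs(seed=0)


@pytest.fixture
def demo_receptor(demo_specs):
    return assign_radii(make_toy_receptor(demo_specs[0]))


@pytest.fixture
def demo_ensembles(demo_specs, demo_receptor):
    out = []
    for i, spec in enumerate(demo_specs, start=1):
        ens = make_pose_ensemble(demo_receptor, spec, experiment_id=f"exp{i}")
        for pose in ens.poses:
            assign_radii(pose)
        out.append(ens)
    return out


def make_atom(serial, element, coords, radius=None, name=None, residue_key=None):
    """Bare atom helper for hand-built geometry tests."""
    return Atom(
        serial=serial,
        name=name or f"{element}{serial}",
        element=element,
        coords=np.asarray(coords, dtype=float),
        vdw_radius=radius,
        is_hydrogen=element.upper() == "H",
        residue_key=residue_key,
    )


def make_pose(atoms, index=1, energy=-5.0):
    return Pose(index=index, atoms=atoms, binding_energy=energy)


def simple_key(resnum=1, chain="A", resname="ALA"):
    return ResidueKey(chain=chain, resnum=resnum, icode="", resname=resname)
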