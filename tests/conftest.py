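import numpy as np
import pytest

from micellekit import Atom, Frame, Trajectory
from micellekit.synthetic import MicelleSpec, build_micelle


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture(scope="session")
def sphere_micelle():
    """Default 60-chain spherical micelle, jitter-free for exact geometry."""
    return build_micelle(MicelleSpec(jitter=0.0, seed=1))


@pytest.fixture(scope="session")
def prolate_micelle():
    """2:1:1 prolate micelle with dense chains."""
    return build_micelle(MicelleSpec(n_surfactants=240, semi_axes=(4.0, 2.0, 2.0),
                                     jitter=0.0, seed=2))


def point_trajectory(coords, box, masses=None, mol_ids=None, names=None,
                     species=None, times=None):
    """Helper: wrap bare coordinate arrays into a Trajectory."""
    coords = np.asarray(coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    masses = np.ones(n) if masses is None else masses
    mol_ids = np.arange(1, n + 1) if mol_ids is None else mol_ids
    names = [f"X{i}" for i in range(n)] if names is None else names
    species = ["Other"] * n if species is None else species
    atoms = [Atom(index=i, atom_name=names[i], residue_name="MOL",
                  residue_id=int(mol_ids[i]), mass=float(masses[i]),
                  species=species[i]) for i in range(n)]
    times = np.arange(coords.shape[0], dtype=float) if times is None else times
    frames = [Frame(coords=c, box=np.asarray(box, float), time=t)
              for c, t in zip(coords, times)]
    return Trajectory(topology=atoms, frames=frames)


@pytest.fixture
def make_point_traj():
    return point_trajectory
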