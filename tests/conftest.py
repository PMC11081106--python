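import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from idpcalc.ensemble import AtomRecord, Conformer
from idpcalc.synthetic import TorsionSpec, build_peptide, generate_ensemble


def make_conformer(atom_specs, label="manual"):
    """Build a conformer from (resseq, resname, name, xyz) tuples."""
    atoms = [
        AtomRecord(serial=i + 1, name=name, altloc=" ", resname=resname,
                   chain="A", resseq=resseq, icode="", x=float(x), y=float(y),
                   z=float(z), element=name[0])
        for i, (resseq, resname, name, (x, y, z)) in enumerate(atom_specs)
    ]
    return Conformer(label=label, chain="A", atoms=atoms)


@pytest.fixture
def dumbbell():
    """Two amide protons exactly 5 A apart."""
    return make_conformer([
        (2, "ALA", "H", (0.0, 0.0, 0.0)),
        (2, "ALA", "CA", (1.0, 0.0, 0.0)),
        (14, "GLY", "H", (3.0, 4.0, 0.0)),
        (14, "GLY", "CA", (3.0, 5.0, 0.0)),
    ])


@pytest.fixture
def pentapeptide():
    """5-residue peptide with known torsions."""
    spec = TorsionSpec(
        "AAGKL",
        phi=[0.0, -math.pi / 3, -2 * math.pi / 3, 1.0, -2.5],
        psi=[2.4, -0.5, 1.1, 3.0, 0.0],
    )
    return spec, build_peptide(spec, label="penta")


@pytest.fixture(scope="session")
def ensemble_dir(tmp_path_factory):
    """10-conformer torsion-sampled ensemble on disk."""
    d = tmp_path_factory.mktemp("ens") / "pdbs"
    ens = generate_ensemble(d, 10, seed=11)
    return d, ens


def random_rigid_transform(rng):
    """A uniform random rotation matrix and a translation vector."""
    # QR of a Gaussian matrix gives a Haar-random orthogonal matrix.
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-50, 50, size=3)


def transform_conformer(conformer, rotation, translation):
    atoms = []
    for a in conformer.atoms:
        x, y, z = rotation @ a.coord + translation
        atoms.append(AtomRecord(serial=a.serial, name=a.name, altloc=a.altloc,
                                resname=a.resname, chain=a.chain, resseq=a.resseq,
                                icode=a.icode, x=x, y=y, z=z, element=a.element))
    return Conformer(label=conformer.label + "_rt", chain=conformer.chain, atoms=atoms)
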