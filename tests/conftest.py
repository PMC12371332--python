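import numpy as np
import pytest

from pocketlit.fixtures import FixtureSpec, PlantedPocket, make_structure
from pocketlit.geometry import AlphaSphere, GeometricPocket
from pocketlit.structures import Atom, ResidueRef, vdw_radius


def pdb_line(serial, name, resname, chain, resid, x, y, z, element, record="ATOM", occ=1.0, altloc=" ", icode=" "):
    name_f = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:5d} {name_f:4s}{altloc}{resname:>3s} {chain}{resid:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def tri_residue_pdb():
    """Hand-written single-chain PDB: ALA, GLY, VAL (sequence AGV)."""
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0, "C"),
        pdb_line(3, "C", "ALA", "A", 1, 2.2, 1.3, 0.0, "C"),
        pdb_line(4, "N", "GLY", "A", 2, 3.8, 0.0, 0.0, "N"),
        pdb_line(5, "CA", "GLY", "A", 2, 5.3, 0.0, 0.0, "C"),
        pdb_line(6, "N", "VAL", "A", 3, 7.6, 0.0, 0.0, "N"),
        pdb_line(7, "CA", "VAL", "A", 3, 9.1, 0.0, 0.0, "C"),
        pdb_line(8, "CB", "VAL", "A", 3, 9.8, 1.3, 0.0, "C"),
        "END",
    ]
    return "\n".join(lines) + "\n"


def octahedron_atoms():
    coords = [(2, 0, 0), (-2, 0, 0), (0, 2, 0), (0, -2, 0), (0, 0, 2), (0, 0, -2)]
    return [
        Atom(serial=i + 1, name=f"C{i}", element="C", coords=np.array(c, float),
             vdw_radius=vdw_radius("C"), is_heavy=True)
        for i, c in enumerate(coords)
    ]


@pytest.fixture
def octahedron_pocket():
    """Worked grid example: octahedral cage of 6 atoms, one alpha sphere."""
    atoms = octahedron_atoms()
    refs = [ResidueRef("A", "ALA", i + 1) for i in range(len(atoms))]
    sphere = AlphaSphere(center=np.zeros(3), radius=2.0)
    return GeometricPocket(id=1, spheres=[sphere], atoms=atoms, atom_residues=refs)


@pytest.fixture
def interface_spec():
    return FixtureSpec(
        seed=1,
        n_chains=2,
        residues_per_chain=30,
        pockets=(PlantedPocket("etomidate-like interface site", tuple(range(10, 16)), interface=True),),
        decoy_count=2,
    )


@pytest.fixture
def tetramer_spec():
    return FixtureSpec(
        seed=2,
        n_chains=4,
        residues_per_chain=30,
        pockets=(PlantedPocket("deep cleft site", tuple(range(10, 16))),),
        decoy_count=1,
    )


@pytest.fixture
def monomer_spec():
    return FixtureSpec(
        seed=3,
        n_chains=1,
        residues_per_chain=25,
        pockets=(PlantedPocket("orthosteric site", (8, 9, 10, 11, 12)),),
    )


@pytest.fixture
def interface_structure(interface_spec):
    return make_structure(interface_spec)
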