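"""Shared fixtures: synthetic complexes and hand-built micro-structures."""

from __future__ import annotations

import numpy as np
import pytest

from micurate.fixtures import FixtureSpec, assemble_complex
from micurate.structure import Atom, ComplexStructure, Residue, VDW_RADII


def mk_atom(name: str, coord, element: str | None = None,
            sidechain: bool | None = None, occupancy: float = 1.0) -> Atom:
    el = element or name[0]
    return Atom(
        name=name,
        element=el,
        coord=np.asarray(coord, dtype=float),
        occupancy=occupancy,
        is_sidechain=(
            sidechain
            if sidechain is not None
            else name not in ("N", "CA", "C", "O", "OXT")
        ),
        vdw_radius=VDW_RADII.get(el, 1.70),
        is_hydrogen=el == "H",
    )


def mk_res(chain: str, idx: int, name: str, atoms: dict) -> Residue:
    """atoms: mapping atom-name -> coordinate (element from first letter)."""
    return Residue(chain, idx, name, [mk_atom(n, c) for n, c in atoms.items()])


def backbone_at(origin, direction=(1.0, 0.0, 0.0)) -> dict:
    """Minimal plausible N/CA/C/O/CB geometry translated to ``origin``."""
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    perp = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(perp, d)) > 0.9:
        perp = np.array([0.0, 1.0, 0.0])
    perp = perp - np.dot(perp, d) * d
    perp /= np.linalg.norm(perp)
    return {
        "N": o - 1.46 * d + 0.3 * perp,
        "CA": o,
        "C": o + 1.52 * d + 0.3 * perp,
        "O": o + 1.52 * d + 1.5 * perp,
        "CB": o + 1.52 * np.cross(d, perp) - 0.4 * perp,
    }


def random_rigid(rng: np.random.Generator):
    """A uniform-ish random proper rotation and a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.uniform(-20, 20, size=3)


@pytest.fixture(scope="session")
def default_spec() -> FixtureSpec:
    return FixtureSpec()


@pytest.fixture(scope="session")
def default_complex(default_spec) -> ComplexStructure:
    """Helix-bundle binder cradling an AAyAA phosphopeptide, 3 contacts."""
    return assemble_complex(default_spec)


@pytest.fixture(scope="session")
def tailed_complex() -> ComplexStructure:
    """Default complex with 6-residue disordered tails on the binder."""
    return assemble_complex(FixtureSpec(disorder_tail_len=6))


@pytest.fixture(scope="session")
def sheet_complex() -> ComplexStructure:
    """Sheet binder with strand-conformation peptide (strand-paired mode)."""
    return assemble_complex(
        FixtureSpec(binder_topology="sheet", peptide_sequence="AAyAA")
    )


@pytest.fixture(scope="session")
def no_contact_complex() -> ComplexStructure:
    """Peptide floated away from the binder: no hotspots anywhere."""
    return assemble_complex(
        FixtureSpec(
            n_contact_residues=0, separation=12.0, phosphate_donor_distances=()
        )
    )


TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.023   1.415   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.308   2.413   0.107  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.990  -0.773  -1.210  1.00  0.00           C
ATOM      6  N   GLY B   1       3.350   1.505  -0.123  1.00  0.00           N
ATOM      7  CA  GLY B   1       4.010   2.800  -0.155  1.00  0.00           C
ATOM      8  C   GLY B   1       5.520   2.650  -0.300  1.00  0.00           C
ATOM      9  O   GLY B   1       6.050   1.540  -0.350  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       1.400   0.200   0.000  0.40  0.00           C
ATOM      4  C   ALA A   1       2.023   1.415   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       1.308   2.413   0.107  1.00  0.00           O
END
"""


@pytest.fixture()
def two_residue_pdb(tmp_path):
    p = tmp_path / "two.pdb"
    p.write_text(TWO_RESIDUE_PDB)
    return p


@pytest.fixture()
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p
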