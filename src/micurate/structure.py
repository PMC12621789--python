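"""Structure parsing, chain-role tagging, and geometric primitives.

The in-memory model is deliberately small: a ``ComplexStructure`` is an
ordered list of residues, each an ordered list of heavy atoms, plus a
chain-role map that tags every chain as ``binder`` or ``target``.  All
downstream annotations (hotspots, packing, conditioning, filters) attach
to this object.  Parsing and writing go through :mod:`gemmi`; altloc
resolution, water/heteroatom policy, and phosphotyrosine (PTR) handling
are applied while converting to the internal model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Van der Waals radii (A) for the elements that occur in heavy-atom
#: protein models.  Fixed published element-radius set; unknown elements
#: fall back to carbon.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})

STANDARD_AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

#: Terminal phosphate oxygens of the PTR chemical component; the
#: bridging ester oxygen that links the phosphate to the tyrosine ring
#: is named OH.
PTR_TERMINAL_PHOSPHATE_OXYGENS = ("O1P", "O2P", "O3P")
PTR_BRIDGING_OXYGEN = "OH"

BINDER = "binder"
TARGET = "target"


class StructureError(ValueError):
    """Raised for unreadable, empty, or inconsistent structures."""


class IncompleteResidueError(StructureError):
    """Raised when a residue lacks atoms an operation requires."""


@dataclass
class Atom:
    """A single heavy atom (or hydrogen, when retained)."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    is_sidechain: bool = False
    vdw_radius: float = DEFAULT_VDW_RADIUS
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(
                f"atom {self.name}: coordinates must be a finite 3-vector"
            )
        if self.vdw_radius <= 0:
            raise StructureError(f"atom {self.name}: vdw_radius must be > 0")

    def copy(self) -> "Atom":
        return Atom(
            self.name,
            self.element,
            self.coord.copy(),
            self.occupancy,
            self.is_sidechain,
            self.vdw_radius,
            self.is_hydrogen,
        )


@dataclass
class Residue:
    """One residue: chain id, author sequence number, name, ordered atoms."""

    chain_id: str
    seq_index: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(
                f"residue {self.chain_id}{self.seq_index} {self.name}: no atoms"
            )
        seen: set[str] = set()
        for a in self.atoms:
            if a.name in seen:
                raise StructureError(
                    f"residue {self.chain_id}{self.seq_index}: duplicate atom "
                    f"name {a.name!r}"
                )
            seen.add(a.name)

    @property
    def key(self) -> tuple[str, int]:
        """(chain_id, seq_index) identifier used throughout the package."""
        return (self.chain_id, self.seq_index)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def backbone(self) -> dict[str, Atom]:
        """Named references to N, CA, C, O when present."""
        out = {}
        for name in ("N", "CA", "C", "O"):
            a = self.atom(name)
            if a is not None:
                out[name] = a
        return out

    def has_backbone(self, names: Sequence[str] = ("N", "CA", "C")) -> bool:
        return all(self.atom(n) is not None for n in names)

    def heavy_coords(self) -> np.ndarray:
        return np.array(
            [a.coord for a in self.atoms if not a.is_hydrogen], dtype=float
        )

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id, self.seq_index, self.name, [a.copy() for a in self.atoms]
        )


@dataclass
class ComplexStructure:
    """A parsed all-atom complex with chains tagged binder or target."""

    residues: list[Residue]
    role_of_chain: dict[str, str] = field(default_factory=dict)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        # residue order within each chain must be monotone in seq_index
        last: dict[str, int] = {}
        for r in self.residues:
            if r.chain_id in last and r.seq_index <= last[r.chain_id]:
                raise StructureError(
                    f"chain {r.chain_id}: residue order not monotone at "
                    f"seq_index {r.seq_index}"
                )
            last[r.chain_id] = r.seq_index

    # -- chain / role helpers -------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def role(self, chain_id: str) -> str:
        return self.role_of_chain.get(chain_id, TARGET)

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def binder_residues(self) -> list[Residue]:
        return [r for r in self.residues if self.role(r.chain_id) == BINDER]

    def target_residues(self) -> list[Residue]:
        return [r for r in self.residues if self.role(r.chain_id) == TARGET]

    def require_interface(self) -> None:
        roles = {self.role(c) for c in self.chain_ids}
        if BINDER not in roles:
            raise StructureError("no binder chain assigned")
        if TARGET not in roles:
            raise StructureError("no target chain")

    # -- atom helpers ---------------------------------------------------------
    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def residue_by_key(self, key: tuple[str, int]) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(key)

    def subset(self, keys: Iterable[tuple[str, int]]) -> "ComplexStructure":
        """New structure keeping only the residues with the given keys."""
        keep = set(keys)
        return ComplexStructure(
            [r.copy() for r in self.residues if r.key in keep],
            dict(self.role_of_chain),
            self.source,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexStructure":
        """Rigid-body copy: x -> R @ x + t for every atom."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = ComplexStructure(
            [r.copy() for r in self.residues], dict(self.role_of_chain), self.source
        )
        for _, a in out.iter_atoms():
            a.coord = rotation @ a.coord + translation
        return out


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper()
    return el if el else "C"


def _is_sidechain(name: str) -> bool:
    return name not in BACKBONE_ATOM_NAMES


def read_structure(
    path: str | Path,
    format: str = "auto",
    keep_hydrogens: bool = True,
    keep_hetero: bool = False,
) -> ComplexStructure:
    """Read a PDB or mmCIF file into a :class:`ComplexStructure`.

    All heavy atoms are retained; hydrogens are retained when present and
    ``keep_hydrogens`` is true.  Alternate locations are resolved to the
    highest occupancy (ties broken by altloc letter order).  Waters and
    heteroatoms other than PTR are excluded unless ``keep_hetero``.
    Chain roles default to ``target``; call :func:`assign_roles` next.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise StructureError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: empty structure (no models)")
    model = st[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.name == "HOH":
                continue
            is_standard = res.name in STANDARD_AA3
            if not is_standard and res.name != "PTR" and not keep_hetero:
                # retain only polymer-like records by default
                if res.het_flag == "H":
                    continue
            atoms = _convert_atoms(res, keep_hydrogens)
            if not atoms:
                continue
            residues.append(
                Residue(chain.name, res.seqid.num, res.name, atoms)
            )
    if not residues:
        raise StructureError(f"{path}: no residues after filtering")
    return ComplexStructure(residues, {}, source=str(path))


def _convert_atoms(res: gemmi.Residue, keep_hydrogens: bool) -> list[Atom]:
    # altloc groups by atom name: highest occupancy wins, ties by letter
    by_name: dict[str, list[gemmi.Atom]] = {}
    order: list[str] = []
    for a in res:
        if a.name not in by_name:
            by_name[a.name] = []
            order.append(a.name)
        by_name[a.name].append(a)
    atoms: list[Atom] = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occ, a.altloc or "~"))
        el = _element_of(best)
        is_h = el == "H"
        if is_h and not keep_hydrogens:
            continue
        atoms.append(
            Atom(
                name=name,
                element=el,
                coord=np.array([best.pos.x, best.pos.y, best.pos.z]),
                occupancy=best.occ,
                is_sidechain=_is_sidechain(name),
                vdw_radius=VDW_RADII.get(el, DEFAULT_VDW_RADIUS),
                is_hydrogen=is_h,
            )
        )
    return atoms


def to_gemmi(structure: ComplexStructure, ori: np.ndarray | None = None) -> gemmi.Structure:
    """Convert to a gemmi Structure (one model; optional ORI pseudoatom)."""
    st = gemmi.Structure()
    st.name = "micurate"
    model = gemmi.Model("1")
    for chain_id in structure.chain_ids:
        chain = gemmi.Chain(chain_id)
        for r in structure.chain_residues(chain_id):
            gres = gemmi.Residue()
            gres.name = r.name
            gres.seqid = gemmi.SeqId(r.seq_index, " ")
            gres.het_flag = "A" if r.name in STANDARD_AA3 else "H"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = a.occupancy
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    if ori is not None:
        chain = gemmi.Chain("Z")
        gres = gemmi.Residue()
        gres.name = "ORI"
        gres.seqid = gemmi.SeqId(1, " ")
        gres.het_flag = "H"
        ga = gemmi.Atom()
        ga.name = "ORI"
        ga.element = gemmi.Element("X")
        ga.pos = gemmi.Position(*np.asarray(ori, dtype=float))
        ga.occ = 1.0
        gres.add_atom(ga)
        chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    return st


def write_structure(
    structure: ComplexStructure,
    path: str | Path,
    ori: np.ndarray | None = None,
) -> None:
    """Write the structure as PDB; ORI, when given, becomes a pseudoatom."""
    st = to_gemmi(structure, ori=ori)
    st.setup_entities()
    doc_path = Path(path)
    # strip the gemmi timestamp remark so identical structures give
    # byte-identical files
    pdb_text = st.make_pdb_string()
    lines = [
        ln
        for ln in pdb_text.splitlines()
        if not ln.startswith("REMARK") and not ln.startswith("CRYST1")
    ]
    doc_path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# roles
# ---------------------------------------------------------------------------

def assign_roles(
    structure: ComplexStructure, binder_chains: Iterable[str]
) -> ComplexStructure:
    """Tag the named chains as binder; every other chain becomes target."""
    binder_chains = set(binder_chains)
    available = structure.chain_ids
    unknown = binder_chains - set(available)
    if unknown:
        raise StructureError(
            f"unknown chain id(s) {sorted(unknown)}; available: {available}"
        )
    roles = {c: (BINDER if c in binder_chains else TARGET) for c in available}
    return ComplexStructure(
        [r.copy() for r in structure.residues], roles, structure.source
    )


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

#: Ideal Calpha-Cbeta bond length (A) for the virtual-Cbeta construction.
CA_CB_BOND_LENGTH = 1.522


def virtual_cbeta(residue: Residue) -> np.ndarray:
    """Actual Cbeta coordinate, or an ideal one built from N/CA/C.

    Glycine (and any residue lacking an explicit CB) gets a virtual
    Cbeta placed at ideal tetrahedral geometry 1.522 A from CA.  The
    construction is rigid-motion equivariant.
    """
    cb = residue.atom("CB")
    if cb is not None and residue.name != "GLY":
        return cb.coord.copy()
    for name in ("N", "CA", "C"):
        if residue.atom(name) is None:
            raise IncompleteResidueError(
                f"residue {residue.chain_id}{residue.seq_index} "
                f"{residue.name}: missing backbone atom {name}"
            )
    n = residue.atom("N").coord
    ca = residue.atom("CA").coord
    c = residue.atom("C").coord
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    v = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc
    norm = np.linalg.norm(v)
    if norm == 0:
        raise IncompleteResidueError(
            f"residue {residue.chain_id}{residue.seq_index}: degenerate backbone"
        )
    return ca + CA_CB_BOND_LENGTH * v / norm


@dataclass
class PhosphateGroup:
    """Phosphate atom group of a phosphotyrosine (PTR) residue."""

    phosphorus: Atom
    terminal_oxygens: list[Atom]
    bridging_oxygen: Atom | None

    @property
    def atoms(self) -> list[Atom]:
        out = [self.phosphorus] + list(self.terminal_oxygens)
        if self.bridging_oxygen is not None:
            out.append(self.bridging_oxygen)
        return out

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)


def phosphate_atoms(residue: Residue) -> PhosphateGroup:
    """Return P and its bonded oxygens for a PTR residue.

    The bridging ester oxygen (OH, linking the phosphate to the tyrosine
    ring) is flagged distinctly from the terminal phosphate oxygens.
    Missing terminal oxygens are tolerated with a warning; a missing P
    raises :class:`IncompleteResidueError`.
    """
    if residue.name != "PTR":
        raise StructureError(
            f"phosphate_atoms requires PTR, got {residue.name} at "
            f"{residue.chain_id}{residue.seq_index}"
        )
    p = residue.atom("P")
    if p is None:
        raise IncompleteResidueError(
            f"PTR {residue.chain_id}{residue.seq_index}: phosphorus atom missing"
        )
    terminals = []
    for name in PTR_TERMINAL_PHOSPHATE_OXYGENS:
        a = residue.atom(name)
        if a is None:
            logger.warning(
                "PTR %s%d: terminal phosphate oxygen %s missing",
                residue.chain_id,
                residue.seq_index,
                name,
            )
        else:
            terminals.append(a)
    bridging = residue.atom(PTR_BRIDGING_OXYGEN)
    if bridging is None:
        logger.warning(
            "PTR %s%d: bridging oxygen OH missing",
            residue.chain_id,
            residue.seq_index,
        )
    return PhosphateGroup(p, terminals, bridging)


def find_ptr_residues(structure: ComplexStructure, role: str | None = None) -> list[Residue]:
    """All PTR residues, optionally restricted to one chain role."""
    out = []
    for r in structure.residues:
        if r.name == "PTR":
            if role is None or structure.role(r.chain_id) == role:
                out.append(r)
    return out
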