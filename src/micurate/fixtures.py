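"""Deterministic toy binder-phosphopeptide complexes for testing and demos.

The generator builds idealized poly-alanine scaffolds (single helix,
three-helix bundle, or small sheet) and a peptide in helix, strand, or
extended conformation, with lowercase ``y`` positions becoming
phosphotyrosine (PTR) carrying a full idealized phosphate group.  The
peptide is placed by a deterministic geometric search so that a requested
number of peptide residues sit within hotspot contact range (Cbeta-Cbeta
<= 7 A) of the binder, pseudo-donor nitrogens are appended to the binder
at requested distances from the terminal phosphate oxygens, and
artificially disordered (extended, non-contacting) tails can be appended
to the binder termini.

This is a geometric stand-in for curated experimental complexes, not a
physical model: side chains beyond Cbeta are omitted except for PTR and
explicit donor groups, and no clash minimization is attempted beyond the
placement search itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from micurate.structure import (
    Atom,
    ComplexStructure,
    Residue,
    StructureError,
    VDW_RADII,
    assign_roles,
    phosphate_atoms,
    virtual_cbeta,
)
from micurate.conditioning import ONE_TO_THREE

# ideal backbone internal coordinates (A, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -120.0, 120.0
EXTENDED_PHI, EXTENDED_PSI = -150.0, 150.0

CONFORMATIONS = {
    "helix": (HELIX_PHI, HELIX_PSI),
    "strand": (STRAND_PHI, STRAND_PSI),
    "extended": (EXTENDED_PHI, EXTENDED_PSI),
}

HOTSPOT_CONTACT_CUTOFF = 7.0


@dataclass
class FixtureSpec:
    """Recipe for one synthetic binder-phosphopeptide complex."""

    binder_topology: str = "helix_bundle"
    binder_length: int = 48
    peptide_sequence: str = "AAyAA"
    separation: float = 5.5
    n_contact_residues: int = 3
    phosphate_donor_distances: tuple[float, ...] = (2.9, 2.9)
    disorder_tail_len: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.binder_topology not in ("helix_bundle", "sheet", "single_helix"):
            raise ValueError(f"unknown binder topology {self.binder_topology!r}")
        if self.binder_length < 10:
            raise ValueError("binder_length must be >= 10")
        if len(self.peptide_sequence) < 3:
            raise ValueError("peptide must have >= 3 residues")
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        if self.n_contact_residues > len(self.peptide_sequence):
            raise ValueError("n_contact_residues exceeds peptide length")
        if self.n_contact_residues > 0 and self.separation > HOTSPOT_CONTACT_CUTOFF:
            raise StructureError(
                f"infeasible: contacts requested at separation "
                f"{self.separation} A > {HOTSPOT_CONTACT_CUTOFF} A"
            )


# ---------------------------------------------------------------------------
# internal-coordinate construction
# ---------------------------------------------------------------------------

def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Place atom d so that |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = dihedral (natural extension reference frame)."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _ideal_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    v = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc
    return ca + 1.522 * v / np.linalg.norm(v)


def _mk_atom(name: str, element: str, coord: np.ndarray, sidechain: bool) -> Atom:
    return Atom(
        name=name,
        element=element,
        coord=np.asarray(coord, dtype=float),
        is_sidechain=sidechain,
        vdw_radius=VDW_RADII.get(element, 1.70),
    )


def _build_chain(
    names: list[str],
    phi: float,
    psi: float,
    chain_id: str = "A",
    start_index: int = 1,
    omega: float = 180.0,
) -> list[Residue]:
    """Poly-residue backbone (N, CA, C, O, CB) at fixed (phi, psi)."""
    n_res = len(names)
    if n_res < 2:
        raise ValueError("chain needs length >= 2")
    # bootstrap the first residue in a fixed local frame
    coords: list[dict[str, np.ndarray]] = [{} for _ in range(n_res)]
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords[0]["N"], coords[0]["CA"], coords[0]["C"] = n0, ca0, c0
    for i in range(1, n_res):
        prev = coords[i - 1]
        ni = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
        cai = place_atom(prev["CA"], prev["C"], ni, BOND_N_CA, ANGLE_C_N_CA, omega)
        ci = place_atom(prev["C"], ni, cai, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords[i]["N"], coords[i]["CA"], coords[i]["C"] = ni, cai, ci
        # carbonyl O of the previous residue, trans to the next N
        prev["O"] = place_atom(ni, prev["CA"], prev["C"], BOND_C_O, ANGLE_CA_C_O, 180.0)
    last = coords[-1]
    last["O"] = place_atom(
        last["N"], last["CA"], last["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0
    )

    residues = []
    for i, name in enumerate(names):
        c = coords[i]
        atoms = [
            _mk_atom("N", "N", c["N"], False),
            _mk_atom("CA", "C", c["CA"], False),
            _mk_atom("C", "C", c["C"], False),
            _mk_atom("O", "O", c["O"], False),
        ]
        if name != "GLY":
            atoms.append(
                _mk_atom("CB", "C", _ideal_cbeta(c["N"], c["CA"], c["C"]), True)
            )
        if name == "PTR":
            atoms.extend(_ptr_sidechain(c["N"], c["CA"], c["C"], atoms[-1].coord))
        residues.append(Residue(chain_id, start_index + i, name, atoms))
    return residues


def _ptr_sidechain(
    n: np.ndarray, ca: np.ndarray, c: np.ndarray, cb: np.ndarray
) -> list[Atom]:
    """Idealized phosphotyrosine side chain past CB (ring + phosphate)."""
    cg = place_atom(n, ca, cb, 1.51, 113.9, 180.0)
    cd1 = place_atom(ca, cb, cg, 1.39, 120.9, 90.0)
    cd2 = place_atom(ca, cb, cg, 1.39, 120.9, -90.0)
    ce1 = place_atom(cb, cg, cd1, 1.39, 121.0, 180.0)
    ce2 = place_atom(cb, cg, cd2, 1.39, 121.0, 180.0)
    cz = place_atom(cg, cd1, ce1, 1.39, 120.0, 0.0)
    oh = place_atom(cd1, ce1, cz, 1.38, 120.0, 180.0)
    p = place_atom(ce1, cz, oh, 1.61, 120.0, 180.0)
    o1p = place_atom(cz, oh, p, 1.50, 109.5, 60.0)
    o2p = place_atom(cz, oh, p, 1.50, 109.5, 180.0)
    o3p = place_atom(cz, oh, p, 1.50, 109.5, -60.0)
    spec = [
        ("CG", "C", cg), ("CD1", "C", cd1), ("CD2", "C", cd2),
        ("CE1", "C", ce1), ("CE2", "C", ce2), ("CZ", "C", cz),
        ("OH", "O", oh), ("P", "P", p),
        ("O1P", "O", o1p), ("O2P", "O", o2p), ("O3P", "O", o3p),
    ]
    return [_mk_atom(nm, el, xyz, True) for nm, el, xyz in spec]


def build_ideal_helix(
    length: int, start: np.ndarray | None = None, chain_id: str = "A",
    start_index: int = 1,
) -> list[Residue]:
    """Ideal poly-alanine alpha helix (phi=-57, psi=-47, omega=180)."""
    if length < 2:
        raise ValueError("helix length must be >= 2")
    residues = _build_chain(
        ["ALA"] * length, HELIX_PHI, HELIX_PSI, chain_id, start_index
    )
    if start is not None:
        shift = np.asarray(start, dtype=float) - residues[0].atom("N").coord
        for r in residues:
            for a in r.atoms:
                a.coord = a.coord + shift
    return residues


def build_phosphopeptide(
    sequence: str, conformation: str = "helix", chain_id: str = "B",
    start_index: int = 1,
) -> list[Residue]:
    """Peptide chain; lowercase ``y`` positions become PTR with a full
    phosphate group at ideal tyrosine + phosphoester geometry."""
    if conformation not in CONFORMATIONS:
        raise ValueError(f"unknown conformation {conformation!r}")
    names = []
    for pos, ch in enumerate(sequence):
        if ch == "y":
            names.append("PTR")
        elif ch in ONE_TO_THREE:
            names.append(ONE_TO_THREE[ch])
        else:
            raise ValueError(
                f"invalid character {ch!r} at position {pos} in peptide sequence"
            )
    phi, psi = CONFORMATIONS[conformation]
    return _build_chain(names, phi, psi, chain_id, start_index)


# ---------------------------------------------------------------------------
# rigid helpers
# ---------------------------------------------------------------------------

def _coords(residues: list[Residue], atom: str = "CA") -> np.ndarray:
    return np.array([r.atom(atom).coord for r in residues if r.atom(atom)])


def _apply(residues: list[Residue], rot: np.ndarray, trans: np.ndarray) -> None:
    for r in residues:
        for a in r.atoms:
            a.coord = rot @ a.coord + trans


def _align_axis_to_z(residues: list[Residue]) -> None:
    """Rotate/translate so the CA principal axis is +z (first residue at
    low z) and the CA centroid sits at the origin."""
    ca = _coords(residues)
    centroid = ca.mean(axis=0)
    u, s, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    cth = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-9:
        rot = np.eye(3) if cth > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + cth)
    _apply(residues, rot, -rot @ centroid)


def _rot_y(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array(
        [[math.cos(a), 0, math.sin(a)], [0, 1, 0], [-math.sin(a), 0, math.cos(a)]]
    )


def _rot_z(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array(
        [[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]]
    )


def _rot_x(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array(
        [[1, 0, 0], [0, math.cos(a), -math.sin(a)], [0, math.sin(a), math.cos(a)]]
    )


def _cbeta_or_ca(r: Residue) -> np.ndarray:
    a = r.atom("CB")
    if a is not None:
        return a.coord
    try:
        return virtual_cbeta(r)  # matches the hotspot Cbeta definition
    except Exception:
        return r.atom("CA").coord


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _build_binder(spec: FixtureSpec) -> list[Residue]:
    topo = spec.binder_topology
    if topo == "single_helix":
        segs = [build_ideal_helix(spec.binder_length)]
        offsets = [np.zeros(3)]
    elif topo == "helix_bundle":
        per = spec.binder_length // 3
        lens = [per, per, spec.binder_length - 2 * per]
        segs = [build_ideal_helix(L) for L in lens]
        # triangular (coiled-coil-like) packing, axes ~9 A apart
        s = 9.0
        offsets = [
            np.array([0.0, 0.0, 0.0]),
            np.array([-s, 0.0, 0.0]),
            np.array([-s / 2, -s * math.sqrt(3) / 2, 0.0]),
        ]
    else:  # sheet
        per = max(3, spec.binder_length // 4)
        n_str = max(2, spec.binder_length // per)
        lens = [per] * (n_str - 1) + [spec.binder_length - per * (n_str - 1)]
        segs = [_build_chain(["ALA"] * L, STRAND_PHI, STRAND_PSI) for L in lens]
        offsets = [np.array([-4.8 * k, 0.0, 0.0]) for k in range(n_str)]
    placed: list[Residue] = []
    for k, seg in enumerate(segs):
        _align_axis_to_z(seg)
        if k % 2 == 1 and topo != "single_helix":
            _apply(seg, _rot_x(180.0), np.zeros(3))
        _apply(seg, np.eye(3), offsets[k])
        placed.extend(seg)
    if topo == "helix_bundle":
        # turn the inter-helix groove toward +x, where the peptide is
        # placed, so contact residues pack against two helices at once
        _apply(placed, _rot_z(-90.0), np.zeros(3))
    # renumber into one contiguous chain A
    out = []
    for i, r in enumerate(placed, start=1):
        out.append(Residue("A", i, r.name, [a.copy() for a in r.atoms]))
    return out


def _place_peptide(
    binder: list[Residue], peptide: list[Residue], spec: FixtureSpec
) -> None:
    """Deterministic search: tilt + offset the peptide (in the +x half
    space) until exactly n_contact_residues peptide residues have Cbeta
    within 7 A of a binder Cbeta, with the closest pair near the
    requested separation."""
    _align_axis_to_z(peptide)
    binder_cb = np.array([_cbeta_or_ca(r) for r in binder])
    base = {id(a): a.coord.copy() for r in peptide for a in r.atoms}
    pep_cb_base = np.array([_cbeta_or_ca(r) for r in peptide])
    n_want = spec.n_contact_residues
    x_edge = binder_cb[:, 0].max()

    def try_placement(alpha: float, x0: float, z0: float) -> tuple[int, float]:
        rot = _rot_y(alpha)
        cb = (rot @ pep_cb_base.T).T + np.array([x0, 0.0, z0])
        dmin = np.array(
            [np.linalg.norm(binder_cb - p, axis=1).min() for p in cb]
        )
        return int((dmin <= HOTSPOT_CONTACT_CUTOFF).sum()), float(dmin.min())

    target_gap = spec.separation if n_want > 0 else max(spec.separation, 11.0)
    # progressively relaxed search: gap tolerance grows if the exact
    # contact count cannot be met near the requested separation
    phases = [
        (0.15, np.arange(0.0, 82.0, 3.0), (0.0,)),
        (0.5, np.arange(0.0, 85.0, 1.5), (0.0, -1.5, 1.5, -3.0, 3.0)),
        (1.2, np.arange(0.0, 85.0, 1.5), (0.0, -1.5, 1.5, -3.0, 3.0, -4.5, 4.5)),
    ]
    best = None
    for tol, alphas, zoffs in phases:
        for alpha in alphas:
            for z0 in zoffs:
                for x0 in np.arange(x_edge, x_edge + 40.0, 0.05):
                    n, gap = try_placement(alpha, x0, z0)
                    if abs(gap - target_gap) <= tol and (
                        n_want == 0 or n == n_want
                    ):
                        best = (alpha, x0, z0)
                        break
                    if gap > target_gap + tol + 0.5:
                        break
                if best:
                    break
            if best:
                break
        if best:
            break
    if best is None:
        raise StructureError(
            f"infeasible fixture geometry: cannot place peptide with "
            f"{n_want} contacts at separation {spec.separation} A"
        )
    rot = _rot_y(best[0])
    trans = np.array([best[1], 0.0, best[2]])
    for r in peptide:
        for a in r.atoms:
            a.coord = rot @ base[id(a)] + trans


def _append_donors(
    binder: list[Residue], peptide: list[Residue], spec: FixtureSpec
) -> None:
    """Pseudo side-chain nitrogen donors at requested distances from the
    terminal phosphate oxygens, attached to the nearest binder residue."""
    if not spec.phosphate_donor_distances:
        return
    ptrs = [r for r in peptide if r.name == "PTR"]
    if not ptrs:
        raise StructureError(
            "phosphate donor distances requested but the peptide has no PTR"
        )
    group = phosphate_atoms(ptrs[0])
    p = group.phosphorus.coord
    terminals = group.terminal_oxygens
    for k, dist in enumerate(spec.phosphate_donor_distances):
        o = terminals[k % len(terminals)]
        direction = o.coord - p
        direction /= np.linalg.norm(direction)
        # spread repeat donors on the same oxygen slightly apart
        jitter_axis = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(jitter_axis) > 1e-6:
            jitter_axis /= np.linalg.norm(jitter_axis)
        offset = 0.35 * (k // len(terminals)) * jitter_axis
        pos = o.coord + dist * direction + offset
        if np.linalg.norm(offset) > 0:
            pos = o.coord + dist * (
                (pos - o.coord) / np.linalg.norm(pos - o.coord)
            )
        host = min(
            binder, key=lambda r: np.linalg.norm(_cbeta_or_ca(r) - pos)
        )
        host.atoms.append(_mk_atom(f"NX{k + 1}", "N", pos, True))


def _append_tails(binder: list[Residue], spec: FixtureSpec) -> list[Residue]:
    """Extended, outward-pointing low-packing tails at both termini."""
    t = spec.disorder_tail_len
    if t == 0:
        return binder
    all_ca = _coords(binder)
    centroid = all_ca.mean(axis=0)

    def tail_from(terminal: Residue, count: int, cid: str) -> list[Residue]:
        seg = _build_chain(["GLY"] * max(count, 2), EXTENDED_PHI, EXTENDED_PSI, cid)
        _align_axis_to_z(seg)
        term_ca = terminal.atom("CA").coord
        out_dir = term_ca - centroid
        out_dir /= np.linalg.norm(out_dir)
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, out_dir)
        cth = float(np.dot(z, out_dir))
        if np.linalg.norm(v) < 1e-9:
            rot = np.eye(3) if cth > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx / (1.0 + cth)
        _apply(seg, rot, np.zeros(3))
        first_ca = seg[0].atom("CA").coord
        _apply(seg, np.eye(3), term_ca + 4.5 * out_dir - first_ca)
        return seg[:count]

    n_tail = tail_from(binder[0], t, "A")
    c_tail = tail_from(binder[-1], t, "A")
    merged = list(reversed(n_tail)) + binder + c_tail
    out = []
    for i, r in enumerate(merged, start=1):
        out.append(Residue("A", i, r.name, [a.copy() for a in r.atoms]))
    return out


def assemble_complex(spec: FixtureSpec) -> ComplexStructure:
    """Build the full synthetic complex described by ``spec``.

    Chain A is the binder, chain B the peptide target; the result is
    fully deterministic for a given spec.
    """
    binder = _build_binder(spec)
    conformation = "strand" if spec.binder_topology == "sheet" else "helix"
    peptide = build_phosphopeptide(spec.peptide_sequence, conformation)
    _place_peptide(binder, peptide, spec)
    _append_donors(binder, peptide, spec)
    binder = _append_tails(binder, spec)
    structure = ComplexStructure(binder + peptide, {}, source="synthetic")
    return assign_roles(structure, {"A"})
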