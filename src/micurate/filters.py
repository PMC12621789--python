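"""Hydrogen-bond counting, phosphotyrosine RMSD, and design accept/reject gates.

Phosphopeptide binder designs are screened with three structural gates:
at least two hydrogen bonds from the binder to the phosphotyrosine's
phosphate group (phospho-specificity), no more than twelve total hydrogen
bonds to the peptide (to penalize excessive phosphate-independent
contacts), and a phosphotyrosine RMSD below 5 A between the designed and
predicted complexes after superposing on the binder.  Side-chain to
side-chain bonds are counted separately as a sequence-specificity signal.
Structure-prediction confidence gates (pLDDT / iPAE / iPTM / PTM) are
applied only when the user supplies both the metric and its threshold.

Hydrogen bonds use a heavy-atom geometric criterion: donor-acceptor
distance <= 3.5 A and antecedent-acceptor-donor angle >= 90 deg, plus a
donor-hydrogen-acceptor angle >= 120 deg when explicit hydrogens exist.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from micurate.structure import (
    BINDER,
    TARGET,
    Atom,
    ComplexStructure,
    Residue,
    StructureError,
    find_ptr_residues,
    PTR_TERMINAL_PHOSPHATE_OXYGENS,
)

logger = logging.getLogger(__name__)

HBOND_DIST_CUTOFF = 3.5
HBOND_ANTECEDENT_ANGLE_MIN = 90.0
HBOND_DHA_ANGLE_MIN = 120.0

# side-chain donor atom names per residue type; backbone N is always a donor
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}

# side-chain acceptor atom names; backbone O/OXT are always acceptors
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "MET": ("SD",),
    "PTR": PTR_TERMINAL_PHOSPHATE_OXYGENS + ("OH",),
}


@dataclass
class HBond:
    donor_atom: Atom
    acceptor_atom: Atom
    donor_residue: tuple[str, int]
    acceptor_residue: tuple[str, int]
    distance: float
    is_sidechain_sidechain: bool
    acceptor_is_phosphate_oxygen: bool


@dataclass
class FilterThresholds:
    """Numeric gates for design filtering.

    Confidence thresholds have no defaults on purpose: they are applied
    only when explicitly supplied together with the measured metric.
    """

    min_phosphate_hbonds: int = 2
    max_peptide_hbonds: int = 12
    max_ptyr_rmsd: float = 5.0
    min_plddt: float | None = None
    max_ipae: float | None = None
    min_iptm: float | None = None
    min_ptm: float | None = None
    max_design_binder_len: int = 160


@dataclass
class FilterReport:
    n_phosphate_hbonds: int
    n_peptide_hbonds_total: int
    n_sidechain_sidechain_hbonds: int
    ptyr_rmsd: float | None
    binder_length: int | None
    confidence: dict[str, float] = field(default_factory=dict)
    verdict: str = "pass"
    fail_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = "fail" if self.fail_reasons else "pass"
        if self.verdict != expected:
            raise ValueError("verdict inconsistent with fail_reasons")

    def to_dict(self) -> dict:
        return {
            "n_phosphate_hbonds": self.n_phosphate_hbonds,
            "n_peptide_hbonds_total": self.n_peptide_hbonds_total,
            "n_sidechain_sidechain_hbonds": self.n_sidechain_sidechain_hbonds,
            "ptyr_rmsd": self.ptyr_rmsd,
            "binder_length": self.binder_length,
            "confidence": dict(self.confidence),
            "verdict": self.verdict,
            "fail_reasons": list(self.fail_reasons),
        }


# ---------------------------------------------------------------------------
# donor / acceptor typing
# ---------------------------------------------------------------------------

def _donor_atoms(res: Residue) -> list[Atom]:
    out = []
    n = res.atom("N")
    if n is not None:
        out.append(n)
    names = set(SIDECHAIN_DONORS.get(res.name, ()))
    for a in res.atoms:
        if a.is_hydrogen:
            continue
        # named side-chain donors, plus any other side-chain nitrogen
        # (covers non-standard residues and synthetic donor groups)
        if a.name in names or (a.is_sidechain and a.element == "N"):
            out.append(a)
    return out


def _acceptor_atoms(res: Residue) -> list[Atom]:
    out = []
    for name in ("O", "OXT"):
        a = res.atom(name)
        if a is not None:
            out.append(a)
    names = set(SIDECHAIN_ACCEPTORS.get(res.name, ()))
    for a in res.atoms:
        if a.name in names and a not in out:
            out.append(a)
    return out


def _antecedent(res: Residue, acceptor: Atom) -> Atom | None:
    """Heavy atom covalently preceding the acceptor: nearest heavy
    neighbor within the residue (bonded by distance)."""
    best = None
    best_d = np.inf
    for a in res.atoms:
        if a is acceptor or a.is_hydrogen:
            continue
        d = float(np.linalg.norm(a.coord - acceptor.coord))
        if d < best_d:
            best, best_d = a, d
    if best is None or best_d > 2.0:
        return None
    return best


def _angle(p0: np.ndarray, apex: np.ndarray, p1: np.ndarray) -> float:
    v0 = p0 - apex
    v1 = p1 - apex
    c = np.dot(v0, v1) / (np.linalg.norm(v0) * np.linalg.norm(v1))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _hydrogens_on(res: Residue, donor: Atom) -> list[Atom]:
    return [
        a
        for a in res.atoms
        if a.is_hydrogen and np.linalg.norm(a.coord - donor.coord) < 1.3
    ]


def _is_terminal_phosphate_oxygen(res: Residue, atom: Atom) -> bool:
    return res.name == "PTR" and atom.name in PTR_TERMINAL_PHOSPHATE_OXYGENS


def detect_hbonds(
    structure: ComplexStructure,
    d_cutoff: float = HBOND_DIST_CUTOFF,
    angle_min: float = HBOND_ANTECEDENT_ANGLE_MIN,
    dha_min: float = HBOND_DHA_ANGLE_MIN,
) -> list[HBond]:
    """Geometric hydrogen bonds between residues (heavy-atom criterion).

    A donor heavy atom D and acceptor A on different residues form a bond
    when ||D - A|| <= ``d_cutoff`` and the antecedent-A-D angle is at
    least ``angle_min``; when D carries explicit hydrogens, at least one
    D-H...A angle must also reach ``dha_min``.  Each D-A pair is counted
    once.
    """
    donors: list[tuple[Residue, Atom]] = []
    acceptors: list[tuple[Residue, Atom]] = []
    for r in structure.residues:
        donors.extend((r, a) for a in _donor_atoms(r))
        acceptors.extend((r, a) for a in _acceptor_atoms(r))
    if not donors or not acceptors:
        return []
    acc_coords = np.array([a.coord for _, a in acceptors])
    tree = cKDTree(acc_coords)
    bonds: list[HBond] = []
    seen: set[tuple[int, int]] = set()
    for di, (dres, datom) in enumerate(donors):
        for ai in tree.query_ball_point(datom.coord, d_cutoff):
            ares, aatom = acceptors[ai]
            if ares.key == dres.key:
                continue
            if (di, ai) in seen:
                continue
            seen.add((di, ai))
            if datom is aatom:
                continue
            dist = float(np.linalg.norm(datom.coord - aatom.coord))
            ante = _antecedent(ares, aatom)
            if ante is not None:
                if _angle(ante.coord, aatom.coord, datom.coord) < angle_min:
                    continue
            else:
                logger.warning(
                    "acceptor %s in %s has no antecedent; angle check skipped",
                    aatom.name,
                    ares.key,
                )
            hyds = _hydrogens_on(dres, datom)
            if hyds and not any(
                _angle(datom.coord, h.coord, aatom.coord) >= dha_min for h in hyds
            ):
                continue
            bonds.append(
                HBond(
                    donor_atom=datom,
                    acceptor_atom=aatom,
                    donor_residue=dres.key,
                    acceptor_residue=ares.key,
                    distance=dist,
                    is_sidechain_sidechain=datom.is_sidechain and aatom.is_sidechain,
                    acceptor_is_phosphate_oxygen=_is_terminal_phosphate_oxygen(
                        ares, aatom
                    ),
                )
            )
    return bonds


def count_phosphate_hbonds(bonds: list[HBond], structure: ComplexStructure) -> int:
    """Bonds from a binder-chain donor to a terminal phosphate oxygen of a
    target-chain PTR."""
    ptrs = find_ptr_residues(structure, role=TARGET)
    if not ptrs:
        raise StructureError("no phosphotyrosine in target")
    ptr_keys = {r.key for r in ptrs}
    n = 0
    for b in bonds:
        if not b.acceptor_is_phosphate_oxygen:
            continue
        if b.acceptor_residue not in ptr_keys:
            continue
        if structure.role(b.donor_residue[0]) == BINDER:
            n += 1
    return n


def count_peptide_hbonds(
    bonds: list[HBond], structure: ComplexStructure
) -> tuple[int, int]:
    """(total binder<->target bonds, side-chain/side-chain subset)."""
    total = 0
    sc = 0
    for b in bonds:
        roles = {
            structure.role(b.donor_residue[0]),
            structure.role(b.acceptor_residue[0]),
        }
        if roles == {BINDER, TARGET}:
            total += 1
            if b.is_sidechain_sidechain:
                sc += 1
    return total, sc


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1) such that ``rotation @ x + translation`` maps mobile
    points onto the reference frame.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point lists must be matching (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    m = mobile - mc
    r = reference - rc
    h = m.T @ r
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12:
        raise ValueError("degenerate (rank-deficient) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    moved = (rot @ mobile.T).T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def _matched_binder_ca(
    designed: ComplexStructure, predicted: ComplexStructure
) -> tuple[np.ndarray, np.ndarray]:
    des_pts, pred_pts = [], []
    for chain_id in designed.chain_ids:
        if designed.role(chain_id) != BINDER:
            continue
        d_chain = designed.chain_residues(chain_id)
        p_chain = predicted.chain_residues(chain_id)
        if len(d_chain) != len(p_chain):
            logger.warning(
                "binder chain %s length mismatch (%d vs %d); using common prefix",
                chain_id,
                len(d_chain),
                len(p_chain),
            )
        for dr, pr in zip(d_chain, p_chain):
            da, pa = dr.atom("CA"), pr.atom("CA")
            if da is not None and pa is not None:
                des_pts.append(da.coord)
                pred_pts.append(pa.coord)
    return np.array(des_pts), np.array(pred_pts)


def ptyr_rmsd(
    designed: ComplexStructure,
    predicted: ComplexStructure,
    atoms: str = "all",
) -> float:
    """Phosphotyrosine RMSD after superposing predicted onto designed.

    The superposition uses matched binder Calpha pairs (chain id +
    sequential position); the RMSD is then taken over the PTR residue's
    shared heavy atoms without further fitting.  ``atoms='phosphate'``
    restricts to the phosphate group (P, O1P, O2P, O3P, OH).
    """
    d_ptrs = find_ptr_residues(designed)
    p_ptrs = find_ptr_residues(predicted)
    if not d_ptrs or not p_ptrs:
        raise StructureError("both structures must contain a PTR residue")
    des_ca, pred_ca = _matched_binder_ca(designed, predicted)
    if len(des_ca) < 3:
        raise StructureError(
            f"need >= 3 matched binder Calpha pairs, got {len(des_ca)}"
        )
    rot, trans, _ = kabsch_superpose(pred_ca, des_ca)

    d_ptr, p_ptr = d_ptrs[0], p_ptrs[0]
    if len(d_ptrs) > 1 or len(p_ptrs) > 1:
        logger.warning("multiple PTR residues; using the first in each structure")
    allowed = None
    if atoms == "phosphate":
        allowed = set(PTR_TERMINAL_PHOSPHATE_OXYGENS) | {"P", "OH"}
    elif atoms != "all":
        raise ValueError(f"unknown atom selection {atoms!r}")
    shared = []
    for a in d_ptr.atoms:
        if a.is_hydrogen:
            continue
        if allowed is not None and a.name not in allowed:
            continue
        b = p_ptr.atom(a.name)
        if b is not None:
            shared.append((a, b))
    if not shared:
        raise StructureError("no shared PTR heavy atoms")
    missing = [
        a.name
        for a in d_ptr.atoms
        if not a.is_hydrogen
        and (allowed is None or a.name in allowed)
        and p_ptr.atom(a.name) is None
    ]
    if missing:
        logger.warning("PTR atoms missing from prediction: %s", missing)
    logger.info("pTyr RMSD over atoms: %s", [a.name for a, _ in shared])
    d_xyz = np.array([a.coord for a, _ in shared])
    p_xyz = np.array([(rot @ b.coord + trans) for _, b in shared])
    return float(np.sqrt(np.mean(np.sum((d_xyz - p_xyz) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# gates
# ---------------------------------------------------------------------------

def apply_filters(
    n_phosphate_hbonds: int,
    n_peptide_hbonds_total: int,
    n_sidechain_sidechain_hbonds: int = 0,
    ptyr_rmsd_value: float | None = None,
    binder_length: int | None = None,
    confidence: dict[str, float] | None = None,
    thresholds: FilterThresholds | None = None,
) -> FilterReport:
    """Apply the design accept/reject gates; degenerate input fails with
    reasons, never an exception.

    Gates: phosphate H-bonds >= 2; total peptide H-bonds <= 12; pTyr
    RMSD < 5 A; binder length < 160; plus any supplied confidence gate.
    A confidence gate whose metric is missing is skipped with a warning.
    """
    thresholds = thresholds or FilterThresholds()
    confidence = confidence or {}
    reasons: list[str] = []
    if n_phosphate_hbonds < thresholds.min_phosphate_hbonds:
        reasons.append("insufficient_phosphate_hbonds")
    if n_peptide_hbonds_total > thresholds.max_peptide_hbonds:
        reasons.append("excess_peptide_hbonds")
    if ptyr_rmsd_value is not None and ptyr_rmsd_value >= thresholds.max_ptyr_rmsd:
        reasons.append("ptyr_rmsd")
    if binder_length is not None and binder_length >= thresholds.max_design_binder_len:
        reasons.append("binder_too_long")

    gates = (
        ("plddt", thresholds.min_plddt, "low_plddt", lambda v, t: v < t),
        ("ipae", thresholds.max_ipae, "high_ipae", lambda v, t: v > t),
        ("iptm", thresholds.min_iptm, "low_iptm", lambda v, t: v < t),
        ("ptm", thresholds.min_ptm, "low_ptm", lambda v, t: v < t),
    )
    for key, thr, reason, bad in gates:
        if thr is None:
            continue
        if key not in confidence:
            logger.warning("confidence metric %r missing; gate skipped", key)
            continue
        if bad(confidence[key], thr):
            reasons.append(reason)
    return FilterReport(
        n_phosphate_hbonds=n_phosphate_hbonds,
        n_peptide_hbonds_total=n_peptide_hbonds_total,
        n_sidechain_sidechain_hbonds=n_sidechain_sidechain_hbonds,
        ptyr_rmsd=ptyr_rmsd_value,
        binder_length=binder_length,
        confidence=dict(confidence),
        verdict="fail" if reasons else "pass",
        fail_reasons=reasons,
    )
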