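"""Side-chain-neighbor packing, folding-quality gates, trimming, cropping.

The side-chain-neighbor count (SCN) measures packing density around a
residue by counting Calpha neighbors inside a soft cone pointing along
the residue's (virtual) Cbeta direction:

    SCN_i = sum_j w_dist(d_ij) * w_ang(theta_ij)

with d_ij the Calpha-Calpha distance, w_dist = 1 / (1 + exp(d_ij - 9)),
cos(theta_ij) the projection of the displacement onto the Calpha->Cbeta
unit vector, and w_ang = ((cos theta + 0.5) / 1.5)^2 for cos theta >
-0.5, else 0.  A residue with SCN > 4.0 counts as well packed ("folded"
at the looser SCN > 1.0 threshold used for terminal trimming).

Curation gates reject a training example when binder_FBSCN < 0.12,
interface_FBSCN < 0.13, the hotspot mask is empty, or the binder exceeds
170 residues.  Disordered binder tails are trimmed with a 9-residue
sliding window tolerating <=0/1/2 folded residues for window lengths
<=4/<=8/>8, and the target is radially cropped to 25 A around a randomly
chosen hotspot (the binder is always fully retained; targets are never
trimmed or packing-scored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from micurate.structure import (
    BINDER,
    ComplexStructure,
    Residue,
    StructureError,
    virtual_cbeta,
)

logger = logging.getLogger(__name__)

SCN_FOLDED_CUT = 4.0
SCN_TRIM_THRESHOLD = 1.0
BINDER_FBSCN_MIN = 0.12
INTERFACE_FBSCN_MIN = 0.13
MAX_BINDER_LEN = 170
TRIM_WINDOW = 9
CROP_RADIUS = 25.0


@dataclass
class PackingReport:
    """FBSCN folding-quality metrics and the curation verdict."""

    scn: dict[tuple[str, int], float | None]
    binder_fbscn: float
    interface_fbscn: float
    n_binder: int
    n_interface: int
    n_hotspots: int
    verdict: str
    reject_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = "reject" if self.reject_reasons else "accept"
        if self.verdict != expected:
            raise ValueError("verdict inconsistent with reject_reasons")

    def to_dict(self) -> dict:
        return {
            "binder_fbscn": self.binder_fbscn,
            "interface_fbscn": self.interface_fbscn,
            "n_binder": self.n_binder,
            "n_interface": self.n_interface,
            "n_hotspots": self.n_hotspots,
            "verdict": self.verdict,
            "reject_reasons": list(self.reject_reasons),
            "scn": {f"{c}:{i}": v for (c, i), v in self.scn.items()},
        }


@dataclass
class CropResult:
    """Outcome of terminal trimming or radial cropping."""

    retained: list[tuple[str, int]]
    trimmed_n_terminal: int = 0
    trimmed_c_terminal: int = 0
    crop_center: tuple[str, int] | None = None
    log: list[str] = field(default_factory=list)


def scn_per_residue(structure: ComplexStructure) -> dict[tuple[str, int], float | None]:
    """Cone-weighted Calpha neighbor count per residue.

    Residues missing backbone atoms are skipped with a warning and
    reported as ``None``.
    """
    cas: list[np.ndarray] = []
    dirs: list[np.ndarray] = []
    has_ca: list[bool] = []
    ok: list[bool] = []
    for r in structure.residues:
        ca_atom = r.atom("CA")
        has_ca.append(ca_atom is not None)
        cas.append(ca_atom.coord if ca_atom is not None else np.zeros(3))
        if not r.has_backbone():
            logger.warning(
                "residue %s%d: missing backbone, SCN skipped", r.chain_id, r.seq_index
            )
            dirs.append(np.zeros(3))
            ok.append(False)
            continue
        cb = virtual_cbeta(r)
        u = cb - cas[-1]
        norm = np.linalg.norm(u)
        dirs.append(u / norm if norm > 0 else np.zeros(3))
        ok.append(True)
    ca_arr = np.asarray(cas)
    has_ca_arr = np.array(has_ca)
    out: dict[tuple[str, int], float | None] = {}
    for i, r in enumerate(structure.residues):
        if not ok[i]:
            out[r.key] = None
            continue
        diff = ca_arr - ca_arr[i]
        d = np.linalg.norm(diff, axis=1)
        # any residue with a Calpha contributes as a neighbor
        valid = has_ca_arr & (d > 1e-9)
        valid[i] = False
        dd = d[valid]
        w_dist = 1.0 / (1.0 + np.exp(dd - 9.0))
        cos_t = diff[valid] @ dirs[i] / dd
        w_ang = np.where(cos_t > -0.5, ((cos_t + 0.5) / 1.5) ** 2, 0.0)
        out[r.key] = float(np.sum(w_dist * w_ang))
    return out


def interface_residues(
    structure: ComplexStructure, cb_cutoff: float = 7.0
) -> np.ndarray:
    """Binder residues whose (virtual) Cbeta is within ``cb_cutoff`` of a
    target Cbeta, ordered as ``structure.binder_residues()``."""
    structure.require_interface()
    binders = structure.binder_residues()
    targets = structure.target_residues()
    if not targets:
        raise StructureError("no target chain")
    t_cb = np.array([virtual_cbeta(r) for r in targets])
    tree = cKDTree(t_cb)
    mask = np.zeros(len(binders), dtype=bool)
    for i, r in enumerate(binders):
        d, _ = tree.query(virtual_cbeta(r))
        mask[i] = d <= cb_cutoff
    return mask


def curation_verdict(
    structure: ComplexStructure,
    scn: dict[tuple[str, int], float | None],
    hotspots: np.ndarray,
    max_binder_len: int = MAX_BINDER_LEN,
    fbscn_min: float = BINDER_FBSCN_MIN,
    iface_fbscn_min: float = INTERFACE_FBSCN_MIN,
    scn_folded_cut: float = SCN_FOLDED_CUT,
) -> PackingReport:
    """Apply the four curation gates and report FBSCN fractions.

    Degenerate inputs yield reject verdicts, never exceptions; an
    interface_FBSCN with zero interface residues is defined as 0.
    """
    binders = structure.binder_residues()
    n_binder = len(binders)
    packed = [
        r for r in binders if (scn.get(r.key) or 0.0) > scn_folded_cut
    ]
    binder_fbscn = len(packed) / n_binder if n_binder else 0.0

    iface_mask = interface_residues(structure)
    iface = [r for r, m in zip(binders, iface_mask) if m]
    iface_packed = [r for r in iface if (scn.get(r.key) or 0.0) > scn_folded_cut]
    interface_fbscn = len(iface_packed) / len(iface) if iface else 0.0

    hotspots = np.asarray(hotspots, dtype=bool)
    reasons: list[str] = []
    if binder_fbscn < fbscn_min:
        reasons.append("low_binder_fbscn")
    if interface_fbscn < iface_fbscn_min:
        reasons.append("low_interface_fbscn")
    if not hotspots.any():
        reasons.append("no_hotspots")
    if n_binder > max_binder_len:
        reasons.append("binder_too_long")
    return PackingReport(
        scn=dict(scn),
        binder_fbscn=binder_fbscn,
        interface_fbscn=interface_fbscn,
        n_binder=n_binder,
        n_interface=len(iface),
        n_hotspots=int(hotspots.sum()),
        verdict="reject" if reasons else "accept",
        reject_reasons=reasons,
    )


def _window_tolerance(w: int) -> int:
    if w <= 4:
        return 0
    if w <= 8:
        return 1
    return 2


def _trim_one_terminus(
    keys: list[tuple[str, int]],
    folded: dict[tuple[str, int], bool],
    window: int,
    from_start: bool,
    bound_key: tuple[str, int] | None,
    log: list[str],
) -> int:
    """Trim one terminus in place; returns the number removed."""
    removed = 0
    overshoot = 0
    while len(keys) > 1:
        w = min(window, len(keys))
        seg = keys[:w] if from_start else keys[-w:]
        tol = _window_tolerance(w)
        n_folded = sum(1 for k in seg if folded.get(k, False))
        if n_folded > tol:
            break
        victim = keys[0] if from_start else keys[-1]
        if bound_key is not None and _is_past_bound(victim, bound_key, from_start):
            # "extend slightly" into the hotspot region: one window at most
            if overshoot >= window:
                log.append(
                    f"trim stopped at hotspot bound {bound_key} (+{overshoot})"
                )
                break
            overshoot += 1
        if from_start:
            keys.pop(0)
        else:
            keys.pop()
        removed += 1
        log.append(
            f"trimmed {'N' if from_start else 'C'}-terminal residue {victim} "
            f"(window {w}, folded {n_folded} <= tol {tol})"
        )
    return removed


def _is_past_bound(
    key: tuple[str, int], bound: tuple[str, int], from_start: bool
) -> bool:
    if key[0] != bound[0]:
        return False
    return key[1] >= bound[1] if from_start else key[1] <= bound[1]


def trim_termini(
    structure: ComplexStructure,
    scn: dict[tuple[str, int], float | None],
    sc_neigh_threshold: float = SCN_TRIM_THRESHOLD,
    window: int = TRIM_WINDOW,
    hotspot_bounds: tuple[tuple[str, int], tuple[str, int]] | None = None,
) -> CropResult:
    """Trim disordered binder tails with a sliding-window tolerance rule.

    A residue is folded iff SCN > ``sc_neigh_threshold``.  From each
    terminus independently: examine the terminal window of
    ``w = min(window, remaining)`` residues; with tolerance 0/1/2 for
    ``w`` <= 4 / <= 8 / > 8, remove the terminal residue while the
    window's folded count is within tolerance, one residue per step.
    When ``hotspot_bounds`` (first, last binder-residue keys of the
    interface region) are given, trimming may extend at most one window
    length past a bound.  Target residues are never trimmed.
    """
    binders = structure.binder_residues()
    if not binders:
        raise StructureError("no binder chain to trim")
    folded = {
        r.key: (scn.get(r.key) or 0.0) > sc_neigh_threshold for r in binders
    }
    log: list[str] = []
    retained: list[tuple[str, int]] = []
    total_n = total_c = 0
    for chain_id in structure.chain_ids:
        if structure.role(chain_id) != BINDER:
            continue
        keys = [r.key for r in structure.chain_residues(chain_id)]
        lo = hotspot_bounds[0] if hotspot_bounds else None
        hi = hotspot_bounds[1] if hotspot_bounds else None
        total_n += _trim_one_terminus(keys, folded, window, True, lo, log)
        total_c += _trim_one_terminus(keys, folded, window, False, hi, log)
        if len(keys) <= 1 and not any(folded.get(k, False) for k in keys):
            log.append(f"chain {chain_id}: trimming stopped at minimum length 1")
        retained.extend(keys)
    # targets pass through untouched
    retained.extend(r.key for r in structure.target_residues())
    return CropResult(
        retained=retained,
        trimmed_n_terminal=total_n,
        trimmed_c_terminal=total_c,
        log=log,
    )


def radial_crop(
    structure: ComplexStructure,
    hotspots: np.ndarray,
    center: str | tuple[str, int] = "random_hotspot",
    radius: float = CROP_RADIUS,
    seed: int = 0,
) -> CropResult:
    """Crop the target to residues near one hotspot; keep the whole binder.

    The center is drawn uniformly from the hotspot residues under the
    seed (or given explicitly as a residue key).  A target residue is
    retained iff any of its heavy atoms lies within ``radius`` of the
    center residue's (virtual) Cbeta.  Binder residues are always
    retained.
    """
    targets = structure.target_residues()
    hotspots = np.asarray(hotspots, dtype=bool)
    idx = np.flatnonzero(hotspots)
    if isinstance(center, str):
        if center != "random_hotspot":
            raise ValueError(f"unknown center mode {center!r}")
        if len(idx) == 0:
            raise StructureError("radial_crop: no hotspots to center on")
        rng = np.random.default_rng(seed)
        center_res = targets[int(rng.choice(idx))]
    else:
        center_res = structure.residue_by_key(tuple(center))
    c = virtual_cbeta(center_res)
    retained = [r.key for r in structure.binder_residues()]
    log = [f"crop center {center_res.key}, radius {radius} A"]
    n_dropped = 0
    for r in targets:
        d = np.linalg.norm(r.heavy_coords() - c, axis=1).min()
        if d <= radius:
            retained.append(r.key)
        else:
            n_dropped += 1
    log.append(f"dropped {n_dropped} target residues beyond {radius} A")
    return CropResult(retained=retained, crop_center=center_res.key, log=log)
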