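"""Solvent-accessible surface area (SASA) and relative accessibility (RASA).

SASA is computed with the Shrake-Rupley point-sampling algorithm on a
deterministic golden-spiral sphere point set, so results are bit-for-bit
reproducible at a fixed sampling density.  Two probe radii matter in this
package: the hotspot gate uses a 2.8 A probe in complex context, while the
RASA conditioning channel uses the conventional 1.4 A water probe
normalized by a fixed per-amino-acid theoretical maximum ASA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from micurate.structure import ComplexStructure, StructureError

logger = logging.getLogger(__name__)

#: Theoretical maximum ASA (A^2) per amino acid, Tien-style normalization.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0,
    # phosphotyrosine normalizes against the tyrosine reference
    "PTR": 263.0,
}

HOTSPOT_GATE_PROBE = 2.8
WATER_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass
class SasaResult:
    """Per-residue SASA (A^2) at a given probe radius."""

    per_residue_sasa: dict[tuple[str, int], float]
    probe_radius: float
    n_points: int
    context: str = "complex"

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        for key, v in self.per_residue_sasa.items():
            if v < -1e-9:
                raise ValueError(f"negative SASA for residue {key}")

    def __getitem__(self, key: tuple[str, int]) -> float:
        return self.per_residue_sasa[key]


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform points on the unit sphere (deterministic)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float,
    n_points: int,
) -> np.ndarray:
    """Shrake-Rupley accessible area per atom against the given occluders."""
    n_atoms = len(coords)
    sphere = golden_spiral_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_r = expanded.max() if n_atoms else 0.0
    out = np.zeros(n_atoms)
    for i in range(n_atoms):
        ri = expanded[i]
        pts = coords[i] + ri * sphere
        # neighbors whose expanded sphere could cover a test point
        neighbor_idx = tree.query_ball_point(coords[i], ri + max_r)
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_idx:
            if j == i:
                continue
            rj = expanded[j]
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > rj * rj
            if not accessible.any():
                break
        out[i] = 4.0 * np.pi * ri * ri * accessible.mean()
    return out


def sasa_per_residue(
    structure: ComplexStructure,
    probe_radius: float = HOTSPOT_GATE_PROBE,
    context: str = "complex",
    n_points: int = DEFAULT_N_POINTS,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Per-residue SASA by summing Shrake-Rupley atom areas.

    ``context='complex'`` uses every atom of the complex as occluder;
    ``context='chain_alone'`` occludes each residue only with atoms of
    its own chain (each chain is evaluated in isolation).
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    if context not in ("complex", "chain_alone"):
        raise ValueError(f"unknown context {context!r}")
    if structure.n_atoms == 0:
        raise StructureError("structure has no atoms")

    per_residue: dict[tuple[str, int], float] = {
        r.key: 0.0 for r in structure.residues
    }
    if context == "complex":
        chain_groups = [structure.residues]
    else:
        chain_groups = [
            structure.chain_residues(c) for c in structure.chain_ids
        ]
    for group in chain_groups:
        coords, radii, owner = [], [], []
        for r in group:
            for a in r.atoms:
                if a.is_hydrogen and not include_hydrogens:
                    continue
                coords.append(a.coord)
                radii.append(a.vdw_radius)
                owner.append(r.key)
        if not coords:
            continue
        areas = _atom_sasa(
            np.asarray(coords), np.asarray(radii), probe_radius, n_points
        )
        for key, area in zip(owner, areas):
            per_residue[key] += float(area)
    return SasaResult(per_residue, probe_radius, n_points, context)


def rasa_per_residue(
    structure: ComplexStructure,
    n_points: int = DEFAULT_N_POINTS,
    context: str = "complex",
) -> dict[tuple[str, int], float | None]:
    """Relative solvent accessibility in [0, 1] per residue.

    RASA = SASA(probe 1.4 A) / max-ASA for the residue type, clipped to
    [0, 1].  PTR normalizes against tyrosine.  Residue types without a
    max-ASA entry are reported as ``None`` (missing), never as zero.
    """
    sasa = sasa_per_residue(
        structure, probe_radius=WATER_PROBE, context=context, n_points=n_points
    )
    out: dict[tuple[str, int], float | None] = {}
    for r in structure.residues:
        ref = MAX_ASA.get(r.name)
        if ref is None:
            logger.warning(
                "residue %s%d %s: no max-ASA reference, RASA missing",
                r.chain_id,
                r.seq_index,
                r.name,
            )
            out[r.key] = None
        else:
            out[r.key] = float(min(1.0, max(0.0, sasa[r.key] / ref)))
    return out
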