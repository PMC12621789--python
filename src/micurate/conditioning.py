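"""Per-token 1D conditioning features and residue-to-atom broadcasting.

Each residue token carries a fixed 29-channel feature row: a 21-slot
amino-acid one-hot (20 standard types plus an unknown slot that also
absorbs PTR, whose identity is kept in metadata), a 3-slot secondary
structure one-hot (helix/strand/coil; all-zero allowed when the channel
is masked out), a motif flag, hotspot and anti-hotspot masks, the
continuous super-hotspot value, and relative solvent accessibility.
Features are residue-level and geometry-free; broadcasting copies each
residue row to all of its atom slots.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from micurate.interface import InterfaceAnnotation
from micurate.structure import ComplexStructure, Residue

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

CHANNEL_NAMES: tuple[str, ...] = (
    tuple(f"aa_{c}" for c in AA_ORDER)
    + ("aa_UNK", "ss_H", "ss_E", "ss_C", "motif_flag",
       "hotspot_mask", "antihotspot_mask", "hotspot_value", "rasa")
)
N_CHANNELS = len(CHANNEL_NAMES)  # 21 + 3 + 1 + 1 + 1 + 1 + 1 = 29

CHANNEL_FORMAT_VERSION = "1"

# dihedral windows (degrees) used by the self-contained SS assigner
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_STRAND_PHI = (-180.0, -80.0)
_STRAND_PSI_A = (80.0, 180.0)
_STRAND_PSI_B = (-180.0, -170.0)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def _phi_psi(chain: list[Residue]) -> list[tuple[float | None, float | None]]:
    out: list[tuple[float | None, float | None]] = []
    for i, r in enumerate(chain):
        phi = psi = None
        if r.has_backbone():
            n, ca, c = (r.atom(x).coord for x in ("N", "CA", "C"))
            if i > 0 and chain[i - 1].atom("C") is not None:
                phi = dihedral(chain[i - 1].atom("C").coord, n, ca, c)
            if i + 1 < len(chain) and chain[i + 1].atom("N") is not None:
                psi = dihedral(n, ca, c, chain[i + 1].atom("N").coord)
        out.append((phi, psi))
    return out


def _in(v: float | None, lo: float, hi: float) -> bool:
    return v is not None and lo <= v <= hi


def _helix_like(pp: tuple[float | None, float | None]) -> bool:
    return _in(pp[0], *_HELIX_PHI) and _in(pp[1], *_HELIX_PSI)


def _strand_like(pp: tuple[float | None, float | None]) -> bool:
    return _in(pp[0], *_STRAND_PHI) and (
        _in(pp[1], *_STRAND_PSI_A) or _in(pp[1], *_STRAND_PSI_B)
    )


def assign_secondary_structure(
    structure: ComplexStructure,
) -> dict[tuple[str, int], str]:
    """Helix/strand/coil tokens from backbone dihedral windows.

    A residue is H when its own (phi, psi) and both neighbors' fall in
    the helical window; E when its own and at least one neighbor's fall
    in the strand window; otherwise C.  Chain termini (undefined phi or
    psi) default to C.
    """
    out: dict[tuple[str, int], str] = {}
    for chain_id in structure.chain_ids:
        chain = structure.chain_residues(chain_id)
        pp = _phi_psi(chain)
        for i, r in enumerate(chain):
            tok = "C"
            if 0 < i < len(chain) - 1:
                if _helix_like(pp[i]) and _helix_like(pp[i - 1]) and _helix_like(pp[i + 1]):
                    tok = "H"
                elif _strand_like(pp[i]) and (
                    _strand_like(pp[i - 1]) or _strand_like(pp[i + 1])
                ):
                    tok = "E"
            out[r.key] = tok
    return out


@dataclass
class ConditioningTensor:
    """Token-by-channel feature matrix with named channel blocks."""

    tokens: list[tuple[str, int]]
    values: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    channel_mask: dict[str, bool] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.tokens), len(self.channel_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.tokens)} tokens x {len(self.channel_names)} channels"
            )
        self._validate()

    def _validate(self) -> None:
        v = self.values
        aa = v[:, :21]
        if not np.allclose(aa.sum(axis=1), 1.0):
            raise ValueError("aa_onehot rows must sum to exactly 1")
        ss = v[:, 21:24]
        sums = ss.sum(axis=1)
        if not np.all((np.isclose(sums, 0.0)) | (np.isclose(sums, 1.0))):
            raise ValueError("ss_token rows must sum to 0 or 1")
        col = {n: i for i, n in enumerate(self.channel_names)}
        hv = v[:, col["hotspot_value"]]
        if np.any((hv < 0) | (hv > 1)):
            raise ValueError("hotspot_value must lie in [0, 1]")
        rasa = v[:, col["rasa"]]
        finite = np.isfinite(rasa)
        if np.any((rasa[finite] < 0) | (rasa[finite] > 1)):
            raise ValueError("rasa must lie in [0, 1] or be missing (NaN)")
        both = (v[:, col["hotspot_mask"]] > 0) & (v[:, col["antihotspot_mask"]] > 0)
        if both.any():
            raise ValueError("hotspot_mask and antihotspot_mask are exclusive")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_names.index(name)]

    # -- text round-trip ----------------------------------------------------
    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write one token per row with named columns (6 significant digits),
        plus a JSON sidecar carrying channel order, mask, and metadata."""
        path = Path(path)
        lines = ["\t".join(("chain", "seq_index") + self.channel_names)]
        for (chain, idx), row in zip(self.tokens, self.values):
            lines.append(
                "\t".join([chain, str(idx)] + [format(x, ".6g") for x in row])
            )
        path.write_text("\n".join(lines) + "\n")
        if sidecar is None:
            sidecar = path.with_suffix(path.suffix + ".json")
        meta = {
            "format_version": CHANNEL_FORMAT_VERSION,
            "channel_names": list(self.channel_names),
            "channel_mask": self.channel_mask,
            "tokens": [[c, i] for c, i in self.tokens],
            "metadata": _jsonable(self.metadata),
        }
        Path(sidecar).write_text(json.dumps(meta, indent=1) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, sidecar: str | Path | None = None) -> "ConditioningTensor":
        path = Path(path)
        lines = path.read_text().splitlines()
        header = lines[0].split("\t")
        channel_names = tuple(header[2:])
        tokens: list[tuple[str, int]] = []
        rows: list[list[float]] = []
        for ln in lines[1:]:
            parts = ln.split("\t")
            tokens.append((parts[0], int(parts[1])))
            rows.append([float(x) for x in parts[2:]])
        mask: dict[str, bool] = {}
        metadata: dict = {}
        if sidecar is None:
            cand = path.with_suffix(path.suffix + ".json")
            sidecar = cand if cand.exists() else None
        if sidecar is not None:
            meta = json.loads(Path(sidecar).read_text())
            mask = meta.get("channel_mask", {})
            metadata = meta.get("metadata", {})
        return cls(tokens, np.array(rows), channel_names, mask, metadata)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def build_conditioning_tensor(
    structure: ComplexStructure,
    annotation: InterfaceAnnotation | None = None,
    rasa: dict[tuple[str, int], float | None] | None = None,
    ss: dict[tuple[str, int], str] | None = None,
    motif_residues: set[tuple[str, int]] | None = None,
    channel_mask: dict[str, bool] | None = None,
) -> ConditioningTensor:
    """One feature row per residue, in structure order.

    Unknown amino acids (including PTR) use the unknown one-hot slot and
    are recorded in metadata.  Channels switched off in ``channel_mask``
    are zero-filled and the mask recorded in the sidecar.  Inputs indexed
    over residues the structure lacks raise an error naming the first
    mismatch.
    """
    tokens = [r.key for r in structure.residues]
    token_set = set(tokens)
    for name, mapping in (("annotation", annotation), ("rasa", rasa), ("ss", ss)):
        if mapping is None:
            continue
        keys = (
            mapping.target_keys
            if isinstance(mapping, InterfaceAnnotation)
            else mapping.keys()
        )
        for k in keys:
            if tuple(k) not in token_set:
                raise ValueError(f"{name} input indexes unknown residue {k}")

    motif_residues = motif_residues or set()
    mask = {name: True for name in ("ss_token", "motif_flag", "hotspot_mask",
                                    "antihotspot_mask", "hotspot_value", "rasa")}
    if channel_mask:
        mask.update(channel_mask)

    hot, anti, hv = ({}, {}, {})
    if annotation is not None:
        hot, anti, hv = annotation.as_dicts()

    col = {n: i for i, n in enumerate(CHANNEL_NAMES)}
    values = np.zeros((len(tokens), N_CHANNELS))
    unknown_residues: list[list] = []
    for row, r in enumerate(structure.residues):
        one = THREE_TO_ONE.get(r.name)
        if one is None:
            values[row, col["aa_UNK"]] = 1.0
            unknown_residues.append([r.chain_id, r.seq_index, r.name])
        else:
            values[row, col[f"aa_{one}"]] = 1.0
        if mask.get("ss_token", True) and ss is not None:
            tok = ss.get(r.key)
            if tok in ("H", "E", "C"):
                values[row, col[f"ss_{tok}"]] = 1.0
        if mask.get("motif_flag", True) and r.key in motif_residues:
            values[row, col["motif_flag"]] = 1.0
        if mask.get("hotspot_mask", True) and hot.get(r.key):
            values[row, col["hotspot_mask"]] = 1.0
        if mask.get("antihotspot_mask", True) and anti.get(r.key):
            values[row, col["antihotspot_mask"]] = 1.0
        if mask.get("hotspot_value", True):
            values[row, col["hotspot_value"]] = hv.get(r.key, 0.0)
        if mask.get("rasa", True) and rasa is not None:
            v = rasa.get(r.key)
            values[row, col["rasa"]] = np.nan if v is None else v
    metadata = {"unknown_residues": unknown_residues}
    if annotation is not None and annotation.ori is not None:
        metadata["ori"] = annotation.ori.tolist()
    return ConditioningTensor(tokens, values, CHANNEL_NAMES, mask, metadata)


def broadcast_to_atoms(
    tensor: ConditioningTensor, structure: ComplexStructure
) -> np.ndarray:
    """Copy each residue's feature row to all of its atom slots.

    The output has one row per atom (total atom count rows), identical
    within a residue.
    """
    if tensor.tokens != [r.key for r in structure.residues]:
        raise ValueError("tensor tokens do not match structure residues")
    rows = []
    for row, r in zip(tensor.values, structure.residues):
        if not r.atoms:
            raise ValueError(f"residue {r.key} has zero atoms")
        rows.append(np.repeat(row[None, :], len(r.atoms), axis=0))
    return np.vstack(rows)
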