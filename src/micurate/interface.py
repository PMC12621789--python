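"""Interface annotation: hotspots, anti-hotspots, super-hotspot values, ORI.

A target residue is a hotspot when its (virtual) Cbeta lies within 7 A of
any binder Cbeta and it is solvent exposed (SASA >= 30 A^2 at probe
2.8 A).  Anti-hotspots are target residues more than 10 A (heavy-atom
minimum distance) from the binder.  Super-hotspot values grade hotspots
by cross-chain Calpha neighbor density: count binder Calpha within 10 A,
optionally jitter by +/-1, cap at 12, normalize to [0, 1].  Hotspot masks
for training examples are downsampled to a coverage budget by scattered
("speckle") or contiguous-patch ("region") sampling, and the ORI noise
origin is placed at the geometric center of the hotspot mask.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from micurate.sasa import SasaResult
from micurate.structure import ComplexStructure, StructureError, virtual_cbeta

logger = logging.getLogger(__name__)

HOTSPOT_CB_CUTOFF = 7.0
HOTSPOT_SASA_MIN = 30.0
ANTIHOTSPOT_DIST_CUTOFF = 10.0
SUPERHOTSPOT_RADIUS = 10.0
SUPERHOTSPOT_CAP = 12


@dataclass
class InterfaceAnnotation:
    """Per-target-residue interface annotation.

    Arrays are aligned with ``structure.target_residues()`` order;
    ``target_keys`` records the residue identifiers.
    """

    target_keys: list[tuple[str, int]]
    hotspot: np.ndarray
    antihotspot: np.ndarray
    hotspot_value: np.ndarray
    ori: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hotspot = np.asarray(self.hotspot, dtype=bool)
        self.antihotspot = np.asarray(self.antihotspot, dtype=bool)
        self.hotspot_value = np.asarray(self.hotspot_value, dtype=float)
        n = len(self.target_keys)
        if not (len(self.hotspot) == len(self.antihotspot) == len(self.hotspot_value) == n):
            raise ValueError("annotation arrays must align with target_keys")
        if np.any(self.hotspot & self.antihotspot):
            raise ValueError("a residue cannot be both hotspot and anti-hotspot")
        if np.any((self.hotspot_value < 0) | (self.hotspot_value > 1)):
            raise ValueError("hotspot_value must lie in [0, 1]")
        if np.any((self.hotspot_value > 0) & ~self.hotspot):
            raise ValueError("hotspot_value > 0 requires hotspot flag")

    def as_dicts(self) -> tuple[dict, dict, dict]:
        h = dict(zip(self.target_keys, self.hotspot.tolist()))
        a = dict(zip(self.target_keys, self.antihotspot.tolist()))
        v = dict(zip(self.target_keys, self.hotspot_value.tolist()))
        return h, a, v


@dataclass
class MaskSamplingConfig:
    """How hotspot/anti-hotspot masks are sampled into training examples."""

    hotspot_inclusion_prob: float = 0.75
    antihotspot_inclusion_prob: float = 0.10
    max_coverage: float = 0.20
    strategy: str = "speckle"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hotspot_inclusion_prob", "antihotspot_inclusion_prob", "max_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.strategy not in ("speckle", "region"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def _target_cbetas(structure: ComplexStructure) -> tuple[list, np.ndarray]:
    residues = structure.target_residues()
    return residues, np.array([virtual_cbeta(r) for r in residues])


def _binder_cbetas(structure: ComplexStructure) -> np.ndarray:
    return np.array([virtual_cbeta(r) for r in structure.binder_residues()])


def detect_hotspots(
    structure: ComplexStructure,
    sasa: SasaResult,
    cb_cutoff: float = HOTSPOT_CB_CUTOFF,
    sasa_min: float = HOTSPOT_SASA_MIN,
) -> np.ndarray:
    """Boolean hotspot mask over target residues.

    Hotspot iff min Cbeta-Cbeta distance to the binder is <= ``cb_cutoff``
    (virtual Cbeta for glycine) and residue SASA >= ``sasa_min``.
    """
    structure.require_interface()
    targets, t_cb = _target_cbetas(structure)
    b_cb = _binder_cbetas(structure)
    if len(b_cb) == 0:
        raise StructureError("no binder chain")
    tree = cKDTree(b_cb)
    dmin, _ = tree.query(t_cb)
    mask = np.zeros(len(targets), dtype=bool)
    for i, r in enumerate(targets):
        mask[i] = dmin[i] <= cb_cutoff and sasa[r.key] >= sasa_min
    return mask


def detect_antihotspots(
    structure: ComplexStructure,
    dist_cutoff: float = ANTIHOTSPOT_DIST_CUTOFF,
) -> np.ndarray:
    """Target residues whose minimum heavy-atom distance to the binder
    exceeds ``dist_cutoff``."""
    structure.require_interface()
    binder_coords = []
    for r in structure.binder_residues():
        binder_coords.append(r.heavy_coords())
    if not binder_coords:
        raise StructureError("no binder chain")
    b = np.vstack(binder_coords)
    tree = cKDTree(b)
    targets = structure.target_residues()
    mask = np.zeros(len(targets), dtype=bool)
    for i, r in enumerate(targets):
        d, _ = tree.query(r.heavy_coords())
        mask[i] = float(np.min(d)) > dist_cutoff
    return mask


def superhotspot_values(
    structure: ComplexStructure,
    hotspots: np.ndarray,
    radius: float = SUPERHOTSPOT_RADIUS,
    cap: int = SUPERHOTSPOT_CAP,
    jitter: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Continuous [0, 1] hotspot weight from cross-chain Calpha density.

    For each hotspot residue, count binder Calpha atoms within ``radius``
    of its Calpha; with ``jitter`` on, add a uniform integer from
    {-1, 0, +1} drawn from a generator seeded with ``seed``; clamp to
    [0, cap] and divide by ``cap``.  Non-hotspots get 0.
    """
    targets = structure.target_residues()
    hotspots = np.asarray(hotspots, dtype=bool)
    if len(hotspots) != len(targets):
        raise ValueError("hotspot mask does not align with target residues")
    binder_ca = np.array(
        [r.atom("CA").coord for r in structure.binder_residues() if r.atom("CA")]
    )
    rng = np.random.default_rng(seed)
    values = np.zeros(len(targets))
    tree = cKDTree(binder_ca) if len(binder_ca) else None
    for i, r in enumerate(targets):
        if not hotspots[i]:
            continue
        ca = r.atom("CA")
        n = 0
        if ca is not None and tree is not None:
            n = len(tree.query_ball_point(ca.coord, radius))
        if jitter:
            n += int(rng.integers(-1, 2))
        values[i] = min(max(n, 0), cap) / cap
    return values


def downsample_hotspots(
    hotspots: np.ndarray,
    config: MaskSamplingConfig,
    structure: ComplexStructure | None = None,
) -> np.ndarray:
    """Downsample a hotspot mask to at most ``max_coverage`` of the target.

    The budget is ``ceil(max_coverage * n_target_residues)``.  The
    ``speckle`` strategy keeps a uniform random subset; ``region`` keeps
    one seeded hotspot plus its nearest hotspot neighbors in 3D (Cbeta
    distance; requires ``structure``).  Deterministic given the seed; the
    output is always a subset of the input.
    """
    hotspots = np.asarray(hotspots, dtype=bool)
    n_target = len(hotspots)
    idx = np.flatnonzero(hotspots)
    if len(idx) == 0:
        logger.warning("downsample_hotspots: empty input mask")
        return hotspots.copy()
    budget = math.ceil(config.max_coverage * n_target)
    if len(idx) <= budget:
        return hotspots.copy()
    rng = np.random.default_rng(config.seed)
    if config.strategy == "speckle":
        keep = rng.choice(idx, size=budget, replace=False)
    else:
        if structure is None:
            raise ValueError("region strategy requires the structure")
        targets = structure.target_residues()
        cbs = np.array([virtual_cbeta(targets[i]) for i in idx])
        seed_pos = int(rng.integers(len(idx)))
        d = np.linalg.norm(cbs - cbs[seed_pos], axis=1)
        order = np.argsort(d, kind="stable")
        keep = idx[order[:budget]]
        logger.info(
            "region downsample: grew patch from hotspot %s",
            targets[idx[seed_pos]].key,
        )
    out = np.zeros_like(hotspots)
    out[np.sort(keep)] = True
    return out


def compute_ori(
    structure: ComplexStructure,
    hotspots: np.ndarray | None = None,
    mode: str = "hotspot_center",
    point: np.ndarray | None = None,
) -> np.ndarray:
    """ORI noise-cloud origin: hotspot-mask center or a user point.

    ``hotspot_center`` is the arithmetic mean of the hotspot residues'
    (virtual) Cbeta coordinates and requires at least one hotspot.
    """
    if mode == "user_point":
        if point is None:
            raise ValueError("user_point mode requires a coordinate")
        point = np.asarray(point, dtype=float)
        if point.shape != (3,):
            raise ValueError("ORI point must be a 3-vector")
        return point.copy()
    if mode != "hotspot_center":
        raise ValueError(f"unknown ORI mode {mode!r}")
    if hotspots is None:
        raise ValueError("hotspot_center mode requires the hotspot mask")
    hotspots = np.asarray(hotspots, dtype=bool)
    targets = structure.target_residues()
    idx = np.flatnonzero(hotspots)
    if len(idx) == 0:
        raise StructureError("cannot place ORI: no hotspots detected")
    cbs = np.array([virtual_cbeta(targets[i]) for i in idx])
    return cbs.mean(axis=0)


def annotate_interface(
    structure: ComplexStructure,
    sasa: SasaResult,
    jitter: bool = False,
    seed: int = 0,
) -> InterfaceAnnotation:
    """Convenience wrapper computing the full annotation in one call."""
    hot = detect_hotspots(structure, sasa)
    anti = detect_antihotspots(structure)
    values = superhotspot_values(structure, hot, jitter=jitter, seed=seed)
    ori = compute_ori(structure, hot) if hot.any() else None
    return InterfaceAnnotation(
        [r.key for r in structure.target_residues()], hot, anti, values, ori
    )
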